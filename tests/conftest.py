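from dataclasses import replace

import pytest

from renalpbpk.drug import (AbsorptionModel, DrugModel, EliminationModel,
                            PhyschemProfile, TransporterKinetics)
from renalpbpk.population import (PopulationSpec, japanese_population,
                                  sample_subject, subject_rng)
from renalpbpk.workflows import bundled_drug


def no_iiv(spec: PopulationSpec) -> PopulationSpec:
    return replace(spec, weight_cv=0.0, gfr_cv=0.0,
                   iiv_cv={k: 0.0 for k in spec.iiv_cv})


@pytest.fixture(scope="session")
def adefovir() -> DrugModel:
    return bundled_drug("adefovir")


@pytest.fixture(scope="session")
def probenecid() -> DrugModel:
    return bundled_drug("probenecid")


@pytest.fixture(scope="session")
def mean_subject():
    """70-kg healthy male at the population means (no variability)."""
    spec = no_iiv(PopulationSpec(name="mean", weight_mean_kg=70.0))
    return sample_subject(spec, subject_rng(0, 0, 0), sex="M")


@pytest.fixture(scope="session")
def mean_japanese_male():
    spec = no_iiv(japanese_population())
    return sample_subject(spec, subject_rng(0, 0, 0), sex="M")


def make_inert_drug(**overrides) -> DrugModel:
    """A neutral, unbound, lipid-free compound: partitions into tissue water
    only. Handy for closed-form reductions."""
    fields = dict(
        name="inert",
        physchem=PhyschemProfile(
            molecular_weight_g_mol=300.0, compound_class="neutral",
            pka_list=[], logp_ow=-30.0, blood_to_plasma_ratio=1.0,
            fu_plasma=1.0),
        absorption=AbsorptionModel(ka_per_h=1.0, fa=1.0),
        transporters=TransporterKinetics(),
        elimination=EliminationModel(),
        kp_scalar=1.0,
    )
    fields.update(overrides)
    return DrugModel(**fields)
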