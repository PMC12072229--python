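"""Virtual subjects, populations, and trial structures.

A population is a recipe: demographic distributions, a GFR distribution,
log-normal inter-individual variability (IIV) on the drug-level parameters
that drive renal secretion, and — for chronic kidney disease (CKD) stages —
the two physiological modifications that carry the disease effect:

* proximal tubular cell (PTC) number falls in proportion to the decrease in
  mean GFR (intact nephron hypothesis), and
* OAT1 relative abundance falls beyond the GFR decline in the later stages
  (1.0 healthy and mild, 0.84 moderate, 0.50 severe).

Subject sampling is deterministic given ``(seed, trial, subject)``, so trials
can be simulated in any order or in parallel without changing results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .partition import BodyComposition, load_tissue_compositions

if TYPE_CHECKING:  # pragma: no cover
    from .model import DosingRegimen

REFERENCE_BODY_WEIGHT_KG = 70.0
HEALTHY_GFR_ML_MIN = 110.0
HEALTHY_PTC_PER_G_1E6 = 60.0
REFERENCE_KIDNEY_MASS_G = 300.0


class CKDStage(str, Enum):
    HEALTHY = "healthy"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


#: stage mean GFR (mL/min); bin midpoints / physiological means
STAGE_GFR_ML_MIN = {
    CKDStage.HEALTHY: HEALTHY_GFR_ML_MIN,
    CKDStage.MILD: 65.0,
    CKDStage.MODERATE: 40.0,
    CKDStage.SEVERE: 25.0,
}

#: OAT1 relative abundance per stage (additional decline beyond GFR)
STAGE_OAT1_ABUNDANCE = {
    CKDStage.HEALTHY: 1.0,
    CKDStage.MILD: 1.0,
    CKDStage.MODERATE: 0.84,
    CKDStage.SEVERE: 0.50,
}


def stage_from_crcl(crcl_ml_min: float) -> CKDStage:
    """Stage renal function from creatinine clearance (mL/min).

    Bins are half-open so they partition [0, inf): severe [0, 30),
    moderate [30, 50), mild [50, 80], healthy (80, inf).
    """
    if crcl_ml_min < 0:
        raise ValueError("creatinine clearance must be >= 0")
    if crcl_ml_min > 80:
        return CKDStage.HEALTHY
    if crcl_ml_min >= 50:
        return CKDStage.MILD
    if crcl_ml_min >= 30:
        return CKDStage.MODERATE
    return CKDStage.SEVERE


def reference_body(body_weight_kg: float = REFERENCE_BODY_WEIGHT_KG) -> BodyComposition:
    """Reference adult body scaled to ``body_weight_kg``.

    Volumes scale linearly with weight; flows and cardiac output scale with
    weight^0.75 (allometric). The reference is a 70-kg adult with cardiac
    output 390 L/h and 5.3 L blood.
    """
    w = body_weight_kg / REFERENCE_BODY_WEIGHT_KG
    volumes_ref = {
        "adipose": 12.0, "bone": 10.2, "brain": 1.45, "gut": 1.65,
        "heart": 0.33, "kidney": 0.31, "liver": 1.80, "lung": 0.50,
        "muscle": 28.0, "skin": 3.30, "spleen": 0.15, "pancreas": 0.10,
        "rest": 1.58,
    }
    flows_ref = {
        "adipose": 19.5, "bone": 19.5, "brain": 46.8, "gut": 44.0,
        "heart": 15.6, "kidney": 74.1, "liver": 25.0, "muscle": 66.3,
        "skin": 19.5, "spleen": 7.8, "pancreas": 3.9, "rest": 48.0,
    }
    q = w ** 0.75
    body = BodyComposition(
        compositions=load_tissue_compositions(),
        volumes={t: v * w for t, v in volumes_ref.items()},
        flows={t: f * q for t, f in flows_ref.items()},
        body_weight_kg=body_weight_kg,
        cardiac_output_l_h=390.0 * q,
        blood_volume_l=5.3 * w,
    )
    body.validate()
    return body


@dataclass
class SubjectPhysiology:
    """One virtual subject: demographics, scaled physiology, kidney scalars."""

    subject_id: str
    sex: str
    age_y: float
    body_weight_kg: float
    body: BodyComposition
    gfr_ml_min: float
    kidney_mass_g: float
    ptc_per_g_1e6: float
    oat1_relative_abundance: float
    hematocrit: float = 0.45
    #: log-normal IIV multipliers applied to drug parameters at model build
    iiv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gfr_ml_min < 0:
            raise ValueError("GFR must be >= 0")
        if not 0 < self.oat1_relative_abundance <= 1:
            raise ValueError("oat1_relative_abundance must lie in (0, 1]")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")

    @property
    def gfr_l_h(self) -> float:
        return self.gfr_ml_min * 60.0 / 1000.0


@dataclass
class PopulationSpec:
    """Distributions from which virtual subjects are drawn."""

    name: str
    stage: CKDStage = CKDStage.HEALTHY
    age_range: tuple[float, float] = (20.0, 50.0)
    proportion_male: float = 0.5
    weight_mean_kg: float = 75.0
    weight_cv: float = 0.12
    #: females drawn lighter by this factor
    female_weight_factor: float = 0.85
    gfr_mean_ml_min: float = HEALTHY_GFR_ML_MIN
    gfr_cv: float = 0.15
    ptc_per_g_1e6: float = HEALTHY_PTC_PER_G_1E6
    oat1_relative_abundance: float = 1.0
    #: log-normal IIV coefficients of variation on drug parameters
    iiv_cv: dict[str, float] = field(
        default_factory=lambda: {"clint_oat1": 0.30, "ka": 0.25, "kp_scalar": 0.20}
    )

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.iiv_cv.values()):
            raise ValueError("IIV CVs must be >= 0")
        if self.weight_cv < 0 or self.gfr_cv < 0:
            raise ValueError("CVs must be >= 0")


def make_ckd_population(base: PopulationSpec, stage: CKDStage | str) -> PopulationSpec:
    """Derive a CKD-stage population from a healthy base.

    The stage sets the mean GFR; PTC number per gram scales with the ratio of
    stage mean GFR to healthy mean GFR; OAT1 relative abundance takes the
    stage value (1.0 / 1.0 / 0.84 / 0.50).
    """
    stage = CKDStage(stage)
    if stage is CKDStage.HEALTHY:
        return base
    gfr_ratio = STAGE_GFR_ML_MIN[stage] / STAGE_GFR_ML_MIN[CKDStage.HEALTHY]
    return replace(
        base,
        name=f"{base.name}-{stage.value}",
        stage=stage,
        gfr_mean_ml_min=STAGE_GFR_ML_MIN[stage],
        ptc_per_g_1e6=scale_ptc_count(base.ptc_per_g_1e6, gfr_ratio),
        oat1_relative_abundance=STAGE_OAT1_ABUNDANCE[stage],
    )


def scale_ptc_count(healthy_ptc_per_g: float, gfr_ratio: float) -> float:
    """Scale PTC number per gram of kidney by the decline in mean GFR."""
    import warnings

    if not 0 < gfr_ratio:
        raise ValueError("gfr_ratio must be > 0")
    if gfr_ratio > 1.0:
        warnings.warn(
            "gfr_ratio > 1: improving renal function is not modeled",
            stacklevel=2,
        )
    return healthy_ptc_per_g * gfr_ratio


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw from a log-normal with arithmetic mean ``mean`` and CV ``cv``."""
    if cv == 0:
        return mean
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.exp(rng.normal(mu, np.sqrt(sigma2))))


def subject_rng(seed: int, trial: int, subject: int) -> np.random.Generator:
    """Counter-based stream: one generator per (seed, trial, subject)."""
    return np.random.default_rng([seed, trial, subject])


def sample_subject(
    spec: PopulationSpec,
    rng: np.random.Generator,
    subject_id: str = "s1",
    sex: Optional[str] = None,
) -> SubjectPhysiology:
    """Draw one virtual subject from the population distributions."""
    if sex is None:
        sex = "M" if rng.random() < spec.proportion_male else "F"
    age = float(rng.uniform(*spec.age_range))
    mean_w = spec.weight_mean_kg * (spec.female_weight_factor if sex == "F" else 1.0)
    weight = _lognormal(rng, mean_w, spec.weight_cv)
    gfr = _lognormal(rng, spec.gfr_mean_ml_min, spec.gfr_cv)
    iiv = {
        name: _lognormal(rng, 1.0, cv) for name, cv in sorted(spec.iiv_cv.items())
    }
    return SubjectPhysiology(
        subject_id=subject_id,
        sex=sex,
        age_y=age,
        body_weight_kg=weight,
        body=reference_body(weight),
        gfr_ml_min=gfr,
        kidney_mass_g=REFERENCE_KIDNEY_MASS_G * weight / REFERENCE_BODY_WEIGHT_KG,
        ptc_per_g_1e6=spec.ptc_per_g_1e6,
        oat1_relative_abundance=spec.oat1_relative_abundance,
        iiv=iiv,
    )


def trial_sexes(n_subjects: int, composition: str) -> list[str]:
    """Resolve a trial's sex composition ('male', 'female' or 'equal')."""
    if composition == "male":
        return ["M"] * n_subjects
    if composition == "female":
        return ["F"] * n_subjects
    if composition == "equal":
        half = n_subjects // 2
        return ["M"] * half + ["F"] * (n_subjects - half)
    raise ValueError(f"unknown sex composition: {composition!r}")


@dataclass
class TrialDesign:
    """Replicate-trial structure plus per-phase dosing and sampling times."""

    name: str
    population: PopulationSpec
    n_trials: int
    n_subjects: int
    sex_composition: str = "equal"
    age_range: tuple[float, float] = (20.0, 50.0)
    #: phase name -> DosingRegimen (victim); perpetrator regimens are separate
    regimens: dict[str, "DosingRegimen"] = field(default_factory=dict)
    perpetrator_regimens: dict[str, "DosingRegimen"] = field(default_factory=dict)
    sampling_times_h: Sequence[float] = ()
    t_end_h: float = 24.0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_subjects < 1:
            raise ValueError("n_trials and n_subjects must be >= 1")
        times = np.asarray(self.sampling_times_h, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    def subjects(self, seed: int):
        """Yield (trial, subject_index, SubjectPhysiology) deterministically."""
        spec = replace(self.population, age_range=self.age_range)
        sexes = trial_sexes(self.n_subjects, self.sex_composition)
        for trial in range(self.n_trials):
            for j in range(self.n_subjects):
                rng = subject_rng(seed, trial, j)
                subj = sample_subject(
                    spec, rng, subject_id=f"t{trial + 1}s{j + 1}", sex=sexes[j]
                )
                yield trial, j, subj


#: Maeda-style DDI crossover: Japanese men, sparse 0-8 h sampling
MAEDA_SAMPLING_H = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)
#: generic verification design sampling, 0-48 h (the long tail matters in
#: severe renal impairment, where the terminal half-life exceeds 12 h)
GENERIC_SAMPLING_H = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0,
                      16.0, 24.0, 36.0, 48.0)


def japanese_population() -> PopulationSpec:
    """Healthy Japanese population: lighter body-weight distribution only —
    no inter-ethnic difference in OAT1 activity is modeled."""
    return PopulationSpec(name="japanese", weight_mean_kg=65.0)


def chinese_population() -> PopulationSpec:
    return PopulationSpec(name="chinese", weight_mean_kg=63.0)


def white_population() -> PopulationSpec:
    return PopulationSpec(name="white", weight_mean_kg=75.0)
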