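"""Tissue-to-plasma partition coefficients (Kp) and steady-state volume.

Kp is predicted mechanistically from tissue composition: drug dissolves in
tissue water according to its ionization at local pH, partitions into neutral
lipid and phospholipid according to lipophilicity, binds extracellular albumin
(acids, neutrals, zwitterions) or associates with acidic phospholipids
(moderate-to-strong bases, with the association constant back-calculated from
red-cell partitioning). Only the unionized species crosses membranes, so
intracellular trapping follows the pH gradient.

All Kp values are total-tissue : total-plasma ratios. A drug-level global
multiplier (``kp_scalar``) can be calibrated once against an observed Vss to
absorb transporter-mediated distribution the composition model cannot see.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .drug import CompoundClass, PhyschemProfile

PLASMA_PH = 7.4
BLOOD_CELL_PH = 7.22
#: plasma water fractional lipid content (Rodgers-Rowland convention)
F_NL_PLASMA = 0.0023
F_NP_PLASMA = 0.0013
#: blood-cell composition used to back-calculate the acidic-phospholipid
#: association constant for bases
F_IW_BC = 0.603
F_NL_BC = 0.0017
F_NP_BC = 0.0029
AP_BC_MG_G = 0.5


class TissueComposition(BaseModel):
    """Fractional composition and local pH of one tissue."""

    tissue: str
    f_ew: float = Field(ge=0)
    f_iw: float = Field(ge=0)
    f_nl: float = Field(ge=0)
    f_np: float = Field(ge=0)
    ap_mg_g: float = Field(ge=0)
    ph_iw: float = Field(ge=6.0, le=7.8)
    albumin_ratio: float = Field(ge=0)

    @model_validator(mode="after")
    def _check_fractions(self) -> "TissueComposition":
        total = self.f_ew + self.f_iw + self.f_nl + self.f_np
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"{self.tissue}: water+lipid fractions sum to {total:.3f} > 1"
            )
        return self


@dataclass
class BodyComposition:
    """Reference-body tissue volumes (L) and blood flows (L/h).

    ``volumes``/``flows`` are keyed by tissue name; the lung carries the whole
    cardiac output and is stored separately in ``flows`` for completeness.
    """

    compositions: dict[str, TissueComposition]
    volumes: dict[str, float]
    flows: dict[str, float]
    body_weight_kg: float
    cardiac_output_l_h: float
    blood_volume_l: float
    hematocrit: float = 0.45
    plasma_ph: float = PLASMA_PH
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Audit closure of the volume and flow budgets (within 5%)."""
        vol = sum(self.volumes.values()) + self.blood_volume_l
        body_volume = self.body_weight_kg / 1.05  # density ~1.05 kg/L
        if abs(vol - body_volume) > 0.05 * body_volume:
            raise ValueError(
                f"tissue+blood volume {vol:.1f} L differs from body volume "
                f"{body_volume:.1f} L by more than 5%"
            )
        flow = sum(q for t, q in self.flows.items() if t != "lung")
        if abs(flow - self.cardiac_output_l_h) > 0.05 * self.cardiac_output_l_h:
            raise ValueError(
                f"sum of tissue flows {flow:.0f} L/h differs from cardiac output "
                f"{self.cardiac_output_l_h:.0f} L/h by more than 5%"
            )


def load_tissue_compositions(path: str | Path | None = None) -> dict[str, TissueComposition]:
    """Read the tissue-composition table (packaged fixture by default).

    The packaged table is parsed once and cached; callers receive a fresh
    shallow copy so the cache cannot be mutated.
    """
    if path is None:
        return dict(_default_compositions())
    df = pd.read_csv(path, comment="#")
    return {
        row.tissue: TissueComposition(**row._asdict())
        for row in df.itertuples(index=False)
    }


@lru_cache(maxsize=1)
def _default_compositions() -> dict[str, TissueComposition]:
    ref = importlib.resources.files("renalpbpk.data") / "tissue_composition.csv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, comment="#")
    return {
        row.tissue: TissueComposition(**row._asdict())
        for row in df.itertuples(index=False)
    }


def _ionized_ratio(compound_class: CompoundClass, pka: list[float], ph: float) -> float:
    """Henderson-Hasselbalch ratio of ionized to unionized species at ``ph``."""
    if compound_class is CompoundClass.NEUTRAL:
        return 0.0
    if compound_class is CompoundClass.MONOPROTIC_ACID:
        return 10.0 ** (ph - pka[0])
    if compound_class in (CompoundClass.DIPROTIC_ACID, CompoundClass.AMPHOLYTE):
        # Ampholytes dominated by acidic groups at physiological pH are handled
        # on the net-acid branch: the two most acidic pKa values are used.
        k1, k2 = sorted(pka)[:2]
        return 10.0 ** (ph - k1) + 10.0 ** (2.0 * ph - k1 - k2)
    if compound_class is CompoundClass.BASE:
        return 10.0 ** (pka[0] - ph)
    raise ValueError(f"unsupported compound class: {compound_class}")


def _is_base_branch(drug: PhyschemProfile) -> bool:
    """Moderate-to-strong bases (pKa >= 7) use the acidic-phospholipid branch."""
    return drug.compound_class is CompoundClass.BASE and max(drug.pka_list) >= 7.0


def _lipid_term(p_ow: float, f_nl: float, f_np: float) -> float:
    return p_ow * f_nl + (0.3 * p_ow + 0.7) * f_np


def kp_rodgers_rowland(
    drug: PhyschemProfile,
    tissue: TissueComposition,
    fu_plasma: float | None = None,
    hematocrit: float = 0.45,
    plasma_ph: float = PLASMA_PH,
) -> float:
    """Predict the total tissue:plasma partition coefficient for one tissue.

    Acids, neutrals, ampholytes and weak bases use the extracellular
    protein-binding branch; moderate-to-strong bases use the acidic
    phospholipid association branch with Ka_AP back-calculated from the
    blood:plasma ratio.

    Returns Kp (total), i.e. Kpu * fu_plasma.
    """
    if fu_plasma is None:
        fu_plasma = drug.fu_plasma
    if not 0 < fu_plasma <= 1:
        raise ValueError("fu_plasma must lie in (0, 1]")
    p_ow = 10.0 ** drug.logp_ow
    x_p = _ionized_ratio(drug.compound_class, drug.pka_list, plasma_ph)
    x_iw = _ionized_ratio(drug.compound_class, drug.pka_list, tissue.ph_iw)

    water = tissue.f_ew + (1.0 + x_iw) / (1.0 + x_p) * tissue.f_iw
    lipid = _lipid_term(p_ow, tissue.f_nl, tissue.f_np) / (1.0 + x_p)

    if _is_base_branch(drug):
        # Association to acidic phospholipids, scaled from red-cell partitioning.
        x_bc = _ionized_ratio(drug.compound_class, drug.pka_list, BLOOD_CELL_PH)
        kpu_bc = (drug.blood_to_plasma_ratio - (1.0 - hematocrit)) / (
            hematocrit * fu_plasma
        )
        if kpu_bc <= 0:
            raise ValueError(
                f"{drug.compound_class.value}: blood_to_plasma_ratio "
                f"{drug.blood_to_plasma_ratio} implies non-positive red-cell "
                "partitioning; cannot derive Ka_AP"
            )
        ka_ap = (
            kpu_bc
            - (1.0 + x_bc) / (1.0 + x_p) * F_IW_BC
            - _lipid_term(p_ow, F_NL_BC, F_NP_BC) / (1.0 + x_p)
        ) * (1.0 + x_p) / (AP_BC_MG_G * x_bc)
        ka_ap = max(ka_ap, 0.0)
        protein = ka_ap * tissue.ap_mg_g * x_iw / (1.0 + x_p)
    else:
        # Extracellular albumin binding, scaled by the tissue:plasma ratio.
        # Only the unionized species partitions into plasma lipid, so that
        # correction carries the same 1/(1+X) factor as the tissue lipid term.
        ka_alb = (
            1.0 / fu_plasma
            - 1.0
            - _lipid_term(p_ow, F_NL_PLASMA, F_NP_PLASMA) / (1.0 + x_p)
        )
        protein = max(ka_alb, 0.0) * tissue.albumin_ratio

    kpu = water + lipid + protein
    kp = kpu * fu_plasma
    if not (kp > 0 and kp < float("inf")):
        raise ValueError(f"non-finite Kp for tissue {tissue.tissue}")
    return kp


def kp_all_tissues(
    drug: PhyschemProfile,
    compositions: dict[str, TissueComposition],
    kp_scalar: float = 1.0,
    fu_plasma: float | None = None,
    hematocrit: float = 0.45,
) -> dict[str, float]:
    """Predict Kp for every tissue, applying the global calibration scalar."""
    return {
        name: kp_scalar
        * kp_rodgers_rowland(drug, comp, fu_plasma=fu_plasma, hematocrit=hematocrit)
        for name, comp in compositions.items()
    }


def vss_from_kps(
    kps: dict[str, float],
    body: BodyComposition,
    blood_to_plasma_ratio: float,
    fu_plasma: float,
) -> float:
    """Steady-state distribution volume (L/kg) from per-tissue Kp values.

    Vss = (V_plasma + sum_t V_t * Kp_t) / body weight. The plasma volume is the
    non-cell fraction of blood.
    """
    missing = [t for t in body.volumes if t not in kps]
    if missing:
        raise ValueError(f"missing Kp for tissue(s): {', '.join(sorted(missing))}")
    v_plasma = body.blood_volume_l * (1.0 - body.hematocrit)
    tissue_sum = sum(body.volumes[t] * kps[t] for t in body.volumes)
    return (v_plasma + tissue_sum) / body.body_weight_kg
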