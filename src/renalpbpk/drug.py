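"""Compound parameter models, validation, and transporter IVIVE scaling.

Every compound simulated by this package is described by a :class:`DrugModel`
collecting physicochemistry, plasma binding, first-order oral absorption,
renal transporter kinetics and (optionally saturable) nonrenal elimination.
Parameters are stored in YAML with units embedded in key names so a file can
be reviewed without consulting code.

Two IVIVE helpers live here: prodrug dose conversion on a molar basis, and
scaling of an in vitro intrinsic clearance (uL/min/1e6 cells) to a whole-organ
clearance (L/h) through a relative expression factor (REF), proximal tubule
cellularity and kidney mass.
"""

from __future__ import annotations

import math
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, model_validator

SCHEMA_VERSION = 1

#: uL/min -> L/h
_UL_PER_MIN_TO_L_PER_H = 60.0 / 1.0e6


class CompoundClass(str, Enum):
    """Ionization class used to select the tissue-partition equation branch."""

    MONOPROTIC_ACID = "monoprotic acid"
    DIPROTIC_ACID = "diprotic acid"
    BASE = "base"
    NEUTRAL = "neutral"
    AMPHOLYTE = "ampholyte"


class PhyschemProfile(BaseModel):
    """Physicochemical and plasma-binding properties of one compound."""

    molecular_weight_g_mol: float = Field(gt=0)
    compound_class: CompoundClass
    pka_list: list[float] = Field(default_factory=list)
    logp_ow: float
    blood_to_plasma_ratio: float = Field(gt=0)
    fu_plasma: float = Field(gt=0, le=1)

    @model_validator(mode="after")
    def _check_pka(self) -> "PhyschemProfile":
        need = {
            CompoundClass.MONOPROTIC_ACID: 1,
            CompoundClass.DIPROTIC_ACID: 2,
            CompoundClass.BASE: 1,
            CompoundClass.NEUTRAL: 0,
            CompoundClass.AMPHOLYTE: 2,
        }[self.compound_class]
        if len(self.pka_list) < need:
            raise ValueError(
                f"compound_class {self.compound_class.value!r} requires at least "
                f"{need} pKa value(s), got {len(self.pka_list)}"
            )
        return self


class AbsorptionModel(BaseModel):
    """First-order oral absorption: one rate constant covers intestinal uptake
    of the (pro)drug and any rapid conversion to the circulating species."""

    ka_per_h: float = Field(gt=0)
    fa: float = Field(gt=0, le=1)
    lag_time_h: float = Field(default=0.0, ge=0)


class TransporterKinetics(BaseModel):
    """Proximal-tubule membrane clearances, in vitro scale (uL/min/1e6 cells)."""

    clint_oat1_invitro_ul_min_1e6: float = Field(default=0.0, ge=0)
    ref_oat1: float = Field(default=1.0, ge=0)
    cl_mrp4_ul_min_1e6: float = Field(default=0.0, ge=0)
    clpd_baso_ul_min_1e6: float = Field(default=0.0, ge=0)
    clpd_apical_ul_min_1e6: float = Field(default=0.0, ge=0)


class EliminationModel(BaseModel):
    """Nonrenal elimination: linear clearance and/or a saturable Vmax/Km pair.

    The saturable term is driven by total venous plasma concentration, so
    ``km_nonrenal_mg_l`` is a total-plasma constant.
    """

    cl_nonrenal_linear_l_h: float = Field(default=0.0, ge=0)
    vmax_nonrenal_mg_h: Optional[float] = Field(default=None, gt=0)
    km_nonrenal_mg_l: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_pair(self) -> "EliminationModel":
        if (self.vmax_nonrenal_mg_h is None) != (self.km_nonrenal_mg_l is None):
            raise ValueError(
                "vmax_nonrenal_mg_h and km_nonrenal_mg_l must be given together"
            )
        return self

    @property
    def saturable(self) -> bool:
        return self.vmax_nonrenal_mg_h is not None


class DrugModel(BaseModel):
    """Complete parameterization of one compound."""

    name: str
    physchem: PhyschemProfile
    absorption: Optional[AbsorptionModel] = None
    transporters: TransporterKinetics = Field(default_factory=TransporterKinetics)
    elimination: EliminationModel = Field(default_factory=EliminationModel)
    kp_scalar: float = Field(default=1.0, gt=0)
    oat13_ki_unbound_um: Optional[float] = Field(default=None, gt=0)
    schema_version: int = SCHEMA_VERSION

    def require_perpetrator(self) -> float:
        """Return the unbound OAT1/3 Ki (uM), erroring if the compound was
        never parameterized as an inhibitor."""
        if self.oat13_ki_unbound_um is None:
            raise ValueError(
                f"{self.name}: oat13_ki_unbound_um is required for a perpetrator"
            )
        return self.oat13_ki_unbound_um


def convert_prodrug_dose(dose_prodrug_mg: float, mw_parent: float, mw_prodrug: float) -> float:
    """Convert a prodrug dose to the molar-equivalent parent dose (mg).

    A 10 mg oral dose of the dipivoxil ester of adefovir, for example, carries
    10 * 273.19 / 501.47 = 5.45 mg of adefovir.
    """
    if dose_prodrug_mg < 0:
        raise ValueError("dose_prodrug_mg must be >= 0")
    if mw_parent <= 0 or mw_prodrug <= 0:
        raise ValueError("molecular weights must be > 0")
    return dose_prodrug_mg * mw_parent / mw_prodrug


def scale_oat1_clint(
    clint_invitro_ul_min_1e6: float,
    ref: float,
    ptc_per_g_kidney_1e6: float,
    kidney_mass_g: float,
) -> float:
    """IVIVE an in vitro OAT1 intrinsic clearance to a whole-organ value (L/h).

    The in vitro clearance (uL/min per 1e6 cells) is multiplied by the relative
    expression factor (in vivo : in vitro transporter abundance), the proximal
    tubule cellularity (1e6 cells per g kidney) and total kidney mass, then
    converted from uL/min to L/h.
    """
    for name, v in (
        ("clint_invitro", clint_invitro_ul_min_1e6),
        ("ref", ref),
        ("ptc_per_g_kidney", ptc_per_g_kidney_1e6),
        ("kidney_mass_g", kidney_mass_g),
    ):
        if v < 0 or math.isnan(v):
            raise ValueError(f"{name} must be >= 0")
    return (
        clint_invitro_ul_min_1e6 * ref * ptc_per_g_kidney_1e6 * kidney_mass_g
    ) * _UL_PER_MIN_TO_L_PER_H


def load_drug_model(path: str | Path) -> DrugModel:
    """Load and validate a drug parameter file (YAML)."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at the document root")
    return DrugModel.model_validate(raw)


def save_drug_model(drug: DrugModel, path: str | Path) -> None:
    """Write a drug parameter file; numbers round-trip bit-exactly as decimal text."""
    path = Path(path)
    payload = drug.model_dump(mode="json", exclude_none=True)
    with path.open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
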