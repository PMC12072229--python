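"""Permeability-limited mechanistic kidney submodel.

The kidney block replaces the perfusion-limited kidney of the whole-body
model with an explicit proximal-tubule unit:

* a renal vascular compartment perfused by renal blood flow,
* glomerular filtration of unbound drug from arterial plasma into the first
  lumen segment (fu * GFR),
* basolateral OAT1-mediated uptake of unbound drug from the renal vascular
  plasma into a single proximal tubular cell (PTC) compartment, divided by a
  competitive inhibition factor when a perpetrator is present,
* apical MRP4 efflux and bidirectional passive diffusion across both
  membranes,
* three tubular lumen segments in series whose fluid flow falls geometrically
  from GFR to the urine flow (water reabsorption concentrates the drug; no
  drug is reabsorbed), draining into a cumulative urine compartment.

With basolateral uptake rate-determining and no drug reabsorption, the
steady-state renal clearance is insensitive to the number of lumen segments.

Whole-organ transporter clearances are IVIVE-scaled from in vitro values via
PTC cellularity, kidney mass and the OAT1 relative expression factor, then
multiplied by the subject's OAT1 relative abundance (CKD effect) and any
inter-individual variability multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .drug import DrugModel, scale_oat1_clint
from .population import SubjectPhysiology, scale_ptc_count  # noqa: F401  (re-export)

if TYPE_CHECKING:  # pragma: no cover
    from .model import SimulationResult

#: single proximal tubular cell volume (L); 1.2 pL
PTC_CELL_VOLUME_L = 1.2e-12
#: urine flow (L/h); 1.4 mL/min
URINE_FLOW_L_H = 0.084
N_LUMEN_SEGMENTS = 3
#: total proximal tubule fluid volume at reference body size (L)
LUMEN_TOTAL_VOLUME_L = 0.045
#: renal vascular blood volume at reference body size (L)
RENAL_VASCULAR_VOLUME_L = 0.07


def filtration_clearance(fu_plasma: float, gfr_l_h: float) -> float:
    """Glomerular filtration clearance of unbound drug: fu * GFR (L/h)."""
    if not 0 < fu_plasma <= 1:
        raise ValueError("fu_plasma must lie in (0, 1]")
    if gfr_l_h < 0:
        raise ValueError("GFR must be >= 0")
    return fu_plasma * gfr_l_h


@dataclass
class KidneyBlock:
    """Resolved per-subject, per-drug kidney parameters (all L/h and L)."""

    renal_blood_flow_l_h: float
    vascular_volume_l: float
    ptc_volume_l: float
    lumen_volumes_l: np.ndarray
    lumen_flows_l_h: np.ndarray  # outflow of each segment; last = urine flow
    gfr_l_h: float
    cl_filtration_l_h: float  # fu * GFR
    cl_uptake_oat1_l_h: float  # whole-organ, unbound-plasma referenced
    cl_mrp4_l_h: float
    cl_pd_baso_l_h: float
    cl_pd_apical_l_h: float
    fu_plasma: float
    blood_to_plasma: float

    def __post_init__(self) -> None:
        flows = np.asarray(self.lumen_flows_l_h, dtype=float)
        inflow = np.concatenate(([self.gfr_l_h], flows[:-1]))
        if self.gfr_l_h > 0 and np.any(flows > inflow + 1e-12):
            raise ValueError("lumen flow must decrease monotonically from GFR to urine")
        if self.vascular_volume_l <= 0 or self.ptc_volume_l <= 0:
            raise ValueError("kidney volumes must be > 0")


def build_kidney_block(subject: SubjectPhysiology, drug: DrugModel) -> KidneyBlock:
    """Resolve the kidney block for one subject and one drug."""
    tr = drug.transporters
    fu = drug.physchem.fu_plasma
    gfr = subject.gfr_l_h
    ptc = subject.ptc_per_g_1e6
    mass = subject.kidney_mass_g
    iiv_clint = subject.iiv.get("clint_oat1", 1.0)

    cl_up = (
        scale_oat1_clint(tr.clint_oat1_invitro_ul_min_1e6, tr.ref_oat1, ptc, mass)
        * subject.oat1_relative_abundance
        * iiv_clint
    )
    # MRP4 and passive diffusion scale with cellularity (membrane area) but
    # carry no REF and no disease abundance adjustment.
    cl_mrp4 = scale_oat1_clint(tr.cl_mrp4_ul_min_1e6, 1.0, ptc, mass)
    cl_pd_b = scale_oat1_clint(tr.clpd_baso_ul_min_1e6, 1.0, ptc, mass)
    cl_pd_a = scale_oat1_clint(tr.clpd_apical_ul_min_1e6, 1.0, ptc, mass)

    w = subject.body_weight_kg / 70.0
    urine_flow = min(URINE_FLOW_L_H, gfr) if gfr > 0 else 0.0
    if gfr > 0:
        # geometric decline of tubular fluid flow across segments
        r = (urine_flow / gfr) ** (1.0 / N_LUMEN_SEGMENTS)
        flows = gfr * r ** np.arange(1, N_LUMEN_SEGMENTS + 1)
    else:
        flows = np.zeros(N_LUMEN_SEGMENTS)
    volumes = np.full(N_LUMEN_SEGMENTS, LUMEN_TOTAL_VOLUME_L * w / N_LUMEN_SEGMENTS)

    return KidneyBlock(
        renal_blood_flow_l_h=subject.body.flows["kidney"],
        vascular_volume_l=RENAL_VASCULAR_VOLUME_L * w,
        ptc_volume_l=ptc * 1e6 * mass * PTC_CELL_VOLUME_L,
        lumen_volumes_l=volumes,
        lumen_flows_l_h=flows,
        gfr_l_h=gfr,
        cl_filtration_l_h=filtration_clearance(fu, gfr),
        cl_uptake_oat1_l_h=cl_up,
        cl_mrp4_l_h=cl_mrp4,
        cl_pd_baso_l_h=cl_pd_b,
        cl_pd_apical_l_h=cl_pd_a,
        fu_plasma=fu,
        blood_to_plasma=drug.physchem.blood_to_plasma_ratio,
    )


def kidney_rates(
    block: KidneyBlock,
    c_art_blood: float,
    a_rv: float,
    a_ptc: float,
    a_lumen: np.ndarray,
    inhibition_factor: float = 1.0,
) -> dict[str, float | np.ndarray]:
    """Rate contributions (mg/h) of the kidney block for the current state.

    ``inhibition_factor`` (>= 1) divides the OAT1 uptake clearance only.
    Returns fluxes keyed by compartment; ``d_arterial`` is the filtration
    drain on the arterial pool, ``to_venous`` the vascular return flow.
    """
    if inhibition_factor < 1.0:
        raise ValueError("inhibition factor must be >= 1")
    fu_bp = block.fu_plasma / block.blood_to_plasma
    cu_art = c_art_blood * fu_bp
    c_rv_b = a_rv / block.vascular_volume_l
    cu_rv = c_rv_b * fu_bp
    c_ptc = a_ptc / block.ptc_volume_l
    c_lu = a_lumen / block.lumen_volumes_l

    filtration = block.cl_filtration_l_h * c_art_blood / block.blood_to_plasma
    uptake = (block.cl_uptake_oat1_l_h / inhibition_factor) * cu_rv
    passive_baso = block.cl_pd_baso_l_h * (cu_rv - c_ptc)
    efflux = block.cl_mrp4_l_h * c_ptc
    passive_apical = block.cl_pd_apical_l_h * (c_ptc - c_lu[0])

    q = block.lumen_flows_l_h
    lumen_out = q * c_lu
    d_lumen = np.empty_like(lumen_out)
    d_lumen[0] = filtration + efflux + passive_apical - lumen_out[0]
    d_lumen[1:] = lumen_out[:-1] - lumen_out[1:]

    return {
        "d_arterial": -filtration,
        "d_vascular": block.renal_blood_flow_l_h * (c_art_blood - c_rv_b)
        - uptake
        - passive_baso,
        "d_ptc": uptake + passive_baso - efflux - passive_apical,
        "d_lumen": d_lumen,
        "d_urine": lumen_out[-1],
        "to_venous": block.renal_blood_flow_l_h * c_rv_b,
    }


@dataclass
class RenalClearances:
    """NCA-derived renal clearance decomposition."""

    cl_r_l_h: float
    cl_filtration_l_h: float
    cl_sec_l_h: float  # cl_r - fu*GFR; may be negative and is reported as such
    fe: float  # fraction of bioavailable dose excreted unchanged in urine
    body_weight_kg: float | None = None

    @property
    def cl_r_l_h_kg(self) -> float:
        if self.body_weight_kg is None:
            raise ValueError("body weight not set")
        return self.cl_r_l_h / self.body_weight_kg

    @property
    def cl_sec_l_h_kg(self) -> float:
        if self.body_weight_kg is None:
            raise ValueError("body weight not set")
        return self.cl_sec_l_h / self.body_weight_kg


def renal_clearance_from_sim(
    result: "SimulationResult",
    interval: tuple[float, float] | None = None,
    fu_gfr_l_h: float | None = None,
    body_weight_kg: float | None = None,
) -> RenalClearances:
    """Compute CLr = Ae/AUC over ``interval`` plus its decomposition.

    ``fu_gfr_l_h`` defaults to the block value stored on the result. Secretion
    clearance is the subtraction CLr - fu*GFR and is *not* clamped at zero.
    """
    from .nca import auc_trapezoid  # local import to avoid a cycle

    times = np.asarray(result.sampling_times_h, dtype=float)
    conc = result.plasma_conc_at(times)
    if interval is None:
        interval = (float(times[0]), float(times[-1]))
    lo, hi = interval
    auc = auc_trapezoid(times, conc, interval=interval)  # ng/mL * h
    if auc <= 0:
        raise ValueError("AUC over the interval is zero; CLr undefined")
    ae = result.urine_at(hi) - result.urine_at(lo)  # mg
    cl_r = ae / auc * 1e6 / 1000.0  # mg/(ng/mL*h) -> L/h
    if fu_gfr_l_h is None:
        fu_gfr_l_h = result.fu_gfr_l_h
    fe = result.urine_at(result.times_h[-1]) / result.bioavailable_dose_mg
    return RenalClearances(
        cl_r_l_h=cl_r,
        cl_filtration_l_h=fu_gfr_l_h,
        cl_sec_l_h=cl_r - fu_gfr_l_h,
        fe=fe,
        body_weight_kg=body_weight_kg,
    )
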