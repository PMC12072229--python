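"""Perpetrator-victim coupling through competitive OAT1 inhibition.

The perpetrator is simulated first under its own regimen; its unbound
concentration in the renal vascular compartment (the basolateral exposure of
the proximal tubule) is interpolated with a monotone cubic and converted to a
time-resolved inhibition factor 1 + Iu(t)/Ki that divides the victim's OAT1
uptake clearance. Inhibition applies to OAT1 uptake only — not to MRP4
efflux, passive diffusion, or filtration — and the perpetrator's kinetics are
unaffected by the victim.

Control and DDI phases of a crossover share the identical subject draw, so
within-subject ratios isolate the interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .drug import DrugModel
from .model import (DosingRegimen, InhibitionSchedule, SimulationResult,
                    build_model, simulate)
from .population import SubjectPhysiology


def inhibition_factor(iu_um, ki_um: float):
    """Competitive inhibition divisor 1 + Iu/Ki (unitless, >= 1)."""
    if ki_um <= 0:
        raise ValueError("Ki must be > 0")
    iu = np.asarray(iu_um, dtype=float)
    if np.any(iu < 0):
        raise ValueError("inhibitor concentrations must be >= 0")
    out = 1.0 + iu / ki_um
    return float(out) if out.ndim == 0 else out


@dataclass
class InhibitionContext:
    """Time-resolved unbound perpetrator exposure at the basolateral membrane."""

    perpetrator: str
    times_h: np.ndarray
    iu_um: np.ndarray
    ki_um: float
    mechanism: str = "competitive"

    def __post_init__(self) -> None:
        if self.ki_um <= 0:
            raise ValueError("Ki must be > 0")
        if np.any(np.asarray(self.iu_um) < -1e-12):
            raise ValueError("inhibitor concentrations must be >= 0")

    def schedule(self, breakpoints_h: tuple[float, ...] = ()) -> InhibitionSchedule:
        """Monotone-cubic interpolant of the inhibition factor over time."""
        iu = np.clip(np.asarray(self.iu_um, dtype=float), 0.0, None)
        interp = PchipInterpolator(self.times_h, iu, extrapolate=False)
        t_lo, t_hi = float(self.times_h[0]), float(self.times_h[-1])
        iu_last = float(iu[-1])

        def factor(t: float) -> float:
            if t <= t_lo:
                return 1.0 + float(iu[0]) / self.ki_um
            if t >= t_hi:
                return 1.0 + iu_last / self.ki_um
            return 1.0 + max(float(interp(t)), 0.0) / self.ki_um

        return InhibitionSchedule(factor, breakpoints_h=breakpoints_h)


def perpetrator_context(
    perp: DrugModel,
    perp_result: SimulationResult,
) -> InhibitionContext:
    """Build the inhibition context from a perpetrator simulation."""
    ki = perp.require_perpetrator()
    iu = perp_result.unbound_renal_vascular_um(
        perp.physchem.fu_plasma,
        perp.physchem.blood_to_plasma_ratio,
        perp.physchem.molecular_weight_g_mol,
    )
    return InhibitionContext(perp.name, perp_result.times_h, iu, ki)


@dataclass
class DDIPair:
    """Control and DDI simulations for one subject (identical parameter draw)."""

    subject: SubjectPhysiology
    control: SimulationResult
    ddi: SimulationResult
    perpetrator: SimulationResult | None


def simulate_ddi_subject(
    victim: DrugModel,
    perpetrator: DrugModel,
    subject: SubjectPhysiology,
    victim_regimen: DosingRegimen,
    perp_regimen: DosingRegimen,
    t_end_h: float,
    sampling_times_h=None,
    grid_step_h: float = 0.05,
) -> DDIPair:
    """Simulate one subject's crossover: control phase and one DDI phase.

    ``victim_regimen`` and ``perp_regimen`` share a common clock; a staggered
    design (perpetrator 2 h before the victim) is expressed by the victim
    events starting at t = 2 h. A zero-dose perpetrator reproduces the control
    phase bit-identically.
    """
    spec_control = build_model(subject, victim)
    control = simulate(spec_control, victim_regimen, t_end_h,
                       sampling_times_h=sampling_times_h, grid_step_h=grid_step_h)

    total_perp_dose = sum(ev.amount_mg for ev in perp_regimen.events)
    if total_perp_dose == 0:
        return DDIPair(subject, control, control, None)

    spec_perp = build_model(subject, perpetrator)
    perp_res = simulate(spec_perp, perp_regimen, t_end_h,
                        grid_step_h=grid_step_h)
    ctx = perpetrator_context(perpetrator, perp_res)
    perp_dose_times = tuple(
        t for t, *_ in perp_regimen.resolved(subject.body_weight_kg)
    )
    spec_ddi = build_model(
        subject, victim, inhibition=ctx.schedule(breakpoints_h=perp_dose_times)
    )
    ddi = simulate(spec_ddi, victim_regimen, t_end_h,
                   sampling_times_h=sampling_times_h, grid_step_h=grid_step_h)
    return DDIPair(subject, control, ddi, perp_res)
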