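"""Non-compartmental analysis, ratio statistics, and acceptance criteria.

AUC uses the linear-up / log-down trapezoid (exact for piecewise-linear
rising and mono-exponential falling segments); AUC extrapolation to infinity
fits the terminal slope to the last three positive concentrations. Summary
statistics follow the clinical-reporting convention: arithmetic mean ±
standard deviation, with crossover ratios summarized as the arithmetic mean
of within-subject ratios.

Prediction-acceptance checks implemented here:

* the fold-error criterion (1.5-fold: 0.67 <= R_pred/obs <= 1.5, matching the
  printed convention for the lower bound), and
* the Guest criterion for DDI ratios, whose bounds narrow toward unity as the
  observed ratio approaches 1 (variability term delta, default 1.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kidney import RenalClearances, renal_clearance_from_sim
from .model import SimulationResult


def auc_trapezoid(
    times_h: np.ndarray,
    conc: np.ndarray,
    interval: Optional[tuple[float, float]] = None,
    method: str = "lin_up_log_down",
) -> float:
    """AUC over ``interval`` by the linear-up / log-down trapezoid (conc*h).

    Falling segments with both concentrations positive use the exact
    exponential integral (c1-c2)*dt/ln(c1/c2); all other segments use the
    linear trapezoid. ``method="linear"`` forces linear throughout.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if interval is None:
        interval = (float(t[0]), float(t[-1]))
    lo, hi = interval
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"interval [{lo}, {hi}] outside data range [{t[0]}, {t[-1]}]")
    inside = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inside], [hi]))
    cc = np.concatenate(([np.interp(lo, t, c)], c[inside], [np.interp(hi, t, c)]))
    if tt.size < 2:
        raise ValueError("need at least two points in the interval")

    dt = np.diff(tt)
    c1, c2 = cc[:-1], cc[1:]
    linear = 0.5 * (c1 + c2) * dt
    if method == "linear":
        return float(linear.sum())
    down = (c2 < c1) & (c2 > 0)
    seg = linear.copy()
    seg[down] = (c1[down] - c2[down]) * dt[down] / np.log(c1[down] / c2[down])
    return float(seg.sum())


def terminal_slope(times_h: np.ndarray, conc: np.ndarray, n_points: int = 3) -> float:
    """Log-linear terminal rate constant (1/h) from the last n positive points."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    pos = c > 0
    if pos.sum() < n_points:
        raise ValueError("not enough positive concentrations for a terminal fit")
    t, c = t[pos][-n_points:], c[pos][-n_points:]
    slope = np.polyfit(t, np.log(c), 1)[0]
    if slope >= 0:
        raise ValueError("terminal phase is not declining; lambda_z undefined")
    return -slope


def auc_to_infinity(times_h: np.ndarray, conc: np.ndarray) -> float:
    """AUC(0-inf): observed AUC plus Clast/lambda_z extrapolation."""
    auc_last = auc_trapezoid(times_h, conc)
    lam = terminal_slope(times_h, conc)
    c_last = float(np.asarray(conc)[np.asarray(conc) > 0][-1])
    return auc_last + c_last / lam


@dataclass
class PKSummary:
    """Per-subject, per-phase NCA metrics."""

    subject_id: str
    phase: str
    cmax_ng_ml: float
    tmax_h: float
    auc_0_t_ng_h_ml: float
    auc_inf_ng_h_ml: float
    ae_mg: float
    cl_r_l_h: float
    cl_r_l_h_kg: float
    cl_sec_l_h_kg: float
    fe: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id, "phase": self.phase,
            "cmax_ng_ml": self.cmax_ng_ml, "tmax_h": self.tmax_h,
            "auc_0_t_ng_h_ml": self.auc_0_t_ng_h_ml,
            "auc_inf_ng_h_ml": self.auc_inf_ng_h_ml, "ae_mg": self.ae_mg,
            "cl_r_l_h": self.cl_r_l_h, "cl_r_l_h_kg": self.cl_r_l_h_kg,
            "cl_sec_l_h_kg": self.cl_sec_l_h_kg, "fe": self.fe,
        }


def pk_summary(
    result: SimulationResult,
    subject_id: str = "s1",
    phase: str = "control",
    dose_time_h: float = 0.0,
    auc_window_h: Optional[float] = None,
) -> PKSummary:
    """NCA on the study sampling times of a simulation.

    ``dose_time_h`` anchors the analysis window when the victim dose is offset
    on the trial clock (staggered DDI designs); Cmax, AUC and CLr are computed
    over [dose_time, dose_time + auc_window] on the sampling grid.
    """
    times = np.asarray(result.sampling_times_h, dtype=float)
    times = times[times >= dose_time_h - 1e-9]
    conc = result.plasma_conc_at(times)
    if auc_window_h is None:
        window_end = float(times[-1])
    else:
        window_end = dose_time_h + auc_window_h
    interval = (dose_time_h, window_end)

    i_max = int(np.argmax(conc))
    auc_t = auc_trapezoid(times, conc, interval=interval)
    try:
        auc_inf = auc_to_infinity(times - dose_time_h, conc)
    except ValueError:
        auc_inf = np.nan

    rc: RenalClearances = renal_clearance_from_sim(
        result, interval=interval, body_weight_kg=result.body_weight_kg
    )
    return PKSummary(
        subject_id=subject_id, phase=phase,
        cmax_ng_ml=float(conc[i_max]), tmax_h=float(times[i_max] - dose_time_h),
        auc_0_t_ng_h_ml=auc_t, auc_inf_ng_h_ml=float(auc_inf),
        ae_mg=result.urine_at(window_end) - result.urine_at(dose_time_h),
        cl_r_l_h=rc.cl_r_l_h, cl_r_l_h_kg=rc.cl_r_l_h_kg,
        cl_sec_l_h_kg=rc.cl_sec_l_h_kg, fe=rc.fe,
    )


@dataclass
class GuestCriterion:
    """DDI prediction-acceptance bounds with variability term delta."""

    delta: float = 1.25

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")


def guest_limits(
    r_obs: float, criterion: GuestCriterion = GuestCriterion()
) -> tuple[float, float]:
    """Acceptance bounds for a predicted DDI ratio given the observed ratio.

    For r_obs >= 1 the limit is L = (delta + 2*(r_obs - 1))/r_obs and the
    predicted ratio must fall in (r_obs/L, r_obs*L); observed ratios below 1
    are evaluated on the reciprocal scale and the bounds inverted, making the
    criterion symmetric under r -> 1/r.
    """
    if r_obs <= 0:
        raise ValueError("observed ratio must be > 0")
    if r_obs < 1.0:
        lo, hi = guest_limits(1.0 / r_obs, criterion)
        return 1.0 / hi, 1.0 / lo
    limit = (criterion.delta + 2.0 * (r_obs - 1.0)) / r_obs
    return r_obs / limit, r_obs * limit


def guest_pass(r_pred: float, r_obs: float,
               criterion: GuestCriterion = GuestCriterion()) -> bool:
    lo, hi = guest_limits(r_obs, criterion)
    return lo <= r_pred <= hi


def fold_error_pass(r_pred_obs: float, fold: float = 1.5) -> bool:
    """True iff the predicted/observed ratio lies within the fold criterion.

    The 1.5-fold test uses the printed convention 0.67 <= R <= 1.5 (lower
    bound 0.67 exactly, not 1/1.5).
    """
    if r_pred_obs <= 0:
        raise ValueError("ratio must be > 0")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    lower = 0.67 if fold == 1.5 else 1.0 / fold
    return lower <= r_pred_obs <= fold


@dataclass
class DDIOutcome:
    """Within-subject DDI ratios plus acceptance flags vs observed ratios."""

    phase: str
    cmax_ratio: float
    auc_ratio: float
    clr_ratio: float
    guest_pass: dict[str, bool] = field(default_factory=dict)
    fold_1_5_pass: dict[str, bool] = field(default_factory=dict)


def ddi_outcome(
    control: PKSummary,
    ddi: PKSummary,
    observed: Optional[dict[str, float]] = None,
    criterion: GuestCriterion = GuestCriterion(),
) -> DDIOutcome:
    """Within-subject ratios (DDI/control) with optional acceptance flags.

    ``observed`` maps metric names ("cmax", "auc", "clr") to observed ratios.
    """
    out = DDIOutcome(
        phase=ddi.phase,
        cmax_ratio=ddi.cmax_ng_ml / control.cmax_ng_ml,
        auc_ratio=ddi.auc_0_t_ng_h_ml / control.auc_0_t_ng_h_ml,
        clr_ratio=ddi.cl_r_l_h / control.cl_r_l_h,
    )
    if observed:
        pred = {"cmax": out.cmax_ratio, "auc": out.auc_ratio, "clr": out.clr_ratio}
        for metric, r_obs in observed.items():
            out.guest_pass[metric] = guest_pass(pred[metric], r_obs, criterion)
            out.fold_1_5_pass[metric] = fold_error_pass(pred[metric] / r_obs)
    return out


def summarize_population(summaries: Sequence[PKSummary]) -> pd.DataFrame:
    """Arithmetic mean, SD and geometric mean of each metric, per phase."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    df = pd.DataFrame([s.as_dict() for s in summaries])
    metrics = [c for c in df.columns if c not in ("subject_id", "phase")]
    rows = []
    for phase, grp in df.groupby("phase", sort=False):
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            rows.append({
                "phase": phase, "metric": m,
                "mean": finite.mean() if finite.size else np.nan,
                "sd": finite.std(ddof=1) if finite.size > 1 else 0.0,
                "geomean": (np.exp(np.log(finite[finite > 0]).mean())
                            if (finite > 0).any() else np.nan),
                "n": int(finite.size),
            })
    return pd.DataFrame(rows)


def mean_ratio(outcomes: Sequence[DDIOutcome], metric: str) -> float:
    """Arithmetic mean of within-subject ratios across a population."""
    vals = [getattr(o, f"{metric}_ratio") for o in outcomes]
    return float(np.mean(vals))
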