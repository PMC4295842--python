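"""FRAP exchange-kinetics analysis.

A single fluorescent spot is photobleached with a short focused pulse and
its recovery tracked as the background-corrected spot/cell intensity ratio

    R = (I_S - I_0) / (I_B - I_0)

where I_S, I_B, I_0 are the mean intensities of the spot ROI, the whole
bacterium, and the extracellular background. R is normalized by the mean
pre- and post-bleach ratios (ten frames each side of the bleach) to the
unrecovered fraction

    N(t) = (R_pre - R(t)) / (R_pre - R_post),

which starts near 1 immediately after the bleach and decays toward
1 - mobile_fraction. N(t) is fit with the bounded exponential

    N(t) = start + (start - end) * (exp(-t/tau) - 1),

start in [0.9, 1.1], end in [-0.1, 0.4], tau > 0. The recovery half-time
is t_half = tau * ln 2 and the mobile (exchangeable) fraction is
(start - end)/start. Fits with r^2 < 0.4 are excluded.

The normalization direction matters and is easy to get backwards: the fit
bounds (start near 1, end near 0.2) are only consistent with a decaying
curve, so N is the *unrecovered* fraction, and a plateau end ~ 0.2
corresponds to a mobile fraction of ~80%.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_REF_FRAMES = 10
DEFAULT_R2_MIN = 0.4
START_BOUNDS = (0.9, 1.1)
END_BOUNDS = (-0.1, 0.4)
TAU_STARTS_S = (20.0, 60.0, 180.0)  # deterministic multi-start grid


class UndefinedRatioError(ValueError):
    """Cell and background intensities coincide; R is undefined."""


class NoBleachError(ValueError):
    """Post-bleach ratio is not below the pre-bleach ratio; nothing to fit."""


@dataclass
class FrapTrace:
    """One photobleaching experiment: per-frame (time, I_S, I_B, I_0) triplets."""

    times: np.ndarray  # s, strictly increasing
    i_spot: np.ndarray  # spot ROI mean, a.u.
    i_cell: np.ndarray  # whole-bacterium ROI mean, a.u.
    i_bg: np.ndarray  # extracellular background ROI mean, a.u.
    bleach_index: int  # index of the first post-bleach frame
    trace_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.i_spot = np.asarray(self.i_spot, dtype=float)
        self.i_cell = np.asarray(self.i_cell, dtype=float)
        self.i_bg = np.asarray(self.i_bg, dtype=float)
        n = self.times.size
        if not (self.i_spot.size == self.i_cell.size == self.i_bg.size == n):
            raise ValueError("intensity columns must match the time axis")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not 0 < self.bleach_index < n:
            raise ValueError("bleach_index must lie inside the trace")

    # --- CSV + JSON-sidecar round trip -------------------------------------

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(
            {"time_s": self.times, "I_spot": self.i_spot,
             "I_cell": self.i_cell, "I_bg": self.i_bg}
        ).to_csv(path, index=False, float_format="%.10g")
        sidecar = {"bleach_index": int(self.bleach_index),
                   "trace_id": self.trace_id, "condition": self.condition}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrapTrace":
        path = Path(path)
        df = pd.read_csv(path)
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(times=df["time_s"].to_numpy(),
                   i_spot=df["I_spot"].to_numpy(),
                   i_cell=df["I_cell"].to_numpy(),
                   i_bg=df["I_bg"].to_numpy(),
                   bleach_index=int(side["bleach_index"]),
                   trace_id=str(side.get("trace_id", path.stem)),
                   condition=str(side.get("condition", "")))


@dataclass
class FitResult:
    start: float = math.nan
    end: float = math.nan
    tau: float = math.nan  # e-folding time constant, s
    r_squared: float = math.nan
    t_half: float = math.nan  # tau * ln 2, s
    mobile_fraction: float = math.nan  # (start - end) / start
    converged: bool = False
    excluded: bool = True
    exclusion_reason: str = ""
    trace_id: str = ""
    condition: str = ""


@dataclass
class GroupSummary:
    condition: str
    n: int  # non-excluded fits only
    mean_t_half: float
    sem_t_half: float
    mean_mobile_fraction: float


def spot_ratio(i_spot, i_cell, i_bg, frame: int | None = None):
    """Background-corrected spot/cell intensity ratio R = (I_S - I_0)/(I_B - I_0)."""
    i_spot = np.asarray(i_spot, dtype=float)
    i_cell = np.asarray(i_cell, dtype=float)
    i_bg = np.asarray(i_bg, dtype=float)
    denom = i_cell - i_bg
    bad = np.atleast_1d(denom == 0)
    if bad.any():
        where = frame if frame is not None else int(np.flatnonzero(bad)[0])
        raise UndefinedRatioError(
            f"I_B == I_0 at frame {where}: spot ratio undefined"
        )
    out = (i_spot - i_bg) / denom
    return float(out) if out.ndim == 0 else out


def normalize_trace(trace: FrapTrace, n_ref_frames: int = DEFAULT_REF_FRAMES
                    ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalize a raw trace to the unrecovered fraction N(t).

    Returns (times from bleach, N values for post-bleach frames, R_pre, R_post).
    R_pre / R_post are the means of ``n_ref_frames`` ratios immediately before
    / after the bleach; N = (R_pre - R)/(R_pre - R_post); the time origin is
    the first post-bleach frame.
    """
    b = trace.bleach_index
    if b < n_ref_frames or trace.times.size - b < n_ref_frames:
        raise ValueError(
            f"need >= {n_ref_frames} frames on each side of the bleach"
        )
    r = spot_ratio(trace.i_spot, trace.i_cell, trace.i_bg)
    r_pre = float(np.mean(r[b - n_ref_frames:b]))
    r_post = float(np.mean(r[b:b + n_ref_frames]))
    if r_pre <= r_post:
        raise NoBleachError(
            f"trace {trace.trace_id!r}: pre-bleach ratio {r_pre:.4g} not above "
            f"post-bleach ratio {r_post:.4g}"
        )
    t = trace.times[b:] - trace.times[b]
    n = (r_pre - r[b:]) / (r_pre - r_post)
    return t, n, r_pre, r_post


def _model(t: np.ndarray, start: float, end: float, tau: float) -> np.ndarray:
    return start + (start - end) * (np.exp(-t / tau) - 1.0)


def fit_recovery(times: np.ndarray, n_values: np.ndarray,
                 r2_min: float = DEFAULT_R2_MIN,
                 trace_id: str = "", condition: str = "") -> FitResult:
    """Bounded least-squares fit of N(t) = start + (start-end)(exp(-t/tau) - 1).

    Multi-start over a fixed tau grid; never raises on valid numeric input —
    non-convergence and poor fits come back flagged ``excluded``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(n_values, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 post-bleach points to fit")

    lo = np.array([START_BOUNDS[0], END_BOUNDS[0], 1e-9])
    hi = np.array([START_BOUNDS[1], END_BOUNDS[1], np.inf])
    best = None
    for tau0 in TAU_STARTS_S:
        x0 = np.clip(np.array([1.0, 0.2, tau0]), lo, hi)
        try:
            sol = optimize.least_squares(
                lambda p: _model(t, *p) - y, x0, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy raises only on bad input
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    fit = FitResult(trace_id=trace_id, condition=condition)
    if best is None:
        fit.exclusion_reason = "optimizer did not converge"
        return fit

    start, end, tau = (float(v) for v in best.x)
    ss_res = float(np.sum((_model(t, start, end, tau) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fit.start, fit.end, fit.tau = start, end, tau
    fit.t_half = tau * math.log(2.0)
    fit.mobile_fraction = (start - end) / start
    fit.converged = True
    if ss_tot == 0.0:
        fit.r_squared = -math.inf
        fit.excluded = True
        fit.exclusion_reason = "degenerate trace (zero variance)"
        return fit
    fit.r_squared = 1.0 - ss_res / ss_tot
    if fit.r_squared < r2_min:
        fit.excluded = True
        fit.exclusion_reason = f"r^2 = {fit.r_squared:.3f} < {r2_min}"
    else:
        fit.excluded = False
    return fit


def fit_trace(trace: FrapTrace, n_ref_frames: int = DEFAULT_REF_FRAMES,
              r2_min: float = DEFAULT_R2_MIN) -> FitResult:
    """normalize_trace + fit_recovery on one raw trace."""
    try:
        t, n, _, _ = normalize_trace(trace, n_ref_frames)
    except NoBleachError as exc:
        return FitResult(trace_id=trace.trace_id, condition=trace.condition,
                         exclusion_reason=str(exc))
    return fit_recovery(t, n, r2_min=r2_min,
                        trace_id=trace.trace_id, condition=trace.condition)


def aggregate_group(fits: list[FitResult], condition: str = "") -> GroupSummary:
    """Mean and SEM of t_half (and mean mobile fraction) over non-excluded fits."""
    kept = [f for f in fits if not f.excluded]
    if len(kept) < 2:
        raise ValueError(
            f"group {condition!r}: need >= 2 non-excluded fits, have {len(kept)}"
        )
    th = np.array([f.t_half for f in kept])
    mf = np.array([f.mobile_fraction for f in kept])
    return GroupSummary(
        condition=condition or (kept[0].condition if kept else ""),
        n=len(kept),
        mean_t_half=float(th.mean()),
        sem_t_half=float(th.std(ddof=1) / np.sqrt(th.size)),
        mean_mobile_fraction=float(mf.mean()),
    )


def compare_groups(a: list[FitResult], b: list[FitResult]
                   ) -> tuple[float, float]:
    """Welch two-sided comparison of t_half between conditions.

    Returns (mean difference a - b in s, p value).
    """
    ta = np.array([f.t_half for f in a if not f.excluded])
    tb = np.array([f.t_half for f in b if not f.excluded])
    if ta.size < 2 or tb.size < 2:
        raise ValueError("each group needs >= 2 non-excluded fits")
    diff = float(ta.mean() - tb.mean())
    if np.allclose(ta.std(), 0) and np.allclose(tb.std(), 0):
        return diff, 1.0 if np.isclose(diff, 0) else 0.0
    res = stats.ttest_ind(ta, tb, equal_var=False)
    return diff, float(res.pvalue)


def recovery_at(fit: FitResult, t: float) -> float:
    """Percent recovered at time t after the bleach: 100*(start - N(t))/start."""
    if not fit.converged:
        raise ValueError("recovery_at needs a converged fit")
    n_t = _model(np.asarray(t, dtype=float), fit.start, fit.end, fit.tau)
    return float(100.0 * (fit.start - n_t) / fit.start)


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    """FitResults as a flat table (one row per trace)."""
    return pd.DataFrame([{
        "trace_id": f.trace_id, "condition": f.condition,
        "start": f.start, "end": f.end, "tau_s": f.tau,
        "t_half_s": f.t_half, "mobile_fraction": f.mobile_fraction,
        "r_squared": f.r_squared, "converged": f.converged,
        "excluded": f.excluded, "exclusion_reason": f.exclusion_reason,
    } for f in fits])
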