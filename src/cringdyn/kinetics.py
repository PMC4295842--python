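"""Export-kinetics and titration analyses.

Two small, self-contained procedures: extracting the slope of the linear
increasing region of a plate-reader fluorescence trace (beta-lactamase
secretion reporter), and ordinary least squares of mean foci per cell on
the amount of expressed protein (cooperative-binding titration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KineticTrace:
    times: np.ndarray  # s, strictly increasing
    fluorescence: np.ndarray  # a.u.
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size < 5:
            raise ValueError("a kinetic trace needs at least 5 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class TitrationPoint:
    amount: float  # quantified protein level, a.u.
    mean_foci_per_cell: float
    n_cells: int = 0

    def __post_init__(self) -> None:
        if 0 < self.n_cells < 170:
            warnings.warn(
                f"titration point with n_cells={self.n_cells} < 170", stacklevel=2
            )


class LowLinearityWarning(UserWarning):
    """No sliding window reached the linearity gate; max-slope fallback used."""


def _window_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and r^2 of an OLS line through one window."""
    res = stats.linregress(t, y)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        # flat (or single-valued) window: a constant line fits exactly
        return float(res.slope), 1.0
    return float(res.slope), float(res.rvalue**2)


def linear_region_slope(trace: KineticTrace, window: int = 10,
                        r2_min: float = 0.95) -> float:
    """Slope (a.u./s) of the steepest well-fit contiguous window.

    Among all contiguous windows of ``window`` points whose OLS fit has
    r^2 >= ``r2_min``, returns the maximal slope; if no window passes the
    gate, falls back to the overall max-slope window and warns.
    """
    n = trace.times.size
    if window > n:
        raise ValueError(f"window of {window} points exceeds trace length {n}")
    if window < 2:
        raise ValueError("window must span at least 2 points")
    slopes, r2s = [], []
    for i in range(n - window + 1):
        s, r2 = _window_fit(trace.times[i:i + window],
                            trace.fluorescence[i:i + window])
        slopes.append(s)
        r2s.append(r2)
    slopes_arr = np.array(slopes)
    r2s_arr = np.array(r2s)
    ok = r2s_arr >= r2_min
    if ok.any():
        return float(slopes_arr[ok].max())
    warnings.warn(
        f"no window of {window} points reached r^2 >= {r2_min}; "
        "returning the max-slope window",
        LowLinearityWarning,
        stacklevel=2,
    )
    return float(slopes_arr.max())


def normalize_rates(slopes: dict[str, list[float] | float],
                    reference_sample: str) -> pd.DataFrame:
    """Express per-sample slopes as percent of the reference sample's mean.

    ``slopes`` maps sample label -> replicate slopes (scalar accepted).
    Returns a frame with per-sample mean percent and SEM over replicates.
    """
    vals = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in slopes.items()}
    if reference_sample not in vals:
        raise KeyError(f"reference sample {reference_sample!r} not among slopes")
    ref = float(vals[reference_sample].mean())
    if ref <= 0:
        raise ValueError(f"reference slope must be positive, got {ref}")
    rows = []
    for sample, v in vals.items():
        pct = 100.0 * v / ref
        sem = float(pct.std(ddof=1) / np.sqrt(pct.size)) if pct.size > 1 else np.nan
        rows.append({"sample": sample, "n": pct.size,
                     "percent_of_reference": float(pct.mean()),
                     "sem": sem})
    return pd.DataFrame(rows)


def titration_regression(points: list[TitrationPoint]) -> tuple[float, float, float]:
    """OLS of mean foci per cell on protein amount: (slope, intercept, r_squared)."""
    if len(points) < 2:
        raise ValueError("need at least 2 titration points")
    x = np.array([p.amount for p in points], dtype=float)
    y = np.array([p.mean_foci_per_cell for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all amounts are equal; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
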