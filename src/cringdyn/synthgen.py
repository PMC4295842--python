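"""Synthetic microscopy generator with known ground truth.

Emulates the three data types the analysis consumes, with the statistical
structure the method assumes:

* **Focus stacks** — diffraction-limited membrane foci, each containing an
  integer number of fluorophores, rendered as pixel-integrated 3-D
  Gaussians on a uniform cytosolic background, z-sectioned at 150 nm.
  Focus centers get a random continuous z offset spanning the stack, so
  part of the axial PSF can fall outside the acquired planes — this
  reproduces the dominant source of per-focus intensity variance in the
  real experiment (foci centered above or below the imaged planes).
  Camera model: Poisson shot noise on signal + background, then additive
  Gaussian read noise. Gain factors cancel in all downstream ratios, so no
  EM-gain excess noise is modelled.

* **FRAP traces** — spot ratio drops by ``bleach_depth`` at the bleach and
  recovers as mobile_fraction * (1 - 2^(-t/t_half)) of the bleached
  amplitude, with Gaussian noise on the ratio scale. Raw (spot, cell,
  background) intensity columns are emitted so the downstream ratio
  computation is exercised, not bypassed.

* **Trajectories** — two-population Brownian motion at the PALM frame
  interval (15.26 ms) with independent per-frame localization error,
  geometric track lengths (memoryless photobleaching), staggered
  photoactivation, and reflective boundaries in a rectangular cell.

Identical seed + config give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .focimetry import ImageStack
from .frap import FrapTrace

_PLACEMENT_MIN_SEP_PX = 6.0  # between focus centers; > the 3 px detection rule
_PLACEMENT_MARGIN_PX = 6  # keeps the measurement ROI inside the frame
_RENDER_BOX_SIGMA = 4.0  # rendering truncated at +/- 4 sigma (<1% loss)


class PlacementError(RuntimeError):
    """Foci could not be placed at the required minimum separation."""


# ---------------------------------------------------------------------------
# configs and ground truth


@dataclass
class StackSimConfig:
    n_stacks: int = 11  # stacks per condition in the stoichiometry experiment
    cells_per_stack: int = 11
    foci_per_cell: int = 10
    copies_per_focus: int = 22  # fluorophores per focus
    unit_intensity: float = 200.0  # photons per fluorophore per frame
    psf_sigma_lateral: float = 100.0  # nm
    psf_sigma_axial: float = 300.0  # nm
    pixel_size: float = 101.3  # nm/px (3 px = 304 nm)
    z_spacing: float = 150.0  # nm
    z_planes: int = 10  # acquisition used 7-15
    cytosolic_background: float = 50.0  # photons/px
    read_noise_sd: float = 2.0  # photons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_focus < 0:
            raise ValueError("copies_per_focus must be >= 0")
        if self.z_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("z_spacing and pixel_size must be positive")
        if self.z_planes < 1:
            raise ValueError("need at least one z-plane")


@dataclass
class FrapSimConfig:
    n_traces: int = 20
    true_t_half: float = 68.2  # s
    mobile_fraction: float = 0.8
    bleach_depth: float = 0.8  # fraction of spot signal removed
    pre_frames: int = 10
    # S1-movie-style acquisition: blocks of (n_frames, interval_s)
    frame_schedule: tuple = ((10, 2.0), (10, 4.0), (10, 6.0),
                            (10, 10.0), (10, 15.0), (10, 20.0))
    noise_sd: float = 0.05  # on the ratio scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_t_half <= 0:
            raise ValueError("true_t_half must be positive")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in (0, 1]")
        for n, dt in self.frame_schedule:
            if n < 1 or dt <= 0:
                raise ValueError("frame_schedule blocks need n >= 1, dt > 0")


@dataclass
class TrajSimConfig:
    # (fraction, D um^2/s) per population; defaults give a majority-mobile
    # mix with a well-separated bound population
    populations: tuple = ((0.6, 0.5), (0.4, 0.005))
    frame_interval: float = 0.01526  # s (15.26 ms frame rate)
    loc_error_sd: float = 0.03  # um, per frame and axis
    mean_track_length: float = 12.0  # geometric (memoryless bleaching)
    n_molecules: int = 500
    cell_bounds: tuple[float, float] = (2.0, 1.0)  # um box, reflective
    n_frames: int = 15000  # movie length over which activations are staggered
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("populations must not be empty")
        fracs = [f for f, _ in self.populations]
        if any(f < 0 for f in fracs) or not math.isclose(sum(fracs), 1.0,
                                                         abs_tol=1e-9):
            raise ValueError("population fractions must be >= 0 and sum to 1")
        if any(d < 0 for _, d in self.populations):
            raise ValueError("diffusion coefficients must be >= 0")
        if self.mean_track_length < 1:
            raise ValueError("mean_track_length must be >= 1")


@dataclass
class GroundTruth:
    """Per-entity true values plus the generating config, file-round-trippable."""

    records: pd.DataFrame
    manifest: dict

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(prefix.with_suffix(".csv"), index=False,
                            float_format="%.17g")
        prefix.with_suffix(".manifest.json").write_text(
            json.dumps(self.manifest, indent=1, default=str))

    @classmethod
    def read(cls, prefix: str | Path) -> "GroundTruth":
        prefix = Path(prefix)
        return cls(records=pd.read_csv(prefix.with_suffix(".csv")),
                   manifest=json.loads(
                       prefix.with_suffix(".manifest.json").read_text()))


# ---------------------------------------------------------------------------
# focus stacks


def _axis_weights(n: int, center: float, sigma: float, lo: int, hi: int
                  ) -> np.ndarray:
    """Pixel-integrated 1-D Gaussian mass over integer bins lo..hi-1."""
    edges = np.arange(lo, hi + 1) - 0.5
    c = (edges - center) / (sigma * math.sqrt(2.0))
    return 0.5 * np.diff(erf(c))


def render_focus(voxels: np.ndarray, center: tuple[float, float, float],
                 total_photons: float, sigma_lateral_px: float,
                 sigma_axial_planes: float) -> None:
    """Add a pixel-integrated 3-D Gaussian of ``total_photons`` in place.

    Truncated at +/- 4 sigma per axis; mass falling outside the stack is
    lost (that is the physics of a focus near the top or bottom plane).
    """
    nz, ny, nx = voxels.shape
    cz, cy, cx = center
    bz = _RENDER_BOX_SIGMA * sigma_axial_planes
    bl = _RENDER_BOX_SIGMA * sigma_lateral_px
    z0, z1 = max(0, math.floor(cz - bz)), min(nz, math.ceil(cz + bz) + 1)
    y0, y1 = max(0, math.floor(cy - bl)), min(ny, math.ceil(cy + bl) + 1)
    x0, x1 = max(0, math.floor(cx - bl)), min(nx, math.ceil(cx + bl) + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    wz = _axis_weights(nz, cz, sigma_axial_planes, z0, z1)
    wy = _axis_weights(ny, cy, sigma_lateral_px, y0, y1)
    wx = _axis_weights(nx, cx, sigma_lateral_px, x0, x1)
    voxels[z0:z1, y0:y1, x0:x1] += (
        total_photons * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
    )


def _place_foci(rng: np.random.Generator, n_cells: int, per_cell: int,
                side: int) -> tuple[np.ndarray, np.ndarray]:
    """Lateral (y, x) centers in vertical cell strips, min-separation enforced."""
    margin = _PLACEMENT_MARGIN_PX
    strip_w = (side - 2 * margin) / n_cells
    placed: list[tuple[float, float]] = []
    cell_ids: list[int] = []
    for cell in range(n_cells):
        x_lo = margin + cell * strip_w
        x_hi = margin + (cell + 1) * strip_w
        for _ in range(per_cell):
            for _attempt in range(2000):
                y = rng.uniform(margin, side - margin)
                x = rng.uniform(x_lo, x_hi)
                if all((y - py) ** 2 + (x - px) ** 2
                       >= _PLACEMENT_MIN_SEP_PX ** 2 for py, px in placed):
                    placed.append((y, x))
                    cell_ids.append(cell)
                    break
            else:
                raise PlacementError(
                    f"could not place focus {len(placed)} at "
                    f">= {_PLACEMENT_MIN_SEP_PX} px separation (frame {side} px)"
                )
    return np.array(placed), np.array(cell_ids)


def _frame_side(n_foci: int) -> int:
    # ~2x the close-packing area at the placement separation
    return max(64, int(math.ceil(math.sqrt(n_foci) * 2.2 * _PLACEMENT_MIN_SEP_PX))
               + 2 * _PLACEMENT_MARGIN_PX)


def simulate_focus_stacks(config: StackSimConfig
                          ) -> tuple[list[ImageStack], GroundTruth]:
    """Render ``n_stacks`` stacks of membrane foci with known copy numbers."""
    rng = np.random.default_rng(config.seed)
    sigma_lat_px = config.psf_sigma_lateral / config.pixel_size
    sigma_ax_pl = config.psf_sigma_axial / config.z_spacing
    n_foci = config.cells_per_stack * config.foci_per_cell
    side = _frame_side(n_foci)
    total = config.copies_per_focus * config.unit_intensity

    stacks: list[ImageStack] = []
    rows: list[dict] = []
    for s in range(config.n_stacks):
        stack_id = f"stack{s:03d}"
        vox = np.zeros((config.z_planes, side, side))
        yx, cells = _place_foci(rng, config.cells_per_stack,
                                config.foci_per_cell, side)
        z_centers = rng.uniform(0.0, config.z_planes - 1.0, size=n_foci)
        for i in range(n_foci):
            before = vox.sum()
            render_focus(vox, (z_centers[i], yx[i, 0], yx[i, 1]),
                         total, sigma_lat_px, sigma_ax_pl)
            rows.append({
                "stack_id": stack_id, "focus_id": i, "cell_id": int(cells[i]),
                "z": z_centers[i], "y": yx[i, 0], "x": yx[i, 1],
                "copies": config.copies_per_focus,
                "signal_in_stack": vox.sum() - before,
            })
        noisy = rng.poisson(vox + config.cytosolic_background).astype(float)
        if config.read_noise_sd > 0:
            noisy += rng.normal(0.0, config.read_noise_sd, size=noisy.shape)
        np.clip(noisy, 0.0, None, out=noisy)
        stacks.append(ImageStack(voxels=noisy, pixel_size=config.pixel_size,
                                 z_spacing=config.z_spacing, stack_id=stack_id))
    truth = GroundTruth(records=pd.DataFrame(rows),
                        manifest={"kind": "focus_stacks", **asdict(config)})
    return stacks, truth


# ---------------------------------------------------------------------------
# FRAP traces


def _schedule_times(schedule) -> np.ndarray:
    intervals = np.concatenate([np.full(n, dt) for n, dt in schedule])
    return np.concatenate([[0.0], np.cumsum(intervals[:-1])])


def frap_ratio_model(t: np.ndarray, t_half: float, mobile_fraction: float,
                     bleach_depth: float) -> np.ndarray:
    """Noise-free post-bleach spot ratio, pre-bleach level 1."""
    recovered = mobile_fraction * (1.0 - np.power(2.0, -t / t_half))
    return 1.0 - bleach_depth * (1.0 - recovered)


def simulate_frap_traces(config: FrapSimConfig
                         ) -> tuple[list[FrapTrace], GroundTruth]:
    """Raw-intensity FRAP traces following a single-exponential recovery."""
    rng = np.random.default_rng(config.seed)
    t_post = _schedule_times(config.frame_schedule)
    dt_pre = config.frame_schedule[0][1]
    t_pre = -dt_pre * np.arange(config.pre_frames, 0, -1)
    times = np.concatenate([t_pre, t_post])
    i_bg, i_cell = 100.0, 300.0  # arbitrary camera levels; ratios cancel them

    traces: list[FrapTrace] = []
    rows: list[dict] = []
    for k in range(config.n_traces):
        r = np.concatenate([
            np.ones(config.pre_frames),
            frap_ratio_model(t_post, config.true_t_half,
                             config.mobile_fraction, config.bleach_depth),
        ])
        if config.noise_sd > 0:
            r = r + rng.normal(0.0, config.noise_sd, size=r.size)
        trace_id = f"trace{k:03d}"
        traces.append(FrapTrace(
            times=times,
            i_spot=i_bg + r * (i_cell - i_bg),
            i_cell=np.full(times.size, i_cell),
            i_bg=np.full(times.size, i_bg),
            bleach_index=config.pre_frames,
            trace_id=trace_id,
        ))
        rows.append({"trace_id": trace_id, "t_half": config.true_t_half,
                     "mobile_fraction": config.mobile_fraction,
                     "plateau": 1.0 - config.mobile_fraction,
                     "bleach_depth": config.bleach_depth})
    truth = GroundTruth(records=pd.DataFrame(rows),
                        manifest={"kind": "frap_traces", **asdict(config)})
    return traces, truth


# ---------------------------------------------------------------------------
# trajectories


def _reflect(v: np.ndarray, length: float) -> np.ndarray:
    v = np.mod(v, 2.0 * length)
    return np.where(v > length, 2.0 * length - v, v)


def simulate_trajectories(config: TrajSimConfig
                          ) -> tuple[pd.DataFrame, GroundTruth]:
    """Two-population Brownian trajectories as a localization table.

    Returns (localizations, ground truth); the table carries ``molecule_id``
    for validation but analysis input is only (frame, x_um, y_um).
    """
    rng = np.random.default_rng(config.seed)
    fracs = np.array([f for f, _ in config.populations])
    ds = np.array([d for _, d in config.populations])
    lx, ly = config.cell_bounds

    loc_rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for m in range(config.n_molecules):
        pop = int(rng.choice(fracs.size, p=fracs))
        d = float(ds[pop])
        length = int(rng.geometric(1.0 / config.mean_track_length))
        start = int(rng.integers(0, max(1, config.n_frames - length)))
        step_sd = math.sqrt(2.0 * d * config.frame_interval)
        x = np.empty(length)
        y = np.empty(length)
        x[0] = rng.uniform(0.0, lx)
        y[0] = rng.uniform(0.0, ly)
        if length > 1:
            dx = rng.normal(0.0, step_sd, size=length - 1)
            dy = rng.normal(0.0, step_sd, size=length - 1)
            x[1:] = _reflect(x[0] + np.cumsum(dx), lx)
            y[1:] = _reflect(y[0] + np.cumsum(dy), ly)
        if config.loc_error_sd > 0:
            x = x + rng.normal(0.0, config.loc_error_sd, size=length)
            y = y + rng.normal(0.0, config.loc_error_sd, size=length)
        loc_rows.append(pd.DataFrame({
            "frame": start + np.arange(length), "x_um": x, "y_um": y,
            "molecule_id": m,
        }))
        truth_rows.append({"molecule_id": m, "population": pop,
                           "D": d, "length": length, "start_frame": start})
    locs = (pd.concat(loc_rows, ignore_index=True)
            .sort_values(["frame", "molecule_id"], kind="stable")
            .reset_index(drop=True))
    truth = GroundTruth(records=pd.DataFrame(truth_rows),
                        manifest={"kind": "trajectories", **asdict(config)})
    return locs, truth
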