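"""Single-particle tracking: linking, diffusion estimation, mobility classes.

Localizations from sptPALM imaging (one molecule photoactivated at a time,
frames every 15.26 ms) are linked frame-to-frame into tracks, each track is
summarized by its single-step diffusion coefficient

    D* = < (dx^2 + dy^2) / (4 dt) >  over consecutive steps,

and molecules are classified as mobile (D* strictly above 0.15 um^2/s) or
bound. With localization error sigma_loc added independently per frame,
D* is biased upward by sigma_loc^2/dt: E[D*] = D + sigma_loc^2/dt. No
correction is applied (classification thresholds are set with the bias in
mind); the formula is documented and tested instead.

Linking is per-frame-pair optimal: among assignments whose displacements
are all <= max_displacement, the maximum-cardinality matching of minimal
total displacement is chosen (Hungarian with a prohibitive cost on gated
pairs). A molecule that finds no partner in the next frame ends its track;
there is no gap closing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

DEFAULT_FRAME_INTERVAL_S = 0.01526  # 15.26 ms frame rate
DEFAULT_MIN_TRACK_LENGTH = 5
DEFAULT_D_THRESHOLD = 0.15  # um^2/s, bound/mobile split on D*
DEFAULT_MAX_DISPLACEMENT_UM = 0.5  # ~5 sigma of a 0.15 um^2/s step at 15.26 ms

_GATE_COST = 1.0e6  # dominates any feasible total displacement


@dataclass
class Track:
    """Ordered localizations of one molecule; consecutive frames, no gaps."""

    frames: np.ndarray  # int, consecutive
    x: np.ndarray  # um
    y: np.ndarray  # um
    track_id: int = -1
    d_star: float = float("nan")  # um^2/s, filled by single_step_D
    label: str = ""  # "bound" | "mobile"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frames.size >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be consecutive (no gaps)")

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass
class MobilitySummary:
    n_tracks: int
    mobile_fraction: float
    track_table: pd.DataFrame  # track_id, length, D_star, label
    step_d_values: np.ndarray  # pooled per-step (dx^2+dy^2)/(4 dt)
    bound_positions: np.ndarray  # (n_bound, 2) mean (x, y) um of bound tracks


def link_tracks(localizations: pd.DataFrame,
                max_displacement: float = DEFAULT_MAX_DISPLACEMENT_UM,
                min_track_length: int = DEFAULT_MIN_TRACK_LENGTH) -> list[Track]:
    """Link a (frame, x_um, y_um) table into tracks.

    Frame pairs are matched by minimal total displacement (Hungarian) with a
    hard gate at ``max_displacement``; tracks shorter than
    ``min_track_length`` are discarded.
    """
    if len(localizations) == 0:
        return []
    df = localizations.sort_values("frame", kind="stable")
    frames = df["frame"].to_numpy(dtype=int)
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)

    open_tracks: list[dict] = []  # last frame == previous frame processed
    closed: list[dict] = []
    prev_frame: int | None = None

    for f in np.unique(frames):
        pts = xy[frames == f]
        if prev_frame is not None and f == prev_frame + 1 and open_tracks:
            ends = np.array([[tr["x"][-1], tr["y"][-1]] for tr in open_tracks])
            dist = np.linalg.norm(ends[:, None, :] - pts[None, :, :], axis=2)
            cost = np.where(dist <= max_displacement, dist, _GATE_COST)
            rows, cols = linear_sum_assignment(cost)
            matched_tracks, matched_pts = set(), set()
            for i, j in zip(rows, cols):
                if dist[i, j] <= max_displacement:
                    tr = open_tracks[i]
                    tr["frames"].append(int(f))
                    tr["x"].append(float(pts[j, 0]))
                    tr["y"].append(float(pts[j, 1]))
                    matched_tracks.add(i)
                    matched_pts.add(j)
            closed.extend(tr for i, tr in enumerate(open_tracks)
                          if i not in matched_tracks)
            open_tracks = [tr for i, tr in enumerate(open_tracks)
                           if i in matched_tracks]
            new_pts = [j for j in range(len(pts)) if j not in matched_pts]
        else:
            closed.extend(open_tracks)
            open_tracks = []
            new_pts = range(len(pts))
        for j in new_pts:
            open_tracks.append({"frames": [int(f)],
                                "x": [float(pts[j, 0])],
                                "y": [float(pts[j, 1])]})
        prev_frame = int(f)
    closed.extend(open_tracks)

    tracks = []
    for tr in closed:
        if len(tr["frames"]) >= min_track_length:
            tracks.append(Track(frames=np.array(tr["frames"]),
                                x=np.array(tr["x"]), y=np.array(tr["y"]),
                                track_id=len(tracks)))
    return tracks


def single_step_D(track: Track,
                  frame_interval: float = DEFAULT_FRAME_INTERVAL_S) -> float:
    """Single-step diffusion coefficient: mean of (dx^2 + dy^2)/(4 dt)."""
    if len(track) < 2:
        raise ValueError("need >= 2 localizations for a diffusion estimate")
    sq = np.diff(track.x) ** 2 + np.diff(track.y) ** 2
    d = float(np.mean(sq) / (4.0 * frame_interval))
    track.d_star = d
    return d


def step_d_values(track: Track,
                  frame_interval: float = DEFAULT_FRAME_INTERVAL_S) -> np.ndarray:
    """Per-step apparent diffusion coefficients (for pooled histograms)."""
    sq = np.diff(track.x) ** 2 + np.diff(track.y) ** 2
    return sq / (4.0 * frame_interval)


def classify_mobility(tracks: list[Track],
                      threshold: float = DEFAULT_D_THRESHOLD,
                      frame_interval: float = DEFAULT_FRAME_INTERVAL_S
                      ) -> MobilitySummary:
    """Label tracks mobile (D* > threshold, strict) or bound; summarize.

    bound_positions are the mean localization of each bound track — for the
    injectisome these concentrate in membrane foci.
    """
    if not tracks:
        raise ValueError("classify_mobility needs at least one track")
    rows, pooled, bound_xy = [], [], []
    n_mobile = 0
    for tr in tracks:
        d = single_step_D(tr, frame_interval)
        mobile = d > threshold
        tr.label = "mobile" if mobile else "bound"
        n_mobile += int(mobile)
        if not mobile:
            bound_xy.append([float(tr.x.mean()), float(tr.y.mean())])
        rows.append({"track_id": tr.track_id, "length": len(tr),
                     "D_star": d, "label": tr.label})
        pooled.append(step_d_values(tr, frame_interval))
    return MobilitySummary(
        n_tracks=len(tracks),
        mobile_fraction=n_mobile / len(tracks),
        track_table=pd.DataFrame(rows),
        step_d_values=np.concatenate(pooled),
        bound_positions=(np.array(bound_xy) if bound_xy
                         else np.empty((0, 2))),
    )


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format (track_id, frame, x_um, y_um) table."""
    if not tracks:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
    return pd.concat([
        pd.DataFrame({"track_id": tr.track_id, "frame": tr.frames,
                      "x_um": tr.x, "y_um": tr.y})
        for tr in tracks
    ], ignore_index=True)
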