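"""Tracking-parameter estimation and trajectory linking.

The linker is a greedy nearest-neighbour frame-to-frame assignment with gap
closing: candidate links within ``radius_factor * exp_displacement`` of a
track's last position are accepted in order of increasing distance, each
localization joining at most one track. This stands in for probabilistic
motion-model linkers whose internals are not published; the per-frame
mode-switching probability ``p_switch`` is carried in the parameter set for
fidelity with that parameterization but is not used by the greedy assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import EXP_DISPLACEMENT_NM, P_BLEACH

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class TrackingParams:
    """Per-dataset linking parameters (lengths in nm, probabilities per frame)."""

    precision: float = 20.0  # nm, per cell
    exp_noise_rate: float = 0.0  # false localizations / frame / µm², per cell
    diffraction_limit: float = 17.0  # nm, global
    exp_displacement: float = EXP_DISPLACEMENT_NM["HER2"]  # nm, global
    p_bleach: float = P_BLEACH["HER2"]  # global
    p_switch: float = 0.01  # carried for fidelity; unused by the greedy linker
    max_gap_frames: int = 1
    radius_factor: float = 3.0

    def __post_init__(self) -> None:
        for p in (self.p_bleach, self.p_switch):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.exp_displacement <= 0 or self.precision < 0:
            raise ValueError("lengths must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")


@dataclass
class Segment:
    """A linked trajectory segment; the unit of MSD analysis."""

    cell_id: int
    segment_id: int
    frames: np.ndarray  # strictly increasing
    xy: np.ndarray  # (n, 2) µm
    uncertainty: np.ndarray  # µm
    mode: Optional[str] = None  # assigned downstream

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> int:
        """Duration in frames, inclusive of both ends."""
        return int(self.frames[-1] - self.frames[0] + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "segment_id": self.segment_id,
                "frame": self.frames,
                "x_um": self.xy[:, 0],
                "y_um": self.xy[:, 1],
                "uncertainty_um": self.uncertainty,
            }
        )


def estimate_p_bleach(durations: Sequence[int], n_censored: int = 0) -> float:
    """Geometric maximum-likelihood estimate of the per-frame bleaching
    probability from trajectory durations (frames): p = n / sum(durations).

    ``n_censored`` counts trajectories cut off by the end of the movie rather
    than by bleaching; with right-censoring the MLE becomes
    (n − n_censored) / sum(durations) (deaths over total exposure).
    """
    durations = np.asarray(durations)
    if durations.size == 0:
        raise ValueError("no durations provided")
    if np.any(durations < 1):
        raise ValueError("durations must be >= 1 frame")
    if not 0 <= n_censored <= durations.size:
        raise ValueError("n_censored out of range")
    return float((durations.size - n_censored) / durations.sum())


def estimate_precision(locs: pd.DataFrame) -> float:
    """Per-cell localization precision: mean of the uncertainty column (nm)."""
    if "uncertainty" not in locs.columns:
        raise ValueError("localization table lacks an 'uncertainty' column")
    return float(locs["uncertainty"].mean() * NM_PER_UM)


def estimate_exp_displacement(locs: pd.DataFrame) -> float:
    """Expected frame-to-frame displacement (nm) from conservative links.

    For each consecutive-frame pair, localizations are linked only when they
    are mutually nearest neighbours; the mean linked distance is returned.
    Ambiguity-prone one-sided matches are dropped, making the estimate robust
    to moderate density.
    """
    by_frame = {f: g[["x", "y"]].to_numpy() for f, g in locs.groupby("frame")}
    dists: list[np.ndarray] = []
    for f, a in by_frame.items():
        b = by_frame.get(f + 1)
        if b is None or len(a) == 0 or len(b) == 0:
            continue
        ta, tb = cKDTree(a), cKDTree(b)
        d_ab, j_ab = tb.query(a)  # for each point in a: nearest in b
        _, i_ba = ta.query(b)  # for each point in b: nearest in a
        mutual = i_ba[j_ab] == np.arange(len(a))
        if mutual.any():
            dists.append(d_ab[mutual])
    if not dists:
        raise ValueError("no linkable consecutive-frame pairs")
    return float(np.concatenate(dists).mean() * NM_PER_UM)


def estimate_noise_rate(locs: pd.DataFrame, fov_area_um2: float) -> float:
    """Localization density per frame per µm² (proxy for the false-positive
    rate parameter of probabilistic linkers)."""
    n_frames = locs["frame"].nunique()
    if n_frames == 0 or fov_area_um2 <= 0:
        raise ValueError("empty table or non-positive area")
    return float(len(locs) / (n_frames * fov_area_um2))


def estimate_diffraction_limit(locs: pd.DataFrame) -> float:
    """1st percentile of same-frame nearest-neighbour distances (nm)."""
    nn = []
    for _, g in locs.groupby("frame"):
        pts = g[["x", "y"]].to_numpy()
        if len(pts) < 2:
            continue
        d, _ = cKDTree(pts).query(pts, k=2)
        nn.append(d[:, 1])
    if not nn:
        raise ValueError("no frames with >= 2 localizations")
    return float(np.percentile(np.concatenate(nn), 1) * NM_PER_UM)


def link_localizations(
    locs: pd.DataFrame, params: TrackingParams, cell_id: int = 0
) -> list[Segment]:
    """Link a localization table (µm) into trajectory segments.

    Greedy nearest-neighbour assignment frame by frame, search radius
    ``radius_factor * exp_displacement``; a track missing up to
    ``max_gap_frames`` consecutive frames may still be extended (gap closing).
    Every localization belongs to at most one segment. The result is invariant
    to input row order (rows are canonically sorted first).
    """
    if locs.empty:
        return []
    locs = locs.sort_values(["frame", "x", "y"], kind="mergesort", ignore_index=True)
    radius = params.radius_factor * params.exp_displacement / NM_PER_UM  # µm

    frames = locs["frame"].to_numpy()
    xy = locs[["x", "y"]].to_numpy()
    unc = (
        locs["uncertainty"].to_numpy()
        if "uncertainty" in locs.columns
        else np.zeros(len(locs))
    )

    # active tracks: lists of row indices; last position & frame cached
    track_rows: list[list[int]] = []
    track_last_xy: list[np.ndarray] = []
    track_last_frame: list[int] = []
    active: list[int] = []

    order = np.unique(frames)
    row_by_frame = {f: np.nonzero(frames == f)[0] for f in order}
    for f in order:
        # retire tracks whose gap budget is exhausted before matching
        active = [t for t in active if f - track_last_frame[t] <= params.max_gap_frames + 1]
        rows = row_by_frame[f]
        pts = xy[rows]
        # candidate (distance, track, point) triples within the search radius
        cand: list[tuple[float, int, int]] = []
        if active and len(rows):
            last = np.array([track_last_xy[t] for t in active])
            tree = cKDTree(last)
            pairs = tree.query_ball_point(pts, r=radius)
            for pi, tlist in enumerate(pairs):
                for ti in tlist:
                    t = active[ti]
                    d = float(np.hypot(*(pts[pi] - track_last_xy[t])))
                    cand.append((d, t, pi))
        cand.sort()
        used_tracks: set[int] = set()
        used_pts: set[int] = set()
        for d, t, pi in cand:
            if t in used_tracks or pi in used_pts:
                continue
            used_tracks.add(t)
            used_pts.add(pi)
            track_rows[t].append(int(rows[pi]))
            track_last_xy[t] = pts[pi]
            track_last_frame[t] = int(f)
        for pi in range(len(rows)):
            if pi not in used_pts:
                t = len(track_rows)
                track_rows.append([int(rows[pi])])
                track_last_xy.append(pts[pi])
                track_last_frame.append(int(f))
                active.append(t)

    segments = []
    for sid, rows_list in enumerate(track_rows):
        idx = np.asarray(rows_list)
        segments.append(
            Segment(
                cell_id=cell_id,
                segment_id=sid,
                frames=frames[idx].astype(int),
                xy=xy[idx],
                uncertainty=unc[idx],
            )
        )
    return segments


def segments_to_table(segments: Iterable[Segment]) -> pd.DataFrame:
    """Concatenate segments into the on-disk table
    (cell_id, segment_id, frame, x_um, y_um, uncertainty_um)."""
    frames = [s.to_frame() for s in segments]
    if not frames:
        return pd.DataFrame(
            columns=["cell_id", "segment_id", "frame", "x_um", "y_um", "uncertainty_um"]
        )
    return pd.concat(frames, ignore_index=True)


def table_to_segments(table: pd.DataFrame) -> list[Segment]:
    segs = []
    for (cell_id, seg_id), g in table.groupby(["cell_id", "segment_id"], sort=True):
        g = g.sort_values("frame")
        segs.append(
            Segment(
                cell_id=int(cell_id),
                segment_id=int(seg_id),
                frames=g["frame"].to_numpy(dtype=int),
                xy=g[["x_um", "y_um"]].to_numpy(),
                uncertainty=g["uncertainty_um"].to_numpy(),
            )
        )
    return segs
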