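"""Synthetic single-particle-tracking data with known ground truth.

Emulates the study's acquisition: per cell a 1000-frame movie at 20 ms
integration, emitters appearing on the basal membrane, surviving a geometric
number of frames (photobleaching), and moving in one of three modes —
immobile, confined (reflecting circular corral) or free 2D Brownian motion.
Recorded localizations are true positions plus isotropic Gaussian noise.
Cells are "imaged" sequentially over ~30 minutes with the ligand added after
the fifth cell, so each cell carries a timestamp relative to ligand addition
and draws its mode fractions from the response profile at that time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ResponseProfile, SimulationConfig

MODES = ("immobile", "confined", "free")


@dataclass
class EmitterTruth:
    emitter_id: int
    mode: str
    D: float  # µm²/s
    start_frame: int
    n_frames: int  # trajectory duration in frames
    positions: np.ndarray  # (n_frames, 2) true positions, µm

    @property
    def bleach_frame(self) -> int:
        return self.start_frame + self.n_frames - 1


@dataclass
class GroundTruth:
    """Per-cell ground truth: emitter-level tracks plus the cell metadata."""

    t_min: float  # minutes relative to ligand addition
    fractions: tuple[float, float, float]  # (f_imm, f_conf, f_free) used
    D_free: float  # µm²/s after any response dip
    emitters: list[EmitterTruth] = field(default_factory=list)

    def mode_counts(self) -> dict[str, int]:
        counts = {m: 0 for m in MODES}
        for e in self.emitters:
            counts[e.mode] += 1
        return counts

    def to_jsonable(self) -> dict:
        return {
            "t_min": self.t_min,
            "fractions": list(self.fractions),
            "D_free": self.D_free,
            "emitters": [
                {
                    "id": e.emitter_id,
                    "mode": e.mode,
                    "D": e.D,
                    "start_frame": e.start_frame,
                    "n_frames": e.n_frames,
                    "bleach_frame": e.bleach_frame,
                }
                for e in self.emitters
            ],
        }


def _response_kernel(t: float, t_peak: float, tau: float, plateau_level: float) -> float:
    """Rise/relaxation kernel: 0 before t=0, linear ramp to 1 at t_peak,
    then exponential relaxation toward plateau_level (fraction of the peak)."""
    if t < 0:
        return 0.0
    if t <= t_peak:
        return t / t_peak
    return plateau_level + (1.0 - plateau_level) * math.exp(-(t - t_peak) / tau)


def response_fractions(
    t: float, profile: ResponseProfile
) -> tuple[float, float, float]:
    """Mode fractions (immobile, confined, free) at time t (minutes, ligand at 0).

    Before ligand addition the baseline fractions are returned; afterwards the
    immobile fraction ramps to its peak at ``t_peak`` and relaxes exponentially
    toward the plateau, the confined fraction stays fixed, and the free
    fraction absorbs the complement.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    rise = profile.peak_f_imm - profile.baseline_f_imm
    if rise > 0:
        plateau_level = (profile.plateau_f_imm - profile.baseline_f_imm) / rise
    else:
        plateau_level = 1.0
    k = _response_kernel(t, profile.t_peak, profile.decay_tau, plateau_level)
    f_imm = profile.baseline_f_imm + rise * k
    f_conf = profile.f_conf
    f_free = 1.0 - f_imm - f_conf
    if f_free < -1e-12:
        raise ValueError("response profile yields negative free fraction")
    return (f_imm, f_conf, max(f_free, 0.0))


def response_d_free(t: float, profile: ResponseProfile, d_free: float) -> float:
    """Free diffusion coefficient at time t: the mobility dip trails the
    immobile-fraction response by ``t_D_lag`` minutes with the same kernel."""
    rise = profile.peak_f_imm - profile.baseline_f_imm
    plateau_level = (profile.plateau_f_imm - profile.baseline_f_imm) / rise if rise > 0 else 1.0
    k = _response_kernel(t - profile.t_D_lag, profile.t_peak, profile.decay_tau, plateau_level)
    return d_free * (1.0 - profile.D_free_dip_fraction * k)


def _confined_walk(
    rng: np.random.Generator, n: int, d: float, dt: float, radius: float, center: np.ndarray
) -> np.ndarray:
    """2D random walk reflected at a disc of the given radius around center."""
    pos = np.empty((n, 2))
    # start uniformly inside the corral
    r = radius * math.sqrt(rng.uniform())
    theta = rng.uniform(0, 2 * math.pi)
    cur = np.array([r * math.cos(theta), r * math.sin(theta)])
    pos[0] = cur
    if n > 1:
        steps = rng.normal(0.0, math.sqrt(2.0 * d * dt), size=(n - 1, 2))
        for i, step in enumerate(steps, start=1):
            cur = cur + step
            norm = float(np.hypot(cur[0], cur[1]))
            if norm > radius:
                # radial fold-back; clamp to the rim for pathological steps
                folded = 2.0 * radius - norm
                cur = cur * (max(folded, 0.0) / norm if folded > 0 else radius / norm)
            pos[i] = cur
    return pos + center


def simulate_cell(
    cfg: SimulationConfig,
    t_cell: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one cell imaged at t_cell minutes relative to ligand addition.

    Returns the localization table (columns frame, x, y, uncertainty, id; µm)
    and the ground truth. Modes are drawn per emitter from the response
    profile evaluated at t_cell; trajectories last a geometric number of
    frames (p_bleach), truncated by the movie end.
    """
    profile = cfg.profile()
    fractions = response_fractions(t_cell, profile)
    if cfg.cell_fraction_jitter > 0:
        fractions = _jitter_fractions(fractions, cfg.cell_fraction_jitter, rng)
    d_free = response_d_free(t_cell, profile, cfg.D_free)

    fov = np.asarray(cfg.fov, dtype=float)
    sigma = cfg.sigma_loc
    modes = rng.choice(3, size=cfg.n_emitters_per_cell, p=np.asarray(fractions))
    durations = rng.geometric(cfg.p_bleach, size=cfg.n_emitters_per_cell)
    if cfg.staggered_starts:
        starts = rng.integers(0, cfg.n_frames, size=cfg.n_emitters_per_cell)
    else:
        starts = np.zeros(cfg.n_emitters_per_cell, dtype=int)

    emitters: list[EmitterTruth] = []
    rows_frame, rows_xy, rows_id = [], [], []
    for eid in range(cfg.n_emitters_per_cell):
        start = int(starts[eid])
        n = int(min(durations[eid], cfg.n_frames - start))
        mode = MODES[modes[eid]]
        if mode == "immobile":
            d_true = 0.0
            origin = rng.uniform(0, fov, size=2)
            pos = np.tile(origin, (n, 1))
        elif mode == "confined":
            d_true = cfg.D_conf
            margin = cfg.confinement_radius
            center = rng.uniform(margin, fov - margin, size=2)
            pos = _confined_walk(rng, n, d_true, cfg.dt, cfg.confinement_radius, center)
        else:
            d_true = d_free
            origin = rng.uniform(0, fov, size=2)
            steps = rng.normal(0.0, math.sqrt(2.0 * d_true * cfg.dt), size=(n, 2))
            steps[0] = 0.0
            pos = origin + np.cumsum(steps, axis=0)
        emitters.append(EmitterTruth(eid, mode, d_true, start, n, pos))
        noisy = pos + rng.normal(0.0, sigma, size=pos.shape) if sigma > 0 else pos
        rows_frame.append(np.arange(start, start + n))
        rows_xy.append(noisy)
        rows_id.append(np.full(n, eid))

    table = pd.DataFrame(
        {
            "frame": np.concatenate(rows_frame),
            "x": np.concatenate(rows_xy)[:, 0],
            "y": np.concatenate(rows_xy)[:, 1],
            "uncertainty": sigma,
            "id": np.concatenate(rows_id),
        }
    ).sort_values(["frame", "x", "y"], kind="mergesort", ignore_index=True)
    truth = GroundTruth(t_min=t_cell, fractions=fractions, D_free=d_free, emitters=emitters)
    return table, truth


def _jitter_fractions(
    fractions: tuple[float, float, float], sd: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Optional cell-to-cell heterogeneity: multiplicative log-normal jitter
    on the mode weights, renormalized."""
    w = np.asarray(fractions) * np.exp(rng.normal(0.0, sd, size=3))
    w = w / w.sum()
    return tuple(w)


def cell_timestamps(cfg: SimulationConfig) -> np.ndarray:
    """Timestamps (minutes, relative to ligand addition) of the sequential
    acquisition: n_cells uniformly spaced over span_min, starting
    ligand_time minutes before the ligand is added."""
    spacing = cfg.span_min / cfg.n_cells
    return -cfg.ligand_time + spacing * np.arange(cfg.n_cells)


def simulate_experiment(
    cfg: SimulationConfig,
) -> list[tuple[int, float, str, pd.DataFrame, GroundTruth]]:
    """Simulate the sequential multi-cell experiment.

    Returns one record per cell: (cell_id, t_min, condition, localization
    table, ground truth). Cells with t_min < 0 are "resting", the rest
    "stimulated". Deterministic for a fixed cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    for cell_id, t in enumerate(cell_timestamps(cfg)):
        table, truth = simulate_cell(cfg, float(t), rng)
        condition = "resting" if t < 0 else "stimulated"
        out.append((cell_id, float(t), condition, table, truth))
    return out
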