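"""MSD analysis, diffusion-coefficient estimation and mode classification.

Per segment: the time-averaged MSD, an ordinary least-squares fit of its
first ``n_fit`` points (MSD(t) = 4 D t + 4 sigma_dyn²), and a three-state
label. A segment is immobile when its fitted D falls below the threshold
D_min derived from the third quartile of the dynamic localization precision;
otherwise an anomalous-diffusion fit MSD(t) = 4 Γ t^α + c decides confined
versus free: confined when the fitted exponent falls below a critical value
calibrated on the null distribution of the same estimator for free Brownian
segments of equal length (see ALPHA_CRIT and scripts/calibrate_classifier.py).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import RunConfig
from .tracking import Segment

MODES = ("immobile", "confined", "free")

#: Critical values of the anomalous exponent for the confined call: the
#: size-q quantile of the estimator's null distribution on free Brownian
#: segments of each length (localization noise 20 nm, dt 20 ms, D pooled over
#: 0.05-0.3 µm²/s). Regenerate with scripts/calibrate_classifier.py. A Wald
#: interval from the fit covariance is miscalibrated here: MSD points are
#: strongly correlated and the null distribution of the exponent is
#: left-skewed, so the test size is set on the null quantiles directly.
ALPHA_CRIT = {
    "lengths": [20, 25, 30, 40, 50, 70, 100, 150, 200, 300, 500, 800],
    0.025: [0.3, 0.355, 0.421, 0.462, 0.511, 0.543, 0.581, 0.64, 0.657, 0.709, 0.72, 0.759],
    0.05: [0.384, 0.457, 0.493, 0.514, 0.571, 0.598, 0.631, 0.679, 0.701, 0.739, 0.76, 0.789],
    0.075: [0.455, 0.497, 0.527, 0.555, 0.603, 0.638, 0.668, 0.706, 0.735, 0.757, 0.78, 0.801],
    0.1: [0.5, 0.542, 0.57, 0.594, 0.631, 0.674, 0.694, 0.732, 0.755, 0.773, 0.798, 0.817],
}


def alpha_critical(length: int, size: float = 0.05) -> float:
    """Length-interpolated critical exponent for the confined-vs-free test."""
    if size not in ALPHA_CRIT:
        raise ValueError(f"no calibration for test size {size}; have {sorted(k for k in ALPHA_CRIT if k != 'lengths')}")
    return float(np.interp(length, ALPHA_CRIT["lengths"], ALPHA_CRIT[size]))


@dataclass(frozen=True)
class MSDCurve:
    lag_times: np.ndarray  # seconds, n*dt
    msd: np.ndarray  # µm²
    counts: np.ndarray  # displacement pairs per lag

    def __post_init__(self):
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be strictly increasing")


@dataclass(frozen=True)
class DiffusionFit:
    D: float  # µm²/s, slope/4; may be negative for noise-dominated segments
    intercept: float  # µm²
    sigma_dyn: Optional[float]  # µm, sqrt(intercept/4) when intercept > 0
    residual: float  # sum of squared fit residuals


@dataclass(frozen=True)
class ModeLabel:
    mode: str  # immobile | confined | free
    alpha: Optional[float]  # anomalous exponent (mobile labels only)
    alpha_se: Optional[float]
    d_min: float  # threshold used


@dataclass
class CellSummary:
    cell_id: int
    t_min: float
    condition: str
    n_segments: int
    D_global: float  # mean of segment D, µm²/s
    f_imm: float
    f_conf: float
    f_free: float
    D_imm: float
    D_conf: float
    D_free: float
    mean_segment_length: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compute_msd(
    seg: Segment,
    max_lag_fraction: float = 0.6,
    n_fit_floor: int = 4,
    max_lag: Optional[int] = None,
) -> MSDCurve:
    """Time-averaged MSD of a segment.

    msd(n) = mean over i of |r_{i+n} - r_i|², computed on frame lags so that
    segments with internal gaps contribute only pairs whose both endpoints
    exist. Lags run up to ``max_lag_fraction`` of the segment length (at
    least ``n_fit_floor`` lags when the segment allows).
    """
    length = len(seg)
    if length < 2:
        raise ValueError("segment must have at least 2 localizations")
    span = int(seg.frames[-1] - seg.frames[0])
    if max_lag is None:
        max_lag = min(span, max(n_fit_floor, int(math.floor(max_lag_fraction * length))))
    max_lag = min(max_lag, span)

    rel = seg.frames - seg.frames[0]
    pos = np.full((span + 1, 2), np.nan)
    pos[rel] = seg.xy
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    counts = np.empty(max_lag, dtype=int)
    for k, n in enumerate(lags):
        disp = pos[n:] - pos[:-n]
        sq = disp[:, 0] ** 2 + disp[:, 1] ** 2
        valid = ~np.isnan(sq)
        counts[k] = int(valid.sum())
        msd[k] = float(sq[valid].mean()) if counts[k] else np.nan
    keep = counts > 0
    dt_placeholder = 1.0  # lag axis in frames here; seconds applied by caller
    return MSDCurve(lag_times=lags[keep] * dt_placeholder, msd=msd[keep], counts=counts[keep])


def msd_in_seconds(curve: MSDCurve, dt: float) -> MSDCurve:
    """Rescale a frame-lag MSD curve to seconds."""
    return MSDCurve(lag_times=curve.lag_times * dt, msd=curve.msd, counts=curve.counts)


def fit_diffusion_coefficient(msd: MSDCurve, n_fit: int = 4, dt: float = 1.0) -> DiffusionFit:
    """OLS line through the first ``n_fit`` MSD points: D = slope/4.

    The intercept estimates 4 sigma_dyn²; sigma_dyn is defined only when the
    intercept is positive. Negative D is retained (noise), never clipped.
    If the curve's lag axis is in frames, dt converts it to seconds.
    """
    if len(msd.msd) < n_fit:
        raise ValueError(f"need at least {n_fit} MSD points, got {len(msd.msd)}")
    t = np.asarray(msd.lag_times[:n_fit], dtype=float) * dt
    y = np.asarray(msd.msd[:n_fit], dtype=float)
    tm, ym = t.mean(), y.mean()
    slope = float(np.sum((t - tm) * (y - ym)) / np.sum((t - tm) ** 2))
    intercept = float(ym - slope * tm)
    resid = float(np.sum((y - (slope * t + intercept)) ** 2))
    sigma_dyn = math.sqrt(intercept / 4.0) if intercept > 0 else None
    return DiffusionFit(D=slope / 4.0, intercept=intercept, sigma_dyn=sigma_dyn, residual=resid)


def compute_d_min(sigma_dyn_values: Sequence[float], dt: float, n_fit: int = 4) -> float:
    """Immobile threshold from the third quartile of the dynamic localization
    precision: D_min = Q3² / (4 dt), the apparent diffusion coefficient a
    noise-only emitter shows over one frame interval.

    Q3 uses the linear-interpolation quartile convention (type 7), fixed
    because it feeds a classification threshold. Published per-target values
    are available as overrides via RunConfig(d_min_mode="override").
    """
    vals = np.asarray([v for v in sigma_dyn_values if v is not None and np.isfinite(v)])
    if vals.size == 0:
        raise ValueError("no defined sigma_dyn values")
    q3 = float(np.percentile(vals, 75))  # numpy default = linear (type 7)
    return q3 * q3 / (4.0 * dt)


def _anomalous_fit(
    t: np.ndarray, y: np.ndarray, n_points: int
) -> tuple[float, float]:
    """Fit msd = 4*Gamma*t**alpha + c; return (alpha, SE(alpha)).

    Points are weighted by the relative standard deviation of a time-averaged
    Brownian MSD (Qian-type error model); alpha is bounded to [0.01, 2].
    The Wald SE is informational only — classification uses the calibrated
    null quantiles. Falls back to a log-log OLS slope when the fit fails.
    """
    lags = t / t[0]  # lag index, assuming the first lag is 1 frame

    def model(tt, gamma, alpha, c):
        return 4.0 * gamma * np.power(tt, alpha) + c

    sig = np.maximum(y, 1e-12) * np.sqrt(
        (2 * lags**2 + 1) / (3 * lags * (n_points - lags + 1))
    )
    g0 = max((y[-1] - y[0]) / (4.0 * (t[-1] - t[0])), 1e-8)
    p0 = (g0, 1.0, max(float(y[0] - 4.0 * g0 * t[0]), 1e-12))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model, t, y, p0=p0, sigma=sig,
                bounds=([1e-9, 0.01, 0.0], [np.inf, 2.0, np.inf]), maxfev=3000,
            )
        alpha = float(popt[1])
        se = float(np.sqrt(pcov[1, 1]))
        if np.isfinite(alpha):
            return alpha, se if np.isfinite(se) else float("nan")
    except (RuntimeError, ValueError):
        pass
    # log-log fallback (positive msd values only)
    mask = y > 0
    if mask.sum() < 3:
        return 0.0, 0.0
    lt, ly = np.log(t[mask]), np.log(y[mask])
    ltm, lym = lt.mean(), ly.mean()
    sxx = np.sum((lt - ltm) ** 2)
    slope = float(np.sum((lt - ltm) * (ly - lym)) / sxx)
    resid = ly - (lym + slope * (lt - ltm))
    dof = max(mask.sum() - 2, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return slope, se


def classify_segment(
    fit: DiffusionFit,
    msd: MSDCurve,
    d_min: float,
    dt: float = 1.0,
    size: float = 0.05,
    n_points: Optional[int] = None,
) -> ModeLabel:
    """Three-state mode label.

    Immobile iff D < d_min (strict; a segment exactly at the threshold is
    mobile). Degenerate all-zero MSD is immobile by convention. Otherwise the
    anomalous exponent α of msd = 4Γt^α + c over the curve's lags decides:
    confined iff α falls below the length-calibrated null quantile of the
    estimator at the given test size, else free.
    """
    if np.allclose(msd.msd, 0.0):
        return ModeLabel(mode="immobile", alpha=None, alpha_se=None, d_min=d_min)
    if fit.D < d_min:
        return ModeLabel(mode="immobile", alpha=None, alpha_se=None, d_min=d_min)
    t = np.asarray(msd.lag_times, dtype=float) * dt
    if n_points is None:
        # recover segment length from the lag bookkeeping (counts at lag 1)
        n_points = int(msd.counts[0]) + 1
    alpha, se = _anomalous_fit(t, np.asarray(msd.msd, dtype=float), n_points)
    mode = "confined" if alpha < alpha_critical(n_points, size) else "free"
    return ModeLabel(mode=mode, alpha=alpha, alpha_se=se, d_min=d_min)


@dataclass
class SegmentAnalysis:
    segment: Segment
    msd: MSDCurve  # lag axis in frames
    fit: DiffusionFit
    label: Optional[ModeLabel] = None


def fit_segments(
    segments: Iterable[Segment], cfg: RunConfig
) -> list[SegmentAnalysis]:
    """Length-filter segments and compute MSD + 4-point diffusion fit each."""
    out = []
    for seg in segments:
        if len(seg) < cfg.min_segment_length:
            continue
        curve = compute_msd(seg, cfg.max_lag_fraction, n_fit_floor=cfg.n_fit)
        if len(curve.msd) < cfg.n_fit:
            continue
        fit = fit_diffusion_coefficient(curve, n_fit=cfg.n_fit, dt=cfg.dt)
        out.append(SegmentAnalysis(segment=seg, msd=curve, fit=fit))
    return out


def pooled_d_min(analyses: Iterable[SegmentAnalysis], cfg: RunConfig) -> float:
    """Dataset-level D_min: pooled sigma_dyn Q3 mapped through the default
    formula, or the configured override."""
    if cfg.d_min_mode == "override":
        return float(cfg.resolved_d_min_override())
    sigmas = [a.fit.sigma_dyn for a in analyses if a.fit.sigma_dyn is not None]
    return compute_d_min(sigmas, dt=cfg.dt, n_fit=cfg.n_fit)


def analyze_cell(
    segments: Sequence[Segment],
    cfg: RunConfig,
    d_min: float,
    cell_id: int = 0,
    t_min: float = float("nan"),
    condition: str = "",
    analyses: Optional[Sequence[SegmentAnalysis]] = None,
) -> Optional[CellSummary]:
    """Per-cell summary: global D, mode fractions, per-mode mean D.

    Segments shorter than the minimum length are dropped; a cell with no
    surviving segments yields None (excluded from cohort means). Per-mode
    mean D for the mobile modes excludes negative fitted D values; D_global
    averages all surviving segments.
    """
    if analyses is None:
        analyses = fit_segments(segments, cfg)
    if not analyses:
        return None
    for a in analyses:
        a.label = classify_segment(
            a.fit, a.msd, d_min, dt=cfg.dt, size=cfg.confinement_size,
            n_points=len(a.segment),
        )
        a.segment.mode = a.label.mode

    d_vals = np.array([a.fit.D for a in analyses])
    modes = np.array([a.label.mode for a in analyses])
    n = len(analyses)

    def mode_mean_d(mode: str) -> float:
        sel = d_vals[modes == mode]
        if mode != "immobile":
            sel = sel[sel > 0]
        return float(sel.mean()) if sel.size else float("nan")

    return CellSummary(
        cell_id=cell_id,
        t_min=t_min,
        condition=condition,
        n_segments=n,
        D_global=float(d_vals.mean()),
        f_imm=float((modes == "immobile").mean()),
        f_conf=float((modes == "confined").mean()),
        f_free=float((modes == "free").mean()),
        D_imm=mode_mean_d("immobile"),
        D_conf=mode_mean_d("confined"),
        D_free=mode_mean_d("free"),
        mean_segment_length=float(np.mean([len(a.segment) for a in analyses])),
    )


def analyze_cells(
    segments_by_cell: dict[int, Sequence[Segment]],
    cfg: RunConfig,
    cell_meta: Optional[dict[int, tuple[float, str]]] = None,
) -> tuple[pd.DataFrame, float]:
    """Cohort analysis: pool sigma_dyn across cells for D_min, then summarize
    each cell. Returns (cell-summary table, D_min used)."""
    fitted = {cid: fit_segments(segs, cfg) for cid, segs in segments_by_cell.items()}
    all_analyses = [a for v in fitted.values() for a in v]
    if not all_analyses:
        raise ValueError("no segments survive the length filter in any cell")
    d_min = pooled_d_min(all_analyses, cfg)
    rows = []
    for cid in sorted(fitted):
        t_min, condition = (cell_meta or {}).get(cid, (float("nan"), ""))
        summary = analyze_cell(
            [], cfg, d_min, cell_id=cid, t_min=t_min, condition=condition,
            analyses=fitted[cid],
        )
        if summary is not None:
            rows.append(summary.as_dict())
    return pd.DataFrame(rows), d_min


def segment_results_table(analyses: Iterable[SegmentAnalysis]) -> pd.DataFrame:
    """Per-segment results: D, sigma_dyn, alpha, label."""
    rows = []
    for a in analyses:
        rows.append(
            {
                "cell_id": a.segment.cell_id,
                "segment_id": a.segment.segment_id,
                "n_points": len(a.segment),
                "D": a.fit.D,
                "intercept": a.fit.intercept,
                "sigma_dyn": a.fit.sigma_dyn,
                "alpha": a.label.alpha if a.label else None,
                "mode": a.label.mode if a.label else None,
            }
        )
    return pd.DataFrame(rows)
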