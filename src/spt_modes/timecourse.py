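"""Time-resolved ligand-response profiles from per-cell summaries.

Cells are pooled into half-open time bins relative to ligand addition
(default 5-minute bins starting at [-5, 0)), baseline intervals are aligned
across conditions, and each property is expressed as a relative change (%)
from its pre-ligand baseline with the standard error of the difference (SED)
as the error bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

FRACTION_PROPS = ("f_imm", "f_conf", "f_free")
PROPERTIES = FRACTION_PROPS + ("D_global", "D_free", "D_conf", "D_imm")


@dataclass(frozen=True)
class TimeBinSummary:
    label: str  # e.g. "[-5,0)"
    t_lo: float  # minutes, inclusive
    t_hi: float  # minutes, exclusive
    n_cells: int
    mean: dict  # property -> mean over cells
    sem: dict  # property -> SEM over cells


@dataclass(frozen=True)
class RelativeChangePoint:
    label: str
    property: str
    rel_change: float  # percent of baseline
    sed: float  # percent, standard error of the difference
    n_cells: int


def _bin_label(lo: float, hi: float) -> str:
    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else f"{v:g}"

    return f"[{fmt(lo)},{fmt(hi)})"


def assign_time_bins(
    cells: pd.DataFrame,
    bin_width: float = 5.0,
    ligand_time: float = 0.0,
) -> list[TimeBinSummary]:
    """Group per-cell summaries into half-open time bins [k·w, (k+1)·w)
    relative to ligand addition and summarize each property as mean ± SEM.

    Bins with no cells are simply absent from the output (never interpolated).
    """
    if cells["t_min"].isna().any() or not np.isfinite(cells["t_min"]).all():
        raise ValueError("every cell needs a finite timestamp")
    t = cells["t_min"].to_numpy() - ligand_time
    k = np.floor(t / bin_width).astype(int)
    out = []
    for kk in sorted(set(k)):
        sub = cells[k == kk]
        lo, hi = kk * bin_width, (kk + 1) * bin_width
        mean, sem = {}, {}
        for p in PROPERTIES:
            if p not in cells.columns:
                continue
            vals = sub[p].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            mean[p] = float(vals.mean()) if vals.size else float("nan")
            sem[p] = (
                float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        out.append(
            TimeBinSummary(
                label=_bin_label(lo, hi), t_lo=lo, t_hi=hi, n_cells=len(sub),
                mean=mean, sem=sem,
            )
        )
    return out


def baseline_bin(bins: list[TimeBinSummary]) -> TimeBinSummary:
    """The pre-ligand [-bin_width, 0) interval."""
    for b in bins:
        if b.t_lo < 0 <= b.t_hi:
            return b
    raise ValueError("no baseline bin covering t < 0")


def baseline_align(
    datasets: dict[str, list[TimeBinSummary]],
    mode: str = "additive",
    properties: tuple[str, ...] = FRACTION_PROPS,
) -> dict[str, list[TimeBinSummary]]:
    """Align each condition's baseline mode fractions to the grand-mean
    baseline across conditions, correcting for cell-to-cell fluctuations in
    the resting state.

    Additive mode (default) shifts every bin of a condition by
    (grand-mean baseline − condition baseline) per property, preserving the
    differences between bins that the relative-change figures display;
    multiplicative mode rescales instead. Fraction triples are renormalized to
    sum to 1 after alignment. The input is not modified.
    """
    if mode == "none":
        return datasets
    if mode not in ("additive", "multiplicative"):
        raise ValueError("alignment mode must be additive|multiplicative|none")
    bases = {c: baseline_bin(b) for c, b in datasets.items()}
    grand = {
        p: float(np.mean([bases[c].mean[p] for c in datasets]))
        for p in properties
    }
    aligned: dict[str, list[TimeBinSummary]] = {}
    for cond, bins in datasets.items():
        base = bases[cond]
        out = []
        for b in bins:
            mean = dict(b.mean)
            sem = dict(b.sem)
            for p in properties:
                if mode == "additive":
                    mean[p] = b.mean[p] + (grand[p] - base.mean[p])
                else:
                    mean[p] = b.mean[p] * (grand[p] / base.mean[p] if base.mean[p] else 1.0)
            frac_sum = sum(mean[p] for p in FRACTION_PROPS if p in mean)
            if frac_sum > 0 and all(p in mean for p in FRACTION_PROPS):
                for p in FRACTION_PROPS:
                    mean[p] /= frac_sum
                    sem[p] = sem[p] / frac_sum
            out.append(replace(b, mean=mean, sem=sem))
        aligned[cond] = out
    return aligned


def relative_change(
    tbin: TimeBinSummary, baseline: TimeBinSummary, prop: str
) -> RelativeChangePoint:
    """Relative change of a property vs the pre-ligand baseline, in percent,
    with the standard error of the difference:

        rc  = (mean_bin − mean_base) / mean_base × 100
        SED = 100 · sqrt(SEM_bin² + SEM_base²) / |mean_base|
    """
    m_base = baseline.mean[prop]
    if m_base == 0 or not np.isfinite(m_base):
        raise ValueError(f"baseline mean of {prop} is zero or undefined")
    m_bin = tbin.mean[prop]
    rc = (m_bin - m_base) / m_base * 100.0
    sed = 100.0 * math.hypot(tbin.sem[prop], baseline.sem[prop]) / abs(m_base)
    return RelativeChangePoint(
        label=tbin.label, property=prop, rel_change=rc, sed=sed, n_cells=tbin.n_cells
    )


def relative_change_series(
    bins: list[TimeBinSummary], prop: str
) -> list[RelativeChangePoint]:
    """Relative-change profile of one property across all bins; the baseline
    bin maps to 0% by construction."""
    base = baseline_bin(bins)
    return [relative_change(b, base, prop) for b in bins]


def bins_to_table(bins: list[TimeBinSummary]) -> pd.DataFrame:
    rows = []
    for b in bins:
        row = {"interval": b.label, "t_lo": b.t_lo, "t_hi": b.t_hi, "n_cells": b.n_cells}
        for p, v in b.mean.items():
            row[f"{p}_mean"] = v
            row[f"{p}_sem"] = b.sem[p]
        rows.append(row)
    return pd.DataFrame(rows)


def relative_change_table(points: list[RelativeChangePoint]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in points])
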