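"""Nonparametric group comparisons with the study's significance scheme.

Normality is screened per group with Shapiro–Wilk (α = 0.05) and recorded,
but nonparametric tests are used for the comparisons regardless: Mann–Whitney
U for independent treatment groups, Wilcoxon signed-rank for paired samples
from the same treatment group. Significance labels: p < 0.05 "*",
p < 0.01 "**", p < 0.001 "***", otherwise unlabeled. Tests are two-sided and
no multiple-testing correction is applied by default (a Bonferroni option
exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    property: str
    group_a: str
    group_b: str
    test: str
    p_value: float
    label: str
    n_a: int
    n_b: int
    normal_a: bool
    normal_b: bool


def star_label(p: float) -> str:
    """Map a p value to the star scheme; p = 0.05 is not significant."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def normality_gate(sample: Sequence[float], alpha: float = 0.05) -> bool:
    """True iff the Shapiro–Wilk test does not reject normality (p >= alpha).

    Degenerate (constant) samples are recorded as non-normal.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        return False
    _, p = sps.shapiro(x)
    return bool(p >= alpha)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    property: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> ComparisonResult:
    """Two-sided Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    The U statistic is computed exactly for group sizes up to 20 (without
    ties) and by the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison requires equal lengths")
        diffs = x - y
        if np.all(diffs == 0):
            p = 1.0
        else:
            _, p = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        test = "wilcoxon"
    else:
        if x.size < 3 or y.size < 3:
            raise ValueError("unpaired comparison requires n >= 3 per group")
        method = "exact" if max(x.size, y.size) <= 20 and _no_ties(x, y) else "asymptotic"
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test = "mannwhitneyu"
    p = float(p)
    return ComparisonResult(
        property=property,
        group_a=group_a,
        group_b=group_b,
        test=test,
        p_value=p,
        label=star_label(p),
        n_a=int(x.size),
        n_b=int(y.size),
        normal_a=normality_gate(x) if x.size >= 3 else False,
        normal_b=normality_gate(y) if y.size >= 3 else False,
    )


def _no_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size == pooled.size


DEFAULT_PROPERTIES = ("D_global", "f_imm", "f_conf", "f_free", "D_free", "D_conf", "D_imm")


def build_report(
    cells: pd.DataFrame,
    properties: Sequence[str] = DEFAULT_PROPERTIES,
    reference: Optional[str] = None,
    bonferroni: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-condition summaries and pairwise comparisons of per-cell values.

    Returns (summary table with mean ± SEM and n per condition and property,
    comparison table with test, raw p, and star label). With a single
    condition the comparison table is empty. ``reference`` restricts
    comparisons to reference-vs-other; otherwise all pairs are tested.
    """
    if "condition" not in cells.columns:
        raise ValueError("cells table needs a 'condition' column")
    conditions = sorted(cells["condition"].unique())
    props = [p for p in properties if p in cells.columns]

    srows = []
    for cond in conditions:
        sub = cells[cells["condition"] == cond]
        for p in props:
            vals = sub[p].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            srows.append(
                {
                    "condition": cond,
                    "property": p,
                    "n_cells": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else float("nan"),
                    "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
                }
            )
    summary = pd.DataFrame(srows)

    pairs = []
    if reference is not None:
        if reference not in conditions:
            raise ValueError(f"unknown reference condition {reference!r}")
        pairs = [(reference, c) for c in conditions if c != reference]
    else:
        pairs = [(a, b) for i, a in enumerate(conditions) for b in conditions[i + 1:]]

    crows = []
    n_tests = max(len(pairs) * len(props), 1)
    for a, b in pairs:
        xa = cells[cells["condition"] == a]
        xb = cells[cells["condition"] == b]
        for p in props:
            va = xa[p].to_numpy(dtype=float)
            vb = xb[p].to_numpy(dtype=float)
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            if va.size < 3 or vb.size < 3:
                continue
            res = compare_groups(va, vb, property=p, group_a=a, group_b=b)
            p_adj = min(res.p_value * n_tests, 1.0) if bonferroni else res.p_value
            crows.append(
                {
                    "property": p,
                    "group_a": a,
                    "group_b": b,
                    "test": res.test,
                    "p_value": p_adj,
                    "label": star_label(p_adj),
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "normal_a": res.normal_a,
                    "normal_b": res.normal_b,
                }
            )
    comparisons = pd.DataFrame(
        crows,
        columns=[
            "property", "group_a", "group_b", "test", "p_value", "label",
            "n_a", "n_b", "normal_a", "normal_b",
        ],
    )
    return summary, comparisons
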