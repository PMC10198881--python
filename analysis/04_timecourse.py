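"""Time-resolved ligand response from the per-cell summaries.

Pools cells into 5-minute intervals relative to ligand addition, expresses
the immobile fraction and the free diffusion coefficient as relative changes
from the pre-ligand baseline (error bars: standard error of the difference),
and writes the binned table, the relative-change table and a dot plot.
"""

import sys
from pathlib import Path

import pandas as pd

from spt_modes import RunConfig, assign_time_bins, relative_change_series
from spt_modes.io import read_stamped_csv, write_stamped_csv
from spt_modes.timecourse import bins_to_table, relative_change_table

OUT = Path("results")


def main() -> None:
    cfg = RunConfig()
    cells = read_stamped_csv(OUT / "cells.csv")
    bins = assign_time_bins(cells, bin_width=cfg.bin_width, ligand_time=cfg.ligand_time)
    write_stamped_csv(bins_to_table(bins), OUT / "timebins.csv", "analysis04", None)

    tables = []
    for prop in ("f_imm", "f_conf", "f_free", "D_free"):
        series = relative_change_series(bins, prop)
        tables.append(relative_change_table(series))
        if prop in ("f_imm", "D_free"):
            line = ", ".join(f"{p.label}: {p.rel_change:+.0f}±{p.sed:.0f}%" for p in series)
            print(f"relative change of {prop}: {line}")
    rc = pd.concat(tables, ignore_index=True)
    write_stamped_csv(rc, OUT / "relative_changes.csv", "analysis04", None)

    peak = max((p for p in rc.itertuples() if p.property == "f_imm"),
               key=lambda p: p.rel_change)
    print(f"immobile fraction peaks in {peak.label} at {peak.rel_change:+.0f}%")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharex=True)
        for ax, prop, color in zip(axes, ("f_imm", "D_free"), ("tab:blue", "tab:orange")):
            sub = rc[rc["property"] == prop]
            x = range(len(sub))
            ax.errorbar(x, sub["rel_change"], yerr=sub["sed"], fmt="o", color=color)
            ax.axhline(0, lw=0.8, color="grey")
            ax.set_xticks(list(x), sub["label"], rotation=45)
            ax.set_ylabel(f"rel. change of {prop} (%)")
            ax.set_xlabel("time interval (min)")
        fig.tight_layout()
        fig.savefig(OUT / "timecourse.png", dpi=150)
        print(f"plot -> {OUT / 'timecourse.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the plot")


if __name__ == "__main__":
    sys.exit(main())
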