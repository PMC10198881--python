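"""Statistical comparison of resting vs stimulated cells.

Applies the Shapiro-Wilk normality screen (recorded, not gating) and the
two-sided Mann-Whitney U test per diffusion property, labels significance
with the star scheme (* p<0.05, ** p<0.01, *** p<0.001), and writes the
summary and comparison tables.
"""

import sys
from pathlib import Path

from spt_modes import build_report
from spt_modes.io import read_stamped_csv, write_stamped_csv

OUT = Path("results")


def main() -> None:
    cells = read_stamped_csv(OUT / "cells.csv")
    summary, comparisons = build_report(cells, reference="resting")
    write_stamped_csv(summary, OUT / "report_summary.csv", "analysis05", None)
    write_stamped_csv(comparisons, OUT / "report_comparisons.csv", "analysis05", None)

    print("per-condition summaries (mean ± SEM):")
    for row in summary.itertuples():
        print(f"  {row.condition:11s} {row.property:9s} "
              f"{row.mean:8.4f} ± {row.sem:.4f}  (n={row.n_cells})")
    print("\nresting vs stimulated (Mann-Whitney U, two-sided):")
    for row in comparisons.itertuples():
        stars = row.label or "n.s."
        print(f"  {row.property:9s} p = {row.p_value:.2e}  {stars}")


if __name__ == "__main__":
    sys.exit(main())
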