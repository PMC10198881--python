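"""Per-segment MSD analysis and three-state mode classification, aggregated
per cell.

Reads results/segments.csv and the experiment manifest, fits the first four
MSD points of every segment with >= 20 localizations (D = slope/4), applies
the immobile threshold D_min and the confined-vs-free exponent test, and
writes per-cell summaries (cells.csv) plus the per-segment table.
"""

import sys
from pathlib import Path

from spt_modes import RunConfig, analyze_cells, classify_segment, table_to_segments
from spt_modes.diffusion import fit_segments, segment_results_table
from spt_modes.io import read_manifest, read_stamped_csv, write_stamped_csv

OUT = Path("results")


def main() -> None:
    cfg = RunConfig()
    manifest = read_manifest(OUT / "experiment" / "manifest.csv")
    meta = {int(r.cell_id): (float(r.t_min), r.condition) for r in manifest.itertuples()}
    segments = table_to_segments(read_stamped_csv(OUT / "segments.csv"))
    by_cell = {}
    for s in segments:
        by_cell.setdefault(s.cell_id, []).append(s)

    cells, d_min = analyze_cells(by_cell, cfg, meta)

    analyses = [a for cid in sorted(by_cell) for a in fit_segments(by_cell[cid], cfg)]
    for a in analyses:
        a.label = classify_segment(a.fit, a.msd, d_min, cfg.dt,
                                   size=cfg.confinement_size, n_points=len(a.segment))
    seg_table = segment_results_table(analyses)
    write_stamped_csv(seg_table, OUT / "segment_results.csv", cfg_hash="analysis03", seed=None)
    write_stamped_csv(cells, OUT / "cells.csv", cfg_hash="analysis03", seed=None)
    print(f"D_min used: {d_min:.4f} µm²/s (mode: {cfg.d_min_mode})")
    print(f"analyzed {len(cells)} cells, {int(cells['n_segments'].sum())} segments")
    resting = cells[cells["condition"] == "resting"]
    stim = cells[cells["condition"] == "stimulated"]
    for name, sub in (("resting", resting), ("stimulated", stim)):
        if len(sub):
            print(
                f"{name:11s}: D_global = {sub['D_global'].mean():.3f} µm²/s, "
                f"fractions imm/conf/free = "
                f"{sub['f_imm'].mean():.3f}/{sub['f_conf'].mean():.3f}/{sub['f_free'].mean():.3f}"
            )


if __name__ == "__main__":
    sys.exit(main())
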