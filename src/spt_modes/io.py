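"""Readers/writers for the pipeline's on-disk formats.

Localization tables use the ThunderSTORM CSV dialect with positions in nm:
``frame,"x [nm]","y [nm]","uncertainty [nm]",id``. All in-memory tables are
in µm. Derived artifacts (segments, cell summaries, time bins) are plain CSV
stamped with the configuration hash and seed in a leading comment line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

NM_PER_UM = 1000.0

LOC_COLUMNS = {"frame": "frame", "x [nm]": "x", "y [nm]": "y", "uncertainty [nm]": "uncertainty"}


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table (µm in memory) as ThunderSTORM-style nm CSV."""
    out = pd.DataFrame(
        {
            "frame": table["frame"].astype(int),
            "x [nm]": table["x"] * NM_PER_UM,
            "y [nm]": table["y"] * NM_PER_UM,
            "uncertainty [nm]": table["uncertainty"] * NM_PER_UM,
        }
    )
    if "id" in table.columns:
        out["id"] = table["id"].astype(int)
    out.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a ThunderSTORM-style localization CSV into µm coordinates.

    Frame numbering is normalized to 0-based (a 1-based dialect, detected by
    the minimum frame index, is shifted down).
    """
    raw = pd.read_csv(path)
    missing = [c for c in LOC_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    table = pd.DataFrame(
        {
            "frame": raw["frame"].astype(int),
            "x": raw["x [nm]"] / NM_PER_UM,
            "y": raw["y [nm]"] / NM_PER_UM,
            "uncertainty": raw["uncertainty [nm]"] / NM_PER_UM,
        }
    )
    if "id" in raw.columns:
        table["id"] = raw["id"].astype(int)
    if len(table) and table["frame"].min() == 1:
        table["frame"] -= 1
    return table


def write_stamped_csv(
    df: pd.DataFrame, path: str | Path, cfg_hash: str, seed: Optional[int]
) -> None:
    """CSV with a provenance comment line (config hash + seed)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_stamped_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(records: list[dict], path: str | Path) -> None:
    """Experiment manifest: one row per cell (cell_id, t_min, condition, path)."""
    pd.DataFrame(records, columns=["cell_id", "t_min", "condition", "path"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth_jsonable: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth_jsonable, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
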