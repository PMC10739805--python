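"""Table serialization with '#'-prefixed metadata headers."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import pandas as pd


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, Any] | None = None,
    sep: str = "\t",
) -> None:
    """Write a table with metadata comment lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a table written by :func:`write_table` (metadata skipped)."""
    return pd.read_csv(path, sep=sep, comment="#")


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a cell-track table (CSV with '#' metadata), restoring attrs."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    if "plate" in meta:
        df.attrs["plate"] = tuple(float(v) for v in meta["plate"].split("x"))
    if "frame_hours" in meta:
        df.attrs["frame_hours"] = float(meta["frame_hours"])
    return df
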