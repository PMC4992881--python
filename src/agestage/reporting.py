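"""Shared table-export helpers: TSV with '#' metadata headers, fixed
6-decimal formatting for reproducible diffs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__


def metadata(**kwargs) -> dict:
    """Standard metadata block written at the top of every output file."""
    meta = {"tool": f"agestage {__version__}"}
    for key, value in kwargs.items():
        if value is not None:
            meta[key] = value
    return meta


def write_tsv(path: str | Path, frame: pd.DataFrame, meta: Optional[dict] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write(frame.to_csv(sep="\t", index=False, float_format="%.6f"))


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
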