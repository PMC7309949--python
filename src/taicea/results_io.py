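"""Writing and re-reading model outputs.

Scalar summaries go to JSON, tables to CSV.  Round-tripping a written file
reproduces integers bit-exactly and floats to 1e-9 (values are written with
17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .markov import CEResults

__all__ = ["write_ce_result", "write_table", "read_table", "read_json"]


def write_ce_result(result: CEResults, destination: str | Path) -> Path:
    """Write arm totals and incremental results as JSON."""
    path = Path(destination)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
    return path


def write_table(table: pd.DataFrame, destination: str | Path) -> Path:
    """Write a result table (tornado, PSA draws, CEAC, trace) as CSV."""
    path = Path(destination)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(source: str | Path) -> pd.DataFrame:
    return pd.read_csv(source)


def read_json(source: str | Path) -> dict:
    with open(source) as fh:
        return json.load(fh)
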