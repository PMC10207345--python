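"""Readers/writers for summaries, scores, and plain-text grids.

Every output CSV can carry ``#``-prefixed header lines stamping the package
version, the seed, and a configuration hash, so pipeline outputs are
self-describing and reruns can be checked for bit-identity.  Summary
tables round-trip losslessly at 12 significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "write_summaries",
    "read_summaries",
    "write_scores",
    "read_scores",
    "read_grid_text",
    "stamp_lines",
]


def stamp_lines(seed=None, config_hash=None, extra=()):
    """Standard provenance header lines for output files."""
    lines = [f"stgap version={__version__}"]
    if seed is not None:
        lines.append(f"seed={seed}")
    if config_hash is not None:
        lines.append(f"config_hash={config_hash}")
    lines.extend(extra)
    return lines


def write_summaries(summary: pd.DataFrame, path, header_lines=()) -> None:
    """Write a posterior-summary table as CSV.

    Columns ``mean``, ``q2.5``, ``q97.5`` are formatted with 12 significant
    digits so write-then-read is lossless; empty tables are an error.
    """
    if len(summary) == 0:
        raise ValueError("refusing to write an empty summary table")
    df = summary.copy()
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df


def write_scores(scores_df: pd.DataFrame, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        scores_df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_grid_text(path) -> np.ndarray:
    """Read a whitespace-delimited text matrix; ``nan`` marks missing cells."""
    return np.loadtxt(path, ndmin=2)
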