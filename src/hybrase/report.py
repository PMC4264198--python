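"""Run summaries and alignment-statistics arithmetic."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def alignment_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Recompute bases and uniquely-mapped percentages from raw read counts.

    Input columns: sample, n_reads, read_length, n_unique. Adds
    ``n_bases = n_reads * read_length`` and
    ``pct_unique = 100 * n_unique / n_reads`` rounded to two decimals, and
    appends an ``overall`` row with summed counts.
    """
    required = {"sample", "n_reads", "read_length", "n_unique"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"alignment stats missing columns: {sorted(missing)}")
    df = stats.copy()
    df["n_bases"] = df["n_reads"] * df["read_length"]
    df["pct_unique"] = (100.0 * df["n_unique"] / df["n_reads"]).round(2)
    overall = pd.DataFrame(
        [
            dict(
                sample="overall",
                n_reads=df["n_reads"].sum(),
                read_length=pd.NA,
                n_unique=df["n_unique"].sum(),
                n_bases=df["n_bases"].sum(),
                pct_unique=round(100.0 * df["n_unique"].sum() / df["n_reads"].sum(), 2),
            )
        ]
    )
    return pd.concat([df, overall], ignore_index=True)


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def collate_summaries(directory: str | Path) -> dict:
    """Merge all ``*.summary.json`` files in a directory into one report."""
    out = {}
    for p in sorted(Path(directory).glob("*.summary.json")):
        with open(p) as fh:
            out[p.name.replace(".summary.json", "")] = json.load(fh)
    return out
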