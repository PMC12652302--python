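"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open in memory.  BED input/output is
0-based half-open; SEG output follows the conventional 1-based inclusive
coordinates (``loc.start``/``loc.end``).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so "chr1" and "1" compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def chrom_sort_key(chrom: str):
    c = normalize_chrom(chrom)
    return (0, int(c)) if re.fullmatch(r"\d+", c) else (1, c)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3+ columns) into (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["chrom"] = out["chrom"].map(normalize_chrom)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if df.shape[1] >= 4:
        out["name"] = df.iloc[:, 3].astype(str)
    bad = out[out["end"] <= out["start"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"{path}: malformed interval {r['chrom']}:{r['start']}-{r['end']} (end <= start)"
        )
    return out


def write_bins_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["gc_ratio"] = out["gc_ratio"].map(lambda g: f"{g:.6f}" if np.isfinite(g) else "NA")
    out.to_csv(path, sep="\t", index=False)


def read_bins_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    required = {"chrom", "start", "end", "n_mappable", "gc_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: bins TSV missing columns {sorted(missing)}")
    return df


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "count" not in df.columns:
        # multi-sample matrix: chrom, start, end, <sample>...
        if df.shape[1] < 4:
            raise ValueError(f"{path}: counts TSV needs chrom, start, end, count columns")
    return df


def write_nrc_tsv(bins: pd.DataFrame, values: np.ndarray, mask: np.ndarray, path) -> None:
    out = bins[["chrom", "start", "end"]].copy()
    out["value"] = values
    out["mask"] = mask.astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_nrc_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "value", "mask"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: NRC TSV missing columns {sorted(missing)}")
    return df


def write_seg(df: pd.DataFrame, path) -> None:
    """Write a SEG table (1-based inclusive coordinates, means to 6 decimals)."""
    out = df[SEG_COLUMNS].copy()
    out["seg.mean"] = out["seg.mean"].map(lambda m: f"{m:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ID": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SEG missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def read_genes(path) -> pd.DataFrame:
    """Gene table: chrom, start, end, symbol — headered TSV or 4-column BED."""
    head = Path(path).open().readline().rstrip("\n").split("\t")
    if "symbol" in head:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    else:
        df = read_bed(path).rename(columns={"name": "symbol"})
    if "symbol" not in df.columns:
        raise ValueError(f"{path}: gene table needs a 4th 'symbol' column")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df[["chrom", "start", "end", "symbol"]]


def read_chrom_sizes(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    return {normalize_chrom(c): int(s) for c, s in zip(df["chrom"], df["size"])}
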