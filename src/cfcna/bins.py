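"""Variable-length genomic bins holding a fixed number of uniquely mappable bases.

Exome read-depth analysis works on the intersection of the capture target
regions with a uniquely-mappable track.  Instead of fixed-width windows, each
bin collects exactly ``bin_mappable_size`` (default 50) mappable-in-target
positions, so its physical span varies with local mappability.  Only
autosomes 1-22 are binned; sex chromosomes show systematic male/female
coverage differences and are never emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AUTOSOMES, chrom_sort_key, normalize_chrom, read_bins_tsv

BIN_COLUMNS = ["chrom", "start", "end", "n_mappable", "gc_ratio"]


@dataclass
class BinSet:
    """Ordered autosomal bins with per-bin GC ratio and a mask of excluded bins.

    ``df`` columns: chrom (str, "1".."22"), start, end (0-based half-open),
    n_mappable (int), gc_ratio (float in [0,1], NaN when unknown), masked
    (bool, True = excluded from analysis).
    """

    df: pd.DataFrame
    genome_tag: str = ""

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        if "masked" not in self.df.columns:
            self.df = self.df.assign(masked=False)
        if "gc_ratio" not in self.df.columns:
            self.df = self.df.assign(gc_ratio=np.nan)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc_ratio"].to_numpy(dtype=float)

    @property
    def masked(self) -> np.ndarray:
        return self.df["masked"].to_numpy(dtype=bool)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @classmethod
    def from_tsv(cls, path, genome_tag: str = "") -> "BinSet":
        df = read_bins_tsv(path)
        df["masked"] = ~np.isfinite(df["gc_ratio"].to_numpy(dtype=float))
        return cls(df[BIN_COLUMNS + ["masked"]], genome_tag=genome_tag)

    def to_tsv(self, path) -> None:
        from .io import write_bins_tsv

        write_bins_tsv(self.df[BIN_COLUMNS], path)


def _merge_intervals(df: pd.DataFrame) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) rows into disjoint sorted runs."""
    ivals = sorted(zip(df["start"], df["end"]))
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _validate_intervals(df: pd.DataFrame, label: str) -> pd.DataFrame:
    bad = df[df["end"] <= df["start"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"{label}: malformed interval {r['chrom']}:{r['start']}-{r['end']} (end <= start)"
        )
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df[df["chrom"].isin(AUTOSOMES)]


def build_bins(
    targets: pd.DataFrame,
    mappable: pd.DataFrame,
    bin_mappable_size: int = 50,
    genome_tag: str = "",
) -> BinSet:
    """Chunk the target/mappable intersection into bins of fixed mappable content.

    Per chromosome the intersection of ``targets`` and ``mappable`` (both
    0-based half-open interval tables) is scanned left to right; every
    consecutive run of ``bin_mappable_size`` mappable-in-target positions
    becomes one bin spanning from its first to one past its last position.
    A trailing run shorter than ``bin_mappable_size`` is dropped, so every
    emitted bin carries exactly ``bin_mappable_size`` mappable bases.  Bins
    never cross chromosome boundaries.
    """
    if bin_mappable_size < 1:
        raise ValueError("bin_mappable_size must be >= 1")
    targets = _validate_intervals(targets, "targets")
    mappable = _validate_intervals(mappable, "mappable")

    rows = []
    chroms = sorted(set(targets["chrom"]) & set(mappable["chrom"]), key=chrom_sort_key)
    for chrom in chroms:
        runs = _intersect(
            _merge_intervals(targets[targets["chrom"] == chrom]),
            _merge_intervals(mappable[mappable["chrom"] == chrom]),
        )
        need = bin_mappable_size
        bin_start = None
        for s, e in runs:
            pos = s
            while e - pos >= need:
                if bin_start is None:
                    bin_start = pos
                pos += need
                rows.append((chrom, bin_start, pos, bin_mappable_size))
                bin_start = None
                need = bin_mappable_size
            if pos < e:
                if bin_start is None:
                    bin_start = pos
                need -= e - pos
        # trailing partial run (need < size with bin open) is dropped

    if not rows:
        warnings.warn("build_bins: empty target/mappable intersection; no bins emitted")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_mappable"])
    df["gc_ratio"] = np.nan
    return BinSet(df, genome_tag=genome_tag)


def compute_gc(bin_set: BinSet, reference) -> BinSet:
    """Fill per-bin GC ratio from a reference sequence source.

    ``reference`` is a pyfaidx.Fasta, a path to an indexed FASTA, or a plain
    dict mapping chromosome label to sequence string.  GC ratio is
    (#G + #C) / (#A + #C + #G + #T) over the full bin footprint [start, end),
    case-insensitive; bins whose denominator is zero (all N) are masked.
    """
    if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        from pyfaidx import Fasta

        reference = Fasta(str(reference))

    def fetch(chrom: str, start: int, end: int) -> str:
        for key in (chrom, f"chr{chrom}"):
            try:
                seq = reference[key]
            except KeyError:
                continue
            if end > len(seq):
                raise ValueError(
                    f"bin {chrom}:{start}-{end} extends beyond chromosome length {len(seq)}"
                )
            return str(seq[start:end])
        raise KeyError(f"chromosome {chrom!r} not found in reference")

    gc = np.full(bin_set.n_bins, np.nan)
    masked = bin_set.masked.copy()
    for idx, row in enumerate(bin_set.df.itertuples(index=False)):
        seq = fetch(row.chrom, row.start, row.end).upper()
        n_gc = seq.count("G") + seq.count("C")
        n_at = seq.count("A") + seq.count("T")
        denom = n_gc + n_at
        if denom == 0:
            masked[idx] = True
        else:
            gc[idx] = n_gc / denom
    df = bin_set.df.copy()
    df["gc_ratio"] = gc
    df["masked"] = masked
    return BinSet(df, genome_tag=bin_set.genome_tag)
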