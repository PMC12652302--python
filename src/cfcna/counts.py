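"""Per-bin read counts RC(i) and median-normalized read counts NRC_raw(i).

A read contributes once, to the bin containing its leftmost aligned position,
so the sum of bin counts equals the number of retained reads.  NRC_raw scales
a count profile by its sample-wide median so that a diploid bin sits at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import BinSet
from .io import normalize_chrom


@dataclass
class CountProfile:
    """Integer read counts aligned index-for-index to a BinSet."""

    sample_id: str
    counts: np.ndarray
    bin_set_ref: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class NrcProfile:
    """Normalized read counts on ratio scale (neutral 1) or log2 scale (neutral 0).

    ``mask`` is True for excluded bins; ``provenance`` records which
    normalization produced the values (raw, corrected, gc_corrected).
    """

    sample_id: str
    values: np.ndarray
    scale: str = "ratio"
    mask: np.ndarray = None
    provenance: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scale not in ("ratio", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]

    def to_log2(self, epsilon: float = 1e-6) -> "NrcProfile":
        if self.scale == "log2":
            return self
        vals = np.log2(np.maximum(self.values, epsilon))
        return NrcProfile(self.sample_id, vals, "log2", self.mask.copy(), self.provenance)


def _bin_index_maps(bin_set: BinSet):
    """Per-chromosome (starts, ends, row offsets) for leftmost-position lookup."""
    maps = {}
    df = bin_set.df
    for chrom, sub in df.groupby("chrom", sort=False):
        maps[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub.index.to_numpy(),
        )
    return maps


def count_reads(
    alignments,
    bin_set: BinSet,
    min_mapq: int = 1,
    drop_duplicates: bool = True,
    sample_id: str | None = None,
) -> CountProfile:
    """Count primary aligned reads per bin from a SAM/BAM file or pysam handle.

    Each retained read (primary, mapped, mapq >= ``min_mapq``, not a duplicate
    when ``drop_duplicates``) adds exactly 1 to the bin containing its leftmost
    aligned position; reads starting outside every bin are ignored.
    """
    import pysam

    close = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        path = str(alignments)
        if sample_id is None:
            sample_id = path.rsplit("/", 1)[-1].split(".")[0]
        alignments = pysam.AlignmentFile(path, check_sq=False)
        close = True
    if sample_id is None:
        sample_id = "sample"

    maps = _bin_index_maps(bin_set)
    counts = np.zeros(bin_set.n_bins, dtype=np.int64)
    seen_chroms: set[str] = set()
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom = normalize_chrom(read.reference_name)
            seen_chroms.add(chrom)
            entry = maps.get(chrom)
            if entry is None:
                continue
            starts, ends, rows = entry
            pos = read.reference_start  # leftmost aligned position, 0-based
            k = np.searchsorted(starts, pos, side="right") - 1
            if k >= 0 and pos < ends[k]:
                counts[rows[k]] += 1
    finally:
        if close:
            alignments.close()

    if counts.sum() == 0 and seen_chroms and not (seen_chroms & set(maps)):
        raise ValueError(
            "no alignment chromosome matches the bin set "
            f"(alignments use {sorted(seen_chroms)[:3]}, bins use {list(maps)[:3]}); "
            "normalize chromosome names (chr1 vs 1)"
        )
    return CountProfile(sample_id, counts, bin_set_ref=bin_set.genome_tag)


def counts_from_tsv(path, bin_set: BinSet | None = None) -> list[CountProfile]:
    """Load count profiles from a TSV (chrom, start, end, then one column per sample)."""
    from .io import read_counts_tsv

    df = read_counts_tsv(path)
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    if bin_set is not None and len(df) != bin_set.n_bins:
        raise ValueError(
            f"{path}: {len(df)} rows but bin set has {bin_set.n_bins} bins"
        )
    if sample_cols == ["count"]:
        sample_cols = [df.attrs.get("sample_id", "sample")]
        df = df.rename(columns={"count": sample_cols[0]})
    return [CountProfile(c, df[c].to_numpy()) for c in sample_cols]


def nrc_raw(profile: CountProfile, mask: np.ndarray | None = None) -> NrcProfile:
    """NRC_raw(i) = RC(i) / median(RC): the sample-wide median-scaled profile.

    The median is taken over unmasked bins; an even-length median is the mean
    of the two central order statistics.
    """
    counts = profile.counts.astype(float)
    if mask is None:
        mask = np.zeros(len(counts), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    med = float(np.median(counts[~mask]))
    if med == 0:
        raise ValueError("insufficient coverage: median read count is 0")
    return NrcProfile(profile.sample_id, counts / med, "ratio", mask, "raw")


def read_count_similarity(profiles: list[CountProfile], mask: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of count profiles on unmasked bins.

    Zero-variance profiles give NaN against every partner (undefined, not 0).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    n = len(profiles[0].counts)
    if any(len(p.counts) != n for p in profiles):
        raise ValueError("profiles are not on the same bin set")
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    ids = [p.sample_id for p in profiles]
    X = np.stack([p.counts[~mask].astype(float) for p in profiles])
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)
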