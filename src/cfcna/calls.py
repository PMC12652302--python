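"""Threshold-based CNA calling, gene annotation, and the inspection-cost metric.

The detection threshold is an empirical null derived from the normal panel:
each panel member is run through the full pipeline (panel normalization,
optional GC correction, CBS) against the remaining members — leave-one-out —
and the threshold is a high percentile (default 99.5) of the pooled absolute
segment means.  Because both test and controls are normals, any segment mean
reflects technical noise, not copy number.

On clean data the leave-one-out percentile can fall far below the noise level
of any single new sample, so the calling stage supports a conservative floor
on the threshold (``DEFAULT_THRESHOLD_FLOOR``, |log2| = 0.15).  The floor
encodes the empirical detection limit of cfDNA read-depth analysis: a
high-level amplification (four copies) diluted to a tumor fraction near 10%
produces |log2| ~ 0.14, and below that ctDNA level copy-number signal is
obscured by normal cfDNA.  Calls can additionally require minimum marker
support (``min_bins``, pipeline default 10 bins ~ 500 mappable bases), since
a segment spanning a handful of bins carries too few observations to trust;
the same filter applies to the null pool so threshold and calls see the same
segment population.

The inspection cost of a gene measures how much of the genome a reviewer
walking segments in descending |mean| order must examine before reaching the
first segment overlapping the gene — total base pairs and segment count.
Cleaner profiles push true events to the top of the ranking and shrink both
totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bins import BinSet
from .counts import CountProfile, nrc_raw
from .normalize import ControlPanel, gc_correct, nrc_corrected
from .segment import SegmentProfile, cbs_segment


DEFAULT_THRESHOLD_FLOOR = 0.15


@dataclass
class DetectionThreshold:
    value: float
    method: str = "loo_normal_percentile"
    percentile: float = 99.5
    n_panel_runs: int = 0

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("threshold must be >= 0")


def compute_threshold(
    panel_counts: list[CountProfile],
    bin_set: BinSet,
    percentile: float = 99.5,
    use_gc_correction: bool = True,
    span: float = 0.3,
    robust_iters: int = 2,
    alpha: float = 0.01,
    n_permutations: int = 10000,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    min_bins: int = 1,
) -> DetectionThreshold:
    """Leave-one-out empirical null threshold from a panel of normals.

    Each normal in turn is treated as the test sample against the remaining
    normals; its pipeline segments' absolute means are pooled across all runs
    and the threshold is the requested percentile of that distribution.
    ``min_bins`` drops segments with insufficient marker support from the
    pool, mirroring the same filter at the calling stage.
    """
    if len(panel_counts) < 3:
        raise ValueError("threshold estimation needs a panel of >= 3 normals")
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    if mask is None:
        mask = bin_set.masked
    pooled = []
    for i, test_counts in enumerate(panel_counts):
        rest = [p for j, p in enumerate(panel_counts) if j != i]
        test = nrc_raw(test_counts, mask=mask)
        panel = ControlPanel([nrc_raw(p, mask=mask) for p in rest])
        if use_gc_correction:
            prof = gc_correct(test, panel, bin_set.gc, span=span, robust_iters=robust_iters)
        else:
            prof = nrc_corrected(test, panel)
        seg = cbs_segment(
            prof, bin_set, alpha=alpha, n_permutations=n_permutations,
            seed=None if seed is None else seed + i,
        )
        keep = seg.segments["n_bins"].to_numpy() >= min_bins
        pooled.append(np.abs(seg.segments["mean"].to_numpy()[keep]))
    pooled = np.concatenate(pooled)
    if len(pooled) == 0 or np.all(pooled == 0):
        import warnings

        warnings.warn("degenerate panel: all segment means are 0; threshold is 0")
        value = 0.0
    else:
        value = float(np.percentile(pooled, percentile))
    return DetectionThreshold(value, "loo_normal_percentile", percentile, len(panel_counts))


def call_cnas(
    profile: SegmentProfile,
    threshold: DetectionThreshold | float,
    min_bins: int = 1,
) -> pd.DataFrame:
    """Classify segments as gain / loss / neutral against a |log2 mean| threshold.

    A segment whose |mean| equals the threshold exactly counts as exceeding.
    Segments supported by fewer than ``min_bins`` unmasked bins are reported
    neutral regardless of their mean (insufficient marker support).
    """
    t = threshold.value if isinstance(threshold, DetectionThreshold) else float(threshold)
    if t < 0:
        raise ValueError("threshold must be >= 0")
    calls = profile.segments.copy()
    mean = calls["mean"].to_numpy()
    state = np.where(mean >= t, "gain", np.where(mean <= -t, "loss", "neutral"))
    state = np.where(calls["n_bins"].to_numpy() < min_bins, "neutral", state)
    calls["state"] = state
    calls["exceeds"] = state != "neutral"
    calls["sample_id"] = profile.sample_id
    return calls


def annotate_genes(calls: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Report genes overlapping (>= 1 bp) any exceeding segment.

    Returns one row per gene: symbol, state ({gain, loss, both, neutral,
    not_assessable}), conflict flag.  A gene on a chromosome absent from the
    profile is not assessable; a gene overlapping both a gain and a loss is
    flagged as a conflict and reported as "both".
    """
    covered = set(calls["chrom"].astype(str))
    exceeding = calls[calls["exceeds"]]
    rows = []
    for g in genes.itertuples(index=False):
        chrom = str(g.chrom)
        if chrom not in covered:
            rows.append((g.symbol, "not_assessable", False))
            continue
        hits = exceeding[
            (exceeding["chrom"].astype(str) == chrom)
            & (exceeding["start"] < g.end)
            & (exceeding["end"] > g.start)
        ]
        states = set(hits["state"])
        if not states:
            rows.append((g.symbol, "neutral", False))
        elif states == {"gain", "loss"}:
            rows.append((g.symbol, "both", True))
        else:
            rows.append((g.symbol, states.pop(), False))
    return pd.DataFrame(rows, columns=["symbol", "state", "conflict"])


def gene_matrix(call_tables: dict, genes: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-sample alteration matrix: +1 gain, -1 loss, 0 neutral, NaN n/a."""
    code = {"gain": 1, "loss": -1, "both": np.nan, "neutral": 0, "not_assessable": np.nan}
    cols = {}
    for sample_id, calls in call_tables.items():
        ann = annotate_genes(calls, genes)
        cols[sample_id] = ann.set_index("symbol")["state"].map(code)
    return pd.DataFrame(cols)


@dataclass
class DetectionCost:
    gene: str
    inspected_length_bp: int
    inspected_segments: int
    found: bool


def detection_cost(profile: SegmentProfile, gene) -> DetectionCost:
    """Cost of reaching ``gene`` when reviewing segments by descending |mean|.

    Segments are ranked by absolute mean (ties in genomic order); genomic
    lengths and counts accumulate until the first segment overlapping the
    gene is included.  If no segment overlaps the gene, ``found`` is False
    and the totals cover the whole profile.
    """
    seg = profile.segments
    if not np.isfinite(seg["mean"]).all():
        raise ValueError("segment means must be finite")
    order = np.argsort(-np.abs(seg["mean"].to_numpy()), kind="stable")
    chrom = str(gene.chrom if hasattr(gene, "chrom") else gene["chrom"])
    g_start = int(gene.start if hasattr(gene, "start") else gene["start"])
    g_end = int(gene.end if hasattr(gene, "end") else gene["end"])
    symbol = str(getattr(gene, "symbol", None) or gene["symbol"])

    total_len = 0
    total_n = 0
    for pos in order:
        row = seg.iloc[pos]
        total_len += int(row["end"] - row["start"])
        total_n += 1
        if str(row["chrom"]) == chrom and row["start"] < g_end and row["end"] > g_start:
            return DetectionCost(symbol, total_len, total_n, True)
    return DetectionCost(symbol, total_len, total_n, False)


def cost_comparison(
    costs_raw: list[DetectionCost],
    costs_corrected: list[DetectionCost],
    costs_gc: list[DetectionCost],
) -> dict:
    """Summaries and paired Wilcoxon tests across the three pipeline conditions.

    Mirrors a three-condition layout (raw, panel-corrected, GC-corrected):
    median and IQR of inspection length and segment count per condition, plus
    paired two-sided Wilcoxon signed-rank tests between consecutive
    conditions.
    """
    lists = {"raw": costs_raw, "corrected": costs_corrected, "gc_corrected": costs_gc}
    n = len(costs_raw)
    if any(len(v) != n for v in lists.values()):
        raise ValueError("cost lists must have equal length")
    genes = [c.gene for c in costs_raw]
    for v in lists.values():
        if [c.gene for c in v] != genes:
            raise ValueError("cost lists must cover the same genes in the same order")

    summary = {}
    for name, v in lists.items():
        lengths = np.array([c.inspected_length_bp for c in v], dtype=float)
        counts = np.array([c.inspected_segments for c in v], dtype=float)
        summary[name] = {
            "median_length_bp": float(np.median(lengths)),
            "iqr_length_bp": tuple(np.percentile(lengths, [25, 75])),
            "median_segments": float(np.median(counts)),
            "iqr_segments": tuple(np.percentile(counts, [25, 75])),
        }

    def paired_p(a, b, attr):
        x = np.array([getattr(c, attr) for c in a], dtype=float)
        y = np.array([getattr(c, attr) for c in b], dtype=float)
        if np.allclose(x, y):
            return 1.0
        method = "exact" if n <= 25 else "approx"
        return float(stats.wilcoxon(x, y, zero_method="wilcox", method=method).pvalue)

    tests = {}
    for (a_name, b_name) in (("raw", "corrected"), ("corrected", "gc_corrected")):
        a, b = lists[a_name], lists[b_name]
        tests[f"{a_name}_vs_{b_name}"] = {
            "p_length": paired_p(a, b, "inspected_length_bp"),
            "p_segments": paired_p(a, b, "inspected_segments"),
        }
    return {"summary": summary, "tests": tests}
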