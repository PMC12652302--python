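"""Cohort-level aggregation of segment profiles and reference-cohort ranking.

Per-sample SEG profiles are projected onto fixed genomic windows (default
0.5 Mbp) by length-weighted averaging of overlapping segment means, averaged
across samples into a cohort profile, and compared against reference cohort
profiles by Spearman correlation on pairwise-complete windows.  Significance
uses the Fisher z transform (z = atanh(rho) * sqrt(n - 3), two-sided normal
p) with Benjamini-Hochberg correction across the references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import chrom_sort_key, normalize_chrom


@dataclass
class AggregatedProfile:
    """Mean log2 segment value per fixed genomic window; NaN where uncovered."""

    label: str
    windows: pd.DataFrame  # chrom, start, end (0-based half-open)
    values: np.ndarray
    window_bp: int = 500_000

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.windows):
            raise ValueError("values and windows length mismatch")


def make_windows(chrom_sizes: dict, window_bp: int = 500_000) -> pd.DataFrame:
    """Tile each chromosome with half-open windows anchored at 0; last window kept short."""
    rows = []
    for chrom in sorted(chrom_sizes, key=chrom_sort_key):
        size = chrom_sizes[chrom]
        for start in range(0, size, window_bp):
            rows.append((normalize_chrom(chrom), start, min(start + window_bp, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def rebin_segments(seg: pd.DataFrame, windows: pd.DataFrame, label: str | None = None) -> AggregatedProfile:
    """Project one sample's SEG rows onto windows by length-weighted mean.

    SEG coordinates are 1-based inclusive; windows half-open.  A window with
    no overlapping segment is undefined (NaN).  Overlapping segments within
    the sample are rejected.
    """
    ids = seg["ID"].unique()
    if len(ids) != 1:
        raise ValueError("rebin_segments expects a single-sample SEG table")
    if label is None:
        label = str(ids[0])
    windows = windows.reset_index(drop=True)
    s = seg.copy()
    s["chrom"] = s["chrom"].map(normalize_chrom)
    s["start0"] = s["loc.start"].astype(np.int64) - 1
    s["end0"] = s["loc.end"].astype(np.int64)

    for chrom, sub in s.groupby("chrom"):
        sub = sub.sort_values("start0")
        prev_end = -1
        prev_idx = None
        for idx, row in sub.iterrows():
            if row["start0"] < prev_end:
                raise ValueError(
                    f"overlapping segments in sample {label} on chrom {chrom}: "
                    f"rows {prev_idx} and {idx}"
                )
            prev_end = row["end0"]
            prev_idx = idx

    wsum = np.zeros(len(windows))
    lsum = np.zeros(len(windows))
    win_by_chrom = {c: sub for c, sub in windows.groupby("chrom")}
    s = s.rename(columns={"seg.mean": "seg_mean"})
    for row in s.itertuples(index=False):
        wins = win_by_chrom.get(row.chrom)
        if wins is None:
            continue
        w_start = wins["start"].to_numpy()
        w_end = wins["end"].to_numpy()
        overlap = np.minimum(w_end, row.end0) - np.maximum(w_start, row.start0)
        hit = overlap > 0
        rows_idx = wins.index.to_numpy()[hit]
        wsum[rows_idx] += overlap[hit] * row.seg_mean
        lsum[rows_idx] += overlap[hit]
    values = np.full(len(windows), np.nan)
    covered = lsum > 0
    values[covered] = wsum[covered] / lsum[covered]
    return AggregatedProfile(label, windows.reset_index(drop=True), values)


def aggregate_cohort(profiles: list[AggregatedProfile], label: str = "cohort") -> AggregatedProfile:
    """Per-window arithmetic mean over samples with defined values."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    w0 = profiles[0].windows
    for p in profiles[1:]:
        if not p.windows[["chrom", "start", "end"]].equals(w0[["chrom", "start", "end"]]):
            raise ValueError("profiles have mismatched windows")
    stack = np.stack([p.values for p in profiles])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows stay NaN
        values = np.nanmean(stack, axis=0)
    return AggregatedProfile(label, w0, values)


def compare_to_references(
    cohort: AggregatedProfile,
    references: list[AggregatedProfile],
    min_windows: int = 10,
) -> pd.DataFrame:
    """Rank reference profiles by Spearman correlation with the cohort.

    Per reference: rho on pairwise-complete windows (average ranks on ties),
    Fisher z = atanh(rho) * sqrt(n - 3), two-sided normal p, BH q across the
    compared references; output sorted by rho descending with rank 1..K.
    References with fewer than ``min_windows`` complete pairs are skipped.
    """
    if not references:
        raise ValueError("need at least one reference profile")
    rows = []
    for ref in references:
        both = np.isfinite(cohort.values) & np.isfinite(ref.values)
        n = int(both.sum())
        if n < min_windows:
            import warnings

            warnings.warn(
                f"reference {ref.label}: only {n} complete windows (< {min_windows}); skipped"
            )
            continue
        rho = stats.spearmanr(cohort.values[both], ref.values[both]).statistic
        rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
        z = np.arctanh(rho_c) * np.sqrt(n - 3)
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"reference": ref.label, "rho": rho, "n_windows": n, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("rho", ascending=False, kind="stable").reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
    return out


def intra_patient_similarity(profiles_by_patient: dict) -> dict:
    """Within-patient pairwise Spearman rho on window values.

    ``profiles_by_patient`` maps patient id to a list of AggregatedProfile;
    singleton patients are skipped.  Returns the per-pair table plus the
    cohort median and IQR of rho.
    """
    rows = []
    for patient, profiles in profiles_by_patient.items():
        if len(profiles) < 2:
            continue
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                a, b = profiles[i], profiles[j]
                both = np.isfinite(a.values) & np.isfinite(b.values)
                if both.sum() < 3:
                    continue
                rho = stats.spearmanr(a.values[both], b.values[both]).statistic
                rows.append({"patient": patient, "pair": (a.label, b.label), "rho": rho})
    table = pd.DataFrame(rows)
    result = {"pairs": table}
    if len(table):
        rho = table["rho"].to_numpy()
        result["median_rho"] = float(np.median(rho))
        result["iqr_rho"] = tuple(np.percentile(rho, [25, 75]))
    return result
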