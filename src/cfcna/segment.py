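"""Circular binary segmentation (CBS) of log2 normalized read-count profiles.

CBS recursively splits each chromosome at the arc (contiguous window on the
circularized bin sequence) maximizing a two-sample t-like statistic between
the arc and its complement.  Significance of the best arc is assessed by a
permutation test of bin order; a segment splits when the permutation p-value
is at most ``alpha``.  Defaults (alpha 0.01, 10,000 permutations, trim 0.025,
no undo step) mirror the documented defaults of the reference R
implementation.  Permutations stop early once a 95% Clopper-Pearson interval
for the p-value lies entirely on one side of ``alpha``; the decision is
deterministic given the seed.

Segmentation operates on log2(NRC) with neutral state 0, so gains and losses
are symmetric; ratio-scale means are reported alongside as ``2**mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta

from .bins import BinSet
from .counts import NrcProfile
from .io import SEG_COLUMNS

_PERM_BLOCK = 100
_SEQ_CONF = 0.05  # two-sided confidence level 95% for the sequential stop


def _trimmed_sd(x: np.ndarray, trim: float) -> float:
    """SD after dropping a fraction ``trim`` of observations from each tail."""
    n = len(x)
    drop = int(np.floor(n * trim))
    xs = np.sort(x)
    core = xs[drop : n - drop] if drop > 0 else xs
    if len(core) < 2:
        return 0.0
    return float(np.std(core, ddof=1))


def _arc_factors(n: int, s: float) -> np.ndarray:
    """Scale factors sqrt(n / (k (n-k))) / s for arc lengths k = 1..n//2."""
    k = np.arange(1, n // 2 + 1, dtype=float)
    return np.sqrt(n / (k * (n - k))) / s


def _max_arc_stat(x: np.ndarray, s: float):
    """Best circular split of ``x``: (t_max, arc_start, arc_len).

    Every circular two-arc split equals some linear window [i, i+k) vs the
    rest with k <= n//2, so those windows are scanned exhaustively.  Ties are
    broken by the leftmost start, then the shortest arc.
    """
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    mean = cs[-1] / n
    factors = _arc_factors(n, s)
    best = (-np.inf, 0, 0)
    for k in range(1, n // 2 + 1):
        w = cs[k:] - cs[:-k]
        d = np.abs(w - k * mean)
        i = int(np.argmax(d))
        t = d[i] * factors[k - 1]
        if t > best[0] or (t == best[0] and (i, k) < (best[1], best[2])):
            best = (t, i, k)
    return best


def _perm_max_stats(x: np.ndarray, factors: np.ndarray, rng, n_perm: int) -> np.ndarray:
    """Max arc statistic for ``n_perm`` random permutations of ``x`` (batched).

    The statistic is invariant to a location shift, so values are mean-centered
    first (the window term W - k*mean drops out), keeping cumulative sums small
    enough that single precision is safe for the permutation comparisons.
    """
    n = len(x)
    xc = (x - x.mean()).astype(np.float32)
    perms = rng.permuted(np.tile(xc, (n_perm, 1)), axis=1)
    cs = np.concatenate(
        [np.zeros((n_perm, 1), dtype=np.float32), np.cumsum(perms, axis=1, dtype=np.float32)],
        axis=1,
    )
    out = np.zeros(n_perm, dtype=np.float32)
    f32 = factors.astype(np.float32)
    for k in range(1, n // 2 + 1):
        w = cs[:, k:] - cs[:, :-k]
        np.abs(w, out=w)
        np.maximum(out, w.max(axis=1) * f32[k - 1], out=out)
    return out.astype(float)


def _split_is_significant(
    x: np.ndarray, t_obs: float, factors: np.ndarray,
    alpha: float, n_permutations: int, rng,
) -> bool:
    """Sequential permutation test: is P(max stat >= t_obs) <= alpha?"""
    done = 0
    exceed = 0
    # permutation stats are single precision; a permutation reproducing the
    # observed arrangement must count as a tie, so compare with a relative slack
    t_ref = t_obs * (1.0 - 1e-4)
    while done < n_permutations:
        block = min(_PERM_BLOCK, n_permutations - done)
        stats = _perm_max_stats(x, factors, rng, block)
        exceed += int((stats >= t_ref).sum())
        done += block
        if exceed == 0:
            upper = 1.0 - (_SEQ_CONF / 2) ** (1.0 / done)
        else:
            upper = float(beta.ppf(1 - _SEQ_CONF / 2, exceed + 1, done - exceed))
        lower = 0.0 if exceed == 0 else float(beta.ppf(_SEQ_CONF / 2, exceed, done - exceed + 1))
        if upper <= alpha:
            return True
        if lower > alpha:
            return False
    return exceed / n_permutations <= alpha


@dataclass
class SegmentProfile:
    """Ordered CBS segments for one sample, with the parameters that made them.

    ``segments`` columns: chrom, start, end (0-based half-open bp),
    first_bin, last_bin (global bin indices), n_bins (unmasked members,
    "num.mark"), mean (mean log2 NRC of member bins).
    """

    sample_id: str
    segments: pd.DataFrame
    parameters: dict = field(default_factory=dict)

    @classmethod
    def from_seg(cls, seg: pd.DataFrame, sample_id: str | None = None) -> "SegmentProfile":
        """Build from a SEG table (1-based inclusive) for a single sample."""
        ids = seg["ID"].unique()
        if sample_id is None:
            if len(ids) != 1:
                raise ValueError("SEG table holds multiple samples; pass sample_id")
            sample_id = ids[0]
        sub = seg[seg["ID"] == sample_id]
        df = pd.DataFrame(
            {
                "chrom": sub["chrom"].astype(str),
                "start": sub["loc.start"].astype(np.int64) - 1,
                "end": sub["loc.end"].astype(np.int64),
                "first_bin": -1,
                "last_bin": -1,
                "n_bins": sub["num.mark"].astype(np.int64),
                "mean": sub["seg.mean"].astype(float),
            }
        ).reset_index(drop=True)
        return cls(sample_id, df)

    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"]).to_numpy()


def _segment_chromosome(
    x: np.ndarray, alpha: float, n_permutations: int, trim: float, rng
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's values; returns (lo, hi) index spans."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2:
            out.append((lo, hi))
            continue
        seg = x[lo:hi]
        s = _trimmed_sd(seg, trim)
        if s == 0:
            out.append((lo, hi))
            continue
        t_obs, i, k = _max_arc_stat(seg, s)
        factors = _arc_factors(n, s)
        if _split_is_significant(seg, t_obs, factors, alpha, n_permutations, rng):
            pieces = [(lo, lo + i), (lo + i, lo + i + k), (lo + i + k, hi)]
            # push in reverse so pieces pop left-to-right (deterministic rng order)
            for p in reversed([p for p in pieces if p[1] > p[0]]):
                stack.append(p)
        else:
            out.append((lo, hi))
    return sorted(out)


def cbs_segment(
    nrc: NrcProfile,
    bin_set: BinSet,
    alpha: float = 0.01,
    n_permutations: int = 10000,
    trim: float = 0.025,
    seed: int | None = None,
) -> SegmentProfile:
    """Segment a per-bin NRC profile into runs of constant copy state.

    ``nrc`` may be on the ratio scale (log2 is applied internally, floored at
    epsilon) or already log2.  Masked bins are skipped: segments span them
    positionally but ``n_bins`` counts unmasked members only.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    prof = nrc.to_log2()
    df = bin_set.df
    if len(prof.values) != len(df):
        raise ValueError("profile and bin set lengths differ")

    ss = np.random.SeedSequence(seed)
    chroms = list(dict.fromkeys(df["chrom"]))
    children = ss.spawn(len(chroms))

    rows = []
    for chrom, child in zip(chroms, children):
        in_chrom = (df["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(in_chrom & ~prof.mask & np.isfinite(prof.values))
        if len(idx) == 0:
            continue
        x = prof.values[idx]
        if len(idx) == 1:
            spans = [(0, 1)]
        else:
            rng = np.random.default_rng(child)
            spans = _segment_chromosome(x, alpha, n_permutations, trim, rng)
        for lo, hi in spans:
            members = idx[lo:hi]
            rows.append(
                (
                    chrom,
                    int(df["start"].iloc[members[0]]),
                    int(df["end"].iloc[members[-1]]),
                    int(members[0]),
                    int(members[-1]),
                    hi - lo,
                    float(np.mean(x[lo:hi])),
                )
            )
    segments = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "first_bin", "last_bin", "n_bins", "mean"]
    )
    params = {
        "alpha": alpha,
        "n_permutations": n_permutations,
        "trim": trim,
        "seed": seed,
    }
    return SegmentProfile(prof.sample_id, segments, params)


def merge_to_seg(profiles: list[SegmentProfile], bin_set: BinSet | None = None) -> pd.DataFrame:
    """Combine segment profiles into a SEG table (1-based inclusive coordinates)."""
    frames = []
    for p in profiles:
        df = pd.DataFrame(
            {
                "ID": p.sample_id,
                "chrom": p.segments["chrom"],
                "loc.start": p.segments["start"] + 1,
                "loc.end": p.segments["end"],
                "num.mark": p.segments["n_bins"],
                "seg.mean": p.segments["mean"],
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SEG_COLUMNS)
    from .io import chrom_sort_key

    out = out.sort_values(
        ["ID", "chrom", "loc.start"],
        key=lambda col: col.map(chrom_sort_key) if col.name == "chrom" else col,
        kind="stable",
    )
    return out.reset_index(drop=True)
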