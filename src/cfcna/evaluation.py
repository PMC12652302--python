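"""Benchmark experiments on synthetic data with known truth.

Each function runs one self-contained experiment at the generator's default
study conditions and returns the quantities a user would inspect to judge the
pipeline: residual GC correlation before/after correction, segmentation
accuracy against brute-force oracles, recovery of diluted copy-number signal,
the inspection-cost ordering across normalization conditions, and
reference-cohort ranking.  All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bins import BinSet
from .calls import (
    DEFAULT_THRESHOLD_FLOOR,
    DetectionThreshold,
    call_cnas,
    compute_threshold,
    cost_comparison,
    detection_cost,
)
from .cohort import aggregate_cohort, compare_to_references, make_windows, rebin_segments
from .counts import NrcProfile, nrc_raw
from .normalize import ControlPanel, gc_correct, nrc_corrected
from .segment import SegmentProfile, cbs_segment, merge_to_seg
from .simulate import (
    CnaEvent,
    SimulationConfig,
    cohort_from_reference,
    make_pseudo_binset,
    make_reference_segs,
    random_events,
    simulate_normals,
    simulate_tumor,
)


# ---------------------------------------------------------------------------
# GC-correction null suite


def gc_correction_null_suite(
    n_runs: int = 20, n_bins: int = 2000, panel_size: int = 4, seed: int = 0
) -> dict:
    """Normal-vs-panel runs with injected GC bias: residual |rho| before/after.

    Each run simulates a fresh panel of normals, treats the first as the test
    sample against the rest, and measures |Spearman rho(NRC, GC)| for the
    panel-normalized profile (before) and the GC-corrected profile (after).
    """
    before, after = [], []
    for r in range(n_runs):
        config = SimulationConfig(n_bins=n_bins, n_normals=panel_size, seed=seed + 1000 + r)
        bin_set = make_pseudo_binset(n_bins, seed=seed + 1000 + r)
        normals, _ = simulate_normals(config, bin_set)
        test = nrc_raw(normals[0])
        panel = ControlPanel([nrc_raw(p) for p in normals[1:]])
        corr = nrc_corrected(test, panel)
        gcc = gc_correct(test, panel, bin_set.gc)
        kb, ka = ~corr.mask, ~gcc.mask
        before.append(abs(stats.spearmanr(corr.values[kb], bin_set.gc[kb]).statistic))
        after.append(abs(stats.spearmanr(gcc.values[ka], bin_set.gc[ka]).statistic))
    before, after = np.array(before), np.array(after)
    p = stats.wilcoxon(before, after, method="exact" if n_runs <= 25 else "approx").pvalue
    return {
        "rho_before": before,
        "rho_after": after,
        "median_rho_before": float(np.median(before)),
        "median_rho_after": float(np.median(after)),
        "wilcoxon_p": float(p),
    }


def read_count_pattern_suite(n_bins: int = 4000, n_normals: int = 8, seed: int = 0) -> dict:
    """Shared read-count structure of simulated normals.

    Reports the mean pairwise Pearson correlation of raw counts across the
    panel and the Pearson correlation between the TI-wavelet-denoised
    panel-averaged NRC signal and the denoised GC ratio signal.
    """
    from .counts import read_count_similarity
    from .normalize import ti_wavelet_denoise

    config = SimulationConfig(n_bins=n_bins, n_normals=n_normals, seed=seed + 61)
    bin_set = make_pseudo_binset(n_bins, seed=seed + 61)
    normals, _ = simulate_normals(config, bin_set)
    sim = read_count_similarity(normals)
    iu = np.triu_indices(n_normals, 1)
    mean_r = float(np.nanmean(sim.values[iu]))

    avg_nrc = np.mean([nrc_raw(p).values for p in normals], axis=0)
    den_nrc = ti_wavelet_denoise(avg_nrc)
    den_gc = ti_wavelet_denoise(bin_set.gc)
    r_gc = float(stats.pearsonr(den_nrc, den_gc).statistic)
    return {"mean_pairwise_r": mean_r, "denoised_nrc_gc_r": r_gc, "n_bins": n_bins}


# ---------------------------------------------------------------------------
# CBS vs brute-force oracles


def _sse_best_split(x: np.ndarray) -> int:
    best, best_c = np.inf, 1
    for c in range(1, len(x)):
        sse = ((x[:c] - x[:c].mean()) ** 2).sum() + ((x[c:] - x[c:].mean()) ** 2).sum()
        if sse < best:
            best, best_c = sse, c
    return best_c


def _sse_best_arc(x: np.ndarray) -> tuple[int, int]:
    """Exhaustive (i, j) search minimizing SSE of a 3-piece split."""
    n = len(x)
    best, best_pair = np.inf, (0, n)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(a, b):
        if b <= a:
            return 0.0
        s, s2 = cs[b] - cs[a], cs2[b] - cs2[a]
        return s2 - s * s / (b - a)

    for i in range(n):
        for j in range(i + 1, n + 1):
            if (i, j) == (0, n):
                continue
            val = sse(0, i) + sse(i, j) + sse(j, n)
            if val < best:
                best, best_pair = val, (i, j)
    return best_pair


def cbs_oracle_suite(n_signals: int = 50, seed: int = 0) -> dict:
    """Seeded <=200-bin signals with 0-2 changepoints: breakpoints vs oracles.

    For single-boundary signals the oracle is an exhaustive SSE split search;
    for interior events it is an exhaustive (i, j) arc SSE search.  A signal
    counts as matched when every detected breakpoint sits within +-1 bin of
    the oracle's and the breakpoint count is right.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    matched = 0
    oracle_bps = 0
    recovered_bps = 0
    for s in range(n_signals):
        n = int(rng.integers(100, 201))
        kind = s % 3  # 0, 1 or 2 changepoints in rotation
        x = rng.normal(0, 0.1, n)
        amp = float(rng.uniform(0.8, 1.2)) * (1 if rng.random() < 0.5 else -1)
        if kind == 1:
            c = int(rng.integers(20, n - 20))
            x[c:] += amp
        elif kind == 2:
            i0 = int(rng.integers(10, n - 50))
            j0 = int(i0 + rng.integers(20, min(60, n - i0 - 10)))
            x[i0:j0] += amp
        bs_df = pd.DataFrame(
            {"chrom": "1", "start": np.arange(n) * 100, "end": np.arange(n) * 100 + 100,
             "n_mappable": 50, "gc_ratio": 0.5}
        )
        seg = cbs_segment(
            NrcProfile("sig", x, "log2"), BinSet(bs_df), seed=seed + 500 + s
        )
        found = sorted(seg.segments["first_bin"].iloc[1:].tolist())
        if kind == 0:
            oracle = []
        elif kind == 1:
            oracle = [_sse_best_split(x)]
        else:
            oracle = list(_sse_best_arc(x))
        matched += len(found) == len(oracle) and all(
            abs(f - o) <= 1 for f, o in zip(found, oracle)
        )
        oracle_bps += len(oracle)
        recovered_bps += sum(any(abs(f - o) <= 1 for f in found) for o in oracle)
    return {
        "n_signals": n_signals,
        "n_matched": matched,
        "match_rate": matched / n_signals,
        "breakpoint_recall": recovered_bps / oracle_bps if oracle_bps else 1.0,
    }


def flat_null_split_rate(
    n_reps: int = 200, n_bins: int = 500, alpha: float = 0.01, seed: int = 0
) -> dict:
    """Fraction of pure-noise chromosomes split at the given alpha."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    bs_df = pd.DataFrame(
        {"chrom": "1", "start": np.arange(n_bins) * 100,
         "end": np.arange(n_bins) * 100 + 100, "n_mappable": 50, "gc_ratio": 0.5}
    )
    bs = BinSet(bs_df)
    splits = 0
    for r in range(n_reps):
        x = rng.normal(0, 0.1, n_bins)
        seg = cbs_segment(NrcProfile("null", x, "log2"), bs, alpha=alpha, seed=seed + 2000 + r)
        splits += len(seg.segments) > 1
    return {"n_reps": n_reps, "n_split": splits, "split_rate": splits / n_reps}


# ---------------------------------------------------------------------------
# Tumor-fraction parameter recovery


def _event_f1(truth_seg: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Event-level precision/recall/F1 of exceeding calls against truth events.

    A truth event is recovered when exceeding segments of the correct
    direction cover >= 50% of it; an exceeding called run (adjacent same-state
    segments merged) is a false positive when it overlaps no truth event.
    """
    exceeding = calls[calls["exceeds"]].copy()
    # merge adjacent same-state exceeding segments into runs
    runs = []
    for (chrom, state), sub in exceeding.groupby(["chrom", "state"]):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples():
            if cur is not None and r.start <= cur[2]:
                cur[2] = max(cur[2], r.end)
            else:
                if cur is not None:
                    runs.append(tuple(cur))
                cur = [chrom, r.start, r.end, state]
        if cur is not None:
            runs.append(tuple(cur))

    truth = truth_seg.rename(columns={"loc.start": "start1", "loc.end": "end1",
                                      "seg.mean": "mean"})
    tp = 0
    for ev in truth.itertuples(index=False):
        direction = "gain" if ev.mean > 0 else "loss"
        ev_start, ev_end = ev.start1 - 1, ev.end1
        cover = 0
        for chrom, s, e, state in runs:
            if str(chrom) == str(ev.chrom) and state == direction:
                cover += max(0, min(e, ev_end) - max(s, ev_start))
        tp += cover >= 0.5 * (ev_end - ev_start)
    fp = 0
    for chrom, s, e, state in runs:
        hit = False
        for ev in truth.itertuples(index=False):
            if str(chrom) == str(ev.chrom) and min(e, ev.end1) - max(s, ev.start1 - 1) > 0:
                hit = True
        fp += not hit
    n_truth = len(truth_seg)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "n_truth": n_truth,
            "precision": precision, "recall": recall, "f1": f1}


def parameter_recovery(
    tumor_fractions=(0.05, 0.3, 0.5),
    n_bins: int = 8000,
    n_tumors: int = 3,
    event_bins: tuple[int, int] = (500, 650),
    seed: int = 0,
    n_permutations: int = 10000,
) -> dict:
    """Recovery of diluted CNA signal from simulated tumors at default depth.

    Tumors carry two events each (one amplification c=4, one single-copy loss
    c=1) of >=500 bins.  Reports, per tumor fraction, the maximum absolute
    error of GC-corrected segment means against log2((1-TF) + TF*c/2) over
    recovered events, and the event-level detection F1 against the panel-null
    threshold with the package's conservative floor and marker-support
    defaults.
    """
    config = SimulationConfig(n_bins=n_bins, seed=seed + 31)
    bin_set = make_pseudo_binset(n_bins, seed=seed + 31)
    normals, truth = simulate_normals(config, bin_set)
    panel = ControlPanel([nrc_raw(p) for p in normals])
    loo = compute_threshold(
        normals, bin_set, percentile=99.5, use_gc_correction=True,
        n_permutations=n_permutations, seed=seed + 600, min_bins=10,
    )
    threshold = DetectionThreshold(
        max(loo.value, DEFAULT_THRESHOLD_FLOOR), loo.method, loo.percentile, loo.n_panel_runs
    )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 33]))
    results = {"threshold": threshold.value, "loo_threshold": loo.value, "per_tf": {}}
    for tf in tumor_fractions:
        errors, f1s = [], []
        for t in range(n_tumors):
            events = []
            chroms = list(dict.fromkeys(bin_set.df["chrom"]))
            for chrom, c in zip(rng.permutation(chroms)[:2], (4, 1)):
                sub = bin_set.df[bin_set.df["chrom"] == chrom]
                width = int(rng.integers(*event_bins))
                lo = int(rng.integers(0, len(sub) - width))
                events.append(
                    CnaEvent(chrom, int(sub["start"].iloc[lo]),
                             int(sub["end"].iloc[lo + width - 1]), c)
                )
            profile, truth_seg = simulate_tumor(
                config, events, tf, bin_set, sample_id=f"tf{tf}_{t}",
                efficiency=truth["efficiency"], sample_seed=300 + t,
            )
            gcc = gc_correct(nrc_raw(profile), panel, bin_set.gc)
            seg = cbs_segment(gcc, bin_set, n_permutations=n_permutations,
                              seed=seed + 700 + t)
            calls = call_cnas(seg, threshold, min_bins=10)
            f1s.append(_event_f1(truth_seg, calls)["f1"])
            # segment-mean recovery: best-overlapping segment per event
            for ev, expected in zip(events, truth_seg["seg.mean"]):
                sub = seg.segments[
                    (seg.segments["chrom"] == ev.chrom)
                    & (seg.segments["start"] < ev.end_bp)
                    & (seg.segments["end"] > ev.start_bp)
                ]
                if len(sub):
                    overlap = np.minimum(sub["end"], ev.end_bp) - np.maximum(sub["start"], ev.start_bp)
                    mean = sub["mean"].iloc[int(np.argmax(overlap))]
                    errors.append(abs(mean - expected))
        results["per_tf"][tf] = {
            "max_abs_mean_error": float(max(errors)) if errors else np.nan,
            "mean_f1": float(np.mean(f1s)),
        }
    return results


# ---------------------------------------------------------------------------
# Inspection-cost ordering across normalization conditions


def cost_ordering_experiment(
    n_bins: int = 8000,
    tumor_fractions=(0.3, 0.5, 0.7),
    seed: int = 0,
    n_permutations: int = 10000,
) -> dict:
    """Median inspection cost for truth genes under raw / corrected / GC-corrected.

    Simulates tumors whose events harbor known marker genes, segments each
    tumor under the three normalization conditions, and accumulates the
    ranked inspection cost of every truth gene in its own tumor.
    """
    config = SimulationConfig(n_bins=n_bins, seed=seed + 41)
    bin_set = make_pseudo_binset(n_bins, seed=seed + 41)
    normals, truth = simulate_normals(config, bin_set)
    panel = ControlPanel([nrc_raw(p) for p in normals])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))

    costs = {"raw": [], "corrected": [], "gc_corrected": []}
    for t, tf in enumerate(tumor_fractions):
        events = random_events(bin_set, rng, n_events=4, min_bins=150, max_bins=350)
        profile, _ = simulate_tumor(
            config, events, tf, bin_set, sample_id=f"tumor{t}",
            efficiency=truth["efficiency"], sample_seed=400 + t,
        )
        raw = nrc_raw(profile)
        conditions = {
            "raw": raw,
            "corrected": nrc_corrected(raw, panel),
            "gc_corrected": gc_correct(raw, panel, bin_set.gc),
        }
        genes = []
        for ev in events:
            mid = (ev.start_bp + ev.end_bp) // 2
            genes.append(pd.Series({"chrom": ev.chrom, "start": mid, "end": mid + 20_000,
                                    "symbol": f"G_{t}_{ev.chrom}_{mid}"}))
        for cond, prof in conditions.items():
            seg = cbs_segment(prof, bin_set, n_permutations=n_permutations,
                              seed=seed + 800 + 10 * t + len(cond))
            for gene in genes:
                costs[cond].append(detection_cost(seg, gene))

    comparison = cost_comparison(costs["raw"], costs["corrected"], costs["gc_corrected"])
    comparison["n_genes"] = len(costs["raw"])
    return comparison


# ---------------------------------------------------------------------------
# Reference-cohort ranking


def reference_ranking_experiment(
    n_references: int = 7,
    n_samples: int = 8,
    n_bins: int = 6000,
    window_bp: int = 500_000,
    seed: int = 0,
) -> dict:
    """A cohort simulated from one reference SEG must rank that reference first.

    Builds one "true" reference and decoys, simulates a cohort of noisy
    attenuated copies of the true reference profile, aggregates, and ranks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 51]))
    bin_set = make_pseudo_binset(n_bins, seed=seed + 51)
    refs = make_reference_segs(bin_set, n_references, rng)
    labels = sorted(refs)
    true_label = labels[0]
    sizes = bin_set.df.groupby("chrom")["end"].max().to_dict()
    windows = make_windows(sizes, window_bp)

    samples = cohort_from_reference(refs[true_label], windows, n_samples, rng)
    cohort = aggregate_cohort(samples)
    ref_profiles = [rebin_segments(refs[l], windows) for l in labels]
    ranking = compare_to_references(cohort, ref_profiles)
    row = ranking[ranking["reference"] == true_label].iloc[0]

    self_rho = compare_to_references(
        cohort, [aggregate_cohort(samples, label="self")]
    )["rho"].iloc[0]
    return {
        "ranking": ranking,
        "true_reference": true_label,
        "true_rank": int(row["rank"]),
        "true_rho": float(row["rho"]),
        "true_q": float(row["q"]),
        "self_rho": float(self_rho),
    }
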