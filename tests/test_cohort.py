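import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfcna.cohort import (
    AggregatedProfile,
    aggregate_cohort,
    compare_to_references,
    intra_patient_similarity,
    make_windows,
    rebin_segments,
)
from cfcna.io import SEG_COLUMNS


def seg_table(rows, sample_id="s"):
    """rows: (chrom, start0, end0, mean) with 0-based half-open input for clarity."""
    return pd.DataFrame(
        [(sample_id, c, s + 1, e, max((e - s) // 100, 1), m) for c, s, e, m in rows],
        columns=SEG_COLUMNS,
    )


def windows_1mb(n, chrom="1"):
    return make_windows({chrom: n * 1_000_000}, 1_000_000)


class TestRebinSegments:
    def test_segment_exactly_covering_one_window(self):
        prof = rebin_segments(seg_table([("1", 0, 1_000_000, 0.7)]), windows_1mb(2))
        assert prof.values[0] == pytest.approx(0.7)
        assert np.isnan(prof.values[1])

    def test_segment_covering_two_windows(self):
        prof = rebin_segments(seg_table([("1", 0, 2_000_000, 0.4)]), windows_1mb(2))
        assert np.allclose(prof.values, 0.4)

    def test_length_weighted_mean_of_half_windows(self):
        rows = [("1", 0, 500_000, 0.0), ("1", 500_000, 1_000_000, 1.0)]
        prof = rebin_segments(seg_table(rows), windows_1mb(1))
        assert prof.values[0] == pytest.approx(0.5)

    def test_overlapping_segments_rejected(self):
        rows = [("1", 0, 600_000, 0.0), ("1", 400_000, 1_000_000, 1.0)]
        with pytest.raises(ValueError, match="overlap"):
            rebin_segments(seg_table(rows), windows_1mb(1))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_conserves_length_weighted_genome_mean(self, seed):
        rng = np.random.default_rng(seed)
        rows, pos = [], 0
        for _ in range(12):
            width = int(rng.integers(200_000, 2_000_000))
            rows.append(("1", pos, pos + width, float(rng.normal(0, 0.5))))
            pos += width
        windows = make_windows({"1": pos}, 500_000)
        prof = rebin_segments(seg_table(rows), windows)
        w_len = (windows["end"] - windows["start"]).to_numpy(dtype=float)
        covered = np.isfinite(prof.values)
        lhs = np.sum(prof.values[covered] * w_len[covered])
        rhs = sum((e - s) * m for _, s, e, m in rows)
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestAggregateCohort:
    def make(self, values, label="p"):
        return AggregatedProfile(label, windows_1mb(len(values)), np.asarray(values, float))

    def test_single_profile_identity(self):
        p = self.make([0.1, 0.2, np.nan])
        agg = aggregate_cohort([p])
        assert np.allclose(agg.values[:2], p.values[:2]) and np.isnan(agg.values[2])

    def test_mean_of_two(self):
        agg = aggregate_cohort([self.make([0.0, 1.0]), self.make([1.0, 1.0])])
        assert agg.values.tolist() == [0.5, 1.0]

    def test_defined_plus_undefined_keeps_defined(self):
        agg = aggregate_cohort([self.make([0.5, np.nan]), self.make([np.nan, np.nan])])
        assert agg.values[0] == 0.5 and np.isnan(agg.values[1])

    def test_window_mismatch_rejected(self):
        a = self.make([0.0, 1.0])
        b = AggregatedProfile("q", windows_1mb(2, chrom="2"), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="window"):
            aggregate_cohort([a, b])


class TestCompareToReferences:
    def profiles(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        wins = windows_1mb(n)
        cohort = AggregatedProfile("cohort", wins, rng.normal(0, 0.5, n))
        decoys = [
            AggregatedProfile(f"decoy{i}", wins, rng.normal(0, 0.5, n)) for i in range(4)
        ]
        return cohort, decoys

    def test_self_comparison_rho_one_rank_one(self):
        cohort, decoys = self.profiles()
        self_ref = AggregatedProfile("self", cohort.windows, cohort.values.copy())
        out = compare_to_references(cohort, decoys + [self_ref])
        assert out["reference"].iloc[0] == "self"
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["rank"].iloc[0] == 1

    def test_negation_gives_minus_one(self):
        cohort, _ = self.profiles()
        neg = AggregatedProfile("neg", cohort.windows, -cohort.values)
        out = compare_to_references(cohort, [neg, cohort])
        assert out.set_index("reference").loc["neg", "rho"] == pytest.approx(-1.0)

    def test_rho_and_bh_match_hand_oracles(self):
        rng = np.random.default_rng(5)
        wins = windows_1mb(12)
        cohort = AggregatedProfile("c", wins, rng.normal(0, 1, 12))
        refs = [AggregatedProfile(f"r{i}", wins, rng.normal(0, 1, 12)) for i in range(4)]
        out = compare_to_references(cohort, refs).set_index("reference")
        ps = []
        for ref in refs:
            # rank-then-Pearson oracle for Spearman
            rho_hand = np.corrcoef(
                stats.rankdata(cohort.values), stats.rankdata(ref.values)
            )[0, 1]
            assert out.loc[ref.label, "rho"] == pytest.approx(rho_hand, abs=1e-12)
            z = np.arctanh(rho_hand) * np.sqrt(12 - 3)
            ps.append(2 * stats.norm.sf(abs(z)))
        # Benjamini-Hochberg step-up by hand for K = 4
        order = np.argsort(ps)
        q_hand = np.empty(4)
        prev = 1.0
        for rank_pos in range(3, -1, -1):
            i = order[rank_pos]
            prev = min(prev, ps[i] * 4 / (rank_pos + 1))
            q_hand[i] = prev
        for i, ref in enumerate(refs):
            assert out.loc[ref.label, "q"] == pytest.approx(q_hand[i], abs=1e-12)

    def test_monotone_transform_invariance(self):
        cohort, decoys = self.profiles(seed=3)
        out1 = compare_to_references(cohort, decoys)
        warped = AggregatedProfile("c", cohort.windows, np.exp(cohort.values) ** 3)
        out2 = compare_to_references(warped, decoys)
        assert np.allclose(out1["rho"], out2["rho"])

    def test_sparse_reference_skipped(self):
        cohort, decoys = self.profiles()
        sparse_vals = np.full(30, np.nan)
        sparse_vals[:5] = 1.0
        sparse = AggregatedProfile("sparse", cohort.windows, sparse_vals)
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_to_references(cohort, decoys + [sparse])
        assert "sparse" not in set(out["reference"])


class TestIntraPatientSimilarity:
    def make(self, values, label):
        return AggregatedProfile(label, windows_1mb(len(values)), np.asarray(values, float))

    def test_duplicate_samples_rho_one(self):
        v = np.random.default_rng(1).normal(0, 1, 40)
        out = intra_patient_similarity({"P1": [self.make(v, "a"), self.make(v, "b")]})
        assert out["median_rho"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        rhos = []
        for i in range(10):
            a = self.make(rng.normal(0, 1, 3000), f"a{i}")
            b = self.make(rng.normal(0, 1, 3000), f"b{i}")
            out = intra_patient_similarity({"P": [a, b]})
            rhos.append(abs(out["median_rho"]))
        assert np.median(rhos) < 0.05

    def test_matches_direct_pairwise_loop(self):
        rng = np.random.default_rng(3)
        groups = {
            "P1": [self.make(rng.normal(0, 1, 20), f"p1s{i}") for i in range(2)],
            "P2": [self.make(rng.normal(0, 1, 20), f"p2s{i}") for i in range(3)],
            "P3": [self.make(rng.normal(0, 1, 20), "only")],  # singleton skipped
        }
        out = intra_patient_similarity(groups)
        expected = []
        for pid in ("P1", "P2"):
            ps = groups[pid]
            for i in range(len(ps)):
                for j in range(i + 1, len(ps)):
                    expected.append(stats.spearmanr(ps[i].values, ps[j].values).statistic)
        assert len(out["pairs"]) == len(expected)  # 1 + 3 pairs
        assert np.allclose(sorted(out["pairs"]["rho"]), sorted(expected))
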