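import itertools

import numpy as np
import pytest
from scipy import stats

from cfcna.counts import CountProfile, NrcProfile, nrc_raw
from cfcna.normalize import (
    ControlPanel,
    fit_gc_loess,
    gc_correct,
    gc_diagnostics,
    nrc_corrected,
    ti_wavelet_denoise,
)


def ratio_profile(values, sample_id="s", mask=None):
    return NrcProfile(sample_id, np.asarray(values, dtype=float), "ratio", mask, "raw")


class TestNrcCorrected:
    def test_self_ratio_is_one(self):
        x = ratio_profile([0.5, 1.0, 2.0, 1.5])
        out = nrc_corrected(x, ControlPanel([x]))
        assert np.allclose(out.unmasked(), 1.0)

    def test_median_of_ratios(self):
        test = ratio_profile([2.0] * 3)
        panel = ControlPanel(
            [ratio_profile([1.0] * 3), ratio_profile([2.0] * 3), ratio_profile([4.0] * 3)]
        )
        out = nrc_corrected(test, panel)
        # ratios {2, 1, 0.5} at every bin -> median 1
        assert np.allclose(out.values, 1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_elementwise_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        test = ratio_profile(rng.uniform(0.5, 2.0, 20))
        controls = [ratio_profile(rng.uniform(0.5, 2.0, 20)) for _ in range(3)]
        out = nrc_corrected(test, ControlPanel(controls))
        for i in range(20):
            ratios = sorted(test.values[i] / c.values[i] for c in controls)
            assert out.values[i] == pytest.approx(ratios[1], abs=1e-12)

    def test_mask_propagates(self):
        test = ratio_profile([1, 1, 1], mask=np.array([True, False, False]))
        panel = ControlPanel([ratio_profile([1, 0.0, 1])])  # bin 1 fails positivity
        out = nrc_corrected(test, panel)
        assert out.mask.tolist() == [True, True, False]


def loess_oracle(x0, x, y, span):
    """Independent tricube weighted-least-squares fit at one query point."""
    n = len(x)
    k = int(span * n)
    d = np.abs(x - x0)
    dmax = np.sort(d)[k - 1]
    w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
    X = np.stack([np.ones(n), x - x0], axis=1)
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return beta[0]


class TestGcLoess:
    def test_constant_response_reproduced(self):
        gc = np.linspace(0.2, 0.8, 40)
        fitted = fit_gc_loess(np.full(40, 3.3), gc, span=0.5)
        assert np.allclose(fitted, 3.3, atol=1e-9)

    def test_linear_response_reproduced(self):
        gc = np.linspace(0.1, 0.9, 60)
        y = 2.0 + 1.5 * gc
        fitted = fit_gc_loess(y, gc, span=0.4, robust_iters=0)
        interior = (gc > 0.2) & (gc < 0.8)
        assert np.allclose(fitted[interior], y[interior], atol=1e-6)

    def test_matches_wls_oracle_at_query_points(self):
        rng = np.random.default_rng(7)
        gc = np.sort(rng.uniform(0.2, 0.8, 50))
        y = np.sin(gc * 4) + rng.normal(0, 0.05, 50)
        fitted = fit_gc_loess(y, gc, span=0.5, robust_iters=0)
        for idx in (10, 25, 40):
            assert fitted[idx] == pytest.approx(loess_oracle(gc[idx], gc, y, 0.5), abs=1e-6)

    def test_too_small_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            fit_gc_loess(np.ones(20), np.linspace(0, 1, 20), span=0.05)

    def test_gc_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="gc"):
            fit_gc_loess(np.ones(20), np.linspace(0, 2, 20), span=0.5)


class TestGcCorrect:
    def test_pure_gc_effect_absorbed(self):
        rng = np.random.default_rng(0)
        gc = np.sort(rng.uniform(0.25, 0.75, 300))
        bias = 1.0 + 0.5 * (gc - 0.5)  # noiseless smooth GC-only effect
        test = ratio_profile(bias)
        panel = ControlPanel([ratio_profile(np.ones(300))])
        out = gc_correct(test, panel, gc)
        interior = (gc > 0.3) & (gc < 0.7)
        assert np.all(np.abs(out.values[interior] - 1.0) < 0.02)

    def test_constant_ratio_two_normalizes_to_one(self):
        gc = np.linspace(0.3, 0.7, 50)
        test = ratio_profile(np.full(50, 2.0))
        panel = ControlPanel([ratio_profile(np.ones(50))])
        out = gc_correct(test, panel, gc)
        assert np.allclose(out.unmasked(), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [3])
    def test_stepwise_recomputation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gc = np.sort(rng.uniform(0.2, 0.8, 100))
        test = ratio_profile(rng.uniform(0.8, 1.2, 100))
        controls = [ratio_profile(rng.uniform(0.8, 1.2, 100)) for _ in range(2)]
        out = gc_correct(test, ControlPanel(controls), gc, span=0.4, robust_iters=1)
        # recompose by hand, control by control
        per_control = []
        for c in controls:
            r = test.values / c.values
            f = fit_gc_loess(r, gc, span=0.4, robust_iters=1)
            per_control.append(r / f)
        expected = np.median(np.stack(per_control), axis=0)
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_invariant_to_global_rescaling_of_test_counts(self, small_panel):
        _, bin_set, profiles, _ = small_panel
        panel = ControlPanel([nrc_raw(p) for p in profiles[1:]])
        base = gc_correct(nrc_raw(profiles[0]), panel, bin_set.gc)
        scaled_counts = CountProfile(profiles[0].sample_id, profiles[0].counts * 3)
        scaled = gc_correct(nrc_raw(scaled_counts), panel, bin_set.gc)
        keep = ~base.mask & ~scaled.mask
        assert np.allclose(base.values[keep], scaled.values[keep], atol=1e-6)

    def test_masked_bins_monotone_nondecreasing(self, small_panel):
        _, bin_set, profiles, _ = small_panel
        raw = nrc_raw(profiles[0])
        panel = ControlPanel([nrc_raw(p) for p in profiles[1:]])
        corr = nrc_corrected(raw, panel)
        gcc = gc_correct(raw, panel, bin_set.gc)
        assert raw.mask.sum() <= corr.mask.sum() <= gcc.mask.sum()


class TestTiWaveletDenoise:
    def test_constant_signal_unchanged(self):
        x = np.full(64, 2.5)
        assert np.allclose(ti_wavelet_denoise(x), x)

    def test_step_location_preserved(self):
        rng = np.random.default_rng(1)
        x = np.zeros(128)
        x[64:] = 10.0
        noisy = x + rng.normal(0, 0.3, 128)
        den = ti_wavelet_denoise(noisy)
        # largest jump of the denoised signal within +-1 of the true step
        jump = int(np.argmax(np.abs(np.diff(den)))) + 1
        assert abs(jump - 64) <= 1

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(2)
        worse = 0
        for _ in range(100):
            x = rng.normal(0, 1, 64)
            if ti_wavelet_denoise(x).var() >= x.var():
                worse += 1
        assert worse == 0

    def test_interpolates_masked_entries(self):
        x = np.sin(np.linspace(0, 3, 32))
        x[5] = np.nan
        out = ti_wavelet_denoise(x)
        assert np.isfinite(out).all()

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ti_wavelet_denoise(np.ones(4))


class TestGcDiagnostics:
    def test_identical_before_after_p_one(self):
        gc = np.linspace(0.3, 0.7, 50)
        profs = [ratio_profile(np.linspace(0.8, 1.2, 50) + 0.01 * i, f"p{i}") for i in range(4)]
        out = gc_diagnostics(profs, profs, gc)
        assert out["wilcoxon_p"] == 1.0

    def test_nrc_equal_to_gc_correlates_perfectly(self):
        gc = np.linspace(0.3, 0.7, 50)
        out = gc_diagnostics([ratio_profile(gc)], [ratio_profile(np.ones(50))], gc)
        assert out["pairs"]["r_before"].iloc[0] == pytest.approx(1.0)
        assert out["pairs"]["rho_before"].iloc[0] == pytest.approx(1.0)

    def test_exact_wilcoxon_matches_sign_enumeration(self):
        # 6 paired |rho| differences -> exact p from all 2^6 sign patterns
        before = np.array([0.30, 0.25, 0.18, 0.22, 0.35, 0.28])
        after = np.array([0.05, 0.02, 0.20, 0.01, 0.04, 0.03])
        d = before - after
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        total = 0
        extreme = 0
        for signs in itertools.product([1, -1], repeat=n):
            w = ranks[np.array(signs) > 0].sum()
            total += 1
            # two-sided: as or more extreme in either direction
            if min(w, n * (n + 1) / 2 - w) <= min(w_obs, n * (n + 1) / 2 - w_obs):
                extreme += 1
        p_enum = extreme / total
        p_scipy = stats.wilcoxon(before, after, method="exact").pvalue
        assert p_scipy == pytest.approx(p_enum, abs=1e-12)
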