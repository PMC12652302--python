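"""Panel normalization and GC-bias correction of normalized read counts.

Two corrections are applied on the ratio scale (neutral copy state = 1):

* control-panel median ratio:
  ``NRC_corrected(i) = median_j( NRC_raw_test(i) / NRC_raw_control_j(i) )``,
  which cancels the capture-efficiency pattern shared across cfDNA WES
  samples; and
* per-control LOESS GC correction:
  each per-control ratio vector ``r_j`` is fitted by a LOESS curve ``f_j``
  with the bin GC ratio as predictor, and the corrected value is
  ``median_j( r_j(i) / f_j(i) )``, which absorbs the smooth GC-dependent
  residual bias that survives the panel ratio.

The module also provides translation-invariant (cycle-spun) Haar wavelet
denoising and before/after GC-correlation diagnostics with a paired Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .counts import NrcProfile

EPSILON = 1e-6


@dataclass
class ControlPanel:
    """Raw ratio-scale NRC profiles from normal subjects plus a joint bin mask.

    A bin enters ``panel_mask`` (True = excluded) if it is masked in any
    member or any member's value falls below ``epsilon`` — those bins cannot
    safely serve as a ratio denominator.
    """

    profiles: list
    epsilon: float = EPSILON

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("control panel needs at least one profile")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        n = len(self.profiles[0].values)
        for p in self.profiles:
            if len(p.values) != n:
                raise ValueError("panel profiles are not on the same bin set")
            if p.scale != "ratio":
                raise ValueError("panel profiles must be on the ratio scale")

    @property
    def panel_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.profiles[0].values), dtype=bool)
        for p in self.profiles:
            mask |= p.mask
            mask |= p.values < self.epsilon
        return mask

    def __len__(self) -> int:
        return len(self.profiles)


def nrc_corrected(test: NrcProfile, panel: ControlPanel) -> NrcProfile:
    """Median over controls of the per-bin test/control ratio."""
    mask = test.mask | panel.panel_mask
    ratios = np.stack([test.values / np.maximum(p.values, panel.epsilon) for p in panel.profiles])
    values = np.median(ratios, axis=0)
    values[mask] = np.nan
    return NrcProfile(test.sample_id, values, "ratio", mask, "corrected")


def fit_gc_loess(
    response: np.ndarray,
    gc: np.ndarray,
    span: float = 0.3,
    robust_iters: int = 2,
    epsilon: float = EPSILON,
) -> np.ndarray:
    """LOESS fit of ``response`` on ``gc``, evaluated at every input point.

    Locally weighted linear regression with tricube weights on the
    span-nearest neighbors in GC, with ``robust_iters`` bisquare
    reweighting passes.  Fitted values are clamped at ``epsilon`` so they can
    serve as divisors.
    """
    response = np.asarray(response, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if len(response) != len(gc):
        raise ValueError("response and gc must have equal length")
    if len(response) < 10:
        raise ValueError("need at least 10 points for a LOESS fit")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if np.nanmin(gc) < 0 or np.nanmax(gc) > 1:
        raise ValueError("gc values must lie in [0, 1]")
    k = int(span * len(response))
    if k < 3:
        raise ValueError(
            f"span {span} gives neighborhoods of {k} < 3 points; increase span"
        )
    fitted = lowess(
        response, gc, frac=span, it=robust_iters, return_sorted=False
    )
    return np.maximum(fitted, epsilon)


def gc_correct(
    test: NrcProfile,
    panel: ControlPanel,
    gc: np.ndarray,
    span: float = 0.3,
    robust_iters: int = 2,
) -> NrcProfile:
    """Per-control LOESS GC correction of the panel-normalized profile.

    For each control j the ratio vector r_j = test/control_j is LOESS-fitted
    against GC on unmasked bins and divided by its fit; the corrected value is
    the median over controls.  Bins where a fit falls to the positivity clamp
    are masked.
    """
    gc = np.asarray(gc, dtype=float)
    mask = test.mask | panel.panel_mask | ~np.isfinite(gc)
    keep = ~mask
    if keep.sum() < 10:
        raise ValueError("fewer than 10 unmasked bins; cannot GC-correct")
    corrected = []
    n_clamped = 0
    for p in panel.profiles:
        r = test.values[keep] / np.maximum(p.values[keep], panel.epsilon)
        f = fit_gc_loess(r, gc[keep], span=span, robust_iters=robust_iters,
                         epsilon=panel.epsilon)
        n_clamped += int((f <= panel.epsilon).sum())
        corrected.append(r / f)
    if n_clamped:
        warnings.warn(f"gc_correct: {n_clamped} fitted values hit the positivity clamp")
    values = np.full(len(test.values), np.nan)
    values[keep] = np.median(np.stack(corrected), axis=0)
    bad = np.zeros_like(mask)
    bad[keep] = ~np.isfinite(values[keep])
    mask = mask | bad
    values[mask] = np.nan
    return NrcProfile(test.sample_id, values, "ratio", mask, "gc_corrected")


def ti_wavelet_denoise(signal: np.ndarray, max_shifts: int = 32, wavelet: str = "haar") -> np.ndarray:
    """Translation-invariant wavelet shrinkage by cycle spinning.

    Masked/NaN entries are linearly interpolated first.  For each of
    ``min(n, max_shifts)`` circular shifts the signal is Haar-decomposed,
    detail coefficients are soft-thresholded at the universal threshold
    ``sigma * sqrt(2 ln n)`` with ``sigma = MAD(finest details) / 0.6745``,
    reconstructed, and unshifted; the output averages the shifts.
    """
    x = np.asarray(signal, dtype=float).copy()
    n = len(x)
    if n < 8:
        raise ValueError("signal must have length >= 8")
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("signal has no finite entries")
    if bad.any():
        idx = np.arange(n)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    if not np.isfinite(x).all():
        raise ValueError("non-finite entries remain after interpolation")

    finest = pywt.wavedec(x, wavelet, level=1)[1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    if thresh == 0:
        return x

    n_shifts = min(n, max_shifts)
    out = np.zeros(n)
    for s in range(n_shifts):
        shifted = np.roll(x, s)
        coeffs = pywt.wavedec(shifted, wavelet)
        coeffs = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]]
        rec = pywt.waverec(coeffs, wavelet)[:n]
        out += np.roll(rec, -s)
    return out / n_shifts


def gc_diagnostics(
    before: list,
    after: list,
    gc: np.ndarray,
    denoise: bool = False,
) -> dict:
    """Per-pair NRC-GC correlations before/after correction plus a paired test.

    Returns a dict with a per-pair table (Pearson r and Spearman rho for each
    condition) and, when at least two pairs are available, the paired
    two-sided Wilcoxon signed-rank test on |Spearman rho| before vs after.
    """
    if len(before) != len(after):
        raise ValueError("before/after lists must be matched")
    gc = np.asarray(gc, dtype=float)
    rows = []
    for b, a in zip(before, after):
        rec = {"pair_id": b.sample_id}
        for tag, prof in (("before", b), ("after", a)):
            keep = ~prof.mask & np.isfinite(prof.values) & np.isfinite(gc)
            v, g = prof.values[keep], gc[keep]
            if denoise:
                v = ti_wavelet_denoise(v)
                g = ti_wavelet_denoise(g)
            rec[f"r_{tag}"] = stats.pearsonr(v, g).statistic
            rec[f"rho_{tag}"] = stats.spearmanr(v, g).statistic
        rows.append(rec)
    table = pd.DataFrame(rows)

    result = {"pairs": table}
    if len(table) >= 2:
        db = np.abs(table["rho_before"])
        da = np.abs(table["rho_after"])
        if np.allclose(db, da):
            result["wilcoxon_stat"], result["wilcoxon_p"] = np.nan, 1.0
        else:
            method = "exact" if len(table) <= 25 else "approx"
            stat, p = stats.wilcoxon(db, da, zero_method="wilcox", method=method)
            result["wilcoxon_stat"], result["wilcoxon_p"] = float(stat), float(p)
    return result
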