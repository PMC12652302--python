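"""Synthetic cfDNA WES count profiles with known truth.

The generator emulates the statistical structure of real cfDNA whole-exome
read counts that the pipeline exploits and corrects:

* a per-bin capture-efficiency pattern ``e_i ~ lognormal(0, capture_sd)``
  drawn once and shared by every sample, reproducing the strong inter-sample
  read-count similarity of cfDNA WES cohorts;
* a smooth unimodal GC-dependent bias multiplier per sample, with per-sample
  amplitude jitter so that ratios between samples retain a residual GC trend
  for the LOESS correction to remove;
* negative-binomial count noise (overdispersed relative to Poisson); and
* CNA events diluted by tumor fraction: a bin inside an event of tumor copy
  number ``c`` has its mean multiplied by ``(1 - TF) + TF * c / 2``.

Coordinates live on a pseudo-genome (4 chromosomes of ~25 Mb by default), so
no external reference is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bins import BinSet
from .counts import CountProfile
from .io import SEG_COLUMNS, write_seg


@dataclass
class CnaEvent:
    """A copy-number event: ``copy_number`` is the tumor copy count (diploid 2)."""

    chrom: str
    start_bp: int
    end_bp: int
    copy_number: int

    def __post_init__(self):
        if self.end_bp <= self.start_bp:
            raise ValueError("event end must exceed start")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")

    def expected_ratio(self, tumor_fraction: float) -> float:
        return (1 - tumor_fraction) + tumor_fraction * self.copy_number / 2.0


@dataclass
class SimulationConfig:
    """Generative settings for synthetic cfDNA WES count profiles.

    depth_mean is the expected reads per bin (~200x exome coverage at
    50-mappable-base bins); capture_sd the lognormal sd of the shared per-bin
    efficiency (0.6 reproduces inter-sample count correlations around 0.95);
    gc_amplitude/gc_jitter parameterize the unimodal GC bias multiplier
    1 + a * (1 - ((gc - gc_peak)/gc_width)^2) with per-sample amplitude
    a ~ Normal(gc_amplitude, gc_jitter); dispersion is the negative-binomial
    size (variance = m + m^2/size).
    """

    n_bins: int = 10_000
    n_normals: int = 8
    depth_mean: float = 200.0
    capture_sd: float = 0.6
    gc_amplitude: float = 0.3
    gc_jitter: float = 0.15
    gc_peak: float = 0.45
    gc_width: float = 0.25
    dispersion: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_bins", "n_normals", "depth_mean", "dispersion", "gc_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.capture_sd < 0 or self.gc_jitter < 0 or self.gc_amplitude < 0:
            raise ValueError("capture_sd, gc_amplitude and gc_jitter must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")


def make_pseudo_binset(
    n_bins: int = 10_000,
    n_chroms: int = 4,
    mean_span: int = 10_000,
    seed: int = 0,
) -> BinSet:
    """Bins on a pseudo-genome: ``n_chroms`` chromosomes, ~``mean_span`` bp per bin.

    Bin spans are drawn uniformly in [0.2, 1.8] * mean_span with small random
    gaps, giving chromosomes of roughly n_bins/n_chroms * mean_span bp.  GC
    ratios follow a clipped normal centered at 0.55: exome capture skews
    GC-rich, so the unimodal coverage bias (peaking near GC 0.45) is falling,
    hence monotone, over most of the observed GC range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    per_chrom = n_bins // n_chroms
    rows = []
    for c in range(n_chroms):
        chrom = str(c + 1)
        n = per_chrom + (n_bins % n_chroms if c == n_chroms - 1 else 0)
        spans = rng.integers(int(0.2 * mean_span), int(1.8 * mean_span), size=n)
        gaps = rng.integers(0, mean_span // 5, size=n)
        pos = 0
        for span, gap in zip(spans, gaps):
            start = pos + int(gap)
            end = start + int(span)
            rows.append((chrom, start, end, 50))
            pos = end
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_mappable"])
    df["gc_ratio"] = np.clip(0.55 + 0.12 * _ar1(len(df), 0.7, rng), 0.25, 0.85)
    return BinSet(df, genome_tag=f"pseudo-{n_chroms}x{per_chrom}")


def _gc_multiplier(gc: np.ndarray, amplitude: float, peak: float, width: float) -> np.ndarray:
    g = 1.0 + amplitude * (1.0 - ((gc - peak) / width) ** 2)
    return np.maximum(g, 0.1)


def _ar1(n: int, phi: float, rng) -> np.ndarray:
    """Stationary unit-variance AR(1) series: regional genomic autocorrelation."""
    z = rng.normal(size=n)
    out = np.empty(n)
    out[0] = z[0]
    c = np.sqrt(1.0 - phi * phi)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + c * z[i]
    return out


def _shared_truth(config: SimulationConfig, bin_set: BinSet, rng):
    # capture efficiency is regionally autocorrelated, like real exome capture
    efficiency = np.exp(config.capture_sd * _ar1(bin_set.n_bins, 0.9, rng))
    return efficiency


def _nb_counts(mean: np.ndarray, size: float, rng) -> np.ndarray:
    # numpy's negative_binomial(n, p): mean = n (1-p)/p  =>  p = n / (n + m)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_normals(config: SimulationConfig, bin_set: BinSet | None = None):
    """Simulate a panel of normal count profiles plus the generative truth.

    Returns ``(profiles, truth)`` where truth holds the shared per-bin
    efficiency, the bin GC ratios, and each sample's GC-bias amplitude.
    """
    if bin_set is None:
        bin_set = make_pseudo_binset(config.n_bins, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    efficiency = _shared_truth(config, bin_set, rng)
    gc = bin_set.gc
    profiles = []
    amplitudes = []
    for j in range(config.n_normals):
        a = max(rng.normal(config.gc_amplitude, config.gc_jitter), 0.0)
        amplitudes.append(a)
        mean = config.depth_mean * efficiency * _gc_multiplier(gc, a, config.gc_peak, config.gc_width)
        counts = _nb_counts(mean, config.dispersion, rng)
        profiles.append(CountProfile(f"normal_{j+1}", counts, bin_set.genome_tag))
    truth = {"efficiency": efficiency, "gc": gc, "amplitudes": np.array(amplitudes)}
    return profiles, truth


def simulate_tumor(
    config: SimulationConfig,
    events: list[CnaEvent],
    tumor_fraction: float,
    bin_set: BinSet | None = None,
    sample_id: str = "tumor",
    efficiency: np.ndarray | None = None,
    sample_seed: int = 2,
):
    """Simulate a tumor cfDNA count profile and its truth SEG.

    Bins inside an event have their mean multiplied by
    ``(1 - TF) + TF * c / 2``; the truth SEG records the expected log2 ratio
    ``log2((1 - TF) + TF * c / 2)`` per event (-inf for a homozygous loss at
    TF = 1).
    """
    if not (0 <= tumor_fraction <= 1):
        raise ValueError("tumor_fraction must be in [0, 1]")
    if bin_set is None:
        bin_set = make_pseudo_binset(config.n_bins, seed=config.seed)
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            if a.chrom == b.chrom and a.start_bp < b.end_bp and b.start_bp < a.end_bp:
                raise ValueError(f"overlapping events on chrom {a.chrom}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, sample_seed]))
    if efficiency is None:
        # same stream layout as simulate_normals so panel and tumor share e_i
        efficiency = _shared_truth(
            config, bin_set, np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        )
    gc = bin_set.gc
    a = max(rng.normal(config.gc_amplitude, config.gc_jitter), 0.0)
    mean = config.depth_mean * efficiency * _gc_multiplier(gc, a, config.gc_peak, config.gc_width)

    dilution = np.ones(bin_set.n_bins)
    starts = bin_set.df["start"].to_numpy()
    ends = bin_set.df["end"].to_numpy()
    chroms = bin_set.df["chrom"].to_numpy()
    truth_rows = []
    for ev in events:
        ratio = ev.expected_ratio(tumor_fraction)
        inside = (chroms == str(ev.chrom)) & (starts >= ev.start_bp) & (ends <= ev.end_bp)
        dilution[inside] = ratio
        with np.errstate(divide="ignore"):
            log2r = np.log2(ratio) if ratio > 0 else -np.inf
        truth_rows.append(
            (sample_id, str(ev.chrom), ev.start_bp + 1, ev.end_bp, int(inside.sum()), log2r)
        )
    counts = _nb_counts(mean * dilution, config.dispersion, rng)
    truth_seg = pd.DataFrame(truth_rows, columns=SEG_COLUMNS)
    return CountProfile(sample_id, counts, bin_set.genome_tag), truth_seg


def random_events(
    bin_set: BinSet,
    rng,
    n_events: int,
    min_bins: int = 300,
    max_bins: int = 800,
    copy_numbers=(0, 1, 3, 4, 5),
) -> list[CnaEvent]:
    """Draw non-overlapping CNA events aligned to bin boundaries."""
    df = bin_set.df
    events: list[CnaEvent] = []
    chrom_list = list(dict.fromkeys(df["chrom"]))
    attempts = 0
    while len(events) < n_events and attempts < 200:
        attempts += 1
        chrom = chrom_list[int(rng.integers(len(chrom_list)))]
        sub = df[df["chrom"] == chrom]
        width = int(rng.integers(min_bins, max_bins + 1))
        if len(sub) <= width + 2:
            continue
        lo = int(rng.integers(0, len(sub) - width))
        start = int(sub["start"].iloc[lo])
        end = int(sub["end"].iloc[lo + width - 1])
        cand = CnaEvent(chrom, start, end, int(rng.choice(copy_numbers)))
        if any(
            cand.chrom == e.chrom and cand.start_bp < e.end_bp and e.start_bp < cand.end_bp
            for e in events
        ):
            continue
        events.append(cand)
    return events


def make_reference_segs(
    bin_set: BinSet, n_references: int, rng, block_bp: int = 3_000_000, sd: float = 0.3
) -> dict:
    """Random reference cohort SEG profiles: piecewise-constant blocks per chromosome."""
    refs = {}
    chrom_extent = bin_set.df.groupby("chrom")["end"].max().to_dict()
    for r in range(n_references):
        label = f"REF{r+1}"
        rows = []
        for chrom, extent in chrom_extent.items():
            pos = 0
            while pos < extent:
                end = min(pos + int(rng.integers(block_bp // 2, block_bp * 2)), int(extent))
                rows.append((label, chrom, pos + 1, end, max((end - pos) // 10_000, 1),
                             float(rng.normal(0.0, sd))))
                pos = end
        refs[label] = pd.DataFrame(rows, columns=SEG_COLUMNS)
    return refs


def cohort_from_reference(
    reference_seg: pd.DataFrame,
    windows: pd.DataFrame,
    n_samples: int,
    rng,
    attenuation: float = 0.6,
    noise_sd: float = 0.15,
) -> list:
    """Per-sample window profiles that echo a reference profile plus noise.

    Emulates a patient cohort whose CNA landscape derives from one cancer
    type: each sample's window value is attenuation * reference + Gaussian
    noise (the attenuation standing in for tumor-fraction dilution).
    """
    from .cohort import AggregatedProfile, rebin_segments

    ref_profile = rebin_segments(reference_seg, windows)
    samples = []
    for i in range(n_samples):
        noise = rng.normal(0.0, noise_sd, size=len(ref_profile.values))
        samples.append(
            AggregatedProfile(f"sample_{i+1}", ref_profile.windows,
                              attenuation * ref_profile.values + noise)
        )
    return samples


def make_fixture_suite(out_dir, seed: int = 17, n_bins: int = 10_000) -> dict:
    """Write a complete desk-scale fixture set and return its manifest.

    Emits: bins TSV over 4 pseudo-chromosomes, a panel of 8 normal count
    profiles, 4 tumors at tumor fractions {0.1, 0.3, 0.5, 0.7} with 3-6
    events each, per-tumor truth SEGs, a toy gene TSV (genes inside and
    outside events), and 6 decoy reference SEGs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(n_bins=n_bins, seed=seed)
    bin_set = make_pseudo_binset(n_bins, seed=seed)
    bin_set.to_tsv(out / "bins.tsv")

    normals, truth = simulate_normals(config, bin_set)
    counts = bin_set.df[["chrom", "start", "end"]].copy()
    for p in normals:
        counts[p.sample_id] = p.counts
    counts.to_csv(out / "normals.counts.tsv", sep="\t", index=False)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    tumor_fractions = [0.1, 0.3, 0.5, 0.7]
    tumor_files = []
    genes_rows = []
    tumor_counts = bin_set.df[["chrom", "start", "end"]].copy()
    for t, tf in enumerate(tumor_fractions):
        events = random_events(bin_set, rng, n_events=int(rng.integers(3, 7)),
                               min_bins=120, max_bins=350)
        sample_id = f"tumor_tf{int(tf*100):02d}"
        profile, truth_seg = simulate_tumor(
            config, events, tf, bin_set, sample_id=sample_id,
            efficiency=truth["efficiency"], sample_seed=100 + t,
        )
        tumor_counts[sample_id] = profile.counts
        write_seg(truth_seg, out / f"{sample_id}.truth.seg")
        tumor_files.append(f"{sample_id}.truth.seg")
        for ev in events[:2]:  # a couple of genes inside events per tumor
            mid = (ev.start_bp + ev.end_bp) // 2
            genes_rows.append((ev.chrom, mid, mid + 20_000, f"GENE_{sample_id}_{ev.chrom}_{mid}"))
    tumor_counts.to_csv(out / "tumors.counts.tsv", sep="\t", index=False)

    # genes outside any event, on each chromosome
    for chrom, sub in bin_set.df.groupby("chrom", sort=False):
        start = int(sub["start"].iloc[5])
        genes_rows.append((chrom, start, start + 20_000, f"GENE_neutral_{chrom}"))
    genes = pd.DataFrame(genes_rows, columns=["chrom", "start", "end", "symbol"])
    genes = genes.drop_duplicates("symbol")
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)

    refs = make_reference_segs(bin_set, 6, rng)
    for label, seg in refs.items():
        write_seg(seg, out / f"{label}.seg")

    chrom_extent = bin_set.df.groupby("chrom")["end"].max()
    chrom_extent.to_csv(out / "chrom_sizes.tsv", sep="\t", header=False)

    manifest = {
        "seed": seed,
        "n_bins": n_bins,
        "config": asdict(config),
        "files": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "tumor_fractions": tumor_fractions,
        "normals": [p.sample_id for p in normals],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
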