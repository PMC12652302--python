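"""End-to-end orchestration: counts -> normalization -> segmentation -> calls -> report.

``run_all`` executes the full pipeline from a plain-text config and writes
every intermediate table to the run directory: per-sample NRC TSVs and SEG
files for the three analysis conditions (raw, panel-corrected,
GC-corrected), the panel-derived detection threshold, CNA calls and the
gene-by-sample alteration matrix, inspection-cost tables, GC-correlation
diagnostics, the reference-cohort ranking, and a structured log recording
parameters, seeds and mask counts per stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bins import BinSet
from .calls import (
    call_cnas,
    compute_threshold,
    cost_comparison,
    detection_cost,
    gene_matrix,
)
from .cohort import aggregate_cohort, compare_to_references, make_windows, rebin_segments
from .counts import CountProfile, counts_from_tsv, nrc_raw
from .io import read_chrom_sizes, read_genes, read_seg, write_nrc_tsv, write_seg
from .normalize import ControlPanel, gc_correct, gc_diagnostics, nrc_corrected
from .segment import SegmentProfile, cbs_segment, merge_to_seg


@dataclass
class PipelineConfig:
    """Validated settings for a pipeline run (see module docstring)."""

    bins: str
    panel_counts: str
    sample_counts: str
    out_dir: str
    genes: str | None = None
    references: list = field(default_factory=list)
    chrom_sizes: str | None = None
    # normalization
    span: float = 0.3
    robust_iters: int = 2
    epsilon: float = 1e-6
    # QC
    min_median_count: int = 30
    # segmentation
    alpha: float = 0.01
    n_permutations: int = 10000
    seed: int = 17
    # threshold
    percentile: float = 99.5
    threshold_floor: float = 0.15
    call_min_bins: int = 10
    per_sample_threshold: bool = False
    # comparison
    window_bp: int = 500_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def validate(self) -> None:
        for attr in ("bins", "panel_counts", "sample_counts"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"config.{attr}: {p} does not exist")
        for p in [self.genes, self.chrom_sizes]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path {p} does not exist")
        for p in self.references:
            if not Path(p).exists():
                raise FileNotFoundError(f"reference SEG {p} does not exist")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must be in (0, 100]")


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory.  Fails fast per stage."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **info):
        log.append({"stage": name, **info})
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    bin_set = BinSet.from_tsv(config.bins)
    panel_profiles = counts_from_tsv(config.panel_counts, bin_set)
    sample_profiles = counts_from_tsv(config.sample_counts, bin_set)
    stage("load", n_bins=bin_set.n_bins, n_panel=len(panel_profiles),
          n_samples=len(sample_profiles))

    # QC gate: minimum median raw read count per sample
    kept, dropped = [], []
    for p in panel_profiles + sample_profiles:
        med = float(np.median(p.counts))
        (kept if med >= config.min_median_count else dropped).append((p.sample_id, med))
    if dropped:
        stage("qc", dropped=dropped)
    drop_ids = {d[0] for d in dropped}
    panel_profiles = [p for p in panel_profiles if p.sample_id not in drop_ids]
    sample_profiles = [p for p in sample_profiles if p.sample_id not in drop_ids]
    if len(panel_profiles) < 3:
        raise RuntimeError("stage qc: fewer than 3 panel samples pass the coverage gate")

    base_mask = bin_set.masked | ~np.isfinite(bin_set.gc)
    panel_raw = [nrc_raw(p, mask=base_mask) for p in panel_profiles]
    panel = ControlPanel(panel_raw, epsilon=config.epsilon)
    stage("panel", masked_bins=int(panel.panel_mask.sum()))

    conditions = ("raw", "corrected", "gc_corrected")
    seg_profiles: dict[str, dict[str, SegmentProfile]] = {c: {} for c in conditions}
    diag_before, diag_after = [], []
    for s_idx, cp in enumerate(sample_profiles):
        sid = cp.sample_id
        try:
            raw = nrc_raw(cp, mask=base_mask)
            corr = nrc_corrected(raw, panel)
            gc_corr = gc_correct(raw, panel, bin_set.gc, span=config.span,
                                 robust_iters=config.robust_iters)
        except Exception as exc:
            raise RuntimeError(f"stage normalize failed for sample {sid}: {exc}") from exc
        for cond, prof in zip(conditions, (raw, corr, gc_corr)):
            write_nrc_tsv(bin_set.df, prof.values, prof.mask, out / f"{sid}.{cond}.nrc.tsv")
            try:
                seg = cbs_segment(
                    prof, bin_set, alpha=config.alpha,
                    n_permutations=config.n_permutations,
                    seed=config.seed + 1000 * s_idx + conditions.index(cond),
                )
            except Exception as exc:
                raise RuntimeError(f"stage segment failed for sample {sid} ({cond}): {exc}") from exc
            seg_profiles[cond][sid] = seg
        diag_before.append(corr)
        diag_after.append(gc_corr)
        stage("sample", sample=sid,
              masked_bins=int(gc_corr.mask.sum()),
              n_segments={c: len(seg_profiles[c][sid].segments) for c in conditions})

    for cond in conditions:
        seg_table = merge_to_seg(list(seg_profiles[cond].values()), bin_set)
        write_seg(seg_table, out / f"samples.{cond}.seg")

    diag = gc_diagnostics(diag_before, diag_after, bin_set.gc)
    diag["pairs"].to_csv(out / "gc_diagnostics.tsv", sep="\t", index=False)
    stage("gc_diagnostics", wilcoxon_p=diag.get("wilcoxon_p"))

    loo = compute_threshold(
        panel_profiles, bin_set, percentile=config.percentile,
        span=config.span, robust_iters=config.robust_iters,
        alpha=config.alpha, n_permutations=config.n_permutations,
        seed=config.seed + 90_000, mask=base_mask, min_bins=config.call_min_bins,
    )
    from .calls import DetectionThreshold

    threshold = DetectionThreshold(
        max(loo.value, config.threshold_floor), loo.method, loo.percentile, loo.n_panel_runs
    )
    stage("threshold", value=threshold.value, loo_value=loo.value,
          floor=config.threshold_floor, percentile=threshold.percentile)

    call_tables = {
        sid: call_cnas(seg, threshold, min_bins=config.call_min_bins)
        for sid, seg in seg_profiles["gc_corrected"].items()
    }
    pd.concat(call_tables.values(), ignore_index=True).to_csv(
        out / "calls.tsv", sep="\t", index=False
    )

    summary: dict = {
        "threshold": threshold.value,
        "wilcoxon_p_gc": diag.get("wilcoxon_p"),
        "segment_counts": {
            c: {sid: len(sp.segments) for sid, sp in seg_profiles[c].items()}
            for c in conditions
        },
    }

    if config.genes:
        genes = read_genes(config.genes)
        matrix = gene_matrix(call_tables, genes)
        matrix.to_csv(out / "gene_matrix.tsv", sep="\t")
        cost_rows = []
        cost_lists = {c: [] for c in conditions}
        for gene in genes.itertuples(index=False):
            for cond in conditions:
                per_sample = [
                    detection_cost(sp, gene) for sp in seg_profiles[cond].values()
                ]
                best = min(per_sample, key=lambda c: (not c.found, c.inspected_length_bp))
                cost_lists[cond].append(best)
                cost_rows.append((gene.symbol, cond, best.inspected_length_bp,
                                  best.inspected_segments, best.found))
        pd.DataFrame(
            cost_rows, columns=["gene", "condition", "length_bp", "n_segments", "found"]
        ).to_csv(out / "costs.tsv", sep="\t", index=False)
        summary["cost_comparison"] = cost_comparison(
            cost_lists["raw"], cost_lists["corrected"], cost_lists["gc_corrected"]
        )
        stage("cost", n_genes=len(genes))

    if config.references:
        if config.chrom_sizes:
            sizes = read_chrom_sizes(config.chrom_sizes)
        else:
            sizes = bin_set.df.groupby("chrom")["end"].max().to_dict()
        windows = make_windows(sizes, config.window_bp)
        sample_aggs = [
            rebin_segments(merge_to_seg([sp], bin_set), windows, label=sid)
            for sid, sp in seg_profiles["gc_corrected"].items()
        ]
        cohort = aggregate_cohort(sample_aggs)
        refs = [rebin_segments(read_seg(p), windows) for p in config.references]
        ranking = compare_to_references(cohort, refs)
        ranking.to_csv(out / "reference_ranking.tsv", sep="\t", index=False)
        summary["reference_ranking"] = ranking.to_dict(orient="records")
        stage("compare", n_references=len(refs))

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    stage("done")
    return out
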