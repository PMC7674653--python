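"""End-to-end pipeline: simulate (or load) -> trim -> map -> dedup -> call ->
calibrate -> filter -> CNV -> annotate, with per-stage counts.

The wild-type strain is sequenced alongside the mutants; calling its reads
against its own assembly yields the false-positive set used both for
shared-variant subtraction and for threshold calibration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from . import align, annotate, calling, nullfilter, preprocess, structvar, synth
from .models import CalibratedThresholds, GenomeRecord, TruthVariant

log = logging.getLogger("clonalvar")


@dataclass
class PipelineConfig:
    """All tunable parameters with their documented defaults."""

    seed: int = 0
    # simulation
    genome_length: int = 100_000
    gc_fraction: float = 0.30
    n_genes: int = 30
    mean_gene_length: int = 900
    mean_coverage: float = 150.0
    read_length: int = 150
    insert_mean: int = 400
    insert_sd: int = 50
    error_rate: float = 0.005
    mean_quality: float = 35.0
    # trimming
    trim_window: int = 4
    trim_min_window_quality: float = 15.0
    trim_min_length: int = 36
    # mapping
    k: int = 21
    max_mismatches: int = 6
    # calling
    min_depth: int = 10
    min_alt_count: int = 3
    min_alt_fraction: float = 0.10
    # null filter fallback thresholds
    rel_cov_min: float = 0.259
    pop_fraction_min: float = 0.308
    # CNV
    cnv_window: int = 100
    cnv_gain_min: float = 1.75
    cnv_loss_max: float = 0.25
    cnv_min_windows: int = 5
    fine_cnv: bool = True
    # clustering
    distance_variant: str = "asymmetric"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def trim_policy(self) -> preprocess.TrimPolicy:
        return preprocess.TrimPolicy(
            window=self.trim_window,
            min_window_quality=self.trim_min_window_quality,
            min_length=self.trim_min_length,
        )

    def fallback_thresholds(self) -> CalibratedThresholds:
        return CalibratedThresholds(self.rel_cov_min, self.pop_fraction_min)


@dataclass
class SampleResult:
    """Per-sample intermediate products of the read-processing stages."""

    pairs: list
    alignments: list
    profile: object
    pileup: list
    raw_calls: list
    stats: dict = field(default_factory=dict)


def process_sample(
    pairs,
    reference: GenomeRecord,
    config: PipelineConfig,
    label: str = "sample",
) -> SampleResult:
    """trim -> map -> dedup -> coverage -> pileup -> raw calls for one
    sequencing run."""
    trimmed, trim_stats = preprocess.trim_pairs(pairs, config.trim_policy())
    alignments, map_stats = align.map_reads(
        trimmed, reference, k=config.k, max_mismatches=config.max_mismatches
    )
    n_dup = align.mark_duplicates(alignments)
    profile = align.coverage_profile(alignments, reference.length, window=config.cnv_window)
    seqs = calling.read_sequence_map(trimmed)
    pileup = calling.build_pileup(align.usable(alignments), reference, seqs)
    raw_calls = calling.call_variants(
        pileup,
        reference,
        mean_depth=profile.mean_depth,
        min_depth=config.min_depth,
        min_alt_count=config.min_alt_count,
        min_alt_fraction=config.min_alt_fraction,
    )
    stats = {
        **trim_stats,
        **map_stats,
        "duplicate_pairs": n_dup,
        "mean_depth": round(profile.mean_depth, 2),
        "raw_calls": len(raw_calls),
    }
    log.info("[%s] %s", label, stats)
    return SampleResult(trimmed, alignments, profile, pileup, raw_calls, stats)


def run_pipeline(
    config: PipelineConfig,
    mutation_specs: list[TruthVariant] | None = None,
) -> dict:
    """Simulate a wild-type self-run and one mutant run, then execute the
    full comparison.  Returns a result dict with per-stage products and a
    ``summary`` of counts; fully deterministic given ``config.seed``.
    """
    reference, features = synth.generate_genome(
        length=config.genome_length,
        gc_fraction=config.gc_fraction,
        n_genes=config.n_genes,
        mean_gene_length=config.mean_gene_length,
        seed=config.seed,
    )
    if mutation_specs:
        mutant_genome, truth = synth.inject_mutations(reference, features, mutation_specs)
    else:
        mutant_genome, truth = reference, []

    sim_kwargs = dict(
        mean_coverage=config.mean_coverage,
        read_length=config.read_length,
        insert_mean=config.insert_mean,
        insert_sd=config.insert_sd,
        error_rate=config.error_rate,
        mean_quality=config.mean_quality,
    )
    wts_pairs = synth.simulate_reads(reference, seed=config.seed + 1, **sim_kwargs)
    mut_pairs = synth.simulate_reads(mutant_genome, seed=config.seed + 2, **sim_kwargs)

    wts = process_sample(wts_pairs, reference, config, label="WTS")
    mut = process_sample(mut_pairs, reference, config, label="mutant")

    thresholds = nullfilter.calibrate_thresholds(wts.raw_calls, config.fallback_thresholds())
    nullfilter.subtract_shared(mut.raw_calls, wts.raw_calls)
    nullfilter.apply_thresholds(mut.raw_calls, thresholds)
    passing = nullfilter.passing(mut.raw_calls)

    cnv_calls = structvar.detect_cnv(
        mut.profile,
        wts.profile,
        gain_min=config.cnv_gain_min,
        loss_max=config.cnv_loss_max,
        min_windows=config.cnv_min_windows,
    )
    structvar.annotate_cnv_calls(cnv_calls, features)
    fine_cnv_calls = []
    if config.fine_cnv:
        fine_wts = align.coverage_profile(
            wts.alignments, reference.length, window=structvar.FINE_WINDOW
        )
        fine_mut = align.coverage_profile(
            mut.alignments, reference.length, window=structvar.FINE_WINDOW
        )
        fine_cnv_calls = structvar.detect_cnv(
            fine_mut,
            fine_wts,
            gain_min=config.cnv_gain_min,
            loss_max=config.cnv_loss_max,
            min_windows=structvar.FINE_MIN_WINDOWS,
        )
        structvar.annotate_cnv_calls(fine_cnv_calls, features)

    annotated = annotate.annotate_variants(passing, features, reference)

    summary = {
        "wts": wts.stats,
        "mutant": mut.stats,
        "thresholds": {
            "rel_cov_min": thresholds.rel_cov_min,
            "pop_fraction_min": thresholds.pop_fraction_min,
            "calibrated_from_wts_calls": len(wts.raw_calls),
        },
        "filter": {
            "raw": len(mut.raw_calls),
            "shared_with_wt": sum(c.filter_status == "shared_with_wt" for c in mut.raw_calls),
            "low_relcov": sum(c.filter_status == "low_relcov" for c in mut.raw_calls),
            "low_fraction": sum(c.filter_status == "low_fraction" for c in mut.raw_calls),
            "pass": len(passing),
        },
        "cnv": {"default_window_calls": len(cnv_calls), "fine_window_calls": len(fine_cnv_calls)},
    }
    return {
        "reference": reference,
        "features": features,
        "mutant_genome": mutant_genome,
        "truth": truth,
        "wts": wts,
        "mutant": mut,
        "thresholds": thresholds,
        "calls": mut.raw_calls,
        "passing": passing,
        "annotated": annotated,
        "cnv_calls": cnv_calls,
        "fine_cnv_calls": fine_cnv_calls,
        "summary": summary,
    }
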