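"""The packaged parameter-recovery study: one simulated mutant strain under
the study's sequencing conditions, scored against its truth table.

The conditions mirror the real experiment at desk scale: a 100 kb genome with
30 genes, a mutant carrying 15 SNPs and 2 short indels plus one ~8 kb tandem
duplication and one 759 bp deletion, 150 bp paired reads at 120x with 0.5%
substitution error, and filter thresholds calibrated from a wild-type
self-run.  Small variants are scored by exact (position, ref, alt) match of
left-aligned representations.
"""

from __future__ import annotations

import numpy as np

from .models import TruthVariant
from .pipeline import PipelineConfig, run_pipeline

N_SNPS = 15
N_INDELS = 2
DUPLICATION_SIZE = 8_000
DELETION_SIZE = 759  # size of the largest published sub-kb loss
EDGE_MARGIN = 1_000  # keep truth variants away from the linearisation ends
EVENT_MARGIN = 500  # and away from duplication/deletion boundaries


def build_mutation_specs(genome, rng: np.random.Generator) -> list[TruthVariant]:
    """Draw the study's mutation set for one mutant strain.

    Event intervals (duplication, deletion) are placed in disjoint thirds of
    the genome; point mutations avoid the events, the genome ends, and each
    other.
    """
    L = genome.length
    dup_start = int(rng.integers(int(0.55 * L), int(0.70 * L) - DUPLICATION_SIZE))
    del_start = int(rng.integers(int(0.30 * L), int(0.45 * L) - DELETION_SIZE))
    blocked = [
        (dup_start - EVENT_MARGIN, dup_start + DUPLICATION_SIZE + EVENT_MARGIN),
        (del_start - EVENT_MARGIN, del_start + DELETION_SIZE + EVENT_MARGIN),
    ]
    specs = [
        TruthVariant("duplication", dup_start, size=DUPLICATION_SIZE),
        TruthVariant("segment_deletion", del_start, size=DELETION_SIZE),
    ]
    taken: list[int] = []

    def free(p: int, pad: int = 20) -> bool:
        if not EDGE_MARGIN <= p <= L - EDGE_MARGIN:
            return False
        if any(lo <= p <= hi for lo, hi in blocked):
            return False
        return all(abs(p - q) > pad for q in taken)

    while sum(s.kind == "snp" for s in specs) < N_SNPS:
        p = int(rng.integers(1, L + 1))
        if not free(p):
            continue
        ref = genome.sequence[p - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        specs.append(TruthVariant("snp", p, ref, alt))
        taken.append(p)
    # one short insertion and one short deletion
    for kind in ("insertion", "deletion"):
        while True:
            p = int(rng.integers(1, L + 1))
            if not free(p):
                continue
            if kind == "insertion":
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                specs.append(TruthVariant("insertion", p, alt_allele=ins))
            else:
                specs.append(TruthVariant("deletion", p, size=int(rng.integers(1, 4))))
            taken.append(p)
            break
    return specs


def score_small_variants(passing, truth) -> dict:
    """Precision/recall of passing calls against the truth table's SNPs and
    short indels (exact left-aligned allele match)."""
    truth_keys = {
        (t.position, t.ref_allele, t.alt_allele)
        for t in truth
        if t.kind in ("snp", "insertion", "deletion")
    }
    call_keys = {c.key for c in passing}
    tp = len(call_keys & truth_keys)
    precision = tp / len(call_keys) if call_keys else float("nan")
    recall = tp / len(truth_keys) if truth_keys else float("nan")
    return {
        "n_truth": len(truth_keys),
        "n_passing": len(call_keys),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }


def score_cnv(result) -> dict:
    """Recovery of the duplication (default windows) and the deletion
    (fine windows) against the truth intervals."""
    truth = {t.kind: t for t in result["truth"]}
    dup = truth["duplication"]
    dele = truth["segment_deletion"]
    dup_interval = (dup.position, dup.position + dup.size - 1)
    del_interval = (dele.position, dele.position + dele.size - 1)

    def overlapping(calls, kind, interval):
        return [
            c
            for c in calls
            if c.kind == kind and c.start <= interval[1] and c.end >= interval[0]
        ]

    gains = overlapping(result["cnv_calls"], "gain", dup_interval)
    losses = overlapping(result["fine_cnv_calls"], "loss", del_interval)
    out = {
        "n_gain_calls": len([c for c in result["cnv_calls"] if c.kind == "gain"]),
        "n_gain_calls_at_duplication": len(gains),
        "n_loss_calls_fine_at_deletion": len(losses),
        "duplication_interval": dup_interval,
        "deletion_interval": del_interval,
    }
    if len(gains) == 1:
        g = gains[0]
        out["gain_copy_ratio"] = g.copy_ratio
        out["gain_start_error"] = abs(g.start - dup_interval[0])
        out["gain_end_error"] = abs(g.end - dup_interval[1])
    if losses:
        lo = min(c.start for c in losses)
        hi = max(c.end for c in losses)
        out["loss_covers_deletion"] = lo <= del_interval[0] and hi >= del_interval[1]
        out["loss_copy_ratio"] = float(np.median([c.copy_ratio for c in losses]))
    return out


def run_recovery_study(seed: int = 1, mean_coverage: float = 120.0) -> dict:
    """Run the full pipeline under the study conditions and score it."""
    config = PipelineConfig(seed=seed, mean_coverage=mean_coverage)
    from . import synth

    genome, features = synth.generate_genome(
        length=config.genome_length,
        gc_fraction=config.gc_fraction,
        n_genes=config.n_genes,
        mean_gene_length=config.mean_gene_length,
        seed=config.seed,
    )
    rng = np.random.default_rng(seed + 1_000)
    specs = build_mutation_specs(genome, rng)
    result = run_pipeline(config, mutation_specs=specs)
    scores = {
        "small_variants": score_small_variants(result["passing"], result["truth"]),
        "cnv": score_cnv(result),
        "thresholds": result["summary"]["thresholds"],
        "filter": result["summary"]["filter"],
    }
    result["scores"] = scores
    return result
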