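import numpy as np
import pytest

from clonalvar import align, calling, synth
from clonalvar.models import Alignment, GenomeRecord, PileupColumn

from .oracles import call_sites, normalize_variant, pileup_recount


def _random_alignments(genome, rng, n=30, read_len=40):
    """Random alignments (some gapped) plus their read sequences."""
    alignments, seqs = [], {}
    bases = "ACGT"
    for i in range(n):
        start = int(rng.integers(1, genome.length - read_len - 12))
        kind = rng.random()
        if kind < 0.6:
            cigar = [("M", read_len)]
        elif kind < 0.8:
            d = int(rng.integers(1, 4))
            t = int(rng.integers(5, read_len - 5))
            cigar = [("M", t), ("D", d), ("M", read_len - t)]
        else:
            ins = int(rng.integers(1, 4))
            t = int(rng.integers(5, read_len - ins - 5))
            cigar = [("M", t), ("I", ins), ("M", read_len - t - ins)]
        qlen = sum(n_ for op, n_ in cigar if op in ("M", "I"))
        seq = "".join(rng.choice(list(bases), size=qlen))
        a = Alignment(f"r{i}/1", f"r{i}", 1, start, cigar, "+", 0, qlen)
        alignments.append(a)
        seqs[a.read_id] = seq
    return alignments, seqs


class TestBuildPileup:
    def test_single_alignment_counts_reference_base(self, toy_genome):
        genome, _ = toy_genome
        a = Alignment("r/1", "r", 1, 101, [("M", 50)], "+", 0, 50)
        seqs = {"r/1": genome.sequence[100:150]}
        pileup = calling.build_pileup([a], genome, seqs)
        col = next(c for c in pileup if c.position == 120)
        assert col.depth == 1
        assert col.base_counts == {genome.sequence[119]: 1}

    def test_two_disagreeing_alignments(self, toy_genome):
        genome, _ = toy_genome
        p = 200
        ref = genome.sequence[p - 1]
        alt = "A" if ref != "A" else "C"
        a1 = Alignment("r1/1", "r1", 1, p, [("M", 30)], "+", 0, 30)
        a2 = Alignment("r2/1", "r2", 1, p, [("M", 30)], "+", 0, 30)
        seqs = {
            "r1/1": genome.sequence[p - 1 : p + 29],
            "r2/1": alt + genome.sequence[p : p + 29],
        }
        pileup = calling.build_pileup([a1, a2], genome, seqs)
        col = next(c for c in pileup if c.position == p)
        assert col.base_counts[ref] == 1 and col.base_counts[alt] == 1

    def test_matches_brute_force_recount(self, toy_genome):
        genome, _ = toy_genome
        rng = np.random.default_rng(17)
        alignments, seqs = _random_alignments(genome, rng)
        pileup = calling.build_pileup(alignments, genome, seqs)
        base_counts, del_counts, ins_events, del_events = pileup_recount(
            alignments, seqs, genome
        )
        by_pos = {c.position: c for c in pileup}
        all_positions = set(base_counts) | set(del_counts)
        assert set(by_pos) == all_positions
        for p in all_positions:
            col = by_pos[p]
            assert col.base_counts == base_counts.get(p, {})
            assert col.deletion_count == del_counts.get(p, 0)
            assert col.insertion_events == ins_events.get(p, {})
            assert col.deletion_events == del_events.get(p, {})

    def test_cigar_past_reference_end_raises(self):
        genome = GenomeRecord("g", "ACGT" * 10)
        a = Alignment("r/1", "r", 1, 35, [("M", 10)], "+", 0, 10)
        with pytest.raises(ValueError, match="reference end"):
            calling.build_pileup([a], genome, {"r/1": "ACGTACGTAC"})


class TestCallVariants:
    def _column(self, position, ref, counts, dels=None, ins=None):
        return PileupColumn(position, counts, deletion_count=0,
                            insertion_events=ins or {}, deletion_events=dels or {})

    def test_alt_fraction_arithmetic(self, toy_genome):
        genome, _ = toy_genome
        p = 500
        ref = genome.sequence[p - 1]
        alt = "G" if ref != "G" else "T"
        col = self._column(p, ref, {ref: 60, alt: 40})
        calls = calling.call_variants([col], genome, mean_depth=100)
        assert len(calls) == 1
        assert calls[0].alt_fraction == pytest.approx(0.40)
        assert calls[0].depth == 100

    def test_min_alt_count_threshold(self, toy_genome):
        genome, _ = toy_genome
        p = 500
        ref = genome.sequence[p - 1]
        alt = "G" if ref != "G" else "T"
        col = self._column(p, ref, {ref: 98, alt: 2})
        assert calling.call_variants([col], genome, mean_depth=100, min_alt_count=3) == []

    def test_matches_exhaustive_per_site_oracle(self, toy_genome):
        genome, _ = toy_genome
        rng = np.random.default_rng(23)
        for _ in range(20):
            pileup = []
            for p in rng.choice(np.arange(10, genome.length - 10), size=40, replace=False):
                p = int(p)
                ref = genome.sequence[p - 1]
                counts = {ref: int(rng.integers(0, 40))}
                for b in "ACGT":
                    if b != ref and rng.random() < 0.5:
                        counts[b] = int(rng.integers(0, 12))
                counts = {b: n for b, n in counts.items() if n}
                ins = {"".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3)))):
                       int(rng.integers(1, 8))} if rng.random() < 0.3 else {}
                dels = {genome.sequence[p : p + int(rng.integers(1, 3))]:
                        int(rng.integers(1, 8))} if rng.random() < 0.3 else {}
                dc = sum(dels.values())
                if not counts and not dc:
                    continue
                pileup.append(PileupColumn(p, counts, deletion_count=dc,
                                           insertion_events=ins, deletion_events=dels))
            calls = calling.call_variants(pileup, genome, mean_depth=30.0,
                                          min_depth=10, min_alt_count=3, min_alt_fraction=0.10)
            got = sorted((c.position, c.ref_allele, c.alt_allele, c.depth, c.alt_count)
                         for c in calls)
            expected = call_sites(pileup, genome, 30.0, 10, 3, 0.10)
            assert got == expected

    def test_calls_are_left_aligned(self):
        # a deletion in a homopolymer must be anchored at its leftmost position
        genome = GenomeRecord("g", "GGCAAAAATTGG")
        col = PileupColumn(6, {"A": 20}, deletion_count=15,
                           deletion_events={"A": 15})
        calls = calling.call_variants([col], genome, mean_depth=30.0)
        assert len(calls) == 1
        c = calls[0]
        expected = normalize_variant(6, "AA", "A", genome.sequence)
        assert (c.position, c.ref_allele, c.alt_allele) == expected
        assert c.position == 3  # anchored on the C before the A-run

    def test_self_reads_against_own_reference_call_nothing(self, toy_genome):
        genome, _ = toy_genome
        pairs = synth.simulate_reads(genome, mean_coverage=20, error_rate=0.0,
                                     low_quality_tail_fraction=0.0, seed=31)
        alignments, _ = align.map_reads(pairs, genome)
        align.mark_duplicates(alignments)
        profile = align.coverage_profile(alignments, genome.length)
        pileup = calling.build_pileup(align.usable(alignments), genome,
                                      calling.read_sequence_map(pairs))
        calls = calling.call_variants(pileup, genome, mean_depth=profile.mean_depth)
        assert calls == []
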