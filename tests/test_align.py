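import numpy as np
import pytest

from clonalvar import align, calling, io, synth
from clonalvar.models import Alignment, GenomeRecord, ReadPair, revcomp


def _pair_from(genome, start, rl=150, frag=400, pid="p0", strand="+"):
    """Construct an error-free pair exactly as the simulator lays it out."""
    frag_seq = genome.sequence[start - 1 : start - 1 + frag]
    left, right = frag_seq[:rl], revcomp(frag_seq[-rl:])
    m1, m2 = (left, right) if strand == "+" else (right, left)
    q = np.full(rl, 35)
    return ReadPair(pid, m1, m2, q.copy(), q.copy(), true_origin=start, true_strand=strand)


class TestMapReads:
    def test_error_free_reads_map_to_their_origin(self, toy_genome):
        genome, _ = toy_genome
        pairs = synth.simulate_reads(genome, mean_coverage=5, error_rate=0.0,
                                     low_quality_tail_fraction=0.0, seed=8)
        alignments, stats = align.map_reads(pairs, genome)
        assert stats["mates_unmapped"] == 0
        by_pair = {}
        for a in alignments:
            assert a.ref_start >= 1 and a.ref_end <= genome.length
            by_pair.setdefault(a.pair_id, []).append(a)
        truth = {p.pair_id: p for p in pairs}
        correct = total = 0
        for pid, mates in by_pair.items():
            t = truth[pid]
            start = min(a.ref_start for a in mates)
            total += 1
            if start == t.true_origin:
                correct += 1
        assert correct / total >= 0.99

    def test_two_substitutions_counted(self, toy_genome):
        genome, _ = toy_genome
        p = 3001
        seq = list(genome.sequence[p - 1 : p + 149])
        for i in (40, 90):
            seq[i] = "A" if seq[i] != "A" else "G"
        pair = ReadPair("x", "".join(seq), revcomp(genome.sequence[p + 249 : p + 399]),
                        np.full(150, 35), np.full(150, 35))
        alignments, _ = align.map_reads([pair], genome)
        a = next(a for a in alignments if a.mate == 1)
        assert a.ref_start == p
        assert a.n_mismatches == 2

    def test_minus_strand_pair_maps_to_recorded_origin(self, toy_genome):
        genome, _ = toy_genome
        pair = _pair_from(genome, 5001, strand="-")
        alignments, _ = align.map_reads([pair], genome)
        m1 = next(a for a in alignments if a.mate == 1)
        assert m1.strand == "-"
        starts = [a.ref_start for a in alignments]
        assert min(starts) == 5001

    def test_short_deletion_recovered_as_gapped_alignment(self, toy_genome):
        genome, _ = toy_genome
        p = 7001
        # read skips 3 reference bases after 70 read bases
        seq = genome.sequence[p - 1 : p - 1 + 70] + genome.sequence[p - 1 + 73 : p - 1 + 153]
        pair = ReadPair("d", seq, revcomp(genome.sequence[p + 299 : p + 449]),
                        np.full(150, 35), np.full(150, 35))
        alignments, _ = align.map_reads([pair], genome)
        a = next(a for a in alignments if a.mate == 1)
        assert a.ref_start == p
        assert ("D", 3) in a.cigar
        assert a.n_mismatches == 0

    def test_unmappable_read_is_omitted(self, toy_genome):
        genome, _ = toy_genome
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=150))
        pair = ReadPair("j", junk, junk, np.full(150, 35), np.full(150, 35))
        alignments, stats = align.map_reads([pair], genome)
        # random 150-mers almost surely share no 21-mer with a 20 kb genome
        assert stats["mates_unmapped"] == 2
        assert alignments == []


class TestMarkDuplicates:
    def _aln(self, pid, mate, start, strand, qsum, length=100):
        return Alignment(f"{pid}/{mate}", pid, mate, start, [("M", length)], strand,
                         0, length, base_quality_sum=qsum)

    def test_distinct_signatures_no_duplicates(self):
        alns = []
        for i, s in enumerate((100, 300, 500)):
            alns += [self._aln(f"p{i}", 1, s, "+", 900), self._aln(f"p{i}", 2, s + 200, "-", 900)]
        assert align.mark_duplicates(alns) == 0
        assert not any(a.is_duplicate for a in alns)

    def test_identical_signature_marks_one(self):
        alns = []
        for i in range(2):
            alns += [self._aln(f"p{i}", 1, 100, "+", 900), self._aln(f"p{i}", 2, 300, "-", 900)]
        assert align.mark_duplicates(alns) == 1
        dup_pairs = {a.pair_id for a in alns if a.is_duplicate}
        assert len(dup_pairs) == 1

    def test_highest_summed_quality_pair_survives(self):
        alns = []
        for i, q in enumerate((900, 905, 910)):
            alns += [self._aln(f"p{i}", 1, 100, "+", q / 2), self._aln(f"p{i}", 2, 300, "-", q / 2)]
        assert align.mark_duplicates(alns) == 2
        survivors = {a.pair_id for a in alns if not a.is_duplicate}
        assert survivors == {"p2"}


class TestCoverageProfile:
    def test_single_alignment_arithmetic(self):
        a = Alignment("r/1", "r", 1, 1, [("M", 100)], "+", 0, 100)
        profile = align.coverage_profile([a], 100, window=100)
        assert profile.mean_depth == 1.0
        assert list(profile.window_depth) == [1.0]

    def test_zero_alignments(self):
        profile = align.coverage_profile([], 500, window=100)
        assert profile.mean_depth == 0.0
        assert (profile.position_depth == 0).all()

    def test_matches_per_position_recount_and_target_coverage(self, toy_genome):
        genome, _ = toy_genome
        pairs = synth.simulate_reads(genome, mean_coverage=30, error_rate=0.0,
                                     low_quality_tail_fraction=0.0, seed=11)
        alignments, _ = align.map_reads(pairs, genome)
        align.mark_duplicates(alignments)
        profile = align.coverage_profile(alignments, genome.length, window=100)
        # brute-force per-position recount
        depth = np.zeros(genome.length)
        for a in align.usable(alignments):
            depth[a.ref_start - 1 : a.ref_end] += 1
        assert (depth == profile.position_depth).all()
        assert abs(profile.mean_depth - 30) / 30 <= 0.10

    def test_window_mean_is_length_weighted(self):
        a = Alignment("r/1", "r", 1, 1, [("M", 150)], "+", 0, 150)
        profile = align.coverage_profile([a], 250, window=100)
        assert list(profile.window_depth) == [1.0, 0.5, 0.0]
        assert profile.mean_depth == pytest.approx(150 / 250)


class TestSamRoundTrip:
    def test_records_survive_round_trip(self, toy_genome, tmp_path):
        genome, _ = toy_genome
        pairs = synth.simulate_reads(genome, mean_coverage=2, seed=12)
        alignments, _ = align.map_reads(pairs, genome)
        align.mark_duplicates(alignments)
        path = tmp_path / "out.sam"
        io.write_sam(alignments, genome, path, read_sequences=calling.read_sequence_map(pairs))
        back, ref_name, ref_len = io.read_sam(path)
        assert ref_name == genome.id and ref_len == genome.length
        assert len(back) == len(alignments)
        for orig, rt in zip(alignments, back):
            assert rt.ref_start == orig.ref_start
            assert rt.cigar == orig.cigar
            assert rt.strand == orig.strand
            assert rt.is_duplicate == orig.is_duplicate
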