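"""Two-half scaffolding: splitting, placement, consensus, IR detection."""

import numpy as np
import pytest

import plastidkit as pk
from plastidkit import scaffolder
from plastidkit.assembler import Contig
from plastidkit.genome import revcomp


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSplitReference:
    def test_toy_interval_arithmetic(self, toy_genome):
        # LSC 1000, IRb 1001-1300, SSC 1301-1500, IRa 1501-1800
        pair = pk.split_reference(toy_genome, ssc_overhang=100, overlap=150)
        assert pair.ref_a_interval == (1, 1400)
        assert len(pair.ref_a) == 1400
        assert pair.ref_b_interval == (1151, 1800)
        assert len(pair.ref_b) == 650
        assert pair.overlap_len == 250

    def test_halves_are_reference_slices(self, toy_genome):
        pair = pk.split_reference(toy_genome, 100, 150)
        assert pair.ref_a == toy_genome.sequence[:1400]
        assert pair.ref_b == toy_genome.sequence[1150:]

    def test_zero_overlap_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            pk.split_reference(toy_genome, 100, 0)

    def test_overlap_wider_than_ir_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            pk.split_reference(toy_genome, 100, 300)

    def test_annotated_sequence_input(self, toy_genome):
        annotation = pk.detect_ir(toy_genome.sequence, min_ir_len=100)
        pair = pk.split_reference((toy_genome.sequence, annotation), 100, 150)
        assert pair.ref_a_interval == (1, 1400)

    def test_unannotated_sequence_is_structural_error(self):
        from plastidkit.genome import RegionAnnotation

        with pytest.raises(scaffolder.StructuralError):
            pk.split_reference((random_dna(2000, 1), RegionAnnotation()), 100, 150)


def brute_force_ir(seq, min_ir_len):
    """O(n^2)-ish oracle: maximal disjoint interval pair with
    seq[b] == revcomp(seq[a]); ties to the smallest start."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    best = None
    for a1 in range(n):
        for b2 in range(n - 1, a1, -1):
            if seq[a1] != comp[seq[b2]]:
                continue
            length = 0
            while (
                a1 + length < n
                and b2 - length >= 0
                and seq[a1 + length] == comp[seq[b2 - length]]
            ):
                length += 1
            # trim so intervals stay disjoint: a-end < b-start
            while length > 0 and a1 + length - 1 >= b2 - length + 1:
                length -= 1
            if length >= min_ir_len:
                cand = (length, a1, b2 - length + 1)
                if best is None or cand[0] > best[0] or (
                    cand[0] == best[0] and cand[1] < best[1]
                ):
                    best = cand
    return best


class TestDetectIR:
    def test_constructed_genome_recovered_exactly(self, toy_genome):
        ann = pk.detect_ir(toy_genome.sequence, min_ir_len=100)
        assert (ann.irb.start, ann.irb.end) == (1001, 1300)
        assert (ann.ira.start, ann.ira.end) == (1501, 1800)
        assert ann.junctions == toy_genome.junctions

    def test_random_sequence_has_no_ir(self):
        ann = pk.detect_ir(random_dna(500, 2), min_ir_len=100)
        assert ann.empty

    def test_matches_brute_force_oracle(self):
        for seed in range(6):
            if seed % 2 == 0:
                g = pk.make_genome(
                    600 + 100 * seed, 150, 120 + 10 * seed, seed=30 + seed
                )
                seq = g.sequence
            else:
                seq = random_dna(1200, 60 + seed)
            ann = pk.detect_ir(seq, min_ir_len=60)
            oracle = brute_force_ir(seq, 60)
            if oracle is None:
                assert ann.empty
            else:
                length, a1, b1 = oracle
                assert (ann.irb.start, ann.irb.end) == (a1 + 1, a1 + length)
                assert (ann.ira.start, ann.ira.end) == (b1 + 1, b1 + length)

    def test_real_scale_region_lengths(self):
        g = pk.make_genome(87022, 18352, 27070, seed=44)
        ann = pk.detect_ir(g.sequence, min_ir_len=1000)
        assert ann.region_lengths() == {
            "LSC": 87022,
            "IRb": 27070,
            "SSC": 18352,
            "IRa": 27070,
        }


@pytest.fixture(scope="module")
def setup():
    genome = pk.make_genome(3000, 600, 700, seed=3)
    pair = pk.split_reference(genome, 300, 300)
    return genome, pair


@pytest.fixture(scope="module")
def small():
    genome = pk.make_genome(3000, 600, 700, seed=5)
    reference = pk.diverge(genome, 0.08, 0.003, seed=6)
    pair = pk.split_reference(reference, 300, 300)
    return genome, reference, pair


class TestPlaceContigs:
    def test_exact_segment_places_forward_full_identity(self, setup):
        genome, pair = setup
        contig = Contig("c", pair.ref_a[499:900], 31, 10.0)
        placements = pk.place_contigs([contig], pair)
        a = [p for p in placements if p.scaffold == "A"]
        assert a and a[0].strand == "+" and a[0].identity == 1.0
        assert (a[0].ref_start, a[0].ref_end) == (500, 900)

    def test_ir_contig_places_on_both_halves(self, setup):
        genome, pair = setup
        contig = Contig("ir", genome.irb[50:650], 31, 10.0)
        placements = pk.place_contigs([contig], pair)
        halves = {p.scaffold for p in placements}
        assert halves == {"A", "B"}
        assert all(p.in_ir for p in placements if p.scaffold == "A")

    def test_unrelated_contig_is_structural_error(self, setup):
        _genome, pair = setup
        junk = Contig("junk", random_dna(400, 77), 31, 10.0)
        with pytest.raises(scaffolder.StructuralError):
            pk.place_contigs([junk], pair)


def _segment_contigs(genome, spans, mutate=()):
    """Exact genome segments as contigs; ``mutate`` holds (contig index,
    0-based genome position, base) substitutions."""
    contigs = []
    for i, (start, end) in enumerate(spans):
        seq = list(genome.sequence[start:end])
        for ci, pos, base in mutate:
            if ci == i and start <= pos < end:
                seq[pos - start] = base
        contigs.append(Contig(f"s{i}", "".join(seq), 31, 10.0))
    return contigs


class TestConsensusAndMerge:
    def _run(self, genome, pair, contigs):
        placements = pk.place_contigs(contigs, pair, 0.7)
        return pk.consensus_and_merge(placements, contigs, pair, min_ir_len=150)

    def test_agreeing_contigs_give_exact_genome(self, small):
        genome, _ref, pair = small
        spans = [(0, 3200), (2800, 4500), (3100, 5000)]
        contigs = _segment_contigs(genome, spans)
        cons = self._run(genome, pair, contigs)
        assert cons.sequence == genome.sequence

    def test_majority_vote_overrules_single_dissenter(self, small):
        genome, _ref, pair = small
        pos = 1500
        base = "A" if genome.sequence[pos] != "A" else "C"
        spans = [(0, 3200), (500, 3600), (1000, 4200), (3100, 5000)]
        contigs = _segment_contigs(genome, spans, mutate=[(1, pos, base)])
        cons = self._run(genome, pair, contigs)
        # column votes {ref, alt, ref} -> majority keeps the genome base
        assert cons.sequence[pos] == genome.sequence[pos]

    def test_tie_resolved_lexicographically_and_logged(self, small):
        genome, _ref, pair = small
        pos = 1500
        ref_base = genome.sequence[pos]
        alt = "A" if ref_base != "A" else "C"
        spans = [(0, 3200), (1000, 4200), (3100, 5000)]
        contigs = _segment_contigs(genome, spans, mutate=[(1, pos, alt)])
        cons = self._run(genome, pair, contigs)
        assert cons.sequence[pos] == min(ref_base, alt)
        assert any(abs(p - (pos + 1)) <= 2 for p in cons.ambiguous_positions)

    def test_permutation_invariance(self, small):
        genome, _ref, pair = small
        spans = [(0, 3200), (2800, 4500), (3100, 5000)]
        contigs = _segment_contigs(genome, spans)
        placements = pk.place_contigs(contigs, pair, 0.7)
        ref_cons = pk.consensus_and_merge(placements, contigs, pair, min_ir_len=150)
        for ordering in ([2, 0, 1], [1, 2, 0]):
            shuffled = [contigs[i] for i in ordering]
            p2 = pk.place_contigs(shuffled, pair, 0.7)
            c2 = pk.consensus_and_merge(p2, shuffled, pair, min_ir_len=150)
            assert c2.sequence == ref_cons.sequence

    def test_zero_length_gap_recorded(self, small):
        genome, _ref, pair = small
        # leave an uncovered hole in the LSC: contigs abut with no overlap
        spans = [(0, 1200), (1400, 3400), (3000, 5000)]
        contigs = _segment_contigs(genome, spans)
        placements = pk.place_contigs(contigs, pair, 0.7)
        cons = pk.consensus_and_merge(placements, contigs, pair, min_ir_len=150)
        assert cons.gap_flags  # adjacency recorded
        # concatenated: the 200 uncovered bases (plus any unconfirmed
        # trimmed flank next to the hole) are absent
        missing = len(genome.sequence) - len(cons.sequence)
        assert 200 <= missing <= 280
        # the two flanks around the recorded gap are genuine genome sequence
        flag = cons.gap_flags[0]
        assert cons.sequence[flag - 50 : flag] in genome.sequence
        assert cons.sequence[flag : flag + 50] in genome.sequence

    def test_requires_placements_on_both_halves(self, small):
        genome, _ref, pair = small
        contigs = _segment_contigs(genome, [(0, 1500)])  # LSC only
        placements = pk.place_contigs(contigs, pair, 0.7)
        with pytest.raises(scaffolder.StructuralError):
            pk.consensus_and_merge(placements, contigs, pair, min_ir_len=150)


class TestEndToEnd:
    def test_full_recovery_at_100_percent_identity(self, e2e_result):
        assert e2e_result["consensus"].sequence == e2e_result["genome"].sequence

    def test_junctions_exact(self, e2e_result):
        cons = e2e_result["consensus"]
        assert cons.annotation.junctions == e2e_result["genome"].junctions
        assert cons.annotation.region_lengths() == {
            "LSC": 7000, "IRb": 1500, "SSC": 1500, "IRa": 1500,
        }

    def test_both_irs_present_and_reverse_complementary(self, e2e_result):
        cons = e2e_result["consensus"]
        ann = cons.annotation
        irb = cons.sequence[ann.irb.start - 1 : ann.irb.end]
        ira = cons.sequence[ann.ira.start - 1 : ann.ira.end]
        assert ira == revcomp(irb)
        assert cons.ir_mismatches == 0

    def test_decoy_genome_not_used_for_binning(self, e2e_result):
        hits = e2e_result["hits"]
        assert set(hits[hits["chloroplast"]]["db_id"]) == {"relative"}
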