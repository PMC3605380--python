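"""Read mapping, pileups and pooled SNP calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastidkit as pk
from plastidkit import popsnp
from plastidkit.genome import revcomp
from plastidkit.synthsim import ReadRecord


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def read(seq, name="r", qual_score=35):
    return ReadRecord(name, seq, chr(qual_score + 33) * len(seq))


@pytest.fixture(scope="module")
def consensus():
    return random_dna(6000, 1)


class TestMapReads:
    def test_perfect_read_accepted(self, consensus):
        alns = pk.map_reads([read(consensus[1000:1100])], consensus)
        assert len(alns) == 1
        assert alns[0].ref_start == 1001 and alns[0].strand == "+"

    def test_reverse_read_accepted(self, consensus):
        alns = pk.map_reads([read(revcomp(consensus[2000:2100]))], consensus)
        assert len(alns) == 1 and alns[0].strand == "-"

    def test_high_identity_accepted(self, consensus):
        seq = list(consensus[3000:3100])
        for i in (10, 30, 50, 70, 85, 90, 95):
            seq[i] = "A" if seq[i] != "A" else "C"
        alns = pk.map_reads([read("".join(seq))], consensus)  # 93% identity
        assert len(alns) == 1

    def test_low_identity_rejected(self, consensus):
        seq = list(consensus[3000:3100])
        for i in range(0, 100, 7):  # ~15% mismatches
            seq[i] = "A" if seq[i] != "A" else "C"
        assert pk.map_reads([read("".join(seq))], consensus) == []

    def test_short_match_rejected_by_length_fraction(self, consensus):
        chimera = consensus[4000:4070] + random_dna(30, 2)
        assert pk.map_reads([read(chimera)], consensus) == []

    def test_repeat_read_randomly_assigned_and_reproducible(self):
        genome = pk.make_genome(2000, 400, 500, seed=3)
        seq = genome.sequence
        ir_read = read(genome.irb[100:200])
        placements = []
        for seed in range(60):
            cfg = popsnp.MappingConfig(seed=seed)
            aln = pk.map_reads([ir_read], seq, cfg)[0]
            assert aln.n_best_sites == 2
            placements.append(aln.ref_start)
        # both IR copies used, roughly half-half
        irb_hits = sum(1 for p in placements if p < 3000)
        sd = (60 * 0.25) ** 0.5
        assert abs(irb_hits - 30) < 3 * sd
        # reproducible per seed
        again = pk.map_reads([ir_read], seq, popsnp.MappingConfig(seed=5))[0]
        ref = pk.map_reads([ir_read], seq, popsnp.MappingConfig(seed=5))[0]
        assert again.ref_start == ref.ref_start

    def test_unique_mode_discards_repeat_reads(self):
        genome = pk.make_genome(2000, 400, 500, seed=3)
        cfg = popsnp.MappingConfig(match_mode="unique")
        assert pk.map_reads([read(genome.irb[100:200])], genome.sequence, cfg) == []

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            pk.map_reads([], "")


class TestPileupCoverage:
    def test_counts_and_coverage(self, consensus):
        reads = [read(consensus[i : i + 100], f"r{i}") for i in range(0, 500, 50)]
        alns = pk.map_reads(reads, consensus)
        cols = pk.pileup(alns, consensus)
        assert cols[0].depth == 1  # only the first read covers base 1
        assert cols[99].depth == 2
        assert pk.coverage(alns, consensus) == pytest.approx(
            sum(a.aligned_len for a in alns) / len(consensus)
        )

    def test_zero_alignments(self, consensus):
        cols = pk.pileup([], consensus)
        assert all(c.depth == 0 for c in cols)
        assert pk.coverage([], consensus) == 0

    def test_low_quality_bases_do_not_vote(self, consensus):
        r = ReadRecord("r", consensus[100:200], chr(2 + 33) * 100)  # Q2 < Q13
        alns = pk.map_reads([r], consensus)
        cols = pk.pileup(alns, consensus)
        assert cols[150].depth == 0

    def test_simulated_coverage_near_nominal(self, snp_experiment):
        for pool in ("pool1", "pool2"):
            cov = pk.coverage(
                snp_experiment["alignments"][pool], snp_experiment["genome"].sequence
            )
            assert abs(cov - 200) < 3 * (200 / np.sqrt(5000))


def make_column(pos, ref, counts):
    return popsnp.PileupColumn(pos=pos, ref=ref, counts=counts)


class TestCallSnps:
    def test_quarter_frequency_called_at_both_thresholds(self):
        col = make_column(10, "A", (150, 50, 0, 0, 0))
        for mvf in (0.1, 0.2):
            calls = pk.call_snps([col], mvf=mvf, min_cov=10)
            assert [(c.pos, c.alt, c.frequency) for c in calls] == [(10, "C", 0.25)]

    def test_fifteen_percent_only_at_low_threshold(self):
        col = make_column(5, "A", (170, 30, 0, 0, 0))
        assert pk.call_snps([col], mvf=0.1, min_cov=10)
        assert not pk.call_snps([col], mvf=0.2, min_cov=10)

    def test_min_coverage_gate(self):
        col = make_column(3, "G", (4, 4, 0, 0, 0))
        assert not pk.call_snps([col], mvf=0.2, min_cov=10)
        assert pk.call_snps([col], mvf=0.2, min_cov=8)

    def test_deletions_never_called(self):
        col = make_column(7, "T", (2, 0, 0, 18, 30))
        calls = pk.call_snps([col], mvf=0.2, min_cov=10)
        assert all(c.alt in "ACGT" for c in calls)
        assert not any(c.alt == "T" for c in calls)  # ref never an alt

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACGT"),
                st.tuples(*[st.integers(min_value=0, max_value=60)] * 5),
            ),
            min_size=1,
            max_size=30,
        ),
        st.floats(min_value=0.05, max_value=0.5),
        st.integers(min_value=1, max_value=40),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_threshold_scan_oracle(self, columns, mvf, min_cov):
        cols = [make_column(i + 1, ref, counts) for i, (ref, counts) in enumerate(columns)]
        calls = pk.call_snps(cols, mvf=mvf, min_cov=min_cov)
        expected = set()
        for col in cols:
            depth = sum(col.counts)
            if depth < min_cov:
                continue
            for base, count in zip("ACGT", col.counts[:4]):
                if base != col.ref and count > 0 and count / depth >= mvf:
                    expected.add((col.pos, base))
        assert {(c.pos, c.alt) for c in calls} == expected

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            pk.call_snps([], mvf=0, min_cov=10)
        with pytest.raises(ValueError):
            pk.call_snps([], mvf=0.2, min_cov=0)


class TestSnpRecovery:
    def test_paper_thresholds_recover_exactly_planted_sites(self, snp_experiment):
        """mvf 20% + minimum coverage 10 retrieves only the real pool SNPs."""
        for pool in ("pool1", "pool2"):
            calls = pk.call_snps(
                snp_experiment["pileups"][pool], mvf=0.2, min_cov=10, pool_id=pool
            )
            assert {(c.pos, c.alt) for c in calls} == snp_experiment["planted"][pool]

    def test_frequencies_near_25_percent(self, snp_experiment):
        calls = pk.call_snps(snp_experiment["pileups"]["pool1"], 0.2, 10)
        assert all(0.15 < c.frequency < 0.36 for c in calls)

    def test_low_threshold_calls_are_superset(self, snp_experiment):
        strict = pk.call_snps(snp_experiment["pileups"]["pool1"], 0.2, 10)
        loose = pk.call_snps(snp_experiment["pileups"]["pool1"], 0.1, 10)
        assert {(c.pos, c.alt) for c in strict} <= {(c.pos, c.alt) for c in loose}


class TestComparePools:
    def _pileups(self, length, overrides):
        out = {}
        for pool, changes in overrides.items():
            cols = [make_column(i + 1, "A", (20, 0, 0, 0, 0)) for i in range(length)]
            for pos, counts in changes.items():
                cols[pos - 1] = make_column(pos, "A", counts)
            out[pool] = cols
        return out

    def test_private_and_shared_classification(self):
        pileups = self._pileups(
            30, {"p1": {5: (15, 5, 0, 0, 0)}, "p2": {5: (20, 0, 0, 0, 0)}}
        )
        calls = {
            "p1": pk.call_snps(pileups["p1"], 0.2, 10, "p1"),
            "p2": pk.call_snps(pileups["p2"], 0.2, 10, "p2"),
        }
        table = pk.compare_pools(calls, pileups)
        row = table[table["pos"] == 5].iloc[0]
        assert row["type"] == "private" and row["pools"] == "p1"

    def test_fixed_difference_detected(self):
        pileups = self._pileups(
            30, {"p1": {8: (0, 0, 0, 20, 0)}, "p2": {8: (0, 20, 0, 0, 0)}}
        )
        calls = {
            "p1": pk.call_snps(pileups["p1"], 0.2, 10, "p1"),
            "p2": pk.call_snps(pileups["p2"], 0.2, 10, "p2"),
        }
        table = pk.compare_pools(calls, pileups)
        assert table[table["pos"] == 8]["fixed_difference"].all()

    def test_identical_pools_no_findings(self):
        pileups = self._pileups(20, {"p1": {}, "p2": {}})
        table = pk.compare_pools({"p1": [], "p2": []}, pileups)
        assert len(table) == 0

    def test_mismatched_lengths_rejected(self):
        a = self._pileups(10, {"p1": {}})["p1"]
        b = self._pileups(12, {"p2": {}})["p2"]
        with pytest.raises(ValueError):
            pk.compare_pools({"p1": [], "p2": []}, {"p1": a, "p2": b})


class TestExports:
    def test_sam_roundtrip_via_pysam(self, tmp_path, consensus):
        import pysam

        reads = [read(consensus[i : i + 100], f"r{i}") for i in range(0, 1000, 100)]
        alns = pk.map_reads(reads, consensus)
        path = tmp_path / "out.sam"
        popsnp.write_sam(path, alns, consensus)
        with pysam.AlignmentFile(str(path)) as fh:
            records = list(fh)
        assert len(records) == len(alns)
        assert records[0].reference_start == alns[0].ref_start - 1

    def test_vcf_parses_with_cyvcf2(self, tmp_path):
        from cyvcf2 import VCF

        calls = {
            "p1": [popsnp.VariantCall("p1", 100, "A", "C", 0.25, 200)],
            "p2": [popsnp.VariantCall("p2", 100, "A", "C", 0.23, 190)],
        }
        path = tmp_path / "out.vcf"
        popsnp.write_vcf(path, calls, consensus_len=5000)
        records = list(VCF(str(path)))
        assert len(records) == 1
        assert records[0].POS == 100 and records[0].ALT == ["C"]
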