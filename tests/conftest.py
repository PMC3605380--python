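"""Shared fixtures: synthetic study-condition datasets built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import plastidkit as pk
from plastidkit import popsnp

TRANSVERSION = {"A": "C", "C": "G", "G": "T", "T": "A"}


def single_copy_positions(genome: pk.QuadripartiteGenome, margin: int = 150) -> list[int]:
    """1-based positions in LSC/SSC at least ``margin`` bp from any junction."""
    regions = genome.regions
    return list(range(1 + margin, regions["LSC"].end - margin)) + list(
        range(regions["SSC"].start + margin, regions["SSC"].end - margin)
    )


@pytest.fixture(scope="session")
def toy_genome() -> pk.QuadripartiteGenome:
    return pk.make_genome(1000, 200, 300, seed=1)


@pytest.fixture(scope="session")
def e2e_result():
    """Full error-free recovery experiment: 11.5 kb quadripartite genome,
    50x paired reads, dual-k assembly, binning against a 10%-diverged
    relative, two-half scaffolding."""
    genome = pk.make_genome(7000, 1500, 1500, seed=1)
    reference = pk.diverge(genome, 0.10, 0.005, seed=101)
    cfg = pk.SimConfig(
        n_pairs=int(50 * len(genome) / 200), seed=201, cp_fraction=1.0
    )
    pairs = pk.simulate_reads([pk.Haplotype(base_genome=genome)], cfg)
    reads = [r for p in pairs for r in p]
    contigs = []
    for k in (55, 71):
        contigs.extend(pk.assemble(reads, k, 200))
    database = [
        ("relative", reference.sequence),
        ("decoy", pk.make_genome(7000, 1500, 1500, seed=999).sequence),
    ]
    kept, hits = pk.bin_contigs(contigs, database)
    pair = pk.split_reference(reference, ssc_overhang=700, overlap=700)
    placements = pk.place_contigs(kept, pair, 0.7)
    consensus = pk.consensus_and_merge(placements, kept, pair, min_ir_len=200)
    return {
        "genome": genome,
        "reference": reference,
        "reads": reads,
        "contigs": contigs,
        "kept": kept,
        "hits": hits,
        "pair": pair,
        "placements": placements,
        "consensus": consensus,
    }


@pytest.fixture(scope="session")
def pipeline_study():
    """Small but complete study: two pools of four with planted variants,
    chloroplast reads a 25% minority, 0.2% per-base error, 50x chloroplast
    coverage, a 10%-diverged scaffold reference and a decoy database entry."""
    from plastidkit import pipeline

    genome = pk.make_genome(5000, 1000, 1000, seed=3)
    reference = pk.diverge(genome, 0.10, 0.005, seed=103)
    database = [
        ("relative", reference.sequence),
        ("decoy", pk.make_genome(5000, 1000, 1000, seed=903).sequence),
    ]
    seq = genome.sequence
    rng = np.random.default_rng(3)
    positions = sorted(
        rng.choice(single_copy_positions(genome), size=6, replace=False).tolist()
    )
    sites1 = [(p, TRANSVERSION[seq[p - 1]], {1}) for p in positions[:3]]
    sites2 = [(p, TRANSVERSION[seq[p - 1]], {2}) for p in positions[3:]]
    n_pairs = int(50 * len(genome) / 200 / 0.25)
    pairs = {
        "pool1": pk.simulate_reads(
            pk.make_pool(genome, 4, sites1, id_prefix="a"),
            pk.SimConfig(n_pairs=n_pairs, seed=7, per_base_error=0.002, cp_fraction=0.25),
        ),
        "pool2": pk.simulate_reads(
            pk.make_pool(genome, 4, sites2, id_prefix="b"),
            pk.SimConfig(n_pairs=n_pairs, seed=8, per_base_error=0.002, cp_fraction=0.25),
        ),
    }
    config = pipeline.RunConfig(
        seed=3, k_values=(41, 55), ssc_overhang=500, overlap=500, min_ir_len=150
    )
    return {
        "genome": genome,
        "reference": reference,
        "database": database,
        "pairs": pairs,
        "config": config,
        "planted": {
            "pool1": {(p, a) for p, a, _ in sites1},
            "pool2": {(p, a) for p, a, _ in sites2},
        },
    }


@pytest.fixture(scope="session")
def pipeline_run(pipeline_study, tmp_path_factory):
    from plastidkit import pipeline

    outdir = tmp_path_factory.mktemp("pipeline_run")
    report, consensus = pipeline.run_all(
        pipeline_study["pairs"],
        pipeline_study["reference"],
        pipeline_study["database"],
        pipeline_study["config"],
        outdir=outdir,
    )
    return report, consensus, outdir


@pytest.fixture(scope="session")
def subsample_rows(pipeline_study, pipeline_run):
    from plastidkit import pipeline

    _report, consensus, _outdir = pipeline_run
    return pipeline.subsample_experiment(
        pipeline_study["pairs"]["pool1"],
        consensus,
        pipeline_study["database"],
        fractions=(1.0, 0.5, 0.25, 0.125),
        config=pipeline_study["config"],
    )


@pytest.fixture(scope="session")
def snp_experiment():
    """Two pools of four haplotypes with ten planted singleton variants
    (25% within-pool frequency) in single-copy regions, ~200x coverage,
    0.2% per-base error, mapped back to the generating genome."""
    genome = pk.make_genome(5000, 1000, 1000, seed=42)
    seq = genome.sequence
    rng = np.random.default_rng(7)
    candidates = single_copy_positions(genome)
    positions = sorted(rng.choice(candidates, size=10, replace=False).tolist())
    sites1 = [(p, TRANSVERSION[seq[p - 1]], {1}) for p in positions[:5]]
    sites2 = [(p, TRANSVERSION[seq[p - 1]], {2}) for p in positions[5:]]
    pools = {
        "pool1": (pk.make_pool(genome, 4, sites1, id_prefix="a"), sites1, 11),
        "pool2": (pk.make_pool(genome, 4, sites2, id_prefix="b"), sites2, 12),
    }
    n_pairs = int(200 * len(genome) / 200)
    out = {"genome": genome, "planted": {}, "alignments": {}, "pileups": {}}
    map_cfg = popsnp.MappingConfig(seed=5)
    for pool_id, (haps, sites, seed) in pools.items():
        cfg = pk.SimConfig(
            n_pairs=n_pairs, seed=seed, per_base_error=0.002, cp_fraction=1.0
        )
        reads = [r for p in pk.simulate_reads(haps, cfg) for r in p]
        alns = pk.map_reads(reads, seq, map_cfg)
        out["alignments"][pool_id] = alns
        out["pileups"][pool_id] = pk.pileup(alns, seq)
        out["planted"][pool_id] = {(p, alt) for p, alt, _c in sites}
    return out
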