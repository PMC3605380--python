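"""End-to-end orchestration: trim, dual-k assembly, binning, scaffolding,
mapping and pooled SNP calling.

The four-step protocol: (1) de-novo assemble trimmed reads by two
independent routes (here: one de Bruijn engine at two k values, or
imported external contigs); (2) screen contigs against a plastome
database, keeping those with an E-value of zero; (3) scaffold the kept
contigs against a distant reference split into two overlapping halves so
both inverted repeats are reconstructed; (4) map the pooled reads back to
the consensus and call SNPs with minimum-variant-frequency and coverage
thresholds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import assembler, cpbin, io, popsnp, readprep, scaffolder
from .genome import QuadripartiteGenome
from .synthsim import ReadRecord


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    quality_limit: float = 0.05
    min_read_len: int = 50
    k_values: tuple[int, ...] = (55, 71)
    min_contig_len: int = 200
    evalue_zero: float = cpbin.EVALUE_ZERO
    ssc_overhang: int = 3000
    overlap: int = 3000
    placement_identity: float = 0.7
    merge_identity: float = 0.9
    min_ir_len: int = 200
    similarity: float = 0.9
    length_fraction: float = 0.8
    match_mode: str = "random"
    mvf: float = 0.2
    min_cov: int = 10

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_digest: str
    seed: int
    n_pairs_in: dict[str, int]
    n_pairs_trimmed: dict[str, int]
    assembly_stats: dict[int, assembler.AssemblyStats]
    n_contigs_total: int
    n_contigs_chloroplast: int
    consensus_length: int
    region_lengths: dict[str, int]
    junctions: dict[str, tuple[int, int]]
    gap_flags: list[int]
    coverage: dict[str, float]
    snp_calls: dict[str, list[popsnp.VariantCall]]
    comparison: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        payload = {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "n_pairs_in": self.n_pairs_in,
            "n_pairs_trimmed": self.n_pairs_trimmed,
            "assembly_stats": {
                str(k): asdict(v) for k, v in self.assembly_stats.items()
            },
            "n_contigs_total": self.n_contigs_total,
            "n_contigs_chloroplast": self.n_contigs_chloroplast,
            "consensus_length": self.consensus_length,
            "region_lengths": self.region_lengths,
            "junctions": {k: list(v) for k, v in self.junctions.items()},
            "gap_flags": self.gap_flags,
            "coverage": {k: round(v, 4) for k, v in self.coverage.items()},
            "snp_calls": {
                pool: [asdict(c) for c in calls]
                for pool, calls in self.snp_calls.items()
            },
            "comparison": self.comparison,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _flatten(pairs: list[tuple[ReadRecord, ReadRecord]]) -> list[ReadRecord]:
    out: list[ReadRecord] = []
    for r1, r2 in pairs:
        out.append(r1)
        out.append(r2)
    return out


def run_all(
    pairs_by_pool: dict[str, list[tuple[ReadRecord, ReadRecord]]],
    reference: QuadripartiteGenome | tuple[str, "scaffolder.RegionAnnotation"] | None,
    database: list[tuple[str, str]],
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
    external_contigs: list[assembler.Contig] | None = None,
    consensus_override: scaffolder.ConsensusGenome | None = None,
) -> tuple[RunReport, scaffolder.ConsensusGenome]:
    """Run the full protocol; returns (report, consensus genome).

    ``external_contigs`` may replace/extend the internal assembler output
    (drop-in for contigs from another assembler).  Every intermediate is
    persisted under ``outdir`` when given.
    """
    if reference is None and consensus_override is None:
        raise ConfigError("missing required field 'reference' (scaffolding enabled)")
    if not database:
        raise ConfigError("missing required field 'database'")
    if not pairs_by_pool:
        raise ConfigError("missing required field 'pairs_by_pool'")
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    provenance = f"plastidkit cfg={config.digest()} seed={config.seed}"

    # 1. trim
    stage = "trim"
    try:
        trim_cfg = readprep.TrimConfig(config.quality_limit, config.min_read_len)
        trimmed = {
            pool: readprep.trim_pairs(pairs, trim_cfg)
            for pool, pairs in pairs_by_pool.items()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    pools = sorted(trimmed)
    assembly_pool = pools[0]  # first pool drives the de-novo assembly
    reads_for_assembly = _flatten(trimmed[assembly_pool])

    # 2. dual-k de novo assembly
    stage = "assemble"
    try:
        stats: dict[int, assembler.AssemblyStats] = {}
        contigs: list[assembler.Contig] = []
        for k in config.k_values:
            cs = assembler.assemble(reads_for_assembly, k, config.min_contig_len)
            stats[k] = assembler.assembly_stats(cs)
            contigs.extend(cs)
        if external_contigs:
            contigs.extend(external_contigs)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # 3. chloroplast binning
    stage = "bin"
    try:
        kept, hit_table = cpbin.bin_contigs(contigs, database, config.evalue_zero)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # 4. two-half scaffolding and consensus
    stage = "scaffold"
    try:
        if consensus_override is not None:
            consensus = consensus_override
            placements = []
        else:
            pair = scaffolder.split_reference(
                reference, config.ssc_overhang, config.overlap
            )
            placements = scaffolder.place_contigs(
                kept, pair, config.placement_identity
            )
            consensus = scaffolder.consensus_and_merge(
                placements, kept, pair, config.merge_identity, config.min_ir_len
            )
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    # 5. mapping + SNP calling per pool
    stage = "map"
    try:
        map_cfg = popsnp.MappingConfig(
            similarity=config.similarity,
            length_fraction=config.length_fraction,
            match_mode=config.match_mode,
            seed=config.seed,
        )
        alignments = {}
        pileups = {}
        cov = {}
        for pool in pools:
            alns = popsnp.map_reads(
                _flatten(trimmed[pool]), consensus.sequence, map_cfg
            )
            alignments[pool] = alns
            pileups[pool] = popsnp.pileup(alns, consensus.sequence)
            cov[pool] = popsnp.coverage(alns, consensus.sequence)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    stage = "call"
    try:
        calls = {
            pool: popsnp.call_snps(
                pileups[pool], config.mvf, config.min_cov, pool_id=pool
            )
            for pool in pools
        }
        comparison = []
        if len(pools) >= 2:
            comparison = popsnp.compare_pools(calls, pileups).to_dict("records")
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, exc) from exc

    report = RunReport(
        config_digest=config.digest(),
        seed=config.seed,
        n_pairs_in={p: len(pairs_by_pool[p]) for p in pools},
        n_pairs_trimmed={p: len(trimmed[p]) for p in pools},
        assembly_stats=stats,
        n_contigs_total=len(contigs),
        n_contigs_chloroplast=len(kept),
        consensus_length=len(consensus.sequence),
        region_lengths=consensus.annotation.region_lengths(),
        junctions=dict(consensus.annotation.junctions),
        gap_flags=list(consensus.gap_flags),
        coverage=cov,
        snp_calls=calls,
        comparison=comparison,
    )

    if out:
        io.write_fasta(
            out / "consensus.fasta", [("consensus", consensus.sequence)], provenance
        )
        io.write_regions_gff3(out / "regions.gff3", "consensus", consensus.annotation)
        io.write_junctions_bed(out / "junctions.bed", "consensus", consensus.annotation)
        hit_table.to_csv(out / "hits.tsv", sep="\t", index=False)
        scaffolder.placements_table(placements).to_csv(
            out / "placements.tsv", sep="\t", index=False
        )
        for pool in pools:
            popsnp.write_sam(
                out / f"{pool}.sam", alignments[pool], consensus.sequence
            )
        popsnp.write_vcf(
            out / "calls.vcf",
            calls,
            len(consensus.sequence),
            provenance=provenance,
        )
        (out / "report.json").write_text(report.to_json())
    return report, consensus


def subsample_experiment(
    pairs: list[tuple[ReadRecord, ReadRecord]],
    consensus: scaffolder.ConsensusGenome,
    database: list[tuple[str, str]],
    fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125),
    config: RunConfig = RunConfig(),
    truth_sites: list[tuple[int, str]] | None = None,
) -> list[dict]:
    """Re-run assembly/mapping on every-nth subsamples of one pool.

    For each fraction 1/2^j: subsample pairs, trim, assemble at the first
    configured k, bin, and check whether the kept contigs tile the
    full-data consensus without uncovered columns (full-genome recovery);
    coverage and SNP recovery come from mapping the subsample onto the
    full-data consensus.
    """
    rows = []
    trim_cfg = readprep.TrimConfig(config.quality_limit, config.min_read_len)
    map_cfg = popsnp.MappingConfig(
        similarity=config.similarity,
        length_fraction=config.length_fraction,
        match_mode=config.match_mode,
        seed=config.seed,
    )
    for frac in fractions:
        n = round(1 / frac)
        if abs(1 / n - frac) > 1e-9:
            raise ValueError(f"fraction {frac} is not 1/n for integer n")
        sub = readprep.subsample_every_nth(pairs, n)
        trimmed = readprep.trim_pairs(sub, trim_cfg)
        reads = _flatten(trimmed)
        contigs = assembler.assemble(reads, config.k_values[0], config.min_contig_len)
        kept, _ = cpbin.bin_contigs(contigs, database, config.evalue_zero)
        recovered = _tiles_without_gaps(kept, consensus.sequence)
        alns = popsnp.map_reads(reads, consensus.sequence, map_cfg)
        cov = popsnp.coverage(alns, consensus.sequence)
        row = {
            "fraction": frac,
            "n_pairs": len(sub),
            "coverage": round(cov, 2),
            "assembled": recovered,
        }
        if truth_sites is not None:
            cols = popsnp.pileup(alns, consensus.sequence)
            calls = popsnp.call_snps(cols, config.mvf, config.min_cov)
            called = {(c.pos, c.alt) for c in calls}
            row["snps_recovered"] = sum(
                1 for site in truth_sites if site in called
            )
        rows.append(row)
    return rows


def _tiles_without_gaps(
    contigs: list[assembler.Contig], consensus_seq: str
) -> bool:
    """Do the contigs cover every consensus column (both IR copies allowed)?"""
    if not contigs:
        return False
    from . import align as _align

    covered = [False] * len(consensus_seq)
    for c in contigs:
        for aln in _align.find_placements(c.sequence, consensus_seq):
            if aln.identity < 0.95:
                continue
            for i in range(aln.t_start, aln.t_end):
                covered[i] = True
    return all(covered)
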