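"""Pooled-sample read mapping and SNP detection.

Reads from each pool are mapped to the assembled consensus with a gapped
aligner; a read is accepted when a sufficient fraction of it aligns
(length fraction) at sufficient identity (similarity).  Reads matching
both inverted-repeat copies equally well are placed at one copy uniformly
at random (seeded) or discarded, per match mode.  SNPs are called from the
pileup with two thresholds: minimum variant frequency (mvf, the smallest
non-reference allele fraction that triggers a call) and minimum coverage.
With four equimolar individuals per pool, a singleton variant is expected
at ~25% frequency, so mvf 20% with minimum coverage 10 retrieves real
pool SNPs while suppressing error-driven calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import align
from .genome import revcomp
from .synthsim import ReadRecord

_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_TO_BASE = "ACGT"
DELETION_IDX = 4


@dataclass(frozen=True)
class MappingConfig:
    similarity: float = 0.9
    length_fraction: float = 0.8
    match_mode: str = "random"  # or "unique"
    seed: int = 0
    min_base_quality: int = 13

    def __post_init__(self) -> None:
        for name, frac in (("similarity", self.similarity), ("length_fraction", self.length_fraction)):
            if not (0 < frac <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.match_mode not in ("random", "unique"):
            raise ValueError("match_mode must be 'random' or 'unique'")


@dataclass(frozen=True)
class ReadAlignment:
    """An accepted read placement on the consensus (1-based ref_start)."""

    read_id: str
    ref_start: int
    strand: str
    cigar: tuple[tuple[int, str], ...]
    seq: str  # oriented aligned query segment
    qual: str  # qualities for the oriented segment
    matches: int
    aligned_len: int
    n_best_sites: int = 1


@dataclass
class PileupColumn:
    pos: int  # 1-based
    ref: str
    counts: tuple[int, int, int, int, int]  # A, C, G, T, deletion

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class VariantCall:
    pool_id: str
    pos: int
    ref: str
    alt: str
    frequency: float
    depth: int


def map_reads(
    reads: list[ReadRecord],
    consensus: str,
    config: MappingConfig = MappingConfig(),
) -> list[ReadAlignment]:
    """Map single-end oriented reads onto the consensus.

    Acceptance: aligned_length/read_length >= length_fraction and
    matches/aligned_length >= similarity, after local trimming of the best
    gapped placement.  Equal-best multi-site reads (the IR copies) are
    placed uniformly at random under ``match_mode='random'`` (seeded) or
    discarded under ``'unique'``.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    rng = np.random.default_rng(config.seed)
    out: list[ReadAlignment] = []
    for read in reads:
        placements = align.find_placements(read.seq, consensus)
        if not placements:
            continue
        n_sites = len(placements)
        if n_sites > 1:
            if config.match_mode == "unique":
                continue
            choice = placements[int(rng.integers(0, n_sites))]
        else:
            choice = placements[0]
        aligned_len = choice.aligned_query_len
        if aligned_len / len(read.seq) < config.length_fraction:
            continue
        if choice.matches / aligned_len < config.similarity:
            continue
        qual = read.qual if choice.strand == "+" else read.qual[::-1]
        oriented = read.seq if choice.strand == "+" else revcomp(read.seq)
        out.append(
            ReadAlignment(
                read_id=read.id,
                ref_start=choice.t_start + 1,
                strand=choice.strand,
                cigar=tuple(choice.cigar),
                seq=oriented[choice.q_start : choice.q_end],
                qual=qual[choice.q_start : choice.q_end],
                matches=choice.matches,
                aligned_len=aligned_len,
                n_best_sites=n_sites,
            )
        )
    return out


def pileup(
    alignments: list[ReadAlignment], consensus: str, min_base_quality: int = 13
) -> list[PileupColumn]:
    """Per-column base counts (A/C/G/T/deletion) from accepted alignments.

    Bases below ``min_base_quality`` do not vote, consistent with the trim
    quality limit.
    """
    counts = np.zeros((5, len(consensus)), dtype=np.int32)
    for a in alignments:
        col = a.ref_start - 1
        qpos = 0
        for n, op in a.cigar:
            if op in "=X":
                for _ in range(n):
                    if ord(a.qual[qpos]) - 33 >= min_base_quality:
                        b = _BASE_TO_IDX.get(a.seq[qpos])
                        if b is not None:
                            counts[b, col] += 1
                    col += 1
                    qpos += 1
            elif op == "D":
                counts[DELETION_IDX, col : col + n] += 1
                col += n
            elif op == "I":
                qpos += n
    cols = []
    for pos in range(len(consensus)):
        cols.append(
            PileupColumn(
                pos=pos + 1,
                ref=consensus[pos],
                counts=tuple(int(c) for c in counts[:, pos]),
            )
        )
    return cols


def coverage(alignments: list[ReadAlignment], consensus: str) -> float:
    """Mean depth = total aligned query bases / consensus length."""
    total = sum(a.aligned_len for a in alignments)
    return total / len(consensus)


def call_snps(
    columns: list[PileupColumn], mvf: float = 0.2, min_cov: int = 10, pool_id: str = "pool"
) -> list[VariantCall]:
    """Threshold SNP caller.

    A site is called when depth >= ``min_cov`` and a non-reference base
    reaches frequency >= ``mvf`` (count/depth, depth including deletion
    observations).  One call per qualifying alt base; deletions are never
    called (SNPs only).
    """
    if not (0 < mvf <= 1):
        raise ValueError("mvf must be in (0, 1]")
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    calls = []
    for col in columns:
        depth = col.depth
        if depth < min_cov:
            continue
        for idx, base in enumerate(_IDX_TO_BASE):
            if base == col.ref:
                continue
            count = col.counts[idx]
            if count > 0 and count / depth >= mvf:
                calls.append(
                    VariantCall(
                        pool_id=pool_id,
                        pos=col.pos,
                        ref=col.ref,
                        alt=base,
                        frequency=round(count / depth, 4),
                        depth=depth,
                    )
                )
    return calls


def compare_pools(
    calls_by_pool: dict[str, list[VariantCall]],
    pileups_by_pool: dict[str, list[PileupColumn]],
    fixed_threshold: float = 0.99,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Classify called sites as shared/private and find fixed differences.

    A fixed difference is a site where each pool is >= ``fixed_threshold``
    one allele and the majority alleles differ between pools.
    """
    if len(calls_by_pool) < 2:
        raise ValueError("need at least two pools")
    lengths = {len(p) for p in pileups_by_pool.values()}
    if len(lengths) != 1:
        raise ValueError("pools were piled up on different consensus lengths")
    pools = sorted(calls_by_pool)
    called_sites: dict[int, set[str]] = {}
    for pool in pools:
        for c in calls_by_pool[pool]:
            called_sites.setdefault(c.pos, set()).add(pool)
    rows = []
    for pos in sorted(called_sites):
        in_pools = called_sites[pos]
        rows.append(
            {
                "pos": pos,
                "type": "shared" if len(in_pools) == len(pools) else "private",
                "pools": ",".join(sorted(in_pools)),
                "fixed_difference": False,
            }
        )
    # fixed differences scanned over all sufficiently covered sites
    n_sites = lengths.pop()
    for i in range(n_sites):
        majors = {}
        ok = True
        for pool in pools:
            col = pileups_by_pool[pool][i]
            depth = col.depth
            if depth < min_cov:
                ok = False
                break
            top = int(np.argmax(col.counts[:4]))
            if col.counts[top] / depth < fixed_threshold:
                ok = False
                break
            majors[pool] = _IDX_TO_BASE[top]
        if ok and len(set(majors.values())) > 1:
            pos = i + 1
            existing = [r for r in rows if r["pos"] == pos]
            if existing:
                existing[0]["fixed_difference"] = True
            else:
                rows.append(
                    {
                        "pos": pos,
                        "type": "fixed",
                        "pools": ",".join(pools),
                        "fixed_difference": True,
                    }
                )
    rows.sort(key=lambda r: r["pos"])
    return pd.DataFrame(rows, columns=["pos", "type", "pools", "fixed_difference"])


def write_sam(
    path: str | Path, alignments: list[ReadAlignment], consensus: str, ref_name: str = "consensus"
) -> None:
    """Write accepted alignments as plain-text SAM (via pysam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_name, "LN": len(consensus)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id.replace("/", "_")
            seg.query_sequence = a.seq
            seg.query_qualities = pysam.qualitystring_to_array(a.qual)
            seg.reference_id = 0
            seg.reference_start = a.ref_start - 1
            seg.flag = 16 if a.strand == "-" else 0
            seg.mapping_quality = 60 if a.n_best_sites == 1 else 0
            seg.cigarstring = "".join(f"{n}{op}" for n, op in a.cigar)
            fh.write(seg)


def write_vcf(
    path: str | Path,
    calls_by_pool: dict[str, list[VariantCall]],
    consensus_len: int,
    ref_name: str = "consensus",
    provenance: str = "",
) -> None:
    """Write pooled calls as VCF v4.2 with AF in INFO, one column per pool."""
    pools = sorted(calls_by_pool)
    by_site: dict[tuple[int, str, str], dict[str, VariantCall]] = {}
    for pool in pools:
        for c in calls_by_pool[pool]:
            by_site.setdefault((c.pos, c.ref, c.alt), {})[pool] = c
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref_name},length={consensus_len}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Pooled alt allele frequency">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Per-pool alt allele frequency">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Pool depth">',
    ]
    if provenance:
        lines.append(f"##source={provenance}")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pools))
    for (pos, ref, alt), per_pool in sorted(by_site.items()):
        freqs = [per_pool[p].frequency for p in pools if p in per_pool]
        info = f"AF={max(freqs):.4f}"
        samples = []
        for p in pools:
            if p in per_pool:
                samples.append(f"{per_pool[p].frequency:.4f}:{per_pool[p].depth}")
            else:
                samples.append(".:.")
        lines.append(
            f"{ref_name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tAF:DP\t" + "\t".join(samples)
        )
    Path(path).write_text("\n".join(lines) + "\n")
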