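"""Synthetic plastome, pool and read simulator.

Everything downstream (assembly, binning, scaffolding, SNP calling) is
exercised on data from this module: random quadripartite genomes, diverged
relatives standing in for a distant scaffold reference, equimolar pools of
haplotypes carrying planted variants, and paired-end reads with a uniform
substitution error model.

Study conditions emulated: 100 bp paired-end reads with ~460 bp inserts,
pools of four equimolar haplotypes (singleton variants at 25% pooled
frequency), and chloroplast reads as a ~5% minority of total genomic reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import DNA_ALPHABET, QuadripartiteGenome, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimConfig:
    """Paired-end read simulation parameters.

    ``cp_fraction`` is the proportion of read pairs drawn from the plastome
    pool; the remainder come from an i.i.d. uniform decoy background
    emulating the nuclear majority of a whole-genome shotgun library.
    """

    n_pairs: int
    seed: int
    read_len: int = 100
    insert_mean: int = 460
    insert_sd: float = 50.0
    per_base_error: float = 0.0
    cp_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if not (0 <= self.per_base_error < 1):
            raise ValueError("per_base_error must be in [0, 1)")
        if self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len")
        if not (0 < self.cp_fraction <= 1):
            raise ValueError("cp_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record (Phred+33 qualities)."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence/quality length mismatch")


@dataclass
class Haplotype:
    """A plastome haplotype: a base genome plus point edits.

    Edits are (1-based position on the full linearized sequence, ref base,
    alt base).  The reverse-complement identity between the IR copies is a
    property of the base genome, not of the haplotype: an edit inside one
    IR copy is applied to that copy only.
    """

    base_genome: QuadripartiteGenome
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    id: str = "hap"

    def __post_init__(self) -> None:
        seq = self.base_genome.sequence
        seen: set[int] = set()
        for pos, ref, alt in self.edits:
            if not (1 <= pos <= len(seq)):
                raise ValueError(f"edit position {pos} outside genome")
            if pos in seen:
                raise ValueError(f"duplicate edit position {pos}")
            seen.add(pos)
            if seq[pos - 1] != ref:
                raise ValueError(
                    f"ref base mismatch at {pos}: genome has {seq[pos - 1]}, edit says {ref}"
                )
            if alt == ref or alt not in DNA_ALPHABET:
                raise ValueError(f"invalid alt base {alt!r} at {pos}")

    @property
    def sequence(self) -> str:
        seq = list(self.base_genome.sequence)
        for pos, _ref, alt in self.edits:
            seq[pos - 1] = alt
        return "".join(seq)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _block_ir_extension(region: str, rng: np.random.Generator) -> str:
    """Make the constructed IR maximal across this single-copy region.

    Both single-copy regions are flanked by the two IR copies (the LSC
    wraps the circular origin).  If the region's first base complements its
    last, the repeat pair could be extended one base into the region,
    shifting the detected junctions; resubstitute the first base until the
    extension is blocked.
    """
    while region[0] == _COMP[region[-1]]:
        region = rng.choice(_BASES).decode() + region[1:]
    return region


def make_genome(
    lsc_len: int, ssc_len: int, ir_len: int, seed: int, id: str = "genome"
) -> QuadripartiteGenome:
    """Random quadripartite genome with the given region lengths.

    The junction-flanking bases of both single-copy regions are constrained
    so the inverted repeat is maximal, i.e. structure detection recovers
    exactly the constructed region lengths.
    """
    if lsc_len <= 0 or ssc_len <= 0 or ir_len <= 0:
        raise ValueError("region lengths must be positive")
    rng = np.random.default_rng(seed)
    lsc = _block_ir_extension(_random_dna(rng, lsc_len), rng)
    ir = _random_dna(rng, ir_len)
    ssc = _block_ir_extension(_random_dna(rng, ssc_len), rng)
    return QuadripartiteGenome(lsc=lsc, ssc=ssc, ir=ir, id=id)


def _mutate(seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        r = rng.random()
        if indel_rate > 0 and r < indel_rate:
            size = int(rng.integers(1, 11))
            if rng.random() < 0.5:
                out.append(_random_dna(rng, size))  # insertion before site
                out.append(seq[i])
                i += 1
            else:
                i += size  # deletion
        else:
            base = seq[i]
            if sub_rate > 0 and rng.random() < sub_rate:
                choices = [b for b in DNA_ALPHABET if b != base]
                base = choices[int(rng.integers(0, 3))]
            out.append(base)
            i += 1
    s = "".join(out)
    return s if s else _random_dna(rng, 1)


def diverge(
    genome: QuadripartiteGenome,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    id: str | None = None,
) -> QuadripartiteGenome:
    """Simulate a diverged relative (e.g. a distant scaffold reference).

    Substitutions and short (1-10 bp) indels are applied independently to
    the LSC, SSC and IR sequences; IRa is then regenerated as the reverse
    complement of the mutated IRb, preserving the quadripartite invariants.
    """
    for name, rate in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not (0 <= rate < 0.5):
            raise ValueError(f"{name} must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    lsc = _block_ir_extension(_mutate(genome.lsc, sub_rate, indel_rate, rng), rng)
    ir = _mutate(genome.ir, sub_rate, indel_rate, rng)
    ssc = _block_ir_extension(_mutate(genome.ssc, sub_rate, indel_rate, rng), rng)
    return QuadripartiteGenome(
        lsc=lsc, ssc=ssc, ir=ir, id=id or f"{genome.id}_diverged"
    )


def make_pool(
    genome: QuadripartiteGenome,
    n_individuals: int,
    variant_sites: list[tuple[int, str, set[int]]],
    seed: int = 0,
    id_prefix: str = "ind",
) -> list[Haplotype]:
    """Equimolar pool of haplotypes carrying planted variants.

    ``variant_sites`` entries are (1-based position, alt base, carrier set);
    carriers index individuals 1..n.  The pooled alt-allele fraction at each
    site is exactly ``len(carriers) / n_individuals`` — e.g. a singleton
    carrier in a pool of four gives the expected 25%.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    seq = genome.sequence
    for pos, alt, carriers in variant_sites:
        if not carriers <= set(range(1, n_individuals + 1)):
            raise ValueError(f"carrier index out of range at site {pos}")
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"variant position {pos} outside genome")
    haps = []
    for i in range(1, n_individuals + 1):
        edits = [
            (pos, seq[pos - 1], alt)
            for pos, alt, carriers in variant_sites
            if i in carriers
        ]
        haps.append(Haplotype(base_genome=genome, edits=edits, id=f"{id_prefix}{i}"))
    return haps


def _phred_char(p_err: float) -> str:
    q = 40 if p_err <= 0 else min(40, max(2, round(-10 * math.log10(p_err))))
    return chr(q + 33)


def simulate_reads(
    haplotypes: list[Haplotype], config: SimConfig
) -> list[tuple[ReadRecord, ReadRecord]]:
    """Simulate paired-end reads from an equimolar haplotype pool.

    Fragments start uniformly on the circular genome (pairs may span the
    origin), come off either strand with equal probability, and mate 2 is
    the reverse complement of the fragment end.  With ``cp_fraction`` < 1,
    the remaining pairs are drawn from an i.i.d. uniform decoy background.
    Base qualities encode the uniform error probability.  Deterministic per
    seed.
    """
    if not haplotypes:
        raise ValueError("haplotypes must be non-empty")
    rng = np.random.default_rng(config.seed)
    seqs = [h.sequence for h in haplotypes]
    qchar = _phred_char(config.per_base_error)
    qual = qchar * config.read_len
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    for idx in range(config.n_pairs):
        insert = max(config.read_len, int(round(rng.normal(config.insert_mean, config.insert_sd))))
        if rng.random() < config.cp_fraction:
            hap_i = int(rng.integers(0, len(seqs)))
            src = seqs[hap_i]
            origin = "cp"
            start = int(rng.integers(0, len(src)))
            frag = src[start:start + insert]
            if len(frag) < insert:  # wrap the circular origin
                frag += src[: insert - len(frag)]
        else:
            origin = "bg"
            frag = _random_dna(rng, insert)
        if rng.random() < 0.5:
            frag = revcomp(frag)
        r1 = frag[: config.read_len]
        r2 = revcomp(frag[-config.read_len:])
        if config.per_base_error > 0:
            r1 = _apply_errors(r1, config.per_base_error, rng)
            r2 = _apply_errors(r2, config.per_base_error, rng)
        name = f"sim_{origin}_{idx}"
        pairs.append(
            (ReadRecord(f"{name}/1", r1, qual), ReadRecord(f"{name}/2", r2, qual))
        )
    return pairs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in DNA_ALPHABET if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)
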