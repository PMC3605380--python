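"""De Bruijn graph unitig assembler.

Reads are decomposed into canonical k-mers (a k-mer and its reverse
complement are one node; k is required odd so no k-mer is its own reverse
complement).  Maximal non-branching paths (unitigs) are emitted as contigs
after a simple error-cleaning pass: a coverage cutoff on singleton k-mers,
removal of short dead-end tips, and popping of low-coverage bubble branches.

Running the same engine at two different k values plays the role of two
independent assemblers: overlap between the two contig sets confirms the
assembly downstream.  Note that the two inverted-repeat copies of a
plastome share canonical k-mers, so the IR collapses into a single unitig;
re-duplicating it is the scaffolder's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import revcomp
from .synthsim import ReadRecord

_ACGT = "ACGT"


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    k: int
    mean_kmer_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    mean_len: float
    max_len: int
    n50: int


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(reads: Iterable[ReadRecord | str], k: int) -> dict[str, int]:
    """Canonical k-mer counts over all reads (both strands implied)."""
    counts: dict[str, int] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = _canon(kmer)
            counts[c] = counts.get(c, 0) + 1
    return counts


def _exts(kmers: set[str], node: str, forward: bool) -> list[str]:
    """Oriented extensions of an oriented k-mer present in the graph."""
    if forward:
        core = node[1:]
        cands = (core + b for b in _ACGT)
    else:
        core = node[:-1]
        cands = (b + core for b in _ACGT)
    return [c for c in cands if _canon(c) in kmers]


def _walk(kmers: set[str], visited: set[str], start: str) -> list[str]:
    """Maximal unambiguous forward walk of oriented k-mers from ``start``."""
    path = []
    cur = start
    while True:
        outs = _exts(kmers, cur, True)
        if len(outs) != 1:
            break
        nxt = outs[0]
        if len(_exts(kmers, nxt, False)) != 1:
            break
        c = _canon(nxt)
        if c in visited:
            break
        path.append(nxt)
        visited.add(c)
        cur = nxt
    return path


def extract_unitigs(kmer_counts: dict[str, int]) -> list[tuple[str, float]]:
    """Maximal non-branching paths as (sequence, mean k-mer coverage).

    Deterministic: seeds are taken in sorted canonical k-mer order, and each
    unitig is reported in its lexicographically smaller orientation.
    """
    kmers = set(kmer_counts)
    visited: set[str] = set()
    unitigs = []
    for start in sorted(kmers):
        if start in visited:
            continue
        visited.add(start)
        fwd = _walk(kmers, visited, start)
        back = _walk(kmers, visited, revcomp(start))
        seq = (
            revcomp("".join(n[-1] for n in back))
            + start
            + "".join(n[-1] for n in fwd)
        )
        k = len(start)
        cov = sum(
            kmer_counts[_canon(seq[i : i + k])] for i in range(len(seq) - k + 1)
        ) / (len(seq) - k + 1)
        rc = revcomp(seq)
        unitigs.append((min(seq, rc), cov))
    return unitigs


def _unitig_end_neighbors(kmers: set[str], seq: str, k: int) -> tuple[list[str], list[str]]:
    back = _exts(kmers, seq[:k], False)
    fwd = _exts(kmers, seq[-k:], True)
    return back, fwd


def _clean_graph(kmer_counts: dict[str, int], k: int) -> dict[str, int]:
    """Remove short dead-end tips and pop bubbles (lower-coverage branch)."""
    counts = dict(kmer_counts)
    for _round in range(2):
        kmers = set(counts)
        unitigs = extract_unitigs(counts)
        doomed: set[str] = set()
        by_signature: dict[frozenset, list[tuple[str, float]]] = {}
        for seq, cov in unitigs:
            back, fwd = _unitig_end_neighbors(kmers, seq, k)
            dead_back, dead_fwd = len(back) == 0, len(fwd) == 0
            if (dead_back != dead_fwd) and len(seq) < 2 * k:
                # tip: remove only when the junction has a competing branch
                junction_side = back if dead_fwd else fwd
                competing = any(
                    len(_exts(kmers, n, forward=dead_fwd)) > 1 for n in junction_side
                )
                if competing:
                    doomed.add(seq)
                    continue
            if back and fwd:
                sig = frozenset(_canon(n) for n in back) | frozenset(
                    _canon(n) for n in fwd
                )
                by_signature.setdefault(sig, []).append((seq, cov))
        for group in by_signature.values():
            if len(group) > 1:  # bubble: keep the best-covered branch
                group.sort(key=lambda t: (-t[1], t[0]))
                for seq, _cov in group[1:]:
                    doomed.add(seq)
        if not doomed:
            break
        for seq in doomed:
            for i in range(len(seq) - k + 1):
                counts.pop(_canon(seq[i : i + k]), None)
    return counts


def assemble(
    reads: Iterable[ReadRecord | str],
    k: int,
    min_contig_len: int = 200,
    coverage_cutoff: int | None = None,
) -> list[Contig]:
    """Assemble reads into unitig contigs at a single k.

    ``coverage_cutoff=None`` applies the automatic rule: k-mers seen exactly
    once are dropped when the mean k-mer coverage exceeds 10 (sequencing
    errors dominate singletons at high depth).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if min_contig_len < 0:
        raise ValueError("min_contig_len must be >= 0")
    reads = list(reads)
    max_read = max((len(r if isinstance(r, str) else r.seq) for r in reads), default=0)
    if k >= max_read and max_read > 0:
        raise ValueError(f"k={k} must be smaller than the read length ({max_read})")
    counts = count_kmers(reads, k)
    if not counts:
        return []
    if coverage_cutoff is None:
        # judge depth on non-singleton k-mers: sequencing errors and any
        # random (non-target) background contribute mostly singletons and
        # would otherwise mask genuinely deep coverage
        nonsingle = [c for c in counts.values() if c > 1]
        mean_cov = sum(nonsingle) / len(nonsingle) if nonsingle else 0.0
        if mean_cov > 10:
            counts = {km: c for km, c in counts.items() if c > 1}
    else:
        counts = {km: c for km, c in counts.items() if c >= coverage_cutoff}
    counts = _clean_graph(counts, k)
    unitigs = [u for u in extract_unitigs(counts) if len(u[0]) >= max(min_contig_len, k)]
    unitigs.sort(key=lambda t: (-len(t[0]), t[0]))
    return [
        Contig(f"contig_k{k}_{i + 1}", seq, k, round(cov, 3))
        for i, (seq, cov) in enumerate(unitigs)
    ]


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that contigs of length >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("lengths must be non-empty")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]


def assembly_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    if not contigs:
        return AssemblyStats(0, 0.0, 0, 0)
    lengths = [len(c) for c in contigs]
    return AssemblyStats(len(contigs), sum(lengths) / len(lengths), max(lengths), n50(lengths))


def k_sweep(
    reads: Iterable[ReadRecord | str],
    k_values: Sequence[int],
    min_contig_len: int = 200,
) -> tuple[int, dict[int, AssemblyStats]]:
    """Assemble at each k; choose the k maximizing N50.

    Ties break by longest contig, then by the smaller k.  Mirrors sweeping
    the hash length and plotting N50 / longest contig per value.
    """
    if not k_values:
        raise ValueError("at least one k value required")
    reads = list(reads)
    table: dict[int, AssemblyStats] = {}
    for k in k_values:
        table[k] = assembly_stats(assemble(reads, k, min_contig_len))
    chosen = min(table, key=lambda k: (-table[k].n50, -table[k].max_len, k))
    return chosen, table
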