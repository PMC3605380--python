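"""Chloroplast contig binning by local alignment against a plastome database.

Contigs are screened with a seed-and-extend ungapped local aligner (exact
word seeds on both strands, X-drop extension) and scored with Karlin-
Altschul statistics: E = K*m*n*exp(-lambda*S).  Contigs whose best E-value
underflows to zero (operationally E <= 1e-180) are classified as
chloroplast; the filter is a binary gate, so ungapped extension suffices
and gapped alignment is left to the scaffolder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from scipy.optimize import brentq

from .assembler import Contig
from .genome import revcomp

#: double-precision proxy for a reported E-value "of zero"
EVALUE_ZERO = 1e-180


@dataclass(frozen=True)
class HomologyHit:
    """Local ungapped alignment of a contig against a database genome.

    Intervals are 1-based inclusive.  For minus-strand hits the contig
    interval refers to the forward contig coordinates of the aligned
    segment.
    """

    contig_id: str
    db_id: str
    score: int
    bitscore: float
    evalue: float
    contig_start: int
    contig_end: int
    db_start: int
    db_end: int
    strand: str


@lru_cache(maxsize=None)
def karlin_altschul_params(
    match: int, mismatch: int, p_match: float = 0.25
) -> tuple[float, float, float]:
    """(lambda, K, H) for an ungapped match/mismatch score scheme.

    lambda is the positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1
    (for uniform base composition: p_match * e^(lambda*match) +
    (1-p_match) * e^(lambda*mismatch) = 1).  K follows the lattice renewal
    series of Karlin-Altschul statistics with span d = gcd(match, |mismatch|);
    for (+1,-2) this yields (1.33, 0.621), matching published ungapped
    nucleotide values.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("require match > 0 > mismatch")
    q = 1.0 - p_match

    def expect(lam: float) -> float:
        return p_match * math.exp(lam * match) + q * math.exp(lam * mismatch) - 1.0

    lam = brentq(expect, 1e-9, 50.0)
    h = lam * (
        p_match * match * math.exp(lam * match)
        + q * mismatch * math.exp(lam * mismatch)
    )
    # sigma = sum_k (1/k) [ P(S_k >= 0) + E(e^{lam S_k}; S_k < 0) ]
    dist: dict[int, float] = {0: 1.0}
    sigma = 0.0
    for k in range(1, 301):
        new: dict[int, float] = {}
        for s, pr in dist.items():
            new[s + match] = new.get(s + match, 0.0) + pr * p_match
            new[s + mismatch] = new.get(s + mismatch, 0.0) + pr * q
        dist = new
        sigma += (
            sum(pr if s >= 0 else pr * math.exp(lam * s) for s, pr in dist.items()) / k
        )
    d = math.gcd(match, -mismatch)
    kappa = d * lam * math.exp(-2.0 * sigma) / (h * (1.0 - math.exp(-lam * d)))
    return lam, kappa, h


def evalue(score: int, m: int, n: int, match: int = 1, mismatch: int = -2) -> float:
    """Karlin-Altschul expectation E = K*m*n*e^(-lambda*S) (0.0 on underflow)."""
    lam, kappa, _ = karlin_altschul_params(match, mismatch)
    log_e = math.log(kappa) + math.log(m) + math.log(n) - lam * score
    return math.exp(log_e) if log_e > -745 else 0.0


def bitscore(score: int, match: int = 1, mismatch: int = -2) -> float:
    lam, kappa, _ = karlin_altschul_params(match, mismatch)
    return (lam * score - math.log(kappa)) / math.log(2)


def _extend(
    q: str, t: str, qi: int, ti: int, word_len: int, match: int, mismatch: int, xdrop: int
) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of a seed; returns (score, qs, qe, ts, te) 0-based half-open."""
    score = word_len * match
    # right extension
    best, cur = score, score
    qe, te = qi + word_len, ti + word_len
    bqe, bte = qe, te
    while qe < len(q) and te < len(t):
        cur += match if q[qe] == t[te] else mismatch
        qe += 1
        te += 1
        if cur > best:
            best, bqe, bte = cur, qe, te
        elif best - cur > xdrop:
            break
    # left extension
    cur = best
    qs, ts = qi, ti
    bqs, bts = qs, ts
    while qs > 0 and ts > 0:
        cur += match if q[qs - 1] == t[ts - 1] else mismatch
        qs -= 1
        ts -= 1
        if cur > best:
            best, bqs, bts = cur, qs, ts
        elif best - cur > xdrop:
            break
    return best, bqs, bqe, bts, bte


#: chaining constraints: co-linear segments may be joined across gaps of at
#: most this many bases (indel-scale, not random co-occurrence scale) ...
CHAIN_MAX_GAP = 100
#: ... at a per-join penalty exceeding what a chance seed hit contributes,
#: so chaining cannot inflate the score of spurious matches.
CHAIN_JOIN_PENALTY = 20


def _chain(hits: list[tuple[int, int, int, int, int]]) -> list[tuple[int, int, int, int, int]]:
    """Best-scoring co-linear chains of ungapped segments (one strand).

    Hits are (score, qs, qe, ts, te) with 0-based half-open coordinates in
    oriented-query space.  Returns merged chain hits (summed score minus
    join penalties, spanning intervals) for chains of >= 2 segments.
    """
    if len(hits) < 2:
        return []
    hits = sorted(hits, key=lambda h: (h[1], h[3]))
    best: list[tuple[int, int]] = [(h[0], -1) for h in hits]  # (chain score, prev)
    for i, (sc_i, qs_i, _qe_i, ts_i, _te_i) in enumerate(hits):
        for j in range(i):
            sc_j, _qs_j, qe_j, _ts_j, te_j = hits[j]
            q_gap = qs_i - qe_j
            t_gap = ts_i - te_j
            if not (-10 <= q_gap <= CHAIN_MAX_GAP and -10 <= t_gap <= CHAIN_MAX_GAP):
                continue
            cand = best[j][0] + sc_i - CHAIN_JOIN_PENALTY
            if cand > best[i][0]:
                best[i] = (cand, j)
    merged = []
    for i, (score, prev) in enumerate(best):
        if prev == -1:
            continue
        j = i
        while best[j][1] != -1:
            j = best[j][1]
        merged.append((score, hits[j][1], hits[i][2], hits[j][3], hits[i][4]))
    return merged


def seed_extend(
    contig: str,
    db_genome: str,
    word_len: int = 11,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 20,
    max_hits: int = 25,
    chain: bool = True,
) -> list[dict]:
    """Ungapped seed-and-extend local alignment on both strands.

    Returns hit dicts sorted by descending score; intervals 1-based
    inclusive in forward coordinates of both sequences.  Overlapping seeds
    on one diagonal are collapsed into a single extended hit.  With
    ``chain=True``, co-linear segments separated by indel-scale gaps are
    additionally reported as merged chain hits with summed score (the
    analogue of sum statistics for a diverged but homologous pair).
    """
    if word_len < 4:
        raise ValueError("word_len must be >= 4")
    if match <= 0 or mismatch >= 0:
        raise ValueError("require match > 0 > mismatch")
    if not contig or not db_genome:
        raise ValueError("empty sequence")
    index: dict[str, list[int]] = {}
    for i in range(len(db_genome) - word_len + 1):
        index.setdefault(db_genome[i : i + word_len], []).append(i)
    m, n = len(contig), len(db_genome)
    raw: list[tuple[str, int, int, int, int, int]] = []  # strand, score, qs, qe, ts, te
    for strand, q in (("+", contig), ("-", revcomp(contig))):
        covered: dict[int, list[tuple[int, int]]] = {}
        found: set[tuple[int, int, int]] = set()
        for qi in range(len(q) - word_len + 1):
            for ti in index.get(q[qi : qi + word_len], ()):
                diag = ti - qi
                if any(a <= qi < b for a, b in covered.get(diag, ())):
                    continue
                score, qs, qe, ts, te = _extend(
                    q, db_genome, qi, ti, word_len, match, mismatch, xdrop
                )
                covered.setdefault(diag, []).append((qs, qe))
                key = (diag, qs, qe)
                if key in found:
                    continue
                found.add(key)
                raw.append((strand, score, qs, qe, ts, te))
    hits: list[dict] = []

    def _emit(strand: str, score: int, qs: int, qe: int, ts: int, te: int, chained: bool) -> None:
        if strand == "+":
            cs, ce = qs + 1, qe
        else:  # map reverse-strand query coords back to forward contig
            cs, ce = m - qe + 1, m - qs
        hits.append(
            {
                "score": score,
                "contig_start": cs,
                "contig_end": ce,
                "db_start": ts + 1,
                "db_end": te,
                "strand": strand,
                "chained": chained,
            }
        )

    for strand, score, qs, qe, ts, te in raw:
        _emit(strand, score, qs, qe, ts, te, False)
    if chain:
        for strand in "+-":
            segs = [(sc, qs, qe, ts, te) for st, sc, qs, qe, ts, te in raw if st == strand]
            for score, qs, qe, ts, te in _chain(segs):
                _emit(strand, score, qs, qe, ts, te, True)
    hits.sort(key=lambda h: (-h["score"], h["db_start"], h["strand"]))
    out = []
    for h in hits[:max_hits]:
        h = dict(h)
        h["evalue"] = evalue(h["score"], m, n, match, mismatch)
        h["bitscore"] = round(bitscore(h["score"], match, mismatch), 2)
        out.append(h)
    return out


def best_hit(
    contig: Contig, database: list[tuple[str, str]], **kwargs
) -> HomologyHit | None:
    """Best-scoring hit of a contig over all database genomes."""
    best: HomologyHit | None = None
    for db_id, db_seq in database:
        hits = seed_extend(contig.sequence, db_seq, **kwargs)
        if not hits:
            continue
        h = hits[0]
        cand = HomologyHit(
            contig_id=contig.id,
            db_id=db_id,
            score=h["score"],
            bitscore=h["bitscore"],
            evalue=h["evalue"],
            contig_start=h["contig_start"],
            contig_end=h["contig_end"],
            db_start=h["db_start"],
            db_end=h["db_end"],
            strand=h["strand"],
        )
        if best is None or cand.score > best.score:
            best = cand
    return best


def bin_contigs(
    contigs: list[Contig],
    database: list[tuple[str, str]],
    evalue_zero: float = EVALUE_ZERO,
    **kwargs,
) -> tuple[list[Contig], pd.DataFrame]:
    """Keep contigs whose best database hit has E <= ``evalue_zero``.

    Returns (kept contigs, per-contig best-hit table in BLAST outfmt-6
    column spirit).  The default threshold operationalizes "E-value of
    zero" as underflow below 1e-180.
    """
    if not database:
        raise ValueError("database must be non-empty")
    rows = []
    kept = []
    for contig in contigs:
        hit = best_hit(contig, database, **kwargs)
        if hit is None:
            continue
        is_cp = hit.evalue <= evalue_zero
        rows.append(
            {
                "contig_id": hit.contig_id,
                "db_id": hit.db_id,
                "score": hit.score,
                "bitscore": hit.bitscore,
                "evalue": hit.evalue,
                "contig_start": hit.contig_start,
                "contig_end": hit.contig_end,
                "db_start": hit.db_start,
                "db_end": hit.db_end,
                "strand": hit.strand,
                "chloroplast": is_cp,
            }
        )
        if is_cp:
            kept.append(contig)
    columns = [
        "contig_id", "db_id", "score", "bitscore", "evalue",
        "contig_start", "contig_end", "db_start", "db_end", "strand", "chloroplast",
    ]
    return kept, pd.DataFrame(rows, columns=columns)
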