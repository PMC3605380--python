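"""Gapped semi-global alignment with local trimming.

edlib provides fast banded edit-distance alignment (infix mode: the whole
query against any window of the target).  Because edlib cannot clip query
ends, a max-sum trim over per-column scores (match +1, mismatch/indel -2)
recovers the best local sub-alignment of the edlib path; terminal query
bases that do not belong to the local alignment are reported as clipped.
This backs both contig placement on a diverged scaffold and read mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from ._util import max_sum_segment
from .genome import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

MATCH_SCORE = 1
GAP_MISMATCH_SCORE = -2


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_str(ops: list[tuple[int, str]]) -> str:
    return "".join(f"{n}{op}" for n, op in ops)


@dataclass(frozen=True)
class LocalAlignment:
    """Trimmed local alignment of a query to a target.

    Coordinates are 0-based half-open; ``q_start``/``q_end`` refer to the
    oriented query (reverse-complemented when ``strand`` is '-').
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    columns: int
    cigar: list[tuple[int, str]]

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def aligned_query_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def clipped_left(self) -> int:
        return self.q_start


def _expand_columns(ops: list[tuple[int, str]]) -> list[str]:
    cols: list[str] = []
    for n, op in ops:
        cols.extend(op * n)
    return cols


def _trim_path(cigar: str) -> tuple[int, int, list[str]]:
    """Best local column range of an alignment path; (start, end, columns)."""
    cols = _expand_columns(parse_cigar(cigar))
    scores = [MATCH_SCORE if c == "=" else GAP_MISMATCH_SCORE for c in cols]
    start, end, _ = max_sum_segment(scores)
    return start, end, cols


def _compress(cols: list[str]) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    for c in cols:
        if ops and ops[-1][1] == c:
            ops[-1] = (ops[-1][0] + 1, c)
        else:
            ops.append((1, c))
    return ops


_GAP = -2.5  # linear gap score for boundary extension
_MAX_EXT = 600  # cap on bases considered in a boundary extension


def _extend_boundary(qseg: str, tseg: str) -> tuple[list[str], int, int, int]:
    """Best gapped extension anchored at position 0 of both segments.

    Plays the role of a gapped X-drop extension: a quadratic DP from the
    anchor, keeping the best-scoring cell.  Returns (columns outward from
    the anchor, query bases consumed, target bases consumed, matches).
    """
    nq, nt = len(qseg), len(tseg)
    if nq == 0 or nt == 0:
        return [], 0, 0, 0
    NEG = float("-inf")
    prev = [j * _GAP for j in range(nt + 1)]
    best = (0.0, 0, 0)
    rows = [prev]
    for i in range(1, nq + 1):
        cur = [i * _GAP] + [NEG] * nt
        qc = qseg[i - 1]
        for j in range(1, nt + 1):
            diag = prev[j - 1] + (MATCH_SCORE if qc == tseg[j - 1] else GAP_MISMATCH_SCORE)
            up = prev[j] + _GAP
            left = cur[j - 1] + _GAP
            cur[j] = max(diag, up, left)
            if cur[j] > best[0]:
                best = (cur[j], i, j)
        rows.append(cur)
        prev = cur
    score, bi, bj = best
    if score <= 0:
        return [], 0, 0, 0
    cols: list[str] = []
    i, j = bi, bj
    matches = 0
    while i > 0 or j > 0:
        here = rows[i][j]
        if i > 0 and j > 0:
            sub = MATCH_SCORE if qseg[i - 1] == tseg[j - 1] else GAP_MISMATCH_SCORE
            if rows[i - 1][j - 1] + sub == here:
                cols.append("=" if sub == MATCH_SCORE else "X")
                matches += sub == MATCH_SCORE
                i -= 1
                j -= 1
                continue
        if i > 0 and rows[i - 1][j] + _GAP == here:
            cols.append("I")
            i -= 1
            continue
        cols.append("D")
        j -= 1
    return cols, bi, bj, matches


def align_local(query: str, target: str, strand: str = "+",
                t_offset: int = 0, q_offset: int = 0, mode: str = "NW") -> LocalAlignment | None:
    """Align an oriented query against a target window and trim locally.

    After the max-sum trim, each boundary is re-extended with an anchored
    gapped DP so that genuine alignment lost to a poor global path head or
    tail (e.g. when the query carries unrelated terminal sequence) is
    recovered.
    """
    res = edlib.align(query, target, task="path", mode=mode)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    loc0 = 0 if mode == "NW" else (res["locations"][0][0] or 0)
    start, end, cols = _trim_path(res["cigar"])
    if end <= start:
        return None
    q_pos = sum(1 for c in cols[:start] if c in "=XI")
    t_pos = sum(1 for c in cols[:start] if c in "=XD")
    seg = cols[start:end]
    matches = sum(1 for c in seg if c == "=")
    q_len = sum(1 for c in seg if c in "=XI")
    t_len = sum(1 for c in seg if c in "=XD")
    q_start, q_end = q_pos, q_pos + q_len
    t_start = t_offset + loc0 + t_pos
    t_end = t_start + t_len
    # left boundary re-extension (anchored at the trimmed start)
    if 0 < q_start and t_start > 0:
        qseg = query[max(0, q_start - _MAX_EXT) : q_start][::-1]
        t_cap = min(len(qseg) + 50, _MAX_EXT)
        tseg = target[max(0, t_start - t_offset - t_cap) : t_start - t_offset][::-1]
        ext, dq, dt, m = _extend_boundary(qseg, tseg)
        if ext:
            seg = ext[::-1] + seg
            q_start -= dq
            t_start -= dt
            matches += m
    # right boundary re-extension
    if q_end < len(query) and t_end - t_offset < len(target):
        qseg = query[q_end : q_end + _MAX_EXT]
        t_cap = min(len(qseg) + 50, _MAX_EXT)
        tseg = target[t_end - t_offset : t_end - t_offset + t_cap]
        ext, dq, dt, m = _extend_boundary(qseg, tseg)
        if ext:
            seg = seg + ext
            q_end += dq
            t_end += dt
            matches += m
    return LocalAlignment(
        q_start=q_offset + q_start,
        q_end=q_offset + q_end,
        t_start=t_start,
        t_end=t_end,
        strand=strand,
        matches=matches,
        columns=len(seg),
        cigar=_compress(seg),
    )


def find_placements(
    query: str, target: str, max_locations: int = 4
) -> list[LocalAlignment]:
    """Best infix placements of a query in a target, both strands.

    Returns the trimmed local alignment at every distinct best-scoring
    location (e.g. both inverted-repeat copies); equally good strand hits
    are all reported.
    """
    results = []
    best_dist = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        res = edlib.align(q, target, task="locations", mode="HW")
        if res["editDistance"] < 0:
            continue
        results.append((strand, q, res))
        d = res["editDistance"]
        best_dist = d if best_dist is None else min(best_dist, d)
    placements: list[LocalAlignment] = []
    for strand, q, res in results:
        if res["editDistance"] != best_dist:
            continue
        for start, end in _cluster_locations(res["locations"], len(q)):
            window_start = max(0, start)
            aln = align_local(
                q, target[window_start : end + 1], strand=strand, t_offset=window_start
            )
            if aln is not None:
                placements.append(aln)
            if len(placements) >= max_locations:
                break
    return placements


_CHUNK = 250  # chunk size for candidate-window voting


def _candidate_windows(query: str, target: str) -> list[tuple[str, int]]:
    """Candidate (strand, projected query start) placements on a target.

    The query is cut into chunks; each chunk's best infix locations vote
    for a projected start of the whole (oriented) query.  A query that
    only partially overlaps the target (a junction spanner, or an
    inverted-repeat copy truncated by a boundary) still gathers votes from
    the chunks that do overlap, and a repeated query collects windows at
    every copy.
    """
    n = len(query)
    offsets = list(range(0, max(n - _CHUNK, 0) + 1, _CHUNK))
    if not offsets:
        offsets = [0]
    votes: dict[tuple[str, int], list[int]] = {}
    for off in offsets:
        sub = query[off : off + _CHUNK]
        per_strand = {}
        for strand, q in (("+", sub), ("-", revcomp(sub))):
            res = edlib.align(q, target, task="locations", mode="HW")
            if res["editDistance"] >= 0:
                per_strand[strand] = res
        if not per_strand:
            continue
        best = min(r["editDistance"] for r in per_strand.values())
        if best > len(sub) * 0.35:  # chunk does not match the target at all
            continue
        for strand, res in per_strand.items():
            if res["editDistance"] != best:
                continue
            oriented_off = off if strand == "+" else n - off - len(sub)
            for loc_start, _loc_end in res["locations"][:4]:
                proj = (loc_start or 0) - oriented_off
                votes.setdefault((strand, round(proj / 150)), []).append(proj)
    clusters = sorted(
        votes.items(), key=lambda kv: (-len(kv[1]), kv[0][1], kv[0][0])
    )
    out = []
    seen: set[tuple[str, int]] = set()
    for (strand, _bucket), projs in clusters[:6]:
        proj = sorted(projs)[len(projs) // 2]
        key = (strand, round(proj / 300))
        if key in seen:
            continue
        seen.add(key)
        out.append((strand, proj))
    return out


def chunked_placements(
    query: str, target: str, margin: int = 150
) -> list[LocalAlignment]:
    """All distinct placements of a (possibly long/partial/repeated) query.

    Chunk voting proposes candidate windows; each window is refined with a
    geometry-matched slice alignment (so an overhang cannot smear the
    global path).  Placements nested inside a better placement on the
    target are dropped.
    """
    n = len(query)
    t_len = len(target)
    found: list[LocalAlignment] = []
    for strand, proj in _candidate_windows(query, target):
        t_lo = max(0, proj - margin)
        t_hi = min(t_len, proj + n + margin)
        # at a clipped boundary keep the query surplus small: a long junk
        # overhang lets the edit-distance path smear it as mismatches
        # across the real alignment instead of paying for a gap run
        q_lo = max(0, t_lo - proj - (30 if t_lo == 0 else 0))
        q_hi = min(n, t_hi - proj + (30 if t_hi == t_len else 0))
        if t_hi - t_lo < 50 or q_hi - q_lo < 50:
            continue
        oriented = query if strand == "+" else revcomp(query)
        aln = align_local(
            oriented[q_lo:q_hi],
            target[t_lo:t_hi],
            strand=strand,
            t_offset=t_lo,
            q_offset=q_lo,
        )
        if aln is not None:
            found.append(aln)
    found.sort(key=lambda a: (-a.matches, a.t_start, a.strand))
    chosen: list[LocalAlignment] = []
    for aln in found:
        nested = any(
            min(aln.t_end, c.t_end) - max(aln.t_start, c.t_start)
            > 0.5 * (aln.t_end - aln.t_start)
            for c in chosen
        )
        if not nested:
            chosen.append(aln)
    return chosen


def _cluster_locations(
    locations: list[tuple[int, int]], qlen: int
) -> list[tuple[int, int]]:
    """Collapse near-identical best locations; keep one per distinct site."""
    out: list[tuple[int, int]] = []
    for start, end in sorted((s if s is not None else 0, e) for s, e in locations):
        if out and abs(start - out[-1][0]) < max(qlen // 2, 20):
            continue
        out.append((start, end))
    return out
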