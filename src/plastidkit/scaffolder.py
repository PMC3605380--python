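"""Two-overlapping-reference scaffolding of chloroplast contigs.

Short-read assembly collapses the two inverted-repeat copies of a plastome
into a single contig, so a single linear reference cannot order both IRs.
The trick: split a (possibly distant) reference into two overlapping
halves — half A from base 1 across IRb into the SSC, half B from just
inside IRb to the end of IRa — place contigs on each half independently
(an IR contig places on both), build a vote-majority consensus per half
from contig bases only, and merge the halves across their overlap.  The
merged consensus is annotated by de-novo inverted-repeat detection.

Coordinates are 1-based inclusive throughout; the reference never
contributes bases to the consensus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import align
from .assembler import Contig
from .genome import QuadripartiteGenome, Region, RegionAnnotation, revcomp


class StructuralError(RuntimeError):
    """Raised when the scaffolding geometry cannot be established."""


@dataclass(frozen=True)
class ScaffoldPair:
    """Two overlapping reference halves with their source intervals."""

    ref_a: str
    ref_a_interval: tuple[int, int]
    ref_b: str
    ref_b_interval: tuple[int, int]
    irb_interval: tuple[int, int]

    @property
    def overlap_len(self) -> int:
        return self.ref_a_interval[1] - self.ref_b_interval[0] + 1


@dataclass(frozen=True)
class Placement:
    contig_id: str
    scaffold: str  # 'A' or 'B'
    ref_start: int  # 1-based inclusive on the scaffold half
    ref_end: int
    strand: str
    identity: float
    in_ir: bool
    clipped_left: int
    clipped_right: int
    aligned_seq: str = ""  # oriented contig segment that aligned
    cigar: tuple[tuple[int, str], ...] = ()  # path of aligned_seq vs the half

    @property
    def junction_candidate(self) -> bool:
        """Terminal clipping suggests the contig spans past the half's end."""
        return self.clipped_left > 20 or self.clipped_right > 20


@dataclass
class ConsensusGenome:
    sequence: str
    annotation: RegionAnnotation
    gap_flags: list[int] = field(default_factory=list)
    ambiguous_positions: list[int] = field(default_factory=list)
    ir_mismatches: int = 0


def split_reference(
    reference: QuadripartiteGenome | tuple[str, RegionAnnotation],
    ssc_overhang: int = 3000,
    overlap: int = 3000,
) -> ScaffoldPair:
    """Split a reference into two overlapping halves around IRb.

    Half A = bases 1 .. IRb_end + ``ssc_overhang`` (into the SSC); half B =
    bases IRb_end - ``overlap`` + 1 .. end (through SSC and all of IRa).
    """
    if isinstance(reference, QuadripartiteGenome):
        seq = reference.sequence
        irb = reference.regions["IRb"]
        irb_start, irb_end = irb.start, irb.end
    else:
        seq, annotation = reference
        if annotation.empty:
            raise StructuralError("reference has no detectable inverted repeat")
        irb_start, irb_end = annotation.irb.start, annotation.irb.end
    ir_len = irb_end - irb_start + 1
    if not (0 < overlap < ir_len):
        raise ValueError(f"overlap must be in (0, IR length={ir_len})")
    if ssc_overhang < 0:
        raise ValueError("ssc_overhang must be >= 0")
    a_end = min(irb_end + ssc_overhang, len(seq))
    b_start = irb_end - overlap + 1
    return ScaffoldPair(
        ref_a=seq[:a_end],
        ref_a_interval=(1, a_end),
        ref_b=seq[b_start - 1 :],
        ref_b_interval=(b_start, len(seq)),
        irb_interval=(irb_start, irb_end),
    )


def place_contigs(
    contigs: list[Contig],
    scaffolds: ScaffoldPair,
    min_identity: float = 0.7,
) -> list[Placement]:
    """Place each contig on each scaffold half by gapped alignment.

    A contig overlapping the IR may legitimately place on both halves (it
    serves as both IR copies) and may place twice on one half (e.g. the
    IRb remnant and IRa of half B).  Placements below ``min_identity`` or
    shorter than 100 aligned bases are dropped; a StructuralError is
    raised only if nothing places at all.
    """
    placements: list[Placement] = []
    halves = (("A", scaffolds.ref_a), ("B", scaffolds.ref_b))
    for contig in contigs:
        n = len(contig.sequence)
        for half_name, half_seq in halves:
            chosen = [
                aln
                for aln in align.chunked_placements(contig.sequence, half_seq)
                if aln.identity >= min_identity
                and aln.aligned_query_len >= min(n, 100)
            ]
            for aln in chosen:
                placements.append(
                    Placement(
                        contig_id=contig.id,
                        scaffold=half_name,
                        ref_start=aln.t_start + 1,
                        ref_end=aln.t_end,
                        strand=aln.strand,
                        identity=round(aln.identity, 4),
                        in_ir=_overlaps_ir(aln, half_name, scaffolds),
                        clipped_left=aln.q_start,
                        clipped_right=n - aln.q_end,
                        aligned_seq=_oriented_segment(contig.sequence, aln),
                        cigar=tuple(aln.cigar),
                    )
                )
    if contigs and not placements:
        raise StructuralError(
            "no contig placed on either scaffold half "
            f"(n_contigs={len(contigs)}, min_identity={min_identity})"
        )
    placements.sort(key=lambda p: (p.scaffold, p.ref_start, p.contig_id))
    return placements


def _oriented_segment(seq: str, aln: align.LocalAlignment) -> str:
    oriented = seq if aln.strand == "+" else revcomp(seq)
    return oriented[aln.q_start : aln.q_end]


def _overlaps_ir(aln: align.LocalAlignment, half: str, scaffolds: ScaffoldPair) -> bool:
    irb_start, irb_end = scaffolds.irb_interval
    if half == "A":
        ir_lo, ir_hi = irb_start, irb_end
    else:
        # in half-B coordinates, the IRb remnant occupies the first overlap_len bases
        b_start = scaffolds.ref_b_interval[0]
        ir_lo, ir_hi = irb_start - b_start + 1, irb_end - b_start + 1
    return aln.t_start + 1 <= ir_hi and aln.t_end >= max(ir_lo, 1)


@dataclass
class _HalfConsensus:
    sequence: str
    gap_flags: list[int]
    ambiguous: list[int]


def consensus_and_merge(
    placements: list[Placement],
    contigs: list[Contig],
    scaffolds: ScaffoldPair,
    min_merge_identity: float = 0.9,
    min_ir_len: int = 200,
) -> ConsensusGenome:
    """Build per-half vote-majority consensi and merge them into one genome.

    Each half is assembled in contig space: placements are laid out in
    reference order, successive contigs are spliced at their mutual
    overlap, and every placed contig casts per-column votes on the growing
    consensus; the final sequence is the column-majority rebuild (the
    reference itself never votes).  The merge aligns the start of half B's
    consensus against the tail of half A's; the junction point replaces
    duplicated sequence so each base of the overlap appears once.  The
    merged sequence is annotated by :func:`detect_ir`.
    """
    by_half: dict[str, list[Placement]] = {"A": [], "B": []}
    for p in placements:
        by_half[p.scaffold].append(p)
    if not by_half["A"] or not by_half["B"]:
        raise StructuralError("need at least one placement on each scaffold half")
    cons = {}
    for half in ("A", "B"):
        ps = sorted(by_half[half], key=lambda p: (p.ref_start, -p.ref_end, p.contig_id))
        cons[half] = _stitch_half(
            ps, {c.id: c.sequence for c in contigs}, min_merge_identity
        )
    merged, cut_gap = _merge_halves(
        cons["A"].sequence, cons["B"].sequence, scaffolds, min_merge_identity
    )
    merged, shift = _circular_close(merged, placements, contigs, scaffolds)
    annotation = detect_ir(merged, min_ir_len=min_ir_len)
    if not annotation.empty and annotation.ira.end < len(merged):
        # canonical linearization ends at IRa: bases past the IRa end are
        # the (circular) start of the LSC and rotate to the front
        extra = len(merged) - annotation.ira.end
        merged = merged[annotation.ira.end :] + merged[: annotation.ira.end]
        shift += extra
        annotation = detect_ir(merged, min_ir_len=min_ir_len)
    gap_flags = [g + shift for g in cons["A"].gap_flags] + [
        g + cut_gap + shift for g in cons["B"].gap_flags
    ]
    ambiguous = [a + shift for a in cons["A"].ambiguous] + [
        a + cut_gap + shift for a in cons["B"].ambiguous
    ]
    ir_mismatches = 0
    if not annotation.empty:
        irb = merged[annotation.irb.start - 1 : annotation.irb.end]
        ira = merged[annotation.ira.start - 1 : annotation.ira.end]
        ir_mismatches = sum(1 for a, b in zip(irb, revcomp(ira)) if a != b)
    return ConsensusGenome(
        sequence=merged,
        annotation=annotation,
        gap_flags=sorted(set(gap_flags)),
        ambiguous_positions=sorted(set(ambiguous)),
        ir_mismatches=ir_mismatches,
    )


def _stitch_half(
    placements: list[Placement],
    contig_seqs: dict[str, str],
    min_overlap_identity: float = 0.9,
) -> _HalfConsensus:
    """Contig-space consensus of one scaffold half.

    The reference only orders and orients the placements; splicing works
    on the full oriented contigs, because a terminal stretch that failed
    to align against the distant reference (and was clipped from the
    placement) is still genuine contig sequence shared with the
    neighbouring contig.  The consensus grows append-only: each next
    contig is anchored at its overlap with the current consensus and
    contributes (a) per-column votes over the overlap and (b) its
    non-overlapping remainder.  When two contigs share no column (the
    anchor fails or the reference says they are disjoint) they are
    concatenated and the position recorded as a zero-length gap.  Finally
    each column is rebuilt by vote majority (ties: lexicographically
    smallest base, position logged as ambiguous; a '-' majority drops the
    column; majority insertions are spliced in).
    """
    consensus: list[str] = []
    votes: list[Counter] = []
    ins_votes: dict[int, list[str]] = {}
    gap_flags: list[int] = []
    prev_ref_end: int | None = None
    # the unaligned tail of the contig currently forming the consensus end;
    # accepted only as far as the next contig's splice confirms it
    pending = ""

    def _append(seg: str) -> None:
        for ch in seg:
            consensus.append(ch)
            votes.append(Counter({ch: 1}))

    def _vote_walk(aln: align.LocalAlignment, seg: str, z: int) -> None:
        col = z + aln.t_start
        qpos = aln.q_start
        for nn, op in aln.cigar:
            if op in "=X":
                for _ in range(nn):
                    if col < len(votes):
                        votes[col][seg[qpos]] += 1
                    col += 1
                    qpos += 1
            elif op == "D":
                for _ in range(nn):
                    if col < len(votes):
                        votes[col]["-"] += 1
                    col += 1
            elif op == "I":
                ins_votes.setdefault(col - 1, []).append(seg[qpos : qpos + nn])
                qpos += nn

    for p in placements:
        oriented = contig_seqs[p.contig_id]
        if p.strand == "-":
            oriented = revcomp(oriented)
        # the full contig, minus the left clip only: the left clip of a
        # *later* placement is real preceding sequence and participates in
        # the splice; trailing clipped sequence is appended too (it is
        # genuine contig sequence continuing past the reference window) --
        # except at the genome end, where it wraps the circular origin and
        # would duplicate the consensus start
        # unaligned tails are never appended: a junction-hopping unitig may
        # continue through the other inverted-repeat context, and interior
        # junction flanks are recovered from the next contig's left clip
        right_cut = len(oriented) - p.clipped_right
        seg = oriented[p.clipped_left : right_cut]
        full = oriented[:right_cut]
        if not seg:
            continue
        tail_drop = oriented[right_cut : right_cut + 150]
        if not consensus:
            _append(seg)
            pending = tail_drop
            prev_ref_end = p.ref_end
            continue
        o_ref = (prev_ref_end or 0) - p.ref_start + 1
        # the left clip joins the splice only for an interior placement: at
        # the reference start it is origin-wrap sequence, not a junction
        # flank, and would pollute the consensus head with votes
        use_clip = p.ref_start > 5 and p.clipped_left <= 150
        lead = full if use_clip else seg
        # contig-space overlap may exceed the reference-projected overlap by
        # the clipped flanks on either side of the junction
        ov = min(
            max(o_ref, 0) + (p.clipped_left if use_clip else 0) + 80,
            len(lead),
            len(consensus),
        )
        spliced = False
        # 1) exact suffix-prefix splice (always holds for agreeing contigs);
        # the previous contig's pending tail is accepted as far as the
        # incoming contig's prefix confirms the resulting junction
        kmax = min(len(lead), ov + len(pending), len(consensus) + len(pending))
        if 0 < kmax <= 700:
            base_tail = "".join(consensus[len(consensus) - min(kmax, len(consensus)) :])
            for j in range(len(pending), -1, -1):
                cj = base_tail + pending[:j]
                hit = 0
                for k in range(min(kmax, len(cj)), 7, -1):
                    if cj.endswith(lead[:k]):
                        hit = k
                        break
                if hit:
                    _append(pending[:j])
                    for i in range(hit):
                        votes[len(consensus) - hit + i][lead[i]] += 1
                    _append(lead[hit:])
                    pending = tail_drop
                    spliced = True
                    break
        # 2) alignment-based splice (overlaps with conflicts, deep overlaps)
        if not spliced and o_ref > -5:
            head = lead[: min(len(lead), ov + 30)]
            w = min(len(consensus), ov + 150)
            tail = "".join(consensus[len(consensus) - w :])
            anchor = align.align_local(head, tail, mode="HW")
            if (
                anchor is not None
                and anchor.identity >= min_overlap_identity
                and anchor.q_start <= (p.clipped_left if use_clip else 0) + 5
                and anchor.aligned_query_len >= 20
            ):
                z = max(0, len(consensus) - w + anchor.t_start - anchor.q_start)
                rem = len(consensus) - z
                q_hi = min(len(lead), rem + 10)
                cur = "".join(consensus[z:])
                aln = align.align_local(lead[:q_hi], cur)
                if aln is not None and aln.identity >= min_overlap_identity:
                    _vote_walk(aln, lead, z)
                    if len(cur) - aln.t_end <= 2:  # p continues past the end
                        o_q = aln.q_end + (len(cur) - aln.t_end)
                        if o_q < len(lead):
                            _append(lead[o_q:])
                            pending = tail_drop
                    spliced = True
        if not spliced:
            if o_ref > 20:
                # the reference says this placement overlaps what is already
                # assembled; failing to splice means the placement (not the
                # consensus) is suspect, so drop it rather than duplicate
                continue
            gap_flags.append(len(consensus))
            _append(seg)
            pending = tail_drop
        prev_ref_end = max(prev_ref_end or 0, p.ref_end)

    out: list[str] = []
    ambiguous: list[int] = []
    for col, counter in enumerate(votes):
        top = max(counter.values())
        winners = sorted(b for b, v in counter.items() if v == top)
        if len(winners) > 1:
            ambiguous.append(len(out) + 1)
        if winners[0] != "-":
            out.append(winners[0])
        ins = ins_votes.get(col)
        if ins:
            ic = Counter(ins)
            ic[""] += sum(counter.values()) - len(ins)
            top_i = max(ic.values())
            iwinners = sorted(s for s, v in ic.items() if v == top_i)
            if "" not in iwinners and iwinners[0]:
                out.append(iwinners[0])
    return _HalfConsensus("".join(out), gap_flags, ambiguous)


def _circular_close(
    merged: str,
    placements: list[Placement],
    contigs: list[Contig],
    scaffolds: ScaffoldPair,
) -> tuple[str, int]:
    """Patch the circular origin using the contig that spans it.

    The plastome is circular but the consensus is linearized at LSC base 1,
    so the contig holding the LSC start also carries, as a clipped prefix,
    the tail of IRa — the sequence on the far side of the origin.  The
    contig is anchored on both sides of the origin with exact 32-mer
    matches (edit-distance paths smear across junk and cannot be trusted
    here) and its own bases replace the junction stretch, repairing
    whatever the reference-guided trims lost at the linearization point.
    When the anchors cannot be placed the consensus is left unchanged.
    Returns (sequence, position shift of former head bases).
    """
    cand = [p for p in placements if p.scaffold == "A"]
    if not cand:
        return merged, 0
    seqs = {c.id: c.sequence for c in contigs}
    p = min(cand, key=lambda q: (q.ref_start, -q.clipped_left))
    if p.clipped_left < 1:
        return merged, 0
    oriented = seqs[p.contig_id] if p.strand == "+" else revcomp(seqs[p.contig_id])
    clip = p.clipped_left
    span = 400
    q = oriented[: min(len(oriented), clip + span)]
    if len(q) <= clip + 40:
        return merged, 0
    w = min(len(merged) // 2, clip + span)
    head_len = min(span + 100, len(merged) - w)

    # head anchor: q's last 32 bases must occur in the consensus head
    word = q[-32:]
    j = merged.find(word, 0, head_len + 32)
    if j < 0:
        return merged, 0
    j2 = j + 32  # q ends at merged position j2

    # tail anchor: q's junk prefix (IRa tail) must occur near the consensus
    # end; for very short prefixes fall back to a direct suffix comparison
    if clip >= 8:
        m = min(32, clip)
        a1 = merged.rfind(q[:m], len(merged) - w)
        if a1 < 0:
            return merged, 0
    else:
        if merged.endswith(q[:clip]):
            a1 = len(merged) - clip
        else:
            a1 = len(merged)  # tail bases genuinely missing; append them
    if a1 <= j2:
        return merged, 0
    new_head = q[clip:]
    merged2 = new_head + merged[j2:a1] + q[:clip]
    shift = len(new_head) - j2
    return merged2, shift


def _merge_halves(
    cons_a: str, cons_b: str, scaffolds: ScaffoldPair, min_identity: float
) -> tuple[str, int]:
    """Splice half-B consensus onto half-A across their shared overlap.

    Returns (merged sequence, consensus position where half B was cut in).
    """
    if not cons_a or not cons_b:
        raise StructuralError("empty half consensus")
    # half B's head (IRb remnant + SSC context) occurs exactly once in half
    # A; a long anchor at high identity fixes the junction unambiguously
    head = cons_b[: min(len(cons_b), scaffolds.overlap_len + 250)]
    aln = align.chunked_placements(head, cons_a)
    usable = [
        a
        for a in aln
        if a.strand == "+"
        and a.identity >= min_identity
        and a.aligned_query_len >= min(100, int(0.5 * len(head)))
        and a.q_start <= 20  # the head must anchor at half B's first column
    ]
    if not usable:
        raise StructuralError(
            "half consensi fail to overlap-align at required identity"
        )
    usable.sort(key=lambda a: -a.matches)
    a0 = usable[0]
    # position in cons_a where cons_b's aligned head starts
    cut_a = a0.t_start - a0.q_start
    merged = cons_a[:cut_a] + cons_b
    return merged, cut_a


def detect_ir(sequence: str, min_ir_len: int = 200) -> RegionAnnotation:
    """Detect the maximal inverted-repeat pair in a linear sequence.

    Finds disjoint intervals (I1 before I2) with seq[I2] equal to the
    reverse complement of seq[I1]), length >= ``min_ir_len``, by seeding on
    shared words with the reverse complement and maximal ungapped
    extension.  The longer inter-IR region is labelled LSC, the shorter
    SSC; four junction coordinates are derived (the IRa/LSC junction wraps
    to base 1).  Returns an empty annotation when nothing qualifies.
    """
    n = len(sequence)
    if n <= 2 * min_ir_len:
        return RegionAnnotation()
    w = max(8, min(min_ir_len, 24))
    rc = revcomp(sequence)
    index: dict[str, list[int]] = {}
    for i in range(n - w + 1):
        index.setdefault(rc[i : i + w], []).append(i)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    best: tuple[int, int, int] | None = None  # (length, a_start, b_start)
    seen: dict[int, list[tuple[int, int]]] = {}
    for i in range(n - w + 1):
        for j_rc in index.get(sequence[i : i + w], ()):
            b_start = n - j_rc - w  # rc position mapped to forward coords
            d = i + (b_start + w - 1)  # anti-diagonal, invariant under extension
            if any(lo <= i <= hi for lo, hi in seen.get(d, ())):
                continue
            a1, a2 = i, i + w - 1  # inclusive
            b1, b2 = b_start, b_start + w - 1
            while a1 > 0 and b2 < n - 1 and sequence[a1 - 1] == comp[sequence[b2 + 1]]:
                a1 -= 1
                b2 += 1
            while a2 + 1 < n and b1 > 0 and sequence[a2 + 1] == comp[sequence[b1 - 1]]:
                a2 += 1
                b1 -= 1
            seen.setdefault(d, []).append((a1, a2))
            if a1 >= b1:  # canonical order: first interval before second
                continue
            if a2 >= b1:  # overlapping intervals cannot be the two IR copies
                continue
            length = a2 - a1 + 1
            if length >= min_ir_len and (
                best is None
                or length > best[0]
                or (length == best[0] and a1 < best[1])
            ):
                best = (length, a1, b1)
    if best is None:
        return RegionAnnotation()
    length, a1, b1 = best
    irb = Region("IRb", a1 + 1, a1 + length)
    ira = Region("IRa", b1 + 1, b1 + length)
    between = (irb.end + 1, ira.start - 1)
    outer_len = (irb.start - 1) + (n - ira.end)
    between_len = between[1] - between[0] + 1
    if outer_len >= between_len:
        lsc = Region("LSC", 1, irb.start - 1) if irb.start > 1 else None
        ssc = Region("SSC", between[0], between[1]) if between_len > 0 else None
    else:
        lsc = Region("LSC", between[0], between[1])
        ssc = Region("SSC", 1, irb.start - 1) if irb.start > 1 else None
    junctions = {
        "J(LSC,IRb)": (irb.start - 1, irb.start),
        "J(IRb,SSC)": (irb.end, irb.end + 1),
        "J(SSC,IRa)": (ira.start - 1, ira.start),
        "J(IRa,LSC)": (ira.end, 1 if ira.end == n else ira.end + 1),
    }
    return RegionAnnotation(irb=irb, ira=ira, lsc=lsc, ssc=ssc, junctions=junctions)


def placements_table(placements: list[Placement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": p.contig_id,
                "scaffold": p.scaffold,
                "ref_start": p.ref_start,
                "ref_end": p.ref_end,
                "strand": p.strand,
                "identity": p.identity,
                "in_ir": p.in_ir,
                "clipped_left": p.clipped_left,
                "clipped_right": p.clipped_right,
            }
            for p in placements
        ],
        columns=[
            "contig_id", "scaffold", "ref_start", "ref_end", "strand",
            "identity", "in_ir", "clipped_left", "clipped_right",
        ],
    )
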