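"""Read preparation: quality trimming, length filtering, subsampling.

Trimming uses the modified-Mott running-sum algorithm: each base scores
``p_limit − p_err(base)`` and the retained read is the contiguous segment
with maximal score sum.  The quality limit (an error probability, default
0.05) is snapped to its integer Phred equivalent (13), so bases at exactly
that quality score zero rather than infinitesimally negative; an all-Q13
read is therefore retained in full.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import max_sum_segment
from .synthsim import ReadRecord


@dataclass(frozen=True)
class TrimConfig:
    quality_limit: float = 0.05
    min_len: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.quality_limit < 1):
            raise ValueError("quality_limit must be in (0, 1)")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class ReadStats:
    n_reads: int
    mean_len: float
    mean_phred: float


def phred_from_prob(p: float) -> int:
    """Integer Phred score for an error probability: floor(−10·log10 p).

    The 0.05 quality limit maps to Phred 13.
    """
    if not (0 < p <= 1):
        raise ValueError("error probability must be in (0, 1]")
    return math.floor(-10 * math.log10(p))


def prob_from_phred(q: int) -> float:
    return 10 ** (-q / 10)


def trim_read(read: ReadRecord, config: TrimConfig = TrimConfig()) -> ReadRecord | None:
    """Running-sum quality trim; returns None when the read is rejected."""
    if len(read.seq) != len(read.qual):
        raise ValueError(f"read {read.id}: sequence/quality length mismatch")
    p_limit = prob_from_phred(phred_from_prob(config.quality_limit))
    scores = [p_limit - prob_from_phred(ord(c) - 33) for c in read.qual]
    start, end, _ = max_sum_segment(scores)
    if end - start < config.min_len:
        return None
    return ReadRecord(read.id, read.seq[start:end], read.qual[start:end])


def trim_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]], config: TrimConfig = TrimConfig()
) -> list[tuple[ReadRecord, ReadRecord]]:
    """Trim both mates; a pair is kept only when both mates survive."""
    out = []
    for r1, r2 in pairs:
        t1, t2 = trim_read(r1, config), trim_read(r2, config)
        if t1 is not None and t2 is not None:
            out.append((t1, t2))
    return out


def subsample_every_nth(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]], n: int
) -> list[tuple[ReadRecord, ReadRecord]]:
    """Deterministic every-nth subsampling of pairs (indices 0, n, 2n, ...).

    Keeping 1/n of the pairs scales coverage by 1/n without any RNG, which is
    how 50% / 25% / 12.5% datasets are derived from the full library.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return [p for i, p in enumerate(pairs) if i % n == 0]


def read_stats(reads: Iterable[ReadRecord]) -> ReadStats:
    n = 0
    total_len = 0
    total_q = 0
    for r in reads:
        n += 1
        total_len += len(r.seq)
        total_q += sum(ord(c) - 33 for c in r.qual)
    if n == 0:
        return ReadStats(0, 0.0, 0.0)
    return ReadStats(n, total_len / n, total_q / total_len if total_len else 0.0)
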