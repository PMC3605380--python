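"""Small shared numeric helpers."""

from __future__ import annotations

from typing import Sequence


def max_sum_segment(scores: Sequence[float]) -> tuple[int, int, float]:
    """Maximal-sum contiguous segment as (start, end_exclusive, sum).

    Ties on the sum break to the leftmost start, then the longest segment.
    The empty segment (sum 0) is a valid answer when all scores are
    negative.
    """
    best = (0.0, 0, 0)  # (sum, start, end)
    prefix = 0.0
    min_prefix, min_idx = 0.0, 0
    eps = 1e-12
    for j, s in enumerate(scores, start=1):
        prefix += s
        total = prefix - min_prefix
        b_sum, b_start, b_end = best
        if total > b_sum + eps or (
            abs(total - b_sum) <= eps
            and (min_idx < b_start or (min_idx == b_start and j > b_end))
        ):
            best = (total, min_idx, j)
        if prefix < min_prefix - eps:
            min_prefix, min_idx = prefix, j
    return best[1], best[2], best[0]
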