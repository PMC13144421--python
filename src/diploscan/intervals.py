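"""Interval arithmetic on 0-based half-open [start, end) tuples."""

from __future__ import annotations

from typing import Iterable


def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; touching intervals are coalesced."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge(intervals))


def overlap_bp(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> int:
    """Total bp of overlap between the unions of two interval sets."""
    ma, mb = merge(a), merge(b)
    i = j = 0
    bp = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if e > s:
            bp += e - s
        if ma[i][1] <= mb[j][1]:
            i += 1
        else:
            j += 1
    return bp


def gaps(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Gaps between consecutive merged intervals (introns from exons)."""
    ivs = merge(intervals)
    return [(ivs[k][1], ivs[k + 1][0]) for k in range(len(ivs) - 1) if ivs[k + 1][0] > ivs[k][1]]
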