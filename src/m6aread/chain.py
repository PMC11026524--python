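"""Decode ligated concatemer reads by local oligo matching and chaining.

Reference oligos are matched locally against each read, and compatible
matches are chained by weighted-interval-scheduling dynamic programming to
reconstruct the ligated unit order and locate every central A. The error
model upstream is substitution-only, so local matching is an exhaustive
ungapped diagonal scan (every read offset scored as match/mismatch against
the full oligo); adjacent chained hits may overlap by a small tolerance to
absorb boundary ambiguity at ligation junctions.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthetic import Oligo

__all__ = [
    "OligoHit",
    "Chain",
    "local_match",
    "chain_hits",
    "decode_read",
    "longest_continuous_segment",
]


@dataclass(frozen=True)
class OligoHit:
    """A local alignment of one reference oligo to a read (half-open coords)."""

    oligo_id: str
    read_start: int
    read_end: int
    score: float
    identity: float

    def __post_init__(self):
        if self.read_start >= self.read_end:
            raise ValueError("read_start must be < read_end")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


@dataclass(frozen=True)
class Chain:
    """Best-scoring set of mutually compatible hits on one read."""

    hits: tuple[OligoHit, ...]
    total_score: float
    central_a_positions: tuple[tuple[int, str], ...] = ()


def _library_items(oligo_library) -> list[tuple[str, str]]:
    if isinstance(oligo_library, Mapping):
        items = [
            (k, v.sequence if isinstance(v, Oligo) else str(v))
            for k, v in oligo_library.items()
        ]
    else:
        items = [(o.oligo_id, o.sequence) for o in oligo_library]
    if not items:
        raise ValueError("oligo library is empty")
    for oid, seq in items:
        if len(seq) < 10:
            raise ValueError(f"oligo {oid} is shorter than 10 nt")
    return items


def local_match(
    read_seq: str,
    oligo_library,
    min_identity: float = 0.8,
    match_score: float = 1.0,
    mismatch_score: float = -1.0,
) -> list[OligoHit]:
    """All full-length local matches of library oligos in a read.

    ``oligo_library`` may be a mapping ``oligo_id -> sequence`` (or
    :class:`~m6aread.synthetic.Oligo`) or an iterable of ``Oligo``. Every
    read offset at which an oligo aligns (ungapped) with identity at least
    ``min_identity`` yields a hit; overlapping near-duplicate hits are left
    for the chaining stage to arbitrate. Hits are sorted by read_start.
    """
    items = _library_items(oligo_library)
    read = np.frombuffer(read_seq.upper().encode(), dtype="S1")
    hits: list[OligoHit] = []
    for oid, seq in items:
        L = len(seq)
        if read.size < L:
            continue
        oligo = np.frombuffer(seq.encode(), dtype="S1")
        windows = np.lib.stride_tricks.sliding_window_view(read, L)
        matches = (windows == oligo).sum(axis=1)
        identity = matches / L
        score = matches * match_score + (L - matches) * mismatch_score
        for off in np.flatnonzero(identity >= min_identity):
            hits.append(
                OligoHit(
                    oligo_id=oid,
                    read_start=int(off),
                    read_end=int(off) + L,
                    score=float(score[off]),
                    identity=float(identity[off]),
                )
            )
    hits.sort(key=lambda h: (h.read_start, h.read_end, h.oligo_id))
    return hits


def chain_hits(
    hits: Sequence[OligoHit],
    overlap_tol: int = 2,
    oligo_library=None,
) -> Chain:
    """Maximum-total-score chain of mutually compatible hits.

    Two hits are compatible when the later one starts no earlier than
    ``overlap_tol`` nt before the earlier one ends. Solved by weighted
    interval scheduling over hits sorted by read_end; on equal totals the
    chain keeping the earlier-starting hit is preferred. If an
    ``oligo_library`` of :class:`Oligo` (or mapping to them) is supplied,
    each chained hit contributes its central A read offset and motif.
    """
    order = sorted(range(len(hits)), key=lambda i: (hits[i].read_end, hits[i].read_start))
    n = len(order)
    ends = [hits[i].read_end for i in order]
    best = [0.0] * (n + 1)
    take = [False] * (n + 1)
    pred = [0] * (n + 1)
    for j in range(1, n + 1):
        h = hits[order[j - 1]]
        # last hit (in end-sorted order) ending at or before start + tol
        p = bisect.bisect_right(ends, h.read_start + overlap_tol, 0, j - 1)
        with_j = h.score + best[p]
        if with_j > best[j - 1]:
            best[j], take[j], pred[j] = with_j, True, p
        else:
            best[j], take[j] = best[j - 1], False
    chosen: list[OligoHit] = []
    j = n
    while j > 0:
        if take[j]:
            chosen.append(hits[order[j - 1]])
            j = pred[j]
        else:
            j -= 1
    chosen.reverse()

    centrals: tuple[tuple[int, str], ...] = ()
    if oligo_library is not None:
        if isinstance(oligo_library, Mapping):
            by_id = {
                k: v for k, v in oligo_library.items() if isinstance(v, Oligo)
            }
        else:
            by_id = {o.oligo_id: o for o in oligo_library}
        out = []
        for h in chosen:
            o = by_id.get(h.oligo_id)
            if o is not None:
                out.append((h.read_start + o.central_offset, o.motif))
        centrals = tuple(out)
    return Chain(hits=tuple(chosen), total_score=best[n], central_a_positions=centrals)


def decode_read(
    read_seq: str,
    oligos: Sequence[Oligo],
    min_identity: float = 0.8,
    overlap_tol: int = 2,
) -> Chain:
    """Match and chain in one step, locating central A positions."""
    hits = local_match(read_seq, oligos, min_identity=min_identity)
    return chain_hits(hits, overlap_tol=overlap_tol, oligo_library=oligos)


def longest_continuous_segment(blocks: Sequence[tuple[int, int]]):
    """Longest contiguous aligned block of a (possibly fragmented) alignment.

    ``blocks`` are half-open (start, end) intervals; returns the longest
    one (leftmost on ties) or ``None`` for an unaligned read.
    """
    best = None
    best_len = -1
    for start, end in blocks:
        if end < start:
            raise ValueError("block end must be >= start")
        if end - start > best_len:
            best, best_len = (start, end), end - start
    return best
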