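"""Grain-unique segment mining over consensus sequences.

"Shared" between two consensus sequences is operationalised as exact
co-occurrence of a length-``w`` window (default w = 6, the shortest peptide
length consistently able to elicit antibodies that recognise the parent
protein). A consensus position is *shared* when at least one window
covering it occurs verbatim in the consensus of another grain; maximal
runs of unshared positions of at least ``min_len`` residues become
candidate segments. A final screen discards segments sharing a window with
off-target prolamins (maize zein, soy glycinin, rice) while keeping the
rejected rows as an audit trail.

Windows containing ambiguity letters never match anything, by design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .seq_io import AMBIGUOUS_RESIDUES


@dataclass(frozen=True)
class SegmentCandidate:
    """A grain-unique stretch of a consensus sequence.

    Coordinates are 0-based half-open on the ungapped consensus.
    ``status`` is ``"candidate"`` or ``"rejected"``; a rejected segment
    carries a machine-readable ``reject_reason``.
    """

    grain: str
    gpt_name: str
    start: int
    end: int
    sequence: str
    status: str = "candidate"
    reject_reason: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment coordinates [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("segment sequence length != end - start")
        if self.status == "candidate" and self.reject_reason:
            raise ValueError("candidate status with non-empty reject_reason")

    @property
    def length(self) -> int:
        return self.end - self.start


def _seq(obj) -> str:
    """Accept either a ConsensusSequence-like object or a plain string."""
    return obj.sequence if hasattr(obj, "sequence") else str(obj)


def mark_shared_positions(cs, others: Iterable, window: int = 6) -> np.ndarray:
    """Boolean mask over ``cs``: True where the position is shared.

    Position ``i`` is shared iff some window ``cs[j:j+w]`` with
    ``j <= i < j+w`` occurs as an exact substring of at least one member
    of ``others``. A window longer than the consensus matches nothing, so
    ``w > len(cs)`` yields an all-False mask, as does an empty ``others``.
    """
    if window < 1:
        raise ValueError(f"window={window}: must be >= 1")
    s = _seq(cs)
    w = window
    mask = np.zeros(len(s), dtype=bool)
    others = list(others)
    if w > len(s) or not others:
        return mask
    kmers: set[str] = set()
    for other in others:
        t = _seq(other)
        kmers.update(t[j:j + w] for j in range(len(t) - w + 1))
    # difference array: +1 at window start, -1 past window end, then prefix-sum
    coverage = np.zeros(len(s) + 1, dtype=np.int64)
    for j in range(len(s) - w + 1):
        win = s[j:j + w]
        if AMBIGUOUS_RESIDUES & set(win):
            continue
        if win in kmers:
            coverage[j] += 1
            coverage[j + w] -= 1
    return np.cumsum(coverage[:-1]) > 0


def extract_unshared_segments(cs, mask: Sequence[bool],
                              min_len: int = 6) -> list[SegmentCandidate]:
    """Maximal runs of unshared positions, kept iff run length >= min_len.

    Returned sorted by start; runs are non-overlapping by construction.
    """
    if min_len < 1:
        raise ValueError(f"min_len={min_len}: must be >= 1")
    s = _seq(cs)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(s),):
        raise ValueError(
            f"mask length {mask.shape} does not match consensus length {len(s)}")
    grain = getattr(cs, "grain", "")
    gpt = getattr(cs, "gpt_name", "")
    segments: list[SegmentCandidate] = []
    i = 0
    while i < len(s):
        if mask[i]:
            i += 1
            continue
        j = i
        while j < len(s) and not mask[j]:
            j += 1
        if j - i >= min_len:
            segments.append(SegmentCandidate(
                grain=grain, gpt_name=gpt, start=i, end=j, sequence=s[i:j]))
        i = j
    return segments


def screen_exclusion(segments: Sequence[SegmentCandidate], exclusion_set: Iterable,
                     window: int = 6) -> list[SegmentCandidate]:
    """Reject segments sharing a length-``window`` substring with the
    exclusion set (off-target prolamins); keep everything, in order, so the
    output doubles as an audit trail. Segments shorter than the window have
    no window to match and pass through.
    """
    if window < 1:
        raise ValueError(f"window={window}: must be >= 1")
    exclusion = [_seq(e) for e in exclusion_set]
    kmers: set[str] = set()
    for t in exclusion:
        kmers.update(t[j:j + window] for j in range(len(t) - window + 1))
    out: list[SegmentCandidate] = []
    for seg in segments:
        if seg.status != "candidate":
            out.append(seg)
            continue
        hit = any(
            seg.sequence[j:j + window] in kmers
            and not (AMBIGUOUS_RESIDUES & set(seg.sequence[j:j + window]))
            for j in range(len(seg.sequence) - window + 1)
        )
        if hit:
            out.append(replace(seg, status="rejected",
                               reject_reason="exclusion_shared"))
        else:
            out.append(seg)
    return out
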