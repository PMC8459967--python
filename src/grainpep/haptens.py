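"""Hydropathy scoring, filtering, ranking and synthesis preparation.

Surviving grain-unique segments are scored with the grand average of
hydropathy (GRAVY; Kyte–Doolittle scale, negative = hydrophilic) and the
longest single-residue run, then filtered: hydrophobic segments are
dropped (buried epitopes, poor conjugation in aqueous buffers), segments
with long homopolymeric runs are dropped (gluten's QQQ.../PPP... repeats
are shared motifs, poor discriminators), and segments longer than 20
residues are dropped (free peptides that long fold into conformations
unlike the parent protein). Survivors are ranked by occurrence in their
grain's consensus set, GPT abundance in gluten and length, and finally
receive synthesis annotations: an N-terminal cysteine is prepended when
the sequence has none (thiol handle for maleimide coupling to the carrier
protein) and the termini are acetylated/amidated (``Ac-...-NH2``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import AlphabetError
from .seq_io import AMBIGUOUS_RESIDUES, STANDARD_RESIDUES
from .uniqueness import SegmentCandidate

#: Kyte & Doolittle (1982) hydropathy values, one per standard residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: fixed rejection vocabulary, in the order the filters are applied
REJECT_REASONS = ("exclusion_shared", "hydrophobic", "repeat_run", "too_long")


def validate_scale(scale: Mapping[str, float]) -> None:
    if set(scale) != STANDARD_RESIDUES:
        missing = STANDARD_RESIDUES - set(scale)
        extra = set(scale) - STANDARD_RESIDUES
        raise ValueError(
            f"hydropathy scale must cover exactly the 20 standard residues "
            f"(missing {sorted(missing)}, extra {sorted(extra)})")
    for res, val in scale.items():
        v = float(val)
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError(f"scale[{res}] is not finite")


def load_scale(path) -> dict[str, float]:
    """Read a two-column (residue, value) TSV hydropathy scale."""
    scale: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, val = line.split("\t")
            scale[res.upper()] = float(val)
    validate_scale(scale)
    return scale


@dataclass(frozen=True)
class HaptenCandidate:
    """A scored grain-unique segment, ready for ranking/synthesis.

    ``occurrence`` counts (possibly overlapping) exact matches of the
    segment across its own grain's consensus set; ``gpt_abundance`` is the
    configured fraction of the GPT in the grain's gluten; ``rank_score``
    is the 1-based rank after ordering (None until ranked).
    """

    grain: str
    gpt_name: str
    start: int
    end: int
    sequence: str
    gravy: float
    max_run: int
    occurrence: int
    status: str = "candidate"
    reject_reason: str = ""
    gpt_abundance: float | None = None
    rank_score: int | None = None
    synthesis_sequence: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def gravy(sequence: str, scale: Mapping[str, float] | None = None,
          on_ambiguity: str = "error") -> float:
    """Grand average of hydropathy: mean per-residue scale value.

    Ambiguity letters have no defined hydropathy; the default policy is to
    raise, ``on_ambiguity="skip"`` averages over the standard residues only.
    """
    if scale is None:
        scale = KYTE_DOOLITTLE
    if on_ambiguity not in ("error", "skip"):
        raise ValueError(f"unknown on_ambiguity policy {on_ambiguity!r}")
    if not sequence:
        raise AlphabetError("GRAVY of an empty sequence is undefined")
    values: list[float] = []
    for res in sequence:
        if res in scale:
            values.append(scale[res])
        elif res in AMBIGUOUS_RESIDUES and on_ambiguity == "skip":
            continue
        else:
            raise AlphabetError(
                f"residue {res!r} has no hydropathy value (ambiguous or unknown)")
    if not values:
        raise AlphabetError(
            f"sequence {sequence!r} has no scorable residues after skipping")
    return sum(values) / len(values)


def max_residue_run(sequence: str) -> int:
    """Length of the longest run of one repeated residue."""
    if not sequence:
        raise ValueError("empty sequence has no residue run")
    best = run = 1
    for prev, cur in zip(sequence, sequence[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def count_occurrences(segment: str, grain_consensus_set: Iterable) -> int:
    """Overlapping exact occurrences of ``segment`` across a grain's consensus set."""
    if not segment:
        raise ValueError("empty segment")
    total = 0
    for cs in grain_consensus_set:
        hay = cs.sequence if hasattr(cs, "sequence") else str(cs)
        i = hay.find(segment)
        while i != -1:
            total += 1
            i = hay.find(segment, i + 1)
    return total


def annotate_candidates(segments: Sequence[SegmentCandidate],
                        grain_consensus_sets: Mapping[str, Sequence],
                        scale: Mapping[str, float] | None = None,
                        on_ambiguity: str = "error") -> list[HaptenCandidate]:
    """Attach GRAVY, max run and occurrence to mined segments.

    ``grain_consensus_sets`` maps grain label to that grain's consensus
    sequences (occurrence is counted within the segment's own grain).
    Rejection status from earlier stages is carried through.
    """
    out: list[HaptenCandidate] = []
    for seg in segments:
        out.append(HaptenCandidate(
            grain=seg.grain, gpt_name=seg.gpt_name, start=seg.start,
            end=seg.end, sequence=seg.sequence,
            gravy=gravy(seg.sequence, scale, on_ambiguity=on_ambiguity),
            max_run=max_residue_run(seg.sequence),
            occurrence=count_occurrences(
                seg.sequence, grain_consensus_sets.get(seg.grain, ())),
            status=seg.status, reject_reason=seg.reject_reason))
    return out


def filter_candidates(candidates: Sequence[HaptenCandidate],
                      gravy_threshold: float = 0.0, max_run: int = 3,
                      max_len: int = 20) -> list[HaptenCandidate]:
    """Apply the hydropathy / repeat / length filters, preserving rejects.

    A candidate is rejected with the FIRST applicable reason, in fixed
    order: "hydrophobic" (GRAVY >= threshold), "repeat_run" (longest run
    exceeds the limit), "too_long" (length > max_len). Already-rejected
    entries pass through untouched; every input row appears in the output.
    """
    out: list[HaptenCandidate] = []
    for c in candidates:
        if c.status != "candidate":
            out.append(c)
        elif c.gravy >= gravy_threshold:
            out.append(replace(c, status="rejected", reject_reason="hydrophobic"))
        elif c.max_run > max_run:
            out.append(replace(c, status="rejected", reject_reason="repeat_run"))
        elif c.length > max_len:
            out.append(replace(c, status="rejected", reject_reason="too_long"))
        else:
            out.append(c)
    return out


def rank_candidates(candidates: Sequence[HaptenCandidate],
                    gpt_abundance: Mapping[str, float],
                    preferred_min_len: int = 9) -> list[HaptenCandidate]:
    """Total deterministic ordering of surviving candidates.

    Lexicographic key: length >= preferred_min_len (prioritised), then
    occurrence, GPT abundance and length (all descending), with ascending
    sequence as the final tiebreak. ``rank_score`` is the 1-based rank.
    """
    for c in candidates:
        if c.status != "candidate":
            raise ValueError(
                f"rank_candidates received a rejected segment "
                f"{c.grain}/{c.gpt_name}[{c.start}:{c.end}]")
        if c.gpt_name not in gpt_abundance:
            raise KeyError(
                f"no gpt_abundance entry for GPT {c.gpt_name!r}")
    ordered = sorted(
        candidates,
        key=lambda c: (
            -(c.length >= preferred_min_len),
            -c.occurrence,
            -gpt_abundance[c.gpt_name],
            -c.length,
            c.sequence,
        ))
    return [
        replace(c, rank_score=i + 1, gpt_abundance=gpt_abundance[c.gpt_name],
                synthesis_sequence=prepare_synthesis(c.sequence))
        for i, c in enumerate(ordered)
    ]


def prepare_synthesis(sequence: str) -> str:
    """Synthesis string: optional N-terminal Cys, acetylated/amidated termini.

    The cysteine is prepended only when the sequence contains none,
    providing the thiol for maleimide click-coupling to the carrier.
    """
    if not sequence:
        raise ValueError("cannot prepare synthesis string for empty sequence")
    core = sequence if "C" in sequence else "C" + sequence
    return f"Ac-{core}-NH2"
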