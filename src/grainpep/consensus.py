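"""Consensus sequence construction from a multiple sequence alignment.

The consensus sequence (CS) of a gluten protein type is the compiled
sequence of the most common amino acid at each alignment column. Columns
where the gap is the modal symbol are dropped so the CS is an ungapped
residue string ready for peptide mining; per-position support (modal votes
over total sequences) and the originating alignment column are retained.

Tie handling is deterministic: a residue beats the gap on equal counts,
and ties among residues go to the alphabetically first one. Ambiguity
letters (X/B/Z/U/O) abstain from the vote — they can never win a column —
but still count in the denominator, so heavily ambiguous columns show low
support rather than fabricated certainty.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import EmptyConsensusError
from .seq_io import AMBIGUOUS_RESIDUES, GAP, ProteinFamily


@dataclass(frozen=True)
class ConsensusSequence:
    """Per-GPT modal sequence with per-position support.

    ``support[i]`` is the fraction of family sequences voting for
    ``sequence[i]``; ``source_columns[i]`` is the alignment column the
    position came from (strictly increasing).
    """

    grain: str
    gpt_name: str
    sequence: str
    support: tuple[float, ...]
    source_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.support) == len(self.source_columns) == n):
            raise ValueError("consensus field lengths disagree")
        if GAP in self.sequence:
            raise ValueError("consensus sequence contains a gap character")
        if any(not 0.0 < s <= 1.0 for s in self.support):
            raise ValueError("support values must lie in (0, 1]")
        if any(b <= a for a, b in zip(self.source_columns, self.source_columns[1:])):
            raise ValueError("source_columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)


def build_consensus(family: ProteinFamily, gap_rule: str = "majority") -> ConsensusSequence:
    """Compute the modal consensus of one aligned family.

    ``gap_rule="majority"`` (default): the gap competes in the vote and a
    gap-majority column is dropped from the consensus. ``gap_rule="ignore"``:
    gaps are excluded from the vote and a column is dropped only when no
    residue votes at all. Support is always relative to the full family
    size, so the two rules are comparable.
    """
    if gap_rule not in ("majority", "ignore"):
        raise ValueError(f"unknown gap_rule {gap_rule!r}")
    n = family.n_sequences
    residues: list[str] = []
    support: list[float] = []
    columns: list[int] = []
    for col in range(family.alignment_length):
        counts = Counter(seq[col] for seq in family.aligned_sequences)
        gap_votes = counts.pop(GAP, 0)
        for amb in AMBIGUOUS_RESIDUES:
            counts.pop(amb, None)  # abstain: never win, still in denominator
        if not counts:
            continue  # no residue votes at all
        # alphabetically-first max-count residue; residue beats gap on a tie
        best = min(sorted(counts), key=lambda r: (-counts[r], r))
        if gap_rule == "majority" and gap_votes > counts[best]:
            continue
        residues.append(best)
        support.append(counts[best] / n)
        columns.append(col)
    if not residues:
        raise EmptyConsensusError(
            f"family {family.grain}/{family.gpt_name}: every column is "
            f"gap-majority; consensus is empty")
    return ConsensusSequence(
        grain=family.grain, gpt_name=family.gpt_name,
        sequence="".join(residues), support=tuple(support),
        source_columns=tuple(columns))
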