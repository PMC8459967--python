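"""Input/output for the formats the pipeline touches.

Alignments arrive as aligned FASTA or Clustal (one file per gluten protein
type, GPT); candidate peptides leave as a tab-separated table; ELISA plate
data arrive as long-format TSV (serum, antigen, reciprocal dilution, OD)
plus a one-column blank table; run parameters come from a YAML config.

Conventions used throughout the package:

* residues are upper-case one-letter codes over the 20 standard amino acids;
* ``-`` is the gap character (``.`` is accepted on input and normalised);
* the ambiguity/nonstandard letters ``X B Z U O`` are accepted at parse time
  but flagged — they abstain from consensus votes, never match a shared
  window and poison GRAVY unless explicitly skipped;
* all coordinates are 0-based, half-open, on the ungapped consensus string.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

from .errors import AlignmentFormatError, AlphabetError, ConfigError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_RESIDUES = frozenset("XBZUO")
GAP = "-"

_FORMAT_MAP = {"aligned-fasta": "fasta", "clustal": "clustal"}

_CANDIDATE_COLUMNS = (
    "grain", "gpt", "start", "end", "sequence", "length", "gravy",
    "max_run", "occurrence", "rank_score", "synthesis_sequence",
    "status", "reject_reason",
)


@dataclass(frozen=True)
class ProteinFamily:
    """One GPT's aligned sequences for one grain.

    All sequences share the alignment length; ids are unique within the
    family. Validation happens at construction so downstream code can rely
    on the invariants.
    """

    grain: str
    gpt_name: str
    aligned_sequences: tuple[str, ...]
    sequence_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "aligned_sequences", tuple(self.aligned_sequences))
        object.__setattr__(self, "sequence_ids", tuple(self.sequence_ids))
        if not self.aligned_sequences:
            raise AlignmentFormatError(
                f"family {self.grain}/{self.gpt_name}: no sequences")
        if len(self.aligned_sequences) != len(self.sequence_ids):
            raise AlignmentFormatError(
                f"family {self.grain}/{self.gpt_name}: "
                f"{len(self.aligned_sequences)} sequences but "
                f"{len(self.sequence_ids)} ids")
        length = len(self.aligned_sequences[0])
        if length == 0:
            raise AlignmentFormatError(
                f"family {self.grain}/{self.gpt_name}: zero-length alignment")
        allowed = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES | {GAP}
        for sid, seq in zip(self.sequence_ids, self.aligned_sequences):
            if len(seq) != length:
                raise AlignmentFormatError(
                    f"record '{sid}': length {len(seq)} != alignment "
                    f"length {length} (ragged alignment)")
            bad = set(seq) - allowed
            if bad:
                raise AlphabetError(
                    f"record '{sid}': unknown residue letter(s) "
                    f"{sorted(bad)}")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise AlignmentFormatError(
                f"family {self.grain}/{self.gpt_name}: duplicate sequence ids")

    @property
    def n_sequences(self) -> int:
        return len(self.aligned_sequences)

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_sequences[0])

    @property
    def ambiguous_ids(self) -> tuple[str, ...]:
        """Ids of records containing ambiguity/nonstandard letters."""
        return tuple(
            sid for sid, seq in zip(self.sequence_ids, self.aligned_sequences)
            if set(seq) & AMBIGUOUS_RESIDUES
        )


def _normalise(raw: str, record_id: str) -> str:
    seq = raw.upper().replace(".", GAP)
    if "*" in seq:
        raise AlphabetError(f"record '{record_id}': stop character '*' rejected")
    bad = set(seq) - STANDARD_RESIDUES - AMBIGUOUS_RESIDUES - {GAP}
    if bad:
        raise AlphabetError(
            f"record '{record_id}': unknown residue letter(s) {sorted(bad)}")
    return seq


def read_alignment(path: str | Path, format: str = "aligned-fasta", *,
                   grain: str, gpt_name: str) -> ProteinFamily:
    """Read one aligned family and validate it.

    ``format`` is ``"aligned-fasta"`` or ``"clustal"``. Lower-case residues
    are upcased and ``.`` gaps normalised to ``-``. Ragged records and
    unknown letters raise errors naming the offending record.
    """
    if format not in _FORMAT_MAP:
        raise ConfigError(
            f"unknown alignment format '{format}'; "
            f"expected one of {sorted(_FORMAT_MAP)}")
    try:
        records = list(SeqIO.parse(str(path), _FORMAT_MAP[format]))
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    if not records:
        raise AlignmentFormatError(f"{path}: no records parsed")
    ids = tuple(rec.id for rec in records)
    seqs = tuple(_normalise(str(rec.seq), rec.id) for rec in records)
    return ProteinFamily(grain=grain, gpt_name=gpt_name,
                         aligned_sequences=seqs, sequence_ids=ids)


def write_family_fasta(family: ProteinFamily, path: str | Path,
                       width: int = 60) -> None:
    """Write an aligned family as wrapped FASTA."""
    with open(path, "w") as fh:
        for sid, seq in zip(family.sequence_ids, family.aligned_sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# consensus / exclusion FASTA

def write_consensus_fasta(consensuses: Iterable, path: str | Path) -> None:
    """Write ungapped consensus sequences with ``>grain|gpt_name`` headers."""
    with open(path, "w") as fh:
        for cs in consensuses:
            fh.write(f">{cs.grain}|{cs.gpt_name}\n{cs.sequence}\n")


def write_consensus_support(consensuses: Iterable, path: str | Path) -> None:
    """Per-position support table (grain, gpt, position, column, residue, support)."""
    with open(path, "w") as fh:
        fh.write("grain\tgpt\tposition\tsource_column\tresidue\tsupport\n")
        for cs in consensuses:
            for i, (col, res, sup) in enumerate(
                    zip(cs.source_columns, cs.sequence, cs.support)):
                fh.write(f"{cs.grain}\t{cs.gpt_name}\t{i}\t{col}\t{res}\t{sup!r}\n")


def read_exclusion_fasta(path: str | Path) -> dict[str, str]:
    """Read an exclusion set (off-target prolamins) as ``{id: sequence}``.

    Sequences are ungapped on read (gap characters stripped) since the
    exclusion screen works on plain residue strings.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise(str(rec.seq), rec.id).replace(GAP, "")
        if rec.id in out:
            raise AlignmentFormatError(f"{path}: duplicate id '{rec.id}'")
        out[rec.id] = seq
    if not out:
        raise AlignmentFormatError(f"{path}: no records parsed")
    return out


# ---------------------------------------------------------------------------
# candidate tables

def write_candidates(candidates: Sequence, path: str | Path) -> None:
    """Write ranked hapten candidates as TSV; row order == input order.

    Floats are serialised with ``repr`` so that a round-trip read
    reproduces every field bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            rank = "" if c.rank_score is None else str(c.rank_score)
            fh.write("\t".join([
                c.grain, c.gpt_name, str(c.start), str(c.end), c.sequence,
                str(c.length), repr(c.gravy), str(c.max_run),
                str(c.occurrence), rank, c.synthesis_sequence,
                c.status, c.reject_reason,
            ]) + "\n")


def read_candidates(path: str | Path) -> list:
    """Read a candidate TSV written by :func:`write_candidates`."""
    from .haptens import HaptenCandidate

    out: list[HaptenCandidate] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CANDIDATE_COLUMNS:
            raise AlignmentFormatError(
                f"{path}: unexpected candidate table header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_CANDIDATE_COLUMNS):
                raise AlignmentFormatError(
                    f"{path}: malformed row {f!r}")
            out.append(HaptenCandidate(
                grain=f[0], gpt_name=f[1], start=int(f[2]), end=int(f[3]),
                sequence=f[4], gravy=float(f[6]), max_run=int(f[7]),
                occurrence=int(f[8]),
                rank_score=int(f[9]) if f[9] else None,
                synthesis_sequence=f[10], status=f[11], reject_reason=f[12],
            ))
    return out


# ---------------------------------------------------------------------------
# ELISA plate tables

def read_plate_table(path: str | Path) -> list:
    """Read a long-format plate TSV into per-(serum, antigen) dilution series.

    Expected columns: serum_id, antigen_id, reciprocal_dilution, od.
    Duplicate (serum, antigen, dilution) rows are an input error.
    """
    from .elisa import DilutionSeries

    rows: dict[tuple[str, str], dict[int, float]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["serum_id", "antigen_id", "reciprocal_dilution", "od"]
        if header != expected:
            raise AlignmentFormatError(
                f"{path}: expected columns {expected}, got {header}")
        for line in fh:
            serum, antigen, dil_s, od_s = line.rstrip("\n").split("\t")
            key = (serum, antigen)
            dil = int(dil_s)
            series = rows.setdefault(key, {})
            if key not in order:
                order.append(key)
            if dil in series:
                raise AlignmentFormatError(
                    f"{path}: duplicate row for serum={serum} "
                    f"antigen={antigen} dilution={dil}")
            series[dil] = float(od_s)
    return [
        DilutionSeries(
            serum_id=serum, antigen_id=antigen,
            reciprocal_dilutions=tuple(sorted(rows[(serum, antigen)])),
            od=tuple(rows[(serum, antigen)][d]
                     for d in sorted(rows[(serum, antigen)])),
        )
        for serum, antigen in order
    ]


def write_plate_table(series_list: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("serum_id\tantigen_id\treciprocal_dilution\tod\n")
        for s in series_list:
            for d, od in zip(s.reciprocal_dilutions, s.od):
                fh.write(f"{s.serum_id}\t{s.antigen_id}\t{d}\t{od!r}\n")


def read_blanks(path: str | Path) -> list[float]:
    """Read a one-column blank-OD table (header ``od``)."""
    vals: list[float] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "od":
            raise AlignmentFormatError(f"{path}: expected header 'od', got {header!r}")
        for line in fh:
            line = line.strip()
            if line:
                vals.append(float(line))
    return vals


def write_blanks(blanks: Iterable[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("od\n")
        for b in blanks:
            fh.write(f"{float(b)!r}\n")


# ---------------------------------------------------------------------------
# configuration

_ENUMS = {
    "titer_mode": {"discrete", "interpolated"},
    "retention_rule_titer": {"strict_greater", "greater_equal"},
    "retention_rule_sensitivity": {"strict_greater", "greater_equal"},
    "consensus_gap_rule": {"majority", "ignore"},
    "uniqueness_scope": {"cross_grain", "all_vs_all"},
    "gravy_on_ambiguity": {"error", "skip"},
}


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their documented defaults.

    Length/window parameters are in residues; ``gravy_threshold`` is on the
    Kyte–Doolittle scale (candidates with GRAVY >= threshold are rejected
    as hydrophobic); ``retention_titer`` is a reciprocal dilution.
    ``gpt_abundance`` maps GPT name to its (illustrative) fraction of the
    grain's gluten, used as a ranking key.
    """

    min_segment_len: int = 6
    shared_window: int = 6
    gravy_threshold: float = 0.0
    max_run: int = 3
    preferred_min_len: int = 9
    max_len: int = 20
    titer_target_od: float = 1.0
    titer_mode: str = "interpolated"
    cutoff_confidence: float = 0.999
    retention_titer: float = 4000.0
    retention_rule_titer: str = "strict_greater"
    retention_rule_sensitivity: str = "greater_equal"
    consensus_gap_rule: str = "majority"
    uniqueness_scope: str = "cross_grain"
    gravy_on_ambiguity: str = "error"
    seed: int = 0
    gpt_abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("min_segment_len", "shared_window", "max_run",
                    "preferred_min_len", "max_len"):
            v = getattr(self, key)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{key}={v!r}: must be an integer >= 1")
        if self.max_len < self.preferred_min_len:
            raise ConfigError(
                f"max_len={self.max_len} < preferred_min_len="
                f"{self.preferred_min_len}: length bounds are inconsistent")
        if not 0.5 < self.cutoff_confidence < 1.0:
            raise ConfigError(
                f"cutoff_confidence={self.cutoff_confidence}: must lie in (0.5, 1)")
        if self.titer_target_od <= 0:
            raise ConfigError(
                f"titer_target_od={self.titer_target_od}: must be > 0")
        if self.retention_titer <= 0:
            raise ConfigError(
                f"retention_titer={self.retention_titer}: must be > 0")
        for key, allowed in _ENUMS.items():
            v = getattr(self, key)
            if v not in allowed:
                raise ConfigError(f"{key}={v!r}: expected one of {sorted(allowed)}")
        if not isinstance(self.gpt_abundance, Mapping):
            raise ConfigError("gpt_abundance must be a mapping of GPT name -> fraction")
        for gpt, frac in self.gpt_abundance.items():
            if not 0.0 <= float(frac) <= 1.0:
                raise ConfigError(
                    f"gpt_abundance[{gpt!r}]={frac}: must lie in [0, 1]")
        self.gpt_abundance = {k: float(v) for k, v in self.gpt_abundance.items()}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config, fill defaults, fail closed on unknown keys.

    ``overrides`` (keyword arguments) take precedence over the file; an
    absent or empty file yields all defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialise a config back to YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
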