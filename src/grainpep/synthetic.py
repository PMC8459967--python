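"""Synthetic inputs with planted ground truth.

Real inputs to the selection pipeline are per-GPT multiple sequence
alignments downloaded from public databases; those are not reproducible
and carry no ground truth. This module generates families with the
statistical structure the analysis assumes, with every answer known in
advance:

* each grain's GPT templates share conserved cores (identical across all
  grains) interleaved with grain-unique inserts whose GRAVY, repeat-run,
  length and exclusion-set properties are constructed to hit a chosen
  fate (selected, or rejected for hydrophobicity / repeats / exclusion
  sharing / sub-threshold length);
* families are the template plus i.i.d. per-position substitutions, so
  the alignment is exact by construction and the consensus recovers the
  template with overwhelming probability at the default noise level;
* ELISA plates are four-parameter-logistic (4PL) OD dilution curves with
  Gaussian noise and a known analytic titer, plus Gaussian blank wells.

Everything is deterministic under a seed; sequence and plate generation
use independent child streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import GenerationError
from .elisa import DilutionSeries
from .haptens import KYTE_DOOLITTLE, max_residue_run
from .seq_io import ProteinFamily

FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: residues with strictly negative Kyte-Doolittle hydropathy
HYDROPHILIC_ALPHABET = "".join(sorted(r for r, v in KYTE_DOOLITTLE.items() if v < 0))
#: residues with strictly positive hydropathy (C excluded; Cys is reserved
#: for the synthesis step and would be atypical inside gluten repeats)
HYDROPHOBIC_ALPHABET = "AFILMV"

FATES = ("selected", "rejected_hydrophobic", "rejected_repeat",
         "rejected_exclusion", "rejected_short")

_GRAINS = ("wheat", "barley", "rye", "oat")
_GPTS = {
    "wheat": ("alpha_beta_gliadin", "gamma_gliadin", "omega5_gliadin",
              "LMW_glutenin", "HMW_glutenin"),
    "barley": ("B_hordein", "C_hordein", "D_hordein", "gamma1_hordein"),
    "rye": ("gamma_secalin", "omega_secalin"),
    "oat": ("avenin", "avenin_like"),
}


@dataclass(frozen=True)
class PlantedSegment:
    grain: str
    gpt_name: str
    start: int
    end: int
    sequence: str
    fate: str

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")


@dataclass
class PlantedTruth:
    """Everything the generator planted, for end-to-end verification."""

    templates: dict[tuple[str, str], str]
    segments: list[PlantedSegment]
    core_spans: dict[tuple[str, str], tuple[tuple[int, int], ...]]
    exclusion: dict[str, str]
    gpt_abundance: dict[str, float]
    window: int

    def segments_with_fate(self, fate: str) -> list[PlantedSegment]:
        return [s for s in self.segments if s.fate == fate]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "window": self.window,
            "templates": [
                {"grain": g, "gpt": t, "template": s}
                for (g, t), s in sorted(self.templates.items())
            ],
            "segments": [dataclasses.asdict(s) for s in self.segments],
            "core_spans": [
                {"grain": g, "gpt": t, "spans": list(map(list, spans))}
                for (g, t), spans in sorted(self.core_spans.items())
            ],
            "exclusion": self.exclusion,
            "gpt_abundance": self.gpt_abundance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# sequence-side generation

def _run_limited(rng: np.random.Generator, length: int, alphabet: str,
                 max_run: int = 3) -> str:
    """Random string over ``alphabet`` with no single-residue run > max_run."""
    out: list[str] = []
    while len(out) < length:
        ch = alphabet[int(rng.integers(len(alphabet)))]
        if len(out) >= max_run and all(c == ch for c in out[-max_run:]):
            continue
        out.append(ch)
    return "".join(out)


def _context_kmers(pep: str, left: str, right: str, w: int) -> set[str]:
    """All length-w windows that overlap ``pep`` when flanked by its context."""
    lf = left[-(w - 1):] if w > 1 else ""
    rf = right[:w - 1] if w > 1 else ""
    ext = lf + pep + rf
    lo, hi = len(lf), len(lf) + len(pep)
    return {
        ext[j:j + w]
        for j in range(len(ext) - w + 1)
        if j + w > lo and j < hi
    }


def _fresh(rng: np.random.Generator, make: Callable[[], str], left: str,
           right: str, registry: set[str], w: int,
           max_tries: int = 5000) -> tuple[str, set[str]]:
    """Draw from ``make`` until every context window is globally novel."""
    for _ in range(max_tries):
        pep = make()
        kmers = _context_kmers(pep, left, right, w)
        if not (kmers & registry):
            return pep, kmers
    raise GenerationError(
        "could not draw a globally unique insert; constraints too tight "
        f"(window={w}, alphabet exhausted after {max_tries} tries)")


def generate_msa(template: str, n_seqs: int, sub_rate: float,
                 seed: int | None = None, *, grain: str = "grain",
                 gpt_name: str = "gpt", gap_rate: float = 0.0,
                 rng: np.random.Generator | None = None) -> ProteinFamily:
    """Family = template + i.i.d. per-position substitutions.

    Each sequence substitutes every position independently with
    probability ``sub_rate`` to a uniformly random *different* residue.
    With ``gap_rate`` > 0, all-gap columns are additionally inserted after
    template positions at that rate (the alignment stays trivially
    correct; consensus coordinates are unaffected because gap-majority
    columns are dropped).
    """
    if not 0.0 <= sub_rate < 0.5:
        raise ValueError(f"sub_rate={sub_rate}: must lie in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng(seed)
    lookup = {c: i for i, c in enumerate(FULL_ALPHABET)}
    idx = np.array([lookup[c] for c in template], dtype=np.int64)
    length = idx.size
    seqs: list[str] = []
    for _ in range(n_seqs):
        mutate = rng.random(length) < sub_rate
        shift = rng.integers(1, len(FULL_ALPHABET), size=length)
        new_idx = np.where(mutate, (idx + shift) % len(FULL_ALPHABET), idx)
        seqs.append("".join(FULL_ALPHABET[i] for i in new_idx))
    if gap_rate > 0.0:
        gap_after = rng.random(length) < gap_rate
        out = []
        for s in seqs:
            parts = []
            for i, ch in enumerate(s):
                parts.append(ch)
                if gap_after[i]:
                    parts.append("-")
            out.append("".join(parts))
        seqs = out
    ids = tuple(f"{grain}_{gpt_name}_{k:03d}" for k in range(n_seqs))
    return ProteinFamily(grain=grain, gpt_name=gpt_name,
                         aligned_sequences=tuple(seqs), sequence_ids=ids)


def _grain_names(n_grains: int, gpts_per_grain: int) -> list[tuple[str, list[str]]]:
    out: list[tuple[str, list[str]]] = []
    for g in range(n_grains):
        if g < len(_GRAINS) and gpts_per_grain <= len(_GPTS[_GRAINS[g]]):
            grain = _GRAINS[g]
            gpts = list(_GPTS[grain][:gpts_per_grain])
        else:
            grain = f"grain{g + 1}"
            gpts = [f"{grain}_gpt{j + 1}" for j in range(gpts_per_grain)]
        out.append((grain, gpts))
    return out


def generate_grain_set(n_grains: int = 4, gpts_per_grain: int = 2,
                       n_seqs: int = 20, sub_rate: float = 0.1,
                       core_len: int = 30, insert_len: tuple[int, int] = (9, 14),
                       decoy_len: int = 10, short_len: int = 4,
                       window: int = 6, seed: int = 0,
                       ) -> tuple[list[ProteinFamily], PlantedTruth]:
    """Grain set with planted shared cores, unique inserts and decoys.

    Every GPT template is ``core0 + selected_insert + core1 + decoy +
    core2`` where the cores are identical across all grains and GPTs (so
    they are shared by construction) and inserts/decoys carry globally
    unique windows (so they are unshared by construction). Decoy fates
    cycle through rejected_hydrophobic / rejected_repeat /
    rejected_exclusion / rejected_short across families. Families are
    produced from the templates by :func:`generate_msa`; decoys with the
    exclusion fate are copied verbatim into the returned exclusion set.
    """
    if min(insert_len) < window or min(insert_len) < 1:
        raise GenerationError("selected insert length must be >= window")
    if decoy_len < window:
        raise GenerationError("decoy length must be >= window")
    if short_len >= window:
        raise GenerationError(
            f"short_len={short_len} must be below the window ({window}) "
            f"so the planted segment stays sub-threshold")
    if core_len < 2 * window:
        raise GenerationError("cores must comfortably exceed the window")

    ss = np.random.SeedSequence(seed)
    rng_layout, rng_msa = [np.random.default_rng(s) for s in ss.spawn(2)]

    registry: set[str] = set()
    cores = [_run_limited(rng_layout, core_len, FULL_ALPHABET) for _ in range(3)]
    for core in cores:
        registry.update(core[j:j + window] for j in range(len(core) - window + 1))

    names = _grain_names(n_grains, gpts_per_grain)
    decoy_cycle = ("rejected_hydrophobic", "rejected_repeat",
                   "rejected_exclusion", "rejected_short")

    templates: dict[tuple[str, str], str] = {}
    core_spans: dict[tuple[str, str], tuple[tuple[int, int], ...]] = {}
    planted: list[PlantedSegment] = []
    exclusion_decoys: list[tuple[str, str]] = []  # (id, sequence)

    fam_index = 0
    for grain, gpts in names:
        for gpt in gpts:
            fate = decoy_cycle[fam_index % len(decoy_cycle)]
            sel_len = int(rng_layout.integers(insert_len[0], insert_len[1] + 1))
            sel, kmers = _fresh(
                rng_layout,
                lambda: _run_limited(rng_layout, sel_len, HYDROPHILIC_ALPHABET),
                cores[0], cores[1], registry, window)
            registry |= kmers

            if fate == "rejected_hydrophobic":
                def make() -> str:
                    return _run_limited(rng_layout, decoy_len, HYDROPHOBIC_ALPHABET)
            elif fate == "rejected_repeat":
                def make() -> str:
                    base = _run_limited(rng_layout, decoy_len, HYDROPHILIC_ALPHABET)
                    pos = int(rng_layout.integers(1, decoy_len - 4))
                    pep = base[:pos] + "QQQQ" + base[pos + 4:]
                    return pep
            elif fate == "rejected_exclusion":
                def make() -> str:
                    return _run_limited(rng_layout, decoy_len, HYDROPHILIC_ALPHABET)
            else:  # rejected_short
                def make() -> str:
                    return _run_limited(rng_layout, short_len, HYDROPHILIC_ALPHABET)

            decoy, kmers = _fresh(rng_layout, make, cores[1], cores[2],
                                  registry, window)
            registry |= kmers
            if fate == "rejected_repeat" and max_residue_run(decoy) <= 3:
                raise GenerationError("repeat decoy lost its planted run")

            template = cores[0] + sel + cores[1] + decoy + cores[2]
            key = (grain, gpt)
            templates[key] = template
            s0 = len(cores[0])
            s1 = s0 + len(sel)
            d0 = s1 + len(cores[1])
            d1 = d0 + len(decoy)
            core_spans[key] = ((0, s0), (s1, d0), (d1, len(template)))
            planted.append(PlantedSegment(grain, gpt, s0, s1, sel, "selected"))
            planted.append(PlantedSegment(grain, gpt, d0, d1, decoy, fate))
            if fate == "rejected_exclusion":
                exclusion_decoys.append((f"exclusion_{grain}_{gpt}", decoy))
            fam_index += 1

    exclusion: dict[str, str] = {}
    for ex_id, decoy in exclusion_decoys:
        bg1, kmers = _fresh(
            rng_layout,
            lambda: _run_limited(rng_layout, 2 * window, FULL_ALPHABET),
            "", decoy, registry, window)
        registry |= kmers
        bg2, kmers = _fresh(
            rng_layout,
            lambda: _run_limited(rng_layout, 2 * window, FULL_ALPHABET),
            decoy, "", registry, window)
        registry |= kmers
        exclusion[ex_id] = bg1 + decoy + bg2

    abundance_ladder = (0.30, 0.20, 0.15, 0.10, 0.08, 0.06, 0.05, 0.04)
    gpt_abundance = {
        gpt: abundance_ladder[j % len(abundance_ladder)]
        for _, gpts in names for j, gpt in enumerate(gpts)
    }

    families = [
        generate_msa(templates[(grain, gpt)], n_seqs, sub_rate,
                     grain=grain, gpt_name=gpt, rng=rng_msa)
        for grain, gpts in names for gpt in gpts
    ]
    truth = PlantedTruth(templates=templates, segments=planted,
                         core_spans=core_spans, exclusion=exclusion,
                         gpt_abundance=gpt_abundance, window=window)
    return families, truth


# ---------------------------------------------------------------------------
# ELISA-side generation

@dataclass(frozen=True)
class ElisaTruth:
    """4PL ground truth for one (serum, antigen) dilution curve.

    OD(d) = lower + (upper - lower) / (1 + (d / inflection)^slope), a
    decreasing sigmoid in reciprocal dilution d for slope > 0.
    """

    serum_id: str
    antigen_id: str
    upper: float          # asymptote at low dilution (A)
    lower: float          # asymptote at high dilution (D)
    inflection: float     # reciprocal dilution at the midpoint (C)
    slope: float          # Hill slope (B)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("4PL upper asymptote must exceed lower")
        if self.inflection <= 0 or self.slope <= 0:
            raise ValueError("4PL inflection and slope must be positive")

    def od(self, d):
        d = np.asarray(d, dtype=float)
        return self.lower + (self.upper - self.lower) / (
            1.0 + (d / self.inflection) ** self.slope)

    def analytic_titer(self, target_od: float = 1.0) -> float | None:
        """Reciprocal dilution where the noise-free curve equals target."""
        if not self.lower < target_od < self.upper:
            return None
        ratio = (self.upper - self.lower) / (target_od - self.lower) - 1.0
        return float(self.inflection * ratio ** (1.0 / self.slope))


@dataclass
class PlateTruth:
    """A full plate: per-pair 4PL curves plus the blank distribution."""

    curves: list[ElisaTruth]
    blank_mean: float = 0.045
    blank_sd: float = 0.008


def generate_elisa_plate(truth: PlateTruth, reciprocal_dilutions: Sequence[int],
                         n_blanks: int = 16, seed: int = 0,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[list[DilutionSeries], list[float]]:
    """Noisy OD readings for every curve plus Gaussian blank wells.

    ODs are the 4PL value plus N(0, noise_sd), truncated at zero; blanks
    are N(blank_mean, blank_sd) truncated at zero.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    dils = tuple(int(d) for d in reciprocal_dilutions)
    series: list[DilutionSeries] = []
    for curve in truth.curves:
        clean = curve.od(dils)
        noisy = np.clip(clean + rng.normal(0.0, curve.noise_sd, len(dils))
                        if curve.noise_sd > 0 else clean, 0.0, None)
        series.append(DilutionSeries(
            serum_id=curve.serum_id, antigen_id=curve.antigen_id,
            reciprocal_dilutions=dils, od=tuple(float(x) for x in noisy)))
    blanks = np.clip(rng.normal(truth.blank_mean, truth.blank_sd, n_blanks),
                     0.0, None)
    return series, [float(b) for b in blanks]


DEFAULT_DILUTION_LADDER = tuple(2000 * 2 ** k for k in range(8))  # 2000..256000


def default_serology_truth(noise_sd: float = 0.02) -> PlateTruth:
    """Shipped demo plate: four sera, one per grain, against four prolamins.

    Each serum reacts strongly with its own grain's prolamin (curve
    crossing OD 1.0 inside the ladder), weakly with one neighbour (upper
    asymptote below target, so no titer) and at background elsewhere.
    """
    grains = ("wheat", "barley", "rye", "oat")
    curves: list[ElisaTruth] = []
    for i, g in enumerate(grains):
        serum = f"serum_{g}"
        for j, antigen in enumerate(grains):
            if i == j:
                curves.append(ElisaTruth(serum, f"{antigen}_prolamin",
                                         upper=2.2, lower=0.05,
                                         inflection=12000 * (i + 1),
                                         slope=1.8, noise_sd=noise_sd))
            elif (j - i) % len(grains) == 1:
                curves.append(ElisaTruth(serum, f"{antigen}_prolamin",
                                         upper=0.6, lower=0.03,
                                         inflection=8000, slope=1.5,
                                         noise_sd=noise_sd))
            else:
                curves.append(ElisaTruth(serum, f"{antigen}_prolamin",
                                         upper=0.08, lower=0.02,
                                         inflection=4000, slope=1.0,
                                         noise_sd=noise_sd))
    return PlateTruth(curves=curves)
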