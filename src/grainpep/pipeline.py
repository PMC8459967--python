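"""End-to-end orchestration of the two analyses.

``run_selection`` chains consensus building, cross-grain uniqueness
mining, the off-target exclusion screen, the hydropathy/repeat/length
filters, ranking and synthesis preparation, producing a ranked candidate
list plus a stage-by-stage funnel manifest. ``run_serology`` chains the
blank cutoff, endpoint titers, serum retention and cross-reactivity
banding. Both enforce the conservation law ``found == kept +
sum(rejected by reason)`` at every stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .consensus import ConsensusSequence, build_consensus
from .elisa import (CutoffResult, DilutionSeries, RetentionFlag, TiterResult,
                    endpoint_titer, frey_cutoff, reactivity_band,
                    retain_sera, retained_sera_ids, specificity_matrix)
from .errors import PipelineError
from .haptens import (HaptenCandidate, REJECT_REASONS, annotate_candidates,
                      filter_candidates, rank_candidates)
from .seq_io import PipelineConfig, ProteinFamily
from .uniqueness import (SegmentCandidate, extract_unshared_segments,
                         mark_shared_positions, screen_exclusion)


@dataclass
class RunManifest:
    """Reproducibility record: config, digests, seed and funnel counts."""

    tool_version: str = __version__
    seed: int | None = None
    config: dict = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        found = self.counts.get("segments_found")
        if found is None:
            return
        kept = self.counts.get("segments_kept", 0)
        rejected = sum(self.counts.get(f"rejected_{r}", 0)
                       for r in REJECT_REASONS)
        if found != kept + rejected:
            raise PipelineError(
                f"manifest conservation violated: found={found}, "
                f"kept={kept}, rejected={rejected}")

    def to_json(self, path: str | Path) -> None:
        self.check_conservation()
        with open(path, "w") as fh:
            json.dump({
                "tool_version": self.tool_version,
                "seed": self.seed,
                "config": self.config,
                "input_digests": self.input_digests,
                "counts": self.counts,
            }, fh, indent=1, sort_keys=True)


def digest_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class SelectionResult:
    consensuses: list[ConsensusSequence]
    segments: list[SegmentCandidate]
    annotated: list[HaptenCandidate]        # full audit trail after filters
    ranked: list[HaptenCandidate]           # survivors in rank order
    manifest: RunManifest
    masks: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    @property
    def audit(self) -> list[HaptenCandidate]:
        """Ranked survivors followed by every rejected segment."""
        return self.ranked + [c for c in self.annotated if c.status == "rejected"]


def run_selection(families: Sequence[ProteinFamily],
                  exclusion_set: Mapping[str, str] | Sequence[str],
                  config: PipelineConfig) -> SelectionResult:
    """Consensus → uniqueness → exclusion → filters → ranking → synthesis."""
    if not families:
        raise PipelineError("selection: no families to process")
    exclusion = (list(exclusion_set.values())
                 if isinstance(exclusion_set, Mapping) else list(exclusion_set))

    try:
        consensuses = [build_consensus(f, gap_rule=config.consensus_gap_rule)
                       for f in families]
    except Exception as exc:
        raise PipelineError(f"consensus stage failed: {exc}") from exc

    by_grain: dict[str, list[ConsensusSequence]] = {}
    for cs in consensuses:
        by_grain.setdefault(cs.grain, []).append(cs)

    segments: list[SegmentCandidate] = []
    masks: dict[tuple[str, str], list[int]] = {}
    for cs in consensuses:
        if config.uniqueness_scope == "cross_grain":
            others = [o for o in consensuses if o.grain != cs.grain]
        else:  # all_vs_all
            others = [o for o in consensuses if o is not cs]
        mask = mark_shared_positions(cs, others, window=config.shared_window)
        masks[(cs.grain, cs.gpt_name)] = [int(x) for x in mask]
        segments.extend(extract_unshared_segments(
            cs, mask, min_len=config.min_segment_len))

    screened = screen_exclusion(segments, exclusion,
                                window=config.shared_window)
    annotated = annotate_candidates(
        screened, by_grain, on_ambiguity=config.gravy_on_ambiguity)
    filtered = filter_candidates(
        annotated, gravy_threshold=config.gravy_threshold,
        max_run=config.max_run, max_len=config.max_len)
    survivors = [c for c in filtered if c.status == "candidate"]
    try:
        ranked = rank_candidates(survivors, config.gpt_abundance,
                                 preferred_min_len=config.preferred_min_len)
    except KeyError as exc:
        raise PipelineError(f"ranking stage failed: {exc}") from exc

    manifest = RunManifest(seed=config.seed, config=_config_dict(config))
    manifest.counts = {
        "families": len(families),
        "consensuses": len(consensuses),
        "segments_found": len(filtered),
        "segments_kept": len(ranked),
    }
    for reason in REJECT_REASONS:
        manifest.counts[f"rejected_{reason}"] = sum(
            1 for c in filtered if c.reject_reason == reason)
    manifest.check_conservation()
    return SelectionResult(consensuses=consensuses, segments=segments,
                           annotated=filtered, ranked=ranked,
                           manifest=manifest, masks=masks)


@dataclass
class SerologyResult:
    cutoff: CutoffResult
    titers: list[TiterResult]
    retention: list[RetentionFlag]
    retained_sera: set[str]
    calls: list
    matrix: "object"           # pandas DataFrame of bands
    manifest: RunManifest


def run_serology(series_list: Sequence[DilutionSeries],
                 blanks: Sequence[float],
                 config: PipelineConfig) -> SerologyResult:
    """Cutoff → titers → retention → banding → specificity matrix.

    Banding uses each pair's strongest signal (OD at the lowest dilution)
    against the serum's maximum such signal, mirroring how categorical
    cross-reactivity intervals are reported relative to the strongest
    signal obtained per serum.
    """
    if not series_list:
        raise PipelineError("serology: no dilution series to process")
    if len(blanks) < 2:
        raise PipelineError("serology: banding requires at least 2 blank wells")
    cutoff = frey_cutoff(blanks, confidence=config.cutoff_confidence)
    titers = [endpoint_titer(s, target_od=config.titer_target_od,
                             mode=config.titer_mode)
              for s in series_list]
    retention = retain_sera(titers, threshold=config.retention_titer,
                            rule=config.retention_rule_sensitivity)
    retained = retained_sera_ids(retention)

    strongest: dict[tuple[str, str], float] = {
        (s.serum_id, s.antigen_id): s.od[0] for s in series_list}
    serum_max: dict[str, float] = {}
    for (serum, _), od in strongest.items():
        serum_max[serum] = max(serum_max.get(serum, 0.0), od)
    calls = [
        reactivity_band(od, serum_max[serum], cutoff.cutoff,
                        serum_id=serum, antigen_id=antigen)
        for (serum, antigen), od in strongest.items()
    ]
    matrix = specificity_matrix(calls)

    manifest = RunManifest(seed=config.seed, config=_config_dict(config))
    manifest.counts = {
        "series": len(series_list),
        "sera": len(serum_max),
        "sera_retained": len(retained),
        "sera_discarded": len(serum_max) - len(retained),
        "titers_censored_below": sum(
            1 for t in titers if t.censored == "below_range"),
        "titers_censored_above": sum(
            1 for t in titers if t.censored == "above_range"),
    }
    return SerologyResult(cutoff=cutoff, titers=titers, retention=retention,
                          retained_sera=retained, calls=calls, matrix=matrix,
                          manifest=manifest)


def _config_dict(config: PipelineConfig) -> dict:
    import dataclasses as _dc
    return _dc.asdict(config)
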