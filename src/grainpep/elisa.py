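"""Indirect-ELISA analytics: endpoint titers, blank cutoff, banding.

The endpoint titer is the highest serum dilution producing an optical
density (OD) of 1.000 at 450 nm. Because two-fold serial dilutions only
sample discrete points, the default mode interpolates the crossing
linearly in log2(reciprocal dilution) space; a discrete mode returning the
last measured dilution at or above target is also provided.

The positivity cutoff follows the blank-based endpoint method of Frey et
al. (1998): a one-sided prediction bound ``mean + sd * t_{conf, n-1} *
sqrt(1 + 1/n)`` over n blank wells, so that a fresh blank exceeds the
cutoff with probability 1 - confidence (99.9% confidence by default).

Cross-reactivity is reported in categorical bands relative to each
serum's strongest signal: +++ (75-100% of the serum maximum), ++ (25-75%),
+ (5-25%), +/- (above cutoff but at most 0.050 OD), - (below cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

BANDS = ("+++", "++", "+", "+/-", "-")

#: OD at or below which a supra-cutoff signal is called marginal ("+/-")
MARGINAL_OD = 0.050


@dataclass(frozen=True)
class DilutionSeries:
    """OD readings of one serum against one antigen over a dilution ladder."""

    serum_id: str
    antigen_id: str
    reciprocal_dilutions: tuple[int, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        d = self.reciprocal_dilutions
        if len(d) != len(self.od):
            raise ValueError("dilution and OD lengths differ")
        if len(d) < 2:
            raise ValueError("a dilution series needs at least 2 points")
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("reciprocal dilutions must be positive, strictly increasing")
        if any(o < 0 for o in self.od):
            raise ValueError("OD values must be non-negative")


@dataclass(frozen=True)
class TiterResult:
    serum_id: str
    antigen_id: str
    titer: float | None          # reciprocal dilution, or None
    mode: str                    # "discrete" | "interpolated"
    censored: str = "not_censored"   # | "above_range" | "below_range"
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class CutoffResult:
    n_blanks: int
    mean_blank: float
    sd_blank: float
    confidence: float
    multiplier: float
    cutoff: float
    degenerate: bool = False


@dataclass(frozen=True)
class ReactivityCall:
    serum_id: str
    antigen_id: str
    band: str
    od: float
    pct_of_max: float
    flagged: bool = False


def endpoint_titer(series: DilutionSeries, target_od: float = 1.0,
                   mode: str = "interpolated") -> TiterResult:
    """Endpoint titer of one dilution series.

    Discrete mode: largest reciprocal dilution whose OD >= target.
    Interpolated mode: the series is scanned from the highest dilution
    down for the last crossing pair (OD_i >= target > OD_{i+1}) and the
    titer interpolated linearly in OD vs log2(reciprocal dilution). All
    ODs >= target → censored "above_range" with titer = max dilution; all
    ODs < target → titer None, censored "below_range". Non-monotone series
    are tolerated (noise) but an OD rise of more than 10% between
    successive dilutions attaches a warning.
    """
    if mode not in ("discrete", "interpolated"):
        raise ValueError(f"unknown titer mode {mode!r}")
    if target_od <= 0:
        raise ValueError("target_od must be positive")
    d = np.asarray(series.reciprocal_dilutions, dtype=float)
    od = np.asarray(series.od, dtype=float)
    warnings = tuple(
        f"OD rises {od[i]:.3f} -> {od[i + 1]:.3f} between dilutions "
        f"{int(d[i])} and {int(d[i + 1])}"
        for i in range(len(od) - 1)
        if od[i + 1] > 1.10 * od[i]
    )
    if np.all(od >= target_od):
        return TiterResult(series.serum_id, series.antigen_id,
                           titer=float(d[-1]), mode=mode,
                           censored="above_range", warnings=warnings)
    if np.all(od < target_od):
        return TiterResult(series.serum_id, series.antigen_id, titer=None,
                           mode=mode, censored="below_range",
                           warnings=warnings)
    if mode == "discrete":
        titer = float(d[od >= target_od].max())
        return TiterResult(series.serum_id, series.antigen_id, titer=titer,
                           mode=mode, warnings=warnings)
    for i in range(len(od) - 2, -1, -1):
        if od[i] >= target_od > od[i + 1]:
            frac = (od[i] - target_od) / (od[i] - od[i + 1])
            log2_titer = math.log2(d[i]) + frac * (math.log2(d[i + 1]) - math.log2(d[i]))
            return TiterResult(series.serum_id, series.antigen_id,
                               titer=float(2.0 ** log2_titer), mode=mode,
                               warnings=warnings)
    # mixed ODs but no downward crossing (severely non-monotone): fall back
    # to the discrete definition and say so.
    titer = float(d[od >= target_od].max())
    return TiterResult(series.serum_id, series.antigen_id, titer=titer,
                       mode=mode,
                       warnings=warnings + (
                           "no downward target crossing; discrete fallback",))


def frey_cutoff(blank_od: Sequence[float], confidence: float = 0.999) -> CutoffResult:
    """Blank-derived positivity cutoff (one-sided prediction bound).

    cutoff = mean + sd * t_{confidence, n-1} * sqrt(1 + 1/n), with the
    sample (n-1 denominator) standard deviation. Zero blank spread yields
    the degenerate cutoff = mean, flagged as such.
    """
    blanks = np.asarray(list(blank_od), dtype=float)
    n = blanks.size
    if n < 2:
        raise ValueError(f"need at least 2 blanks, got {n}")
    if not 0.5 < confidence < 1.0:
        raise ValueError(f"confidence={confidence}: must lie in (0.5, 1)")
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    multiplier = float(stats.t.ppf(confidence, n - 1) * math.sqrt(1.0 + 1.0 / n))
    if sd == 0.0:
        return CutoffResult(n, mean, sd, confidence, multiplier,
                            cutoff=mean, degenerate=True)
    return CutoffResult(n, mean, sd, confidence, multiplier,
                        cutoff=mean + sd * multiplier)


@dataclass(frozen=True)
class RetentionFlag:
    serum_id: str
    antigen_id: str
    titer: float | None
    retained: bool
    rule: str


def retain_sera(titers: Sequence[TiterResult], threshold: float = 4000.0,
                rule: str = "strict_greater") -> list[RetentionFlag]:
    """Flag each titer against the retention threshold.

    ``strict_greater`` (titer screening stage) keeps titer > threshold —
    a titer at exactly the threshold is discarded; ``greater_equal``
    (prolamin sensitivity stage) keeps titer >= threshold. A missing titer
    (None) is discarded under both rules.
    """
    if rule not in ("strict_greater", "greater_equal"):
        raise ValueError(f"unknown retention rule {rule!r}")
    out: list[RetentionFlag] = []
    for t in titers:
        if t.titer is None:
            keep = False
        elif rule == "strict_greater":
            keep = t.titer > threshold
        else:
            keep = t.titer >= threshold
        out.append(RetentionFlag(t.serum_id, t.antigen_id, t.titer, keep, rule))
    return out


def retained_sera_ids(flags: Sequence[RetentionFlag]) -> set[str]:
    """Sera retained on at least one antigen (either prolamin form)."""
    return {f.serum_id for f in flags if f.retained}


def reactivity_band(od: float, serum_max_od: float, cutoff: float,
                    serum_id: str = "", antigen_id: str = "") -> ReactivityCall:
    """Assign the categorical cross-reactivity band for one well.

    Decision order: below cutoff → "-"; at most 0.050 OD → "+/-";
    otherwise by fraction of the serum's maximum signal: >=75% "+++",
    25-75% "++", else "+". The corner where the OD exceeds 0.050 but
    falls under 5% of the serum maximum is assigned "+" and flagged.
    """
    if serum_max_od <= 0:
        raise ValueError("serum_max_od must be positive")
    if od < 0 or cutoff < 0:
        raise ValueError("OD and cutoff must be non-negative")
    pct = od / serum_max_od
    if od < cutoff:
        return ReactivityCall(serum_id, antigen_id, "-", od, pct)
    if od <= MARGINAL_OD:
        return ReactivityCall(serum_id, antigen_id, "+/-", od, pct)
    if pct >= 0.75:
        return ReactivityCall(serum_id, antigen_id, "+++", od, pct)
    if pct >= 0.25:
        return ReactivityCall(serum_id, antigen_id, "++", od, pct)
    return ReactivityCall(serum_id, antigen_id, "+", od, pct,
                          flagged=pct < 0.05)


def specificity_matrix(calls: Sequence[ReactivityCall]) -> pd.DataFrame:
    """Serum x antigen table of bands; untested cells hold "n/a".

    Rows/columns are sorted for reproducibility; duplicate (serum,
    antigen) pairs are an input error.
    """
    seen: set[tuple[str, str]] = set()
    for c in calls:
        key = (c.serum_id, c.antigen_id)
        if key in seen:
            raise ValueError(f"duplicate reactivity call for {key}")
        seen.add(key)
    if not calls:
        return pd.DataFrame()
    sera = sorted({c.serum_id for c in calls})
    antigens = sorted({c.antigen_id for c in calls})
    table = pd.DataFrame("n/a", index=pd.Index(sera, name="serum_id"),
                         columns=pd.Index(antigens, name="antigen_id"))
    for c in calls:
        table.loc[c.serum_id, c.antigen_id] = c.band
    return table


def render_matrix(table: pd.DataFrame, path_tsv=None, path_txt=None) -> str:
    """Write the band matrix as TSV and/or aligned text; return the text."""
    text = table.to_string()
    if path_tsv is not None:
        table.to_csv(path_tsv, sep="\t")
    if path_txt is not None:
        with open(path_txt, "w") as fh:
            fh.write(text + "\n")
    return text
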