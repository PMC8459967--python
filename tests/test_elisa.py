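"""Endpoint titers, Frey cutoff, retention rules and banding."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from grainpep.elisa import (DilutionSeries, TiterResult, endpoint_titer,
                            frey_cutoff, reactivity_band, retain_sera,
                            specificity_matrix)

LADDER = (2000, 4000, 8000, 16000)


def _series(od, dil=LADDER, serum="s", antigen="a"):
    return DilutionSeries(serum, antigen, dil, tuple(od))


class TestEndpointTiter:
    def test_interpolated_log2_crossing(self):
        # crossing between 8000 (1.2) and 16000 (0.8): fraction 0.5,
        # titer = 8000 * 2^0.5 ~ 11314
        r = endpoint_titer(_series([1.8, 1.4, 1.2, 0.8]))
        assert r.titer == pytest.approx(8000 * math.sqrt(2), rel=1e-12)
        assert r.censored == "not_censored"

    def test_discrete_mode(self):
        r = endpoint_titer(_series([1.8, 1.4, 1.2, 0.8]), mode="discrete")
        assert r.titer == 8000

    def test_all_above_target_censored(self):
        r = endpoint_titer(_series([1.8, 1.6, 1.4, 1.2]))
        assert r.censored == "above_range"
        assert r.titer == 16000

    def test_all_below_target_no_titer(self):
        r = endpoint_titer(_series([0.9, 0.6, 0.4, 0.2]))
        assert r.titer is None
        assert r.censored == "below_range"

    def test_exact_target_at_measured_dilution_modes_agree(self):
        od = [1.8, 1.0, 0.6, 0.3]
        ri = endpoint_titer(_series(od), mode="interpolated")
        rd = endpoint_titer(_series(od), mode="discrete")
        assert ri.titer == pytest.approx(rd.titer) == 4000

    def test_interpolated_titer_within_bracketing_dilutions(self):
        r = endpoint_titer(_series([1.7, 1.3, 1.1, 0.4]))
        assert 8000 <= r.titer <= 16000

    def test_non_monotone_rise_attaches_warning(self):
        r = endpoint_titer(_series([1.8, 1.4, 1.6, 0.8]))
        assert r.warnings

    def test_monotone_series_no_warning(self):
        r = endpoint_titer(_series([1.8, 1.4, 1.2, 0.8]))
        assert r.warnings == ()

    def test_last_crossing_wins_with_noise_dip(self):
        # dips below target at 4000, recovers, finally crosses after 8000:
        # the scan from the highest dilution finds the 8000->16000 pair
        r = endpoint_titer(_series([1.8, 0.95, 1.2, 0.8]))
        assert 8000 <= r.titer <= 16000

    @given(st.lists(st.floats(0.0, 3.0), min_size=4, max_size=4),
           st.floats(0.01, 0.5))
    def test_raising_od_never_decreases_titer(self, od, bump):
        od = sorted(od, reverse=True)  # a proper decreasing dilution curve
        base = endpoint_titer(_series(od))
        raised = endpoint_titer(_series([o + bump for o in od]))
        key = lambda r: -1.0 if r.titer is None else r.titer
        assert key(raised) >= key(base)


class TestFreyCutoff:
    def test_multiplier_against_t_quantile(self):
        """n=10, conf 0.999: multiplier t_{0.999,9}*sqrt(1.1) ~ 4.507."""
        rng = np.random.default_rng(5)
        blanks = list(0.050 + 0.010 * rng.standard_normal(10))
        r = frey_cutoff(blanks, confidence=0.999)
        assert r.multiplier == pytest.approx(4.5066, abs=2e-3)
        assert r.cutoff == pytest.approx(
            r.mean_blank + r.sd_blank * r.multiplier, abs=1e-12)

    def test_reference_blank_moments(self):
        # mean 0.050, sd 0.010 exactly: cutoff ~ 0.0951
        blanks = [0.050 - 0.010, 0.050 + 0.010] * 5
        sd = np.std(blanks, ddof=1)
        r = frey_cutoff(blanks, confidence=0.999)
        assert r.mean_blank == pytest.approx(0.050)
        assert r.cutoff == pytest.approx(0.050 + sd * 4.50656, abs=1e-4)

    def test_zero_sd_degenerate(self):
        r = frey_cutoff([0.05] * 8)
        assert r.degenerate
        assert r.cutoff == 0.05

    def test_monotone_in_confidence(self):
        blanks = [0.04, 0.05, 0.06, 0.045, 0.055]
        assert (frey_cutoff(blanks, 0.999).cutoff
                > frey_cutoff(blanks, 0.99).cutoff)

    def test_too_few_blanks(self):
        with pytest.raises(ValueError):
            frey_cutoff([0.05])


class TestRetention:
    def _titer(self, value):
        return TiterResult("s", "a", value, "interpolated")

    def test_threshold_titer_discarded_under_strict_rule(self):
        flags = retain_sera([self._titer(4000.0)], 4000, "strict_greater")
        assert not flags[0].retained

    def test_threshold_titer_retained_under_greater_equal(self):
        flags = retain_sera([self._titer(4000.0)], 4000, "greater_equal")
        assert flags[0].retained

    def test_missing_titer_discarded_under_both(self):
        for rule in ("strict_greater", "greater_equal"):
            assert not retain_sera([self._titer(None)], 4000, rule)[0].retained

    def test_flag_records_rule(self):
        flags = retain_sera([self._titer(8000.0)], 4000, "greater_equal")
        assert flags[0].rule == "greater_equal"


class TestBanding:
    def test_strong_signal(self):
        call = reactivity_band(1.5, 1.6, 0.08)
        assert call.band == "+++"
        assert call.pct_of_max == pytest.approx(0.9375)

    def test_marginal_low_od(self):
        assert reactivity_band(0.045, 1.6, 0.030).band == "+/-"

    def test_below_cutoff(self):
        assert reactivity_band(0.02, 1.6, 0.030).band == "-"

    def test_undefined_corner_flagged_plus(self):
        # above 0.050 OD but under 5% of the serum maximum
        call = reactivity_band(0.06, 2.0, 0.03)
        assert call.band == "+"
        assert call.flagged

    @pytest.mark.parametrize("od,expected", [
        (0.050, "+/-"),      # boundary: at most 0.050 is marginal
        (1.5, "+++"),        # exactly 75% of 2.0
        (0.5, "++"),         # exactly 25% of 2.0
        (0.499, "+"),
    ])
    def test_band_boundaries(self, od, expected):
        assert reactivity_band(od, 2.0, 0.03).band == expected

    @given(st.floats(0.0, 3.0))
    def test_totality_and_exclusivity(self, od):
        call = reactivity_band(od, 1.6, 0.08)
        assert call.band in ("+++", "++", "+", "+/-", "-")
        assert (call.band == "-") == (od < 0.08)

    def test_nonpositive_max_errors(self):
        with pytest.raises(ValueError):
            reactivity_band(0.5, 0.0, 0.03)


class TestSpecificityMatrix:
    def _call(self, serum, antigen, band="+"):
        from grainpep.elisa import ReactivityCall
        return ReactivityCall(serum, antigen, band, 0.5, 0.5)

    def test_untested_cells_na(self):
        calls = [self._call(s, a) for s, a in
                 [("s1", "a1"), ("s1", "a2"), ("s1", "a3"),
                  ("s2", "a1"), ("s2", "a2")]]
        table = specificity_matrix(calls)
        assert table.shape == (2, 3)
        assert (table == "n/a").sum().sum() == 1
        assert table.loc["s2", "a3"] == "n/a"

    def test_empty_input(self):
        assert specificity_matrix([]).empty

    def test_duplicate_cell_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            specificity_matrix([self._call("s", "a"), self._call("s", "a")])
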