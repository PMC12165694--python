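"""CT scoring, population curves, mobility metrics, and the test battery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from _oracles import oracle_events
from larvaquant.behavior import (BaselineWindow, CTEventSet, PercentTrace,
                                 area_change_pct, detect_ct, group_statistics,
                                 min_run_frames, mobility_metrics,
                                 population_curves, summarize_animal)
from larvaquant.video import AreaTrace, MobilityTrace


def _pct(values, dt=1 / 30):
    values = np.asarray(values, dtype=float)
    return PercentTrace(t=np.arange(len(values)) * dt, pct=values,
                        valid=np.ones(len(values), dtype=bool))


class TestAreaChange:
    def test_constant_area_zero_percent(self):
        trace = AreaTrace(t=np.arange(10) / 30, area=np.full(10, 1000.0),
                          valid=np.ones(10, dtype=bool))
        pct = area_change_pct(trace, BaselineWindow(0, 0.2))
        assert np.allclose(pct.pct, 0.0)

    def test_ten_percent_drop_exact(self):
        area = np.full(20, 1000.0)
        area[10:] = 900.0
        trace = AreaTrace(t=np.arange(20) / 30, area=area,
                          valid=np.ones(20, dtype=bool))
        pct = area_change_pct(trace, BaselineWindow(0, 10 / 30))
        assert np.allclose(pct.pct[10:], -10.0)

    def test_short_baseline_rejected(self):
        trace = AreaTrace(t=np.arange(10) / 30, area=np.full(10, 1000.0),
                          valid=np.ones(10, dtype=bool))
        with pytest.raises(ValueError, match="fewer than 5"):
            area_change_pct(trace, BaselineWindow(0, 3 / 30))


class TestDetectCT:
    def test_whole_window_below_is_one_event(self):
        pct = _pct(np.full(150, -12.0))
        events = detect_ct(pct, window=(0.0, 5.0))
        assert len(events) == 1
        assert events.events[0].duration_s == pytest.approx(5.0)

    def test_above_threshold_no_event(self):
        events = detect_ct(_pct(np.full(150, -9.0)), window=(0.0, 5.0))
        assert len(events) == 0

    @pytest.mark.parametrize("dip_s,expected", [(0.4, 0), (0.6, 1)])
    def test_minimum_duration_discretization(self, dip_s, expected):
        # at 30 fps: 0.4 s = 12 < 15 frames -> rejected; 0.6 s = 18 -> kept
        n = 300
        pct = np.zeros(n)
        k = round(dip_s * 30)
        pct[60:60 + k] = -15.0
        events = detect_ct(_pct(pct), window=(0.0, 10.0))
        assert len(events) == expected
        if expected:
            assert events.events[0].duration_s == pytest.approx(dip_s)

    def test_threshold_is_inclusive(self):
        pct = np.zeros(60)
        pct[15:30] = -10.0  # exactly at threshold, exactly 0.5 s at 30 fps
        assert len(detect_ct(_pct(pct))) == 1
        pct[15:30] = -9.999
        assert len(detect_ct(_pct(pct))) == 0

    def test_agrees_with_runlength_oracle(self):
        rng = np.random.default_rng(42)
        dt = 1 / 30
        need = min_run_frames(0.5, dt)
        for _ in range(100):
            vals = rng.normal(-10, 3, 300)
            events = detect_ct(_pct(vals), window=(0.0, 10.0))
            oracle = oracle_events(vals, -10.0, need)
            assert len(events) == len(oracle)
            for ev, (i0, n) in zip(events.events, oracle):
                assert ev.start_s == pytest.approx(i0 * dt)
                assert ev.duration_s == pytest.approx(n * dt)

    @given(st.integers(0, 2**31 - 1), st.floats(-15, -5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_duration_monotone_in_threshold(self, seed, threshold):
        # a more permissive (lower-|value|) threshold never shortens CT time
        rng = np.random.default_rng(seed)
        vals = rng.normal(-10, 4, 150)
        pct = _pct(vals)
        stim = (0.0, 5.0)

        def total(thr):
            ev = detect_ct(pct, threshold=thr, window=stim)
            return summarize_animal(pct, ev, stim).ct_duration

        assert total(threshold) <= total(threshold + 1.0) + 1e-9


class TestSummarize:
    def test_no_events(self):
        pct = _pct(np.zeros(300))
        m = summarize_animal(pct, CTEventSet(events=[]), (5.0, 10.0))
        assert m.ct_duration == 0.0 and not m.responded

    def test_half_stimulus_at_minus_20(self):
        n = 300
        vals = np.zeros(n)
        vals[150:225] = -20.0  # second half of a 5-10 s stimulus at 30 fps
        pct = _pct(vals)
        events = detect_ct(pct, window=(5.0, 10.0))
        m = summarize_animal(pct, events, (5.0, 10.0))
        assert m.ct_magnitude == pytest.approx(-10.0)
        assert m.ct_duration == pytest.approx(2.5)
        assert m.responded


class TestPopulationCurves:
    def test_all_below_is_hundred(self):
        animals = [_pct(np.full(300, -15.0)) for _ in range(5)]
        curves = population_curves(animals, window=(0.0, 10.0))
        assert np.allclose(curves.instantaneous_pct_ct, 100.0)
        assert curves.peak_pct_ct == 100.0

    def test_quarter_respond(self):
        resp = np.zeros(300)
        resp[150:] = -20.0
        animals = [_pct(resp)] + [_pct(np.zeros(300)) for _ in range(3)]
        curves = population_curves(animals, window=(0.0, 10.0))
        assert curves.cumulative_pct_ct[-1] == pytest.approx(25.0)
        assert np.all(np.diff(curves.cumulative_pct_ct) >= 0)

    def test_staggered_onsets_step_at_schedule(self):
        dt = 1 / 30
        animals = []
        onsets = [2.0, 4.0, 6.0]
        for onset in onsets:
            vals = np.zeros(300)
            vals[int(onset / dt):] = -20.0
            animals.append(_pct(vals))
        curves = population_curves(animals, window=(0.0, 10.0))
        for frac, onset in zip((1 / 3, 2 / 3, 1.0), onsets):
            after = curves.t >= onset + dt
            before = curves.t < onset - dt
            assert curves.cumulative_pct_ct[after][0] == pytest.approx(100 * frac)
            if before.any():
                assert curves.cumulative_pct_ct[before][-1] < 100 * frac

    def test_peak_bounds_instantaneous(self):
        rng = np.random.default_rng(0)
        animals = [_pct(rng.normal(-8, 4, 300)) for _ in range(6)]
        curves = population_curves(animals, window=(0.0, 10.0))
        assert np.all(curves.instantaneous_pct_ct <= curves.peak_pct_ct)


class TestMobilityMetrics:
    def _mob(self, values, dt=1 / 30):
        values = np.asarray(values, dtype=float)
        valid = np.ones(len(values), dtype=bool)
        valid[0] = False
        return MobilityTrace(t=np.arange(len(values)) * dt,
                             raw_mobility=values, valid=valid)

    def test_constant_mobility_zero_change(self):
        mob = self._mob(np.full(300, 40.0))
        m = mobility_metrics(mob, BaselineWindow(0, 5), (5.0, 10.0))
        assert m.mobility_change == pytest.approx(0.0)
        assert not m.immobile and m.immobility_duration == 0.0

    def test_halved_mobility(self):
        vals = np.full(300, 40.0)
        vals[150:] = 20.0
        m = mobility_metrics(self._mob(vals), BaselineWindow(0, 5), (5.0, 10.0))
        assert m.mobility_change == pytest.approx(-50.0)
        assert m.immobile
        assert m.immobility_duration == pytest.approx(5.0)

    def test_zero_baseline_unscorable(self):
        m = mobility_metrics(self._mob(np.zeros(300)),
                             BaselineWindow(0, 5), (5.0, 10.0))
        assert m.unscorable


class TestGroupStatistics:
    def _table(self, spec):
        rows = []
        for genotype, (n_resp, n_tot, dur, mag) in spec.items():
            for i in range(n_tot):
                rows.append({"genotype": genotype, "responded": i < n_resp,
                             "ct_duration": dur + 0.01 * i, "ct_magnitude": mag + 0.1 * i})
        return pd.DataFrame(rows)

    def test_identical_groups_fisher_p_one(self):
        df = self._table({"ctrl": (5, 10, 2.0, -15.0), "g1": (5, 10, 2.0, -15.0)})
        out = group_statistics(df, ["ctrl"])
        fisher = out[out["test"] == "fisher_exact_bh"]
        assert fisher["raw_p"].iloc[0] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # [[10,0],[0,10]]: exact two-sided p from the hypergeometric pmf
        df = self._table({"ctrl": (0, 10, 1.0, -5.0), "g1": (10, 10, 3.0, -20.0)})
        out = group_statistics(df, ["ctrl"])
        p = out[out["test"] == "fisher_exact_bh"]["raw_p"].iloc[0]
        rv = hypergeom(20, 10, 10)
        support = np.arange(0, 11)
        pmf = rv.pmf(support)
        expected = pmf[pmf <= rv.pmf(10) * (1 + 1e-9)].sum()
        assert p == pytest.approx(expected, rel=1e-6)
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-6)

    def test_bh_adjustment_by_hand(self):
        # BH on (0.01, 0.02, 0.9): p*(m/rank), monotone -> (0.03, 0.03, 0.9)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.9], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.9])

    def test_battery_reports_all_metrics(self):
        df = self._table({"ctrl": (3, 8, 1.0, -8.0), "g1": (7, 8, 3.0, -20.0),
                          "g2": (1, 8, 0.5, -4.0)})
        out = group_statistics(df, ["ctrl"])
        assert set(out["metric"]) == {"pct_ct_response", "ct_duration", "ct_magnitude"}
        assert (out["adj_p"] >= out["raw_p"] - 1e-12).all()
        assert set(out["genotype"]) == {"g1", "g2"}

    def test_missing_control_rejected(self):
        df = self._table({"g1": (5, 10, 2.0, -15.0)})
        with pytest.raises(ValueError, match="control"):
            group_statistics(df, ["ctrl"])
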