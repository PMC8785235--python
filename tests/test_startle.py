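"""Tap-event extraction, responder thresholds/classification, habituation."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_startle_session, make_trace
from larvaphen import startle_habituation as sh
from larvaphen import synthetic_data as sd
from larvaphen.errors import DataError


def constant_session(rate=1.0, n=2, condition="control"):
    return make_startle_session(
        [
            make_trace(np.full(110, rate), subject_id=f"{condition}{i}",
                       condition=condition)
            for i in range(n)
        ]
    )


class TestTapEvents:
    def test_default_train_yields_25_events(self):
        ev = sh.extract_tap_events(constant_session())
        assert ev.groupby("subject_id")["tap"].count().eq(25).all()

    def test_constant_rate_event_distance(self):
        ev = sh.extract_tap_events(constant_session())
        assert np.allclose(ev["distance_mm"], 2.0)

    def test_window_past_trace_end_rejected(self):
        session = make_startle_session([make_trace(np.ones(100))])
        with pytest.raises(DataError, match="past the trace"):
            sh.extract_tap_events(session)

    def test_event_sums_match_bruteforce(self, rng):
        traces = [
            make_trace(rng.gamma(2.0, 1.0, 110), subject_id=f"s{i}")
            for i in range(5)
        ]
        session = make_startle_session(traces)
        ev = sh.extract_tap_events(session).set_index(["subject_id", "tap"])
        for tr in traces:
            for k, (a, b) in enumerate(session.stimuli.windows(), start=1):
                brute = sum(
                    tr.distances[i]
                    for i in range(len(tr))
                    if a <= tr.t0 + i * tr.bin_width < b
                )
                assert ev.loc[(tr.subject_id, k), "distance_mm"] == pytest.approx(
                    brute, rel=1e-12
                )


class TestThresholds:
    def test_constant_baseline_zero_sd(self):
        thr = sh.compute_thresholds(constant_session(rate=1.0))
        assert thr["control"] == pytest.approx(1.0)

    def test_alternating_baseline_closed_form(self):
        # 60 s alternating 0/2 mm: mean 1, sample SD sqrt(60/59)
        d = np.ones(110)
        d[:60] = np.tile([0.0, 2.0], 30)
        session = make_startle_session([make_trace(d)])
        thr = sh.compute_thresholds(session)
        assert thr["control"] == pytest.approx(1.0 + 2.0 * math.sqrt(60.0 / 59.0),
                                               rel=1e-12)

    def test_threshold_scales_with_locomotion(self):
        lo = sh.compute_thresholds(constant_session(rate=0.5))["control"]
        hi = sh.compute_thresholds(constant_session(rate=1.0))["control"]
        assert lo == pytest.approx(hi / 2.0)

    def test_too_few_baseline_bins_rejected(self):
        session = constant_session(n=1)
        with pytest.raises(DataError, match="baseline bins"):
            sh.compute_thresholds(session, (0.0, 5.0))

    def test_baseline_must_precede_stimuli(self):
        with pytest.raises(ValueError, match="precede"):
            sh.compute_thresholds(constant_session(), (0.0, 80.0))


class TestClassification:
    def test_event_above_threshold_is_responder(self):
        ev = pd.DataFrame(
            {"subject_id": ["a"], "condition": ["control"], "tap": [1],
             "distance_mm": [2.0 * 1.5 * 2.0]}
        )
        m = sh.classify_responders(ev, {"control": 1.5})
        assert bool(m.calls["responded"].iloc[0])

    def test_rate_exactly_at_threshold_is_non_responder(self):
        ev = pd.DataFrame(
            {"subject_id": ["a"], "condition": ["control"], "tap": [1],
             "distance_mm": [1.5 * 2.0]}
        )
        m = sh.classify_responders(ev, {"control": 1.5})
        assert not bool(m.calls["responded"].iloc[0])

    def test_missing_threshold_rejected(self):
        ev = pd.DataFrame(
            {"subject_id": ["a"], "condition": ["treated"], "tap": [1],
             "distance_mm": [1.0]}
        )
        with pytest.raises(ValueError, match="treated"):
            sh.classify_responders(ev, {"control": 1.5})

    def test_matrix_matches_bruteforce_loop(self, rng):
        rows = []
        for cond, thr in [("control", 1.2), ("treated", 0.8)]:
            for i in range(6):
                for tap in range(1, 11):
                    rows.append({"subject_id": f"{cond}{i}", "condition": cond,
                                 "tap": tap,
                                 "distance_mm": float(rng.gamma(2.0, 1.2))})
        ev = pd.DataFrame(rows)
        thr = {"control": 1.2, "treated": 0.8}
        m = sh.classify_responders(ev, thr)
        for _, row in m.calls.iterrows():
            expect = (row["distance_mm"] / 2.0) > thr[row["condition"]]
            assert bool(row["responded"]) == expect
        # proportions equal brute-force per condition x tap means
        for (cond, tap), grp in ev.groupby(["condition", "tap"]):
            brute = np.mean(grp["distance_mm"] / 2.0 > thr[cond])
            got = m.proportions.query("condition == @cond and tap == @tap")["p_hat"]
            assert got.iloc[0] == pytest.approx(brute)

    def test_proportions_invariant_to_subject_order(self, rng):
        rows = []
        for i in range(8):
            for tap in range(1, 6):
                rows.append({"subject_id": f"s{i}", "condition": "control",
                             "tap": tap, "distance_mm": float(rng.gamma(2.0, 1.0))})
        ev = pd.DataFrame(rows)
        m1 = sh.classify_responders(ev, {"control": 1.0})
        m2 = sh.classify_responders(ev.iloc[::-1].reset_index(drop=True),
                                    {"control": 1.0})
        pd.testing.assert_frame_equal(m1.proportions, m2.proportions)


class TestHabituationModels:
    def _two_condition_session(self, seed, p_first_treated=None, p_last_treated=None):
        cfg = sd.default_control_config()
        cfg.n_subjects = 12
        cfg.seed = seed
        cfg.conditions = {
            "control": sd.ConditionSpec(),
            "treated": sd.ConditionSpec(
                p_first=p_first_treated, p_last=p_last_treated
            ),
        }
        return sd.simulate_session("startle", cfg)

    def test_constant_p_gives_near_zero_slope(self):
        ests, ses = [], []
        for seed in range(10):
            cfg = sd.default_control_config()
            cfg.n_subjects = 12
            cfg.seed = 600 + seed
            cfg.p_first = cfg.p_last = 0.5
            cfg.conditions = {
                "control": sd.ConditionSpec(),
                "treated": sd.ConditionSpec(),
            }
            session = sd.simulate_session("startle", cfg)
            ev = sh.extract_tap_events(session)
            res = sh.fit_habituation_slope(ev)
            ests.append(res.slopes["control"][0])
        m = np.mean(ests)
        se_m = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(m) < 2 * se_m + 0.005

    def test_slower_habituation_gives_positive_interaction(self):
        # treated keeps responding (p stays high): treated - control slope > 0
        hits = 0
        for seed in range(10):
            session = self._two_condition_session(
                700 + seed, p_first_treated=0.88, p_last_treated=0.6
            )
            ev = sh.extract_tap_events(session)
            res = sh.fit_habituation_slope(ev)
            (c,) = res.contrasts
            hits += c.estimate > 0
        assert hits >= 9

    def test_single_tap_rejected(self):
        ev = pd.DataFrame(
            {"subject_id": ["a", "b"], "condition": ["control", "treated"],
             "tap": [1, 1], "distance_mm": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            sh.fit_habituation_slope(ev)

    def test_responder_curve_interaction_lrt_detects_difference(self):
        session = self._two_condition_session(
            800, p_first_treated=0.88, p_last_treated=0.65
        )
        ev = sh.extract_tap_events(session)
        thr = sh.compute_thresholds(session)
        m = sh.classify_responders(ev, thr)
        res = sh.fit_responder_curve(m)
        assert res.lrt_result[0] >= 0
        assert res.lrt_result[2] < 0.05

    def test_responder_curve_single_condition_rejected(self):
        cfg = sd.default_control_config()
        cfg.n_subjects = 6
        session = sd.simulate_session("startle", cfg)
        ev = sh.extract_tap_events(session)
        m = sh.classify_responders(ev, sh.compute_thresholds(session))
        with pytest.raises(ValueError):
            sh.fit_responder_curve(m)
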