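"""Dependent variables, sign conventions, exclusions, aggregation."""

import numpy as np
import pandas as pd
import pytest

from gazereach.design import BlockKind, Direction
from gazereach.events import DetectionParams, EventSet, Saccade, detect_trial_events
from gazereach.geometry import SampleSeries
from gazereach.metrics import (
    METRIC_COLUMNS,
    anticipatory_deviation,
    apply_exclusions,
    compute_trial_metrics,
    reach_kinematics,
    reactive_deviations,
    summarize,
    TrialMetrics,
)
from gazereach.simulate import (
    CohortParams,
    DisplayGeometry,
    minimum_jerk,
    simulate_trial,
)
from test_simulate import make_spec


def const_gaze(x_val, n=700, rate=250.0):
    t = np.arange(n) / rate
    return SampleSeries(t, {"x": np.full(n, float(x_val)), "y": np.zeros(n)}, rate)


class TestAnticipatoryDeviation:
    def test_sign_follows_eventual_direction(self):
        g = const_gaze(0.5)
        assert anticipatory_deviation(g, 0.0, Direction.RIGHT) == pytest.approx(0.5)
        assert anticipatory_deviation(g, 0.0, Direction.LEFT) == pytest.approx(-0.5)

    def test_window_excludes_post_motion_samples(self):
        t = np.arange(1000) / 250.0
        x = np.where(t < 2.5, 1.0, 50.0)
        g = SampleSeries(t, {"x": x, "y": np.zeros_like(x)}, 250.0)
        assert anticipatory_deviation(g, 0.0, Direction.RIGHT) == pytest.approx(1.0)

    def test_no_valid_samples_absent(self):
        g = const_gaze(np.nan)
        assert anticipatory_deviation(g, 0.0, Direction.RIGHT) is None

    def test_unbiased_noise_free_simulator_gives_exact_zero(self):
        p = CohortParams(
            anticipatory_mean_by_block={b: 0.0 for b in BlockKind},
            anticipatory_sd_between={b: 0.0 for b in BlockKind},
            anticipatory_sd_within=0.0,
            fixation_jitter_sd=0.0,
            exclusion_rate=0.0,
        )
        rec = simulate_trial(make_spec(), params=p, seed=0)
        assert anticipatory_deviation(rec.gaze, 0.0, rec.spec.direction) == 0.0


class TestReactiveDeviations:
    def _events_with_fixation(self, cx, start=3.0, end=3.2, onset=None):
        from gazereach.events import Fixation

        ev = EventSet()
        ev.first_catchup = Saccade(2.8, 2.83, 3.0, 1)
        ev.fixations = [Fixation(start, end, cx, 0.0, 0.1)]
        ev.reach_onset_t = onset
        return ev

    def _target(self, value=0.0):
        t = np.arange(0, 5.0, 0.004)
        return SampleSeries(t, {"x": np.full(t.size, value)}, 250.0)

    def test_centroid_on_midline_zero(self):
        ev = self._events_with_fixation(0.0)
        after, _ = reactive_deviations(ev, self._target(0.0), Direction.RIGHT)
        assert after == pytest.approx(0.0)

    def test_sign_rule_leftward_trial(self):
        """1 cm right of the midline on a leftward trial is trailing (−1)."""
        ev = self._events_with_fixation(1.0, onset=3.1)
        after, at_reach = reactive_deviations(ev, self._target(0.0), Direction.LEFT)
        assert after == pytest.approx(-1.0)
        assert at_reach == pytest.approx(-1.0)

    def test_missing_events_absent(self):
        ev = EventSet()
        after, at_reach = reactive_deviations(ev, self._target(), Direction.RIGHT)
        assert after is None and at_reach is None


class TestReachKinematics:
    def _hand(self, extent=20.0, duration=0.54, start=3.97, rate=100.0):
        # straight 3-D path of total length `extent`, minimum-jerk timed
        t = np.arange(0, 6.0, 1 / rate)
        frac = minimum_jerk(np.clip((t - start) / duration, 0, 1))
        dz = 15.0
        dy = np.sqrt(extent**2 - dz**2)
        wz = dz * (1 - frac) + 0.4
        wy = -dy * (1 - frac)
        ch = {}
        for name in ("wrist", "index", "thumb"):
            ch[f"{name}_x"] = np.zeros_like(t)
            ch[f"{name}_y"] = wy.copy()
            ch[f"{name}_z"] = wz + (8.0 if name == "wrist" else 0.0)
        return SampleSeries(t, ch, rate)

    def test_minimum_jerk_peak_speed_closed_form(self):
        """Peak speed of a 20 cm, 0.54 s minimum-jerk reach is
        1.875 · 20 / 0.54 ≈ 69.4 cm/s."""
        hand = self._hand(extent=20.0, duration=0.54, start=3.97)
        ev = EventSet()
        ev.reach_onset_t = 3.97
        ev.contact_t = 3.97 + 0.54
        peak, duration, latency = reach_kinematics(hand, ev, tone_t=3.0)
        assert peak == pytest.approx(1.875 * 20.0 / 0.54, rel=0.015)
        assert duration == pytest.approx(0.54)
        assert latency == pytest.approx(0.97)

    def test_missing_events_absent(self):
        hand = self._hand()
        assert reach_kinematics(hand, EventSet(), 3.0) == (None, None, None)


class TestExclusions:
    def _target(self, speed=15.0, half_width=36.0, contact=4.5):
        t = np.arange(0, 6.5, 0.004)
        x = speed * np.clip(t - 2.5, 0, contact - 2.5)
        return SampleSeries(t, {"x": x}, 250.0)

    def _events(self, onset=3.97, contact=4.5, contact_x=None):
        ev = EventSet()
        ev.reach_onset_t = onset
        ev.contact_t = contact
        ev.contact_x = 15.0 * (contact - 2.5) if contact_x is None else contact_x
        return ev

    def _apply(self, ev, geometry=None):
        m = TrialMetrics(anticipatory_deviation=0.1)
        return apply_exclusions(
            m, ev, make_spec(), self._target(), geometry or DisplayGeometry()
        )

    def test_reach_before_tone_excluded(self):
        m = self._apply(self._events(onset=2.9))
        assert m.excluded and m.exclusion_reason == "early_reach"

    def test_contact_within_target_extent_kept(self):
        # target centre at contact is 30 cm; 7 cm wide target
        m = self._apply(self._events(contact_x=30.0 + 3.4))
        assert not m.excluded

    def test_contact_outside_target_extent_missed(self):
        m = self._apply(self._events(contact_x=30.0 + 4.1))
        assert m.excluded and m.exclusion_reason == "missed_grasp"

    def test_target_escape_on_narrow_screen(self):
        g = DisplayGeometry(screen_half_width=20.0)
        m = TrialMetrics(anticipatory_deviation=0.1)
        m = apply_exclusions(m, self._events(), make_spec(), self._target(), g)
        assert m.excluded and m.exclusion_reason == "target_escaped"

    def test_missing_contact_is_equipment(self):
        ev = EventSet()
        ev.reach_onset_t = 3.97
        m = self._apply(ev)
        assert m.excluded and m.exclusion_reason == "equipment"


class TestSummarize:
    def _table(self):
        rows = []
        rng = np.random.default_rng(0)
        for p in range(4):
            for b in ("no_bias", "biased_1", "biased_2"):
                for i in range(6):
                    rows.append(
                        {
                            "participant": p,
                            "group": "right" if p % 2 == 0 else "left",
                            "block": b,
                            "trial": i,
                            "direction": "right",
                            "is_distractor": i == 5,
                            **{c: rng.normal() for c in METRIC_COLUMNS},
                            "excluded": i == 4,
                            "exclusion_reason": "early_reach" if i == 4 else "none",
                        }
                    )
        return pd.DataFrame(rows)

    def test_only_included_experimental_trials_count(self):
        s = summarize(self._table())
        assert (s["n_included"] == 4).all()
        assert len(s) == 12

    def test_single_trial_summary_equals_trial(self):
        t = self._table()
        t = t[(t.participant == 0) & (t.block == "no_bias") & (t.trial == 0)]
        s = summarize(t)
        assert len(s) == 1
        for c in METRIC_COLUMNS:
            assert s[c].iloc[0] == pytest.approx(t[c].iloc[0])

    def test_permutation_invariance(self):
        t = self._table()
        shuffled = t.sample(frac=1.0, random_state=7)
        a = summarize(t).sort_values(["participant", "block"]).reset_index(drop=True)
        b = summarize(shuffled).sort_values(["participant", "block"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_each_included_trial_in_exactly_one_summary(self):
        t = self._table()
        s = summarize(t)
        included = (~t.excluded & ~t.is_distractor).sum()
        assert s["n_included"].sum() == included


class TestEndToEndTrial:
    def test_sign_antisymmetry_under_mirroring(self):
        """Mirrored noise-free trials yield identical signed metrics."""
        base = CohortParams()
        sym = {
            (g, b): base.catchup_fixation_offset[(Direction.RIGHT, b)]
            for g in Direction for b in BlockKind
        }
        sym_r = {
            (g, b): base.reach_fixation_offset[(Direction.RIGHT, b)]
            for g in Direction for b in BlockKind
        }
        p = CohortParams(
            fixation_jitter_sd=0.0, hand_noise_sd=0.0, exclusion_rate=0.0,
            catchup_fixation_offset=sym, reach_fixation_offset=sym_r,
        )
        out = {}
        for d in (Direction.RIGHT, Direction.LEFT):
            rec = simulate_trial(make_spec(d), params=p, seed=31)
            ev = detect_trial_events(rec.gaze, rec.hand, 2.5, 3.0)
            out[d] = compute_trial_metrics(rec, ev)
        for c in METRIC_COLUMNS:
            assert getattr(out[Direction.RIGHT], c) == pytest.approx(
                getattr(out[Direction.LEFT], c), abs=1e-6
            )

    def test_injected_corruption_recovered_with_reason(self, small_cohort_trials):
        t = small_cohort_trials
        corrupt = t[t.gt_corruption != "none"]
        assert len(corrupt) > 0
        assert corrupt.excluded.all()
        assert (corrupt.exclusion_reason == corrupt.gt_corruption).all()

    def test_exclusion_fraction_near_generator_rate(self, small_cohort_trials):
        exp = small_cohort_trials[~small_cohort_trials.is_distractor]
        frac = exp.excluded.mean()
        n = len(exp)
        tol = 3 * np.sqrt(0.061 * 0.939 / n)
        assert abs(frac - 0.061) < tol + 0.01

    def test_anticipatory_metric_recovers_injected_offsets(self, small_cohort_trials):
        t = small_cohort_trials[~small_cohort_trials.is_distractor]
        err = t.anticipatory_deviation - t.gt_anticipatory_offset
        assert err.abs().max() < 0.02  # jitter-average noise only
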