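"""Offset correction, dive delimitation, wiggles/steps, phases, exclusions."""

import numpy as np
import pytest

import oracles
from sealdive import segmentation as seg
from sealdive.simulate import (SimConfig, StepSpec, WiggleSpec,
                               simulate_deployment, simulate_dive_profile)


def trapezoid_dive(depth_m=100.0, flat_s=800, ramp_speed=1.0, pad_s=100):
    """Surface - constant-speed descent - flat - ascent - surface."""
    ramp = int(depth_m / ramp_speed)
    prof = np.concatenate([
        np.zeros(pad_s),
        np.arange(1, ramp + 1) * ramp_speed,
        np.full(flat_s, depth_m),
        depth_m - np.arange(1, ramp + 1) * ramp_speed,
        np.zeros(pad_s),
    ])
    return prof


class TestZeroOffset:
    def test_no_drift_is_near_identity(self, deployment12):
        cfg, dep, truth = deployment12
        raw = np.round(truth.depth_true_m / 0.5) * 0.5
        corrected, _ = seg.zero_offset_correct(raw)
        assert np.max(np.abs(corrected - raw)) <= 0.5

    def test_constant_offset_recovered(self, deployment12):
        _, _, truth = deployment12
        raw = np.round(truth.depth_true_m / 0.5) * 0.5 + 2.0
        corrected, offset = seg.zero_offset_correct(raw)
        surface = corrected[raw - 2.0 < 0.5]
        assert np.median(offset) == pytest.approx(2.0, abs=0.5)
        assert np.max(np.abs(surface)) <= 0.5

    def test_linear_drift_followed(self):
        # 12 h of dives under a 1 m/h ramp: corrected surfaces within 0.75 m
        cfg = SimConfig(seed=5, n_dives=35, pressure_drift_m_per_h=1.0)
        dep, truth = simulate_deployment(cfg)
        corrected, _ = seg.zero_offset_correct(dep.depth.values)
        surface_mask = truth.depth_true_m < 0.25
        assert np.max(np.abs(corrected[surface_mask])) <= 0.75


class TestDetectDives:
    def test_shallow_profile_no_dives(self):
        assert seg.detect_dives(np.full(1000, 10.0)) == []

    def test_trapezoid_exact_boundaries(self):
        prof = trapezoid_dive(depth_m=100, flat_s=800, ramp_speed=1.0)
        dives = seg.detect_dives(prof)
        assert len(dives) == 1
        d = dives[0]
        # depth exceeds 15 m from sample pad+16 (16 m) on the 1 m/s ramp
        assert prof[d.start_s] > 15 and prof[d.start_s - 1] <= 15
        assert prof[d.end_s - 1] > 15 and prof[d.end_s] <= 15
        assert d.excluded is None

    @pytest.mark.parametrize("flat_s,flag", [
        (200, "too_short"),      # ~400 s dive
        (1800, "too_long"),      # ~2000 s dive
        (700, None),
    ])
    def test_duration_bounds(self, flat_s, flag):
        prof = trapezoid_dive(depth_m=100, flat_s=flat_s, ramp_speed=1.0)
        (dive,) = seg.detect_dives(prof)
        assert dive.excluded == flag

    def test_correction_then_detection_idempotent(self, deployment12):
        _, dep, _ = deployment12
        corrected, _ = seg.zero_offset_correct(dep.depth.values)
        once = [(d.start_s, d.end_s) for d in seg.detect_dives(corrected)]
        corrected2, _ = seg.zero_offset_correct(corrected)
        twice = [(d.start_s, d.end_s) for d in seg.detect_dives(corrected2)]
        # re-correction may nudge the sub-resolution baseline; threshold
        # crossings move by at most one sample
        assert len(once) == len(twice)
        for (a0, b0), (a1, b1) in zip(once, twice):
            assert abs(a0 - a1) <= 1 and abs(b0 - b1) <= 1


class TestVerticalSpeed:
    def test_linear_descent_and_ascent(self):
        down = np.arange(0, 100, 1.0)
        up = np.arange(100, 0, -0.8)
        assert seg.vertical_speed(down)[5:-5] == pytest.approx(1.0)
        assert seg.vertical_speed(up)[5:-5] == pytest.approx(-0.8)

    def test_matches_oracle(self, rng):
        d = np.cumsum(rng.uniform(-1, 1, 300))
        np.testing.assert_allclose(seg.vertical_speed(d),
                                   oracles.smoothed_speed(d), atol=1e-12)


class TestWigglesSteps:
    def test_v_shaped_dive_has_no_events(self):
        depth, _ = simulate_dive_profile(700, 300.0)
        dmask = depth > 15
        a, b = np.where(dmask)[0][[0, -1]]
        events = seg.find_wiggles_steps(depth[a:b + 1])
        assert events == []

    def test_single_wiggle_recovered_within_2s(self):
        depth, truth = simulate_dive_profile(
            900, 300.0, wiggles=(WiggleSpec(60, 30, 15.0),))
        a = int(np.where(depth > 15)[0][0])
        b = int(np.where(depth > 15)[0][-1]) + 1
        events = [e for e in seg.find_wiggles_steps(depth[a:b])
                  if e.kind == "wiggle"]
        assert len(events) == 1
        wa, wb = truth["wiggles"][0]
        assert abs((events[0].start_s + a) - wa) <= 2
        assert abs((events[0].end_s + a) - wb) <= 2

    def test_step_covered_at_least_90pct(self):
        depth, truth = simulate_dive_profile(
            900, 300.0, steps=(StepSpec(60, 30, 0.2),))
        a = int(np.where(depth > 15)[0][0])
        b = int(np.where(depth > 15)[0][-1]) + 1
        steps = [e for e in seg.find_wiggles_steps(depth[a:b]) if e.kind == "step"]
        sa, sb = truth["steps"][0]
        covered = sum(min(sb, e.end_s + a) - max(sa, e.start_s + a)
                      for e in steps if e.end_s + a > sa and e.start_s + a < sb)
        assert covered >= 0.9 * (sb - sa)

    def test_step_speed_bound_asserted(self):
        with pytest.raises(ValueError, match=r"0, 0.35|0.35"):
            simulate_dive_profile(900, 300.0, steps=(StepSpec(60, 30, 0.4),))

    def test_reported_events_satisfy_definitions(self, analysis12):
        for dv in analysis12.dives:
            d = analysis12.depth_corrected[dv.start_s:dv.end_s]
            vs = seg.vertical_speed(d)
            for e in dv.events:
                s, t = e.start_s - dv.start_s, e.end_s - dv.start_s
                if e.kind == "wiggle":
                    # a wiggle holds an interior local depth maximum
                    assert np.any(np.diff(np.sign(vs[s:t])) < 0)
                else:
                    assert np.all((vs[s:t] > 0) & (vs[s:t] < 0.35))


class TestDelimit:
    def test_deep_wiggle_bounds_bottom(self):
        depth, truth = simulate_dive_profile(
            900, 300.0, wiggles=(WiggleSpec(80, 30, 15.0),))
        a = int(np.where(depth > 15)[0][0])
        b = int(np.where(depth > 15)[0][-1]) + 1
        d = depth[a:b]
        events = seg.find_wiggles_steps(d)
        phases, fallback = seg.delimit_bottom(d, events)
        assert not fallback
        bot = phases[1]
        w = [e for e in events if e.kind == "wiggle"][0]
        assert (bot.start_s, bot.end_s) == (w.start_s, w.end_s)

    def test_shallow_wiggle_triggers_fallback(self):
        # wiggle on the descent at ~50% of max depth: not a qualifying event
        ramp = np.arange(1, 301, 1.0)
        wig = 150 + 10 * np.sin(np.pi * np.arange(30) / 30)
        prof = np.concatenate([ramp[:150], wig, ramp[150:], np.full(200, 300.0),
                               ramp[::-1]])
        events = seg.find_wiggles_steps(prof)
        phases, fallback = seg.delimit_bottom(prof, events)
        assert fallback
        assert prof[phases[1].start_s] > 0.75 * prof.max()

    def test_partition_is_exact(self, analysis12):
        for dv in analysis12.dives:
            kinds = [p.kind for p in dv.phases]
            assert kinds == ["descent", "bottom", "ascent"]
            assert dv.phases[0].start_s == dv.start_s
            assert dv.phases[2].end_s == dv.end_s
            for p0, p1 in zip(dv.phases, dv.phases[1:]):
                assert p0.end_s == p1.start_s


class TestDriftFlag:
    def test_synthetic_drift_dive_flagged(self, deployment12, analysis12):
        _, _, truth = deployment12
        flags = [dv.excluded == "drift" for dv in analysis12.dives]
        assert flags == truth.drift_flags

    def test_short_low_effort_segment_not_flagged(self):
        vs = np.full(400, 0.3)
        eff = np.full(400, 0.2)
        eff[:100] = 0.0                      # only 100 s of passivity
        assert not seg.flag_drift_dive(vs, eff, effort_p10=0.01)

    def test_active_dive_not_flagged(self):
        vs = np.full(600, 1.5)
        eff = np.full(600, 0.2)
        assert not seg.flag_drift_dive(vs, eff, effort_p10=0.01)

    def test_constructed_drift_segment_flagged(self):
        vs = np.full(600, 0.3)
        eff = np.zeros(600)
        assert seg.flag_drift_dive(vs, eff, effort_p10=0.01)


class TestOracleEquivalence:
    def test_full_segmentation_matches_bruteforce(self):
        """Boundaries, events and phases equal an independent oracle, 100 dives."""
        n_checked = 0
        for s in range(4):
            cfg = SimConfig(seed=900 + s, n_dives=30, drift_dive_every=None)
            dep, _ = simulate_deployment(cfg)
            corrected, _ = seg.zero_offset_correct(dep.depth.values)
            dives = seg.detect_dives(corrected)
            assert [(d.start_s, d.end_s) for d in dives] == \
                oracles.dive_boundaries(corrected)
            for dv in dives:
                d = corrected[dv.start_s:dv.end_s]
                events = seg.find_wiggles_steps(d)
                ow, os_ = oracles.wiggles_steps(d)
                assert [(e.start_s, e.end_s) for e in events
                        if e.kind == "wiggle"] == ow
                assert [(e.start_s, e.end_s) for e in events
                        if e.kind == "step"] == os_
                phases, fb = seg.delimit_bottom(d, events)
                od, ob, oa, ofb = oracles.three_phases(list(d), ow, os_)
                assert fb == ofb
                assert (phases[0].start_s, phases[0].end_s) == od
                assert (phases[1].start_s, phases[1].end_s) == ob
                assert (phases[2].start_s, phases[2].end_s) == oa
                n_checked += 1
            if n_checked >= 100:
                break
        assert n_checked >= 100

    def test_truth_bottom_mostly_inside_delimited_bottom(self, deployment12,
                                                         analysis12):
        _, _, truth = deployment12
        tot = ins = 0
        for ph, drift in zip(truth.phases, truth.drift_flags):
            if ph is None or drift:
                continue
            a, b = ph["bottom"]
            for dv in analysis12.dives:
                if dv.start_s <= a < dv.end_s:
                    bot = dv.phases[1]
                    tot += b - a
                    ins += max(0, min(b, bot.end_s) - max(a, bot.start_s))
        assert ins / tot >= 0.90
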