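"""Event detection, strength tiering, Bhattacharyya overlap, and
acoustic-control subsets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from salieeg.salience_events import (bhattacharyya, detect_events,
                                     erb_bandwidth, exclusion_subsets,
                                     feature_at_events, score_and_tier)
from salieeg.types import SalienceCurve


def _sigmoid_curve(center=30.0, dur=60.0, fs=10.0, h=0.5, tau=0.4):
    t = np.arange(int(dur * fs)) / fs
    return SalienceCurve(h / (1 + np.exp(-(t - center) / tau)), fs)


class TestDetectEvents:
    def test_single_sigmoid_detected_at_center(self):
        ev = detect_events(_sigmoid_curve(center=30.0))
        assert len(ev) == 1
        assert abs(ev["time"].iloc[0] - 30.0) <= 0.5  # 1 s smoothing shift

    def test_monotone_ramp_yields_no_event(self):
        t = np.linspace(0, 1, 600)
        ev = detect_events(SalienceCurve(t, 10.0))
        assert len(ev) == 0

    def test_two_rises_ten_seconds_apart(self):
        t = np.arange(600) / 10.0
        v = 0.4 / (1 + np.exp(-(t - 20) / 0.3)) \
            + 0.4 / (1 + np.exp(-(t - 30) / 0.3))
        ev = detect_events(SalienceCurve(v, 10.0))
        assert len(ev) == 2
        assert abs(ev["time"].iloc[0] - 20) < 1 and \
            abs(ev["time"].iloc[1] - 30) < 1

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError, match="empty"):
            detect_events(SalienceCurve(np.array([]), 10.0))


class TestScoreAndTier:
    def test_tertiles_of_351_events_have_117_each(self):
        rng = np.random.default_rng(0)
        ev = pd.DataFrame({"time": np.arange(351.0),
                           "slope": rng.uniform(0.01, 0.2, 351),
                           "peak": rng.uniform(0.2, 1.0, 351),
                           "scene": 0})
        out = score_and_tier(ev)
        assert out["tier"].value_counts().to_dict() == \
            {"high": 117, "mid": 117, "low": 117}

    def test_identical_events_get_equal_strength_stable_tiers(self):
        ev = pd.DataFrame({"time": [1.0, 2.0, 3.0], "slope": 0.1,
                           "peak": 0.5, "scene": 0})
        out = score_and_tier(ev)
        assert np.allclose(out["strength"], out["strength"].iloc[0])
        assert list(out["tier"]) == ["high", "mid", "low"]  # stable order

    def test_doubling_one_slope_raises_its_rank(self):
        rng = np.random.default_rng(1)
        ev = pd.DataFrame({"time": np.arange(30.0),
                           "slope": rng.uniform(0.05, 0.1, 30),
                           "peak": rng.uniform(0.4, 0.6, 30), "scene": 0})
        before = score_and_tier(ev)
        ev2 = ev.copy()
        ev2.loc[7, "slope"] *= 2
        after = score_and_tier(ev2)
        rank_b = (before["strength"] > before["strength"].iloc[7]).sum()
        rank_a = (after["strength"] > after["strength"].iloc[7]).sum()
        assert rank_a < rank_b

    def test_strength_invariant_to_affine_curve_rescale(self):
        rng = np.random.default_rng(2)
        ev = pd.DataFrame({"time": np.arange(12.0),
                           "slope": rng.uniform(0.05, 0.2, 12),
                           "peak": rng.uniform(0.3, 0.9, 12), "scene": 0})
        scaled = ev.assign(slope=ev["slope"] * 3 + 0.0,
                           peak=ev["peak"] * 3)  # z-scoring absorbs scale
        np.testing.assert_allclose(score_and_tier(ev)["strength"],
                                   score_and_tier(scaled)["strength"],
                                   atol=1e-12)

    def test_fewer_than_three_events_flagged(self):
        ev = pd.DataFrame({"time": [1.0], "slope": [0.1], "peak": [0.5],
                           "scene": 0})
        with pytest.raises(ValueError, match="3 events"):
            score_and_tier(ev)


class TestBhattacharyya:
    def test_identical_samples_give_one(self, rng):
        a = rng.standard_normal(500)
        assert bhattacharyya(a, a) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert bhattacharyya(np.zeros(50), np.ones(50) * 10, bins=4) == 0.0

    def test_half_overlap_two_bins_equals_sqrt_half(self):
        # a uniform on [0, 1), b uniform on [1, 2); with 2 bins over [0, 2]
        # p = (1, 0), q = (.5, .5) gives sum sqrt(p q) = sqrt(.5)
        a = np.linspace(0.0, 0.999, 200)
        b = np.concatenate([np.linspace(0.0, 0.999, 100),
                            np.linspace(1.001, 2.0, 100)])
        bc = bhattacharyya(a, b, bins=2)
        assert bc == pytest.approx(np.sqrt(0.5), abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 30))
    def test_bounds_and_symmetry(self, seed, bins):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(40), r.standard_normal(40) + r.uniform(0, 3)
        bc = bhattacharyya(a, b, bins)
        assert 0.0 <= bc <= 1.0 + 1e-12
        assert bc == pytest.approx(bhattacharyya(b, a, bins))


class TestExclusions:
    @pytest.fixture()
    def toy(self):
        t = np.arange(0, 100, 0.1)
        events = pd.DataFrame({"time": np.arange(8) * 10.0 + 5.0,
                               "slope": 0.1, "peak": 0.5, "scene": 0})
        rng = np.random.default_rng(0)
        tracks = pd.DataFrame({c: rng.standard_normal(len(t)) for c in
                               ("loudness", "brightness", "harmonicity",
                                "pitch", "scale", "erb440")})
        tracks.insert(0, "time", t)
        return events, tracks

    def test_loudness_exclusion_drops_quarter(self, toy):
        events, tracks = toy
        subs = exclusion_subsets(events, tracks)
        assert len(subs["loudness_excluded"]) == 6

    def test_median_splits_are_balanced(self, toy):
        events, tracks = toy
        subs = exclusion_subsets(events, tracks)
        assert len(subs["harmonicity_low"]) == 4
        assert len(subs["harmonicity_high"]) == 4

    def test_erb_exclusion_independent_of_broadband_loudness(self, toy):
        events, tracks = toy
        # event 0 is loudest in broadband but quietest in the ERB band
        tracks.loc[:, "loudness"] = 0.0
        tracks.loc[tracks["time"].between(4, 6), "loudness"] = 10.0
        tracks.loc[:, "erb440"] = 1.0
        tracks.loc[tracks["time"].between(4, 6), "erb440"] = -10.0
        subs = exclusion_subsets(events, tracks)
        assert 5.0 not in subs["loudness_excluded"]["time"].values
        assert 5.0 in subs["erb440_excluded"]["time"].values

    def test_too_few_events_error(self, toy):
        _, tracks = toy
        with pytest.raises(ValueError, match="< 4"):
            exclusion_subsets(pd.DataFrame({"time": [1.0]}), tracks)


def test_erb_bandwidth_at_440_is_about_72_hz():
    assert erb_bandwidth(440.0) == pytest.approx(72.2, abs=1.0)


def test_feature_at_events_window_mean():
    track = pd.DataFrame({"time": np.arange(0, 10, 0.1),
                          "loudness": np.arange(100, dtype=float)})
    v = feature_at_events(pd.DataFrame({"time": [5.0]}), track, "loudness")
    assert v[0] == pytest.approx(50.0, abs=1.0)
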