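"""Generator-level checks: construction identities, determinism, and
parameter recovery through the downstream estimators."""

import numpy as np
import pandas as pd
import pytest

from thermoniche import synth
from thermoniche.synth import (CaptureSimConfig, CommunitySimConfig,
                               SensorSimConfig, SpeciesProfile, StackGeometry,
                               TraceSimConfig, simulate_captures,
                               simulate_community, simulate_flight_trace,
                               simulate_frame_stack, simulate_sensor_log)
from thermoniche.thermal_niche import compute_endothermy, fit_slope
from thermoniche.thermal_niche import FlightTraces
from thermoniche.thermography import extract_roi_trace
from thermoniche.community import AbundanceMatrix, indval


def as_flight_traces(fts, species="sp"):
    return FlightTraces(individual_id="i0", species=species, mass=0.3,
                        activity="diurnal", habitat="native_forest",
                        window=fts.window, t_th=fts.t_th, t_abd=fts.t_abd,
                        t_env=fts.t_env)


class TestFlightTrace:
    def test_noise_free_endothermy_is_exact(self, noise_free_flight):
        """With no noise and saturated warm-up, mean(T_th - T_env) over the
        flight window equals the planted excess temperature."""
        ft = as_flight_traces(noise_free_flight)
        assert compute_endothermy(ft) == pytest.approx(5.0, abs=1e-3)

    def test_planted_slope_recovered_by_ols(self):
        """A planted thorax cooling trend is recovered by the slope fit to
        within the closed-form OLS standard error."""
        # fast warm-up so the trend inside the flight window is purely linear
        profile = SpeciesProfile(name="cooling", slope_th_true=-0.003,
                                 warmup_rate=5.0, noise_sd=0.1,
                                 mechanism_true="NONE")
        cfg = TraceSimConfig(seed=7)
        fts = simulate_flight_trace(profile, cfg)
        slope = fit_slope(fts.t_th, fts.window)
        t = cfg.times
        mask = fts.window.mask(t)
        tw = t[mask]
        se = 0.1 / np.sqrt(np.sum((tw - tw.mean()) ** 2))
        assert slope == pytest.approx(-0.003, abs=4 * se)

    def test_same_seed_bit_identical(self):
        profile = SpeciesProfile(name="sp", noise_sd=0.3)
        a = simulate_flight_trace(profile, TraceSimConfig(seed=42))
        b = simulate_flight_trace(profile, TraceSimConfig(seed=42))
        for ta, tb in zip(a.traces(), b.traces()):
            np.testing.assert_array_equal(ta.values, tb.values)

    def test_truth_records_parameters(self, noise_free_flight):
        truth = noise_free_flight.truth
        assert truth["profile_endothermy_true"] == 5.0
        assert truth["cfg_seed"] == 0
        assert truth["n_frames_in_window"] > 1000

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            SpeciesProfile(name="bad", endothermy_true=float("nan"))
        with pytest.raises(ValueError):
            TraceSimConfig(duration=float("inf"))

    def test_duration_below_40s_rejected(self):
        with pytest.raises(ValueError):
            TraceSimConfig(duration=30.0)

    def test_mechanism_profile_invariants(self):
        with pytest.raises(ValueError):
            SpeciesProfile(name="bad", mechanism_true="APHT",
                           slope_th_true=0.01, slope_abd_true=0.01)
        with pytest.raises(ValueError):
            SpeciesProfile(name="bad", mechanism_true="AAHT",
                           slope_th_true=-0.01, slope_abd_true=0.01)

    def test_endothermy_recovery_mae_bound(self):
        """Over 200 noisy individuals the mean absolute error of recovered
        endothermy stays below 3 * noise_sd / sqrt(n_frames in window)."""
        profile = SpeciesProfile(name="sp", endothermy_true=4.0,
                                 warmup_rate=5.0, noise_sd=0.3)
        errors = []
        for seed in range(200):
            fts = simulate_flight_trace(profile, TraceSimConfig(seed=seed))
            est = compute_endothermy(as_flight_traces(fts))
            errors.append(abs(est - fts.truth["expected_endothermy"]))
        n_frames = fts.truth["n_frames_in_window"]
        # endothermy averages the difference of two noisy traces: the
        # per-sample SD is sqrt(2)*noise_sd, comfortably under the 3x bound
        assert np.mean(errors) < 3 * 0.3 / np.sqrt(n_frames)


class TestFrameStack:
    def test_patch_max_equals_trace_value(self, noise_free_flight):
        stack, rois = simulate_frame_stack(noise_free_flight, seed=3)
        thorax = next(r for r in rois if r.label == "thorax")
        k = 100
        r0, r1, c0, c1 = thorax.bounds()
        assert stack.frames[k, r0:r1, c0:c1].max() == pytest.approx(
            noise_free_flight.t_th.values[k])

    def test_round_trip_identity_at_zero_noise(self, noise_free_flight):
        stack, rois = simulate_frame_stack(noise_free_flight, seed=3)
        for roi, trace in zip(sorted(rois, key=lambda r: r.label),
                              sorted(noise_free_flight.traces(),
                                     key=lambda t: t.roi_label)):
            rec = extract_roi_trace(stack, roi)
            np.testing.assert_allclose(rec.values, trace.values)

    def test_one_pixel_jitter_absorbed(self, noise_free_flight):
        """Patches jittered +/-1 px are still recovered exactly by the max
        over the 3x3 window at the exact centers."""
        geom = StackGeometry(jitter_px=1)
        stack, rois = simulate_frame_stack(noise_free_flight, geom, seed=3)
        thorax = next(r for r in rois if r.label == "thorax")
        rec = extract_roi_trace(stack, thorax)
        np.testing.assert_allclose(rec.values, noise_free_flight.t_th.values)

    def test_overlapping_patches_rejected(self, noise_free_flight):
        geom = StackGeometry(centers={"thorax": (20, 20), "abdomen": (20, 22),
                                      "environment": (45, 60)})
        with pytest.raises(ValueError, match="overlap"):
            simulate_frame_stack(noise_free_flight, geom)

    def test_mismatched_time_base_rejected(self, noise_free_flight):
        other = simulate_flight_trace(
            SpeciesProfile(name="sp"), TraceSimConfig(frame_rate=10.0))
        with pytest.raises(ValueError, match="time base"):
            simulate_frame_stack([noise_free_flight.t_th,
                                  noise_free_flight.t_abd, other.t_env])


class TestCommunityCapturesSensor:
    def test_perfect_indicator_scores_100(self):
        """A species with all abundance in habitat 1 and present at all of
        its sites gets IndVal exactly 100 downstream."""
        counts, hab, _ = simulate_community(CommunitySimConfig(seed=0))
        counts["planted"] = 0
        counts.loc[hab == "native_forest", "planted"] = 10
        iv = indval(AbundanceMatrix(counts=counts, habitat_of_site=hab),
                    n_permutations=99, seed=0)
        row = iv[(iv.species == "planted") & (iv.habitat == "native_forest")]
        assert row["indval"].iloc[0] == 100.0

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            CommunitySimConfig(sites_per_habitat=1)
        with pytest.raises(ValueError):
            CaptureSimConfig(total_captures=0)
        with pytest.raises(ValueError):
            SensorSimConfig(interval_minutes=7)

    def test_capture_period_share_matches_planted_fraction(self):
        """diurnal_fraction=0.9, 100 captures: period-1 share lands within
        binomial tolerance of 90% and the truth sidecar matches the data."""
        pool = [SpeciesProfile(name="d", activity_true="diurnal")]
        captures, truth = simulate_captures(
            CaptureSimConfig(total_captures=100, seed=5), species_pool=pool,
            diurnal_fraction={"d": 0.9})
        ts = pd.to_datetime(captures["timestamp"])
        hours = ts.dt.hour + ts.dt.minute / 60.0
        share = ((hours >= 7) & (hours < 18)).mean()
        assert truth["n_period1"].iloc[0] == int(round(share * 100))
        assert abs(share - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 100)

    def test_sensor_amplitude_construction(self):
        log, truth = simulate_sensor_log(
            SensorSimConfig(diel_amplitude=10.5, noise_sd=0.0))
        assert truth["amplitude"] == pytest.approx(21.0)

    def test_seeded_reproducibility(self):
        a, _ = simulate_sensor_log(SensorSimConfig(seed=9))
        b, _ = simulate_sensor_log(SensorSimConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)
        ca, _, _ = simulate_community(CommunitySimConfig(seed=9))
        cb, _, _ = simulate_community(CommunitySimConfig(seed=9))
        pd.testing.assert_frame_equal(ca, cb)


def test_default_pool_mirrors_reference_table():
    pool = synth.default_species_pool()
    ref = synth.load_species_reference()
    assert len(pool) == len(ref) == 17
    by_name = {p.name: p for p in pool}
    saph = by_name["Coprophanaeus saphirinus"]
    assert saph.mechanism_true == "APHT"
    assert saph.endothermy_true == pytest.approx(7.254)
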