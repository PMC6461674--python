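"""Crosstalk corrections, FRET computation and parameter estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from trifret.correction import (
    CorrectionParams, apply_corrections, compute_fret, estimate_corrections,
)
from trifret.synthetic import (
    EventTimeline, KineticConfig, PhotoConfig, ground_truth_table, render_traces,
)
from trifret.trace_io import AlexSeries, Manifest, pair_alex_frames


def alex_from_rows(rows):
    cols = ["molecule_id", "time_s", "I532_cy3", "I532_cy5", "I532_a750",
            "I638_cy5", "I638_a750"]
    return AlexSeries(pd.DataFrame(rows, columns=cols))


class TestComputeFret:
    @pytest.mark.parametrize("i532, expected", [
        ((30.0, 50.0, 20.0), 0.70),
        ((100.0, 0.0, 0.0), 0.0),     # donor-only
        ((0.0, 60.0, 40.0), 1.0),
    ])
    def test_exit_side_arithmetic(self, i532, expected):
        a = alex_from_rows([(0, 0.0, *i532, 25.0, 75.0)])
        fret = compute_fret(a, denom_floor=1.0)
        assert fret.frames["E_exit"].iloc[0] == pytest.approx(expected)

    def test_entry_side_arithmetic(self):
        a = alex_from_rows([(0, 0.0, 30.0, 50.0, 20.0, 25.0, 75.0)])
        fret = compute_fret(a, denom_floor=1.0)
        assert fret.frames["E_entry"].iloc[0] == pytest.approx(0.75)

    def test_low_denominator_flagged_not_dropped(self):
        a = alex_from_rows([(0, 0.0, 0.1, 0.1, 0.1, 0.1, 0.1)])
        fret = compute_fret(a, denom_floor=10.0)
        assert len(fret.frames) == 1
        assert not fret.frames["exit_valid"].iloc[0]
        assert not fret.frames["entry_valid"].iloc[0]
        assert math.isnan(fret.frames["E_exit"].iloc[0])

    @given(c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        base = (30.0, 50.0, 20.0, 25.0, 75.0)
        a = alex_from_rows([(0, 0.0, *base)])
        b = alex_from_rows([(0, 0.0, *(c * v for v in base))])
        fa = compute_fret(a, denom_floor=1e-9).frames
        fb = compute_fret(b, denom_floor=1e-9).frames
        assert fa["E_exit"].iloc[0] == pytest.approx(fb["E_exit"].iloc[0])
        assert fa["E_entry"].iloc[0] == pytest.approx(fb["E_entry"].iloc[0])

    def test_out_of_range_raises(self):
        # valid denominator but E_exit = 1 - 200/80 = -1.5, far beyond noise
        a = alex_from_rows([(0, 0.0, 200.0, -60.0, -60.0, 25.0, 75.0)])
        with pytest.raises(ValueError, match="hard range"):
            compute_fret(a, denom_floor=1.0)


class TestApplyCorrections:
    def test_zero_params_identity(self):
        a = alex_from_rows([(0, 0.0, 30.0, 50.0, 20.0, 25.0, 75.0)])
        out = apply_corrections(a, CorrectionParams()).frames
        for c in ("I532_cy3", "I532_cy5", "I532_a750", "I638_cy5", "I638_a750"):
            assert out[c].iloc[0] == a.frames[c].iloc[0]

    def test_all_zero_record_stays_zero(self):
        a = alex_from_rows([(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)])
        params = CorrectionParams(d_cy5_532=0.05, d_a750_638=0.05,
                                  b_cy3_to_cy5=0.1, b_cy5_to_a750=0.1,
                                  s_cy3=0.8, s_a750=1.25)
        out = apply_corrections(a, params).frames
        for c in ("I532_cy3", "I532_cy5", "I532_a750", "I638_cy5", "I638_a750"):
            assert out[c].iloc[0] == 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CorrectionParams(b_cy3_to_cy5=1.0)
        with pytest.raises(ValueError):
            CorrectionParams(s_cy3=0.0)


class TestRoundTrip:
    def test_noiseless_corrections_recover_ideal_split(self, noiseless_dataset):
        """Corrected 532 intensities equal the ideal cascade split to 1e-9."""
        timelines, traces, _, photo = noiseless_dataset
        aligned = pair_alex_frames(traces)
        corr = apply_corrections(aligned, photo.to_correction_params())
        N = photo.photon_budget
        tl = timelines[0]
        g = corr.molecule(tl.molecule_id)
        t532 = g["time_532_s"].to_numpy()
        e1 = tl.e1(t532)
        e2_532 = tl.e2(t532)
        np.testing.assert_allclose(g["I532_cy3"], N * (1 - e1), atol=1e-9 * N)
        # the per-channel identity needs E2 constant across the ALEX cycle
        # (the direct-excitation reference comes from the 638 half-frame);
        # the residuals cancel exactly in the FRET ratios either way
        flat = e2_532 == tl.e2(g["time_638_s"].to_numpy())
        np.testing.assert_allclose(g["I532_cy5"][flat],
                                   (N * e1 * (1 - e2_532))[flat], atol=1e-9 * N)
        np.testing.assert_allclose(g["I532_a750"][flat],
                                   (N * e1 * e2_532)[flat], atol=1e-9 * N)

    def test_full_round_trip_reproduces_ground_truth(self, noiseless_dataset):
        """render -> correct -> FRET equations returns E1(t), E2(t) to 1e-9."""
        timelines, traces, _, photo = noiseless_dataset
        aligned = pair_alex_frames(traces)
        corr = apply_corrections(aligned, photo.to_correction_params())
        fret = compute_fret(corr, denom_floor=1e-6)
        for tl in timelines:
            g = fret.molecule(tl.molecule_id)
            np.testing.assert_allclose(
                g["E_exit"], tl.e1(g["time_532_s"].to_numpy()), atol=1e-9)
            np.testing.assert_allclose(
                g["E_entry"], tl.e2(g["time_638_s"].to_numpy()), atol=1e-9)


def calibration_dataset(photo, duration=120.0, seed=0):
    """Static-FRET molecules with staggered bleach orders covering every
    segment type the estimator needs."""
    cfg = KineticConfig(seed=seed, n_molecules=1)
    inf = math.inf
    plans = [
        # (bleach_cy3, bleach_cy5, bleach_a750)
        (inf, 40.0, inf),    # Cy5 first: b_cy3_to_cy5, g_cy3 step, d_a750_638
        (inf, 40.0, inf),
        (inf, inf, 40.0),    # A750 first: b_cy5_to_a750, g_a750 step
        (inf, inf, 40.0),
        (40.0, inf, inf),    # Cy3 first: d_cy5_532
        (40.0, inf, inf),
        (80.0, 30.0, 60.0),  # everything dies: backgrounds
        (80.0, 30.0, 60.0),
    ]
    timelines = [
        EventTimeline(i, 1e6, 1.0, cfg, b3, b5, b7)
        for i, (b3, b5, b7) in enumerate(plans)
    ]
    rng = np.random.default_rng(seed)
    traces = render_traces(timelines, photo, Manifest(), rng, duration_s=duration)
    return timelines, traces, ground_truth_table(timelines)


class TestEstimateCorrections:
    def test_noiseless_estimates_are_exact(self):
        photo = PhotoConfig.noiseless()
        _, traces, truth = calibration_dataset(photo)
        res = estimate_corrections(traces, truth)
        p, want = res.params, photo.to_correction_params()
        for f in ("d_cy5_532", "d_a750_638", "b_cy3_to_cy5", "b_cy5_to_a750",
                  "s_cy3", "s_a750"):
            assert getattr(p, f) == pytest.approx(getattr(want, f), abs=1e-6), f
        assert not res.defaulted

    def test_noisy_bleedthrough_within_tolerance(self):
        photo = PhotoConfig()  # b_cy3_to_cy5 = 0.10 with default noise
        _, traces, truth = calibration_dataset(photo, seed=4)
        res = estimate_corrections(traces, truth)
        assert res.params.b_cy3_to_cy5 == pytest.approx(0.10, abs=0.01)
        assert res.params.b_cy5_to_a750 == pytest.approx(0.10, abs=0.01)
        assert res.params.d_cy5_532 == pytest.approx(0.05, abs=0.01)
        assert res.backgrounds["cy3"] == pytest.approx(photo.bg_cy3, abs=1.0)

    def test_zero_crosstalk_estimates_near_zero(self):
        photo = PhotoConfig(d_cy5_532=0.0, d_a750_638=0.0,
                            b_cy3_to_cy5=0.0, b_cy5_to_a750=0.0)
        _, traces, truth = calibration_dataset(photo, seed=6)
        res = estimate_corrections(traces, truth)
        for f in ("d_cy5_532", "d_a750_638", "b_cy3_to_cy5", "b_cy5_to_a750"):
            assert getattr(res.params, f) < 0.005, f

    def test_no_bleach_events_all_defaulted(self):
        photo = PhotoConfig.noiseless()
        cfg = KineticConfig(n_molecules=1)
        tls = [EventTimeline(0, 1e6, 1.0, cfg)]
        rng = np.random.default_rng(0)
        traces = render_traces(tls, photo, Manifest(), rng, duration_s=20.0)
        res = estimate_corrections(traces, ground_truth_table(tls))
        assert res.defaulted == {"d_cy5_532", "d_a750_638", "b_cy3_to_cy5",
                                 "b_cy5_to_a750", "s_cy3", "s_a750"}
        assert res.params == CorrectionParams()

    @pytest.mark.parametrize("duration, tol", [(60.0, 0.02), (120.0, 0.01), (240.0, 0.006)])
    def test_estimates_tighten_with_segment_length(self, duration, tol):
        photo = PhotoConfig()
        _, traces, truth = calibration_dataset(photo, duration=duration, seed=8)
        res = estimate_corrections(traces, truth)
        assert res.params.b_cy3_to_cy5 == pytest.approx(0.10, abs=tol)
        assert res.params.d_cy5_532 == pytest.approx(0.05, abs=tol)
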