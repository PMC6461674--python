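"""Bleach-step detection, onset breakpoint fitting and event extraction."""

import math

import numpy as np
import pytest

from trifret.correction import apply_corrections, compute_fret
from trifret.detection import (
    DetectionParams, detect_all_bleach, detect_bleach_steps, detect_onset,
    extract_events, find_down_steps,
)
from trifret.pipeline import analyze_traces
from trifret.synthetic import (
    EventTimeline, KineticConfig, PhotoConfig, ground_truth_table, render_traces,
)
from trifret.trace_io import Manifest, pair_alex_frames

DT = 0.1


class TestFindDownSteps:
    def test_single_clean_step(self):
        t = np.arange(300) * DT
        y = np.where(np.arange(300) < 150, 1000.0, 0.0)
        steps = find_down_steps(t, y)
        assert len(steps) == 1
        assert steps[0][0] == 150          # first post-step sample
        assert steps[0][1] == pytest.approx(1000.0, rel=0.1)

    def test_constant_series_no_steps(self):
        t = np.arange(100) * DT
        assert find_down_steps(t, np.full(100, 500.0)) == []

    def test_two_equal_steps_both_found(self):
        y = np.concatenate([np.full(100, 1000.0), np.full(100, 500.0),
                            np.full(100, 0.0)])
        steps = find_down_steps(np.arange(300) * DT, y)
        assert [k for k, _ in steps] == [100, 200]

    def test_gradual_ramp_rejected(self):
        """A FRET ramp over tens of frames is not a photobleach step."""
        y = np.concatenate([np.full(100, 500.0),
                            np.linspace(500.0, 100.0, 40),
                            np.full(100, 100.0)])
        assert find_down_steps(np.arange(len(y)) * DT, y) == []


class TestDetectBleachSteps:
    def _render_one(self, b3=math.inf, b5=math.inf, b7=math.inf, photo=None):
        cfg = KineticConfig(n_molecules=1)
        tl = EventTimeline(0, 4.0, 3.0, cfg, b3, b5, b7)
        photo = photo or PhotoConfig()
        traces = render_traces([tl], photo, Manifest(),
                               np.random.default_rng(5), duration_s=60.0)
        return traces.frames, photo

    def test_cy5_bleach_found_near_truth(self):
        g, photo = self._render_one(b5=30.0)
        r = detect_bleach_steps(g, corrections=photo.to_correction_params())
        assert r.bleach_cy5 == pytest.approx(30.0, abs=0.3)
        assert r.single_step
        assert math.isinf(r.bleach_cy3) and math.isinf(r.bleach_a750)

    def test_no_bleach_vacuously_single_step(self):
        g, photo = self._render_one()
        r = detect_bleach_steps(g, corrections=photo.to_correction_params())
        assert r.single_step
        assert math.isinf(r.bleach_cy5)

    def test_fret_event_not_mistaken_for_bleach(self):
        """The entry/exit FRET transitions redistribute photons between
        channels but must not register as photobleaching."""
        g, photo = self._render_one()
        r = detect_bleach_steps(g, corrections=photo.to_correction_params())
        assert r.n_steps == {"cy3": 0, "cy5": 0, "a750": 0}

    def test_too_short_trace_flagged(self):
        g, _ = self._render_one()
        r = detect_bleach_steps(g.iloc[:10])
        assert not r.single_step


def piecewise(n_base, n_ramp, y0, y1, noise_sd=0.0, seed=0):
    """Baseline for n_base samples, then a linear ramp to y1 over n_ramp."""
    t = np.arange(n_base + n_ramp) * DT
    t0 = t[n_base]
    y = np.where(t <= t0, y0, y0 + (y1 - y0) * (t - t0) / (t[-1] - t0))
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(y))
    return t, y, t0


class TestDetectOnset:
    def test_noiseless_onset_exact(self):
        t, y, t0 = piecewise(100, 100, 0.6, 0.2)
        on = detect_onset(t, y, DetectionParams(), direction="decrease")
        assert on is not None
        assert on.time == pytest.approx(t0, abs=1e-6)

    def test_subsample_breakpoint_recovered(self):
        """A ramp starting between two samples is located continuously."""
        t = np.arange(200) * DT
        t0 = 100 * DT + 0.037
        y = np.where(t <= t0, 0.6, 0.6 - 0.002 * (t - t0) / DT)
        on = detect_onset(t, y, DetectionParams(), direction="decrease")
        assert on.time == pytest.approx(t0, abs=1e-6)

    def test_noisy_onset_accuracy(self):
        """SD 0.05 noise on a baseline + 2.5 s ramp + plateau series (the
        generator's transition geometry), 200 seeded repeats: median
        |error| <= 2 frames, 95th percentile within 5 frames."""
        from trifret.detection import _onset_on_window

        n_base, n_ramp, n_tail = 100, 25, 75
        t = np.arange(n_base + n_ramp + n_tail) * DT
        t0, t1 = t[n_base], t[n_base + n_ramp]
        clean = np.interp(t, [t0, t1], [0.6, 0.2])
        clean[t <= t0] = 0.6
        errs = []
        for seed in range(200):
            y = clean + np.random.default_rng(seed).normal(0, 0.05, len(t))
            on = _onset_on_window(t, y, DetectionParams(), "decrease")
            assert on is not None
            errs.append(abs(on.time - t0) / DT)
        errs = np.array(errs)
        assert np.median(errs) <= 2.0
        assert np.quantile(errs, 0.95) <= 5.0

    def test_flat_noisy_series_none(self):
        rng = np.random.default_rng(1)
        t = np.arange(200) * DT
        y = 0.5 + rng.normal(0, 0.05, 200)
        assert detect_onset(t, y, DetectionParams(), direction="decrease") is None

    def test_wrong_direction_none(self):
        t, y, _ = piecewise(100, 100, 0.2, 0.6)  # increase
        assert detect_onset(t, y, DetectionParams(), direction="decrease") is None
        assert detect_onset(t, y, DetectionParams(), direction="increase") is not None

    def test_too_short_series_none(self):
        assert detect_onset([0.0, 0.1], [0.1, 0.9], DetectionParams()) is None


class TestExtractEvents:
    def test_noiseless_lags_within_one_alex_cycle(self, noiseless_dataset):
        timelines, traces, truth, photo = noiseless_dataset
        fret, events = analyze_traces(traces, photo.to_correction_params(),
                                      denom_floor=1e-6)
        m = events.rows.merge(truth, on="molecule_id", suffixes=("_det", "_true"))
        complete = m[m["t_lag_s_det"].notna()]
        assert len(complete) == len(timelines)
        cycle = 2 * traces.manifest.frame_interval_s
        err = (complete["t_lag_s_det"] - complete["t_lag_s_true"]).abs()
        assert (err <= cycle + 1e-9).all()

    def test_lag_never_negative(self, noisy_dataset):
        _, traces, _, photo = noisy_dataset
        _, events = analyze_traces(
            traces, photo.to_correction_params(),
            background={"cy3": photo.bg_cy3, "cy5": photo.bg_cy5,
                        "a750": photo.bg_a750})
        lags = events.rows["t_lag_s"].dropna()
        assert (lags >= 0).all()
        assert "frac_unconstrained_exit_before_entry" in events.diagnostics

    def test_every_molecule_flagged_once(self, noisy_dataset):
        _, traces, _, photo = noisy_dataset
        _, events = analyze_traces(
            traces, photo.to_correction_params(),
            background={"cy3": photo.bg_cy3, "cy5": photo.bg_cy5,
                        "a750": photo.bg_a750})
        assert sorted(events.rows["molecule_id"]) == sorted(
            traces.frames["molecule_id"].unique())

    def _fret_for(self, timelines, photo, duration=60.0):
        traces = render_traces(timelines, photo, Manifest(),
                               np.random.default_rng(0), duration_s=duration)
        bleach = ground_truth_table(timelines).assign(single_step=True)
        aligned = pair_alex_frames(traces)
        corr = apply_corrections(aligned, photo.to_correction_params())
        fret = compute_fret(corr, denom_floor=1e-6, bleach_table=bleach)
        return fret, bleach

    def test_early_cy5_bleach_no_transitions_is_no_event(self):
        cfg = KineticConfig(n_molecules=1)
        tl = EventTimeline(0, 1e6, 1.0, cfg, bleach_cy5=2.0)
        fret, bleach = self._fret_for([tl], PhotoConfig.noiseless())
        events = extract_events(fret, bleach_table=bleach)
        assert events.rows["flag"].iloc[0] == "no_event"

    def test_entry_then_bleach_is_censored(self):
        cfg = KineticConfig(n_molecules=1)
        tl = EventTimeline(0, 5.0, 100.0, cfg, bleach_cy5=30.0)
        fret, bleach = self._fret_for([tl], PhotoConfig.noiseless())
        events = extract_events(fret, bleach_table=bleach)
        row = events.rows.iloc[0]
        assert row["flag"] == "entry_only+censored_by_bleach"
        assert row["t_censor_s"] == pytest.approx(30.0 - row["t_entry_s"], abs=0.5)

    def test_multi_step_bleach_excluded(self):
        cfg = KineticConfig(n_molecules=1)
        tl = EventTimeline(0, 5.0, 3.0, cfg)
        fret, bleach = self._fret_for([tl], PhotoConfig.noiseless())
        bleach["single_step"] = False
        events = extract_events(fret, bleach_table=bleach)
        assert events.rows["flag"].iloc[0] == "multi_step_bleach"
        assert math.isnan(events.rows["t_lag_s"].iloc[0])


def test_detect_all_bleach_covers_all_molecules(noisy_dataset):
    _, traces, _, photo = noisy_dataset
    table = detect_all_bleach(traces, corrections=photo.to_correction_params())
    assert len(table) == traces.frames["molecule_id"].nunique()
    assert table["single_step"].mean() > 0.9
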