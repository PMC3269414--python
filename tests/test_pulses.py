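"""Pulse detection: trimmed smoothing, curvature widths, phases, counts."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporepulse.activity import colony_activity
from sporepulse.colony import SimConfig, simulate_microcolony
from sporepulse.errors import (ConfigError, ConsistencyError,
                               InsufficientDataError)
from sporepulse.pulses import (Pulse, assign_cycle_phase, detect_colony_pulses,
                               detect_pulses, pulses_per_cycle_stats,
                               trimmed_window_smooth)

from conftest import make_tree


def raised_cosine(n, center, half_width, amplitude=1.0, baseline=0.0):
    x = np.arange(n, dtype=float)
    u = (x - center) / half_width
    return baseline + np.where(np.abs(u) < 1,
                               0.5 * amplitude * (1 + np.cos(np.pi * u)), 0.0)


class TestTrimmedSmooth:
    def test_constant_series_unchanged(self):
        s = trimmed_window_smooth(np.full(20, 3.7))
        assert np.allclose(s, 3.7)

    def test_window_arithmetic(self):
        """Window [1..7]: reject 1 and 7, mean of {2,3,4,5,6} is 4."""
        s = trimmed_window_smooth(np.arange(1.0, 8.0), window=7)
        assert s[3] == 4.0

    @pytest.mark.parametrize("pos", range(2, 18))
    def test_single_spike_rejected(self, pos):
        """A lone spike is always the window maximum, hence trimmed away."""
        x = np.full(20, 2.0)
        x[pos] = 100.0
        s = trimmed_window_smooth(x)
        assert s[pos] == 2.0

    def test_parameter_validation(self):
        with pytest.raises(ConfigError):
            trimmed_window_smooth(np.ones(10), window=4)
        with pytest.raises(ConfigError):
            trimmed_window_smooth(np.ones(10), window=1)
        with pytest.raises(InsufficientDataError):
            trimmed_window_smooth(np.ones(5), window=7)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_output_bounded_by_window_extremes(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(30)
        s = trimmed_window_smooth(x)
        assert s.shape == x.shape
        assert np.all(s >= x.min()) and np.all(s <= x.max())

    def test_no_phase_shift_on_symmetric_pulses(self):
        """Raw-vs-smoothed cross-correlation peaks at lag zero."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            center = rng.integers(10, 20)
            x = raised_cosine(30, center, rng.integers(5, 9), amplitude=5.0)
            s = trimmed_window_smooth(x)
            xc = x - x.mean()
            sc = s - s.mean()
            corr = np.correlate(sc, xc, mode="full")
            lag = int(np.argmax(corr)) - (len(x) - 1)
            assert lag == 0


class TestDetectPulses:
    def test_single_bump(self):
        s = raised_cosine(40, 20, 8, amplitude=4.0)
        pulses = detect_pulses(s)
        assert len(pulses) == 1
        assert pulses[0].peak_frame == 20
        assert pulses[0].amplitude == pytest.approx(4.0)

    def test_two_bumps_and_curvature_width(self):
        """Negative curvature of a raised cosine spans half its support."""
        half = 8
        s = raised_cosine(60, 15, half) + raised_cosine(60, 45, half)
        pulses = detect_pulses(s)
        assert [p.peak_frame for p in pulses] == [15, 45]
        for p in pulses:
            # analytic: curvature of 0.5A(1+cos(pi u/w)) is negative for
            # |u| < w/2, i.e. over ~w frames around the peak
            assert abs(p.width - half) <= 1

    def test_subthreshold_ripple_ignored(self):
        rng = np.random.default_rng(0)
        s = 1.0 + 0.01 * rng.standard_normal(50)
        assert detect_pulses(trimmed_window_smooth(s), min_size=5.0) == []

    def test_empty_series(self):
        assert detect_pulses(np.array([])) == []

    def test_shift_equivariance(self):
        base = raised_cosine(50, 20, 7, amplitude=3.0)
        for k in (1, 5, 9):
            shifted = np.concatenate([np.zeros(k), base])[:50]
            p0 = detect_pulses(base)[0]
            pk = detect_pulses(shifted)[0]
            assert pk.peak_frame == p0.peak_frame + k

    def test_min_size_monotone(self):
        rng = np.random.default_rng(1)
        s = trimmed_window_smooth(rng.random(80) + raised_cosine(80, 40, 10, 3.0))
        counts = [len(detect_pulses(s, min_size=m)) for m in (0, 1, 5, 20, 100)]
        assert counts == sorted(counts, reverse=True)

    def test_plateau_tie_breaks_leftmost(self):
        s = np.zeros(20)
        s[8:11] = 2.0
        pulses = detect_pulses(s)
        assert len(pulses) == 1 and pulses[0].peak_frame == 8


class TestCyclePhase:
    def test_phase_at_birth_and_midpoint(self):
        tree = make_tree({"1": (None, 0, 40, "divided"),
                          "10": ("1", 40, 80, "censored"),
                          "11": ("1", 40, 80, "censored")})
        pulses = [Pulse("1", 0, 1.0, 3, 3.0),
                  Pulse("1", 20, 1.0, 3, 3.0),
                  Pulse("10", 60, 1.0, 3, 3.0)]
        out = assign_cycle_phase(pulses, tree)
        assert out[0].phase == 0.0
        assert out[1].phase == 0.5
        assert out[2].phase == 0.5 and out[2].cycle_index == 1

    def test_peak_outside_cycle_rejected(self):
        tree = make_tree({"1": (None, 0, 10, "censored")})
        with pytest.raises(ConsistencyError):
            assign_cycle_phase([Pulse("1", 15, 1.0, 3, 3.0)], tree)

    def test_unknown_cell_rejected(self):
        tree = make_tree({"1": (None, 0, 10, "censored")})
        with pytest.raises(ConsistencyError):
            assign_cycle_phase([Pulse("2", 5, 1.0, 3, 3.0)], tree)

    def test_injected_phase_recovered(self):
        """Pulses injected at phase 0.6 give a phase histogram mode there."""
        phases = []
        for seed in (0, 1):
            col = simulate_microcolony(SimConfig(seed=seed))
            act = colony_activity(col, "yfp")
            phases.extend(p.phase for p in detect_colony_pulses(act, col))
        phases = np.asarray(phases)
        hist, edges = np.histogram(phases, bins=np.arange(0, 1.05, 0.05))
        mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
        assert abs(mode - 0.6) <= 0.05  # one 10-min frame of a 24-frame cycle


class TestPulsesPerCycle:
    def test_one_pulse_every_cycle(self):
        tree = make_tree({"1": (None, 0, 10, "divided"),
                          "10": ("1", 10, 20, "censored"),
                          "11": ("1", 10, 20, "censored")})
        pulses = [Pulse(c, f, 1.0, 3, 3.0) for c, f in
                  (("1", 5), ("10", 15), ("11", 15))]
        stats = pulses_per_cycle_stats(pulses, tree)
        assert stats.counts.tolist() == [1, 1, 1]
        assert stats.observed[1] == 3
        # degenerate variance 0 < binomial variance n p (1-p) unless p=1
        assert stats.counts.var() <= stats.n_null * stats.p_null * (1 - stats.p_null) + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_binomial_null_not_rejected_on_null_data(self, seed):
        """Counts drawn from the null itself pass the goodness of fit."""
        rng = np.random.default_rng(seed)
        n_cells = 400
        spec = {str(i + 1): (None, 0, 10, "censored") for i in range(n_cells)}
        tree = make_tree(spec)
        pulses = []
        for i in range(n_cells):
            for k in range(rng.binomial(3, 0.3)):
                pulses.append(Pulse(str(i + 1), 2 + k, 1.0, 3, 3.0))
        stats = pulses_per_cycle_stats(pulses, tree, n_null=3)
        assert stats.pvalue > 0.01

    def test_wildtype_modal_count_is_one(self, wildtype_colony):
        act = colony_activity(wildtype_colony, "yfp")
        pulses = detect_colony_pulses(act, wildtype_colony)
        stats = pulses_per_cycle_stats(pulses, wildtype_colony)
        values, counts = np.unique(stats.counts, return_counts=True)
        assert values[counts.argmax()] == 1

    def test_empty_colony_rejected(self):
        from sporepulse.colony import Microcolony
        with pytest.raises(InsufficientDataError):
            pulses_per_cycle_stats([], Microcolony())


class TestRecallPrecision:
    def test_recall_precision_wildtype_noise(self):
        """>= 0.9 recall and precision against injected ground truth over
        100+ traces at the wild-type noise level (amplitude CV 0.2)."""
        tp = fp = n_true = 0
        for seed in (0, 1):
            cfg = SimConfig(seed=seed)
            col = simulate_microcolony(cfg)
            act = colony_activity(col, "yfp")
            by_cell = collections.defaultdict(list)
            for p in detect_colony_pulses(act, col):
                by_cell[p.cell_id].append(p)
            for c in col:
                if c.n_frames < 7:
                    continue
                n_true += 1
                matched = False
                for p in sorted(by_cell[c.cell_id], key=lambda p: -p.amplitude):
                    close = abs(p.peak_frame * cfg.frame_interval_min
                                - c.true_pulse_time) <= 3 * cfg.frame_interval_min
                    if close and not matched:
                        matched = True
                        tp += 1
                    else:
                        fp += 1
        assert n_true >= 100
        assert tp / n_true >= 0.9
        assert tp / (tp + fp) >= 0.9
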