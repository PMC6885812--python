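import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from neurocult.event_detection import detect_events
from neurocult.imaging_io import RoiMap, extract_traces
from neurocult.synthetic_data import (
    GroundTruth,
    SimConfig,
    simulate_ct_table,
    simulate_respirometry,
    simulate_stack,
    simulate_traces,
    transient_kernel,
    transient_visible_duration,
)
from neurocult.expression_ddct import delta_ct, fold_change


class TestSimConfig:
    def test_defaults_valid(self):
        cfg = SimConfig()
        assert cfg.frame_rate == 4.0
        assert cfg.n_frames == 1200

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duration": 0.0},
            {"frame_rate": -1.0},
            {"sync_fraction": 1.5},
            {"noise_sd": -0.1},
            {"amplitude": -5.0},
            {"rise_tau": 3.0, "decay_tau": 0.5},
            {"event_rate": float("nan")},
            {"n_cells": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestTransientKernel:
    def test_unit_peak(self):
        t = np.linspace(0, 30, 10001)
        k = transient_kernel(t, 0.5, 3.0)
        assert k.max() == pytest.approx(1.0, abs=1e-6)

    def test_zero_before_onset(self):
        k = transient_kernel(np.array([-1.0, -0.01]), 0.5, 3.0)
        assert np.all(k == 0.0)

    def test_visible_duration_default_kinetics(self):
        # decays to 10% of peak ~8.5 s after onset at the default taus
        dur = transient_visible_duration(0.5, 3.0)
        assert 8.0 < dur < 9.5
        level = transient_kernel(np.array([dur]), 0.5, 3.0)[0]
        assert level == pytest.approx(0.1, abs=1e-9)


class TestSimulateTraces:
    def test_no_signal_sources_constant_baseline(self):
        cfg = SimConfig(
            n_cells=3,
            duration=30,
            event_rate=0.0,
            network_event_rate=0.0,
            noise_sd=0.0,
            baseline=42.0,
        )
        traces, truth = simulate_traces(cfg)
        assert len(traces) == 3
        for tr in traces:
            assert np.all(tr.values == 42.0)
        assert truth.total_events == 0

    def test_poisson_event_count(self):
        # 10 cells x 5 min x 2/min -> raw onset count ~ Poisson(100)
        cfg = SimConfig(n_cells=10, duration=300, event_rate=2.0, seed=5)
        _, truth = simulate_traces(cfg)
        total = sum(len(o) for o in truth.onsets)
        assert abs(total - 100) <= 3 * math.sqrt(100)

    def test_deterministic(self):
        cfg = SimConfig(n_cells=4, duration=60, noise_sd=2.0, seed=9)
        t1, g1 = simulate_traces(cfg)
        t2, g2 = simulate_traces(cfg)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.values, b.values)
        assert g1 == g2

    def test_adding_cell_preserves_existing_traces(self):
        base = SimConfig(n_cells=3, duration=60, noise_sd=1.0, seed=3)
        bigger = dataclasses.replace(base, n_cells=4)
        t3, _ = simulate_traces(base)
        t4, _ = simulate_traces(bigger)
        for a, b in zip(t3, t4):
            assert np.array_equal(a.values, b.values)

    def test_quantize_clips_to_8bit_integers(self):
        cfg = SimConfig(
            n_cells=2, duration=30, baseline=240.0, amplitude=100.0,
            event_rate=4.0, noise_sd=5.0, quantize=True, seed=2,
        )
        traces, _ = simulate_traces(cfg)
        for tr in traces:
            assert tr.values.min() >= 0 and tr.values.max() <= 255
            assert np.all(tr.values == np.rint(tr.values))

    def test_event_times_within_recording(self):
        cfg = SimConfig(n_cells=5, duration=60, event_rate=4.0, seed=1)
        _, truth = simulate_traces(cfg)
        for cell_events in truth.events:
            for onset, offset in cell_events:
                assert 0 <= onset < offset <= 60

    def test_network_events_recruit_subset(self):
        cfg = SimConfig(
            n_cells=20, duration=120, event_rate=0.0,
            network_event_rate=2.0, sync_fraction=0.8, sync_jitter=0.05, seed=4,
        )
        _, truth = simulate_traces(cfg)
        assert truth.network_events
        fractions = [len(p) / 20 for _, p in truth.network_events]
        assert 0.5 < np.mean(fractions) < 1.0

    def test_poisson_law_chi_square(self):
        # per-cell raw counts over 1000 cells must fit Poisson(rate*minutes)
        cfg = SimConfig(n_cells=1000, duration=60, event_rate=2.0, seed=13)
        _, truth = simulate_traces(cfg)
        counts = np.array([len(o) for o in truth.onsets])
        mean = 2.0
        edges = np.arange(0, 8)
        observed = np.array(
            [np.sum(counts == e) for e in edges[:-1]] + [np.sum(counts >= 7)]
        )
        probs = stats.poisson.pmf(edges[:-1], mean)
        probs = np.append(probs, 1 - probs.sum())
        chi2 = np.sum((observed - 1000 * probs) ** 2 / (1000 * probs))
        p = stats.chi2.sf(chi2, len(observed) - 1)
        assert p > 0.01

    def test_round_trip_detection_when_well_separated(self):
        cfg = SimConfig(
            n_cells=8, duration=300, event_rate=0.6, noise_sd=0.0, seed=21
        )
        traces, truth = simulate_traces(cfg)
        visible = transient_visible_duration(cfg.rise_tau, cfg.decay_tau)
        for tr, onsets in zip(traces, truth.onsets):
            gaps_ok = all(
                b - a > visible for a, b in zip(onsets, onsets[1:])
            ) and (not onsets or onsets[-1] + visible < cfg.duration)
            if not gaps_ok or not onsets:
                continue
            assert len(detect_events(tr)) == len(onsets)


class TestSimulateStack:
    def test_single_roi_zero_noise_roundtrip(self):
        img = np.zeros((20, 20), dtype=np.int32)
        img[5:12, 6:13] = 1
        cfg = SimConfig(n_cells=1, duration=30, event_rate=2.0, noise_sd=0.0, seed=6)
        stack, traces, _ = simulate_stack(cfg, RoiMap(img))
        extracted = extract_traces(stack, RoiMap(img), cfg.frame_rate)
        assert np.allclose(extracted[0].values, traces[0].values, rtol=0, atol=1e-9)

    def test_background_is_baseline_at_zero_noise(self):
        img = np.zeros((10, 10), dtype=np.int32)
        img[2:4, 2:4] = 1
        cfg = SimConfig(n_cells=1, duration=10, noise_sd=0.0, baseline=33.0, seed=0)
        stack, _, _ = simulate_stack(cfg, RoiMap(img))
        assert np.all(stack[:, 0, 0] == 33.0)

    def test_empty_roi_map_pure_background(self):
        img = np.zeros((8, 8), dtype=np.int32)
        cfg = SimConfig(n_cells=1, duration=10, noise_sd=0.0, baseline=12.0, seed=0)
        stack, traces, truth = simulate_stack(cfg, RoiMap(img))
        assert traces == []
        assert truth.total_events == 0
        assert np.all(stack == 12.0)

    def test_overlapping_masks_rejected(self):
        a = np.zeros((6, 6), dtype=bool)
        b = np.zeros((6, 6), dtype=bool)
        a[1:4, 1:4] = True
        b[3:5, 3:5] = True
        with pytest.raises(ValueError, match="overlap"):
            RoiMap.from_masks({1: a, 2: b})

    def test_quantized_stack_is_uint8(self):
        img = np.zeros((10, 10), dtype=np.int32)
        img[2:5, 2:5] = 1
        cfg = SimConfig(
            n_cells=1, duration=10, noise_sd=2.0, quantize=True, seed=3
        )
        stack, _, _ = simulate_stack(cfg, RoiMap(img))
        assert stack.dtype == np.uint8


class TestSimulateRespirometry:
    MEANS = {
        "Sham": {"V4_gm": 73.99, "V3": 50.0, "V4_succ": 80.0},
        "Hypoxia": {"V4_gm": 88.8, "V3": 40.0, "V4_succ": 90.0},
    }

    def test_sd_zero_reproduces_means(self):
        table = simulate_respirometry(self.MEANS, sd=0.0, n=4, seed=1)
        for group, means in self.MEANS.items():
            sub = table[table["group"] == group]
            assert len(sub) == 4
            for state, value in means.items():
                assert np.all(sub[state] == value)

    def test_deterministic(self):
        t1 = simulate_respirometry(self.MEANS, sd=3.0, n=5, seed=7)
        t2 = simulate_respirometry(self.MEANS, sd=3.0, n=5, seed=7)
        assert t1.equals(t2)

    def test_truncated_positive(self):
        means = {"G": {"V4_gm": 0.5, "V3": 0.5, "V4_succ": 0.5}}
        table = simulate_respirometry(means, sd=5.0, n=50, seed=2)
        assert (table[["V4_gm", "V3", "V4_succ"]] > 0).all().all()

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            simulate_respirometry(self.MEANS, sd=0.0, n=0)

    def test_nonpositive_mean(self):
        with pytest.raises(ValueError):
            simulate_respirometry(
                {"G": {"V4_gm": 0.0, "V3": 1.0, "V4_succ": 1.0}}, n=2
            )


class TestSimulateCtTable:
    def test_fold_one_zero_noise_recovered_exactly(self):
        folds = {"Sham": {"Hif1a": 1.0}, "Hypoxia": {"Hif1a": 1.0}}
        table = simulate_ct_table(folds, noise_sd=0.0, n=3)
        out = fold_change(delta_ct(table), "Sham")
        assert np.all(out["fold"] == 1.0)

    def test_fold_four_shifts_ct_two_cycles(self):
        table = simulate_ct_table(
            {"G": {"Hif1a": 4.0}}, base_ct=25.0, noise_sd=0.0, n=1
        )
        target = table[table["gene"] == "Hif1a"]["Ct"].iloc[0]
        assert target == pytest.approx(23.0)

    def test_recovery_with_noise(self):
        folds = {"Sham": {"Hif1a": 1.0}, "Hypoxia": {"Hif1a": 2.5}}
        table = simulate_ct_table(folds, noise_sd=0.1, n=6, seed=11)
        out = fold_change(delta_ct(table), "Sham")
        row = out[(out["group"] == "Hypoxia")].iloc[0]
        assert abs(row["fold"] - 2.5) <= 3 * row["sem"]

    def test_invalid_fold(self):
        with pytest.raises(ValueError):
            simulate_ct_table({"G": {"Hif1a": 0.0}})

    def test_deterministic(self):
        folds = {"A": {"g": 2.0}}
        t1 = simulate_ct_table(folds, noise_sd=0.3, n=4, seed=5)
        t2 = simulate_ct_table(folds, noise_sd=0.3, n=4, seed=5)
        assert t1.equals(t2)


def test_ground_truth_json_roundtrip(tmp_path):
    cfg = SimConfig(
        n_cells=3, duration=60, event_rate=2.0,
        network_event_rate=1.0, sync_fraction=0.5, seed=8,
    )
    _, truth = simulate_traces(cfg)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    assert GroundTruth.from_json(path) == truth
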