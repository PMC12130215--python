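"""z-scoring, windowing/scaling, premovement flags, labeling, balancing, folds."""

import numpy as np
import pandas as pd
import pytest

from neurouq import (
    DecodingSample,
    extract_segments,
    flag_premovement,
    label_samples,
    make_folds,
    upsample_minority,
    zscore_to_baseline,
)
from neurouq.preprocess import make_decoding_dataset
from neurouq.synth import (
    AgentParams,
    PopulationRecording,
    PopulationSpec,
    TaskConfig,
    simulate_session,
    N_FRAMES,
)


def _recording_from(traces, trial_table=None):
    n, _, t = traces.shape
    tt = trial_table if trial_table is not None else pd.DataFrame(
        {
            "trial_index": np.arange(t),
            "trial_type": ["go"] * t,
            "frequency": [600.0] * t,
            "outcome": ["hit"] * t,
            "lick": [True] * t,
        }
    )
    return PopulationRecording(
        traces=traces, trial_table=tt, neuron_ids=[f"n{i}" for i in range(n)]
    )


class TestZScore:
    def test_hand_computed_example(self):
        """Baseline {1,2,3} (population sd), post value 5 -> z = 3 / sqrt(2/3)."""
        traces = np.zeros((1, N_FRAMES, 1))
        traces[0, :30, 0] = np.resize([1.0, 2.0, 3.0], 30)
        traces[0, 30, 0] = 5.0
        z = zscore_to_baseline(_recording_from(traces))
        sd = np.std([1.0, 2.0, 3.0])  # ddof=0
        assert z.z[0, 30, 0] == pytest.approx((5.0 - 2.0) / sd)

    def test_idempotent_on_standardized_baseline(self, rng):
        traces = rng.standard_normal((3, N_FRAMES, 4))
        z1 = zscore_to_baseline(_recording_from(traces))
        base = z1.z[:, :30, :]
        assert np.allclose(base.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(base.std(axis=1), 1.0, atol=1e-12)

    def test_constant_baseline_errors_by_default(self):
        traces = np.ones((1, N_FRAMES, 1))
        with pytest.raises(ValueError, match="zero sd"):
            zscore_to_baseline(_recording_from(traces))

    def test_zero_policy_flags_and_zeroes(self):
        traces = np.ones((1, N_FRAMES, 1))
        z = zscore_to_baseline(_recording_from(traces), degenerate_policy="zero")
        assert np.all(z.z == 0.0)
        assert z.degenerate[0, 0]


class TestSegments:
    def test_default_window_has_nine_frames_in_unit_range(self, small_recording):
        samples = extract_segments(small_recording)
        assert all(s.segment.shape == (40, 9) for s in samples)
        allv = np.concatenate([s.segment.ravel() for s in samples])
        assert allv.min() >= 0.0 and allv.max() <= 1.0

    def test_window_covers_seven_poststimulus_frames(self):
        """Frames 29-37 with onset at frame 31: 7 frames at/after onset = 0.233 s."""
        a, b = 29, 37
        onset = 31
        post = b - onset + 1
        assert post == 7
        assert post / 30 == pytest.approx(0.233, abs=5e-4)

    def test_nonstandard_window_warns_but_proceeds(self, small_recording):
        with pytest.warns(UserWarning, match="expected 9"):
            samples = extract_segments(small_recording, frame_window=(29, 40))
        assert samples[0].segment.shape[1] == 12

    def test_scaling_scopes(self, small_recording):
        for scope in ("per_neuron", "per_segment", "global"):
            samples = extract_segments(small_recording, scaling=scope)
            v = np.concatenate([s.segment.ravel() for s in samples])
            assert v.min() >= 0.0 and v.max() <= 1.0


class TestPremovement:
    def _coords(self, disp, where=100):
        c = np.zeros((1, 640, 2))
        c[0, where, 0] = disp
        return c

    def test_strict_threshold(self):
        assert flag_premovement(self._coords(61.0))[0]
        assert not flag_premovement(self._coords(60.0))[0]

    def test_outside_window_not_flagged(self):
        assert not flag_premovement(self._coords(100.0, where=300))[0]

    def test_missing_coordinates_flagged_conservatively(self):
        c = self._coords(0.0)
        c[0, 90, :] = np.nan
        assert flag_premovement(c)[0]

    def test_recovers_simulator_ground_truth(self):
        rec = simulate_session(
            TaskConfig(n_trials=100, stimulus_mix={"go": 0.5, "no-go": 0.5}),
            AgentParams.expert(),
            PopulationSpec(n_neurons=3),
            np.random.default_rng(8),
            premove_prob=0.3,
        )
        flags = flag_premovement(rec.paw)
        assert np.array_equal(flags, rec.trial_table["premovement_true"].to_numpy())


def _samples_from(meta_rows):
    return [
        DecodingSample(segment=np.zeros((2, 9)), meta=dict(m)) for m in meta_rows
    ]


class TestLabeling:
    def test_stimulus_mode_keeps_anchors_only(self):
        samples = _samples_from(
            [
                {"frequency": 200.0, "outcome": "CR", "lick": False},
                {"frequency": 280.0, "outcome": "PL", "lick": True},
                {"frequency": 600.0, "outcome": "hit", "lick": True},
            ]
        )
        out = label_samples(samples, "stimulus")
        assert [s.label for s in out] == [0, 1]

    def test_response_mode_labels_probe_lick(self):
        samples = _samples_from([{"frequency": 280.0, "outcome": "PL", "lick": True}])
        out = label_samples(samples, "response")
        assert out[0].label == 1

    def test_ur_and_premovement_excluded(self):
        samples = _samples_from(
            [
                {"frequency": np.nan, "outcome": "UR", "lick": True},
                {"frequency": 600.0, "outcome": "hit", "lick": True, "premovement": True},
                {"frequency": 600.0, "outcome": "hit", "lick": True},
            ]
        )
        out = label_samples(samples, "response")
        assert len(out) == 1

    def test_response_pair_mode(self):
        samples = _samples_from(
            [
                {"frequency": 600.0, "outcome": "hit", "lick": True},
                {"frequency": 600.0, "outcome": "miss", "lick": False},
                {"frequency": 200.0, "outcome": "CR", "lick": False},
            ]
        )
        out = label_samples(samples, "response_pair", pair=("miss", "hit"))
        assert sorted(s.label for s in out) == [0, 1]
        with pytest.raises(ValueError, match="fewer than 2"):
            label_samples(samples[:1], "response_pair", pair=("miss", "CR"))


class TestUpsampling:
    def test_cycle_duplication_balances(self):
        mk = lambda lab, n: [
            DecodingSample(segment=np.zeros((1, 9)), label=lab) for _ in range(n)
        ]
        out = upsample_minority(mk(0, 10) + mk(1, 90))
        labels = np.array([s.label for s in out])
        assert (labels == 0).sum() == 90 and (labels == 1).sum() == 90

    def test_balanced_input_unchanged(self):
        mk = lambda lab, n: [
            DecodingSample(segment=np.zeros((1, 9)), label=lab) for _ in range(n)
        ]
        samples = mk(0, 5) + mk(1, 5)
        assert upsample_minority(samples) == samples

    def test_empty_minority_errors(self):
        samples = [DecodingSample(segment=np.zeros((1, 9)), label=1) for _ in range(9)]
        with pytest.raises(ValueError):
            upsample_minority(samples)


class TestFolds:
    def test_partition_proportions_20_fold(self):
        labels = np.resize([0, 1], 4000)
        splits = make_folds(labels, k=20, seed=1)
        assert len(splits) == 20
        sp = splits[0]
        assert len(sp.test_idx) == 200
        assert len(sp.train_idx) == 3040
        assert len(sp.val_idx) == 760

    def test_test_sets_partition_dataset(self):
        labels = np.resize([0, 1], 200)
        splits = make_folds(labels, k=10, seed=0)
        all_test = np.concatenate([s.test_idx for s in splits])
        assert len(all_test) == 200 and len(np.unique(all_test)) == 200
        for s in splits:
            assert not (set(s.train_idx) & set(s.val_idx))
            assert not (set(s.train_idx) & set(s.test_idx))
            assert not (set(s.val_idx) & set(s.test_idx))

    def test_stratification_of_test_folds(self):
        labels = np.resize([0, 1], 400)
        for sp in make_folds(labels, k=10, seed=3):
            ratio = np.asarray(labels)[sp.test_idx].mean()
            assert abs(ratio - 0.5) <= 0.05

    def test_reproducible_and_seed_sensitive(self):
        labels = np.resize([0, 1], 100)
        a = make_folds(labels, k=5, seed=9)
        b = make_folds(labels, k=5, seed=9)
        c = make_folds(labels, k=5, seed=10)
        assert all(np.array_equal(x.test_idx, y.test_idx) for x, y in zip(a, b))
        assert any(not np.array_equal(x.test_idx, y.test_idx) for x, y in zip(a, c))

    def test_small_class_rejected(self):
        labels = [0] * 50 + [1] * 3
        with pytest.raises(ValueError, match="at least k"):
            make_folds(labels, k=5, seed=0)


class TestDatasetAssembly:
    def test_prev_outcome_follows_session_order(self):
        rec = simulate_session(
            TaskConfig(n_trials=50, stimulus_mix={"go": 0.5, "no-go": 0.5}),
            AgentParams.expert(),
            PopulationSpec(n_neurons=3),
            np.random.default_rng(2),
            premove_prob=0.0,
        )
        ds = make_decoding_dataset([rec], label_mode="response")
        tt = rec.trial_table
        kept = {s.meta["trial_index"]: s for s in ds}
        for idx, s in kept.items():
            if idx == 0:
                assert s.meta["prev_outcome"] is None
            else:
                assert s.meta["prev_outcome"] == tt["outcome"].iloc[idx - 1]
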