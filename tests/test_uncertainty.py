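"""MC dropout mechanics: variance bounds, mask-enumeration oracle, grouping."""

import numpy as np
import pandas as pd
import pytest

from neurouq import DecodingSample, group_uncertainty, mcd_infer, run_protocol
from neurouq.model import ModelConfig, forward_batch, init_params, pad_batch
from neurouq.uncertainty import UQProtocolConfig, predictive_entropy


class _BitRNG:
    """Stub rng whose uniform draws realise a prescribed dropout mask.

    Bits are consumed in draw order; 1 keeps the unit (u >= p), 0 drops it.
    """

    def __init__(self, bits):
        self.bits = list(bits)

    def random(self, shape):
        size = int(np.prod(shape))
        out = np.array([0.999 if self.bits.pop(0) else 0.0 for _ in range(size)])
        return out.reshape(shape)


class TestMCDInfer:
    def test_zero_dropout_gives_zero_variance(self):
        cfg = ModelConfig(
            latent_dim=12, dropout_embed=0.0, dropout_residual=0.0, dropout_attention=0.0
        )
        params = init_params(cfg, np.random.default_rng(0))
        seg = np.random.default_rng(1).random((6, 9))
        mean, var = mcd_infer(params, seg, T=50, rng=np.random.default_rng(2), config=cfg)
        assert var == pytest.approx(0.0, abs=1e-24)
        assert 0.0 <= mean <= 1.0

    def test_t_below_two_rejected(self):
        cfg = ModelConfig(latent_dim=12)
        params = init_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="T"):
            mcd_infer(params, np.zeros((2, 9)), T=1, config=cfg)

    def test_variance_bounds(self):
        cfg = ModelConfig(latent_dim=12, dropout_embed=0.3, dropout_residual=0.3)
        params = init_params(cfg, np.random.default_rng(0))
        segs = [np.random.default_rng(i).random((5, 9)) for i in range(8)]
        mean, var = mcd_infer(params, segs, T=40, rng=np.random.default_rng(3), config=cfg)
        assert np.all(var >= 0.0) and np.all(var <= 0.25)
        assert np.all((mean >= 0.0) & (mean <= 1.0))

    def test_matches_exhaustive_mask_enumeration(self):
        """Single dropout site (embedding, 1 neuron, latent 2 -> 2 mask bits):
        the MC variance converges to the exact enumeration over all 4 masks."""
        p_drop = 0.3
        cfg = ModelConfig(
            latent_dim=2,
            n_heads=1,
            n_blocks=1,
            dropout_embed=p_drop,
            dropout_residual=0.0,
            dropout_attention=0.0,
        )
        params = init_params(cfg, np.random.default_rng(5))
        seg = np.random.default_rng(6).random((1, 9))
        x, mask = pad_batch([seg])

        outs, probs = [], []
        for b0 in (0, 1):
            for b1 in (0, 1):
                # attention dropout off: only the 2 embedding bits are drawn
                out = forward_batch(params, x, mask, cfg, dropout=True, rng=_BitRNG([b0, b1]))
                outs.append(out[0, 1])
                w0 = (1 - p_drop) if b0 else p_drop
                w1 = (1 - p_drop) if b1 else p_drop
                probs.append(w0 * w1)
        probs = np.array(probs)
        outs = np.array(outs)
        exact_mean = (probs * outs).sum()
        exact_var = (probs * (outs - exact_mean) ** 2).sum()

        t = 100_000
        mean, var = mcd_infer(params, seg, T=t, rng=np.random.default_rng(7), config=cfg)
        assert mean == pytest.approx(exact_mean, abs=4 * np.sqrt(exact_var / t) + 1e-9)
        assert var == pytest.approx(exact_var, rel=0.05)

    def test_mean_prediction_converges_with_passes(self):
        """sd of the MC mean shrinks ~1/sqrt(T): T=100 vs T=10000 repeats."""
        cfg = ModelConfig(latent_dim=8, dropout_embed=0.2, dropout_residual=0.2)
        params = init_params(cfg, np.random.default_rng(8))
        seg = np.random.default_rng(9).random((4, 9))

        def spread(T, reps=6):
            means = [
                mcd_infer(params, seg, T=T, rng=np.random.default_rng(100 + i), config=cfg)[0]
                for i in range(reps)
            ]
            return np.std(means)

        assert spread(10_000) < spread(100)


@pytest.fixture(scope="module")
def tiny_dataset():
    rng = np.random.default_rng(0)
    out = []
    for i in range(60):
        lab = i % 2
        seg = rng.random((6, 9)) * 0.5
        if lab:
            seg[:2] += 0.4
        out.append(
            DecodingSample(
                segment=np.clip(seg, 0, 1),
                label=lab,
                meta={
                    "trial_id": f"t{i}",
                    "day": 1 + (i % 4),
                    "frequency": [200.0, 600.0][lab],
                    "outcome": ["CR", "hit"][lab],
                    "prev_outcome": "hit",
                },
            )
        )
    return out


class TestProtocol:
    def test_every_trial_scored_once_per_seed(self, tiny_dataset):
        cfg = ModelConfig(latent_dim=8, n_iterations=10, eval_every=10, seed=0)
        table = run_protocol(
            tiny_dataset, cfg, UQProtocolConfig(k_folds=3, n_seeds=2, T=5), seed=4
        )
        assert len(table) == 2 * len(tiny_dataset)
        per_seed = table.groupby("seed")["trial_id"].nunique()
        assert (per_seed == len(tiny_dataset)).all()
        assert table["uncertainty"].between(0.0, 0.25).all()
        assert table["mean_prediction"].between(0.0, 1.0).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UQProtocolConfig(T=1)
        with pytest.raises(ValueError):
            UQProtocolConfig(k_folds=1)


class TestGrouping:
    def _records(self):
        return pd.DataFrame(
            {
                "trial_id": ["a", "a", "b", "b", "c", "c"],
                "seed": [0, 1, 0, 1, 0, 1],
                "day": [1, 1, 1, 1, 7, 7],
                "frequency": [200.0] * 4 + [600.0] * 2,
                "outcome": ["CR", "CR", "CR", "CR", "hit", "hit"],
                "prev_outcome": [None, None, "CR", "CR", "hit", "hit"],
                "uncertainty": [0.1, 0.3, 0.2, 0.2, 0.05, 0.15],
            }
        )

    def test_seed_average_then_group(self):
        out = group_uncertainty(self._records(), by="day").set_index("day")
        # trials a and b (day 1) have seed means 0.2 and 0.2
        assert out.loc[1, "mean"] == pytest.approx(0.2)
        assert out.loc[1, "n"] == 2
        assert out.loc[7, "mean"] == pytest.approx(0.1)

    def test_weighted_group_means_recover_grand_mean(self):
        out = group_uncertainty(self._records(), by="response_type")
        grand = (out["mean"] * out["n"]).sum() / out["n"].sum()
        per_trial = self._records().groupby("trial_id")["uncertainty"].mean()
        assert grand == pytest.approx(per_trial.mean())

    def test_learning_stage_mapping(self):
        out = group_uncertainty(self._records(), by="learning_stage").set_index(
            "learning_stage"
        )
        assert out.loc["naive", "n"] == 2
        assert out.loc["expert", "n"] == 1

    def test_empty_category_reported_with_zero_n(self):
        out = group_uncertainty(
            self._records(), by="day", categories=[1, 7, 8]
        ).set_index("day")
        assert out.loc[8, "n"] == 0
        assert np.isnan(out.loc[8, "mean"])

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            group_uncertainty(pd.DataFrame(), by="day")

    def test_prev_current_pair_keys(self):
        out = group_uncertainty(self._records(), by="prev_current_pair")
        keys = set(out["prev_current_pair"])
        assert ("CR", "CR") in keys and ("hit", "hit") in keys


def test_uncertainty_decreases_with_snr():
    """Mean MCD variance falls monotonically over three planted SNR levels."""
    from neurouq.model import train_model
    from neurouq.preprocess import make_decoding_dataset, make_folds
    from neurouq.synth import (
        AgentParams,
        PopulationSpec,
        TaskConfig,
        generate_schedule,
        simulate_behavior,
        synthesize_population,
    )

    uncs = []
    for amp in (1.0, 2.5, 6.0):
        rng = np.random.default_rng(31)  # same seed: only the amplitude moves
        sched = simulate_behavior(
            generate_schedule(
                TaskConfig(n_trials=160, stimulus_mix={"go": 0.5, "no-go": 0.5}), rng
            ),
            AgentParams.expert(),
            rng,
        )
        rec = synthesize_population(
            sched,
            PopulationSpec(
                n_neurons=20,
                frac_go_neurons=0.3,
                frac_lick_neurons=0.0,
                response_amplitude=amp,
                gain_variability=0.2,
                choice_coupling=0.0,
            ),
            rng,
        )
        ds = make_decoding_dataset([rec], label_mode="response")
        sp = make_folds(ds, k=4, seed=0)[0]
        cfg = ModelConfig(
            latent_dim=12, n_iterations=300, eval_every=100, learning_rate=1e-3, seed=0
        )
        ckpt = train_model([ds[i] for i in sp.train_idx], [ds[i] for i in sp.val_idx], cfg)
        _, var = mcd_infer(
            ckpt,
            [ds[i].segment for i in sp.test_idx],
            T=100,
            rng=np.random.default_rng(1),
        )
        uncs.append(var.mean())
    assert uncs[0] > uncs[1] > uncs[2]


def test_predictive_entropy_peaks_at_half():
    e = predictive_entropy(np.array([0.01, 0.5, 0.99]))
    assert e[1] == max(e)
    assert e[1] == pytest.approx(np.log(2))
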