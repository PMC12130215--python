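"""Monte Carlo dropout uncertainty and the k-fold x seeds protocol.

Uncertainty of one trial is the variance, across T stochastic forward passes
with dropout enabled, of the decoder's class-1 probability.  It is an
arbitrary-unit quantity bounded by 0.25 (the variance of a [0, 1] variable).
Predictive entropy of the mean prediction is exposed as a secondary metric.

The full protocol trains k_folds x n_seeds models (defaults 20 x 10, T = 1000
passes) so that every non-excluded trial receives one uncertainty estimate per
seed; per-trial values are averaged over seeds before group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ModelConfig, Checkpoint, train_model, forward_batch, pad_batch
from .preprocess import DecodingSample, make_folds, upsample_minority

__all__ = ["UQProtocolConfig", "mcd_infer", "run_protocol", "group_uncertainty"]


@dataclass
class UQProtocolConfig:
    k_folds: int = 20
    n_seeds: int = 10
    T: int = 1000
    upsample: bool = False
    #: which trials the dataset builder must exclude before the protocol runs,
    #: and under which labeling; consumed by the CLI when assembling datasets
    label_mode: str = "response"
    exclusions: tuple = ("premovement", "UR")

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("T must be >= 2 (variance undefined below that)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def mcd_infer(
    checkpoint,
    segments,
    T: int = 1000,
    rng: np.random.Generator | None = None,
    config: ModelConfig | None = None,
    batch_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the class-1 probability over T dropout passes.

    ``segments`` is one (n, 9) matrix or a list of them; returns arrays of
    per-trial means and variances (scalars squeeze out for a single segment).
    """
    if T < 2:
        raise ValueError("T must be >= 2 for a variance")
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(checkpoint, Checkpoint):
        params, config = checkpoint.params, checkpoint.config
    else:
        params = checkpoint
        if config is None:
            raise ValueError("config required with raw parameters")
    single = isinstance(segments, np.ndarray) and segments.ndim == 2
    seglist = [segments] if single else [np.asarray(s) for s in segments]
    bs = batch_size or config.batch_test

    means = np.empty(len(seglist))
    variances = np.empty(len(seglist))
    for i in range(0, len(seglist), bs):
        chunk = seglist[i : i + bs]
        x, mask = pad_batch(chunk)
        p1 = np.empty((T, len(chunk)))
        for t in range(T):
            p1[t] = forward_batch(params, x, mask, config, dropout=True, rng=rng)[:, 1]
        means[i : i + len(chunk)] = p1.mean(axis=0)
        variances[i : i + len(chunk)] = p1.var(axis=0, ddof=0)
    if single:
        return float(means[0]), float(variances[0])
    return means, variances


def run_protocol(
    dataset: Sequence[DecodingSample],
    model_config: ModelConfig,
    protocol: UQProtocolConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold x n-seed Monte Carlo dropout over a labeled dataset.

    Exclusions (premovement, UR) are expected to have been applied when the
    dataset was labeled.  Returns one row per (trial, seed) with the trial's
    mean prediction, uncertainty and metadata.  All randomness derives from
    ``seed`` via independent substreams per (seed, fold).
    """
    protocol = protocol or UQProtocolConfig()
    labels = [s.label for s in dataset]
    root = np.random.SeedSequence(seed)
    seed_seqs = root.spawn(protocol.n_seeds)

    rows = []
    for s_idx, sseq in enumerate(seed_seqs):
        fold_seed = int(sseq.generate_state(1)[0] % (2**31 - 1))
        splits = make_folds(labels, k=protocol.k_folds, seed=fold_seed)
        for split in splits:
            sub = sseq.spawn(1)[0]
            cfg = replace(model_config, seed=int(sub.generate_state(1)[0] % (2**31 - 1)) + split.fold_id)
            train = [dataset[i] for i in split.train_idx]
            if protocol.upsample:
                train = upsample_minority(train)
            ckpt = train_model(train, [dataset[i] for i in split.val_idx], cfg)
            rng = np.random.default_rng(np.random.SeedSequence((fold_seed, split.fold_id)))
            test = [dataset[i] for i in split.test_idx]
            mean, var = mcd_infer(ckpt, [t.segment for t in test], T=protocol.T, rng=rng)
            for t_local, idx in enumerate(split.test_idx):
                m = dataset[idx].meta
                rows.append(
                    {
                        "trial_id": m.get("trial_id", idx),
                        "day": m.get("day"),
                        "frequency": m.get("frequency"),
                        "outcome": m.get("outcome"),
                        "prev_outcome": m.get("prev_outcome"),
                        "label": dataset[idx].label,
                        "mean_prediction": mean[t_local],
                        "uncertainty": var[t_local],
                        "fold": split.fold_id,
                        "seed": s_idx,
                    }
                )
    return pd.DataFrame(rows)


_STAGE_BY_DAY = lambda d: "naive" if d <= 3 else ("expert" if d >= 6 else "middle")


def group_uncertainty(
    records: pd.DataFrame,
    by: str = "day",
    categories: Sequence | None = None,
) -> pd.DataFrame:
    """Mean / sem / n of seed-averaged per-trial uncertainty per group.

    ``by`` is one of ``day``, ``frequency``, ``response_type`` (the outcome),
    ``prev_current_pair`` (previous trial's outcome paired with the current
    one) or ``learning_stage`` (days 1-3 naive, 6-8 expert).  Per-trial
    uncertainties are first averaged across protocol seeds.  ``categories``
    optionally fixes the group set; empty groups then report n = 0 and no mean.
    """
    if len(records) == 0:
        raise ValueError("no uncertainty records")
    agg = {"uncertainty": "mean", "day": "first", "frequency": "first",
           "outcome": "first", "prev_outcome": "first"}
    per_trial = records.groupby("trial_id", dropna=False).agg(agg).reset_index()
    if by == "day":
        keys = per_trial["day"]
    elif by == "frequency":
        keys = per_trial["frequency"]
    elif by == "response_type":
        keys = per_trial["outcome"]
    elif by == "prev_current_pair":
        keys = list(zip(per_trial["prev_outcome"], per_trial["outcome"]))
    elif by == "learning_stage":
        keys = per_trial["day"].map(_STAGE_BY_DAY)
    else:
        raise ValueError(f"unknown grouping {by!r}")
    per_trial = per_trial.assign(_group=pd.Series(keys, index=per_trial.index))
    g = per_trial.groupby("_group", dropna=True)["uncertainty"]
    out = pd.DataFrame(
        {"mean": g.mean(), "sem": g.sem(ddof=1), "n": g.size()}
    ).rename_axis(by)
    if categories is not None:
        out = out.reindex(categories)
        out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()


def predictive_entropy(mean_prediction: np.ndarray) -> np.ndarray:
    """Binary entropy (nats) of the MCD mean prediction, a secondary UQ metric."""
    p = np.clip(np.asarray(mean_prediction, dtype=float), 1e-12, 1 - 1e-12)
    return -(p * np.log(p) + (1 - p) * np.log(1 - p))
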