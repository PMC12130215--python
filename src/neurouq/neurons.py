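"""Go-neuron and lick-neuron classification from baseline z-scored traces.

A go neuron must (1) cross z > 2 within +200 ms (6 frames) of stimulus onset
in more than 60% of go trials, (2) sit in the top 5% of a label-permutation
null of the ROC AUC separating go from non-go trials, and (3) show no such
activity in FA and UR trials.  A lick neuron must satisfy the analogous
criteria (1) and (2) with traces realigned to lick onset.

The per-trial scalar fed to the ROC is the peak z within the 6-frame
post-onset window.  "No activity" on FA/UR is operationalised as a
criterion-1 event rate of at most 40% on those trials: the z > 2-in-6-frames
event fires on roughly 15% of pure-noise trials, so the bound sits between
that floor and the 60% activity criterion.  Lick events are measured as the
post-lick *increase* over the immediately pre-lick frames, so that a
stimulus-locked transient still decaying through the lick does not register
as lick-locked.  All thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ZScoredRecording
from .synth import ONSET_INDEX, N_FRAMES

__all__ = ["ClassifierParams", "permutation_auc", "classify_go", "classify_lick"]


@dataclass
class ClassifierParams:
    z_threshold: float = 2.0
    window_frames: int = 6  # +200 ms at 30 fps
    min_event_fraction: float = 0.6  # "> 60% of trials", strict
    auc_percentile_min: float = 95.0
    fa_ur_event_max: float = 0.4
    n_permutations: int = 1000


def _rank_auc(activity: np.ndarray, positive: np.ndarray) -> float:
    """ROC AUC ("positive class higher") via the rank-sum identity, midranks for ties."""
    n1 = int(positive.sum())
    n0 = len(positive) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one trial in each class")
    order = np.argsort(activity, kind="mergesort")
    ranks = np.empty(len(activity))
    ranks[order] = np.arange(1, len(activity) + 1)
    # midranks for ties
    vals, inv, cnt = np.unique(activity, return_inverse=True, return_counts=True)
    if len(vals) < len(activity):
        cum = np.cumsum(cnt)
        mid = cum - (cnt - 1) / 2.0
        ranks = mid[inv]
    return float((ranks[positive].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def permutation_auc(
    activity: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Observed AUC plus its percentile against a label-permutation null.

    The percentile is the fraction of permuted AUCs at or below the observed
    one (ties counted half, i.e. midrank), times 100.
    """
    if rng is None:
        rng = np.random.default_rng()
    activity = np.asarray(activity, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 trials per class")

    auc = _rank_auc(activity, labels)

    # vectorised null: AUC is a linear function of the summed positive ranks
    n = len(labels)
    n1 = int(labels.sum())
    n0 = n - n1
    vals, inv, cnt = np.unique(activity, return_inverse=True, return_counts=True)
    cum = np.cumsum(cnt)
    ranks = (cum - (cnt - 1) / 2.0)[inv]
    perm_sums = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_sums[i] = ranks[rng.permutation(n)[:n1]].sum()
    null_aucs = (perm_sums - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    less = np.count_nonzero(null_aucs < auc - 1e-12)
    equal = np.count_nonzero(np.abs(null_aucs - auc) <= 1e-12)
    percentile = 100.0 * (less + 0.5 * equal) / n_permutations
    return auc, float(percentile)


def _event_stats(
    z: np.ndarray, onsets: np.ndarray, params: ClassifierParams, relative: bool = False
):
    """Per neuron x trial: event flag and scalar response in the post-onset window.

    ``onsets`` gives each trial's 0-based alignment frame; the window is the
    6 frames strictly after it.  With ``relative`` the response is the
    post-window peak minus the mean of the 6 frames up to and including the
    alignment frame (a lick-locked *increase*), otherwise the raw peak z.
    """
    n, _, t = z.shape
    events = np.zeros((n, t), dtype=bool)
    peaks = np.full((n, t), -np.inf)
    for j in range(t):
        a = int(onsets[j])
        start = a + 1
        stop = min(start + params.window_frames, N_FRAMES)
        if start >= N_FRAMES:
            continue
        resp = z[:, start:stop, j].max(axis=1)
        if relative:
            pre = z[:, max(0, a - params.window_frames + 1) : a + 1, j].mean(axis=1)
            resp = resp - pre
        events[:, j] = resp > params.z_threshold
        peaks[:, j] = resp
    return events, peaks


def _classify(
    z: np.ndarray,
    onsets: np.ndarray,
    positive_trials: np.ndarray,
    neuron_ids,
    params: ClassifierParams,
    rng: np.random.Generator,
    veto_trials: np.ndarray | None = None,
    relative: bool = False,
) -> pd.DataFrame:
    events, peaks = _event_stats(z, onsets, params, relative=relative)
    rows = []
    for i in range(z.shape[0]):
        c1 = events[i, positive_trials].mean() > params.min_event_fraction
        auc, pct = permutation_auc(
            peaks[i], positive_trials, n_permutations=params.n_permutations, rng=rng
        )
        c2 = pct >= params.auc_percentile_min
        if veto_trials is None:
            c3, vacuous = True, False
        elif not veto_trials.any():
            c3, vacuous = True, True
        else:
            c3 = events[i, veto_trials].mean() <= params.fa_ur_event_max
            vacuous = False
        rows.append(
            {
                "neuron_id": neuron_ids[i],
                "c1_event_rate": c1,
                "c2_auc_top5": c2,
                "c3_no_fa_ur": c3,
                "c3_vacuous": vacuous,
                "auc": auc,
                "auc_percentile": pct,
                "n_permutations": params.n_permutations,
            }
        )
    return pd.DataFrame(rows)


def classify_go(
    zrec: ZScoredRecording,
    params: ClassifierParams | None = None,
    rng: np.random.Generator | None = None,
    neuron_ids=None,
) -> pd.DataFrame:
    """Per-neuron go classification: all three criteria must hold.

    Go trials are the positive class; the ROC contrasts them against every
    other trial.  When no FA or UR trials exist, criterion 3 is vacuously true
    and flagged in the ``c3_vacuous`` column.
    """
    params = params or ClassifierParams()
    if rng is None:
        rng = np.random.default_rng()
    tt = zrec.trial_table
    ttype = tt["trial_type"].to_numpy()
    go = ttype == "go"
    if not go.any():
        raise ValueError("no go trials in the recording")
    veto = np.isin(tt["outcome"].to_numpy(), ["FA", "UR"])
    onsets = np.full(len(tt), ONSET_INDEX)
    ids = neuron_ids if neuron_ids is not None else list(range(zrec.z.shape[0]))
    df = _classify(zrec.z, onsets, go, ids, params, rng, veto_trials=veto)
    df["is_go"] = df["c1_event_rate"] & df["c2_auc_top5"] & df["c3_no_fa_ur"]
    return df


def classify_lick(
    zrec: ZScoredRecording,
    params: ClassifierParams | None = None,
    rng: np.random.Generator | None = None,
    neuron_ids=None,
) -> pd.DataFrame:
    """Per-neuron lick classification on lick-realigned activity (two criteria).

    Lick trials use their own lick frame as the alignment point; non-lick
    trials (which have no lick to realign to) are summarised at the median
    lick frame so the ROC contrast is computed over comparable windows.
    Events and the ROC summary are post-lick increases over the pre-lick
    frames, so stimulus transients decaying through the lick do not qualify.
    """
    params = params or ClassifierParams()
    if rng is None:
        rng = np.random.default_rng()
    tt = zrec.trial_table
    if "lick_frame" not in tt.columns:
        raise ValueError("trial table lacks lick frames")
    lick_frames = tt["lick_frame"].to_numpy()
    licked = lick_frames >= 0
    if not licked.any():
        raise ValueError("no lick trials in the recording")
    onsets = np.where(licked, lick_frames, int(np.median(lick_frames[licked])))
    ids = neuron_ids if neuron_ids is not None else list(range(zrec.z.shape[0]))
    df = _classify(zrec.z, onsets, licked, ids, params, rng, veto_trials=None, relative=True)
    df = df.drop(columns=["c3_no_fa_ur", "c3_vacuous"])
    df["is_lick"] = df["c1_event_rate"] & df["c2_auc_top5"]
    return df
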