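"""From recordings to labeled, scaled, windowed decoding samples and CV folds.

Frame conventions (fixed across the package): frames are numbered 1-based and
inclusive in all public APIs, matching the trial layout (baseline frames 1-30,
stimulus onset frame 31).  The default decoding window is frames 29-37 - nine
frames of which seven are at or after onset, i.e. 0.233 s of post-stimulus
activity, early enough to precede the trained animals' minimum response time.

Two parallel scalings feed different consumers: baseline z-scores (per neuron,
per trial, population-sd denominator) feed neuron classification, while the
decoder consumes min-max-scaled raw traces (per neuron over the whole session
by default, preserving trial-to-trial amplitude differences that carry choice
information).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .synth import PopulationRecording, N_FRAMES, PAW_FPS

__all__ = [
    "DecodingSample",
    "ZScoredRecording",
    "DatasetSplit",
    "zscore_to_baseline",
    "extract_segments",
    "flag_premovement",
    "label_samples",
    "make_decoding_dataset",
    "upsample_minority",
    "make_folds",
]

DEFAULT_WINDOW = (29, 37)  # 1-based inclusive
DEFAULT_BASELINE = (1, 30)


@dataclass
class DecodingSample:
    """One trial's (n_neurons, 9) scaled segment plus label and trial metadata."""

    segment: np.ndarray
    label: int | None = None
    label_mode: str | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class ZScoredRecording:
    """Baseline z-scored traces, same shape as the source recording."""

    z: np.ndarray  # (n_neurons, 120, n_trials)
    baseline_window: tuple
    trial_table: pd.DataFrame
    degenerate: np.ndarray | None = None  # (n_neurons, n_trials) flags where sd was 0


@dataclass
class DatasetSplit:
    fold_id: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 0


def _to_slice(window_1based: tuple) -> slice:
    a, b = window_1based
    return slice(a - 1, b)


def zscore_to_baseline(
    recording: PopulationRecording,
    baseline_window: tuple = DEFAULT_BASELINE,
    degenerate_policy: str = "error",
) -> ZScoredRecording:
    """Per neuron, per trial: z = (x - baseline mean) / baseline sd.

    The baseline is the 1-s pre-stimulus phase (frames 1-30).  The sd uses the
    population denominator (ddof 0).  A zero baseline sd raises by default;
    with ``degenerate_policy='zero'`` the affected neuron/trial emits zeros
    and is flagged.
    """
    sl = _to_slice(baseline_window)
    if sl.stop <= sl.start:
        raise ValueError("baseline window is empty")
    x = recording.traces
    mu = x[:, sl, :].mean(axis=1, keepdims=True)
    sd = x[:, sl, :].std(axis=1, keepdims=True, ddof=0)
    bad = sd[:, 0, :] == 0.0
    if bad.any():
        if degenerate_policy == "error":
            raise ValueError(
                f"{int(bad.sum())} neuron/trial baselines have zero sd; "
                "pass degenerate_policy='zero' to emit zeros instead"
            )
        if degenerate_policy != "zero":
            raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (x - mu) / safe_sd
    z = np.where(sd == 0.0, 0.0, z)
    return ZScoredRecording(
        z=z,
        baseline_window=baseline_window,
        trial_table=recording.trial_table,
        degenerate=bad if bad.any() else None,
    )


def extract_segments(
    recording: PopulationRecording,
    frame_window: tuple = DEFAULT_WINDOW,
    scaling: str = "per_neuron",
) -> list[DecodingSample]:
    """Min-max scale traces to [0, 1], then cut the decoding window per trial.

    ``scaling`` scopes the min/max: ``per_neuron`` (default; over all frames
    and trials of the session), ``per_segment`` (within each extracted
    segment) or ``global`` (whole session tensor).  Constant traces map to 0.
    """
    a, b = frame_window
    if not (1 <= a <= b <= N_FRAMES):
        raise ValueError(f"frame window must lie within 1..{N_FRAMES}")
    if b - a + 1 != 9:
        warnings.warn(
            f"decoding window {frame_window} has {b - a + 1} frames (expected 9); proceeding",
            stacklevel=2,
        )
    x = recording.traces
    sl = _to_slice(frame_window)

    def _scale(arr, lo, hi):
        rng_ = hi - lo
        rng_ = np.where(rng_ == 0.0, 1.0, rng_)
        return np.clip((arr - lo) / rng_, 0.0, 1.0)

    if scaling == "per_neuron":
        lo = x.min(axis=(1, 2), keepdims=True)
        hi = x.max(axis=(1, 2), keepdims=True)
        scaled = _scale(x, lo, hi)[:, sl, :]
    elif scaling == "global":
        scaled = _scale(x, x.min(), x.max())[:, sl, :]
    elif scaling == "per_segment":
        seg = x[:, sl, :]
        lo = seg.min(axis=(0, 1), keepdims=True)
        hi = seg.max(axis=(0, 1), keepdims=True)
        scaled = _scale(seg, lo, hi)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")

    tt = recording.trial_table
    out = []
    for j in range(recording.n_trials):
        row = tt.iloc[j]
        out.append(
            DecodingSample(
                segment=scaled[:, :, j].copy(),
                label=None,
                meta={
                    "trial_id": f"{recording.session_id}_t{int(row['trial_index']):04d}",
                    "trial_type": row["trial_type"],
                    "frequency": row["frequency"],
                    "outcome": row.get("outcome"),
                    "lick": bool(row["lick"]) if "lick" in row else None,
                    "day": row.get("day", recording.day),
                    "session_id": recording.session_id,
                    "mouse_id": recording.mouse_id,
                    "trial_index": int(row["trial_index"]),
                    "premovement": bool(row["premovement"]) if "premovement" in row else None,
                },
            )
        )
    return out


def flag_premovement(
    paw_coords: np.ndarray,
    threshold_px: float = 60.0,
    window_s: tuple = (0.5, 1.0),
    fps: int = PAW_FPS,
) -> np.ndarray:
    """Premovement mask per trial from paw coordinates (trials, samples, 2).

    A trial is flagged when the Euclidean displacement from the position at the
    window start strictly exceeds ``threshold_px`` anywhere inside the 0.5-1.0 s
    pre-stimulus window.  Trials with missing (NaN) coordinates in the window
    are flagged conservatively, so they are excluded downstream.
    """
    w0, w1 = int(round(window_s[0] * fps)), int(round(window_s[1] * fps))
    win = paw_coords[:, w0:w1, :]
    disp = np.linalg.norm(win - win[:, :1, :], axis=2)
    with np.errstate(invalid="ignore"):
        flags = np.nanmax(disp, axis=1) > threshold_px
    unknown = np.isnan(win).any(axis=(1, 2))
    return flags | unknown


_UQ_OUTCOME_LABELS = {"hit": 1, "FA": 1, "PL": 1, "RO": 1, "UR": 1, "miss": 0, "CR": 0, "PNL": 0}


def label_samples(
    samples: Sequence[DecodingSample],
    label_mode: str = "stimulus",
    pair: tuple | None = None,
    exclude_premovement: bool = True,
    exclude_ur: bool = True,
) -> list[DecodingSample]:
    """Attach binary labels and apply mode-specific trial filters.

    ``stimulus``: keeps only 200/600 Hz trials (0 <-> 200 Hz, 1 <-> 600 Hz).
    ``response``: all frequencies, 0 <-> no lick, 1 <-> lick; UR trials are
    dropped when ``exclude_ur`` (they are always licked by cue, not choice).
    ``response_pair``: keeps exactly the two outcomes in ``pair``, labelling
    ``pair[0]`` as 0 and ``pair[1]`` as 1 (e.g. ("miss", "hit")).
    Premovement trials are excluded whenever the flag is available.
    """
    if label_mode not in ("stimulus", "response", "response_pair"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    if label_mode == "response_pair":
        if pair is None or len(pair) != 2:
            raise ValueError("response_pair mode requires pair=(outcome0, outcome1)")

    out = []
    for s in samples:
        m = s.meta
        if exclude_premovement and m.get("premovement"):
            continue
        if label_mode == "stimulus":
            if m.get("frequency") not in (200.0, 600.0):
                continue
            label = 1 if m["frequency"] == 600.0 else 0
        elif label_mode == "response":
            if exclude_ur and m.get("outcome") == "UR":
                continue
            lick = m.get("lick")
            if lick is None:
                lick = _UQ_OUTCOME_LABELS.get(m.get("outcome"))
                if lick is None:
                    continue
            label = int(lick)
        else:
            if m.get("outcome") not in pair:
                continue
            label = int(m["outcome"] == pair[1])
        out.append(DecodingSample(segment=s.segment, label=label, label_mode=label_mode, meta=m))

    if label_mode == "response_pair":
        present = {s.meta.get("outcome") for s in out}
        if len(present) < 2:
            raise ValueError(f"fewer than 2 outcomes of pair {pair} present in data")
    return out


def make_decoding_dataset(
    recordings: Sequence[PopulationRecording],
    label_mode: str = "response",
    pair: tuple | None = None,
    frame_window: tuple = DEFAULT_WINDOW,
    scaling: str = "per_neuron",
    exclude_premovement: bool = True,
    exclude_ur: bool = True,
    use_true_premovement: bool = False,
) -> list[DecodingSample]:
    """Extract, annotate previous-trial outcomes, and label across sessions.

    Premovement flags come from each recording's paw trajectories when present
    (or from the simulator's ground-truth flags with ``use_true_premovement``).
    """
    all_samples = []
    for rec in recordings:
        samples = extract_segments(rec, frame_window=frame_window, scaling=scaling)
        tt = rec.trial_table
        if use_true_premovement and "premovement_true" in tt.columns:
            flags = tt["premovement_true"].to_numpy(dtype=bool)
        elif rec.paw is not None:
            flags = flag_premovement(rec.paw)
        else:
            flags = np.zeros(len(tt), dtype=bool)
        outcomes = tt["outcome"].tolist() if "outcome" in tt.columns else [None] * len(tt)
        for j, s in enumerate(samples):
            s.meta["premovement"] = bool(flags[j])
            s.meta["prev_outcome"] = outcomes[j - 1] if j > 0 else None
        all_samples.extend(samples)
    return label_samples(
        all_samples,
        label_mode=label_mode,
        pair=pair,
        exclude_premovement=exclude_premovement,
        exclude_ur=exclude_ur,
    )


def upsample_minority(train_samples: Sequence[DecodingSample]) -> list[DecodingSample]:
    """Duplicate minority-class samples (cycling in order) until classes balance.

    Intended for the training partition only; duplicating into validation or
    test sets would leak and inflate accuracy.
    """
    labels = np.asarray([s.label for s in train_samples])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes to balance")
    if counts.min() == 0:
        raise ValueError("minority class is empty")
    if counts[0] == counts[1]:
        return list(train_samples)
    minority = classes[np.argmin(counts)]
    minority_samples = [s for s in train_samples if s.label == minority]
    need = int(counts.max() - counts.min())
    extra = [minority_samples[i % len(minority_samples)] for i in range(need)]
    return list(train_samples) + extra


def make_folds(
    labels: Sequence[int] | Sequence[DecodingSample],
    k: int = 20,
    train_frac_of_rest: float = 0.8,
    seed: int = 0,
) -> list[DatasetSplit]:
    """Stratified k-fold test partition; the remainder splits 80/20 train/val.

    With k = 20 this yields the 76% / 19% / 5% train/validation/test
    proportions.  The k test sets partition the dataset; splits depend only on
    (labels, k, seed).
    """
    if len(labels) and isinstance(labels[0], DecodingSample):
        labels = [s.label for s in labels]
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("dataset smaller than k")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("each class needs at least k members to stratify")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for fold_id, (rest, test) in enumerate(skf.split(np.zeros(len(y)), y), start=1):
        tr, va = train_test_split(
            rest,
            train_size=train_frac_of_rest,
            stratify=y[rest],
            random_state=seed + fold_id,
        )
        splits.append(
            DatasetSplit(
                fold_id=fold_id,
                train_idx=np.sort(tr),
                val_idx=np.sort(va),
                test_idx=np.sort(test),
                seed=seed,
            )
        )
    return splits
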