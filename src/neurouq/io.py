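"""HDF5 / CSV persistence for recordings, trial tables and result tables.

Recording schema (versioned in ``/meta``): ``/traces`` holds the
(neurons x frames x trials) tensor, ``/trial_table`` one dataset per column
(strings as UTF-8 bytes), ``/paw`` the optional paw trajectories, and
``/meta`` attributes carry frame rate and identifiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .synth import PopulationRecording

SCHEMA_VERSION = "1"

__all__ = [
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_splits_csv",
    "read_splits_csv",
    "SCHEMA_VERSION",
]


def _encode_column(values: pd.Series):
    arr = values.to_numpy()
    if arr.dtype == object or arr.dtype.kind in "U":
        return np.array(["" if v is None or v is np.nan else str(v) for v in arr], dtype="S32")
    return arr


def write_recording(path: str, rec: PopulationRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces, compression="gzip", compression_opts=4)
        tg = f.create_group("trial_table")
        for col in rec.trial_table.columns:
            tg.create_dataset(col, data=_encode_column(rec.trial_table[col]))
        if rec.paw is not None:
            f.create_dataset("paw", data=rec.paw, compression="gzip", compression_opts=4)
        if rec.ground_truth:
            gg = f.create_group("ground_truth")
            for k, v in rec.ground_truth.items():
                gg.create_dataset(k, data=np.asarray(v))
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["frame_rate"] = rec.frame_rate
        meta.attrs["session_id"] = rec.session_id
        meta.attrs["mouse_id"] = rec.mouse_id
        meta.attrs["day"] = rec.day
        meta.create_dataset("neuron_ids", data=np.array(rec.neuron_ids, dtype="S32"))


_BOOL_COLS = {"lick", "premovement", "premovement_true"}
_INT_COLS = {"trial_index", "lick_frame", "day"}


def read_recording(path: str) -> PopulationRecording:
    with h5py.File(path, "r") as f:
        traces = f["traces"][...]
        cols = {}
        for col in f["trial_table"]:
            data = f["trial_table"][col][...]
            if data.dtype.kind == "S":
                vals = [v.decode() for v in data]
                cols[col] = [None if v == "" else v for v in vals]
            else:
                cols[col] = data
        tt = pd.DataFrame(cols)
        for c in tt.columns:
            if c in _BOOL_COLS and tt[c].dtype != bool:
                tt[c] = tt[c].astype(bool)
        meta = f["meta"]
        rec = PopulationRecording(
            traces=traces,
            trial_table=tt,
            neuron_ids=[v.decode() for v in meta["neuron_ids"][...]],
            frame_rate=int(meta.attrs["frame_rate"]),
            session_id=str(meta.attrs["session_id"]),
            mouse_id=str(meta.attrs["mouse_id"]),
            day=int(meta.attrs["day"]),
            ground_truth={k: f["ground_truth"][k][...] for k in f.get("ground_truth", [])},
            paw=f["paw"][...] if "paw" in f else None,
        )
    return rec


def write_dataset(path: str, samples) -> None:
    """Persist labeled decoding samples (variable neuron counts) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["n_samples"] = len(samples)
        for i, s in enumerate(samples):
            g = f.create_group(f"samples/{i:06d}")
            g.create_dataset("segment", data=np.asarray(s.segment))
            g.attrs["label"] = -1 if s.label is None else int(s.label)
            g.attrs["label_mode"] = s.label_mode or ""
            for k, v in (s.meta or {}).items():
                if v is None:
                    continue
                g.attrs[f"meta_{k}"] = v


def read_dataset(path: str):
    from .preprocess import DecodingSample

    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f["samples"]):
            g = f["samples"][key]
            label = int(g.attrs["label"])
            meta = {
                k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in g.attrs.items()
                if k.startswith("meta_")
            }
            out.append(
                DecodingSample(
                    segment=g["segment"][...],
                    label=None if label < 0 else label,
                    label_mode=str(g.attrs["label_mode"]) or None,
                    meta=meta,
                )
            )
    return out


def write_splits_csv(path: str, splits, trial_ids=None) -> None:
    """Fold assignments as tidy CSV: trial_id, fold, role, seed."""
    rows = []
    for sp in splits:
        for role, idx in (("train", sp.train_idx), ("val", sp.val_idx), ("test", sp.test_idx)):
            for i in idx:
                rows.append(
                    {
                        "trial_id": trial_ids[i] if trial_ids is not None else i,
                        "fold": sp.fold_id,
                        "role": role,
                        "seed": sp.seed,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_splits_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
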