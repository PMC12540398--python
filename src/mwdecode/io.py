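"""Dataset directory I/O.

A dataset directory holds one HDF5 file per participant (EEG epochs, force
traces, ratings, labels), a ``manifest.csv`` with one row per trial, and a
``dataset.json`` recording the task and effect configurations and the seed,
so that a written dataset round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import EffectConfig, TaskConfig
from .synth import ParticipantRecord, SyntheticDataset, TrialRecord

_CONFIG_FILE = "dataset.json"
_MANIFEST_FILE = "manifest.csv"


class DatasetIOError(OSError):
    """Raised when a dataset directory is malformed or unreadable."""


def _participant_file(path: Path, pid: str) -> Path:
    return path / f"sub-{pid}.h5"


def write_dataset(ds: SyntheticDataset, path) -> None:
    """Write a dataset directory (HDF5 per participant + manifest + config)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cfg = {
        "task_config": dataclasses.asdict(ds.task_config),
        "effect_config": dataclasses.asdict(ds.effect_config),
        "seed": ds.seed,
        "participants": [p.participant_id for p in ds.participants],
    }
    (path / _CONFIG_FILE).write_text(json.dumps(cfg, indent=2))

    rows = []
    for part in ds.participants:
        with h5py.File(_participant_file(path, part.participant_id), "w") as f:
            f.attrs["participant_id"] = part.participant_id
            f.create_dataset(
                "eeg", data=np.stack([t.eeg for t in part.trials]),
                compression="gzip", compression_opts=1)
            f.create_dataset(
                "force_target",
                data=np.stack([t.force_target for t in part.trials]))
            f.create_dataset(
                "force_output",
                data=np.stack([t.force_output for t in part.trials]))
            f.create_dataset(
                "rating", data=np.array([t.rating for t in part.trials]))
            f.create_dataset(
                "probe_time_s",
                data=np.array([t.probe_time_s for t in part.trials]))
            f.create_dataset(
                "condition_label",
                data=np.array([t.condition_label for t in part.trials],
                              dtype="S12"))
        for t in part.trials:
            rows.append({
                "participant_id": t.participant_id,
                "trial_index": t.trial_index,
                "rating": t.rating,
                "probe_time_s": t.probe_time_s,
                "condition_label": t.condition_label,
            })
    pd.DataFrame(rows).to_csv(path / _MANIFEST_FILE, index=False)


def read_dataset(path) -> SyntheticDataset:
    """Read back a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    cfg_file = path / _CONFIG_FILE
    if not cfg_file.is_file():
        raise DatasetIOError(f"missing {cfg_file}")
    try:
        cfg = json.loads(cfg_file.read_text())
    except json.JSONDecodeError as exc:
        raise DatasetIOError(f"malformed {cfg_file}: {exc}") from exc

    task_cfg = TaskConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in cfg["task_config"].items()})
    effect_cfg = EffectConfig(**cfg["effect_config"])

    participants: list[ParticipantRecord] = []
    for pid in cfg["participants"]:
        fname = _participant_file(path, pid)
        if not fname.is_file():
            raise DatasetIOError(f"missing participant file {fname}")
        try:
            with h5py.File(fname, "r") as f:
                eeg = f["eeg"][()]
                target = f["force_target"][()]
                output = f["force_output"][()]
                rating = f["rating"][()]
                probe = f["probe_time_s"][()]
                labels = [s.decode() for s in f["condition_label"][()]]
        except (OSError, KeyError) as exc:
            raise DatasetIOError(
                f"cannot parse participant file {fname}: {exc}") from exc
        trials = [
            TrialRecord(participant_id=pid, trial_index=i,
                        rating=float(rating[i]), eeg=eeg[i],
                        force_target=target[i], force_output=output[i],
                        condition_label=labels[i],
                        probe_time_s=float(probe[i]))
            for i in range(eeg.shape[0])
        ]
        participants.append(ParticipantRecord(participant_id=pid,
                                              trials=trials))
    return SyntheticDataset(participants=participants, task_config=task_cfg,
                            effect_config=effect_cfg, seed=cfg["seed"])
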