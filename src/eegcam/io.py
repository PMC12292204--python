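"""Dataset container I/O.

One HDF5 file holds the epoch stacks (one group per subject, one dataset
per task); a JSON sidecar carries the epoch geometry and labels; the
montage travels as a CSV (name,x,y,region).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import h5py
import numpy as np
import pandas as pd

from .montage import Montage
from .synth import Dataset, Epoch, EpochSpec, SubjectRecord, TASKS


def save_montage_csv(montage: Montage, path) -> None:
    pd.DataFrame({
        "name": montage.channel_names,
        "x": montage.positions[:, 0],
        "y": montage.positions[:, 1],
        "region": [montage.region_map[n] for n in montage.channel_names],
    }).to_csv(path, index=False)


def load_montage_csv(path) -> Montage:
    df = pd.read_csv(path)
    return Montage(
        tuple(df["name"]),
        df[["x", "y"]].to_numpy(dtype=float),
        dict(zip(df["name"], df["region"])),
    )


def save_dataset(dataset: Dataset, h5_path, sidecar_path=None,
                 montage_path=None) -> None:
    h5_path = Path(h5_path)
    sidecar_path = Path(sidecar_path or h5_path.with_suffix(".json"))
    montage_path = Path(montage_path or h5_path.with_name("montage.csv"))
    meta: Dict = {
        "epoch_spec": {
            "fs": dataset.spec.fs, "t_start": dataset.spec.t_start,
            "t_end": dataset.spec.t_end, "n_channels": dataset.spec.n_channels,
            "n_samples": dataset.spec.n_samples,
        },
        "montage_file": montage_path.name,
        "subjects": [],
    }
    with h5py.File(h5_path, "w") as f:
        for subj in dataset.subjects:
            grp = f.create_group(subj.subject_id)
            entry = {"subject_id": subj.subject_id, "group": subj.group,
                     "n_trials": {}}
            for task in TASKS:
                eps = [ep for ep in subj.epochs if ep.task == task]
                entry["n_trials"][task] = len(eps)
                if eps:
                    grp.create_dataset(
                        task, data=np.stack([ep.data for ep in eps]),
                        compression="gzip", compression_opts=4)
            meta["subjects"].append(entry)
    sidecar_path.write_text(json.dumps(meta, indent=2))
    save_montage_csv(dataset.montage, montage_path)


def load_dataset(h5_path, sidecar_path=None, montage_path=None) -> Dataset:
    h5_path = Path(h5_path)
    sidecar_path = Path(sidecar_path or h5_path.with_suffix(".json"))
    meta = json.loads(sidecar_path.read_text())
    spec = EpochSpec(**meta["epoch_spec"])
    montage_path = Path(montage_path or h5_path.parent / meta["montage_file"])
    montage = load_montage_csv(montage_path)
    subjects: List[SubjectRecord] = []
    with h5py.File(h5_path, "r") as f:
        for entry in meta["subjects"]:
            sid, group = entry["subject_id"], entry["group"]
            epochs: List[Epoch] = []
            for task in TASKS:
                if entry["n_trials"].get(task, 0) and task in f[sid]:
                    for arr in f[sid][task][...]:
                        epochs.append(Epoch(arr, sid, group, task))
            subjects.append(SubjectRecord(sid, group, epochs))
    return Dataset(spec, montage, subjects)
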