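"""Reading and writing EEG recordings and label sequences.

Three on-disk forms are supported:

* a plain **matrix + JSON-header fixture format**: ``<stem>.json`` holds the
  sampling rate, channel labels, unit-sphere positions, reference state and
  annotations; ``<stem>.tsv`` holds the channels x samples matrix as
  tab-separated text.  This is the writable interchange format.
* **BrainVision** (``.vhdr``) and **EDF** files, read through MNE-Python.
* label sequences as one-label-per-line text with a small JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import Annotation, EEGRecording, LabelSequence

__all__ = [
    "write_fixture",
    "read_fixture",
    "read_brainvision",
    "read_edf",
    "write_labels",
    "read_labels",
    "write_model",
    "read_model",
    "write_labels_rle",
    "read_labels_rle",
]


def write_fixture(rec: EEGRecording, stem) -> tuple[Path, Path]:
    """Write a recording as ``<stem>.json`` + ``<stem>.tsv``."""
    stem = Path(stem)
    header = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "positions": rec.positions.tolist(),
        "reference": rec.reference,
        "annotations": [
            [a.onset, a.duration, a.condition, a.run] for a in rec.annotations
        ],
    }
    json_path = stem.with_suffix(".json")
    tsv_path = stem.with_suffix(".tsv")
    json_path.write_text(json.dumps(header))
    np.savetxt(tsv_path, rec.data, delimiter="\t", fmt="%.6g")
    return json_path, tsv_path


def read_fixture(stem) -> EEGRecording:
    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    data = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    return EEGRecording(
        data=data,
        fs=header["fs"],
        channel_labels=header["channel_labels"],
        positions=np.asarray(header["positions"]),
        reference=header.get("reference", "original"),
        annotations=[Annotation(*a) for a in header.get("annotations", [])],
    )


def _from_mne_raw(raw, condition_map=None) -> EEGRecording:
    """Convert an MNE Raw object (EEG channels only) to an EEGRecording."""
    raw = raw.copy().pick("eeg")
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = list(raw.ch_names)
    mont = raw.get_montage()
    if mont is not None:
        ch_pos = mont.get_positions()["ch_pos"]
        pos = np.array([ch_pos[l] for l in labels], dtype=float)
        pos = pos - pos.mean(axis=0)
        norms = np.linalg.norm(pos, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        pos = pos / norms
    else:
        from .montage import standard_1010_montage

        std = standard_1010_montage(labels)
        pos = std.positions
    anns = []
    for ann in raw.annotations:
        desc = ann["description"]
        cond = condition_map.get(desc, desc) if condition_map else desc
        anns.append(Annotation(float(ann["onset"]), float(ann["duration"]), cond))
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        positions=pos,
        annotations=anns,
    )


def read_brainvision(vhdr_path, condition_map=None) -> EEGRecording:
    """Read a BrainVision triplet (.vhdr/.vmrk/.eeg)."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return _from_mne_raw(raw, condition_map)


def read_edf(edf_path, condition_map=None) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    return _from_mne_raw(raw, condition_map)


def write_labels(seq: LabelSequence, stem) -> tuple[Path, Path]:
    """One label per line, with fs/n_classes/condition in a JSON sidecar."""
    stem = Path(stem)
    meta = {"fs": seq.fs, "n_classes": seq.n_classes, "condition": seq.condition}
    json_path = stem.with_suffix(".json")
    txt_path = stem.with_suffix(".labels.txt")
    json_path.write_text(json.dumps(meta))
    np.savetxt(txt_path, seq.labels, fmt="%d")
    return json_path, txt_path


def write_model(model, path) -> Path:
    """Serialize a microstate model as JSON (maps row-major)."""
    path = Path(path)
    payload = {
        "channel_labels": list(model.channel_labels),
        "n_classes": model.n_classes,
        "maps": model.maps.tolist(),
        "cost_f": None if np.isnan(model.cost_f) else model.cost_f,
        "cv": None if np.isnan(model.cv) else model.cv,
        "gev": None if np.isnan(model.gev_) else model.gev_,
        "seed": model.seed,
        "label_names": model.label_names,
    }
    path.write_text(json.dumps(payload))
    return path


def read_model(path):
    from .microstates import MicrostateModel

    d = json.loads(Path(path).read_text())
    nan = float("nan")
    return MicrostateModel(
        maps=np.asarray(d["maps"], dtype=float),
        channel_labels=d["channel_labels"],
        cost_f=d["cost_f"] if d["cost_f"] is not None else nan,
        cv=d["cv"] if d["cv"] is not None else nan,
        gev_=d["gev"] if d["gev"] is not None else nan,
        seed=d.get("seed"),
        label_names=d.get("label_names"),
    )


def write_labels_rle(seq: LabelSequence, path) -> Path:
    """Compact run-length CSV: one row per run (label, length)."""
    path = Path(path)
    labels = seq.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    lines = [f"# fs={seq.fs} n_classes={seq.n_classes} condition={seq.condition}",
             "label,length"]
    lines += [f"{labels[s]},{e - s}" for s, e in zip(starts, ends)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_labels_rle(path) -> LabelSequence:
    lines = Path(path).read_text().strip().splitlines()
    meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split(" "))
    runs = [tuple(map(int, ln.split(","))) for ln in lines[2:]]
    labels = np.concatenate([np.full(n, lab, dtype=np.int64) for lab, n in runs])
    return LabelSequence(
        labels=labels,
        fs=float(meta["fs"]),
        n_classes=int(meta["n_classes"]),
        condition=meta.get("condition", ""),
    )


def read_labels(stem) -> LabelSequence:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    labels = np.loadtxt(stem.with_suffix(".labels.txt"), dtype=np.int64, ndmin=1)
    return LabelSequence(
        labels=labels,
        fs=meta["fs"],
        n_classes=meta["n_classes"],
        condition=meta.get("condition", ""),
    )
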