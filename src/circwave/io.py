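"""Manifest/config handling, HDF5 stack persistence and run bookkeeping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .evaluate import FoldPlan, LeakageReport, verify_no_leakage  # re-export

__all__ = ["load_manifest", "save_stack_store", "load_stack_store",
           "RunConfig", "verify_no_leakage", "LeakageReport", "save_fold_plan",
           "load_fold_plan"]

REQUIRED_COLUMNS = ("subject_id", "label", "image_path")
DEFAULT_CLASSES = ("normal", "DME", "AMD")


def load_manifest(path, classes=DEFAULT_CLASSES) -> pd.DataFrame:
    """Load and validate a manifest CSV (subject_id, label, image_path)."""
    manifest = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    unknown = set(manifest["label"]) - set(classes)
    if unknown:
        raise ValueError(f"manifest contains unknown labels {sorted(unknown)}")
    dup = manifest["image_path"][manifest["image_path"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate image paths in manifest: {sorted(set(dup))}")
    return manifest


def save_stack_store(path, data: np.ndarray, channels, ids) -> None:
    """Persist an N x H x W x C float32 stack store with channel metadata."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError("stack store expects a homogeneous N x H x W x C array")
    if len(ids) != len(data):
        raise ValueError("one id per stack is required")
    chan = np.array([f"{n}:{s}:{b}" for n, s, b in channels])
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("channels", data=chan.astype("S"))
        f.create_dataset("ids", data=np.asarray(ids, dtype="S"))
        f.create_dataset("source_shape", data=np.asarray(data.shape[1:3]))


def load_stack_store(path):
    """Load a stack store; returns (data, channels, ids)."""
    with h5py.File(path, "r") as f:
        for key in ("data", "channels", "ids"):
            if key not in f:
                raise KeyError(f"stack store {path} is missing dataset {key!r}")
        data = f["data"][...]
        channels = []
        for raw in f["channels"][...]:
            name, stage, band = raw.decode().split(":")
            channels.append((name, int(stage), band))
        ids = [s.decode() for s in f["ids"][...]]
    return data, channels, ids


@dataclass
class RunConfig:
    """Serializable description of one run; all four seeds are explicit."""

    profile: str = "phantom"
    transform: str = "circwave"
    transform_params: dict = field(default_factory=dict)
    head: str = "msvm"
    kernel: str = "rbf"
    K: int = 5
    inner_K: int = 4
    cnn_epochs: int = 12
    seeds: dict = field(default_factory=lambda: {"data": 0, "folds": 1,
                                                 "cnn": 2, "head": 3})
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"data", "folds", "cnn", "head"} - set(self.seeds)
        if missing:
            raise ValueError(f"seeds must be explicit; missing {sorted(missing)}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def save_fold_plan(plan: FoldPlan, path) -> None:
    import json

    payload = {"K": plan.K, "seed": plan.seed, "outer_test": plan.outer_test,
               "inner": plan.inner}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_fold_plan(path) -> FoldPlan:
    import json

    payload = json.loads(Path(path).read_text())
    return FoldPlan(K=payload["K"], outer_test=payload["outer_test"],
                    inner=payload["inner"], seed=payload["seed"])
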