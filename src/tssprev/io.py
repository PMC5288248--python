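"""Delimited-text input/output and run manifests.

All files the package writes are plain comma-separated text with a header
row; metadata travels in leading ``#``-comment lines, and each results file
gets a JSON manifest recording the configuration, seed and package version
needed to reproduce it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .simulator import LabeledPredictions, get_scenario

__all__ = [
    "write_labeled_predictions",
    "read_labeled_predictions",
    "write_results",
    "read_results",
    "write_manifest",
]

PathLike = Union[str, Path]


def write_labeled_predictions(data: LabeledPredictions, path: PathLike) -> None:
    """Write one dataset as two-column CSV with metadata comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scenario: {data.scenario.name}\n")
        fh.write(f"# n_total: {data.n_total}\n")
        fh.write(f"# prevalence: {data.prevalence!r}\n")
        if data.seed is not None:
            fh.write(f"# seed: {data.seed}\n")
        fh.write("label,probability\n")
        for lab, prob in zip(data.labels, data.probs):
            fh.write(f"{int(lab)},{float(prob)!r}\n")


def read_labeled_predictions(path: PathLike) -> LabeledPredictions:
    """Read a dataset written by :func:`write_labeled_predictions`."""
    path = Path(path)
    meta: dict[str, str] = {}
    labels: list[int] = []
    probs: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    meta[key.strip()] = value.strip()
                continue
            first = line.split(",", 1)[0]
            if first == "label":
                continue
            lab_s, prob_s = line.split(",")
            labels.append(int(lab_s))
            probs.append(float(prob_s))
    if "scenario" not in meta:
        raise ValueError(f"{path} lacks a '# scenario:' metadata line")
    seed: Optional[object] = meta.get("seed")
    return LabeledPredictions(
        labels=np.asarray(labels, dtype=np.int8),
        probs=np.asarray(probs, dtype=float),
        scenario=get_scenario(meta["scenario"]),
        prevalence=float(meta["prevalence"]),
        seed=seed,
    )


def write_results(df: pd.DataFrame, path: PathLike, comments: Optional[dict] = None) -> None:
    """Write a results table as CSV with ``#`` metadata comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_results(path: PathLike) -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")


def write_manifest(
    results_path: PathLike,
    config,
    seed: int,
    runtime_s: float,
    extra: Optional[dict] = None,
) -> Path:
    """Write the JSON manifest accompanying a results file.

    The manifest echoes the full configuration, the root seed, the package
    version and per-run timing, which together suffice to reproduce the
    results file bit-for-bit.
    """
    results_path = Path(results_path)
    manifest_path = results_path.with_suffix(results_path.suffix + ".manifest.json")
    try:
        config_echo = asdict(config)
    except TypeError:
        config_echo = dict(config) if not isinstance(config, dict) else config
    payload = {
        "results_file": results_path.name,
        "config": _jsonable(config_echo),
        "seed": seed,
        "package_version": __version__,
        "runtime_s": round(runtime_s, 3),
        "written_at_unix": int(time.time()),
    }
    if extra:
        payload.update(_jsonable(extra))
    with open(manifest_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
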