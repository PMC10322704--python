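"""Session storage: landmark CSV, HDF5 trace store, TSV events, manifests.

A session directory holds:

* ``landmarks.csv``  — DeepLabCut-dialect CSV (scorer/bodyparts/coords
  3-row header; x, y, likelihood triplet per landmark)
* ``traces.h5``      — /cells/{raw,halo,time}, /behavior/{time,speed,lick}
* ``events.tsv``     — onset_s, type, value (rewards, stimulation epochs)
* ``speed.csv``      — time_s, speed_cmps
* ``ground_truth.json`` — generative weights/shares (synthetic sessions)
* ``manifest.yaml``  — rates, seeds and every parameter affecting results
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import synthetic as syn

__all__ = [
    "SessionBundle",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_events_tsv",
    "read_events_tsv",
    "save_session",
    "load_session",
    "manifest_hash",
    "dump_json",
]

log = logging.getLogger(__name__)

SCORER = "pupilcode-synthetic"
BODYPARTS = [f"pupil_edge_{i}" for i in range(8)]
EVENT_COLUMNS = ["onset_s", "type", "value"]


def write_landmarks_csv(path: str | Path, time_s: np.ndarray, x: np.ndarray,
                        y: np.ndarray, confidence: np.ndarray,
                        scorer: str = SCORER) -> None:
    """Write landmarks in the DeepLabCut CSV dialect."""
    n, k = x.shape
    cols = pd.MultiIndex.from_tuples(
        [(scorer, BODYPARTS[j], c) for j in range(k) for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"])
    data = np.empty((n, 3 * k))
    data[:, 0::3] = x
    data[:, 1::3] = y
    data[:, 2::3] = confidence
    pd.DataFrame(data, columns=cols).to_csv(path, index=True, index_label=None)


def read_landmarks_csv(path: str | Path,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Read a DeepLabCut-dialect landmark CSV -> (x, y, likelihood, bodyparts)."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                     float_precision="round_trip")
    coords = df.columns.get_level_values("coords")
    for needed in ("x", "y", "likelihood"):
        if needed not in set(coords):
            raise ValueError(f"landmark CSV missing '{needed}' coordinate columns")
    bodyparts = list(dict.fromkeys(df.columns.get_level_values("bodyparts")))
    x = df.loc[:, (slice(None), slice(None), "x")].to_numpy()
    y = df.loc[:, (slice(None), slice(None), "y")].to_numpy()
    conf = df.loc[:, (slice(None), slice(None), "likelihood")].to_numpy()
    return x, y, conf, bodyparts


def write_events_tsv(path: str | Path, events: pd.DataFrame) -> None:
    if list(events.columns) != EVENT_COLUMNS:
        raise ValueError(f"events must have columns {EVENT_COLUMNS}")
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"events TSV missing column '{col}'")
    return df


def manifest_hash(manifest: dict) -> str:
    """Stable hash of the canonical YAML form of a manifest."""
    canonical = yaml.safe_dump(manifest, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def dump_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(_to_jsonable(obj), sort_keys=True, indent=2) + "\n")


@dataclass
class SessionBundle:
    """In-memory session as loaded from disk."""

    manifest: dict
    landmark_time_s: np.ndarray
    landmark_x: np.ndarray
    landmark_y: np.ndarray
    landmark_conf: np.ndarray
    cell_time_s: np.ndarray
    cell_raw: np.ndarray
    halo_raw: np.ndarray
    behavior_time_s: np.ndarray
    speed_cmps: np.ndarray
    lick_wave: np.ndarray
    events: pd.DataFrame
    truth: dict | None = None

    @property
    def reward_times_s(self) -> np.ndarray:
        rewards = self.events[self.events["type"] == "reward"]
        return rewards["onset_s"].to_numpy(float)

    @property
    def stim_epochs(self) -> list[tuple[float, float, float]]:
        stim = self.events[self.events["type"] == "stim_on"]
        return [(float(r.onset_s), float(r.onset_s) + float(json.loads(r.value)["duration_s"]),
                 float(json.loads(r.value)["frequency_hz"]))
                for r in stim.itertuples()]


def save_session(session: syn.Session, out_dir: str | Path) -> Path:
    """Write a synthetic session to a directory; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lm = session.landmarks
    write_landmarks_csv(out / "landmarks.csv", lm.time_s, lm.x, lm.y, lm.confidence)

    with h5py.File(out / "traces.h5", "w") as f:
        g = f.create_group("cells")
        g.create_dataset("raw", data=session.cell_raw)
        g.create_dataset("halo", data=session.halo_raw)
        g.create_dataset("time", data=session.cell_time_s)
        b = f.create_group("behavior")
        b.create_dataset("time", data=session.behavior.time_s)
        b.create_dataset("speed", data=session.behavior.speed_cmps)
        b.create_dataset("lick", data=session.behavior.lick_wave)

    rows = [{"onset_s": float(t), "type": "reward", "value": "1"}
            for t in session.behavior.reward_times_s]
    rows += [{"onset_s": float(on), "type": "stim_on",
              "value": json.dumps({"duration_s": float(off - on),
                                   "frequency_hz": float(fr)}, sort_keys=True)}
             for on, off, fr in session.behavior.stim_epochs]
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values(
        "onset_s", kind="stable").reset_index(drop=True)
    write_events_tsv(out / "events.tsv", events)

    pd.DataFrame({"time_s": session.behavior.time_s,
                  "speed_cmps": session.behavior.speed_cmps}
                 ).to_csv(out / "speed.csv", index=False)

    t = session.truth
    dump_json({
        "weights": t.weights, "noise_var": t.noise_var,
        "variance_shares": t.variance_shares, "noise_share": t.noise_share,
        "unique_contrib_pct": t.unique_contrib_pct,
        "labels": list(t.labels), "predictor_names": list(t.predictor_names),
        "bout_onsets_s": session.behavior.bout_onsets_s,
        "bout_offsets_s": session.behavior.bout_offsets_s,
    }, out / "ground_truth.json")

    cfg = session.config
    manifest = {
        "paths": {"landmarks": "landmarks.csv", "traces": "traces.h5",
                  "events": "events.tsv", "speed": "speed.csv",
                  "ground_truth": "ground_truth.json"},
        "subject_id": "synthetic", "group_id": "synthetic",
        "rates_hz": {"pupil": cfg.pupil_rate_hz, "cells": cfg.cell_rate_hz},
        "parameters": {
            "duration_s": cfg.duration_s, "n_cells": cfg.n_cells,
            "n_rewards": cfg.n_rewards,
            "reward_interval_s": list(cfg.reward_interval_s),
            "confidence_threshold": 0.9, "f0_percentile": 10.0,
            "r2_threshold": 0.05, "major_cutoff_pct": 20.0,
            "minor_cutoff_pct": 10.0, "run_threshold_cmps": 1.0,
            "k_bout_clusters": 4, "noise_sd": cfg.noise_sd,
            "calcium_tau_s": cfg.calcium_tau_s,
        },
        "seed": cfg.seed,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out / "manifest.yaml"


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"session file missing: {path}")
    return path


def load_session(manifest_path: str | Path) -> SessionBundle:
    """Load and validate a session directory from its manifest.

    Raises named failures for missing files, bad columns, non-monotone time
    and trace-length mismatches.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    manifest = yaml.safe_load(_require(manifest_path).read_text())
    for key in ("paths", "rates_hz", "parameters", "seed"):
        if key not in manifest:
            raise ValueError(f"manifest missing key '{key}'")
    root = manifest_path.parent
    paths = {k: root / v for k, v in manifest["paths"].items()}

    x, y, conf, _ = read_landmarks_csv(_require(paths["landmarks"]))
    pupil_rate = float(manifest["rates_hz"]["pupil"])
    if pupil_rate <= 0:
        raise ValueError("pupil rate must be positive")
    lm_time = np.arange(x.shape[0]) / pupil_rate

    with h5py.File(_require(paths["traces"]), "r") as f:
        for group, names in (("cells", ("raw", "halo", "time")),
                             ("behavior", ("time", "speed", "lick"))):
            if group not in f:
                raise ValueError(f"traces.h5 missing group '/{group}'")
            for name in names:
                if name not in f[group]:
                    raise ValueError(f"traces.h5 missing dataset '/{group}/{name}'")
        cell_raw = f["cells/raw"][()]
        halo_raw = f["cells/halo"][()]
        cell_time = f["cells/time"][()]
        b_time = f["behavior/time"][()]
        speed = f["behavior/speed"][()]
        lick = f["behavior/lick"][()]

    if cell_raw.shape != halo_raw.shape:
        raise ValueError(f"cell/halo shape mismatch: {cell_raw.shape} vs {halo_raw.shape}")
    if cell_raw.shape[1] != len(cell_time):
        raise ValueError(
            f"trace length mismatch: cells have {cell_raw.shape[1]} samples "
            f"but time axis has {len(cell_time)}")
    for name, t in (("cell", cell_time), ("behavior", b_time)):
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone {name} time axis")
    if len(speed) != len(b_time) or len(lick) != len(b_time):
        raise ValueError(
            f"behavior length mismatch: time {len(b_time)}, speed {len(speed)}, "
            f"lick {len(lick)}")

    events = read_events_tsv(_require(paths["events"]))
    speed_df = pd.read_csv(_require(paths["speed"]), float_precision="round_trip")
    for col in ("time_s", "speed_cmps"):
        if col not in speed_df.columns:
            raise ValueError(f"speed CSV missing column '{col}'")

    truth = None
    gt_path = paths.get("ground_truth")
    if gt_path is not None and gt_path.exists():
        truth = json.loads(gt_path.read_text())

    return SessionBundle(
        manifest=manifest, landmark_time_s=lm_time, landmark_x=x,
        landmark_y=y, landmark_conf=conf, cell_time_s=cell_time,
        cell_raw=cell_raw, halo_raw=halo_raw, behavior_time_s=b_time,
        speed_cmps=speed, lick_wave=lick, events=events, truth=truth)
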