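"""End-to-end session report: runs the analysis stages and writes results.

Reproduces the figure-level quantities of the study design from any
session: mean pupil size over the last 10 s of each stimulation train (per
frequency), pupil baselines at -2 s and +6 s from run onset, the per-cell
encoding table with contribution percentages, the pupil/reward pie counts
at the 20 % cutoff and the ON/OFF correlation split.

Everything is deterministic given the manifest (all seeds live there); the
results JSON embeds the manifest hash and package version so two runs on
the same manifest are byte-identical.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import bouts as bt
from . import encoding as enc
from . import io as pio
from . import preprocess as pp
from . import pupil as pu
from . import timeseries as ts

__all__ = ["run_report", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("pupil", "preprocess", "encode", "correlate", "align", "bouts")
_STAGE_DEPS = {
    "pupil": (),
    "preprocess": (),
    "encode": ("pupil", "preprocess"),
    "correlate": ("encode",),
    "align": ("pupil",),
    "bouts": ("pupil",),
}


def run_report(manifest_path: str | Path, stages: tuple[str, ...] = ALL_STAGES,
               out_dir: str | Path | None = None,
               make_plots: bool = False) -> dict:
    """Run ``stages`` on a saved session and write ``results.json``.

    Stages must form a dependency-closed set (a stage whose prerequisite is
    absent fails loudly, naming the missing stage).  An empty stage list is
    a warned no-op.
    """
    session = pio.load_session(manifest_path)
    root = Path(manifest_path).parent if not Path(manifest_path).is_dir() \
        else Path(manifest_path)
    out = Path(out_dir) if out_dir is not None else root / "report"
    out.mkdir(parents=True, exist_ok=True)

    if not stages:
        warnings.warn("empty stage list: nothing to do")
        return {}
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {list(ALL_STAGES)}")
    for s in stages:
        missing = [d for d in _STAGE_DEPS[s] if d not in stages]
        if missing:
            raise ValueError(f"stage '{s}' requires missing stage(s) {missing}")

    params = session.manifest["parameters"]
    pupil_rate = float(session.manifest["rates_hz"]["pupil"])
    seed = int(session.manifest["seed"])
    results: dict = {
        "manifest_hash": pio.manifest_hash(session.manifest),
        "package_version": __version__,
        "stages": list(stages),
    }
    state: dict = {}

    if "pupil" in stages:
        trace = pu.extract_pupil_trace(
            session.landmark_x, session.landmark_y, session.landmark_conf,
            session.landmark_time_s,
            confidence_threshold=float(params["confidence_threshold"]))
        state["pupil"] = trace
        pd.DataFrame({
            "time_s": trace.time_s, "radius_px": trace.radius_px,
            "area_px2": trace.area_px2,
            "interpolated": trace.interpolated.astype(int),
        }).to_csv(out / "pupil.csv", index=False)
        results["pupil"] = {
            "n_frames": len(trace.time_s),
            "fraction_interpolated": float(trace.interpolated.mean()),
            "mean_radius_px": float(trace.radius_px.mean()),
        }

    if "preprocess" in stages:
        dff, mapping = pp.preprocess_imaging(
            session.cell_raw, session.halo_raw,
            baseline_percentile=float(params["f0_percentile"]))
        state["dff"] = dff
        results["preprocess"] = {"n_rois": int(session.cell_raw.shape[0]),
                                 "n_cells": int(dff.shape[0])}

    if "encode" in stages:
        trace = state["pupil"]
        dff = state["dff"]
        pupil_c = np.interp(session.cell_time_s, trace.time_s, trace.radius_px)
        speed_c = np.interp(session.cell_time_s, session.behavior_time_s,
                            session.speed_cmps)
        lick_c = np.interp(session.cell_time_s, session.behavior_time_s,
                           session.lick_wave)
        predictors = enc.build_predictor_set(
            session.cell_time_s, pupil_c, speed_c, lick_c, dff)
        table = enc.encode_session(
            dff, predictors, r2_threshold=float(params["r2_threshold"]),
            major_cutoff=float(params["major_cutoff_pct"]))
        state["encoding"] = table
        state["predictors"] = predictors
        table.to_csv(out / "encoding.csv")
        pio.dump_json({"chosen_kernel_index": predictors.chosen_kernel_index},
                      out / "chosen_spline.json")
        kept = table[table["kept"]]
        label_counts = {k: int((kept["label"] == k).sum())
                        for k in ("pupil", "reward", "both", "other")}
        results["encode"] = {
            "n_cells": int(len(table)),
            "n_kept": int(table["kept"].sum()),
            "chosen_kernel_index": predictors.chosen_kernel_index,
            "label_counts": label_counts,
            "mean_r2_full": float(table["r2_full"].mean()),
            "mean_contrib": {nm: float(kept[f"contrib_{nm}"].mean())
                             for nm in predictors.names},
        }

    if "correlate" in stages:
        table = state["encoding"]
        dff = state["dff"]
        predictors = state["predictors"]
        kept_idx = table.index[table["kept"]].to_numpy()
        r, on_off = ts.correlate_and_classify(dff[kept_idx], predictors.pupil)
        results["correlate"] = {
            "n_on": int((on_off == "ON").sum()),
            "n_off": int((on_off == "OFF").sum()),
            "mean_abs_r": float(np.abs(r).mean()),
        }

    if "align" in stages:
        trace = state["pupil"]
        stim = session.stim_epochs
        by_freq: dict[str, dict] = {}
        for freq in sorted({e[2] for e in stim}):
            onsets = np.array([on for on, _, fr in stim if fr == freq])
            dur = stim[0][1] - stim[0][0]
            try:
                aligned = pu.align_to_events(
                    trace.time_s, trace.radius_px, onsets,
                    window_s=(-5.0, dur + 10.0),
                    baseline_window_s=(-5.0, 0.0),
                    response_window_s=(dur - 10.0, dur))
            except ValueError:
                continue
            by_freq[f"{freq:g}"] = {
                "n_trains": int(len(aligned.event_times_s)),
                "mean_last10s_radius_px": float(aligned.response.mean()),
                "mean_baseline_radius_px": float(aligned.baseline.mean()),
            }
        results["align"] = {"stim_last10s_by_freq_hz": by_freq}

    if "bouts" in stages:
        trace = state["pupil"]
        detected = bt.detect_bouts(session.speed_cmps, pupil_rate,
                                   run_threshold=float(params["run_threshold_cmps"]))
        run_mask, rest_mask = bt.run_rest_partition(
            session.speed_cmps, float(params["run_threshold_cmps"]))
        bout_res: dict = {
            "n_bouts": len(detected),
            "run_fraction": float(run_mask.mean()),
            "mean_radius_run_px": float(trace.radius_px[run_mask].mean())
            if run_mask.any() else None,
            "mean_radius_rest_px": float(trace.radius_px[rest_mask].mean())
            if rest_mask.any() else None,
        }
        if detected:
            onsets = np.array([b.onset_s for b in detected])
            aligned = pu.align_to_events(
                trace.time_s, trace.radius_px, onsets, window_s=(-2.0, 8.0),
                baseline_window_s=(-2.0, -2.0 + 1.0 / pupil_rate),
                response_window_s=(6.0, 6.0 + 1.0 / pupil_rate))
            bout_res["pupil_at_minus2s_px"] = float(aligned.baseline.mean())
            bout_res["pupil_at_plus6s_px"] = float(aligned.response.mean())
            k = min(int(params["k_bout_clusters"]), len(detected))
            labels, _, wss = bt.cluster_bouts(detected, k, seed)
            bout_res["k_clusters"] = k
            bout_res["cluster_sizes"] = np.bincount(labels, minlength=k).tolist()
            bout_res["within_cluster_ss"] = float(wss)
            pd.DataFrame({
                "onset_s": [b.onset_s for b in detected],
                "offset_s": [b.offset_s for b in detected],
                "cluster": labels,
            }).to_csv(out / "bouts.csv", index=False)
        results["bouts"] = bout_res

    if make_plots:
        _write_plots(state, out)

    pio.dump_json(results, out / "results.json")
    log.info("report written to %s", out)
    return results


def _write_plots(state: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "pupil" in state:
        fig, ax = plt.subplots(figsize=(8, 2.5))
        tr = state["pupil"]
        ax.plot(tr.time_s, tr.radius_px, lw=0.5)
        ax.set(xlabel="time (s)", ylabel="pupil radius (px)")
        fig.tight_layout()
        fig.savefig(out / "pupil_trace.png", dpi=120)
        plt.close(fig)
    if "encoding" in state:
        table = state["encoding"]
        kept = table[table["kept"]]
        if len(kept):
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(kept.get("contrib_pupil"), kept.get("contrib_reward"), s=12)
            ax.set(xlabel="pupil contribution (%)", ylabel="reward contribution (%)")
            fig.tight_layout()
            fig.savefig(out / "contributions.png", dpi=120)
            plt.close(fig)
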