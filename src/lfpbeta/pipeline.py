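"""End-to-end orchestration: simulate/load -> artifacts -> beta ->
connectivity -> behavior -> tidy tables + run manifest.

A single master seed deterministically spawns per-stage random streams, so
two runs with identical config produce byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .artifacts import (
    detect_artifacts,
    excluded_trials_beta,
    excluded_trials_connectivity,
    masks_to_frame,
)
from .beta import (
    compute_channel_tfmap,
    compute_session_beta,
    make_blocks,
    measures_to_frame,
    time_of_max_beta,
)
from .behavior import day_satisfies_criterion, label_sessions, session_performance
from .connectivity import (
    connectivity_for_pair,
    network_summary,
    results_to_frame,
    select_trials,
    session_cross_spectra,
)
from .io import read_recording
from .simulate import SimConfig, generate_learning_sequence
from .stats import export_tidy
from .timefreq import downsample

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


@dataclass
class RunConfig:
    """Pipeline configuration; every default is the analysis default."""

    scenario: str | None = "acquisition"
    input_paths: list[str] = field(default_factory=list)
    n_sessions: int = 8
    sim: SimConfig = field(default_factory=SimConfig)
    band: tuple[float, float, float] = (17.0, 28.0, 0.5)
    alpha: float = 0.01
    n_surrogates: int = 2000
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "lfpbeta_out"
    run_connectivity: bool = True
    phase: str = "P1"

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["sim"]["coupled_pairs"] = {
            f"{a}|{b}": list(v) for (a, b), v in self.sim.coupled_pairs.items()
        }
        return d


def validate_inputs(paths: list[str]) -> list[str]:
    """Structural checks on HDF5 + events inputs; returns violations."""
    violations: list[str] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            violations.append(f"{p}: file not found")
            continue
        try:
            rec = read_recording(p)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            violations.append(f"{p}: unreadable ({exc})")
            continue
        if rec.fs < 200.0:
            violations.append(f"{p}: fs={rec.fs} Hz too low (beta band near Nyquist)")
        starts = rec.events.starts
        if np.any(np.diff(starts) <= 0):
            violations.append(f"{p}: trial start times not strictly increasing")
        if np.any(rec.events.ends > rec.duration) or np.any(starts < 0):
            violations.append(f"{p}: event times outside the recording")
    return violations


def _analyze_session(rec, cfg: RunConfig, rng_seed: int):
    """Analyze one recording; returns dict of per-stage tables."""
    t_start = time.perf_counter()
    masks = {}
    if rec.fs > 500.0:
        for s in rec.structures:
            masks[s] = detect_artifacts(rec.channels[s], rec.fs, channel=s)
    else:
        log.info("fs=%s Hz <= 500: artifact detection skipped", rec.fs)

    tfmaps = {
        s: compute_channel_tfmap(rec.channels[s], rec.fs, s) for s in rec.structures
    }
    measures = compute_session_beta(rec, masks, tfmaps=tfmaps)
    mdf = measures_to_frame(measures)
    mdf.insert(0, "session", rec.session_label)
    mdf.insert(0, "rat", rec.rat_id)

    blocks = make_blocks(rec.events, measures)
    bdf = pd.DataFrame(
        [
            {"rat": rec.rat_id, "session": rec.session_label, "block": b.block,
             "performance": b.performance,
             **{f"median_beta_{s}": v for s, v in b.median_beta.items()}}
            for b in blocks
        ]
    )

    conn_df = pd.DataFrame()
    net_row = None
    if cfg.run_connectivity and len(rec.structures) >= 2:
        excluded = excluded_trials_connectivity(rec.events, masks) if masks else set()
        try:
            trial_ids = select_trials(rec.events, excluded)
        except ValueError as exc:
            log.warning("connectivity skipped for %s: %s", rec.session_label, exc)
            trial_ids = None
        if trial_ids is not None:
            raw_ds = {
                s: downsample(rec.channels[s], rec.fs, 200.0) for s in rec.structures
            }
            id_to_row = {int(t): i for i, t in enumerate(rec.events.df["trial"])}
            tmax = {
                tid: time_of_max_beta(
                    tfmaps, raw_ds,
                    float(rec.events.starts[id_to_row[tid]]),
                    float(rec.events.ends[id_to_row[tid]]),
                )
                for tid in trial_ids
            }
            css = session_cross_spectra(tfmaps, rec.events, trial_ids, tmax)
            rng = np.random.default_rng(rng_seed)
            results = [
                connectivity_for_pair(cs, n_surrogates=cfg.n_surrogates, seed=rng)
                for cs in css
            ]
            conn_df = results_to_frame(results)
            conn_df.insert(0, "session", rec.session_label)
            conn_df.insert(0, "rat", rec.rat_id)
            net = network_summary(results, alpha=cfg.alpha)
            net_row = {
                "rat": rec.rat_id, "session": rec.session_label,
                "hub_index": net.hub_index,
                **{f"prop_{s}": v for s, v in net.structure_link_proportion.items()},
            }

    perf = session_performance(rec.events)
    crit = day_satisfies_criterion(rec.events)
    log.info("session %s analyzed in %.1f s (%d trials)",
             rec.session_label, time.perf_counter() - t_start, len(rec.events))
    return {
        "measures": mdf, "blocks": bdf, "connectivity": conn_df,
        "network": net_row, "masks": masks, "performance": perf,
        "criterion": crit,
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    conn_seeds = seeds[1].generate_state(1024)

    if cfg.input_paths:
        sessions = [(read_recording(p), None) for p in cfg.input_paths]
    elif cfg.scenario:
        sim = SimConfig(**{**asdict_sim(cfg.sim), "seed": cfg.seed})
        sessions = generate_learning_sequence(sim, cfg.scenario, cfg.n_sessions)
    else:
        raise FileNotFoundError("stage load: no inputs and no scenario")

    all_measures, all_blocks, all_conn, all_net, all_masks = [], [], [], [], []
    labels_rows = []
    crit_flags = []
    for k, (rec, _truth) in enumerate(sessions):
        res = _analyze_session(rec, cfg, int(conn_seeds[k]))
        all_measures.append(res["measures"])
        all_blocks.append(res["blocks"])
        if len(res["connectivity"]):
            all_conn.append(res["connectivity"])
        if res["network"] is not None:
            all_net.append(res["network"])
        mdf = masks_to_frame(res["masks"])
        mdf.insert(0, "session", rec.session_label)
        all_masks.append(mdf)
        crit_flags.append(res["criterion"])
        labels_rows.append({
            "rat": rec.rat_id, "day": k, "session": rec.session_label,
            "performance": res["performance"],
        })

    labels = label_sessions(crit_flags, phase=cfg.phase)
    for row, lab in zip(labels_rows, labels):
        row["label"] = str(lab)

    export_tidy(pd.concat(all_measures, ignore_index=True), out / "beta_trials.csv")
    export_tidy(
        pd.concat(all_blocks, ignore_index=True) if all_blocks else pd.DataFrame(),
        out / "beta_blocks.csv",
    )
    export_tidy(
        pd.concat(all_conn, ignore_index=True) if all_conn else pd.DataFrame(
            columns=["rat", "session", "structure_a", "structure_b",
                     "max_diff", "p_surrogate", "n_trials", "n_surrogates"]),
        out / "connectivity.csv",
    )
    export_tidy(pd.DataFrame(all_net), out / "network.csv")
    export_tidy(pd.DataFrame(labels_rows), out / "session_labels.csv")
    export_tidy(
        pd.concat(all_masks, ignore_index=True) if all_masks else pd.DataFrame(),
        out / "artifact_epochs.csv",
    )

    manifest = {
        "package": "lfpbeta",
        "version": __version__,
        "config": cfg.to_manifest(),
        "n_sessions": len(sessions),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def asdict_sim(sim: SimConfig) -> dict:
    d = asdict(sim)
    d["coupled_pairs"] = dict(sim.coupled_pairs)
    return d
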