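"""End-to-end orchestration: simulate -> segment -> call -> stats -> flow.

Every stage reads and writes plain artifacts (TIFF/TSV/CSV/JSON) under the
run directory so it can be re-run from disk alone, and derives its RNG seed
deterministically from the global seed plus the stage name.  The run report
collects the headline numbers (zero-class fraction, lambda, chi-squared and
p per scheme, per-construct Hill statistics, half-max ratio) along with
config hash and seeds for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import (CONSTRUCT_GFP, CONSTRUCT_MGFP, ConfigError, DataError,
                     RunConfig)
from .lineage import Pedigree, classify_switch, group_switching_cells
from .eventstats import (count_events, estimate_lambda, gof_monte_carlo,
                         poisson_expected)
from .flowfit import fit_hill, gate_events, normalize_events, summarize_fits
from .synth import (render_movie, simulate_pedigrees, simulate_strain_day)
from .imaging import measure_traces, register_frames, segment_frame

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "segment", "call", "eventstats", "flowfit")

__all__ = ["run_pipeline", "classify_pedigrees", "run_event_statistics",
           "run_flow_fits", "ALL_STAGES"]


# ---------------------------------------------------------------------------
# Stage helpers (usable directly from Python)
# ---------------------------------------------------------------------------

def classify_pedigrees(pedigrees: Sequence[Pedigree], config: RunConfig,
                       ) -> tuple[pd.DataFrame, dict]:
    """Call every cell in every trap and group switching cells.

    Returns a tidy calls table and ``groups_by_trap`` (trap_id -> list of
    SwitchGroup, empty where no cell switched).
    """
    sw = config.switch
    opts = config.call
    rows = []
    groups_by_trap = {}
    for ped in pedigrees:
        calls = {}
        for name, rec in ped.records.items():
            if rec.trace is None:
                raise DataError(f"cell {name} has no trace; run simulate first")
            call = classify_switch(
                rec.trace, sw.white_level, sw.opaque_level,
                frame_interval=sw.frame_interval,
                persistence_frames=opts.persistence_frames,
                smooth_window_frames=opts.smooth_window_frames,
                nucleus_lost_frame=rec.nucleus_lost_frame)
            calls[name] = call
        groups = group_switching_cells(
            ped, calls, frame_interval=sw.frame_interval,
            synchrony_frames=opts.synchrony_frames)
        groups_by_trap[ped.trap_id] = groups
        group_of = {}
        label_of = {}
        for gi, g in enumerate(groups):
            for n in g.cells:
                group_of[n] = gi
                label_of[n] = g.label
        for name, call in calls.items():
            rows.append(dict(
                trap_id=ped.trap_id, cell_id=name, state=call.state,
                t_activation_start=call.t_activation_start,
                t_max=call.t_max, rise_10_90=call.rise_10_90,
                group_id=group_of.get(name, -1),
                group_label=label_of.get(name, "")))
    return pd.DataFrame(rows), groups_by_trap


def run_event_statistics(groups_by_trap: dict, config: RunConfig,
                         seed: Optional[int] = None) -> dict:
    """Per-scheme event counts, zero-class lambda, and Monte-Carlo GOF."""
    opts = config.eventstats
    seed = config.stage_seed("eventstats") if seed is None else seed
    out = {"n_traps": len(groups_by_trap), "schemes": {}}
    for scheme in opts.schemes:
        table = count_events(groups_by_trap, scheme)
        lam = estimate_lambda(max(table.n_zero, 1), table.n_traps) \
            if table.n_zero > 0 else float("nan")
        entry = {"counts_total": int(table.counts.sum()),
                 "n_zero": table.n_zero}
        if table.n_zero > 0:
            null = poisson_expected(lam, table.n_traps, k_max=opts.k_max)
            gof = gof_monte_carlo(table, null, reps=opts.reps,
                                  seed=seed + scheme)
            entry.update({"lambda": lam, "chi2": gof.statistic,
                          "p": gof.p_value, "reps": gof.reps})
        out["schemes"][str(scheme)] = entry
    out["zero_class_fraction"] = out["schemes"][str(opts.schemes[0])]["n_zero"] \
        / max(len(groups_by_trap), 1)
    return out


def run_flow_fits(config: RunConfig, seed: Optional[int] = None,
                  n_strains: int = 4, n_days: int = 2) -> dict:
    """Fit both fusion constructs across replicate synthetic strain-days.

    Simulates ``n_strains * n_days`` datasets per construct, runs the full
    gate -> normalize -> fit pipeline on each (with the < 2 nM hormone
    cutoff for the dimerizing fusion), and aggregates.
    """
    seed = config.stage_seed("flowfit") if seed is None else seed
    fcfg = config.flow
    fits = []
    per_fit = []
    for ci, construct in enumerate((CONSTRUCT_MGFP, CONSTRUCT_GFP)):
        cutoff = fcfg.gfp_decline_threshold if construct == CONSTRUCT_GFP else None
        for si in range(n_strains):
            for day in range(1, n_days + 1):
                sub_seed = (seed + 7919 * ci + 101 * si + day) % (2**31)
                plate = simulate_strain_day(
                    construct, fcfg, strain=f"{construct}-{si}", day=day,
                    seed=sub_seed)
                gated, _ = gate_events(plate.events, config.gates)
                norm, _ = normalize_events(gated)
                fit = fit_hill(norm["gfp_n"].to_numpy(),
                               norm["mcherry_n"].to_numpy(),
                               hormone=norm["hormone_nM"].to_numpy(),
                               x_max_conc=cutoff)
                fits.append((construct, day, fit))
                per_fit.append(dict(construct=construct, strain=si, day=day,
                                    h=fit.h, K=fit.K, c=fit.c, d=fit.d,
                                    n_points=fit.n_points,
                                    converged=fit.converged))
    summary = summarize_fits(fits, ratio_order=(CONSTRUCT_MGFP, CONSTRUCT_GFP))
    per = summary.per_construct
    return {
        "fits": per_fit,
        "per_construct": {
            cstr: {k: (None if isinstance(v, float) and math.isnan(v) else
                       float(v)) if k != "n" else int(v)
                   for k, v in row.items()}
            for cstr, row in per.iterrows()},
        "halfmax_ratio_mgfp_over_gfp": float(summary.halfmax_ratio),
        "welch_p_h": float(summary.p_h),
        "welch_p_logK": float(summary.p_logK),
    }


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig,
                 stages: Sequence[str] = ALL_STAGES,
                 outdir: Optional[str] = None) -> dict:
    """Execute the requested stages in order and write a JSON run report.

    Stage order is simulate -> segment -> call -> eventstats / flowfit;
    each stage that depends on an upstream artifact raises a
    :class:`DataError` naming the stage to run first.
    """
    config.validate()
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}; valid: {ALL_STAGES}")
    stages = [s for s in ALL_STAGES if s in stages]
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    report: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in stages},
        "stages_run": list(stages),
        "artifacts": {},
    }

    pedigrees = None
    ground_truth = None
    if "simulate" in stages:
        pedigrees, ground_truth = simulate_pedigrees(
            config.switch, seed=config.stage_seed("simulate"))
        ped_path = out / "pedigree.tsv"
        ground_truth.cells.to_csv(ped_path, sep="\t", index=False)
        ground_truth.events.to_csv(out / "events_truth.tsv", sep="\t",
                                   index=False)
        report["artifacts"]["pedigree"] = str(ped_path)
        report["simulate"] = {
            "n_traps": ground_truth.n_traps,
            "n_cells": int(len(ground_truth.cells)),
            "n_events_truth": int(len(ground_truth.events)),
            "n_zero_event_traps_truth": ground_truth.n_zero_event_traps,
        }

    if "segment" in stages:
        if pedigrees is None:
            raise DataError("segment requires the simulate stage first")
        n_demo = min(config.n_render_traps, len(pedigrees))
        seg_rows = []
        for ped in pedigrees[:n_demo]:
            movie, masks, mgt = render_movie(
                ped, config.switch, seed=config.stage_seed("segment"))
            movie.to_tiff(out / f"{ped.trap_id}.tif")
            offsets, registered = register_frames(movie)
            lf = segment_frame(registered.dic(0), config.segmentation)
            traces = measure_traces(registered, masks)
            traces.to_csv(out / f"{ped.trap_id}_traces.tsv", sep="\t",
                          index=False)
            seg_rows.append(dict(trap_id=ped.trap_id,
                                 n_objects_frame0=lf.n_objects,
                                 n_rendered=len(mgt.label_map),
                                 n_dropped=len(mgt.dropped),
                                 max_offset=float(np.abs(offsets).max())))
        report["segment"] = seg_rows

    calls_df = None
    groups_by_trap = None
    if "call" in stages:
        if pedigrees is None:
            raise DataError("call requires the simulate stage first")
        calls_df, groups_by_trap = classify_pedigrees(pedigrees, config)
        calls_path = out / "calls.tsv"
        calls_df.to_csv(calls_path, sep="\t", index=False)
        report["artifacts"]["calls"] = str(calls_path)
        report["call"] = {
            "n_cells": int(len(calls_df)),
            "n_switching": int((calls_df.state == "switching").sum()),
            "n_groups": int(sum(len(g) for g in groups_by_trap.values())),
        }

    if "eventstats" in stages:
        if groups_by_trap is None:
            raise DataError("eventstats requires the call stage first")
        stats = run_event_statistics(groups_by_trap, config)
        report["eventstats"] = stats
        for scheme in config.eventstats.schemes:
            table = count_events(groups_by_trap, scheme)
            table.counts.to_csv(out / f"counts_scheme{scheme}.tsv", sep="\t")

    if "flowfit" in stages:
        report["flowfit"] = run_flow_fits(config)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    report["artifacts"]["report"] = str(report_path)
    return report
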