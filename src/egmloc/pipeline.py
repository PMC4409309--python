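"""End-to-end orchestration: generate, preprocess, extract, label, evaluate.

`run_experiment` drives the full experimental grid — tasks x feature sets
x learners — and writes a long-format CSV report plus a JSON summary. All
randomness flows from one master seed through `numpy.random.SeedSequence`
so reruns with an identical configuration are byte-identical. Cohort
generation and preprocessing are cached inside the output directory, keyed
by a hash of the relevant configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as egm_io
from .cohort import CohortConfig, SiteRecord, generate_cohort
from .evaluate import (
    EvalConfig,
    LopoResult,
    accuracy,
    combine_binary,
    leave_one_patient_out,
    spatial_resolution,
    stratify_by_tissue,
)
from .features import FeatureSetId, assemble, extract_features
from .preprocess import (
    WINDOW_PRE_MS,
    BeatTemplate,
    average_beats,
    detect_beat_anchors,
    remove_baseline,
    remove_stimulus,
)
from .regionalize import OCTANT_CODES, recenter

__all__ = [
    "RunConfig",
    "TASKS",
    "site_templates",
    "build_feature_table",
    "feature_matrix",
    "run_experiment",
    "cohort_config_from_dict",
    "run_config_from_dict",
]

log = logging.getLogger(__name__)

TASKS = (
    "apical_basal",
    "septal_lateral",
    "superior_inferior",
    "octant_multiclass",
    "octant_binary_combination",
    "coordinate_regression",
)

_AXIS_TASKS = {
    "apical_basal": "axis_ab",
    "septal_lateral": "axis_sl",
    "superior_inferior": "axis_si",
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experimental run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    tasks: tuple = TASKS
    feature_sets: tuple = (FeatureSetId.F_2VR1T,)
    learners: tuple = ("svm-gk",)
    out_dir: str = "egmloc_run"
    grids: dict = field(default_factory=dict)  # learner kind -> HyperGrid | dict | None
    smooth_param: float | None = None
    stim_half_width_ms: float = 8.0

    def validate(self) -> None:
        if not self.tasks or not self.feature_sets or not self.learners:
            raise ValueError("tasks, feature_sets and learners must be non-empty")
        for t in self.tasks:
            if t not in TASKS:
                raise ValueError(f"unknown task {t!r}")
        for k in self.learners:
            if k not in ("mlp", "rbfnn", "pnn", "svm-gk", "svm-pk", "krr"):
                raise ValueError(f"unknown learner kind {k!r}")


def cohort_config_from_dict(d: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a plain (YAML/JSON) mapping."""
    return CohortConfig(**d)


def run_config_from_dict(d: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a plain (YAML/JSON) mapping.

    Nested ``cohort`` and ``eval`` mappings become their config
    dataclasses; ``tasks``, ``feature_sets`` and ``learners`` lists become
    tuples.
    """
    d = dict(d)
    if "cohort" in d and isinstance(d["cohort"], dict):
        d["cohort"] = cohort_config_from_dict(d["cohort"])
    if "eval" in d and isinstance(d["eval"], dict):
        ev = dict(d["eval"])
        if "tissue_strata" in ev:
            ev["tissue_strata"] = tuple(ev["tissue_strata"])
        d["eval"] = EvalConfig(**ev)
    for key in ("tasks", "feature_sets", "learners"):
        if key in d:
            d[key] = tuple(d[key])
    return RunConfig(**d)


def site_templates(
    site: SiteRecord,
    smooth_param: float | None = None,
    stim_half_width_ms: float = 8.0,
) -> dict[str, BeatTemplate]:
    """Preprocess one site into its four beat templates.

    Keys: ``ff`` / ``bip`` (stimulus kept) and ``ff_nostim`` /
    ``bip_nostim`` (stimulus excised). Far-field peak deflections anchor
    both leads; the stimulus offset inside the window is estimated from
    the recorded stimulus times.
    """
    kw = {} if smooth_param is None else {"smooth_param": smooth_param}
    ff_clean = remove_baseline(site.far_field, **kw)
    bip_clean = remove_baseline(site.bipolar, **kw)
    stims = site.far_field.stimulus_times_ms
    if stims.size >= 2:
        cycle = float(np.median(np.diff(np.sort(stims))))
    else:
        cycle = 400.0
    anchors = detect_beat_anchors(ff_clean, refractory_ms=0.5 * cycle)
    ff_t = average_beats(ff_clean, anchors)
    bip_t = average_beats(bip_clean, anchors)
    out = {"ff": ff_t, "bip": bip_t}
    if stims.size:
        # lag from each anchor to the latest stimulus at or before it
        lags = []
        sorted_stims = np.sort(stims)
        for a in anchors:
            before = sorted_stims[sorted_stims <= a + 1e-9]
            if before.size:
                lags.append(a - before[-1])
        tau_p = float(np.median(lags)) if lags else WINDOW_PRE_MS
        offset = WINDOW_PRE_MS - tau_p
        out["ff_nostim"] = remove_stimulus(ff_t, offset, stim_half_width_ms)
        out["bip_nostim"] = remove_stimulus(bip_t, offset, stim_half_width_ms)
    else:  # no stimulus bookkeeping: treat the averaged beats as artifact-free
        out["ff_nostim"] = dataclasses.replace(ff_t, with_stimulus=False)
        out["bip_nostim"] = dataclasses.replace(bip_t, with_stimulus=False)
    return out


def build_feature_table(
    sites: list[SiteRecord],
    templates: dict[str, dict[str, BeatTemplate]],
) -> pd.DataFrame:
    """Site metadata, recentered coordinates, and scalar features."""
    rows = []
    for s in sites:
        tset = templates[s.site_id]
        feats = extract_features(tset["ff_nostim"], tset["bip_nostim"])
        row = {
            "patient_id": s.patient_id,
            "site_id": s.site_id,
            "octant": s.octant.code,
            "axis_ab": s.octant.axis_ab,
            "axis_sl": s.octant.axis_sl,
            "axis_si": s.octant.axis_si,
            "tissue": s.tissue,
            "x": s.coords[0],
            "y": s.coords[1],
            "z": s.coords[2],
        }
        row.update(feats.as_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    # per-patient recentering of the navigation coordinates
    rec = np.empty((len(table), 3))
    for pid, idx in table.groupby("patient_id").groups.items():
        rec[np.asarray(idx)] = recenter(table.loc[idx, ["x", "y", "z"]].to_numpy())
    table[["rx", "ry", "rz"]] = rec
    return table


def feature_matrix(
    set_id: FeatureSetId | str,
    table: pd.DataFrame,
    templates: dict[str, dict[str, BeatTemplate]] | None = None,
) -> np.ndarray:
    """Input matrix (rows follow ``table``) for one feature set."""
    set_id = FeatureSetId(set_id)
    if set_id in (
        FeatureSetId.D1_FF_STIM,
        FeatureSetId.D1_FF_NOSTIM,
        FeatureSetId.D1_BIP_STIM,
        FeatureSetId.D1_CONCAT_STIM,
    ):
        if templates is None:
            raise ValueError("raw-waveform feature sets need the templates")
        ff_key = "ff_nostim" if set_id is FeatureSetId.D1_FF_NOSTIM else "ff"
        rows = []
        for sid in table["site_id"]:
            tset = templates[sid]
            rows.append(assemble(set_id, ff=tset[ff_key], bip=tset["bip"]))
        return np.stack(rows)
    cols = {
        FeatureSetId.F_3V: ["v_I", "v_P", "v_F"],
        FeatureSetId.F_3V1T: ["v_I", "v_P", "v_F", "t_ob"],
        FeatureSetId.F_3V3T: ["v_I", "v_P", "v_F", "t_I", "t_P", "t_F"],
        FeatureSetId.F_2VR1T: ["v_FP", "v_IP", "t_ob"],
    }[set_id]
    return table[cols].to_numpy(dtype=float)


def _config_digest(config: CohortConfig) -> str:
    payload = dataclasses.asdict(config)
    payload["octant_counts"] = sorted(payload["octant_counts"].items())
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _prepare(config: RunConfig) -> tuple[list[SiteRecord], dict, pd.DataFrame]:
    """Generate (or reload) the cohort, templates and feature table."""
    out = Path(config.out_dir)
    digest = _config_digest(config.cohort)
    cache = out / "cache" / digest
    if (cache / "features.csv").exists():
        log.info("reusing cached cohort/features under %s", cache)
        sites = egm_io.read_cohort(cache / "cohort")
        templates = egm_io.read_templates(cache / "templates")
        table = egm_io.read_feature_table(cache / "features.csv")
        return sites, templates, table
    sites = generate_cohort(config.cohort)
    templates = {
        s.site_id: site_templates(s, config.smooth_param, config.stim_half_width_ms)
        for s in sites
    }
    table = build_feature_table(sites, templates)
    cache.mkdir(parents=True, exist_ok=True)
    egm_io.write_cohort(sites, cache / "cohort")
    egm_io.write_templates(templates, cache / "templates")
    egm_io.write_feature_table(table, cache / "features.csv")
    return sites, templates, table


def _check_octant_classes(labels: np.ndarray) -> None:
    missing = sorted(set(OCTANT_CODES) - set(labels))
    if missing:
        raise ValueError(
            f"octant classification needs every octant class represented; missing: {', '.join(missing)}"
        )


def _lopo(
    config: RunConfig,
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    pids: np.ndarray,
    task: str,
) -> LopoResult:
    grid = config.grids.get(kind, None)
    return leave_one_patient_out(X, y, pids, kind, grid, config.eval, task=task)


def run_experiment(config: RunConfig) -> pd.DataFrame:
    """Run the requested grid and write ``report.csv`` / ``summary.json``.

    Returns the long-format report: one row per
    (task, feature set, learner, tissue stratum, metric).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites, templates, table = _prepare(config)
    rows = []
    for task in config.tasks:
        strata = config.eval.tissue_strata if task == "coordinate_regression" else ("both",)
        kinds = ("krr",) if task == "coordinate_regression" else tuple(
            k for k in config.learners if k != "krr"
        )
        if task == "coordinate_regression" and "krr" not in config.learners:
            continue
        if not kinds:
            continue
        for set_id in config.feature_sets:
            set_id = FeatureSetId(set_id)
            for kind in kinds:
                for stratum in strata:
                    sub = stratify_by_tissue(table, stratum)
                    sub = sub.reset_index(drop=True)
                    X = feature_matrix(set_id, sub, templates)
                    pids = sub["patient_id"].to_numpy()
                    cell = dict(
                        task=task,
                        feature_set=set_id.value,
                        learner=kind,
                        stratum=stratum,
                    )
                    if task in _AXIS_TASKS:
                        y = sub[_AXIS_TASKS[task]].to_numpy()
                        res = _lopo(config, kind, X, y, pids, "classification")
                        rows.append(
                            cell | {"metric": "accuracy_pct", "value": accuracy(res.predictions, y), "n": len(y)}
                        )
                    elif task == "octant_multiclass":
                        y = sub["octant"].to_numpy()
                        _check_octant_classes(y)
                        res = _lopo(config, kind, X, y, pids, "classification")
                        rows.append(
                            cell | {"metric": "accuracy_pct", "value": accuracy(res.predictions, y), "n": len(y)}
                        )
                    elif task == "octant_binary_combination":
                        y = sub["octant"].to_numpy()
                        _check_octant_classes(y)
                        halves = {}
                        for axis_task, col in _AXIS_TASKS.items():
                            res = _lopo(config, kind, X, sub[col].to_numpy(), pids, "classification")
                            halves[col] = res.predictions
                        combined = combine_binary(
                            halves["axis_ab"], halves["axis_sl"], halves["axis_si"]
                        )
                        rows.append(
                            cell | {"metric": "accuracy_pct", "value": accuracy(combined, y), "n": len(y)}
                        )
                    elif task == "coordinate_regression":
                        Y = sub[["rx", "ry", "rz"]].to_numpy(dtype=float)
                        res = _lopo(config, kind, X, Y, pids, "regression")
                        _, mean_cm, sd_cm = spatial_resolution(res.predictions, Y)
                        rows.append(cell | {"metric": "distance_mean_cm", "value": mean_cm, "n": len(Y)})
                        rows.append(cell | {"metric": "distance_sd_cm", "value": sd_cm, "n": len(Y)})
    report = pd.DataFrame(rows)
    report.to_csv(out / "report.csv", index=False, float_format="%.10g")
    summary = {
        "n_sites": len(table),
        "n_patients": int(table["patient_id"].nunique()),
        "cells": rows,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float) + "\n")
    return report
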