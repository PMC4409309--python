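"""Plain-text cohort, template and feature I/O.

A cohort directory holds one ``manifest.csv`` (identifiers, coordinates,
labels, pacing settings, and — for synthetic cohorts — the ground-truth
morphology parameters) plus one two-column ``time_ms,mV`` CSV per site and
lead under ``signals/``. Metadata rides in ``#``-prefixed header lines.
Floats are written with 17 significant digits so round trips are lossless.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DeflectionParams, SiteRecord
from .preprocess import BeatTemplate, EgmRecording
from .regionalize import OctantLabel

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_templates",
    "read_templates",
    "write_feature_table",
    "read_feature_table",
]

_FMT = "%.17g"
_TRUTH_FIELDS = [f.name for f in dataclasses.fields(DeflectionParams)]


def _write_signal(path: Path, rec: EgmRecording) -> None:
    stim = ",".join(_FMT % t for t in rec.stimulus_times_ms)
    with path.open("w", newline="") as fh:
        fh.write(f"# lead={rec.lead}\n")
        fh.write(f"# sampling_interval_ms={_FMT % rec.sampling_interval_ms}\n")
        fh.write(f"# stimulus_times_ms={stim}\n")
        fh.write("time_ms,mV\n")
        for t, v in zip(rec.times_ms, rec.samples):
            fh.write(f"{_FMT % t},{_FMT % v}\n")


def _read_signal(path: Path) -> EgmRecording:
    meta: dict[str, str] = {}
    samples = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
            elif line and not line.startswith("time_ms"):
                _, v = line.split(",")
                samples.append(float(v))
    stim_raw = meta.get("stimulus_times_ms", "")
    stims = np.array([float(x) for x in stim_raw.split(",") if x])
    return EgmRecording(
        lead=meta["lead"],
        samples=np.array(samples),
        sampling_interval_ms=float(meta["sampling_interval_ms"]),
        stimulus_times_ms=stims,
    )


def write_cohort(sites: list[SiteRecord], out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "signals").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sites:
        row = {
            "patient_id": s.patient_id,
            "site_id": s.site_id,
            "x": s.coords[0],
            "y": s.coords[1],
            "z": s.coords[2],
            "octant": s.octant.code,
            "tissue": s.tissue,
        }
        if s.truth is not None:
            for name in _TRUTH_FIELDS:
                row[f"truth_{name}"] = getattr(s.truth, name)
        rows.append(row)
        _write_signal(out / "signals" / f"{s.site_id}_far_field.csv", s.far_field)
        _write_signal(out / "signals" / f"{s.site_id}_bipolar.csv", s.bipolar)
    with (out / "manifest.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        for row in rows:
            writer.writerow(
                {k: (_FMT % v if isinstance(v, float) else v) for k, v in row.items()}
            )


def read_cohort(in_dir: str | Path) -> list[SiteRecord]:
    src = Path(in_dir)
    sites = []
    with (src / "manifest.csv").open() as fh:
        for row in csv.DictReader(fh):
            truth = None
            if f"truth_{_TRUTH_FIELDS[0]}" in row:
                truth = DeflectionParams(
                    **{name: float(row[f"truth_{name}"]) for name in _TRUTH_FIELDS}
                )
            sid = row["site_id"]
            sites.append(
                SiteRecord(
                    patient_id=row["patient_id"],
                    site_id=sid,
                    coords=np.array([float(row["x"]), float(row["y"]), float(row["z"])]),
                    octant=OctantLabel.from_code(row["octant"]),
                    tissue=row["tissue"],
                    far_field=_read_signal(src / "signals" / f"{sid}_far_field.csv"),
                    bipolar=_read_signal(src / "signals" / f"{sid}_bipolar.csv"),
                    truth=truth,
                )
            )
    return sites


def _write_template(path: Path, tpl: BeatTemplate) -> None:
    with path.open("w", newline="") as fh:
        fh.write(f"# lead={tpl.lead}\n")
        fh.write(f"# sampling_interval_ms={_FMT % tpl.sampling_interval_ms}\n")
        fh.write(f"# anchor_index={tpl.anchor_index}\n")
        fh.write(f"# time_origin_ms={_FMT % tpl.time_origin_ms}\n")
        fh.write(f"# with_stimulus={int(tpl.with_stimulus)}\n")
        fh.write("time_ms,mV\n")
        for t, v in zip(tpl.times_ms, tpl.samples):
            fh.write(f"{_FMT % t},{_FMT % v}\n")


def _read_template(path: Path) -> BeatTemplate:
    meta: dict[str, str] = {}
    samples = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
            elif line and not line.startswith("time_ms"):
                samples.append(float(line.split(",")[1]))
    return BeatTemplate(
        lead=meta["lead"],
        samples=np.array(samples),
        sampling_interval_ms=float(meta["sampling_interval_ms"]),
        anchor_index=int(meta["anchor_index"]),
        time_origin_ms=float(meta["time_origin_ms"]),
        with_stimulus=bool(int(meta["with_stimulus"])),
    )


def write_templates(
    templates: dict[str, dict[str, BeatTemplate]], out_dir: str | Path
) -> None:
    """Write per-site template sets ``{site_id: {key: template}}``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for site_id, tset in templates.items():
        for key, tpl in tset.items():
            _write_template(out / f"{site_id}__{key}.csv", tpl)


def read_templates(in_dir: str | Path) -> dict[str, dict[str, BeatTemplate]]:
    out: dict[str, dict[str, BeatTemplate]] = {}
    for path in sorted(Path(in_dir).glob("*__*.csv")):
        site_id, _, key = path.stem.partition("__")
        out.setdefault(site_id, {})[key] = _read_template(path)
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=_FMT)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
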