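"""Waveform file I/O.

Dialect: one CSV per subject with a ``time_s`` column followed by
``<site>_P_mmHg``, ``<site>_Q_mls``, ``<site>_A_cm2`` triplets per site,
plus a JSON sidecar holding the subject parameters, the scaled network
(geometry, stiffness, Windkessels), site definitions, path lengths and
theoretical wave speeds. A cohort is a directory of such pairs with a
``cohort_manifest.csv`` listing subjects and their sampled parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._defaults import MMHG
from .errors import FormatError
from .virtual_cohort import (
    ArterialNetwork,
    ArterialSegment,
    SubjectParameters,
    SubjectRecord,
    WaveformSet,
    WindkesselOutlet,
)

__all__ = ["write_subject", "read_subject", "write_cohort", "read_cohort",
           "MANIFEST_NAME"]

MANIFEST_NAME = "cohort_manifest.csv"
_FLOAT_FMT = "%.12g"


def _network_to_dict(net: ArterialNetwork) -> dict:
    return {
        "segments": {
            n: {"length": s.length, "radius_prox": s.radius_prox,
                "radius_dist": s.radius_dist,
                "wall_thickness": s.wall_thickness,
                "youngs_modulus": s.youngs_modulus,
                "wall_class": s.wall_class}
            for n, s in net.segments.items()},
        "bifurcations": [list(b) for b in net.bifurcations],
        "conjunctions": [list(c) for c in net.conjunctions],
        "inlet": net.inlet,
        "outlets": {
            n: dataclasses.asdict(wk) for n, wk in net.outlets.items()},
        "sites": {k: [v[0], v[1]] for k, v in net.sites.items()},
    }


def _network_from_dict(d: dict) -> ArterialNetwork:
    return ArterialNetwork(
        segments={n: ArterialSegment(name=n, **spec)
                  for n, spec in d["segments"].items()},
        bifurcations=[tuple(b) for b in d["bifurcations"]],
        conjunctions=[tuple(c) for c in d["conjunctions"]],
        inlet=d["inlet"],
        outlets={n: WindkesselOutlet(**wk) for n, wk in d["outlets"].items()},
        sites={k: (v[0], float(v[1])) for k, v in d["sites"].items()},
    )


def write_subject(record: SubjectRecord, directory: str | Path) -> Path:
    """Write ``<subject_id>.csv`` + ``<subject_id>.json``; returns the CSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wf = record.waveforms
    cols = {"time_s": wf.time}
    for site in wf.sites:
        cols[f"{site}_P_mmHg"] = wf.pressure(site) / MMHG
        cols[f"{site}_Q_mls"] = wf.flow(site) * 1e6
        cols[f"{site}_A_cm2"] = wf.area(site) * 1e4
    csv_path = directory / f"{record.subject_id}.csv"
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)

    meta = {
        "subject_id": record.subject_id,
        "parameters": dataclasses.asdict(record.parameters),
        "sampling_rate": wf.sampling_rate,
        "period": wf.period,
        "sites": wf.sites,
        "path_lengths": record.network.path_lengths,
        "theoretical_pwv": record.theoretical_pwv,
        "network": _network_to_dict(record.network),
    }
    (directory / f"{record.subject_id}.json").write_text(
        json.dumps(meta, indent=1))
    return csv_path


def read_subject(path: str | Path) -> SubjectRecord:
    """Read a subject back from its CSV (or CSV/JSON path prefix)."""
    path = Path(path)
    if path.suffix == ".json":
        path = path.with_suffix(".csv")
    if not path.exists():
        raise FormatError(f"waveform file not found: {path}")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError("missing required column 'time_s'")

    sites = meta["sites"]
    data: dict[str, dict[str, np.ndarray]] = {}
    for site in sites:
        series = {}
        for key, suffix, scale in (("P", "P_mmHg", MMHG),
                                   ("Q", "Q_mls", 1e-6),
                                   ("A", "A_cm2", 1e-4)):
            col = f"{site}_{suffix}"
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
            series[key] = df[col].to_numpy() * scale
        data[site] = series

    wf = WaveformSet(sites=list(sites), sampling_rate=meta["sampling_rate"],
                     period=meta["period"], data=data)
    params = SubjectParameters(**meta["parameters"])
    net = _network_from_dict(meta["network"])
    return SubjectRecord(parameters=params, network=net, waveforms=wf,
                         theoretical_pwv=meta["theoretical_pwv"],
                         subject_id=meta["subject_id"])


def write_cohort(records: list[SubjectRecord], directory: str | Path,
                 failures: list[dict] | None = None) -> Path:
    """Write all subjects plus the cohort manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_subject(rec, directory)
        row = {"subject_id": rec.subject_id, "status": "ok"}
        row.update(dataclasses.asdict(rec.parameters))
        rows.append(row)
    for fail in failures or []:
        rows.append({"subject_id": fail.get("subject_id", "unknown"),
                     "status": fail.get("error", "failed")})
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=_FLOAT_FMT)
    return manifest


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    """Load every successfully simulated subject listed in the manifest."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FormatError(f"no {MANIFEST_NAME} in {directory}")
    df = pd.read_csv(manifest)
    records = []
    for _, row in df.iterrows():
        if row.get("status", "ok") != "ok":
            continue
        records.append(read_subject(directory / f"{row['subject_id']}.csv"))
    return records
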