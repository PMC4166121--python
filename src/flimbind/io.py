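"""Readers and writers for decay histograms, sensorgrams and parameter files.

All numeric CSV/JSON output is serialized with 12+ significant digits so
write-then-read round-trips are exact to within float parsing.  Malformed
rows are reported with their 1-based line number in the file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import InjectionSchedule, SingleStateParams, TwoStateParams
from .decay import DecayModel
from .sensorgram import Sensorgram, SensorgramSet
from .tcspc import AcquisitionConfig, IRFSpec, TCSPCDataset

__all__ = [
    "write_decay_csv",
    "read_decay_csv",
    "write_sensorgram_csv",
    "read_sensorgram_csv",
    "write_sensorgram_set",
    "read_sensorgram_set",
    "write_json",
    "read_json",
    "write_params_json",
    "read_params_json",
    "read_fasta",
]

_FLOAT_FMT = "%.12g"


def _numeric_or_die(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    converted = pd.to_numeric(frame[column], errors="coerce")
    bad = converted.isna() & frame[column].notna()
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: non-numeric value {frame[column][bad.idxmax()]!r} "
            f"in column {column!r} at line {line}"
        )
    if converted.isna().any():
        line = int(converted.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing value in column {column!r} at line {line}")
    return converted.to_numpy()


def write_decay_csv(dataset: TCSPCDataset, path) -> None:
    """Write ``time_ns,counts,irf_counts`` plus a JSON sidecar ``<path>.meta.json``."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_ns": dataset.channel_times_ns,
            "counts": dataset.counts.astype(int),
            "irf_counts": dataset.irf_counts.astype(int),
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "acquisition": dataclasses.asdict(dataset.acq),
        "seed": dataset.meta.get("seed"),
    }
    irf = dataset.meta.get("irf")
    if isinstance(irf, IRFSpec):
        meta["irf"] = dataclasses.asdict(irf)
    write_json(meta, path.with_suffix(path.suffix + ".meta.json"))


def read_decay_csv(path) -> TCSPCDataset:
    """Read a decay CSV (and its sidecar, when present) back into a dataset."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    expected = {"time_ns", "counts", "irf_counts"}
    if set(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    times = _numeric_or_die(frame, "time_ns", path)
    counts = _numeric_or_die(frame, "counts", path)
    irf_counts = _numeric_or_die(frame, "irf_counts", path)

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta: dict = {}
    if sidecar.exists():
        doc = read_json(sidecar)
        acq = AcquisitionConfig(**doc["acquisition"])
        meta = {"seed": doc.get("seed")}
        if "irf" in doc:
            meta["irf"] = IRFSpec(**doc["irf"])
    else:
        dt_ps = float(np.median(np.diff(times))) * 1000.0
        acq = AcquisitionConfig(
            n_channels=len(times),
            channel_width_ps=dt_ps,
            rep_period_ns=len(times) * dt_ps / 1000.0,
            total_counts=max(float(counts.sum()), 1.0),
        )
    return TCSPCDataset(
        channel_times_ns=times,
        counts=counts.astype(np.int64),
        irf_counts=irf_counts.astype(np.int64),
        acq=acq,
        meta=meta,
    )


def _phase_labels(sg: Sensorgram) -> list[str]:
    bounds = sg.schedule.boundaries_s
    labels = [p.label or f"phase_{i + 1}" for i, p in enumerate(sg.schedule.phases)]
    idx = np.clip(
        np.searchsorted(bounds, sg.time_s, side="right") - 1, 0, len(labels) - 1
    )
    return [labels[i] for i in idx]


def write_sensorgram_csv(sg: Sensorgram, path) -> None:
    """Write ``time_s,response_RU,phase_label`` for one trace."""
    frame = pd.DataFrame(
        {
            "time_s": sg.time_s,
            "response_RU": sg.response_ru,
            "phase_label": _phase_labels(sg),
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sensorgram_csv(path, schedule: InjectionSchedule, concentration_M: float) -> Sensorgram:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    for col in ("time_s", "response_RU"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return Sensorgram(
        time_s=_numeric_or_die(frame, "time_s", path),
        response_ru=_numeric_or_die(frame, "response_RU", path),
        schedule=schedule,
        concentration_M=concentration_M,
    )


def write_sensorgram_set(sset: SensorgramSet, directory, stem: str = "trace") -> Path:
    """Write one CSV per trace plus a ``<stem>_manifest.json`` describing the set.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sg in enumerate(sset.sensorgrams):
        name = f"{stem}_{i:02d}.csv"
        write_sensorgram_csv(sg, directory / name)
        entries.append(
            {
                "file": name,
                "concentration_M": sg.concentration_M,
                "schedule": sg.schedule.to_dict(),
            }
        )
    manifest = {
        "mode": sset.mode,
        "traces": entries,
        "seed": sset.meta.get("seed"),
        "noise_sd": sset.meta.get("noise_sd"),
    }
    manifest_path = directory / f"{stem}_manifest.json"
    write_json(manifest, manifest_path)
    return manifest_path


def read_sensorgram_set(manifest_path) -> SensorgramSet:
    manifest_path = Path(manifest_path)
    doc = read_json(manifest_path)
    traces = []
    for entry in doc["traces"]:
        schedule = InjectionSchedule.from_dict(entry["schedule"])
        traces.append(
            read_sensorgram_csv(
                manifest_path.parent / entry["file"],
                schedule,
                float(entry["concentration_M"]),
            )
        )
    return SensorgramSet(
        sensorgrams=tuple(traces),
        mode=doc["mode"],
        meta={"seed": doc.get("seed"), "noise_sd": doc.get("noise_sd")},
    )


def write_json(doc: Mapping, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_params_json(params, path) -> None:
    """Serialize a DecayModel, SingleStateParams or TwoStateParams to JSON."""
    if isinstance(params, DecayModel):
        doc = {"kind": "decay_model", **params.to_dict()}
    elif isinstance(params, SingleStateParams):
        doc = {"kind": "single_state", **dataclasses.asdict(params)}
    elif isinstance(params, TwoStateParams):
        doc = {"kind": "two_state", **dataclasses.asdict(params)}
    else:
        raise TypeError(f"unsupported parameter object {type(params).__name__}")
    write_json(doc, path)


def read_params_json(path):
    doc = read_json(path)
    kind = doc.pop("kind", None)
    if kind == "decay_model":
        return DecayModel.from_dict(doc)
    if kind == "single_state":
        return SingleStateParams(**doc)
    if kind == "two_state":
        return TwoStateParams(**doc)
    raise ValueError(f"{path}: unknown or missing parameter kind {kind!r}")


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
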