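"""File formats: spike CSV, raw-trace HDF5, scenario YAML, result tables.

Spike tables are plain CSV with ``electrode_id,time_s`` columns preceded
by ``#``-prefixed metadata lines (recording bounds, geometry, seed and a
hash of the generating configuration), so a file round-trips to an
identical :class:`~measync.core.WellRecording`.  Times are serialized with
6 decimal places (1 us resolution, beyond 20 kHz sampling).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .bursts import SBFEvent
from .core import ElectrodeGeometry, SpikeTrain, WellRecording
from .detect import RawTrace
from .simulate import EpochSpec, GroundTruth, SimParams
from .synchrony import SynchronyStat, stats_frame

__all__ = [
    "config_hash",
    "write_spike_csv",
    "read_spike_csv",
    "write_raw_hdf5",
    "read_raw_hdf5",
    "write_events_csv",
    "read_events_csv",
    "write_stats_csv",
    "write_ground_truth_csv",
    "load_scenario",
    "save_scenario",
]


def config_hash(config: dict) -> str:
    """Short SHA-256 of a canonical-JSON configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _metadata_lines(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in meta.items()]


def _read_metadata(path: Path) -> tuple[dict, int]:
    meta, n_skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n_skip


def write_spike_csv(
    well: WellRecording,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Write a well as ``electrode_id,time_s`` CSV with metadata header."""
    path = Path(path)
    g = well.geometry
    meta = {
        "t_start": f"{well.t_start:.6f}",
        "t_stop": f"{well.t_stop:.6f}",
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "pitch_um": g.pitch,
        "electrode_ids": ",".join(g.electrode_ids),
    }
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_sha256"] = config_hash(config)
    lines = _metadata_lines(meta) + ["electrode_id,time_s"]
    for tr in well.trains:
        lines.extend(f"{tr.electrode_id},{t:.6f}" for t in tr.timestamps)
    path.write_text("\n".join(lines) + "\n")


def read_spike_csv(path: str | Path) -> WellRecording:
    """Read a spike CSV written by :func:`write_spike_csv`.

    Bounds and geometry come from the metadata header; rows with duplicate
    (electrode, time) entries are rejected.
    """
    path = Path(path)
    meta, n_skip = _read_metadata(path)
    df = pd.read_csv(path, skiprows=n_skip)
    for col in ("electrode_id", "time_s"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if df.duplicated(subset=["electrode_id", "time_s"]).any():
        bad = df[df.duplicated(subset=["electrode_id", "time_s"])].iloc[0]
        raise ValueError(
            f"duplicate spike row: electrode {bad.electrode_id} at {bad.time_s}"
        )
    geometry = ElectrodeGeometry(
        n_rows=int(meta.get("n_rows", 4)),
        n_cols=int(meta.get("n_cols", 4)),
        pitch=float(meta.get("pitch_um", 350.0)),
        electrode_ids=tuple(meta["electrode_ids"].split(","))
        if "electrode_ids" in meta
        else (),
    )
    if "t_start" in meta and "t_stop" in meta:
        t0, t1 = float(meta["t_start"]), float(meta["t_stop"])
    else:
        t0 = float(df["time_s"].min()) if len(df) else 0.0
        t1 = float(df["time_s"].max()) if len(df) else 0.0
    trains = []
    for eid in geometry.electrode_ids:
        ts = np.sort(df.loc[df["electrode_id"] == eid, "time_s"].to_numpy(float))
        trains.append(SpikeTrain(eid, ts, t0, t1))
    return WellRecording(geometry, tuple(trains))


def write_raw_hdf5(traces: Sequence[RawTrace], path: str | Path) -> None:
    """One dataset per electrode with sampling_rate/t_start attributes."""
    with h5py.File(path, "w") as fh:
        for tr in traces:
            ds = fh.create_dataset(tr.electrode_id, data=tr.samples)
            ds.attrs["sampling_rate"] = tr.sampling_rate
            ds.attrs["t_start"] = tr.t_start


def read_raw_hdf5(path: str | Path) -> list[RawTrace]:
    """Read raw traces; lengths and sampling rates must be consistent."""
    traces = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            ds = fh[name]
            if "sampling_rate" not in ds.attrs:
                raise ValueError(f"dataset {name!r} lacks sampling_rate attribute")
            x = ds[()]
            if x.size == 0:
                raise ValueError(f"dataset {name!r} is empty")
            traces.append(
                RawTrace(
                    name,
                    float(ds.attrs["sampling_rate"]),
                    np.asarray(x, float),
                    float(ds.attrs.get("t_start", 0.0)),
                )
            )
    if len({tr.samples.size for tr in traces}) > 1:
        raise ValueError("electrode traces have mismatched lengths")
    return traces


def write_events_csv(events: Iterable[SBFEvent], path: str | Path) -> None:
    rows = [
        {
            "t_start": e.t_start,
            "t_end": e.t_end,
            "n_spikes": e.n_spikes,
            "n_electrodes": len(e.participating_electrodes),
            "electrodes": ";".join(sorted(e.participating_electrodes)),
        }
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["t_start", "t_end", "n_spikes", "n_electrodes", "electrodes"]
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[SBFEvent]:
    df = pd.read_csv(path)
    return [
        SBFEvent(
            float(r.t_start),
            float(r.t_end),
            int(r.n_spikes),
            frozenset(str(r.electrodes).split(";")) if isinstance(r.electrodes, str) else frozenset(),
        )
        for r in df.itertuples()
    ]


def write_stats_csv(
    stats: Sequence[SynchronyStat],
    path: str | Path,
    geometry: ElectrodeGeometry | None = None,
) -> None:
    stats_frame(stats, geometry).to_csv(path, index=False)


def write_ground_truth_csv(truth: GroundTruth, directory: str | Path) -> None:
    """Export ground truth as plain CSV tables under a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.sbf_times, columns=["t_start", "t_end"]).to_csv(
        directory / "sbf_times.csv", index=False
    )
    rows = [
        {"electrode_id": eid, "index": k, "label": lab}
        for eid, labs in truth.spike_labels.items()
        for k, lab in enumerate(labs)
    ]
    pd.DataFrame(rows, columns=["electrode_id", "index", "label"]).to_csv(
        directory / "spike_labels.csv", index=False
    )
    pd.DataFrame(truth.coupling).to_csv(directory / "coupling.csv", index=False)


def save_scenario(
    params: SimParams, protocol: Sequence[EpochSpec], path: str | Path
) -> None:
    """Write a simulation scenario (parameters + epochs) as YAML."""
    doc = {
        "params": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(params).items()
        },
        "epochs": [
            {
                "label": ep.label,
                "t0": ep.t0,
                "t1": ep.t1,
                "sporadic_mult": ep.sporadic_mult,
                "sbf_mult": ep.sbf_mult,
                "intra_burst_mult": ep.intra_burst_mult,
                "coupling_mult": ep.coupling_mult,
            }
            for ep in protocol
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path: str | Path) -> tuple[SimParams, list[EpochSpec]]:
    """Read a YAML/JSON scenario file into (SimParams, protocol)."""
    doc = yaml.safe_load(Path(path).read_text())
    raw = dict(doc.get("params", {}))
    if raw.get("coupling") is not None:
        raw["coupling"] = np.asarray(raw["coupling"], dtype=float)
    params = SimParams(**raw)
    epochs = [
        EpochSpec(
            label=str(ep["label"]),
            t0=float(ep["t0"]),
            t1=float(ep["t1"]),
            sporadic_mult=float(ep.get("sporadic_mult", 1.0)),
            sbf_mult=float(ep.get("sbf_mult", 1.0)),
            intra_burst_mult=float(ep.get("intra_burst_mult", 1.0)),
            coupling_mult=float(ep.get("coupling_mult", 1.0)),
        )
        for ep in doc.get("epochs", [])
    ]
    return params, epochs
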