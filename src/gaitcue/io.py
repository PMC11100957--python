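"""File formats: CSV streams with a JSON metadata header, JSON intervals,
configs and reports, optional HDF5 for long streams.

The stream CSV carries one ``#``-prefixed JSON header line with the sensor
metadata followed by columns ``t, ax, ay, az, gx, gy, gz`` (seconds, m/s²,
°/s).  Interval documents are versioned JSON.
"""

from __future__ import annotations

import json
import os
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import (
    CueingConfig,
    FogEpisode,
    ImuStream,
    MotionPhase,
    StreamMeta,
    ValidationError,
    check_non_overlapping,
)

STREAM_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
INTERVAL_SCHEMA = "gaitcue-intervals-1"


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    return "hdf5" if ext in (".h5", ".hdf5") else "csv"


def write_imu_stream(stream: ImuStream, path: str, format: str | None = None) -> None:
    stream.validate()
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(stream.meta.to_dict()) + "\n")
            df = pd.DataFrame(
                np.column_stack([stream.t, stream.acc, stream.gyr]), columns=STREAM_COLUMNS
            )
            df.to_csv(fh, index=False)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=stream.t)
            fh.create_dataset("acc", data=stream.acc)
            fh.create_dataset("gyr", data=stream.gyr)
            for k, v in stream.meta.to_dict().items():
                fh.attrs[k] = v
    else:
        raise ValidationError(f"unknown stream format {fmt!r}")


def read_imu_stream(path: str, format: str | None = None) -> ImuStream:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("#"):
            raise ValidationError("stream CSV must begin with a '#' JSON metadata header")
        meta = StreamMeta.from_dict(json.loads(first.lstrip("#").strip()))
        df = pd.read_csv(path, comment="#")
        missing = [c for c in STREAM_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"stream CSV missing columns: {missing}")
        stream = ImuStream(
            t=df["t"].to_numpy(),
            acc=df[["ax", "ay", "az"]].to_numpy(),
            gyr=df[["gx", "gy", "gz"]].to_numpy(),
            meta=meta,
        )
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            meta = StreamMeta.from_dict({k: fh.attrs[k] for k in fh.attrs})
            meta.sensor_id = str(meta.sensor_id)
            stream = ImuStream(t=fh["t"][:], acc=fh["acc"][:], gyr=fh["gyr"][:], meta=meta)
    else:
        raise ValidationError(f"unknown stream format {fmt!r}")
    return stream.validate()


Interval = Union[MotionPhase, FogEpisode]


def write_intervals(intervals: Sequence[Interval], path: str) -> None:
    """Write motion phases and FoG episodes as one versioned JSON document."""
    phases = [iv for iv in intervals if isinstance(iv, MotionPhase)]
    episodes = [iv for iv in intervals if isinstance(iv, FogEpisode)]
    if len(phases) + len(episodes) != len(intervals):
        raise ValidationError("intervals must be MotionPhase or FogEpisode instances")
    check_non_overlapping(episodes, "FoG episodes")
    doc = {
        "schema": INTERVAL_SCHEMA,
        "motion_phases": [p.to_dict() for p in sorted(phases, key=lambda p: p.start)],
        "fog_episodes": [e.to_dict() for e in sorted(episodes, key=lambda e: e.start)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_intervals(path: str) -> Tuple[List[MotionPhase], List[FogEpisode]]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != INTERVAL_SCHEMA:
        raise ValidationError(f"unexpected interval schema {doc.get('schema')!r}")
    phases = [MotionPhase.from_dict(d) for d in doc.get("motion_phases", [])]
    episodes = [FogEpisode.from_dict(d) for d in doc.get("fog_episodes", [])]
    return phases, episodes


def write_cueing_config(config: CueingConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=1)


def read_cueing_config(path: str) -> CueingConfig:
    with open(path) as fh:
        return CueingConfig.from_dict(json.load(fh))


def write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonify)


def read_json(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj)!r}")
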