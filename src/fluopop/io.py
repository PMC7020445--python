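"""Readers and writers for the pipeline's on-disk formats.

Movies and label masks travel as TIFF; traces, spikes, features, ROI and
profile tables as CSV; boundaries, manifests and test results as JSON;
configuration as YAML. Trace CSVs put cell_id in the first column and one
column per frame with the header holding the time in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .population import ClassBoundaries, SubpopulationProfile, CLASS_ORDER
from .segmentation import LabelMask, Movie, _roi_table
from .traces import SpikeTrain, TraceSet

__all__ = [
    "FormatError",
    "load_movie",
    "write_movie",
    "write_mask",
    "read_mask",
    "write_traces",
    "read_traces",
    "write_ground_truth",
    "write_features",
    "write_spikes",
    "write_profiles",
    "write_boundaries",
    "read_boundaries",
    "write_yaml",
    "read_yaml",
    "write_json",
]


class FormatError(ValueError):
    """An input file is not in the expected format."""


def load_movie(path, frame_interval: float = 10.0) -> Movie:
    """Read a multi-frame grayscale TIFF as a Movie.

    Frames are taken in acquisition order; the frame interval comes from
    configuration (10 s by default). RGB or single-frame files are
    rejected with a hint.
    """
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - remediation hint wanted
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        raise FormatError(
            f"{path} holds a single frame; a time-lapse stack (frames x h x w) is required"
        )
    if data.ndim != 3:
        raise FormatError(
            f"{path} has shape {data.shape}; expected a grayscale stack — "
            "convert RGB movies to single-channel first"
        )
    return Movie(data=data.astype(float), frame_interval=frame_interval)


def write_movie(path, movie: Movie) -> None:
    tifffile.imwrite(path, movie.data.astype(np.float32))


def write_mask(path, mask: LabelMask, roi_csv=None) -> None:
    """Label mask as 16-bit single-frame TIFF, optionally with an ROI CSV."""
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    if roi_csv is not None:
        mask.roi_table.to_csv(roi_csv, index=False)


def read_mask(path) -> LabelMask:
    labels = np.asarray(tifffile.imread(path)).astype(np.int32)
    return LabelMask(labels, _roi_table(labels))


def write_traces(path, traces: TraceSet) -> None:
    df = pd.DataFrame(traces.raw, columns=[f"{t:g}" for t in traces.times])
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, index=False)


def read_traces(path, condition_label: str = "") -> TraceSet:
    df = pd.read_csv(path)
    if df.columns[0] != "cell_id":
        raise FormatError(f"{path}: first column must be cell_id")
    times = np.array([float(c) for c in df.columns[1:]])
    if times.size >= 2:
        dt = float(np.diff(times).mean())
    else:
        dt = 10.0
    return TraceSet(
        cell_ids=list(df["cell_id"]),
        raw=df.iloc[:, 1:].to_numpy(dtype=float),
        frame_interval=dt,
        condition_label=condition_label,
    )


def write_ground_truth(path, dataset) -> None:
    rows = [
        {
            "cell_id": g.cell_id,
            "true_class": g.true_class.value,
            "spike_frames": ";".join(str(int(f)) for f in g.true_spike_times),
        }
        for g in dataset.ground_truth
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_features(path, features: pd.DataFrame) -> None:
    features.to_csv(path, index=False)


def write_spikes(path, spike_trains: list[SpikeTrain], frame_interval: float) -> None:
    rows = []
    for st in spike_trains:
        for f, a in zip(st.spike_frames, st.spike_amplitudes):
            rows.append(
                {"cell_id": st.cell_id, "frame": int(f),
                 "time_s": float(f * frame_interval), "amplitude": float(a)}
            )
    pd.DataFrame(rows, columns=["cell_id", "frame", "time_s", "amplitude"]).to_csv(
        path, index=False
    )


def write_profiles(path, profiles: list[SubpopulationProfile]) -> None:
    pd.DataFrame([p.as_row() for p in profiles]).to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_boundaries(path, boundaries: ClassBoundaries) -> None:
    Path(path).write_text(json.dumps(boundaries.to_dict(), indent=2) + "\n")


def read_boundaries(path) -> ClassBoundaries:
    return ClassBoundaries.from_dict(json.loads(Path(path).read_text()))


def write_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
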