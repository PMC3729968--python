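"""File formats owned by the pipeline.

Sensor layouts are CSV (channel_id, x, y, z, ox, oy, oz; meters), atlases
and RSN memberships are JSON, epoched recordings are HDF5 (one group per
subject, dataset ``data`` shaped channels x samples x epochs with ``fs``
and ``epoch_samples`` attributes), covariates are TSV, adjacency matrices
are CSV with ROI labels as header (plus a long-form edge-list TSV), and
statistics tables are TSV.  Text round trips preserve 12+ significant
digits; HDF5 round trips are bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bands import FrequencyBand, get_band
from .connectivity import AdjacencyMatrix
from .geometry import HeadModel, ROIAtlas, SensorArray
from .recording import EpochedRecording
from .rsn import validate_rsns

_FLOAT_FMT = "%.17g"


def write_sensors_csv(sensors: SensorArray, path) -> None:
    df = pd.DataFrame({
        "channel_id": sensors.channel_ids,
        "x": sensors.positions[:, 0], "y": sensors.positions[:, 1],
        "z": sensors.positions[:, 2],
        "ox": sensors.orientations[:, 0], "oy": sensors.orientations[:, 1],
        "oz": sensors.orientations[:, 2]})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sensors_csv(path) -> SensorArray:
    df = pd.read_csv(path)
    required = ["channel_id", "x", "y", "z", "ox", "oy", "oz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return SensorArray(
        channel_ids=tuple(df["channel_id"].astype(str)),
        positions=df[["x", "y", "z"]].to_numpy(float),
        orientations=df[["ox", "oy", "oz"]].to_numpy(float))


def write_atlas_json(atlas: ROIAtlas, path, head: HeadModel | None = None) -> None:
    payload = {"rois": {lab: atlas.voxels[lab].tolist()
                        for lab in atlas.labels}}
    if head is not None:
        payload["head"] = {"sphere_center": head.sphere_center.tolist(),
                           "sphere_radius": head.sphere_radius}
    Path(path).write_text(json.dumps(payload))


def read_atlas_json(path) -> tuple[ROIAtlas, HeadModel | None]:
    payload = json.loads(Path(path).read_text())
    if "rois" not in payload:
        raise ValueError(f"{path}: missing 'rois' object")
    atlas = ROIAtlas({lab: np.asarray(v, dtype=float)
                      for lab, v in payload["rois"].items()})
    head = None
    if "head" in payload:
        head = HeadModel(np.asarray(payload["head"]["sphere_center"]),
                         float(payload["head"]["sphere_radius"]))
    return atlas, head


def write_rsns_json(rsns: dict[str, list[str]], path) -> None:
    Path(path).write_text(json.dumps(rsns, indent=1))


def read_rsns_json(path, atlas_labels=None) -> dict[str, list[str]]:
    rsns = json.loads(Path(path).read_text())
    if not isinstance(rsns, dict):
        raise ValueError(f"{path}: RSN file must map names to label lists")
    if atlas_labels is not None:
        try:
            validate_rsns(rsns, atlas_labels)
        except ValueError as err:
            raise ValueError(f"{path}: {err}") from err
    return rsns


def write_recordings_h5(recordings: dict[str, EpochedRecording], path) -> None:
    with h5py.File(path, "w") as f:
        for sid, rec in recordings.items():
            g = f.create_group(sid)
            g.create_dataset("data", data=rec.data)
            g.attrs["fs"] = rec.fs
            g.attrs["epoch_samples"] = rec.epoch_samples
            if rec.channel_ids is not None:
                g.attrs["channel_ids"] = list(rec.channel_ids)


def append_recording_h5(rec: EpochedRecording, subject_id: str, path) -> None:
    with h5py.File(path, "a") as f:
        if subject_id in f:
            raise ValueError(f"{path}: subject {subject_id!r} already stored")
        g = f.create_group(subject_id)
        g.create_dataset("data", data=rec.data)
        g.attrs["fs"] = rec.fs
        g.attrs["epoch_samples"] = rec.epoch_samples
        if rec.channel_ids is not None:
            g.attrs["channel_ids"] = list(rec.channel_ids)


def read_recordings_h5(path) -> dict[str, EpochedRecording]:
    out: dict[str, EpochedRecording] = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            g = f[sid]
            if "data" not in g:
                raise ValueError(f"{path}: subject {sid!r} lacks 'data'")
            ids = g.attrs.get("channel_ids")
            out[sid] = EpochedRecording(
                data=g["data"][()], fs=float(g.attrs["fs"]),
                channel_ids=tuple(str(c) for c in ids)
                if ids is not None else None,
                subject_id=sid)
    return out


def write_beamformer_h5(weights: np.ndarray, covariance: np.ndarray, path,
                        subject_id: str | None = None) -> None:
    """Export spatial filters: datasets ``weights`` (voxels x channels) and
    ``covariance`` (channels x channels), optionally grouped by subject."""
    with h5py.File(path, "a") as f:
        g = f.create_group(subject_id) if subject_id else f
        g.create_dataset("weights", data=np.asarray(weights, dtype=float))
        g.create_dataset("covariance",
                         data=np.asarray(covariance, dtype=float))


def read_beamformer_h5(path, subject_id: str | None = None):
    with h5py.File(path, "r") as f:
        g = f[subject_id] if subject_id else f
        if "weights" not in g or "covariance" not in g:
            raise ValueError(f"{path}: missing 'weights' or 'covariance' "
                             "dataset")
        return g["weights"][()], g["covariance"][()]


def write_covariates_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_adjacency_csv(A: AdjacencyMatrix, path) -> None:
    pd.DataFrame(A.values, index=list(A.labels),
                 columns=list(A.labels)).to_csv(
        path, float_format=_FLOAT_FMT)


def read_adjacency_csv(path, band: FrequencyBand | str,
                       subject_id: str | None = None) -> AdjacencyMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    if isinstance(band, str):
        band = get_band(band)
    return AdjacencyMatrix(values=df.to_numpy(float), band=band,
                           labels=tuple(df.columns), subject_id=subject_id)


def adjacency_long_frame(matrices: list[AdjacencyMatrix]) -> pd.DataFrame:
    """Long-form edge list (roi_a, roi_b, band, subject, pli)."""
    rows = []
    for A in matrices:
        iu = np.triu_indices(A.n_rois, k=1)
        for i, j in zip(*iu):
            rows.append((A.labels[i], A.labels[j], A.band.name,
                         A.subject_id, A.values[i, j]))
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "band",
                                       "subject", "pli"])


def write_results_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
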