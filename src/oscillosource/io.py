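"""Serialisation: trials, leadfields and IMF sets to HDF5/NPZ/CSV.

Dataset layout for trials files:
  epochs            (trials, N, T) float
  fs                scalar
  sensor_positions  (N, 3)
  ground_truth/components   (trials, 3, T)    [optional]
  ground_truth/phases       (trials, 3, T)
  ground_truth/frequencies  (trials, 3, T)
  ground_truth/clean        (trials, N, T)

Leadfields: HDF5 or NPZ with ``L``, ``vertex_positions``,
``vertex_orientations``, ``sensor_positions`` (plus optional
``roi_vertices``); a plain CSV holding only the gain matrix is accepted
as a fallback (geometry must then be supplied separately).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .emd import IMFSet
from .synthdata import Geometry, GroundTruth, Leadfield, SensorEpoch

__all__ = [
    "save_trials",
    "load_trials",
    "save_leadfield",
    "load_leadfield",
    "save_imfset",
    "load_imfset",
    "read_mep_csv",
]


def save_trials(path, epochs: list[SensorEpoch],
                truths: list[GroundTruth] | None = None) -> None:
    data = np.stack([e.data for e in epochs])
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=data)
        f.create_dataset("fs", data=epochs[0].fs)
        if epochs[0].sensor_positions is not None:
            f.create_dataset("sensor_positions",
                             data=epochs[0].sensor_positions)
        if truths is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("components",
                             data=np.stack([t.components for t in truths]))
            g.create_dataset("phases",
                             data=np.stack([t.phases for t in truths]))
            g.create_dataset("frequencies",
                             data=np.stack([t.frequencies for t in truths]))
            g.create_dataset("clean",
                             data=np.stack([t.clean_projection
                                            for t in truths]))


def load_trials(path) -> tuple[list[SensorEpoch], list[GroundTruth] | None]:
    with h5py.File(path, "r") as f:
        data = f["epochs"][()]
        fs = float(f["fs"][()])
        pos = f["sensor_positions"][()] if "sensor_positions" in f else None
        epochs = [SensorEpoch(data=d, fs=fs, sensor_positions=pos)
                  for d in data]
        truths = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            comps = g["components"][()]
            phases = g["phases"][()]
            freqs = g["frequencies"][()]
            clean = g["clean"][()]
            truths = [
                GroundTruth(components=comps[i], phases=phases[i],
                            frequencies=freqs[i],
                            distractors=np.zeros((0, comps.shape[-1])),
                            clean_projection=clean[i])
                for i in range(comps.shape[0])
            ]
    return epochs, truths


def save_leadfield(path, lf: Leadfield) -> None:
    path = Path(path)
    fields = dict(
        L=lf.L,
        sensor_positions=lf.geometry.sensor_positions,
        vertex_positions=lf.geometry.vertex_positions,
        vertex_orientations=lf.geometry.vertex_orientations,
        roi_vertices=lf.geometry.roi_vertices,
    )
    if path.suffix == ".npz":
        np.savez(path, **fields)
    else:
        with h5py.File(path, "w") as f:
            for k, v in fields.items():
                f.create_dataset(k, data=v)


def load_leadfield(path, geometry: Geometry | None = None) -> Leadfield:
    path = Path(path)
    if path.suffix == ".csv":
        L = np.loadtxt(path, delimiter=",")
        if geometry is None:
            raise ValueError("CSV leadfields carry no geometry; pass one")
        return Leadfield(L=L, geometry=geometry)
    if path.suffix == ".npz":
        d = dict(np.load(path))
    else:
        with h5py.File(path, "r") as f:
            d = {k: f[k][()] for k in f}
    geom = Geometry(
        sensor_positions=d["sensor_positions"],
        vertex_positions=d["vertex_positions"],
        vertex_orientations=d["vertex_orientations"],
        roi_vertices=d.get("roi_vertices", np.array([], int)),
    )
    return Leadfield(L=d["L"], geometry=geom)


def save_imfset(path, imfset: IMFSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("imfs", data=np.stack(imfset.imfs)
                         if imfset.imfs else np.zeros((0, 0)))
        f.create_dataset("residual", data=imfset.residual)
        f.create_dataset("fs", data=imfset.fs)


def load_imfset(path) -> IMFSet:
    with h5py.File(path, "r") as f:
        imfs = [c for c in f["imfs"][()]]
        return IMFSet(imfs=imfs, residual=f["residual"][()],
                      fs=float(f["fs"][()]))


def save_correlation_traces(path, traces: dict[str, np.ndarray],
                            fs: float, t0: float = 0.0) -> None:
    """Write per-band correlation traces rho_f(t) to CSV (or HDF5 for
    ``.h5`` paths) with a time column in seconds relative to stimulus."""
    path = Path(path)
    T = len(next(iter(traces.values())))
    time = t0 + np.arange(T) / fs
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("time_s", data=time)
            for band, rho in traces.items():
                f.create_dataset(band, data=np.asarray(rho, float))
    else:
        df = pd.DataFrame({"time_s": time})
        for band, rho in traces.items():
            df[band] = np.asarray(rho, float)
        df.to_csv(path, index=False)


def load_correlation_traces(path) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Inverse of :func:`save_correlation_traces`; returns
    ``(traces, time_s)``."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            time = f["time_s"][()]
            traces = {k: f[k][()] for k in f if k != "time_s"}
        return traces, time
    df = pd.read_csv(path)
    time = df.pop("time_s").to_numpy()
    return {c: df[c].to_numpy() for c in df.columns}, time


def read_mep_csv(path) -> np.ndarray:
    """Per-trial MEP peak-to-peak amplitudes from a single-column CSV
    with header ``mep_mv``."""
    df = pd.read_csv(path)
    if "mep_mv" not in df.columns:
        raise ValueError("MEP CSV must have a 'mep_mv' column")
    z = df["mep_mv"].to_numpy(dtype=float)
    if z.size < 3 or not np.all(np.isfinite(z)):
        raise ValueError("MEP vector must be finite with at least 3 trials")
    return z
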