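"""Result serialization: tidy CSV tables, HDF5 containers, manifests.

Every run writes a ``manifest.json`` carrying the configuration hash,
seed and package version so that any output table can be regenerated
bit-identically.  Long recordings (spikes, weight snapshots, traces) go
into one HDF5 container with groups /spikes, /weights, /traces and
/config; small summary tables are written as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import config_hash

__all__ = ["write_results", "write_spikes_csv", "read_spikes_csv",
           "write_hdf5"]


def write_spikes_csv(trains, path) -> None:
    """Two-column spike table: source_id, time_ms (header row)."""
    from .stimuli import spike_trains_to_frame

    spike_trains_to_frame(trains).to_csv(path, index=False)


def read_spikes_csv(path):
    """Read a two-column spike table back into SpikeTrain objects."""
    from .stimuli import SpikeTrain

    df = pd.read_csv(path)
    return [SpikeTrain(int(sid), np.sort(g["time_ms"].to_numpy()))
            for sid, g in df.groupby("source_id")]


def write_hdf5(path, spikes=None, weights=None, traces=None, config=None):
    """Write long recordings into the standard HDF5 container layout."""
    import h5py

    with h5py.File(path, "w") as f:
        if spikes is not None:
            g = f.create_group("spikes")
            for sid, times in enumerate(spikes):
                g.create_dataset(str(sid), data=np.asarray(times, dtype=float))
        if weights is not None:
            g = f.create_group("weights")
            for t, w in weights.items():
                g.create_dataset(f"t_{t}", data=np.asarray(w))
        if traces is not None:
            g = f.create_group("traces")
            for name, arr in traces.items():
                g.create_dataset(name, data=np.asarray(arr))
        if config is not None:
            g = f.create_group("config")
            g.attrs["json"] = json.dumps(config, sort_keys=True, default=str)


def write_results(result, out_dir, overwrite: bool = False) -> dict:
    """Write a ProtocolResult to ``out_dir``; returns the manifest.

    Refuses to overwrite an existing result directory unless asked.
    """
    from . import __version__

    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True (--overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(result.config),
        "seed": result.seed,
        "package_version": __version__,
        "files": [],
    }
    if result.table is not None and len(result.table):
        table_path = out / "result.csv"
        result.table.to_csv(table_path, index=False,
                            float_format="%.12g")
        manifest["files"].append(table_path.name)
    scalars = {k: v for k, v in result.extras.items()
               if np.isscalar(v) or isinstance(v, (bool, int, float, str))}
    if scalars:
        (out / "summary.json").write_text(
            json.dumps(scalars, indent=2, sort_keys=True, default=float))
        manifest["files"].append("summary.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
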