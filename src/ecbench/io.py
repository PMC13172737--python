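"""Readers, writers and run manifests.

Array artifacts (coupling tensors, time-series panels) serialize to HDF5;
tabular artifacts (edge lists, metric matrices, sweep results) to TSV/CSV.
A JSON run manifest records the configuration hash, seeds and per-file
checksums so any sweep can be re-run from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .metrics import ECMatrix
from .netgen import CouplingMatrix, CouplingTensor
from .simulate import TimeSeriesPanel

__all__ = [
    "write_tensor",
    "read_tensor",
    "tensor_to_edgelist",
    "write_panel",
    "read_panel",
    "write_ecmatrix",
    "write_manifest",
]


class FormatError(ValueError):
    pass


def write_tensor(tensor: CouplingTensor, path) -> None:
    """HDF5 container: /coeffs, /adj plus scalar attributes."""
    adj = (np.abs(tensor.coeffs).max(axis=2) > 0).astype(np.int8)
    np.fill_diagonal(adj, 0)
    with h5py.File(path, "w") as f:
        f.create_dataset("coeffs", data=tensor.coeffs)
        f.create_dataset("adj", data=adj)
        f.attrs["n_nodes"] = tensor.n_nodes
        f.attrs["max_lag"] = tensor.max_lag
        f.attrs["edge_prob"] = tensor.edge_prob
        f.attrs["gain"] = tensor.gain
        if tensor.seed is not None:
            f.attrs["seed"] = tensor.seed


def read_tensor(path) -> CouplingTensor:
    with h5py.File(path, "r") as f:
        coeffs = f["coeffs"][()]
        return CouplingTensor(
            n_nodes=int(f.attrs["n_nodes"]),
            max_lag=int(f.attrs["max_lag"]),
            coeffs=coeffs,
            edge_prob=float(f.attrs["edge_prob"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            gain=float(f.attrs["gain"]),
        )


def tensor_to_edgelist(tensor: CouplingTensor, path) -> None:
    """Plain-text TSV edge list: target, source, lag, weight."""
    m, n, l = np.nonzero(tensor.coeffs)
    df = pd.DataFrame(
        {"target": m, "source": n, "lag": l + 1, "weight": tensor.coeffs[m, n, l]}
    )
    df.to_csv(path, sep="\t", index=False)


def write_panel(panel: TimeSeriesPanel, path) -> None:
    """HDF5 (.h5/.hdf5) or wide CSV (one row per node, node_id first column)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=panel.data)
            f.attrs["sampling_interval"] = panel.sampling_interval
            f.attrs["node_ids"] = [str(i) for i in panel.node_ids]
            if panel.noise_applied is not None:
                f.attrs["snr"] = panel.noise_applied
            if panel.source_tensor_seed is not None:
                f.attrs["seed"] = panel.source_tensor_seed
    else:
        df = pd.DataFrame(panel.data, index=[str(i) for i in panel.node_ids])
        df.index.name = "node_id"
        df.to_csv(path)


def read_panel(path) -> TimeSeriesPanel:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ids = [s if isinstance(s, str) else s.decode() for s in f.attrs.get("node_ids", [])]
            return TimeSeriesPanel(
                data=f["data"][()],
                sampling_interval=float(f.attrs.get("sampling_interval", 1.0)),
                node_ids=list(ids),
                noise_applied=float(f.attrs["snr"]) if "snr" in f.attrs else None,
                source_tensor_seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )
    try:
        df = pd.read_csv(path, index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed panel table {path}: {exc}") from exc
    data = df.to_numpy(dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise FormatError(f"{path}: expected a channels x samples table")
    bad_rows = np.nonzero(~np.isfinite(data).all(axis=1))[0]
    if bad_rows.size:
        raise FormatError(
            f"{path}: malformed or incomplete row(s) {[str(df.index[i]) for i in bad_rows]}"
        )
    return TimeSeriesPanel(data=data, node_ids=[str(i) for i in df.index])


def write_ecmatrix(ec: ECMatrix, path, node_ids=None, runtime_seconds: float | None = None) -> None:
    """Square CSV with node-id headers plus a JSON sidecar of provenance."""
    path = Path(path)
    n = ec.scores.shape[0]
    ids = [str(i) for i in (node_ids or range(n))]
    df = pd.DataFrame(ec.scores, index=ids, columns=ids)
    df.index.name = "target"
    df.to_csv(path)
    sidecar = {
        "metric_id": ec.metric_id,
        "max_lag": ec.max_lag,
        "n_nodes": n,
        "runtime_seconds": runtime_seconds,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, root_seed: int, files: list, version: str) -> Path:
    """JSON run manifest: config hash, seeds, timestamps and file checksums."""
    out_dir = Path(out_dir)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package_version": version,
        "config": config,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "root_seed": root_seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {
            str(Path(f).name): _sha256(Path(f)) for f in files if Path(f).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
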