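"""Dataset and result serialization.

Primary dataset container is HDF5 (one dataset per condition plus grid and
metadata attributes); a plain-text fallback writes one TSV per condition
plus a JSON sidecar, for environments where binary artifacts are unwanted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ERPDataset, GroundTruth
from .neural import ModelSpec

__all__ = ["save_dataset_h5", "load_dataset_h5", "save_dataset_text",
           "load_dataset_text", "posterior_to_json"]


def save_dataset_h5(dataset: ERPDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["rate_hz"] = dataset.rate_hz
        f.attrs["window_ms"] = list(dataset.window_ms)
        f.attrs["conditions"] = [c.encode() for c in dataset.conditions]
        f.create_dataset("grid", data=dataset.grid)
        g = f.create_group("y")
        for c in dataset.conditions:
            g.create_dataset(c, data=dataset.y[c])
        if dataset.truth is not None:
            f.attrs["ground_truth"] = dataset.truth.to_json()


def load_dataset_h5(path) -> ERPDataset:
    import h5py

    with h5py.File(path, "r") as f:
        conditions = [c.decode() if isinstance(c, bytes) else str(c)
                      for c in f.attrs["conditions"]]
        ds = ERPDataset(
            y={c: f["y"][c][()] for c in conditions},
            grid=f["grid"][()],
            conditions=conditions,
            rate_hz=float(f.attrs["rate_hz"]),
            window_ms=tuple(f.attrs["window_ms"]),
            truth=_truth_from_json(f.attrs.get("ground_truth")),
        )
    return ds


def _truth_from_json(text) -> GroundTruth | None:
    if text is None:
        return None
    d = json.loads(text)
    return GroundTruth(
        spec=ModelSpec.from_json(json.dumps(d["spec"])),
        theta=np.asarray(d["theta"], dtype=float),
        leadfield=np.asarray(d["leadfield"], dtype=float),
        noise_variance=d["noise_variance"],
        snr=d["snr"], n_trials=d["n_trials"], seed=d["seed"],
    )


def save_dataset_text(dataset: ERPDataset, directory) -> None:
    """TSV-per-condition fallback with a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c in dataset.conditions:
        df = pd.DataFrame(dataset.y[c].T)
        df.insert(0, "time_ms", dataset.grid)
        df.to_csv(directory / f"y_{c}.tsv", sep="\t", index=False)
    meta = {
        "rate_hz": dataset.rate_hz,
        "window_ms": list(dataset.window_ms),
        "conditions": dataset.conditions,
    }
    if dataset.truth is not None:
        meta["ground_truth"] = json.loads(dataset.truth.to_json())
    (directory / "dataset.json").write_text(json.dumps(meta, indent=1))


def load_dataset_text(directory) -> ERPDataset:
    directory = Path(directory)
    meta = json.loads((directory / "dataset.json").read_text())
    y = {}
    grid = None
    for c in meta["conditions"]:
        df = pd.read_csv(directory / f"y_{c}.tsv", sep="\t")
        grid = df["time_ms"].to_numpy()
        y[c] = df.drop(columns="time_ms").to_numpy().T
    truth = None
    if "ground_truth" in meta:
        truth = _truth_from_json(json.dumps(meta["ground_truth"]))
    return ERPDataset(y=y, grid=grid, conditions=meta["conditions"],
                      rate_hz=meta["rate_hz"], window_ms=tuple(meta["window_ms"]),
                      truth=truth)


def posterior_to_json(posterior) -> str:
    return json.dumps({
        "theta_mean": list(posterior.mean),
        "theta_sd": list(np.sqrt(np.maximum(np.diag(posterior.covariance), 0.0))),
        "lambda": list(posterior.lam),
        "free_energy_trace": list(posterior.free_energy),
        "iterations": posterior.iterations,
        "converged": bool(posterior.converged),
        "timings": posterior.timings,
    }, indent=1)
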