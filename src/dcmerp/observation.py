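"""Sensor-space observation model: lead-field projection of source activity.

The mapping from source pyramidal depolarization to channel data is linear,
h = L x, with L a fixed gain (lead-field) matrix.  No head modelling is done
here; lead fields are supplied externally or sampled at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neural import ModelSpec, ParameterVector, StimulusInput, integrate

__all__ = ["LeadField", "sample_leadfield", "predict_response", "stack_response"]


@dataclass
class LeadField:
    """Gain matrix mapping n_s source potentials (mV) to n_channels sensors (a.u.)."""

    L: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if not np.all(np.isfinite(self.L)):
            raise ValueError("lead field must be finite")
        if np.any(~self.L.any(axis=0)):
            raise ValueError("lead field has an all-zero column (unobservable source)")

    @property
    def n_channels(self) -> int:
        return self.L.shape[0]

    @property
    def n_sources(self) -> int:
        return self.L.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.L).to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "LeadField":
        return cls(pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float))


def sample_leadfield(n_channels: int, n_sources: int, seed: int) -> LeadField:
    """Random lead field: seeded standard-normal entries, unit column norms."""
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n_channels, n_sources))
    L /= np.linalg.norm(L, axis=0, keepdims=True)
    return LeadField(L)


def predict_response(spec: ModelSpec, theta: ParameterVector, leadfield: LeadField,
                     stim: StimulusInput, grid: np.ndarray,
                     conditions: list[str] | None = None) -> dict[str, np.ndarray]:
    """Predicted sensor response h = L x per condition (n_channels x n_time)."""
    if leadfield.n_sources != spec.n_sources:
        raise ValueError(
            f"lead field has {leadfield.n_sources} sources, model has {spec.n_sources}"
        )
    conditions = list(conditions) if conditions is not None else list(spec.conditions)
    return {c: leadfield.L @ integrate(spec, theta, c, stim, grid) for c in conditions}


def stack_response(response: dict[str, np.ndarray], conditions: list[str]) -> np.ndarray:
    """Flatten per-condition channel x time matrices into one data vector.

    Ordering is (condition, channel, time), the layout the inverter uses.
    """
    return np.concatenate([np.asarray(response[c]).ravel() for c in conditions])
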