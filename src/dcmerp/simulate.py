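"""Synthetic ERP data with known ground truth, plus the benchmark
manipulations: data-length extension by epoch concatenation and
model-complexity scaling.

Defaults mirror common evoked-response acquisition: 250 Hz sampling over a
0-900 ms peristimulus window.  Noise is additive Gaussian sensor noise whose
variance is calibrated so the trial-averaged signal-to-noise ratio (peak
signal power over post-averaging noise power) equals the requested value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .neural import ModelSpec, ParameterVector, StimulusInput
from .observation import LeadField, predict_response, sample_leadfield

__all__ = [
    "ERPDataset",
    "GroundTruth",
    "default_grid",
    "generate_dataset",
    "extend_data_length",
    "scale_model_complexity",
]


def default_grid(rate_hz: float = 250.0, window_ms: tuple[float, float] = (0.0, 900.0)) -> np.ndarray:
    """Peristimulus sampling grid in ms: window/period + 1 points."""
    period = 1000.0 / rate_hz
    n = int(round((window_ms[1] - window_ms[0]) / period)) + 1
    return window_ms[0] + period * np.arange(n)


@dataclass
class GroundTruth:
    """Everything needed to regenerate a synthetic dataset exactly."""

    spec: ModelSpec
    theta: np.ndarray
    leadfield: np.ndarray
    noise_variance: float
    snr: float
    n_trials: int
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "spec": json.loads(self.spec.to_json()),
            "theta": list(self.theta),
            "leadfield": np.asarray(self.leadfield).tolist(),
            "noise_variance": self.noise_variance,
            "snr": self.snr,
            "n_trials": self.n_trials,
            "seed": self.seed,
        }, indent=1)


@dataclass
class ERPDataset:
    """Averaged evoked response: channels x time per condition, with metadata."""

    y: dict[str, np.ndarray]
    grid: np.ndarray
    conditions: list[str]
    rate_hz: float
    window_ms: tuple[float, float]
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for c in self.conditions:
            arr = np.asarray(self.y[c], dtype=float)
            if arr.shape[1] != self.grid.size:
                raise ValueError(f"condition {c!r}: {arr.shape[1]} samples vs grid {self.grid.size}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"condition {c!r} contains non-finite values")
            self.y[c] = arr

    @property
    def n_channels(self) -> int:
        return next(iter(self.y.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return self.grid.size


def generate_dataset(spec: ModelSpec, theta: ParameterVector, leadfield: LeadField,
                     stim: StimulusInput, grid: np.ndarray, snr: float = 10.0,
                     n_trials: int = 1, seed: int = 0) -> ERPDataset:
    """Simulate an averaged evoked response with calibrated sensor noise.

    The clean response h comes from the observation model; per-trial noise
    variance is set to n_trials * peak(h^2) / snr so that after averaging
    n_trials trials the peak-signal-to-noise power ratio equals ``snr``.
    ``snr = inf`` returns the noiseless response.  Deterministic under seed.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    grid = np.asarray(grid, dtype=float)
    clean = predict_response(spec, theta, leadfield, stim, grid)
    peak_power = max(float(np.max(h * h)) for h in clean.values())
    rng = np.random.default_rng(seed)
    if np.isinf(snr):
        trial_var = 0.0
        y = {c: h.copy() for c, h in clean.items()}
    else:
        trial_var = n_trials * peak_power / snr
        avg_sd = np.sqrt(trial_var / n_trials)
        y = {c: h + avg_sd * rng.standard_normal(h.shape) for c, h in clean.items()}
    period = grid[1] - grid[0] if grid.size > 1 else 1.0
    truth = GroundTruth(spec=spec, theta=theta.values.copy(), leadfield=leadfield.L.copy(),
                        noise_variance=trial_var, snr=snr, n_trials=n_trials, seed=seed)
    return ERPDataset(y=y, grid=grid, conditions=list(spec.conditions),
                      rate_hz=1000.0 / period, window_ms=(float(grid[0]), float(grid[-1])),
                      truth=truth)


def extend_data_length(dataset: ERPDataset, target_length: int) -> ERPDataset:
    """Tile the epoch along time and truncate to ``target_length`` samples.

    This is the data-length manipulation used for execution-time scaling:
    sample k of the extended data equals sample k mod n of the original.
    """
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    n = dataset.n_samples
    reps = int(np.ceil(target_length / n))
    y = {c: np.tile(arr, (1, reps))[:, :target_length] for c, arr in dataset.y.items()}
    period = 1000.0 / dataset.rate_hz
    grid = dataset.grid[0] + period * np.arange(target_length)
    return ERPDataset(y=y, grid=grid, conditions=list(dataset.conditions),
                      rate_hz=dataset.rate_hz,
                      window_ms=(float(grid[0]), float(grid[-1])),
                      truth=dataset.truth)


def scale_model_complexity(base_spec: ModelSpec, target_n: int) -> ModelSpec:
    """Grow a model until its free-parameter count equals ``target_n``.

    Connections are enabled in a deterministic row-major order: forward,
    backward, lateral, then condition modulations (when the model has a
    non-baseline condition), then per-source intrinsic deviations
    (H_e, H_i, tau_e, tau_i per source), and finally duplicated-prior
    intrinsic padding parameters, mirroring how benchmark complexities are
    forced to a designed value.  Fails if ``target_n`` is below the base
    complexity.
    """
    spec = replace(
        base_spec,
        F_mask=base_spec.F_mask.copy(), B_mask=base_spec.B_mask.copy(),
        L_mask=base_spec.L_mask.copy(), U_mask=base_spec.U_mask.copy(),
        M_mask=base_spec.M_mask.copy(),
        intrinsic_free=list(base_spec.intrinsic_free),
    )
    n = spec.n_free
    if target_n < n:
        raise ValueError(f"target complexity {target_n} is below the base complexity {n}")
    ns = spec.n_sources
    off_diag = [(i, j) for i in range(ns) for j in range(ns) if i != j]
    for kind in ("F", "B", "L"):
        mask = getattr(spec, f"{kind}_mask")
        for i, j in off_diag:
            if n >= target_n:
                return spec
            if not mask[i, j]:
                mask[i, j] = True
                n = spec.n_free
    n_mod_conditions = len(spec.conditions) - 1
    if n_mod_conditions > 0:
        for i, j in off_diag:
            if n >= target_n:
                return spec
            if not spec.M_mask[i, j] and n + n_mod_conditions <= target_n:
                spec.M_mask[i, j] = True
                n = spec.n_free
    for name in ("H_e", "H_i", "tau_e", "tau_i"):
        for s in range(ns):
            if n >= target_n:
                return spec
            if (name, s) not in spec.intrinsic_free:
                spec.intrinsic_free.append((name, s))
                n = spec.n_free
    if n < target_n:
        spec.n_extra = base_spec.n_extra + (target_n - n)
    assert spec.n_free == target_n
    return spec


def make_benchmark_dataset(n_sources: int = 5, n_channels: int = 16,
                           n_samples: int = 500, seed: int = 0) -> ERPDataset:
    """A fully connected network driven at source 0, for engine benchmarks."""
    masks = ~np.eye(n_sources, dtype=bool)
    U = np.zeros(n_sources, dtype=bool)
    U[0] = True
    spec = ModelSpec(n_sources, masks.copy(), masks.copy(), masks.copy(), U)
    theta = ParameterVector(spec)
    lf = sample_leadfield(n_channels, n_sources, seed)
    grid = default_grid()[:n_samples]
    if grid.size < n_samples:
        base = generate_dataset(spec, theta, lf, StimulusInput(), default_grid(),
                                snr=np.inf, seed=seed)
        return extend_data_length(base, n_samples)
    return generate_dataset(spec, theta, lf, StimulusInput(), grid, snr=np.inf, seed=seed)
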