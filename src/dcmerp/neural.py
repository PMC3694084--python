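"""Jansen-type neural-mass network model for evoked responses.

Each cortical source is a three-population neural mass (spiny stellate,
pyramidal, inhibitory interneurons) with second-order synaptic kinetics;
sources are coupled by forward, backward and lateral extrinsic connections
and driven by a deterministic stimulus input.  The module provides the state
equations, their analytic Jacobian, and a local-linearization integrator.

Units: membrane potentials in mV, time in ms, rate constants in 1/ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm
from scipy.special import expit

__all__ = [
    "SourceParameters",
    "ModelSpec",
    "ParameterVector",
    "StimulusInput",
    "IntegrationDivergedError",
    "sigmoid",
    "sigmoid_derivative",
    "effective_connectivity",
    "state_derivative",
    "system_jacobian",
    "integrate",
    "N_STATES_PER_SOURCE",
]

#: David-Friston layout: 3 populations x (potential + current) plus the
#: second-order pair for the pyramidal depolarization that is read out.
N_STATES_PER_SOURCE = 9

# state column indices within a source's 9-vector
_V_STEL, _V_PYR_E, _V_PYR_I, _I_STEL, _I_PYR_E, _I_PYR_I, _V_INH, _I_INH, _V_PYR = range(9)


@dataclass(frozen=True)
class SourceParameters:
    """Intrinsic biophysical constants of one neural-mass source.

    Defaults are the standard Jansen/DCM values; all overridable.
    """

    H_e: float = 4.0       # excitatory synaptic gain (mV)
    H_i: float = 32.0      # inhibitory synaptic gain (mV)
    tau_e: float = 8.0     # excitatory time constant (ms)
    tau_i: float = 16.0    # inhibitory time constant (ms)
    gamma: tuple[float, float, float, float] = (128.0, 128.0 * 0.8, 128.0 * 0.25, 128.0 * 0.25)
    r: float = 0.56        # sigmoid slope (1/mV)
    eta: float = 6.0       # sigmoid threshold (mV)

    def __post_init__(self) -> None:
        if self.H_e <= 0 or self.H_i <= 0 or self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic gains and time constants must be strictly positive")
        if any(g < 0 for g in self.gamma):
            raise ValueError("intrinsic coupling constants must be nonnegative")


#: kinds of free parameters, in canonical packing order
_EXTRINSIC_KINDS = ("F", "B", "L")
_INTRINSIC_NAMES = ("H_e", "H_i", "tau_e", "tau_i")

#: prior-mean extrinsic coupling strengths (a.u.), scaled by exp(theta).
#: The centered sigmoid transmits efficiently only above a few mV (threshold
#: eta = 6 mV), so these are calibrated once so that the stimulus drives the
#: receiving stellate population to ~8 mV and extrinsic afferents deliver
#: several mV downstream, putting inter-source transmission in the sigmoid's
#: steep region (secondary/primary response ratio ~0.3, stable rest point).
DEFAULT_CONNECTION_MEANS = {"F": 2048.0, "B": 1024.0, "L": 256.0, "U": 512.0}


@dataclass
class ModelSpec:
    """Architecture of a DCM network: which connections exist and which
    parameters are free.

    Masks are boolean (n_s x n_s) with zero diagonal; ``U_mask`` marks which
    sources receive the stimulus input.  ``M_mask`` marks connections whose
    gain is modulated in every non-baseline condition (one free modulation
    parameter per enabled entry per non-baseline condition).  ``conditions``
    lists condition labels; the first is the baseline.

    ``intrinsic_free`` lists (parameter-name, source-index) pairs whose
    log-deviation from the shared :class:`SourceParameters` is estimated.
    ``input_free`` toggles free log-scalings of the stimulus onset and width.
    ``n_extra`` appends padding parameters (duplicated-prior intrinsic
    H_e deviations, cycling over sources) used to scale model complexity.
    """

    n_sources: int
    F_mask: np.ndarray
    B_mask: np.ndarray
    L_mask: np.ndarray
    U_mask: np.ndarray
    M_mask: np.ndarray | None = None
    conditions: list[str] = field(default_factory=lambda: ["standard"])
    intrinsic_free: list[tuple[str, int]] = field(default_factory=list)
    input_free: tuple[bool, bool] = (False, False)
    n_extra: int = 0
    base: SourceParameters = field(default_factory=SourceParameters)
    connection_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONNECTION_MEANS))

    def __post_init__(self) -> None:
        n = self.n_sources
        for name in ("F_mask", "B_mask", "L_mask"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if m.diagonal().any():
                raise ValueError(f"{name} must have a zero diagonal")
            setattr(self, name, m)
        self.U_mask = np.asarray(self.U_mask, dtype=bool)
        if self.U_mask.shape != (n,):
            raise ValueError(f"U_mask must have length {n}")
        if self.M_mask is None:
            self.M_mask = np.zeros((n, n), dtype=bool)
        self.M_mask = np.asarray(self.M_mask, dtype=bool)
        if self.M_mask.shape != (n, n):
            raise ValueError(f"M_mask must be {n}x{n}")
        union = self.F_mask | self.B_mask | self.L_mask
        if (self.M_mask & ~union).any():
            raise ValueError("M_mask may only modulate enabled extrinsic connections")
        for name, src in self.intrinsic_free:
            if name not in _INTRINSIC_NAMES:
                raise ValueError(f"unknown intrinsic parameter {name!r}")
            if not 0 <= src < n:
                raise ValueError(f"intrinsic source index {src} out of range")
        if self.n_extra < 0:
            raise ValueError("n_extra must be nonnegative")

    # -- free-parameter bookkeeping -------------------------------------

    def parameter_index(self) -> list[tuple]:
        """Canonical packing order of the free parameters.

        Entries are ``('F'|'B'|'L', i, j)``, ``('U', i)``,
        ``('mod', cond, i, j)``, ``('intr', name, i)``, ``('input', what)``
        and ``('extra', k)``.
        """
        index: list[tuple] = []
        for kind in _EXTRINSIC_KINDS:
            mask = getattr(self, f"{kind}_mask")
            for i, j in zip(*np.nonzero(mask)):
                index.append((kind, int(i), int(j)))
        for i in np.nonzero(self.U_mask)[0]:
            index.append(("U", int(i)))
        for cond in self.conditions[1:]:
            for i, j in zip(*np.nonzero(self.M_mask)):
                index.append(("mod", cond, int(i), int(j)))
        for name, src in self.intrinsic_free:
            index.append(("intr", name, int(src)))
        if self.input_free[0]:
            index.append(("input", "onset"))
        if self.input_free[1]:
            index.append(("input", "width"))
        for k in range(self.n_extra):
            index.append(("extra", k))
        return index

    @property
    def n_free(self) -> int:
        """Model complexity N: the number of free parameters."""
        return len(self.parameter_index())

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        d = {
            "n_sources": self.n_sources,
            "F_mask": self.F_mask.astype(int).tolist(),
            "B_mask": self.B_mask.astype(int).tolist(),
            "L_mask": self.L_mask.astype(int).tolist(),
            "U_mask": self.U_mask.astype(int).tolist(),
            "M_mask": self.M_mask.astype(int).tolist(),
            "conditions": self.conditions,
            "intrinsic_free": [[n, s] for n, s in self.intrinsic_free],
            "input_free": list(self.input_free),
            "n_extra": self.n_extra,
            "base": {
                "H_e": self.base.H_e, "H_i": self.base.H_i,
                "tau_e": self.base.tau_e, "tau_i": self.base.tau_i,
                "gamma": list(self.base.gamma), "r": self.base.r, "eta": self.base.eta,
            },
            "connection_means": self.connection_means,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        base = d.get("base", {})
        if "gamma" in base:
            base["gamma"] = tuple(base["gamma"])
        return cls(
            n_sources=d["n_sources"],
            F_mask=np.asarray(d["F_mask"], dtype=bool),
            B_mask=np.asarray(d["B_mask"], dtype=bool),
            L_mask=np.asarray(d["L_mask"], dtype=bool),
            U_mask=np.asarray(d["U_mask"], dtype=bool),
            M_mask=np.asarray(d["M_mask"], dtype=bool),
            conditions=list(d.get("conditions", ["standard"])),
            intrinsic_free=[(n, s) for n, s in d.get("intrinsic_free", [])],
            input_free=tuple(d.get("input_free", (False, False))),
            n_extra=int(d.get("n_extra", 0)),
            base=SourceParameters(**base),
            connection_means=dict(d.get("connection_means", DEFAULT_CONNECTION_MEANS)),
        )


class ParameterVector:
    """Flat vector of free log-scaling parameters with a lossless
    bidirectional map to the structured (matrix) form.

    All free parameters are log-scalings relative to positive prior means, so
    positivity of gains and time constants is structural.  The vector length
    equals the model complexity N.
    """

    def __init__(self, spec: ModelSpec, values: np.ndarray | None = None):
        self.spec = spec
        self.index = spec.parameter_index()
        if values is None:
            values = np.zeros(len(self.index))
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.index),):
            raise ValueError(
                f"expected {len(self.index)} free parameters, got shape {values.shape}"
            )
        self.values = values
        self._pos = {entry: k for k, entry in enumerate(self.index)}

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.spec, self.values.copy())

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(self.spec, values)

    def __getitem__(self, entry: tuple) -> float:
        return float(self.values[self._pos[entry]])

    def __setitem__(self, entry: tuple, value: float) -> None:
        self.values[self._pos[entry]] = value

    def position(self, entry: tuple) -> int:
        return self._pos[entry]

    def to_structured(self) -> dict:
        """Expand the flat vector into per-kind dictionaries/matrices."""
        n = self.spec.n_sources
        out: dict = {
            k: np.zeros((n, n)) for k in _EXTRINSIC_KINDS
        }
        out["U"] = np.zeros(n)
        out["mod"] = {c: np.zeros((n, n)) for c in self.spec.conditions[1:]}
        out["intr"] = {}
        out["input"] = {}
        out["extra"] = np.zeros(self.spec.n_extra)
        for k, entry in enumerate(self.index):
            v = self.values[k]
            kind = entry[0]
            if kind in _EXTRINSIC_KINDS:
                out[kind][entry[1], entry[2]] = v
            elif kind == "U":
                out["U"][entry[1]] = v
            elif kind == "mod":
                out["mod"][entry[1]][entry[2], entry[3]] = v
            elif kind == "intr":
                out["intr"][(entry[1], entry[2])] = v
            elif kind == "input":
                out["input"][entry[1]] = v
            else:
                out["extra"][entry[1]] = v
        return out

    @classmethod
    def from_structured(cls, spec: ModelSpec, structured: dict) -> "ParameterVector":
        pv = cls(spec)
        for k, entry in enumerate(pv.index):
            kind = entry[0]
            if kind in _EXTRINSIC_KINDS:
                pv.values[k] = structured[kind][entry[1], entry[2]]
            elif kind == "U":
                pv.values[k] = structured["U"][entry[1]]
            elif kind == "mod":
                pv.values[k] = structured["mod"][entry[1]][entry[2], entry[3]]
            elif kind == "intr":
                pv.values[k] = structured["intr"][(entry[1], entry[2])]
            elif kind == "input":
                pv.values[k] = structured["input"][entry[1]]
            else:
                pv.values[k] = structured["extra"][entry[1]]
        return pv


@dataclass(frozen=True)
class StimulusInput:
    """Deterministic stimulus: a Gaussian bump u(t) on the peristimulus axis."""

    onset: float = 60.0      # ms
    width: float = 16.0      # ms (Gaussian sigma)
    amplitude: float = 1.0   # a.u.

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("stimulus width must be nonnegative")

    def sample(self, grid: np.ndarray, theta: "ParameterVector | None" = None) -> np.ndarray:
        """Evaluate u on the grid, applying free onset/width log-scalings."""
        grid = np.asarray(grid, dtype=float)
        onset, width = self.onset, self.width
        if theta is not None:
            if theta.spec.input_free[0]:
                onset = onset * np.exp(theta[("input", "onset")])
            if theta.spec.input_free[1]:
                width = width * np.exp(theta[("input", "width")])
        if width == 0:
            return np.where(grid == onset, self.amplitude, 0.0)
        u = self.amplitude * np.exp(-0.5 * ((grid - onset) / width) ** 2)
        if not np.all(np.isfinite(u)):
            raise ValueError("stimulus input is not finite on the grid")
        return u

    def sample_with_rate(self, grid: np.ndarray, theta: "ParameterVector | None" = None):
        """u and du/dt (per ms) on the grid."""
        grid = np.asarray(grid, dtype=float)
        u = self.sample(grid, theta)
        onset, width = self.onset, self.width
        if theta is not None:
            if theta.spec.input_free[0]:
                onset = onset * np.exp(theta[("input", "onset")])
            if theta.spec.input_free[1]:
                width = width * np.exp(theta[("input", "width")])
        du = np.zeros_like(u) if width == 0 else -(grid - onset) / width**2 * u
        return u, du


class IntegrationDivergedError(RuntimeError):
    """Raised when the state trajectory becomes non-finite."""

    def __init__(self, time_index: int):
        super().__init__(f"state diverged (non-finite) at time index {time_index}")
        self.time_index = time_index


# ---------------------------------------------------------------------------
# firing-rate nonlinearity


def sigmoid(v, params: SourceParameters = SourceParameters()):
    """Centered sigmoid mapping membrane potential (mV) to firing rate (a.u.).

    S(v) = 1/(1+exp(-r(v-eta))) - 1/(1+exp(r*eta)), so S(0) = 0 at rest.
    """
    r, eta = params.r, params.eta
    return expit(r * (np.asarray(v, dtype=float) - eta)) - expit(-r * eta)


def sigmoid_derivative(v, params: SourceParameters = SourceParameters()):
    """dS/dv of the centered sigmoid (1/mV per a.u.)."""
    r, eta = params.r, params.eta
    s = expit(r * (np.asarray(v, dtype=float) - eta))
    return r * s * (1.0 - s)


# ---------------------------------------------------------------------------
# effective connectivity


def effective_connectivity(spec: ModelSpec, theta: ParameterVector, condition: str):
    """Dense coupling matrices C^F, C^B, C^L (n_s x n_s) and C^U (n_s).

    Entry (i, j) is prior_mean * exp(theta) with the condition-specific
    modulation gain exp(theta_mod) applied on modulated connections in
    non-baseline conditions.  Entries outside the masks are exactly zero.
    """
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}; known: {spec.conditions}")
    s = theta.to_structured()
    baseline = spec.conditions[0]
    mod_gain = np.ones((spec.n_sources, spec.n_sources))
    if condition != baseline:
        mod_gain = np.where(spec.M_mask, np.exp(s["mod"][condition]), 1.0)
    out = {}
    for kind in _EXTRINSIC_KINDS:
        mask = getattr(spec, f"{kind}_mask")
        out[kind] = np.where(mask, spec.connection_means[kind] * np.exp(s[kind]) * mod_gain, 0.0)
    out["U"] = np.where(spec.U_mask, spec.connection_means["U"] * np.exp(s["U"]), 0.0)
    return out["F"], out["B"], out["L"], out["U"]


# ---------------------------------------------------------------------------
# compiled per-(theta, condition) arrays used by the derivative and Jacobian


class _Compiled:
    """Dense arrays for fast repeated evaluation of f and J."""

    def __init__(self, spec: ModelSpec, theta: ParameterVector, condition: str):
        n = spec.n_sources
        self.n = n
        self.AF, self.AB, self.AL, self.CU = effective_connectivity(spec, theta, condition)
        self.ABL = self.AB + self.AL
        s = theta.to_structured()
        base = spec.base
        self.He = np.full(n, base.H_e)
        self.Hi = np.full(n, base.H_i)
        self.te = np.full(n, base.tau_e)
        self.ti = np.full(n, base.tau_i)
        for (name, src), v in s["intr"].items():
            arr = {"H_e": self.He, "H_i": self.Hi, "tau_e": self.te, "tau_i": self.ti}[name]
            arr[src] *= np.exp(v)
        # padding parameters: duplicated-prior H_e deviations, cycling sources
        for k in range(spec.n_extra):
            self.He[k % n] *= np.exp(s["extra"][k])
        g = np.asarray(base.gamma)
        self.g1, self.g2, self.g3, self.g4 = (np.full(n, gi) for gi in g)
        self.params = base
        # Lumped synaptic drive constants in per-ms form.  The canonical
        # second-order kinetics x'' = (H/tau)*input - 2x'/tau - x/tau^2 are
        # written with tau in seconds; with time in ms this brings a 1/1000
        # into the drive term, giving the standard DC synaptic gain
        # H * tau[s] (~0.03 mV per unit firing for the excitatory kernel).
        self.ke = self.He / self.te / 1000.0
        self.ki = self.Hi / self.ti / 1000.0
        # cached index arrays and the state-independent part of the Jacobian
        self._idx = {c: np.arange(n) * 9 + c for c in range(9)}
        idx = self._idx
        Jc = np.zeros((9 * n, 9 * n))
        te, ti = self.te, self.ti
        for v_col, i_col in ((_V_STEL, _I_STEL), (_V_PYR_E, _I_PYR_E),
                             (_V_PYR_I, _I_PYR_I), (_V_INH, _I_INH)):
            Jc[idx[v_col], idx[i_col]] = 1.0
        for v_col, i_col, tau in ((_V_STEL, _I_STEL, te), (_V_PYR_E, _I_PYR_E, te),
                                  (_V_INH, _I_INH, te), (_V_PYR_I, _I_PYR_I, ti)):
            Jc[idx[i_col], idx[v_col]] = -1.0 / tau**2
            Jc[idx[i_col], idx[i_col]] = -2.0 / tau
        Jc[idx[_V_PYR], idx[_I_PYR_E]] = 1.0
        Jc[idx[_V_PYR], idx[_I_PYR_I]] = -1.0
        self._Jconst = Jc
        eye = np.eye(n)
        self._W_stel = self.ke[:, None] * (self.AF + self.g1 * eye)
        self._W_pyr = self.ke[:, None] * self.ABL
        self._W_inh = self.ke[:, None] * (self.ABL + self.g3 * eye)
        self._ix = {
            "stel9": np.ix_(idx[_I_STEL], idx[_V_PYR]),
            "pyr9": np.ix_(idx[_I_PYR_E], idx[_V_PYR]),
            "inh9": np.ix_(idx[_I_INH], idx[_V_PYR]),
        }

    def derivative(self, x: np.ndarray, u: float) -> np.ndarray:
        n = self.n
        X = x.reshape(n, 9)
        S9 = sigmoid(X[:, _V_PYR], self.params)
        S0 = sigmoid(X[:, _V_STEL], self.params)
        S6 = sigmoid(X[:, _V_INH], self.params)
        f = np.empty_like(X)
        te, ti, ke, ki = self.te, self.ti, self.ke, self.ki
        f[:, _V_STEL] = X[:, _I_STEL]
        f[:, _I_STEL] = (ke * (self.AF @ S9 + self.g1 * S9 + self.CU * u)
                         - 2.0 * X[:, _I_STEL] / te - X[:, _V_STEL] / te**2)
        f[:, _V_PYR_E] = X[:, _I_PYR_E]
        f[:, _I_PYR_E] = (ke * (self.ABL @ S9 + self.g2 * S0)
                          - 2.0 * X[:, _I_PYR_E] / te - X[:, _V_PYR_E] / te**2)
        f[:, _V_PYR_I] = X[:, _I_PYR_I]
        f[:, _I_PYR_I] = (ki * self.g4 * S6
                          - 2.0 * X[:, _I_PYR_I] / ti - X[:, _V_PYR_I] / ti**2)
        f[:, _V_INH] = X[:, _I_INH]
        f[:, _I_INH] = (ke * (self.ABL @ S9 + self.g3 * S9)
                        - 2.0 * X[:, _I_INH] / te - X[:, _V_INH] / te**2)
        f[:, _V_PYR] = X[:, _I_PYR_E] - X[:, _I_PYR_I]
        return f.ravel()

    def jacobian(self, x: np.ndarray, u: float) -> np.ndarray:
        n = self.n
        X = x.reshape(n, 9)
        d9 = sigmoid_derivative(X[:, _V_PYR], self.params)
        d0 = sigmoid_derivative(X[:, _V_STEL], self.params)
        d6 = sigmoid_derivative(X[:, _V_INH], self.params)
        J = self._Jconst.copy()
        idx = self._idx
        # firing-rate couplings (cross-source through the pyramidal output)
        J[self._ix["stel9"]] = self._W_stel * d9[None, :]
        J[self._ix["pyr9"]] = self._W_pyr * d9[None, :]
        J[idx[_I_PYR_E], idx[_V_STEL]] = self.ke * self.g2 * d0
        J[idx[_I_PYR_I], idx[_V_INH]] = self.ki * self.g4 * d6
        J[self._ix["inh9"]] = self._W_inh * d9[None, :]
        return J


def _check_state(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size != N_STATES_PER_SOURCE * spec.n_sources:
        raise ValueError(
            f"state must have {N_STATES_PER_SOURCE * spec.n_sources} entries, got {x.size}"
        )
    return x


def state_derivative(x, u: float, spec: ModelSpec, theta: ParameterVector,
                     condition: str | None = None) -> np.ndarray:
    """dx/dt (per ms) of the coupled neural-mass network."""
    if condition is None:
        condition = spec.conditions[0]
    return _Compiled(spec, theta, condition).derivative(_check_state(x, spec), u)


def system_jacobian(x, u: float, spec: ModelSpec, theta: ParameterVector,
                    condition: str | None = None) -> np.ndarray:
    """Analytic system Jacobian df/dx (9 n_s x 9 n_s, per ms)."""
    if condition is None:
        condition = spec.conditions[0]
    return _Compiled(spec, theta, condition).jacobian(_check_state(x, spec), u)


def integrate(spec: ModelSpec, theta: ParameterVector, condition: str,
              stim: StimulusInput, grid: np.ndarray,
              x0: np.ndarray | None = None) -> np.ndarray:
    """Integrate the network by local linearization; return the pyramidal
    depolarization of each source on the grid (n_s x n_time, mV).

    The update is the local-linearization step
    x_{k+1} = x_k + (expm(dt J_k) - I) J_k^{-1} f(x_k, u_k) augmented with the
    input-rate term dt^2 phi_2(dt J_k) (df/du) u'(t_k) (exponential
    Rosenbrock-Euler), which keeps second-order accuracy for a time-varying
    stimulus and reduces to the plain update when u is constant.  Both terms
    are evaluated through one augmented matrix exponential, which is exact
    and well defined even where J_k is singular (the explicit J^{-1} form
    with a pseudo-inverse fallback is algebraically identical whenever f is
    in the range of J).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a 1-d array of time points")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    comp = _Compiled(spec, theta, condition)
    n_s = spec.n_sources
    n_states = N_STATES_PER_SOURCE * n_s
    x = np.zeros(n_states) if x0 is None else _check_state(x0, spec).copy()
    u, du = stim.sample_with_rate(grid, theta)
    out = np.empty((n_s, grid.size))
    out[:, 0] = x.reshape(n_s, 9)[:, _V_PYR]
    # x9 never enters any state equation (row 9 of J is row 2 - row 3
    # exactly, so dx9 = dx2 - dx3 holds for the exact update too); advance
    # the nonsingular reduced system and propagate x9 by that identity.
    red = np.array([i * 9 + c for i in range(n_s) for c in range(9) if c != _V_PYR])
    i_v2 = np.arange(n_s) * 8 + _V_PYR_E
    i_v3 = np.arange(n_s) * 8 + _V_PYR_I
    i_pyr = np.arange(n_s) * 9 + _V_PYR
    m = red.size
    dfdu = np.zeros(m)  # input enters the stellate current equations only
    stel = np.arange(n_s) * 8 + _I_STEL
    M = np.zeros((m + 2, m + 2))
    M[m, m + 1] = 1.0
    for k in range(grid.size - 1):
        dt = grid[k + 1] - grid[k]
        f = comp.derivative(x, u[k])[red]
        Jfull = comp.jacobian(x, u[k])
        J = Jfull[np.ix_(red, red)]
        # fold the x9 column into x2/x3 (x9 = x2 - x3 + const along the flow)
        col9 = Jfull[np.ix_(red, i_pyr)]
        J[:, i_v2] += col9
        J[:, i_v3] -= col9
        dfdu[stel] = comp.ke * comp.CU * du[k]
        M[:m, :m] = J
        M[:m, m] = dfdu
        M[:m, m + 1] = f
        dx = expm(dt * M)[:m, m + 1]
        x[red] += dx
        x[i_pyr] += dx[i_v2] - dx[i_v3]
        if not np.all(np.isfinite(x)):
            raise IntegrationDivergedError(k + 1)
        out[:, k + 1] = x.reshape(n_s, 9)[:, _V_PYR]
    return out


# ---------------------------------------------------------------------------
# convenience builders


def two_source_spec(backward: bool = True, lateral: bool = False,
                    conditions: list[str] | None = None,
                    modulate_all: bool = False) -> ModelSpec:
    """A minimal two-source network: forward 0->1, optional backward 1->0.

    Masks follow the (target, source) convention: mask[i, j] couples
    source j's output into target i.
    """
    F = np.zeros((2, 2), dtype=bool)
    F[1, 0] = True
    B = np.zeros((2, 2), dtype=bool)
    if backward:
        B[0, 1] = True
    L = np.zeros((2, 2), dtype=bool)
    if lateral:
        L[0, 1] = L[1, 0] = True
    U = np.array([True, False])
    M = (F | B | L) if modulate_all else None
    return ModelSpec(2, F, B, L, U, M_mask=M,
                     conditions=conditions or ["standard"])


def trajectory_to_tsv(grid: np.ndarray, traj: np.ndarray, path) -> None:
    """Write a source trajectory as TSV: time column + one column per source."""
    import pandas as pd

    df = pd.DataFrame({"time_ms": np.asarray(grid, dtype=float)})
    for i in range(traj.shape[0]):
        df[f"source_{i}"] = traj[i]
    df.to_csv(path, sep="\t", index=False)
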