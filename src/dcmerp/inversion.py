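"""Variational-Laplace EM inversion of the generative model.

The E-step is a Gauss-Newton ascent on the free energy with respect to the
parameters; the M-step is a restricted-maximum-likelihood (ReML) Fisher
scoring update of the noise log-precisions that accounts for posterior
parameter uncertainty through the log-determinant of the posterior
covariance.  Both steps accept a proposal only if it does not decrease the
free energy, so the recorded F trace is non-decreasing by construction.

The free energy is the Laplace bound

    F = -1/2 e' Pi e + 1/2 log|Pi| - 1/2 (t-m)' S0^-1 (t-m)
        + 1/2 log |Sq| / |S0| - (n/2) log 2 pi

with e = y - h(theta), Pi the observation precision, (m, S0) the prior and
Sq the posterior covariance from the Gauss-Newton curvature.  For a linear
generative map and fixed Pi this equals the log marginal likelihood exactly
at the posterior mode.

Everything runs in double precision on a single arithmetic path, so serial
and parallel Jacobian backends yield identical trajectories.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import jacobian as jac_engine
from .neural import ModelSpec, ParameterVector, StimulusInput
from .observation import LeadField, predict_response, stack_response

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "PrecisionModel",
    "PosteriorEstimate",
    "InversionOptions",
    "default_priors",
    "e_step",
    "m_step",
    "free_energy",
    "invert",
    "invert_forward",
]

#: default prior variances of the log-scaling parameters, by class
PRIOR_VARIANCES = {
    "F": 1.0 / 16, "B": 1.0 / 16, "L": 1.0 / 16, "U": 1.0 / 16,
    "mod": 1.0 / 32, "intr": 1.0 / 128, "extra": 1.0 / 128, "input": 1.0 / 16,
}

LAMBDA_CLIP = 32.0


@dataclass
class PriorSpec:
    """Gaussian prior over the free parameters (diagonal by default).

    Zero-variance entries mark frozen parameters, which never move and
    contribute nothing to the free energy.
    """

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean and variance must have the same shape")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be nonnegative")

    @property
    def free(self) -> np.ndarray:
        return self.variance > 0


def default_priors(spec: ModelSpec) -> PriorSpec:
    """Zero-mean log-scaling priors with class-specific shrinkage variances."""
    index = spec.parameter_index()
    var = np.array([PRIOR_VARIANCES[e[0]] for e in index])
    return PriorSpec(mean=np.zeros(len(index)), variance=var)


class PrecisionModel:
    """Observation precision Pi(lambda) = sum_i exp(lambda_i) Q_i.

    Components Q_i are diagonal, stored as nonnegative weight vectors over
    the flattened data; this covers the global-identity and per-channel
    block structures used here while keeping all algebra O(n).
    """

    def __init__(self, components: list[np.ndarray], lam0: np.ndarray | None = None):
        if not components:
            raise ValueError("at least one precision component is required")
        self.components = [np.asarray(q, dtype=float) for q in components]
        n = self.components[0].size
        if any(q.size != n for q in self.components):
            raise ValueError("precision components must have equal length")
        if any((q < 0).any() for q in self.components):
            raise ValueError("precision components must be nonnegative")
        cover = np.sum(self.components, axis=0)
        if np.any(cover <= 0):
            raise ValueError("precision components must cover every data point")
        self.lam0 = np.zeros(len(self.components)) if lam0 is None else np.asarray(lam0, float)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def weights(self, lam: np.ndarray) -> np.ndarray:
        """Diagonal of Pi(lambda)."""
        lam = np.asarray(lam, dtype=float)
        return np.sum([np.exp(l) * q for l, q in zip(lam, self.components)], axis=0)

    @classmethod
    def identity(cls, n: int, lam0: float = 0.0) -> "PrecisionModel":
        return cls([np.ones(n)], np.array([lam0]))

    @classmethod
    def per_channel(cls, n_channels: int, n_time: int, n_conditions: int = 1) -> "PrecisionModel":
        """One component per channel, replicated over conditions and time."""
        comps = []
        for c in range(n_channels):
            q = np.zeros((n_conditions, n_channels, n_time))
            q[:, c, :] = 1.0
            comps.append(q.ravel())
        return cls(comps)


@dataclass
class PosteriorEstimate:
    """Posterior over theta plus the hyperparameters and the F trace."""

    mean: np.ndarray
    covariance: np.ndarray
    lam: np.ndarray
    free_energy: list[float]
    iterations: int
    converged: bool
    free_mask: np.ndarray
    timings: dict = field(default_factory=dict)

    @property
    def final_free_energy(self) -> float:
        return self.free_energy[-1]


@dataclass
class InversionOptions:
    backend: str = "serial"            # serial | pool
    strategy: str = "blockX"           # task arrangement for the pool backend
    workers: int | None = None
    fd_step: float = jac_engine.DEFAULT_FD_STEP
    tolerance: float = 0.01            # dF threshold of the convergence rule
    max_iterations: int = 128
    max_halvings: int = 8
    m_step_iterations: int = 4
    update_hyperparameters: bool = True


# ---------------------------------------------------------------------------
# free energy


def _posterior_precision(J: np.ndarray, w: np.ndarray, priors: PriorSpec,
                         ridge_logger=logger):
    """Gauss-Newton curvature P = J' Pi J + S0^-1 on the free subspace."""
    free = priors.free
    Jf = J[:, free]
    P = Jf.T @ (w[:, None] * Jf) + np.diag(1.0 / priors.variance[free])
    sign, logdet = np.linalg.slogdet(P)
    if sign <= 0 or not np.isfinite(logdet):
        ridge = 1e-8 * np.trace(P) / P.shape[0]
        ridge_logger.info("singular curvature; adding ridge %.3e", ridge)
        P = P + ridge * np.eye(P.shape[0])
        sign, logdet = np.linalg.slogdet(P)
    return P, logdet


def free_energy(y: np.ndarray, h: np.ndarray, theta: np.ndarray, lam: np.ndarray,
                priors: PriorSpec, precision: PrecisionModel, J: np.ndarray) -> float:
    """Variational-Laplace bound on the log evidence (nats)."""
    e = y - h
    w = precision.weights(lam)
    free = priors.free
    d = theta[free] - priors.mean[free]
    _, logdet_P = _posterior_precision(J, w, priors)
    n = y.size
    F = (-0.5 * np.sum(w * e * e)
         + 0.5 * np.sum(np.log(w))
         - 0.5 * np.sum(d * d / priors.variance[free])
         - 0.5 * logdet_P - 0.5 * np.sum(np.log(priors.variance[free]))
         - 0.5 * n * np.log(2.0 * np.pi))
    if not np.isfinite(F):
        raise FloatingPointError(
            f"free energy is not finite (fit {np.sum(w * e * e):.3g}, "
            f"logdetP {logdet_P:.3g}, lam {lam})"
        )
    return float(F)


# note: log|Sq|/|S0| = -log|P| - sum log(prior variance); the two log-variance
# terms above combine the prior normalizer and the Occam factor.


# ---------------------------------------------------------------------------
# E- and M-steps


def e_step(y: np.ndarray, theta: np.ndarray, lam: np.ndarray, priors: PriorSpec,
           J: np.ndarray, precision: PrecisionModel, predict=None, h=None,
           max_halvings: int = 8):
    """Gauss-Newton proposal for theta with Levenberg-style step halving.

    Returns (theta', h(theta'), F(theta'), halvings).  When ``predict`` is
    None the full step is returned unchecked (the linear-model path).
    """
    if h is None:
        if predict is None:
            raise ValueError("either h or predict must be supplied")
        h = predict(theta)
    e = y - h
    w = precision.weights(lam)
    free = priors.free
    Jf = J[:, free]
    P, _ = _posterior_precision(J, w, priors)
    g = Jf.T @ (w * e) + (priors.mean[free] - theta[free]) / priors.variance[free]
    delta = np.linalg.solve(P, g)
    full = np.zeros_like(theta)
    full[free] = delta
    if predict is None:
        return theta + full, None, None, 0
    F0 = free_energy(y, h, theta, lam, priors, precision, J)
    scale, halvings = 1.0, 0
    while True:
        cand = theta + scale * full
        try:
            h_c = predict(cand)
            F_c = free_energy(y, h_c, cand, lam, priors, precision, J)
        except Exception:  # divergence at the proposal: treat as a rejected step
            F_c = -np.inf
        if F_c >= F0:
            return cand, h_c, F_c, halvings
        if halvings >= max_halvings:
            return theta, h, F0, halvings
        scale /= 2.0
        halvings += 1


def m_step(residuals: np.ndarray, J: np.ndarray, lam: np.ndarray,
           precision: PrecisionModel, priors: PriorSpec,
           n_inner: int = 4, y: np.ndarray | None = None,
           h: np.ndarray | None = None, theta: np.ndarray | None = None):
    """ReML Fisher-scoring update of the noise log-precisions.

    The gradient accounts for posterior parameter uncertainty via
    tr(Sq J' Q_i J).  Each inner step is accepted only if it does not
    decrease F (evaluated when y/h/theta are supplied); lambda is clipped
    to +/- 32.  A non-finite gradient leaves lambda unchanged.
    """
    e = np.asarray(residuals, dtype=float)
    lam = np.asarray(lam, dtype=float).copy()
    free = priors.free
    Jf = J[:, free]
    track_F = y is not None and h is not None and theta is not None
    F_prev = (free_energy(y, h, theta, lam, priors, precision, J)
              if track_F else None)
    for _ in range(n_inner):
        w = precision.weights(lam)
        P, _ = _posterior_precision(J, w, priors)
        Sq = np.linalg.inv(P)
        # rows of J Sq J' needed only on the diagonal
        diag_JSJ = np.einsum("ij,jk,ik->i", Jf, Sq, Jf)
        g = np.empty(precision.n_components)
        I = np.empty((precision.n_components, precision.n_components))
        for i, qi in enumerate(precision.components):
            g[i] = 0.5 * np.exp(lam[i]) * (
                np.sum(qi / w) - np.sum(qi * e * e) - np.sum(qi * diag_JSJ)
            )
        for i, qi in enumerate(precision.components):
            for j, qj in enumerate(precision.components):
                I[i, j] = 0.5 * np.exp(lam[i] + lam[j]) * np.sum(qi * qj / (w * w))
        if not np.all(np.isfinite(g)):
            logger.warning("non-finite ReML gradient; leaving lambda unchanged")
            return lam
        try:
            step = np.linalg.solve(I, g)
        except np.linalg.LinAlgError:
            step = g / np.maximum(np.diag(I), 1e-12)
        accepted = False
        scale = 1.0
        for _ in range(8):
            cand = np.clip(lam + scale * step, -LAMBDA_CLIP, LAMBDA_CLIP)
            if track_F:
                try:
                    F_c = free_energy(y, h, theta, cand, priors, precision, J)
                except FloatingPointError:
                    F_c = -np.inf
                if F_c >= F_prev:
                    lam, F_prev, accepted = cand, F_c, True
                    break
                scale /= 2.0
            else:
                lam, accepted = cand, True
                break
        if not accepted:
            break
    return lam


# ---------------------------------------------------------------------------
# full EM loops


def invert_forward(y: np.ndarray, predict, jacobian, priors: PriorSpec,
                   precision: PrecisionModel | None = None,
                   options: InversionOptions | None = None) -> PosteriorEstimate:
    """EM inversion of an arbitrary forward map.

    ``predict(theta) -> flat response``; ``jacobian(theta, base) ->
    ResponseJacobian``.  The ERP-specific :func:`invert` wraps this with the
    neural/observation forward model and the task-parallel engine.
    """
    y = np.asarray(y, dtype=float).ravel()
    if precision is None:
        precision = PrecisionModel.identity(y.size)
    if options is None:
        options = InversionOptions()
    theta = priors.mean.copy()
    lam = precision.lam0.copy()
    h = predict(theta)
    t_jac = t_step = 0.0
    slow = 0
    F_trace: list[float] = []
    converged = False
    it = 0
    J = None
    for it in range(1, options.max_iterations + 1):
        t0 = time.perf_counter()
        rj = jacobian(theta, h)
        if rj.failed:
            if len(rj.failed) > 0.5 * rj.n_params:
                raise RuntimeError(
                    f"EM aborted: {len(rj.failed)}/{rj.n_params} Jacobian tasks "
                    f"diverged (parameters {rj.failed[:8]}...)"
                )
            logger.warning("%d Jacobian tasks diverged; columns zeroed", len(rj.failed))
        J = rj.matrix
        t_jac += time.perf_counter() - t0
        t0 = time.perf_counter()
        if not F_trace:
            F_trace.append(free_energy(y, h, theta, lam, priors, precision, J))
        cand_theta, cand_h, _, halvings = e_step(
            y, theta, lam, priors, J, precision, predict=predict, h=h,
            max_halvings=options.max_halvings,
        )
        cand_lam = lam
        if options.update_hyperparameters:
            cand_lam = m_step(y - cand_h, J, lam, precision, priors,
                              n_inner=options.m_step_iterations,
                              y=y, h=cand_h, theta=cand_theta)
        F = free_energy(y, cand_h, cand_theta, cand_lam, priors, precision, J)
        t_step += time.perf_counter() - t0
        dF = F - F_trace[-1]
        # accept only if the bound did not decrease (J recomputation can
        # lower the Occam term slightly near convergence; such iterations
        # are reverted, keeping the recorded trace non-decreasing)
        if dF >= 0:
            theta, h, lam = cand_theta, cand_h, cand_lam
            F_trace.append(F)
        else:
            F_trace.append(F_trace[-1])
            dF = 0.0
        logger.info("EM %02d: F=%.4f dF=%.5f halvings=%d lam=%s",
                    it, F_trace[-1], dF, halvings, np.round(lam, 3))
        slow = slow + 1 if dF < options.tolerance else 0
        if slow >= 2:
            converged = True
            break
    w = precision.weights(lam)
    P, _ = _posterior_precision(J, w, priors)
    free = priors.free
    cov = np.zeros((theta.size, theta.size))
    cov[np.ix_(free, free)] = np.linalg.inv(P)
    return PosteriorEstimate(
        mean=theta, covariance=cov, lam=lam, free_energy=F_trace,
        iterations=it, converged=converged, free_mask=free,
        timings={"jacobian_s": t_jac, "update_s": t_step},
    )


def invert(dataset, spec: ModelSpec, leadfield: LeadField,
           priors: PriorSpec | None = None, stim: StimulusInput | None = None,
           precision: PrecisionModel | None = None,
           options: InversionOptions | None = None) -> PosteriorEstimate:
    """Invert an ERP dataset under a model architecture.

    ``dataset`` provides ``y`` (dict condition -> channels x time), ``grid``
    (ms) and ``conditions``; see :class:`dcmerp.simulate.ERPDataset`.
    """
    if priors is None:
        priors = default_priors(spec)
    if stim is None:
        stim = StimulusInput()
    if options is None:
        options = InversionOptions()
    conditions = list(dataset.conditions)
    y = np.concatenate([np.asarray(dataset.y[c], dtype=float).ravel() for c in conditions])
    grid = np.asarray(dataset.grid, dtype=float)

    def predict(values: np.ndarray) -> np.ndarray:
        theta = ParameterVector(spec, values)
        return stack_response(
            predict_response(spec, theta, leadfield, stim, grid, conditions), conditions
        )

    frozen = ~priors.free

    def jacobian(values: np.ndarray, base: np.ndarray):
        theta = ParameterVector(spec, values)
        kwargs = dict(step=options.fd_step, frozen=frozen, base=base,
                      conditions=conditions, on_error="collect")
        if options.backend == "pool":
            return jac_engine.response_jacobian_parallel(
                spec, theta, leadfield, stim, grid, strategy=options.strategy,
                workers=options.workers, **kwargs)
        return jac_engine.response_jacobian_serial(
            spec, theta, leadfield, stim, grid, **kwargs)

    return invert_forward(y, predict, jacobian, priors, precision, options)
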