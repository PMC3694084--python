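"""Finite-difference response Jacobian dh/dtheta, serial or on a worker pool.

Each column of the response Jacobian requires one re-integration of the
neuronal model at a perturbed parameter value; the columns are mutually
independent, so the N integrations form an embarrassingly parallel task set.
The task -> worker mapping is delegated to :mod:`dcmerp.scheduler`; every
task performs the same arithmetic regardless of placement, so parallel and
serial results agree to machine precision.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import scheduler
from .neural import ModelSpec, ParameterVector, StimulusInput
from .observation import LeadField, predict_response, stack_response

logger = logging.getLogger(__name__)

__all__ = [
    "JacobianTask",
    "ResponseJacobian",
    "JacobianTaskError",
    "make_tasks",
    "response_jacobian_serial",
    "response_jacobian_parallel",
    "fd_jacobian",
]

DEFAULT_FD_STEP = 1e-4


@dataclass(frozen=True)
class JacobianTask:
    """One perturbed-parameter integration task."""

    task_id: int
    param_index: int
    step: float
    theta: np.ndarray  # full perturbed parameter vector


@dataclass
class ResponseJacobian:
    """dh/dtheta: flattened (condition, channel, time) rows x N columns."""

    matrix: np.ndarray
    steps: np.ndarray
    failed: list[int] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]


class JacobianTaskError(RuntimeError):
    """Integration failed at a perturbed parameter point."""

    def __init__(self, param_index: int, cause: Exception):
        super().__init__(f"integration diverged for parameter {param_index}: {cause}")
        self.param_index = param_index


def make_tasks(theta: ParameterVector, step=DEFAULT_FD_STEP) -> list[JacobianTask]:
    """One forward-difference task per free parameter (ids 0..N-1).

    ``step`` is a scalar or a callable mapping parameter index -> step size;
    parameters are log-scalings, so a fixed absolute step is appropriate.
    """
    n = len(theta)
    if n == 0:
        raise ValueError("parameter vector has no free parameters (N = 0)")
    step_of = step if callable(step) else (lambda i: step)
    tasks = []
    for i in range(n):
        v = theta.values.copy()
        v[i] += step_of(i)
        tasks.append(JacobianTask(task_id=i, param_index=i, step=step_of(i), theta=v))
    return tasks


def _erp_predict(spec: ModelSpec, leadfield: LeadField, stim: StimulusInput,
                 grid: np.ndarray, conditions: list[str]):
    def predict(values: np.ndarray) -> np.ndarray:
        theta = ParameterVector(spec, values)
        return stack_response(
            predict_response(spec, theta, leadfield, stim, grid, conditions), conditions
        )
    return predict


def fd_jacobian(predict, theta: ParameterVector, step=DEFAULT_FD_STEP,
                frozen: np.ndarray | None = None, base: np.ndarray | None = None,
                executor: ThreadPoolExecutor | None = None,
                task_order: list[int] | None = None,
                on_error: str = "raise") -> ResponseJacobian:
    """One-sided forward-difference Jacobian of an arbitrary response map.

    ``frozen`` marks parameters whose column is fixed to zero (no task is
    run for them).  The base response h(theta) is computed once and shared
    by every task.  ``task_order`` only changes execution order; the
    assembled matrix is ordered by parameter index regardless.
    """
    tasks = make_tasks(theta, step)
    if frozen is None:
        frozen = np.zeros(len(theta), dtype=bool)
    if base is None:
        base = predict(theta.values)
    base = np.asarray(base, dtype=float)
    J = np.zeros((base.size, len(tasks)))
    failed: list[int] = []

    def run(task: JacobianTask):
        try:
            return (predict(task.theta) - base) / task.step
        except Exception as exc:  # noqa: BLE001 - divergence surfaces per-task
            if on_error == "raise":
                raise JacobianTaskError(task.param_index, exc) from exc
            return exc

    live = [t for t in tasks if not frozen[t.param_index]]
    if task_order is not None:
        order = {tid: k for k, tid in enumerate(task_order)}
        live = sorted(live, key=lambda t: order[t.task_id])
    if executor is None:
        results = [(t, run(t)) for t in live]
    else:
        results = list(zip(live, executor.map(run, live)))
    for task, col in results:
        if isinstance(col, Exception):
            failed.append(task.param_index)
        else:
            J[:, task.param_index] = col
    steps = np.array([t.step for t in tasks])
    return ResponseJacobian(matrix=J, steps=steps, failed=sorted(failed))


def response_jacobian_serial(spec: ModelSpec, theta: ParameterVector,
                             leadfield: LeadField, stim: StimulusInput,
                             grid: np.ndarray, conditions: list[str] | None = None,
                             step=DEFAULT_FD_STEP, frozen: np.ndarray | None = None,
                             base: np.ndarray | None = None,
                             on_error: str = "raise") -> ResponseJacobian:
    """Reference serial computation of dh/dtheta."""
    conditions = list(conditions) if conditions is not None else list(spec.conditions)
    predict = _erp_predict(spec, leadfield, stim, grid, conditions)
    return fd_jacobian(predict, theta, step=step, frozen=frozen, base=base,
                       on_error=on_error)


def response_jacobian_parallel(spec: ModelSpec, theta: ParameterVector,
                               leadfield: LeadField, stim: StimulusInput,
                               grid: np.ndarray, conditions: list[str] | None = None,
                               step=DEFAULT_FD_STEP, frozen: np.ndarray | None = None,
                               base: np.ndarray | None = None,
                               strategy: str = "blockX",
                               descriptor: scheduler.FabricDescriptor | None = None,
                               workers: int | None = None,
                               on_error: str = "raise") -> ResponseJacobian:
    """dh/dtheta on a thread-pool fabric under a task-arrangement strategy.

    The arrangement decides the dispatch order (blocks in index order, tasks
    within a block in their round-robin/sequential order); each task's
    arithmetic is identical to the serial path, so the result matches
    :func:`response_jacobian_serial` to within the accumulation of identical
    floating-point operations (exactly, in practice).  Backend failure falls
    back to the serial path with a logged warning.
    """
    conditions = list(conditions) if conditions is not None else list(spec.conditions)
    predict = _erp_predict(spec, leadfield, stim, grid, conditions)
    if descriptor is None:
        descriptor = scheduler.FabricDescriptor()
    assignment = scheduler.assign(len(theta), strategy, descriptor)
    task_order = [tid for block in assignment.blocks for tid in block]
    try:
        with ThreadPoolExecutor(max_workers=workers) as executor:
            return fd_jacobian(predict, theta, step=step, frozen=frozen, base=base,
                               executor=executor, task_order=task_order,
                               on_error=on_error)
    except JacobianTaskError:
        raise
    except Exception:
        logger.warning("parallel backend failed; falling back to serial", exc_info=True)
        return fd_jacobian(predict, theta, step=step, frozen=frozen, base=base,
                           task_order=task_order, on_error=on_error)
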