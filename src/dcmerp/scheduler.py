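"""Task-arrangement strategies for a block/warp execution fabric.

Models how independent integration tasks are laid out on a GPU-like fabric
(thread blocks scheduled on streaming multiprocessors, warps executing in
lockstep within a block) and scores arrangements with a deterministic
makespan cost model.  Three arrangements are implemented:

* ``thread`` (thread-first): fill a block to capacity before opening the next;
* ``block`` (block-first): one task per block, first thread only;
* ``blockX``: round-robin tasks over exactly X blocks, where X is the
  fabric's concurrent-block limit, spilling to a fresh set of X blocks once
  all are full.

X equals (number of SMs) x (resident-block limit per SM) and can also be
detected empirically from the step pattern of the cost curve.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FabricDescriptor",
    "TaskAssignment",
    "CostReport",
    "STRATEGIES",
    "resident_block_limit",
    "concurrency_limit",
    "assign",
    "makespan",
    "detect_concurrency_limit",
    "schedule_table",
]

STRATEGIES = ("thread", "block", "blockX")

#: resident thread blocks per streaming multiprocessor, by capability class
_RESIDENT_LIMITS = {"1.x": 8, "2.x": 8, "3.x": 16}


def resident_block_limit(capability_class: str) -> int:
    """Maximum resident thread blocks per SM for a compute-capability class."""
    try:
        return _RESIDENT_LIMITS[capability_class]
    except KeyError:
        raise ValueError(
            f"unknown capability class {capability_class!r}; known: {sorted(_RESIDENT_LIMITS)}"
        ) from None


@dataclass(frozen=True)
class FabricDescriptor:
    """Abstract execution fabric.

    The concurrency limit X = n_sm * per_sm_resident_limit is the number of
    blocks that can run simultaneously.  The default mirrors an 8-SM device
    of capability class 2.x (X = 64) with 1024-thread blocks and 32-wide
    warps.
    """

    n_sm: int = 8
    per_sm_resident_limit: int = 8
    block_capacity: int = 1024
    warp_width: int = 32

    def __post_init__(self) -> None:
        for name in ("n_sm", "per_sm_resident_limit", "block_capacity", "warp_width"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @classmethod
    def from_capability(cls, n_sm: int, capability_class: str,
                        block_capacity: int = 1024, warp_width: int = 32) -> "FabricDescriptor":
        return cls(n_sm, resident_block_limit(capability_class), block_capacity, warp_width)

    @property
    def concurrency_limit(self) -> int:
        return self.n_sm * self.per_sm_resident_limit


def concurrency_limit(descriptor: FabricDescriptor) -> int:
    """X: maximum number of simultaneously resident blocks on the fabric."""
    return descriptor.concurrency_limit


@dataclass
class TaskAssignment:
    """An ordered layout of task ids into thread blocks."""

    strategy: str
    blocks: list[list[int]]
    block_capacity: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for b, block in enumerate(self.blocks):
            if not block:
                raise ValueError(f"block {b} is empty")
            if len(block) > self.block_capacity:
                raise ValueError(f"block {b} exceeds capacity {self.block_capacity}")
            seen.update(block)
        n = sum(len(b) for b in self.blocks)
        if len(seen) != n:
            raise ValueError("task ids are not unique across blocks")

    @property
    def n_tasks(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def block_sizes(self) -> list[int]:
        return [len(b) for b in self.blocks]


@dataclass
class CostReport:
    """Deterministic cost of executing an assignment, in abstract time units."""

    makespan: int
    wave_count: int
    wave_durations: list[int] = field(default_factory=list)


def assign(n_tasks: int, strategy: str, descriptor: FabricDescriptor | None = None) -> TaskAssignment:
    """Lay out task ids 0..n_tasks-1 into thread blocks.

    ``thread``: fill blocks of ``block_capacity`` sequentially.
    ``block``: one task per block.
    ``blockX``: round-robin (strided single-task passes) over X blocks; when
    all X blocks are full, open another set of X blocks for the remainder.
    Empty blocks are never emitted, so blockX yields min(n, X) blocks per set.
    """
    if descriptor is None:
        descriptor = FabricDescriptor()
    if n_tasks < 1:
        raise ValueError("n_tasks must be >= 1")
    cap = descriptor.block_capacity
    if strategy == "thread":
        blocks = [list(range(k, min(k + cap, n_tasks))) for k in range(0, n_tasks, cap)]
    elif strategy == "block":
        blocks = [[i] for i in range(n_tasks)]
    elif strategy == "blockX":
        X = descriptor.concurrency_limit
        blocks = []
        start = 0
        while start < n_tasks:
            m = min(n_tasks - start, X * cap)
            nb = min(m, X)
            blocks.extend(list(range(start + b, start + m, nb)) for b in range(nb))
            start += m
    else:
        raise ValueError(f"unknown strategy {strategy!r}; known: {STRATEGIES}")
    return TaskAssignment(strategy, blocks, cap)


def makespan(assignment: TaskAssignment, descriptor: FabricDescriptor | None = None) -> CostReport:
    """Score an assignment with the wave/warp cost model.

    Blocks launch in index order in waves of at most X concurrent blocks; a
    block's duration is ceil(size / warp_width) (its warps serialize); a
    wave lasts as long as its slowest block; the makespan is the sum of wave
    durations.  This reproduces the step pattern of the cost curve as the
    block count crosses multiples of X.
    """
    if descriptor is None:
        descriptor = FabricDescriptor()
    X = descriptor.concurrency_limit
    w = descriptor.warp_width
    sizes = assignment.block_sizes
    durations = [
        max(math.ceil(s / w) for s in sizes[k:k + X]) for k in range(0, len(sizes), X)
    ]
    return CostReport(makespan=sum(durations), wave_count=len(durations),
                      wave_durations=durations)


def _probe_cost(n_blocks: int, descriptor: FabricDescriptor) -> int:
    """Cost of a probe workload of single-task blocks (the detection program)."""
    sizes = [1] * n_blocks
    X = descriptor.concurrency_limit
    return sum(1 for _ in range(0, len(sizes), X))


def detect_concurrency_limit(probe_mode: str, candidates, seed: int = 0,
                             descriptor: FabricDescriptor | None = None) -> int:
    """Detect X from the first step-up of the probe cost curve.

    ``simulated`` mode runs the makespan model against ``descriptor`` (the
    fabric under probe) using only its cost outputs; the detected value
    equals the fabric's true X whenever the candidate list brackets the
    step.  ``wallclock`` mode times a small benchmark on the host per
    candidate and returns the plateau edge; the result is hardware-dependent.
    If no step is detected, the largest candidate is returned with a warning.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    if probe_mode == "simulated":
        if descriptor is None:
            descriptor = FabricDescriptor()
        costs = [_probe_cost(c, descriptor) for c in candidates]
    elif probe_mode == "wallclock":
        costs = [_wallclock_probe(c, seed) for c in candidates]
    else:
        raise ValueError(f"unknown probe mode {probe_mode!r}")
    baseline = costs[0]
    threshold = baseline * 1.5 if probe_mode == "wallclock" else baseline
    for prev, (c, cost) in zip(candidates, list(zip(candidates, costs))[1:]):
        if cost > threshold:
            return prev
    logger.warning("no cost step detected up to %d; returning largest candidate",
                   candidates[-1])
    return candidates[-1]


def _wallclock_probe(n_blocks: int, seed: int) -> float:
    """Best-effort host timing of n_blocks small workloads (not deterministic)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(256)
    t0 = time.perf_counter()
    for _ in range(n_blocks):
        np.log1p(np.abs(a)).sum()
    return time.perf_counter() - t0


def schedule_table(task_counts, strategies=STRATEGIES,
                   descriptor: FabricDescriptor | None = None):
    """Tabulate (n_tasks, strategy, blocks, makespan) over a sweep.

    Returns a pandas DataFrame; the CLI writes it as TSV.
    """
    import pandas as pd

    if descriptor is None:
        descriptor = FabricDescriptor()
    rows = []
    for n in task_counts:
        for s in strategies:
            a = assign(int(n), s, descriptor)
            c = makespan(a, descriptor)
            rows.append({"n_tasks": int(n), "strategy": s,
                         "blocks": len(a.blocks), "makespan": c.makespan,
                         "waves": c.wave_count})
    return pd.DataFrame(rows)
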