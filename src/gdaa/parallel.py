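"""Two-tier parallel execution: permutation workers × gene-block lanes.

Coarse grain: whole permutations are dispatched dynamically (pull-based) to
worker processes — an idle worker receives exactly one not-yet-assigned
permutation at a time, so heterogeneous per-permutation cost balances
automatically. Fine grain: within a worker the m genes are split into P
contiguous blocks, one per lane (thread); lanes read one shared copy of the
permuted expression matrix and the moment arrays and write disjoint slices
of the output vector.

Results are keyed by permutation index, never by arrival order, and workers
draw no random numbers, so the null matrix is a pure function of
(data, plan, G) — identical for every executor configuration.
"""

from __future__ import annotations

import hashlib
import os
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, wait
from dataclasses import dataclass

import numpy as np

from .correlation import GroupData
from .io import ConfigError, GdaaError


@dataclass(frozen=True)
class ExecutorConfig:
    """Parallel layout: worker processes × lanes per worker.

    ``max_in_flight`` caps simultaneously dispatched permutations (default:
    one per worker, the pull granularity). ``pin_cpus`` is an optional
    affinity hint, off by default; it is an OS tuning knob, never part of
    correctness — results are invariant to every valid configuration.
    """

    n_workers: int = 1
    threads_per_worker: int = 1
    max_in_flight: int | None = None
    pin_cpus: bool = False

    def __post_init__(self) -> None:
        if self.n_workers < 1 or self.threads_per_worker < 1:
            raise ConfigError("workers and lanes must both be >= 1")
        if self.max_in_flight is not None and self.max_in_flight < 1:
            raise ConfigError("max_in_flight must be >= 1 when given")


def gene_block_split(m: int, P: int) -> list[range]:
    """Split gene indices 0..m-1 into P contiguous ranges, sizes within 1."""
    if P < 1:
        raise ConfigError(f"lane count P={P} must be >= 1")
    if P > m:
        raise ConfigError(f"cannot split m={m} genes across P={P} lanes")
    base, extra = divmod(m, P)
    blocks: list[range] = []
    start = 0
    for j in range(P):
        size = base + (1 if j < extra else 0)
        blocks.append(range(start, start + size))
        start += size
    return blocks


# --- worker-process plumbing -------------------------------------------------
# The work function is shipped once per worker via the pool initializer, so
# per-task messages carry only the permutation index.

_WORKER_STATE: dict = {}


def _worker_init(work_fn, lanes: int, pin: bool) -> None:
    _WORKER_STATE["fn"] = work_fn
    _WORKER_STATE["lanes"] = lanes
    if pin:
        try:
            ncpu = os.cpu_count() or 1
            os.sched_setaffinity(0, {os.getpid() % ncpu})
        except (AttributeError, OSError):  # best-effort hint only
            pass


def _worker_run(k: int):
    return k, _WORKER_STATE["fn"](k, _WORKER_STATE["lanes"])


def dispatch(plan, work_fn, config: ExecutorConfig | None = None) -> np.ndarray:
    """Run ``work_fn(k, lanes)`` for every permutation index k of ``plan``.

    Returns the K × m matrix whose row k is the work function's output for
    permutation k. With one worker the loop runs in-process (lanes still
    apply inside ``work_fn``); otherwise a process pool pulls indices from a
    bounded window. A worker failure aborts the run, reporting the failing
    and unfinished permutation indices; a duplicate completion is an
    internal error.
    """
    if config is None:
        config = ExecutorConfig()
    K = plan.K
    if K == 0:
        raise ConfigError("permutation plan is empty")
    lanes = config.threads_per_worker

    if config.n_workers == 1:
        rows = [np.asarray(work_fn(k, lanes), dtype=np.float64) for k in range(K)]
        return np.stack(rows)

    rows_by_k: list[np.ndarray | None] = [None] * K
    window = min(K, config.max_in_flight or config.n_workers)
    with ProcessPoolExecutor(
        max_workers=config.n_workers,
        initializer=_worker_init,
        initargs=(work_fn, lanes, config.pin_cpus),
    ) as pool:
        next_k = 0
        pending = set()
        while next_k < min(window, K):
            pending.add(pool.submit(_worker_run, next_k))
            next_k += 1
        while pending:
            done, pending = wait(pending, return_when=FIRST_COMPLETED)
            for fut in done:
                exc = fut.exception()
                if exc is not None:
                    unfinished = [k for k, r in enumerate(rows_by_k) if r is None]
                    raise GdaaError(
                        f"worker failed ({exc!r}); unfinished permutations: "
                        f"{unfinished[:10]}{'...' if len(unfinished) > 10 else ''}"
                    ) from exc
                k, row = fut.result()
                if rows_by_k[k] is not None:
                    raise GdaaError(f"internal error: duplicate completion for permutation {k}")
                rows_by_k[k] = np.asarray(row, dtype=np.float64)
                if next_k < K:
                    pending.add(pool.submit(_worker_run, next_k))
                    next_k += 1
    missing = [k for k, r in enumerate(rows_by_k) if r is None]
    if missing:
        raise GdaaError(f"internal error: permutations never completed: {missing}")
    return np.stack(rows_by_k)


def shared_checksum(group: GroupData) -> str:
    """Digest of a group's shared arrays, for read-only contract assertions."""
    h = hashlib.sha256()
    for arr in group.cols + group.centered + (group.sums, group.sums_sq, group.var):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()
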