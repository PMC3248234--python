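"""Permutation plan, null distribution, p-values, and the end-to-end driver.

The null hypothesis for gene i is that its correlation vector has the same
joint distribution under both conditions. The null distribution of the
N-statistic is approximated by pooling the 2n subjects, shuffling, splitting
into two equal halves, and recomputing the whole subgroup/correlation/
N-statistic pipeline — K times. The permutation p-value is the fraction of
null statistics at least as large as the observed one (ties count as
exceedances), so p-values live on the grid {0, 1/K, ..., 1} and p = 0 is
possible (no +1 smoothing). The extended Bonferroni adjustment p̃ = p·m
controls the per-family error rate — an expected count of false positives —
and is deliberately not capped at 1.

All K permutations are drawn centrally from one seeded PCG64 generator and
shipped to workers as index vectors; workers never draw random numbers,
which together with index-keyed result collection makes the serialized
result a pure function of (inputs, G, K, seed).
"""

from __future__ import annotations

import functools
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .correlation import partition_subgroups, prepare_group
from .io import ConfigError, ExpressionMatrix, GdaaResult
from .nstat import nstat_block
from .parallel import ExecutorConfig, dispatch, gene_block_split


@dataclass(frozen=True)
class PermutationPlan:
    """K seeded permutations of the pooled subject indices 0..2n-1."""

    seed: int
    n_total: int
    permutations: np.ndarray  # K × n_total, each row a bijection

    @property
    def K(self) -> int:
        return self.permutations.shape[0]


def make_permutation_plan(n_total: int, K: int, seed: int) -> PermutationPlan:
    """Draw K uniform permutations of 0..n_total-1 from PCG64(seed).

    ``n_total`` is the pooled subject count and must be even (the null split
    is into two equal halves) and at least 8 (two subgroups of two per
    half). Deterministic given (n_total, K, seed).
    """
    if n_total % 2 != 0:
        raise ConfigError("pooled sample count must be even for an equal split")
    if n_total < 8:
        raise ConfigError("need at least 4 samples per condition")
    if K < 1:
        raise ConfigError("permutation count K must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_total) for _ in range(K)])
    return PermutationPlan(seed, n_total, perms)


@dataclass(frozen=True)
class NullDistribution:
    """K × m matrix of permutation N-statistics (row k = permutation k)."""

    stats: np.ndarray

    def __post_init__(self) -> None:
        stats = np.asarray(self.stats, dtype=np.float64)
        object.__setattr__(self, "stats", stats)
        if stats.ndim != 2:
            raise ConfigError("null distribution must be a K × m matrix")
        if not np.isfinite(stats).all():
            raise ConfigError("non-finite permutation statistic")
        if np.any(stats < -1e-9):
            raise ConfigError("negative permutation statistic beyond roundoff")

    @property
    def K(self) -> int:
        return self.stats.shape[0]

    @property
    def m(self) -> int:
        return self.stats.shape[1]


def _check_perm(perm: np.ndarray, n_total: int) -> np.ndarray:
    perm = np.asarray(perm)
    if perm.shape != (n_total,) or not np.array_equal(np.sort(perm), np.arange(n_total)):
        raise ValueError("permutation vector is not a bijection on the pooled samples")
    return perm


def split_permuted(pooled: ExpressionMatrix, perm) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split the pooled matrix into two equal pseudo-conditions.

    Group A′ receives columns perm[0..n-1] and B′ columns perm[n..2n-1], in
    permuted order.
    """
    perm = _check_perm(perm, pooled.n)
    n = pooled.n // 2
    ids = np.asarray(pooled.sample_ids, dtype=object)
    a = ExpressionMatrix(pooled.gene_ids, list(ids[perm[:n]]), pooled.values[:, perm[:n]])
    b = ExpressionMatrix(pooled.gene_ids, list(ids[perm[n:]]), pooled.values[:, perm[n:]])
    return a, b


def _group_nstats(values_a: np.ndarray, values_b: np.ndarray, G: int,
                  lanes: int = 1, strict: bool = False) -> np.ndarray:
    """N-statistic vector for two equal-size groups (the fine-grain stage)."""
    n = values_a.shape[1]
    part = partition_subgroups(n, G)
    group_a = prepare_group(values_a, part, strict=strict)
    group_b = prepare_group(values_b, part, strict=strict)
    m = values_a.shape[0]
    out = np.empty(m, dtype=np.float64)
    if lanes == 1:
        nstat_block(group_a, group_b, range(m), out)
    else:
        blocks = gene_block_split(m, lanes)
        with ThreadPoolExecutor(max_workers=lanes) as ex:
            futs = [ex.submit(nstat_block, group_a, group_b, blk, out) for blk in blocks]
            for f in futs:
                f.result()
    return out


def _permutation_worker(k: int, lanes: int, *, values: np.ndarray,
                        permutations: np.ndarray, G: int, strict: bool = False) -> np.ndarray:
    perm = permutations[k]
    n = values.shape[1] // 2
    xa = np.ascontiguousarray(values[:, perm[:n]])
    xb = np.ascontiguousarray(values[:, perm[n:]])
    return _group_nstats(xa, xb, G, lanes=lanes, strict=strict)


def permutation_statistic(pooled: ExpressionMatrix, perm, G: int,
                          lanes: int = 1, strict: bool = False) -> np.ndarray:
    """N-statistic vector for one permutation of the pooled data.

    Pure function of (pooled, perm, G): composes the equal split, contiguous
    subgrouping of the shuffled order, moment computation, correlation rows
    and per-gene statistics.
    """
    perm = _check_perm(perm, pooled.n)
    if pooled.n % 2 != 0:
        raise ConfigError("pooled sample count must be even")
    n = pooled.n // 2
    xa = np.ascontiguousarray(pooled.values[:, perm[:n]])
    xb = np.ascontiguousarray(pooled.values[:, perm[n:]])
    return _group_nstats(xa, xb, G, lanes=lanes, strict=strict)


def compute_null(pooled: ExpressionMatrix, plan: PermutationPlan, G: int,
                 executor: ExecutorConfig | None = None,
                 strict: bool = False) -> NullDistribution:
    """Run all K permutations through the executor; row k = permutation k."""
    if plan.n_total != pooled.n:
        raise ConfigError("permutation plan does not match pooled sample count")
    work_fn = functools.partial(
        _permutation_worker,
        values=pooled.values,
        permutations=plan.permutations,
        G=G,
        strict=strict,
    )
    return NullDistribution(dispatch(plan, work_fn, executor))


#: Relative tolerance for judging a permutation statistic "equal" to the
#: observed one. Ties count as exceedances; with subgroups of two subjects
#: every correlation is ±1 and N-statistics tie structurally, so equality of
#: floating-point values must be judged up to roundoff or pipelines differing
#: by one ulp would count the same tie differently.
TIE_RTOL = 1e-9


def permutation_pvalues(n_star: np.ndarray, null: NullDistribution) -> np.ndarray:
    """p_i = #(N_ik >= N_i*) / K, ties counted as exceedances.

    Equality is judged at relative tolerance :data:`TIE_RTOL`, so a null
    statistic within roundoff of the observed one counts as an exceedance.
    """
    n_star = np.asarray(n_star, dtype=np.float64)
    if n_star.shape != (null.m,):
        raise ValueError("observed statistic length does not match null distribution")
    thresh = n_star - TIE_RTOL * (1.0 + np.abs(n_star))
    return (null.stats >= thresh[None, :]).sum(axis=0) / float(null.K)


def adjust_pvalues(p: np.ndarray, m: int) -> np.ndarray:
    """Extended Bonferroni (PFER) adjustment p̃ = p · m, uncapped."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values outside [0, 1]")
    return p * m


def observed_nstat(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix, G: int,
                   strict: bool = False) -> np.ndarray:
    """Observed N* from the unpermuted data (single lane, as dispatched
    before any parallel work begins)."""
    _validate_pair(expr_a, expr_b, G)
    return _group_nstats(expr_a.values, expr_b.values, G, lanes=1, strict=strict)


def _validate_pair(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix, G: int) -> None:
    if expr_a.gene_ids != expr_b.gene_ids:
        raise ConfigError("the two conditions must list identical gene ids in the same order")
    if expr_a.n != expr_b.n:
        raise ConfigError(
            f"unequal sample counts ({expr_a.n} vs {expr_b.n}); the permutation "
            "null requires an equal split"
        )
    if expr_a.m < 2:
        raise ConfigError("need at least 2 genes to form correlation vectors")
    if expr_a.n < 4:
        raise ConfigError("need at least 4 samples per condition (two subgroups of two)")
    if G > expr_a.n // 2 or G < 1:
        raise ConfigError(f"G={G} invalid for n={expr_a.n} samples per condition")


def pool_conditions(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix) -> ExpressionMatrix:
    """Concatenate the two conditions column-wise (A first), with sample ids
    prefixed by condition to keep them unique."""
    ids = [f"A:{s}" for s in expr_a.sample_ids] + [f"B:{s}" for s in expr_b.sample_ids]
    return ExpressionMatrix(
        expr_a.gene_ids, ids, np.concatenate([expr_a.values, expr_b.values], axis=1)
    )


def run_gdaa(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix, G: int, K: int,
             seed: int, executor: ExecutorConfig | None = None,
             strict: bool = False) -> GdaaResult:
    """The full differential-association analysis.

    Observed N* from the unpermuted data, a K-permutation null via the
    executor, permutation p-values and the PFER adjustment. Fully determined
    by (inputs, G, K, seed), independent of the executor configuration.
    """
    _validate_pair(expr_a, expr_b, G)
    if K < 1:
        raise ConfigError("permutation count K must be >= 1")
    n_star = observed_nstat(expr_a, expr_b, G, strict=strict)
    pooled = pool_conditions(expr_a, expr_b)
    plan = make_permutation_plan(pooled.n, K, seed)
    null = compute_null(pooled, plan, G, executor=executor, strict=strict)
    p = permutation_pvalues(n_star, null)
    p_adj = adjust_pvalues(p, expr_a.m)
    return GdaaResult(expr_a.gene_ids, n_star, p, p_adj, K=K, G=G, seed=seed)
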