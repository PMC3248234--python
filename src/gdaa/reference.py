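"""Naive reference pipeline for equivalence testing (small inputs only).

Recomputes the whole analysis with independent building blocks: per-pair
correlations via :func:`scipy.stats.pearsonr`, the Fisher transform applied
scalar-by-scalar, and the brute-force N-statistic with explicit entry-i
exclusion. It shares only the permutation plan with the production path
(the plan is infrastructure, not the statistic), so matching p-value vectors
exercise every numerical stage of the fast implementation.

Cost is O(m² · n · G) Python-level loops per permutation — use for m up to a
few dozen.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.stats

from .correlation import FISHER_CLAMP, CorrelationSample, SubgroupPartition, partition_subgroups
from .io import ExpressionMatrix, GdaaResult
from .nstat import n_statistic_bruteforce
from .pipeline import (
    TIE_RTOL,
    _validate_pair,
    adjust_pvalues,
    make_permutation_plan,
    pool_conditions,
    split_permuted,
)


def reference_correlation_sample(values: np.ndarray, part: SubgroupPartition) -> CorrelationSample:
    """Per-pair scipy correlations, Fisher-transformed, diagonal zero."""
    m = values.shape[0]
    mats = []
    for idx in part.subgroups:
        block = values[:, idx]
        w = np.zeros((m, m), dtype=np.float64)
        for i in range(m):
            for j in range(i + 1, m):
                if np.ptp(block[i]) == 0.0 or np.ptp(block[j]) == 0.0:
                    r = 0.0
                else:
                    r = float(scipy.stats.pearsonr(block[i], block[j]).statistic)
                r = min(max(r, -FISHER_CLAMP), FISHER_CLAMP)
                w[i, j] = w[j, i] = math.atanh(r)
        mats.append(w)
    return CorrelationSample(mats)


def reference_group_nstats(values_a: np.ndarray, values_b: np.ndarray, G: int) -> np.ndarray:
    n = values_a.shape[1]
    part = partition_subgroups(n, G)
    corr_a = reference_correlation_sample(values_a, part)
    corr_b = reference_correlation_sample(values_b, part)
    return n_statistic_bruteforce(corr_a, corr_b)


def run_reference(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix, G: int,
                  K: int, seed: int) -> GdaaResult:
    """End-to-end naive analysis; same (G, K, seed) contract as run_gdaa."""
    _validate_pair(expr_a, expr_b, G)
    n_star = reference_group_nstats(expr_a.values, expr_b.values, G)
    pooled = pool_conditions(expr_a, expr_b)
    plan = make_permutation_plan(pooled.n, K, seed)
    null = np.empty((K, expr_a.m), dtype=np.float64)
    for k in range(K):
        perm_a, perm_b = split_permuted(pooled, plan.permutations[k])
        null[k] = reference_group_nstats(perm_a.values, perm_b.values, G)
    p = np.empty(expr_a.m, dtype=np.float64)
    for i in range(expr_a.m):
        # ties count as exceedances, judged at the same roundoff tolerance
        # as the production pipeline
        thresh = n_star[i] - TIE_RTOL * (1.0 + abs(n_star[i]))
        p[i] = sum(1 for k in range(K) if null[k, i] >= thresh) / K
    return GdaaResult(expr_a.gene_ids, n_star, p, adjust_pvalues(p, expr_a.m),
                      K=K, G=G, seed=seed)
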