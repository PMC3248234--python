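"""Subgroup partitioning and Fisher-transformed correlation-vector samples.

The differential-association test never looks at mean expression. Its raw
material is, for each gene i and each disjoint subgroup of subjects, the
vector of Fisher-z transformed Pearson correlations between gene i and every
other gene. Splitting the n subjects of one condition into G subgroups of at
least two subjects each yields a sample of G such correlation vectors per
gene per condition, which the N-statistic then compares across conditions.

Correlations are assembled from per-subgroup *moment arrays* — the m × G
sums and sums of squares of expression within subgroups — with the pairwise
cross-products computed on the fly. The moment arrays are computed once per
(permuted) group and are read-only thereafter; every consumer (full-matrix
sample, per-gene lane computation, observed and permuted statistics) goes
through the same row routine, which is what makes results bit-identical
across parallel execution layouts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import ConfigError, DegenerateDataError, ExpressionMatrix

logger = logging.getLogger("gdaa")

#: Correlations are clamped to |r| <= 1 - 1e-12 before the Fisher transform
#: so that w = atanh(r) is always finite and Euclidean kernels never see Inf.
FISHER_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class SubgroupPartition:
    """Ordered disjoint index sets covering samples 0..n-1, each of size >= 2."""

    subgroups: tuple[np.ndarray, ...]

    @property
    def G(self) -> int:
        return len(self.subgroups)

    @property
    def n(self) -> int:
        return sum(len(s) for s in self.subgroups)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.subgroups)


def partition_subgroups(n: int, G: int) -> SubgroupPartition:
    """Split sample indices 0..n-1 into G contiguous, near-equal subgroups.

    Sizes differ by at most 1 (the first ``n mod G`` subgroups get the extra
    subject) and every subgroup has at least two members, as required to
    compute correlations within it. Assignment is contiguous over the current
    sample order; under permutations the order itself is freshly shuffled, so
    contiguity is equivalent to a random partition there.
    """
    if G < 1:
        raise ConfigError(f"subgroup count G={G} must be >= 1")
    if G > n // 2:
        raise ConfigError(
            f"G={G} subgroups of n={n} samples would leave a subgroup with "
            "fewer than two subjects"
        )
    base, extra = divmod(n, G)
    sizes = [base + 1] * extra + [base] * (G - extra)
    bounds = np.cumsum([0] + sizes)
    subgroups = tuple(
        np.arange(bounds[j], bounds[j + 1], dtype=np.intp) for j in range(G)
    )
    return SubgroupPartition(subgroups)


@dataclass(frozen=True)
class SubgroupMoments:
    """Per-gene, per-subgroup sums and sums of squares of expression.

    Entry (i, j) of ``sums`` is sum_{l in subgroup j} x_il and of ``sums_sq``
    is sum_{l in subgroup j} x_il^2. These two m × G arrays are the only
    marginal statistics the correlation formula needs.
    """

    sums: np.ndarray
    sums_sq: np.ndarray


def compute_subgroup_moments(expr, part: SubgroupPartition) -> SubgroupMoments:
    """Exact per-gene sums and sums of squares within each subgroup.

    ``expr`` may be an :class:`ExpressionMatrix` or a raw genes × samples
    array.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=np.float64)
    n = values.shape[1]
    for idx in part.subgroups:
        if idx.min() < 0 or idx.max() >= n:
            raise ConfigError("partition indices out of range for expression matrix")
    sums = np.stack([values[:, idx].sum(axis=1) for idx in part.subgroups], axis=1)
    sums_sq = np.stack([(values[:, idx] ** 2).sum(axis=1) for idx in part.subgroups], axis=1)
    return SubgroupMoments(sums, sums_sq)


def pearson_correlation(x, y, strict: bool = False) -> float:
    """Pearson correlation via the single-pass moment formula.

    r = (n Σxy − Σx Σy) / sqrt((n Σx² − (Σx)²)(n Σy² − (Σy)²)).

    If either vector has zero variance the correlation is undefined; by
    convention 0.0 is returned with a logged warning (``strict=True`` raises
    instead), which keeps long permutation runs total.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("pearson_correlation needs two equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("pearson_correlation needs vectors of length >= 2")
    num = n * float(x @ y) - float(x.sum()) * float(y.sum())
    vx = n * float(x @ x) - float(x.sum()) ** 2
    vy = n * float(y @ y) - float(y.sum()) ** 2
    if vx <= 0.0 or vy <= 0.0:
        if strict:
            raise DegenerateDataError("zero-variance vector in correlation")
        logger.warning("zero-variance vector in correlation; returning r=0")
        return 0.0
    return num / math.sqrt(vx * vy)


def fisher_transform(r: float) -> float:
    """Fisher z-transform w = ½ log((1+r)/(1−r)), clamped to stay finite.

    ``r`` is first clamped to |r| <= 1 − 1e-12, so w(±1) ≈ ±14.17 rather than
    ±Inf. Values of |r| beyond 1 by more than roundoff are rejected.
    """
    r = float(r)
    if abs(r) > 1.0 + 1e-9:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    r = min(max(r, -FISHER_CLAMP), FISHER_CLAMP)
    return float(np.arctanh(r))


@dataclass(frozen=True)
class GroupData:
    """Read-shared per-group working set: subgroup blocks + moment arrays.

    ``cols[k]`` is the contiguous m × n_k block of expression columns for
    subgroup k and ``centered[k]`` the same block with the subgroup gene
    means (``sums``/n_k) subtracted; ``var`` holds the centered sums of
    squares Σ(x − x̄)². All arrays are published read-only: lanes (threads)
    may read them concurrently but hold private workspace only for their own
    genes' correlation rows.
    """

    cols: tuple[np.ndarray, ...]
    centered: tuple[np.ndarray, ...]
    sizes: tuple[int, ...]
    sums: np.ndarray
    sums_sq: np.ndarray
    var: np.ndarray
    zero_var: np.ndarray

    @property
    def G(self) -> int:
        return len(self.cols)

    @property
    def m(self) -> int:
        return self.cols[0].shape[0]


def prepare_group(values: np.ndarray, part: SubgroupPartition,
                  moments: SubgroupMoments | None = None,
                  strict: bool = False) -> GroupData:
    """Build the shared working set for one (possibly permuted) group.

    Computes the subgroup moment arrays (or reuses precomputed ones),
    centers each subgroup block on its gene means, and marks everything
    read-only — the publication point of the read-sharing contract.

    Variances and cross-products are taken on the centered blocks rather
    than expanded from the raw moments: the expanded form n·Σxy − Σx·Σy
    cancels catastrophically for small subgroups with near-constant genes,
    where |r| must land within ~1e-12 of 1 for the Fisher clamp to engage
    consistently. The shared ``sums`` array supplies the means; ``sums_sq``
    is retained in the published set.
    """
    values = np.asarray(values, dtype=np.float64)
    if moments is None:
        moments = compute_subgroup_moments(values, part)
    sizes = part.sizes
    cols = tuple(np.ascontiguousarray(values[:, idx]) for idx in part.subgroups)
    centered = tuple(
        cols[k] - (moments.sums[:, k] / sizes[k])[:, None] for k in range(part.G)
    )
    var = np.stack([(c * c).sum(axis=1) for c in centered], axis=1)
    zero_var = var <= 0.0
    if zero_var.any():
        if strict:
            raise DegenerateDataError(
                f"{int(zero_var.sum())} zero-variance gene/subgroup pairs"
            )
        logger.warning(
            "%d zero-variance gene/subgroup pairs; their correlations are set to 0",
            int(zero_var.sum()),
        )
    for arr in cols + centered + (moments.sums, moments.sums_sq, var, zero_var):
        arr.flags.writeable = False
    return GroupData(cols, centered, sizes, moments.sums, moments.sums_sq, var, zero_var)


def gene_corr_rows(group: GroupData, i: int) -> np.ndarray:
    """Fisher-z correlation rows of gene ``i``: a G × m array.

    Row k is gene i's correlation vector within subgroup k over the full gene
    axis, with the self-entry forced to 0. The cross-products Σ(x−x̄)(y−ȳ)
    are computed on the fly as one matrix-vector product per subgroup against
    the shared centered block. Because the zero diagonal contributes 0 to any
    Euclidean distance between two rows of the same gene, full-row distances
    equal the entry-i-excluded distances exactly.
    """
    G = group.G
    rows = np.empty((G, group.m), dtype=np.float64)
    for k in range(G):
        C = group.centered[k]
        cross = C @ C[i]
        den = np.sqrt(group.var[i, k] * group.var[:, k])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cross / den
        r[den == 0.0] = 0.0
        np.clip(r, -FISHER_CLAMP, FISHER_CLAMP, out=r)
        w = np.arctanh(r)
        w[i] = 0.0
        rows[k] = w
    return rows


@dataclass(frozen=True)
class CorrelationSample:
    """G Fisher-z correlation matrices (m × m, symmetric, zero diagonal).

    ``w[k][i, j]`` is the transformed correlation of genes i and j within
    subgroup k; row i (with the zero self-entry) is gene i's correlation
    vector in that subgroup.
    """

    w: list[np.ndarray]

    @property
    def G(self) -> int:
        return len(self.w)

    @property
    def m(self) -> int:
        return self.w[0].shape[0]


def correlation_sample(expr, part: SubgroupPartition,
                       moments: SubgroupMoments | None = None,
                       strict: bool = False) -> CorrelationSample:
    """Materialize the full G-matrix correlation sample for one group.

    Convenient for small problems and for the observed statistic; the
    permutation lanes use :func:`gene_corr_rows` directly and never build the
    m × m matrices. Both paths share the same row routine, so the values are
    bit-identical.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr, dtype=np.float64)
    group = prepare_group(values, part, moments=moments, strict=strict)
    m, G = group.m, group.G
    mats = [np.empty((m, m), dtype=np.float64) for _ in range(G)]
    for i in range(m):
        rows = gene_corr_rows(group, i)
        for k in range(G):
            mats[k][i] = rows[k]
    return CorrelationSample(mats)
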