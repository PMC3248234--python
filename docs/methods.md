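# Methods

## Model and procedure

For two phenotypes A and B with `n` subjects each and `m` genes of log-scale
expression, the null hypothesis for gene `i` is that the joint distribution
of its correlation vector — its Fisher-z Pearson correlations with all other
genes — is the same in both conditions. Because a single correlation matrix
per condition is one observation, each condition's subjects are divided into
`G` disjoint subgroups (each of size ≥ 2, sizes differing by at most 1), and
the `G` within-subgroup correlation vectors form a sample from the
correlation vector's distribution. The two samples are compared per gene
with the energy-distance N-statistic under the Euclidean kernel; all three
double sums run over every ordered subgroup pair, self-pairs included (they
contribute zero within-group). The statistic is nonnegative up to roundoff
and equals zero when the two samples coincide.

The null distribution is obtained by pooling the `2n` subjects, shuffling,
splitting into equal halves and recomputing everything; `K` repetitions give
the per-gene null sample `N_ik`. The p-value counts exceedances including
ties, `p_i = #(N_ik ≥ N_i*)/K`, so p-values lie on the grid `{0, 1/K, …, 1}`
and `p = 0` is attainable (no smoothing term is added). The multiplicity
adjustment is `p̃_i = p_i · m`, the extended Bonferroni form that controls
the per-family error rate; as an expected count it may exceed 1 and is not
capped.

## Parameters

| parameter | meaning | constraint / default |
|---|---|---|
| `G` | subgroups per condition | `1 ≤ G ≤ ⌊n/2⌋`; required user choice. Larger `G` gives more correlation-vector replicates but fewer subjects per correlation estimate; `G = 10` at `n = 100` is a typical operating point. |
| `K` | permutations | ≥ 1; p-value resolution is `1/K`. Multiple-testing-adjusted inference needs `K ≫ m` (10⁴ at microarray scale); tests here use 20–500. |
| `seed` | PCG64 seed for the permutation plan | all randomness flows from it |
| `workers × lanes` | executor shape | any values ≥ 1; never affects results |
| `strict` | zero-variance handling | off: `r = 0` with a logged warning; on: abort |

## Subgrouping and permutation conventions

Subgroup assignment is contiguous over the current sample order (subgroup 1
gets the first `⌈n/G⌉` columns, and so on, remainders spread over the first
subgroups). For the observed statistic this is a fixed, reproducible choice;
different partitions give (slightly) different `N*`. Under permutations the
pooled order is freshly shuffled before the contiguous split, so contiguity
is equivalent to a random partition there. Unequal condition sizes are
rejected up front: the null construction splits the pool into halves of
equal size, which presupposes equal `n`.

The permutation plan (K index vectors over `0..2n−1`) is drawn centrally
once and shipped to workers; workers never touch a random generator. This,
plus keying results by permutation index rather than completion order, is
what makes the output a pure function of `(inputs, G, K, seed)`.

## Numerical choices

- **Fisher clamp.** Correlations are clamped to `|r| ≤ 1 − 1e-12` before
  `atanh`, so transformed values are finite (≈ ±14.17 at the clamp) and
  kernels never propagate infinities. Rankings are insensitive to the exact
  clamp value.
- **Centered correlation arithmetic.** The expanded moment formula
  `n·Σxy − Σx·Σy` cancels catastrophically for small subgroups whose genes
  take close values — precisely the `|r| → 1` regime where the clamp must
  engage consistently. Production correlations are therefore computed on
  subgroup blocks centered at their gene means (means come from the shared
  `sums` array): cross-products and variances on centered data keep the
  relative error of `r` at the ulp level near ±1. The scalar
  `pearson_correlation` helper keeps the classical single-pass formula; the
  two agree to ~1e-12 on well-conditioned data.
- **Zero variance.** A gene constant within a subgroup has no defined
  correlation; its entries are set to 0 with one logged warning per group
  (strict mode aborts instead). This keeps K-permutation runs total — a
  failure halfway through the null would discard all completed work.
- **Zero-diagonal convention.** The correlation vector of gene `i` excludes
  entry `i`. Storing full rows with `w[i,i] = 0` makes full-row Euclidean
  distances equal the excluded-entry distances exactly (both rows contribute
  0 at position `i`), enabling one vectorized code path; the brute-force
  oracle excludes the entry explicitly, which doubles as a check of the
  convention.
- **Fixed kernel reduction.** Each per-gene pair sum accumulates its G²
  distances in ascending order. Any fixed order shared by all code paths
  yields bit-identical results across executor shapes; the sorted order is
  additionally invariant under swapping the two samples, so
  `N(A,B) == N(B,A)` holds exactly rather than to a few ulps.
- **Tie tolerance.** Exceedances `N_ik ≥ N_i*` treat values within relative
  tolerance `1e-9` of `N_i*` as ties (counted). With subgroups of two
  subjects every correlation is exactly ±1 and the statistics live on a
  discrete lattice; mathematically tied values computed by different but
  equally valid arithmetic differ by ulps, and a raw comparison would count
  the same tie inconsistently.

## Execution model and data sharing

Two tiers. Coarse grain: worker processes pull one permutation index at a
time from a bounded window (default one in flight per worker;
`max_in_flight` caps it), so stragglers never stall the queue; a worker
failure aborts the run with the unfinished indices named. Fine grain: inside
a worker, genes are split into contiguous blocks of near-equal size, one per
lane; lanes read a single shared copy of the permuted expression blocks and
the `m × G` moment arrays (published read-only — mutation raises) and write
disjoint slices of the output vector. Lane-private workspace is one `G × m`
row set per side per gene. Consolidating lanes into fewer workers therefore
shrinks the total footprint: `W` workers of `P` lanes allocate `W` copies of
the shared arrays plus `W·P` lane workspaces. CPU pinning is exposed only as
an off-by-default hint (`pin_cpus`); it is an OS scheduling knob with no
bearing on results.

The observed statistic is computed once, single-lane, before any dispatch;
the master performs no numerical work while permutations are in flight.

## Synthetic data

`generate_null_pair` draws both conditions i.i.d. standard normal — a global
null for type-I error checks. `generate_da_pair` plants a block of
`da_genes` genes equicorrelated at `rho_A` in condition A and `rho_B` in B
(single-factor construction `x = √ρ·f + √(1−ρ)·ε` for ρ ≥ 0, Cholesky of the
equicorrelation matrix for feasible negative ρ; feasibility requires
`ρ > −1/(d−1)`), at positions drawn uniformly over the gene axis; all other
genes are independent. Defaults (m=200, n=60, 20 planted genes, ρ 0.8 vs 0)
are the package's reference detectability conditions. The generator
perturbs exactly what the test measures — the correlation structure — with
no mean shift, so mean-based tests have no power on it by construction.

What it does not emulate: heavy-tailed or count-like expression, probe-level
artifacts, normalization residue, correlated background blocks, batch
effects. Passing tests demonstrate the statistic's behavior under a clean
Gaussian factor model, not robustness to real microarray noise.

## Problem sizes used in the shipped checks

The statistical checks run at deliberately modest sizes chosen so the whole
suite replays quickly on one CPU: oracle equivalence at `m ≤ 25, G ≤ 5`;
global-null calibration pooled over 10 replicates of `m=40, n=40, G=4,
K=200` (400 tests, rejection rate at α=0.05 checked against a 99% binomial
band widened for the dependence induced by sharing one permutation set
across genes); signal recovery at the reference detectability conditions
with `K=200`. The method itself has no size-dependent logic — the same code
paths execute at microarray scale, only longer.

## Known limitations

- p-values are permutation-exact only up to `1/K`; `p = 0` means "below
  resolution", not literal impossibility.
- The observed `N*` depends on the (fixed, contiguous) subgroup assignment;
  no averaging over partitions is performed.
- Pearson correlation with the Fisher transform is the only association
  measure, and the extended Bonferroni/PFER the only adjustment; FDR-style
  procedures are intentionally out of scope.
- Workers and lanes live on one machine; the worker contract is
  transport-agnostic but no cluster backend is provided.
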