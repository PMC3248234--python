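# gdaa — gene differential association analysis

Differential *expression* analysis asks whether a gene's mean level changes
between two phenotypes. This package implements the complementary question:
does a gene change its **relationships** with all other genes? Such
*differentially associated* (DA) genes carry information hidden in the
inter-gene correlation structure and are invisible to mean-based tests.

## The statistic

Given log-scale expression for `m` genes over `n` subjects per condition
(A and B), the subjects of each condition are split into `G` disjoint
subgroups of at least two. Within each subgroup, gene `i` gets a
**correlation vector** `w_i`: the Fisher z-transformed Pearson correlations
between gene `i` and every other gene,

    w_ik = ½ log((1 + r_ik) / (1 − r_ik)).

This yields a sample of `G` vectors per condition for each gene. The two
samples are compared by the energy-distance **N-statistic** with the
Euclidean kernel `L(x, y) = ‖x − y‖₂`:

    N_i = 2/G² Σ_k Σ_l L(w_i(A,k), w_i(B,l))
        − 1/G² Σ_k Σ_l L(w_i(A,k), w_i(A,l))
        − 1/G² Σ_k Σ_l L(w_i(B,k), w_i(B,l)).

Significance comes from a permutation null: pool the `2n` subjects, shuffle,
split into two equal halves, recompute all `N_i`; repeat `K` times. The
p-value is `p_i = #(N_ik ≥ N_i*) / K` (ties count as exceedances) and the
per-family error rate (PFER) adjustment is `p̃_i = p_i · m`, deliberately
**not** capped at 1 — a PFER is an expected count of false positives.

Because `K` is typically large (10⁴ for a fine multiple-testing-adjusted
analysis) the package ships a two-tier parallel executor: permutations are
pulled dynamically by worker processes; inside a worker the per-gene
computation is split across lanes that share one copy of the permuted
expression matrix and the subgroup moment arrays. Results are **byte-
identical across every executor shape** — parallelism is a performance knob,
never a source of nondeterminism.

## Worked example

Simulate 50 genes × 20 samples per condition with an 8-gene block that is
equicorrelated at ρ = 0.8 in condition A and uncorrelated in B, then run the
analysis with 4 subgroups and 500 permutations on 2 workers × 2 lanes:

```sh
gdaa simulate --genes 50 --samples 20 --da-genes 8 --rho-a 0.8 --rho-b 0.0 \
     --seed 42 --out-a A.tsv --out-b B.tsv --truth truth.txt
gdaa run --expr-a A.tsv --expr-b B.tsv --subgroups 4 --permutations 500 \
     --seed 7 --workers 2 --lanes 2 --out results.tsv
```

The truth file lists the planted genes `g03 g04 g20 g29 g34 g41 g46 g49`.
Sorting `results.tsv` by p-value (ties broken by the statistic) gives:

```
gene_id  n_statistic  p_value  p_adjusted
g29      5.978        0        0
g20      5.276        0        0
g04      4.885        0        0
g03      4.883        0        0
g46      4.582        0        0
g41      4.587        0.002    0.1
g49      4.608        0.004    0.2
g48      4.078        0.024    1.2
g34      4.253        0.028    1.4
```

Eight of the top nine genes are the planted ones. `p_value = 0` means no
permutation statistic reached the observed value (possible because the
estimator uses no smoothing); `p_adjusted` is on the PFER scale, so `1.2`
means "at this threshold one would expect ≈1.2 false positives among all 50
genes". `gdaa oracle` runs a deliberately naive reference pipeline (scipy
correlations, literal loops) for equivalence checking on small inputs.

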