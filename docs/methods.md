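# Methods

## Data model

Genotypes are dichotomized before any search: with minor-allele dosage
g ∈ {0,1,2}, code 1 ⇔ g = 2 (homozygous minor, the "recessive" genotype) and
code 2 ⇔ g ∈ {0,1} (the merged homozygous-major/heterozygous class). The
minor allele is inferred from pooled case+control allele counts (ties broken
lexicographically) and can be overridden per SNP, which matters when a
published table fixes the genotype labels a priori. Loaders enforce complete
data — a row with a missing or unparseable cell is rejected, never imputed —
and accept delimited text (allele-pair strings or dosages, dialect detected
per column) or biallelic VCF with a sample→phenotype map, where the ALT
allele is taken as minor. SNP indices are 1-based in all user-facing output.

## Objective and statistics

A k-SNP barcode's fitness is the control-minus-case matching frequency; it
lies in [−1, 1], is antisymmetric under swapping phenotype labels, and can
only shrink in |match set| as constraints are appended. The default search
direction is protective (maximize); `direction="risk"` negates the objective.

Every model is summarized on its 2×2 (match vs Others) × (case vs control)
table:

* **Odds ratio** ad/bc. A zero in b or c raises a distinct error
  (`ZeroCellError`) rather than applying a silent continuity correction.
* **Wald CI** exp(ln OR ± z₁₋α/₂·√(1/a+1/b+1/c+1/d)); requires all four
  cells positive. The exact normal quantile (≈1.959964) is used, not 1.96.
* **Pearson chi-square**, df = 1, *without* Yates correction (the corrected
  statistic does not reproduce the reference p-values from the same counts);
  computed via `scipy.stats.chi2_contingency(correction=False)` and
  cross-checked in the tests against the closed form
  n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)).
* **Post-hoc power** of the two-sided two-proportion z-test at the observed
  proportions, pooled SE under the null and unpooled under the alternative
  (formula in the README). The reference tables never state their power
  formula; this one was identified by matching the printed values — it
  reproduces the three headline powers (0.792, 0.339, 0.750) exactly at three
  decimals and every other row within 0.002, while the noncentral-chi-square
  alternative (λ = observed χ²) gives 0.798 for the top model and was
  rejected. A caveat discovered while validating it by simulation: the
  *pooled* chi-square test is slightly more powerful than the unpooled z-test
  at these margins (exact rejection probability 0.806 vs 0.794 at the top
  model's proportions), so the formula should be read as the power of the
  unpooled z-test, not of the chi-square test. Power is undefined (error)
  only when both proportions are degenerate or the alternative SE vanishes.
* No multiple-testing correction is applied; reports carry the model count so
  users can Bonferroni-adjust externally.

Ranking sorts by fitness (descending), then p-value, then lexicographic
barcode order. Models with zero matches get NaN statistics (fitness 0) and
sort last among ties. Exact fitness ties between distinct barcodes do occur
(two reference pair models share counts 35/43, and on the fixture the best
3- and 4-SNP tables are attained by more than one SNP tuple); which tied
barcode is listed first is implementation-defined.

## PSO engine

Particles are continuous vectors of length 2k: SNP dimensions bounded by
[1, n_snps], genotype dimensions by [1, 2]. Initialization is uniform within
bounds; velocities start uniform in ±(x_max−x_min) per dimension and stay
clamped there. The inertia weight decreases linearly,
w(g) = (w_max−w_min)(G−g)/G + w_min, spanning [0.4, 0.9] inclusive over
g = 0..G; `run_pso` passes g = 1..G to the G update steps, so the first
executed step uses w just below w_max. Velocity updates draw r₁, r₂
independently *per dimension* (the standard choice; a per-particle draw is
the other defensible reading). Positions are clamped to bounds (no
reflection). Defaults — population 50, 100 generations, c₁ = c₂ = 2,
w 0.9→0.4 — follow the standard linearly-decreasing-weight configuration.

Decoding rounds half-away-from-zero and clamps; duplicate SNP indices after
rounding are repaired by redrawing the offending dimension uniformly among
unused indices from the run's RNG stream, so every evaluated barcode has k
distinct SNPs. pbest/gbest replacement requires strictly greater fitness
(ties keep the incumbent); the run stops after a fixed generation budget with
no convergence early-exit, and the gbest history is therefore nondecreasing.
Runs are bit-reproducible from the seed. `run_pso` memoizes fitness per
decoded barcode, which on small panels makes a full run cost roughly one
dictionary lookup per particle-generation. k is fixed per run; a k-range
search is a loop over fixed-k runs.

The exhaustive enumerator is the oracle: all C(n,k)·2^k canonical barcodes,
refused above a guard threshold (default 10⁷ models) where the PSO is the
intended tool. On the bundled 5-SNP fixture (40–80 models per k) the swarm
reaches the enumerated optimum in 100/100 seeds for every k in 2..5.

## Synthetic data

`generate_dataset` draws each SNP independently per phenotype group at a
specified code-1 frequency; an optional planted barcode receives exact match
counts per group (constrained individuals pinned to the barcode's codes,
unconstrained ones rejection-sampled away from it, with a bounded-retry
error when the spec is near-infeasible). It deliberately omits linkage
disequilibrium, penetrance-model epistasis and population stratification:
all reported statistics depend only on the planted joint event and the
marginals, so passing tests demonstrate correctness of counting, statistics
and search — not robustness to LD structure or confounding in real cohorts.

`reconstruct_fixture` rebuilds the 345-case / 290-control, five-SNP *ORAI1*
cohort at the individual level from its published summary counts. The
published marginal and joint counts pin the table almost completely — e.g.
the (SNP1,SNP3) pair count forces every SNP1-code-1 carrier into SNP3-code 2,
and the (SNP1,SNP4)/(SNP3,SNP4) counts nest SNP4-code-1 inside both — so a
closed-form block assignment (15 genotype-profile blocks per group) satisfies
all 18 constraints *exactly*: per-SNP marginals, all ten published pairwise
match counts and the best 2/3/4/5-SNP joint counts. The only unreported pair,
(SNP3,SNP5), leaves two free overlap parameters; they are set near
independence (4 cases / 3 controls), which keeps every unreported pair
model's fitness (max 0.0198) below the tenth reported model's 0.0222, so
exhaustive ranking returns exactly the published top ten in the published
order. The construction is fully deterministic (no randomness remains), and
the verification report lists each constraint with observed vs expected
counts. One internal inconsistency of the published pair table is flagged
rather than hidden: its (2-4)/(1-1) row prints an Others control total of 261
where the cohort requires 262, and a p-value of 0.010 where the printed
counts yield ≈0.008 under every correction variant; the package reports its
own consistent values for that model.

## Numerical and design choices

* Dichotomization, matching and contingency counting are pure integer
  operations; fitness comparisons in the search use exact float equality only
  against values produced by the identical code path (the memo cache).
* Report formatting follows the conventional precision of case-control
  association tables (ORs/CIs/p/power to 3 decimals in combination tables, 2
  in the single-SNP table) with full-precision duplicates in `*_exact`
  columns of the TSV output.
* Degenerate inputs: empty barcodes, non-canonical SNP orderings, codes
  outside {1,2}, out-of-panel indices, multiallelic or missing VCF genotypes
  and infeasible planting specs all raise typed errors early.
* Minimum barcode size is k = 2; single-SNP associations are a separate
  reporting path (`single_snp_table`), not barcodes.

## Limitations

* Wald CIs and the z-test power are large-sample approximations; with cells
  below ~5 an exact (Fisher) test — deliberately out of scope — would be
  preferable.
* The PSO guarantees no global optimum on large panels; the ≥95% hit rates
  demonstrated here are specific to tiny (≤80-model) spaces.
* The fixture reproduces the published cohort's *summary* structure, not its
  true individual-level LD; analyses sensitive to unreported joint classes
  (in particular any (SNP3,SNP5) model) reflect the near-independence fill,
  not the original data.
* Problem sizes in the test suite (635 individuals, 5 SNPs, 100-seed search
  replications, 2,000-table CI coverage and 20,000-replicate power
  simulations) were chosen to make every check exact or tightly convergent on
  a single CPU.
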