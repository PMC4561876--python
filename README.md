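# snpbarcode

Search case-control genotype data for multi-SNP genotype combinations
("SNP barcodes") that are protectively associated with a binary phenotype,
using a particle swarm optimizer (PSO) with an exhaustive-enumeration oracle
and an exact 2×2 association-statistics layer.

## The problem

Single-SNP association tests often miss combinations of genotypes that act
jointly. A *SNP barcode* is a set of k distinct SNPs, each paired with one
dichotomized genotype class: code 1 is the homozygous-minor ("recessive")
genotype, code 2 the merged homozygous-major/heterozygous class. An
individual *matches* the barcode when they carry every coded genotype. The
search objective is the frequency difference

    f(X) = |X ∩ controls| / n_controls − |X ∩ cases| / n_cases ,

so maximizing f targets *protective* models — barcodes over-represented in
controls (odds ratio < 1 for case status). With n SNPs and k-SNP barcodes the
space holds C(n,k)·2^k models; on small panels it is enumerated exactly, on
large ones a PSO explores it.

Each candidate barcode is scored on the 2×2 table (match vs Others) × (case
vs control) with counts a,b,c,d:

* odds ratio `OR = ad/bc` with Wald CI `exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))`
* uncorrected Pearson chi-square p (df = 1)
* post-hoc power of the two-sided two-proportion z-test at the observed
  matching proportions p₁ = a/n_cases, p₂ = c/n_controls:
  `power = Φ((|Δp|−z·SE₀)/SE₁) + Φ((−|Δp|−z·SE₀)/SE₁)` with pooled SE₀ and
  unpooled SE₁.

The PSO encodes a barcode as a continuous vector of length 2k (k SNP-index
dimensions, k genotype dimensions), initialized uniformly within bounds and
updated with the classic velocity rule under a linearly decreasing inertia
weight (w: 0.9 → 0.4); positions decode to barcodes by rounding, with
duplicate SNP indices redrawn among unused ones. Defaults: population 50,
100 generations, c₁ = c₂ = 2.

A built-in fixture reconstructs a 635-individual cohort (345 breast-cancer
cases / 290 controls) over five *ORAI1* SNPs (rs12320939, rs12313273,
rs7135617, rs6486795, rs712853) from published summary counts, so the whole
pipeline is testable without downloads; its verification report confirms
every count constraint.

## Worked example

```
$ snpbarcode make-fixture -o orai1.tsv --report orai1_report.json
wrote 635 individuals x 5 SNPs; 18/18 count constraints satisfied

$ snpbarcode run orai1.tsv --k 2 --top-n 3 -o report.tsv
-- 2-SNP models ------------------------------------------------
barcode               case/ctrl        OR          95% CI       P   power  fitness
1-2/1-1               15/29          0.409     0.215-0.779   0.005   0.792   0.0565
2-4/1-1               15/28          0.425     0.223-0.813   0.008   0.750   0.0531
1-3/1-2               67/71          0.743     0.509-1.085   0.123   0.339   0.0506
```

The top row says: the barcode on SNPs (1,2) = (rs12320939, rs12313273) with
genotype codes (1,1) — i.e. rs12320939-TT together with rs12313273-CC — is
carried by 15/345 cases but 29/290 controls, a frequency difference (fitness)
of 5.65%. Its odds ratio of 0.409 (95% CI 0.215–0.779, P = 0.005) marks a
significantly protective combination, and the two-proportion test had 79.2%
post-hoc power at these counts. A single barcode can be inspected directly:

```
$ snpbarcode evaluate orai1.tsv 1-2/1-1
barcode        1-2/1-1
case match     15/345
control match  29/290
odds ratio     0.409
95% CI         0.215-0.779
chi2 / P       7.805 / 0.005
power          0.792
fitness        0.0565
```

The same search as a library, statsmodels-style:

```python
from snpbarcode import BarcodeSearch, reconstruct_fixture

dataset, report = reconstruct_fixture()
res = BarcodeSearch(dataset, k=range(2, 6)).fit(method="exhaustive", top_n=10)
print(res.summary())          # ranked tables per k
best = res.best_per_k[5]      # 1-2-3-4-5/1-1-2-1-2, OR 0.425, counts 15/28
```

`fit(method="pso", params=PSOParams(seed=...))` runs the swarm instead; on
this 5-SNP panel it reaches the enumerated optimum for every k in 2..5 across
100 seeds.

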