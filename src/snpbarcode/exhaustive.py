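"""Exhaustive enumeration of k-SNP barcodes: the search oracle.

Deliberately simple and obviously correct: every one of the
C(n_snps, k) * 2^k canonical (SNP set, genotype codes) models is evaluated.
A guard threshold refuses combinatorial sizes where the heuristic search is
the intended tool.
"""

from __future__ import annotations

import math
from itertools import combinations, product
from typing import Iterator, List

from .barcode import SNPBarcode
from .exceptions import SearchSpaceError
from .genotypes import GenotypeDataset
from .stats import AssocResult, evaluate_barcode

DEFAULT_GUARD = 10_000_000


def n_models(n_snps: int, k: int) -> int:
    return math.comb(n_snps, k) * 2 ** k


def enumerate_barcodes(n_snps: int, k: int,
                       guard: int = DEFAULT_GUARD) -> Iterator[SNPBarcode]:
    """Yield every canonical k-SNP barcode on an n_snps panel."""
    if not 2 <= k <= n_snps:
        raise ValueError(f"need 2 <= k <= n_snps, got k={k}, n_snps={n_snps}")
    total = n_models(n_snps, k)
    if total > guard:
        raise SearchSpaceError(
            f"{total} models exceeds the enumeration guard ({guard}); "
            "use the PSO engine for panels this large")
    for snps in combinations(range(1, n_snps + 1), k):
        for codes in product((1, 2), repeat=k):
            yield SNPBarcode(snps, codes)


def _sort_key(r: AssocResult):
    # fitness descending, then smaller p, then lexicographic barcode;
    # NaN p-values (degenerate tables) sort last within a fitness tie
    p = r.p_value if r.p_value == r.p_value else float("inf")
    return (-r.fitness, p, r.barcode.snp_indices, r.barcode.genotype_codes)


def rank_models(dataset: GenotypeDataset, k: int, top_n: int | None = None,
                alpha: float = 0.05, direction: str = "protective",
                guard: int = DEFAULT_GUARD) -> List[AssocResult]:
    """All k-SNP models ranked by fitness (ties: p-value, then barcode order)."""
    results = [evaluate_barcode(dataset, bc, alpha=alpha, direction=direction,
                                on_degenerate="nan")
               for bc in enumerate_barcodes(dataset.n_snps, k, guard=guard)]
    results.sort(key=_sort_key)
    return results if top_n is None else results[:top_n]


def best_model(dataset: GenotypeDataset, k: int, alpha: float = 0.05,
               direction: str = "protective",
               guard: int = DEFAULT_GUARD) -> AssocResult:
    """The fitness-maximal k-SNP model."""
    return rank_models(dataset, k, top_n=1, alpha=alpha, direction=direction,
                       guard=guard)[0]


def best_per_k(dataset: GenotypeDataset, k_min: int = 2, k_max: int | None = None,
               alpha: float = 0.05, direction: str = "protective",
               guard: int = DEFAULT_GUARD) -> List[AssocResult]:
    """Best model for each barcode size k in k_min..k_max (default: n_snps)."""
    if k_max is None:
        k_max = dataset.n_snps
    if k_max > dataset.n_snps:
        raise ValueError(f"k_max={k_max} exceeds panel size {dataset.n_snps}")
    return [best_model(dataset, k, alpha=alpha, direction=direction, guard=guard)
            for k in range(k_min, k_max + 1)]
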