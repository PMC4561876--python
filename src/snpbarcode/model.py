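"""High-level modelling interface: build a search model from data, fit it,
inspect a results object.

    >>> model = BarcodeSearch(dataset, k=2)
    >>> res = model.fit(method="exhaustive", top_n=10)
    >>> print(res.summary())

`fit` dispatches to the exhaustive enumerator (the default on small panels)
or the particle swarm optimizer; either way the results object carries the
ranked association records (odds ratio, Wald CI, chi-square p, post-hoc
power, fitness) and formats them the way case-control association tables are
usually reported.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Union

import pandas as pd

from . import exhaustive as _exhaustive
from .barcode import SNPBarcode
from .genotypes import GenotypeDataset, read_genotype_table
from .pso import PSOParams, PSORun, run_pso
from .stats import AssocResult, evaluate_barcode, results_to_dataframe, \
    single_snp_table


class BarcodeSearch:
    """Search model for protective (or risk) k-SNP genotype combinations.

    Parameters
    ----------
    dataset
        Case-control genotype data.
    k
        Barcode size, or a (k_min, k_max) range searched per size.
    direction
        "protective" maximizes control-minus-case matching frequency
        (odds ratio < 1 models); "risk" negates the objective.
    alpha
        Significance level for CIs, tests and power.
    """

    def __init__(self, dataset: GenotypeDataset,
                 k: Union[int, Sequence[int]] = 2,
                 direction: str = "protective", alpha: float = 0.05):
        self.dataset = dataset
        if isinstance(k, int):
            self.k_values = [k]
        else:
            self.k_values = list(k)
        for kk in self.k_values:
            if not 2 <= kk <= dataset.n_snps:
                raise ValueError(f"k={kk} outside 2..{dataset.n_snps}")
        self.direction = direction
        self.alpha = alpha

    @classmethod
    def from_file(cls, path: str, k: Union[int, Sequence[int]] = 2,
                  phenotype_column: str = "phenotype", case_label: str = "case",
                  **kwargs) -> "BarcodeSearch":
        dataset = read_genotype_table(path, phenotype_column=phenotype_column,
                                      case_label=case_label)
        return cls(dataset, k=k, **kwargs)

    def fit(self, method: str = "exhaustive", top_n: int = 10,
            params: Optional[PSOParams] = None) -> "BarcodeSearchResults":
        """Run the search for every configured k and collect ranked results."""
        per_k: dict[int, List[AssocResult]] = {}
        runs: dict[int, PSORun] = {}
        for k in self.k_values:
            if method == "exhaustive":
                per_k[k] = _exhaustive.rank_models(
                    self.dataset, k, top_n=top_n, alpha=self.alpha,
                    direction=self.direction)
            elif method == "pso":
                run = run_pso(self.dataset, k, params=params,
                              direction=self.direction, alpha=self.alpha)
                runs[k] = run
                per_k[k] = [run.best]
            else:
                raise ValueError(f"unknown method {method!r}")
        return BarcodeSearchResults(self, method, per_k, runs)

    def evaluate(self, barcode: Union[SNPBarcode, str]) -> AssocResult:
        """Statistics for one explicit barcode (parse "1-2/1-1" strings)."""
        if isinstance(barcode, str):
            barcode = SNPBarcode.parse(barcode)
        return evaluate_barcode(self.dataset, barcode, alpha=self.alpha,
                                direction=self.direction, on_degenerate="nan")

    def single_snp_results(self) -> List[AssocResult]:
        """Per-SNP (code-1 vs code-2) association table."""
        return single_snp_table(self.dataset, alpha=self.alpha)


class BarcodeSearchResults:
    """Fit outcome: ranked models per barcode size plus search diagnostics."""

    def __init__(self, model: BarcodeSearch, method: str,
                 results_per_k: dict, pso_runs: dict):
        self.model = model
        self.method = method
        self.results_per_k = results_per_k
        self.pso_runs = pso_runs

    @property
    def best_per_k(self) -> dict:
        return {k: rs[0] for k, rs in self.results_per_k.items()}

    @property
    def best(self) -> AssocResult:
        return max(self.best_per_k.values(), key=lambda r: r.fitness)

    def to_frame(self, decimals: Optional[int] = 3) -> pd.DataFrame:
        frames = []
        for k, rs in sorted(self.results_per_k.items()):
            df = results_to_dataframe(rs, decimals=decimals)
            df.insert(0, "k", k)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path: str, decimals: Optional[int] = 3) -> None:
        self.to_frame(decimals=decimals).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "SNP barcode association search",
            "=" * 64,
            f"method: {self.method}    direction: {self.model.direction}"
            f"    alpha: {self.model.alpha}",
            f"individuals: {ds.n_individuals} "
            f"({ds.n_cases} cases / {ds.n_controls} controls), "
            f"{ds.n_snps} SNPs",
            "",
        ]
        header = (f"{'barcode':<22}{'case/ctrl':<12}{'OR':>7}{'95% CI':>16}"
                  f"{'P':>8}{'power':>8}{'fitness':>9}")
        for k, rs in sorted(self.results_per_k.items()):
            lines.append(f"-- {k}-SNP models " + "-" * (64 - 15 - len(str(k))))
            lines.append(header)
            for r in rs:
                ci = f"{r.ci_low:.3f}-{r.ci_high:.3f}"
                lines.append(
                    f"{str(r.barcode):<22}"
                    f"{r.table.case_match}/{r.table.control_match:<10}"
                    f"{r.odds_ratio:>7.3f}{ci:>16}{r.p_value:>8.3f}"
                    f"{r.power:>8.3f}{r.fitness:>9.4f}")
            lines.append("")
        return "\n".join(lines)
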