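"""Association statistics for barcode 2x2 tables.

For a table with ``a`` matching cases, ``b`` non-matching cases, ``c`` matching
controls and ``d`` non-matching controls, the layer computes

* the odds ratio ``OR = ad / bc`` of case status in the barcode group relative
  to the Others group,
* the Wald confidence interval ``exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d))``,
* the uncorrected Pearson chi-square test on the 2x2 table (df = 1), and
* the post-hoc power of the two-sided two-proportion z-test at the observed
  matching proportions p_case = a/n_cases and p_ctrl = c/n_controls, with the
  pooled standard error under the null and the unpooled one under the
  alternative:

      power = Phi((|dp| - z*SE0)/SE1) + Phi((-|dp| - z*SE0)/SE1)

  where dp = p_ctrl - p_case, SE0 = sqrt(pbar(1-pbar)(1/n1 + 1/n2)) with the
  pooled proportion pbar, and SE1 = sqrt(p1(1-p1)/n1 + p2(1-p2)/n2).

No continuity correction and no multiple-testing adjustment are applied; the
exact normal quantile (not 1.96) is used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .barcode import ContingencyTable, SNPBarcode, contingency, fitness_from_table
from .exceptions import DegenerateTableError, ZeroCellError
from .genotypes import GenotypeDataset


def odds_ratio(table: ContingencyTable) -> float:
    """Odds ratio (a*d)/(b*c); raises :class:`ZeroCellError` if b or c is zero."""
    if table.b == 0 or table.c == 0:
        raise ZeroCellError(
            f"odds ratio undefined/infinite for table "
            f"({table.a},{table.b},{table.c},{table.d}): zero denominator cell")
    return (table.a * table.d) / (table.b * table.c)


def wald_ci(table: ContingencyTable, alpha: float = 0.05) -> Tuple[float, float]:
    """Wald confidence interval for the odds ratio at level 1 - alpha."""
    if min(table.a, table.b, table.c, table.d) == 0:
        raise ZeroCellError(
            f"Wald CI undefined for table with a zero cell "
            f"({table.a},{table.b},{table.c},{table.d})")
    z = sps.norm.ppf(1 - alpha / 2)
    log_or = math.log(odds_ratio(table))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def pearson_chi2(table: ContingencyTable) -> Tuple[float, float]:
    """Uncorrected Pearson chi-square statistic and p-value (df = 1)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise DegenerateTableError(
            f"chi-square undefined: zero margin in table ({a},{b},{c},{d})")
    chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(chi2), float(p)


def posthoc_power(table: ContingencyTable, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-sided two-proportion z-test at the observed
    matching proportions (see module docstring for the formula)."""
    n1, n2 = table.n_cases, table.n_controls
    if n1 == 0 or n2 == 0:
        raise DegenerateTableError("empty phenotype group")
    p1 = table.a / n1
    p2 = table.c / n2
    if p1 in (0.0, 1.0) and p2 in (0.0, 1.0):
        raise DegenerateTableError(
            f"power undefined at degenerate proportions p_case={p1}, p_ctrl={p2}")
    z = sps.norm.ppf(1 - alpha / 2)
    pbar = (table.a + table.c) / (n1 + n2)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if se1 == 0:
        raise DegenerateTableError("zero standard error under the alternative")
    diff = abs(p2 - p1)
    return float(sps.norm.cdf((diff - z * se0) / se1)
                 + sps.norm.cdf((-diff - z * se0) / se1))


@dataclass(frozen=True)
class AssocResult:
    """Full statistical record for one barcode (or single-SNP reference).

    Undefined statistics (zero cells / degenerate margins) are NaN when the
    record was built with ``on_degenerate="nan"``.
    """

    barcode: Union[SNPBarcode, str]
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    power: float
    fitness: float
    alpha: float = 0.05

    def to_dict(self) -> dict:
        bc = self.barcode
        return {
            "snps": "-".join(map(str, bc.snp_indices)) if isinstance(bc, SNPBarcode) else str(bc),
            "genotypes": "-".join(map(str, bc.genotype_codes)) if isinstance(bc, SNPBarcode) else "",
            "case_match": self.table.case_match,
            "case_other": self.table.case_other,
            "control_match": self.table.control_match,
            "control_other": self.table.control_other,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "chi2": self.chi2,
            "p_value": self.p_value,
            "power": self.power,
            "fitness": self.fitness,
        }


def evaluate_table(table: ContingencyTable,
                   barcode: Union[SNPBarcode, str],
                   alpha: float = 0.05,
                   direction: str = "protective",
                   on_degenerate: str = "raise") -> AssocResult:
    """Compose OR, Wald CI, chi-square, power and fitness for one 2x2 table.

    ``on_degenerate="nan"`` replaces undefined statistics with NaN instead of
    raising, which ranking and search loops use to tolerate zero-match models.
    """
    if on_degenerate not in ("raise", "nan"):
        raise ValueError("on_degenerate must be 'raise' or 'nan'")
    fit = fitness_from_table(table, direction=direction)
    values = {}
    for name, fn in (("or", lambda: odds_ratio(table)),
                     ("ci", lambda: wald_ci(table, alpha)),
                     ("chi2", lambda: pearson_chi2(table)),
                     ("power", lambda: posthoc_power(table, alpha))):
        try:
            values[name] = fn()
        except (ZeroCellError, DegenerateTableError):
            if on_degenerate == "raise":
                raise
            values[name] = None
    ci = values["ci"] or (math.nan, math.nan)
    chi2p = values["chi2"] or (math.nan, math.nan)
    return AssocResult(
        barcode=barcode, table=table,
        odds_ratio=values["or"] if values["or"] is not None else math.nan,
        ci_low=ci[0], ci_high=ci[1],
        chi2=chi2p[0], p_value=chi2p[1],
        power=values["power"] if values["power"] is not None else math.nan,
        fitness=fit, alpha=alpha)


def evaluate_barcode(dataset: GenotypeDataset, barcode: SNPBarcode,
                     alpha: float = 0.05, direction: str = "protective",
                     on_degenerate: str = "raise") -> AssocResult:
    """Evaluate one barcode against a dataset: 2x2 counts plus all statistics."""
    return evaluate_table(contingency(dataset, barcode), barcode,
                          alpha=alpha, direction=direction,
                          on_degenerate=on_degenerate)


def single_snp_table(dataset: GenotypeDataset, alpha: float = 0.05) -> List[AssocResult]:
    """Per-SNP association of the code-1 (homozygous-minor) class vs code 2."""
    out = []
    for j in range(1, dataset.n_snps + 1):
        gc = dataset.genotype_counts(j)
        table = ContingencyTable(case_match=gc.case_code1, case_other=gc.case_code2,
                                 control_match=gc.control_code1,
                                 control_other=gc.control_code2)
        label = dataset.snps[j - 1].label
        out.append(evaluate_table(table, barcode=label, alpha=alpha,
                                  on_degenerate="nan"))
    return out


def results_to_dataframe(results: List[AssocResult],
                         decimals: Optional[int] = 3) -> pd.DataFrame:
    """Tabulate results; rounded display columns plus full-precision twins."""
    df = pd.DataFrame([r.to_dict() for r in results])
    if decimals is not None:
        for col in ("odds_ratio", "ci_low", "ci_high", "chi2", "p_value",
                    "power", "fitness"):
            df[f"{col}_exact"] = df[col]
            df[col] = df[col].round(decimals)
    return df


def write_results_tsv(results: List[AssocResult], path: str,
                      decimals: Optional[int] = 3) -> None:
    results_to_dataframe(results, decimals=decimals).to_csv(path, sep="\t",
                                                            index=False)
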