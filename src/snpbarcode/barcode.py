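"""SNP barcodes, barcode matching and the frequency-difference fitness.

A SNP barcode is an ordered set of distinct SNPs, each paired with one
dichotomized genotype code (1 = homozygous-minor, 2 = merged major/het class).
An individual matches the barcode when every coded genotype is present. The
search objective ("fitness") is the barcode's matching frequency among
controls minus its matching frequency among cases, so that maximizing it
targets protective genotype combinations (odds ratio < 1 for case status).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .genotypes import GenotypeDataset


@dataclass(frozen=True)
class SNPBarcode:
    """Canonical barcode: strictly increasing 1-based SNP indices + codes."""

    snp_indices: Tuple[int, ...]
    genotype_codes: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_indices", tuple(int(i) for i in self.snp_indices))
        object.__setattr__(self, "genotype_codes",
                           tuple(int(c) for c in self.genotype_codes))
        if len(self.snp_indices) != len(self.genotype_codes):
            raise ValueError("snp_indices and genotype_codes length mismatch")
        if len(self.snp_indices) == 0:
            raise ValueError("empty barcode")
        if any(b <= a for a, b in zip(self.snp_indices, self.snp_indices[1:])):
            raise ValueError(f"snp_indices {self.snp_indices} must be strictly "
                             "increasing (canonical form)")
        if self.snp_indices[0] < 1:
            raise ValueError("SNP indices are 1-based")
        if any(c not in (1, 2) for c in self.genotype_codes):
            raise ValueError(f"genotype codes {self.genotype_codes} must be 1 or 2")

    @property
    def k(self) -> int:
        return len(self.snp_indices)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[int, int]]) -> "SNPBarcode":
        """Build the canonical barcode from possibly unsorted (snp, code) pairs."""
        ordered = sorted(pairs)
        return cls(tuple(p[0] for p in ordered), tuple(p[1] for p in ordered))

    @classmethod
    def parse(cls, text: str) -> "SNPBarcode":
        """Parse the serialized form ``"1-2/1-1"`` (SNPs / genotype codes)."""
        try:
            snp_part, code_part = text.split("/")
            snps = [int(t) for t in snp_part.split("-")]
            codes = [int(t) for t in code_part.split("-")]
        except ValueError as exc:
            raise ValueError(f"malformed barcode string {text!r}; expected "
                             "e.g. '1-2/1-1'") from exc
        if len(snps) != len(codes):
            raise ValueError(f"barcode string {text!r}: {len(snps)} SNPs but "
                             f"{len(codes)} genotype codes")
        return cls.from_pairs(zip(snps, codes))

    def __str__(self) -> str:
        return ("-".join(map(str, self.snp_indices)) + "/"
                + "-".join(map(str, self.genotype_codes)))

    def validate_against(self, n_snps: int) -> None:
        if self.snp_indices[-1] > n_snps:
            raise ValueError(f"barcode {self} references SNP "
                             f"{self.snp_indices[-1]} on a {n_snps}-SNP panel")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of (barcode match vs others) x (case vs control)."""

    case_match: int
    case_other: int
    control_match: int
    control_other: int

    def __post_init__(self) -> None:
        if min(self.case_match, self.case_other,
               self.control_match, self.control_other) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def a(self) -> int:
        return self.case_match

    @property
    def b(self) -> int:
        return self.case_other

    @property
    def c(self) -> int:
        return self.control_match

    @property
    def d(self) -> int:
        return self.control_other

    @property
    def n_cases(self) -> int:
        return self.case_match + self.case_other

    @property
    def n_controls(self) -> int:
        return self.control_match + self.control_other


def match_mask(dataset: GenotypeDataset, barcode: SNPBarcode) -> np.ndarray:
    """Boolean vector over individuals: True where the barcode matches."""
    barcode.validate_against(dataset.n_snps)
    cols = np.asarray(barcode.snp_indices) - 1
    codes = np.asarray(barcode.genotype_codes, dtype=dataset.codes.dtype)
    return (dataset.codes[:, cols] == codes).all(axis=1)


def matches(dataset: GenotypeDataset, barcode: SNPBarcode, individual: int) -> bool:
    """Whether one individual (0-based row) carries every coded genotype."""
    barcode.validate_against(dataset.n_snps)
    row = dataset.codes[individual]
    return all(row[i - 1] == c
               for i, c in zip(barcode.snp_indices, barcode.genotype_codes))


def contingency(dataset: GenotypeDataset, barcode: SNPBarcode) -> ContingencyTable:
    """2x2 counts of the barcode group vs the Others group by phenotype."""
    m = match_mask(dataset, barcode)
    a = int((m & dataset.is_case).sum())
    c = int((m & ~dataset.is_case).sum())
    return ContingencyTable(case_match=a, case_other=dataset.n_cases - a,
                            control_match=c, control_other=dataset.n_controls - c)


def fitness(dataset: GenotypeDataset, barcode: SNPBarcode,
            direction: str = "protective") -> float:
    """Control matching frequency minus case matching frequency, in [-1, 1].

    ``direction="risk"`` negates the value so that maximization targets
    barcodes enriched in cases instead.
    """
    t = contingency(dataset, barcode)
    value = t.control_match / t.n_controls - t.case_match / t.n_cases
    if direction == "protective":
        return value
    if direction == "risk":
        return -value
    raise ValueError(f"direction must be 'protective' or 'risk', got {direction!r}")


def fitness_from_table(t: ContingencyTable, direction: str = "protective") -> float:
    """Fitness recomputed from an existing 2x2 table."""
    value = t.control_match / t.n_controls - t.case_match / t.n_cases
    return value if direction == "protective" else -value
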