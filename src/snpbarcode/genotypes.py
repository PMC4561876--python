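"""Case-control genotype data model and I/O.

Genotypes are stored dichotomized: code 1 is the homozygous-minor ("recessive")
class, code 2 the merged homozygous-major/heterozygous ("dominant") class. In
minor-allele dosage terms the mapping is {2} -> 1 and {0, 1} -> 2. All loaders
enforce complete data: a row with a missing or unparseable cell is rejected, not
imputed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import GenotypeParseError

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class SNPInfo:
    """Per-SNP metadata: identifier and the allele pair behind the two codes.

    ``minor_allele``/``major_allele`` may be ``None`` when the input carried
    only numeric dosages; genotype class labels then fall back to the codes.
    """

    label: str
    minor_allele: Optional[str] = None
    major_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.minor_allele is not None and self.minor_allele == self.major_allele:
            raise ValueError(f"{self.label}: minor and major allele are both "
                             f"{self.minor_allele!r}")

    @property
    def recessive_genotype_label(self) -> str:
        """Label of the code-1 class, e.g. ``"TT"`` for minor allele T."""
        if self.minor_allele is None:
            return "1"
        return self.minor_allele * 2

    @property
    def dominant_genotype_label(self) -> str:
        """Label of the merged code-2 class, e.g. ``"GG/GT"``."""
        if self.minor_allele is None or self.major_allele is None:
            return "2"
        return f"{self.major_allele * 2}/{self.major_allele}{self.minor_allele}"


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-phenotype counts of the two genotype classes at one SNP."""

    case_code1: int
    case_code2: int
    control_code1: int
    control_code2: int


@dataclass
class GenotypeDataset:
    """Individuals x SNPs matrix of dichotomized codes with binary phenotype.

    Parameters
    ----------
    codes
        Integer matrix, one row per individual, entries in {1, 2}.
    is_case
        Boolean vector, True for cases.
    snps
        Ordered SNP metadata, one entry per column of ``codes``.
    """

    codes: np.ndarray
    is_case: np.ndarray
    snps: Sequence[SNPInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if not self.snps:
            self.snps = [SNPInfo(label=f"SNP{j + 1}") for j in range(self.codes.shape[1])]
        if len(self.snps) != self.codes.shape[1]:
            raise ValueError("snps metadata length does not match matrix width")
        if self.is_case.shape != (self.codes.shape[0],):
            raise ValueError("phenotype length does not match number of individuals")
        bad = ~np.isin(self.codes, (1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"genotype code at row {i}, column {j} is "
                             f"{self.codes[i, j]}; codes must be 1 or 2")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("dataset needs at least one case and one control")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    @property
    def snp_labels(self) -> list[str]:
        return [s.label for s in self.snps]

    def genotype_counts(self, snp_index: int) -> GenotypeCounts:
        """Counts of code 1/2 per phenotype at a SNP (1-based index)."""
        if not 1 <= snp_index <= self.n_snps:
            raise IndexError(f"snp_index {snp_index} out of range 1..{self.n_snps}")
        col = self.codes[:, snp_index - 1]
        case1 = int(((col == 1) & self.is_case).sum())
        ctrl1 = int(((col == 1) & ~self.is_case).sum())
        return GenotypeCounts(
            case_code1=case1,
            case_code2=self.n_cases - case1,
            control_code1=ctrl1,
            control_code2=self.n_controls - ctrl1,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Code matrix plus phenotype column as a DataFrame."""
        df = pd.DataFrame(self.codes, columns=self.snp_labels)
        df["phenotype"] = np.where(self.is_case, CASE, CONTROL)
        return df


def dichotomize_dosage(dosage: np.ndarray) -> np.ndarray:
    """Map minor-allele dosage {0,1,2} to codes: 2 -> 1 (recessive), 0/1 -> 2."""
    dosage = np.asarray(dosage)
    if not np.isin(dosage, (0, 1, 2)).all():
        raise GenotypeParseError("dosage values must be 0, 1 or 2")
    return np.where(dosage == 2, 1, 2).astype(np.int8)


def genotype_counts(dataset: GenotypeDataset, snp_index: int) -> GenotypeCounts:
    """Module-level alias of :meth:`GenotypeDataset.genotype_counts`."""
    return dataset.genotype_counts(snp_index)


def _resolve_delimiter(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_phenotype(values: pd.Series, case_label: str,
                     control_label: Optional[str]) -> np.ndarray:
    labels = set(values.astype(str))
    if case_label not in labels:
        raise GenotypeParseError(f"no row carries the case label {case_label!r}")
    others = labels - {case_label}
    if control_label is None:
        if len(others) != 1:
            raise GenotypeParseError(
                f"cannot infer control label: phenotype column contains {sorted(labels)}")
        control_label = others.pop()
    else:
        unknown = others - {control_label}
        if unknown:
            raise GenotypeParseError(f"unknown phenotype label(s) {sorted(unknown)}")
    return (values.astype(str) == case_label).to_numpy()


def _column_is_dosage(col: pd.Series) -> bool:
    try:
        as_int = col.astype(int)
    except (ValueError, TypeError):
        return False
    return bool(as_int.isin([0, 1, 2]).all())


def _parse_allele_column(col: pd.Series, label: str,
                         minor_override: Optional[str]) -> tuple[np.ndarray, SNPInfo]:
    cells = col.astype(str).str.strip().str.upper()
    if not cells.str.fullmatch(r"[ACGT]{2}").all():
        bad = cells.index[~cells.str.fullmatch(r"[ACGT]{2}").fillna(False)][0]
        raise GenotypeParseError(
            f"column {label!r}, row {bad}: cell {col.loc[bad]!r} is not an allele pair")
    allele_counts: dict[str, int] = {}
    for pair in cells:
        for a in pair:
            allele_counts[a] = allele_counts.get(a, 0) + 1
    # two most frequent alleles define the locus; ties broken lexicographically
    ranked = sorted(allele_counts, key=lambda a: (-allele_counts[a], a))
    observed = ranked[:2]
    for idx, pair in cells.items():
        for a in pair:
            if a not in observed:
                raise GenotypeParseError(
                    f"column {label!r}, row {idx}: allele {a!r} outside the "
                    f"SNP's two observed alleles {observed}")
    if len(ranked) == 1:
        if minor_override is None:
            raise GenotypeParseError(
                f"column {label!r} is monomorphic ({ranked[0]}); supply the minor "
                "allele explicitly via minor_alleles")
        if minor_override == ranked[0]:
            minor, major = minor_override, "?"
        else:
            minor, major = minor_override, ranked[0]
    else:
        if minor_override is not None:
            if minor_override not in observed:
                raise GenotypeParseError(
                    f"column {label!r}: minor-allele override {minor_override!r} "
                    f"not among observed alleles {observed}")
            minor = minor_override
        else:
            # less frequent allele; lexicographic on ties
            minor = min(observed, key=lambda a: (allele_counts[a], a))
        major = next(a for a in observed if a != minor)
    dosage = cells.map(lambda pair: sum(a == minor for a in pair)).to_numpy()
    return dichotomize_dosage(dosage), SNPInfo(label=label, minor_allele=minor,
                                               major_allele=major)


def read_genotype_table(path: str, phenotype_column: str = "phenotype",
                        case_label: str = CASE,
                        control_label: Optional[str] = None,
                        delimiter: Optional[str] = None,
                        minor_alleles: Optional[Mapping[str, str]] = None,
                        ) -> GenotypeDataset:
    """Load a delimited genotype table into a :class:`GenotypeDataset`.

    The table has a header row of SNP labels plus one phenotype column, one
    row per individual. Genotype cells are either allele-pair strings
    ("GT", "TT", ...) or minor-allele dosages 0/1/2; the dialect is detected
    per column. The minor allele is inferred as the less frequent allele over
    all individuals (ties broken lexicographically) unless overridden through
    ``minor_alleles`` (label -> allele).
    """
    if not os.path.exists(path):
        raise GenotypeParseError(f"no such file: {path}")
    sep = _resolve_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise GenotypeParseError(f"{path}: empty file") from exc
    if df.empty:
        raise GenotypeParseError(f"{path}: no data rows")
    if phenotype_column not in df.columns:
        raise GenotypeParseError(f"{path}: missing phenotype column "
                                 f"{phenotype_column!r}")
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0])
        raise GenotypeParseError(f"{path}: incomplete row {row} (missing cell); "
                                 "complete data required")
    is_case = _parse_phenotype(df[phenotype_column], case_label, control_label)
    minor_alleles = dict(minor_alleles or {})
    columns, snps = [], []
    for label in df.columns:
        if label == phenotype_column:
            continue
        col = df[label]
        if _column_is_dosage(col):
            columns.append(dichotomize_dosage(col.astype(int).to_numpy()))
            snps.append(SNPInfo(label=label))
        else:
            codes, info = _parse_allele_column(col, label, minor_alleles.get(label))
            columns.append(codes)
            snps.append(info)
    if not columns:
        raise GenotypeParseError(f"{path}: no genotype columns")
    return GenotypeDataset(codes=np.column_stack(columns), is_case=is_case, snps=snps)


def write_genotype_table(dataset: GenotypeDataset, path: str,
                         fmt: str = "dosage",
                         delimiter: Optional[str] = None) -> None:
    """Write a dataset as a delimited genotype table.

    ``fmt="dosage"`` writes code 1 as dosage 2 and code 2 as dosage 0, which
    round-trips the code matrix exactly regardless of allele frequencies.
    ``fmt="alleles"`` writes the homozygous-minor and homozygous-major
    genotype strings (requires allele metadata).
    """
    sep = _resolve_delimiter(path, delimiter)
    df = pd.DataFrame(index=range(dataset.n_individuals))
    for j, info in enumerate(dataset.snps):
        col = dataset.codes[:, j]
        if fmt == "dosage":
            df[info.label] = np.where(col == 1, 2, 0)
        elif fmt == "alleles":
            if info.minor_allele is None or info.major_allele is None:
                raise ValueError(f"{info.label}: allele metadata required for "
                                 "allele-string output")
            df[info.label] = np.where(col == 1, info.minor_allele * 2,
                                      info.major_allele * 2)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    df["phenotype"] = np.where(dataset.is_case, CASE, CONTROL)
    df.to_csv(path, sep=sep, index=False)


def _load_phenotype_map(phenotype_map) -> dict[str, str]:
    if isinstance(phenotype_map, Mapping):
        return dict(phenotype_map)
    mapping: dict[str, str] = {}
    with open(phenotype_map) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GenotypeParseError(
                    f"phenotype map line {line!r}: expected 'sample label'")
            mapping[parts[0]] = parts[1]
    return mapping


def read_vcf_with_phenotypes(vcf_path: str, phenotype_map,
                             case_label: str = CASE,
                             control_label: Optional[str] = None,
                             ) -> GenotypeDataset:
    """Load genotypes from a VCF plus a sample -> phenotype mapping.

    Sites must be biallelic with no missing GT (no-missing-data policy). The
    ALT allele is taken as the minor allele, so GT dosage of ALT maps to the
    codes exactly as in :func:`read_genotype_table`; SNP labels come from the
    ID column (falling back to CHROM:POS).
    """
    import pysam

    mapping = _load_phenotype_map(phenotype_map)
    with pysam.VariantFile(vcf_path) as vcf:
        samples = list(vcf.header.samples)
        missing = [s for s in samples if s not in mapping]
        if missing:
            raise GenotypeParseError(
                f"sample(s) absent from phenotype map: {missing}")
        columns, snps = [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeParseError(
                    f"site {rec.chrom}:{rec.pos} is not biallelic")
            dosages = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    raise GenotypeParseError(
                        f"missing genotype for sample {s} at {rec.chrom}:{rec.pos}")
                dosages.append(sum(1 for a in gt if a == 1))
            label = rec.id or f"{rec.chrom}:{rec.pos}"
            columns.append(dichotomize_dosage(np.asarray(dosages)))
            snps.append(SNPInfo(label=label, minor_allele=str(rec.alts[0]),
                                major_allele=str(rec.ref)))
    if not columns:
        raise GenotypeParseError(f"{vcf_path}: no variant records")
    labels = pd.Series([mapping[s] for s in samples])
    is_case = _parse_phenotype(labels, case_label, control_label)
    return GenotypeDataset(codes=np.column_stack(columns), is_case=is_case, snps=snps)


def write_vcf(dataset: GenotypeDataset, path: str,
              sample_names: Optional[Iterable[str]] = None) -> None:
    """Write a minimal VCF 4.2 text twin of the dataset (code 1 -> 1/1, 2 -> 0/0)."""
    names = list(sample_names) if sample_names is not None else [
        f"IND{i + 1}" for i in range(dataset.n_individuals)]
    if len(names) != dataset.n_individuals:
        raise ValueError("sample_names length mismatch")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j, info in enumerate(dataset.snps):
            ref = info.major_allele or "A"
            alt = info.minor_allele or "C"
            gts = ["1/1" if c == 1 else "0/0" for c in dataset.codes[:, j]]
            fh.write(f"1\t{j + 1}\t{info.label}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_phenotype_map(dataset: GenotypeDataset, path: str,
                        sample_names: Optional[Iterable[str]] = None) -> list[str]:
    """Write the two-column sample/phenotype companion file; returns the names."""
    names = list(sample_names) if sample_names is not None else [
        f"IND{i + 1}" for i in range(dataset.n_individuals)]
    with open(path, "w") as fh:
        for name, case in zip(names, dataset.is_case):
            fh.write(f"{name}\t{CASE if case else CONTROL}\n")
    return names
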