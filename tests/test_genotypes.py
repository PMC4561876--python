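"""Genotype data model and I/O: dichotomization, parsing, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpbarcode import (GenotypeDataset, GenotypeParseError, SNPInfo,
                        read_genotype_table, read_vcf_with_phenotypes,
                        write_genotype_table)
from snpbarcode.genotypes import (dichotomize_dosage, write_phenotype_map,
                                  write_vcf)
from snpbarcode.simulate import PlantSpec, generate_dataset


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


class TestDichotomization:
    def test_dosage_mapping(self):
        np.testing.assert_array_equal(
            dichotomize_dosage(np.array([0, 1, 2, 2, 0])),
            np.array([2, 2, 1, 1, 2]))

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_pure_function_of_dosage(self, dosages):
        codes = dichotomize_dosage(np.array(dosages))
        assert all((c == 1) == (d == 2) for c, d in zip(codes, dosages))

    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(GenotypeParseError):
            dichotomize_dosage(np.array([0, 3]))


class TestReadGenotypeTable:
    def test_allele_pair_toy_file(self, tmp_path):
        # minor allele inferred from pooled counts: T appears 3 times, G 5
        p = tmp_path / "toy.tsv"
        write_lines(p, ["snpA\tphenotype", "TT\tcase", "GT\tcase",
                        "GG\tcontrol", "GG\tcontrol"])
        ds = read_genotype_table(p)
        assert ds.snps[0].minor_allele == "T"
        np.testing.assert_array_equal(ds.codes[:, 0], [1, 2, 2, 2])
        assert ds.n_cases == 2 and ds.n_controls == 2

    def test_minor_allele_override_flips_codes(self, tmp_path):
        p = tmp_path / "toy.tsv"
        write_lines(p, ["snpA\tphenotype", "TT\tcase", "TT\tcase",
                        "GT\tcontrol", "GG\tcontrol"])
        ds = read_genotype_table(p, minor_alleles={"snpA": "G"})
        np.testing.assert_array_equal(ds.codes[:, 0], [2, 2, 2, 1])

    def test_case_count_from_label(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_lines(p, ["s1\tphenotype", "0\tcase", "1\tcase", "2\tcontrol"])
        ds = read_genotype_table(p, case_label="case")
        assert ds.n_cases == 2

    def test_dosage_dialect(self, tmp_path):
        p = tmp_path / "t.csv"
        write_lines(p, ["s1,phenotype", "2,case", "1,case", "0,control"])
        ds = read_genotype_table(p)
        np.testing.assert_array_equal(ds.codes[:, 0], [1, 2, 2])

    def test_unknown_phenotype_label_errors(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_lines(p, ["s1\tphenotype", "TT\tcase", "GT\tweird", "GG\tcontrol"])
        with pytest.raises(GenotypeParseError, match="weird"):
            read_genotype_table(p, case_label="case", control_label="control")

    def test_third_allele_errors_with_location(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_lines(p, ["s1\tphenotype", "TT\tcase", "GT\tcase", "GG\tcontrol",
                        "GA\tcontrol", "GT\tcontrol", "TT\tcase"])
        with pytest.raises(GenotypeParseError, match="s1"):
            read_genotype_table(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(GenotypeParseError):
            read_genotype_table(p)

    def test_missing_cell_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_lines(p, ["s1\ts2\tphenotype", "TT\tGG\tcase", "GT\t\tcontrol"])
        with pytest.raises(GenotypeParseError, match="incomplete"):
            read_genotype_table(p)


class TestRoundTrip:
    def test_table_round_trip_identity(self, tmp_path, random_dataset):
        ds = random_dataset(seed=5)
        p = tmp_path / "rt.tsv"
        write_genotype_table(ds, p)
        back = read_genotype_table(p)
        np.testing.assert_array_equal(back.codes, ds.codes)
        np.testing.assert_array_equal(back.is_case, ds.is_case)

    def test_vcf_and_table_twins_agree(self, tmp_path):
        spec = PlantSpec(n_cases=30, n_controls=30,
                         snp_code1_freqs=[(0.3, 0.3)] * 5, seed=11)
        ds = generate_dataset(spec)
        tsv, vcf, pmap = (tmp_path / "d.tsv", tmp_path / "d.vcf",
                          tmp_path / "d.pheno")
        write_genotype_table(ds, tsv)
        names = write_phenotype_map(ds, pmap)
        write_vcf(ds, vcf, sample_names=names)
        from_tsv = read_genotype_table(tsv)
        from_vcf = read_vcf_with_phenotypes(vcf, pmap)
        np.testing.assert_array_equal(from_tsv.codes, from_vcf.codes)
        np.testing.assert_array_equal(from_tsv.is_case, from_vcf.is_case)


class TestVCF:
    def _write_vcf(self, path, body):
        header = ("##fileformat=VCFv4.2\n##contig=<ID=1>\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n')
        path.write_text(header + body)

    def test_gt_translation(self, tmp_path):
        p = tmp_path / "m.vcf"
        self._write_vcf(p, "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
                           "1\t1\trs1\tG\tT\t.\tPASS\t.\tGT\t1/1\t0/1\n")
        ds = read_vcf_with_phenotypes(p, {"A": "case", "B": "control"})
        np.testing.assert_array_equal(ds.codes[:, 0], [1, 2])
        assert ds.snps[0].label == "rs1"

    def test_sample_missing_from_map_errors(self, tmp_path):
        p = tmp_path / "m.vcf"
        self._write_vcf(p, "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
                           "1\t1\trs1\tG\tT\t.\tPASS\t.\tGT\t1/1\t0/1\n")
        with pytest.raises(GenotypeParseError, match="B"):
            read_vcf_with_phenotypes(p, {"A": "case"})

    def test_missing_gt_errors(self, tmp_path):
        p = tmp_path / "m.vcf"
        self._write_vcf(p, "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
                           "1\t1\trs1\tG\tT\t.\tPASS\t.\tGT\t./.\t0/1\n")
        with pytest.raises(GenotypeParseError, match="missing"):
            read_vcf_with_phenotypes(p, {"A": "case", "B": "control"})

    def test_multiallelic_errors(self, tmp_path):
        p = tmp_path / "m.vcf"
        self._write_vcf(p, "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
                           "1\t1\trs1\tG\tT,C\t.\tPASS\t.\tGT\t1/1\t0/2\n")
        with pytest.raises(GenotypeParseError, match="biallelic"):
            read_vcf_with_phenotypes(p, {"A": "case", "B": "control"})


class TestGenotypeCounts:
    def test_fixture_marginals_match_published(self, fixture_dataset):
        expected = [(67, 71), (20, 29), (55, 51), (35, 43), (33, 28)]
        for j, (case1, ctrl1) in enumerate(expected, start=1):
            gc = fixture_dataset.genotype_counts(j)
            assert (gc.case_code1, gc.control_code1) == (case1, ctrl1)

    def test_counts_partition_group_sizes(self, random_dataset):
        ds = random_dataset(seed=2)
        for j in range(1, ds.n_snps + 1):
            gc = ds.genotype_counts(j)
            assert gc.case_code1 + gc.case_code2 == ds.n_cases
            assert gc.control_code1 + gc.control_code2 == ds.n_controls

    def test_index_out_of_range(self, random_dataset):
        with pytest.raises(IndexError):
            random_dataset().genotype_counts(0)
        with pytest.raises(IndexError):
            random_dataset().genotype_counts(99)

    def test_planted_frequency_recovered(self):
        spec = PlantSpec(n_cases=100, n_controls=10_000,
                         snp_code1_freqs=[(0.5, 0.2)], seed=7)
        ds = generate_dataset(spec)
        gc = ds.genotype_counts(1)
        assert abs(gc.control_code1 / 10_000 - 0.2) < 0.01


class TestInvariants:
    def test_codes_outside_1_2_rejected(self):
        with pytest.raises(ValueError, match="1 or 2"):
            GenotypeDataset(codes=np.array([[1, 3]]),
                            is_case=np.array([True]))

    def test_needs_both_phenotype_groups(self):
        with pytest.raises(ValueError):
            GenotypeDataset(codes=np.ones((3, 2), dtype=int),
                            is_case=np.ones(3, dtype=bool))

    def test_snpinfo_labels(self):
        info = SNPInfo("rs1", minor_allele="T", major_allele="G")
        assert info.recessive_genotype_label == "TT"
        assert info.dominant_genotype_label == "GG/GT"

    def test_snpinfo_rejects_equal_alleles(self):
        with pytest.raises(ValueError):
            SNPInfo("rs1", minor_allele="T", major_allele="T")
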