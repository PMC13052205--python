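import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divscan.formats import (
    MISSING,
    FormatError,
    GenomicInterval,
    read_bed,
    read_gff3_genes,
    read_popmap,
    read_table,
    read_vcf,
    write_bed,
    write_table,
    write_vcf,
)
from .conftest import make_matrix

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##contig=<ID=chrX,length=50000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def write_text_vcf(path, body, header=VCF_HEADER):
    path.write_text(header + body)
    return path


class TestReadVcf:
    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t60\tPASS\t.\tGT\t0/0\t0/1\n"
            "chr1\t200\t.\tA\tG,T\t60\tPASS\t.\tGT\t0/1\t1/2\n"
            "chr1\t300\t.\tAT\tA\t60\tPASS\t.\tGT\t0/1\t0/0\n"
            "chr1\t400\t.\tC\tT\t60\tPASS\t.\tGT\t1/1\t0/0\n"
        )
        m = read_vcf(write_text_vcf(tmp_path / "a.vcf", body))
        assert (m.n_sites, m.n_samples) == (2, 2)
        assert m.ingest_counts["multiallelic"] == 1
        assert m.ingest_counts["indel"] == 1
        assert list(m.sites["pos"]) == [100, 400]

    def test_missing_and_half_missing_coded_missing(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t60\tPASS\t.\tGT\t./.\t0/1\n"
            "chr1\t200\t.\tA\tG\t60\tPASS\t.\tGT\t./1\t0|1\n"
        )
        m = read_vcf(write_text_vcf(tmp_path / "a.vcf", body))
        assert m.calls[0, 0] == MISSING
        assert m.calls[0, 1] == 1
        assert m.calls[1, 0] == MISSING  # half-missing
        assert m.calls[1, 1] == 1  # phased separator ignored

    def test_all_sites_input_keeps_invariant_records(self, tmp_path):
        lines = [
            f"chr1\t{100 + 10 * i}\t.\tA\t.\t60\tPASS\t.\tGT\t0/0\t0/0\n" for i in range(8)
        ]
        lines += [
            "chr1\t500\t.\tA\tG\t60\tPASS\t.\tGT\t0/1\t1/1\n",
            "chr1\t600\t.\tC\tT\t60\tPASS\t.\tGT\t0/0\t0/1\n",
        ]
        m = read_vcf(write_text_vcf(tmp_path / "a.vcf", "".join(sorted(lines, key=lambda s: int(s.split("\t")[1])))))
        assert m.n_sites == 10
        assert int(m.sites["is_variant"].sum()) == 2
        # invariant rows: all non-missing calls are hom-ref
        inv = m.calls[~m.sites["is_variant"].to_numpy()]
        assert set(np.unique(inv)) <= {0, MISSING}

    def test_region_and_chromosome_exclusion(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t60\tPASS\t.\tGT\t0/0\t0/1\n"
            "chr1\t250\t.\tA\tG\t60\tPASS\t.\tGT\t0/1\t0/1\n"
            "chrX\t100\t.\tA\tG\t60\tPASS\t.\tGT\t0/1\t0/1\n"
        )
        path = write_text_vcf(tmp_path / "a.vcf", body)
        m = read_vcf(path, exclude_chroms=["chrX"])
        assert list(m.sites["chrom"].unique()) == ["chr1"]
        assert m.ingest_counts["excluded_chrom"] == 1
        m2 = read_vcf(path, region=GenomicInterval("chr1", 0, 200))
        assert list(m2.sites["pos"]) == [100]

    def test_vcf_without_gt_rejected(self, tmp_path):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        )
        path = write_text_vcf(tmp_path / "a.vcf", "", header=header)
        with pytest.raises(FormatError, match="GT"):
            read_vcf(path)

    def test_write_read_roundtrip(self, tmp_path, rng):
        calls = rng.integers(-1, 3, size=(30, 4)).astype(np.int8)
        is_variant = rng.random(30) < 0.7
        calls[~is_variant] = np.where(calls[~is_variant] == MISSING, MISSING, 0)
        m = make_matrix(calls, is_variant=is_variant)
        write_vcf(m, tmp_path / "rt.vcf")
        back = read_vcf(tmp_path / "rt.vcf")
        assert np.array_equal(back.calls, m.calls)
        assert list(back.sites["pos"]) == list(m.sites["pos"])
        assert list(back.sites["is_variant"]) == list(m.sites["is_variant"])


class TestPopmap:
    def test_study_design_sizes(self, tmp_path):
        rows = [f"G{i}\tGLG" for i in range(1, 8)] + ["wls1\tWL", "wls2\tWL"]
        path = tmp_path / "popmap.tsv"
        path.write_text("\n".join(rows) + "\n")
        pm = read_popmap(path)
        assert len(pm.samples_of("GLG")) == 7
        assert len(pm.samples_of("WL")) == 2
        # order invariance
        path.write_text("\n".join(rows[::-1]) + "\n")
        assert read_popmap(path).assignments == pm.assignments

    def test_empty_and_duplicate_rejected(self, tmp_path):
        path = tmp_path / "popmap.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_popmap(path)
        path.write_text("A\tpop1\nA\tpop2\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_popmap(path)

    def test_two_population_contract(self, two_pop_map):
        assert two_pop_map.require_two() == ("GLG", "WL")
        with pytest.raises(ValueError):
            two_pop_map.validate_against(["G1", "stranger"])


GFF = """##gff-version 3
chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=m1;Parent=g1
chr1\tsrc\texon\t1\t50\t.\t+\t.\tParent=m1
chr1\tsrc\tgene\t201\t300\t.\t-\t.\tID=g2
chr2\tsrc\tgene\t51\t150\t.\t+\t.\tID=g3
"""


class TestGff3:
    def test_gene_extraction_and_coordinate_conversion(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF)
        genes = read_gff3_genes(path)
        assert [g.gene_id for g in genes] == ["g1", "g2", "g3"]
        # GFF3 1..100 -> half-open [0, 100)
        assert (genes[0].interval.start, genes[0].interval.end) == (0, 100)
        assert genes[1].strand == "-"

    def test_malformed_coordinates_name_the_line(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("chr1\ts\tgene\t100\t50\t.\t+\t.\tID=g1\n")
        with pytest.raises(FormatError, match=":1"):
            read_gff3_genes(path)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.gff3"
        path.write_text(
            "chr1\ts\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr1\ts\tgene\t20\t30\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_gff3_genes(path)


class TestBedAndTables:
    def test_bed_roundtrip_identity(self, tmp_path):
        regions = [
            GenomicInterval("chr1", 0, 50_000),
            GenomicInterval("chr2", 100, 250),
            GenomicInterval("chr1", 60_000, 70_000),
        ]
        path = tmp_path / "r.bed"
        write_bed(regions, path)
        assert path.read_text().splitlines()[0] == "chr1\t0\t50000"
        assert read_bed(path) == sorted(regions)

    def test_empty_region_list(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed([], path)
        assert path.read_text() == ""

    def test_table_roundtrip_full_precision(self, tmp_path, rng):
        df = pd.DataFrame({"x": rng.random(5), "name": list("abcde"), "k": [1, 2, 3, 4, 5]})
        path = tmp_path / "t.tsv"
        write_table(df, path)
        back = read_table(path)
        np.testing.assert_allclose(back["x"], df["x"], rtol=1e-12)
        assert list(back["name"]) == list(df["name"])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(pos=st.integers(1, 1000), start=st.integers(0, 900), size=st.integers(1, 200))
def test_vcf_position_window_convention(pos, start, size):
    """A SNP at 1-based pos p lies in half-open window [s, e) iff s <= p-1 < e."""
    end = start + size
    w = GenomicInterval("chr1", start, end)
    assert w.contains_pos(pos - 1) == (start <= pos - 1 < end)
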