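"""VCF/BED normalization, allele counting, binning and ingestion."""

import gzip

import pytest

import fedvar
from fedvar.errors import (
    DuplicateTableError,
    IngestError,
    RowValidationError,
    VcfParseError,
)
from fedvar.synthetic_data import FIXTURE_EXPECTED_COUNTS, FIXTURE_VARIANTS


class TestNormalizeVcfRecord:
    def test_one_based_pos_maps_to_zero_based_half_open(self):
        records = fedvar.normalize_vcf_record(
            ["12", "112241766", "rs671", "G", "A"]
        )
        assert len(records) == 1
        (rec,) = records
        assert (rec.start_position, rec.end_position) == (112241765, 112241766)
        assert rec.rsid == "rs671"

    def test_multiallelic_site_splits_per_alternate(self):
        records = fedvar.normalize_vcf_record(["1", "100", ".", "AT", "A,ATT"])
        assert [r.alternate_bases for r in records] == ["A", "ATT"]
        assert all(r.start_position == 99 and r.end_position == 101
                   for r in records)
        assert all(r.rsid is None for r in records)

    def test_monomorphic_alt_dot_yields_empty_list(self):
        assert fedvar.normalize_vcf_record(["1", "1", ".", "A", "."]) == []

    @pytest.mark.parametrize("fields", [
        ["1", "0", ".", "A", "T"],
        ["1", "-5", ".", "A", "T"],
        ["1", "x", ".", "A", "T"],
        ["1", "10", ".", "", "T"],
        ["1", "10", ".", "A", ""],
    ])
    def test_malformed_lines_raise_naming_the_line(self, fields):
        with pytest.raises(VcfParseError, match="line 42"):
            fedvar.normalize_vcf_record(fields, line_number=42)

    def test_ac_an_from_genotype_columns(self):
        records = fedvar.normalize_vcf_record(
            ["1", "10", ".", "A", "T", ".", "PASS", ".", "GT",
             "0/1", "1/1", "0/0"]
        )
        assert (records[0].ac, records[0].an) == (3, 6)

    def test_ac_an_from_info_when_no_genotypes(self):
        records = fedvar.normalize_vcf_record(
            ["1", "10", ".", "A", "T,G", ".", "PASS", "AC=5,2;AN=20"]
        )
        assert [(r.ac, r.an) for r in records] == [(5, 20), (2, 20)]

    def test_no_counts_available_defaults_to_zero(self):
        (rec,) = fedvar.normalize_vcf_record(
            ["1", "10", ".", "A", "T", ".", "PASS", "DP=10"]
        )
        assert (rec.ac, rec.an) == (0, 0)

    def test_passthrough_fields_preserved_in_extra(self):
        (rec,) = fedvar.normalize_vcf_record(
            ["1", "10", "rs1", "A", "T", "50", "PASS", "DP=3", "GT",
             "0/1", "0/0"],
            sample_names=["X", "Y"], keep_genotypes=True,
        )
        assert rec.extra["QUAL"] == "50"
        assert rec.extra["FILTER"] == "PASS"
        assert rec.extra["INFO"] == "DP=3"
        assert rec.extra["X"] == "0/1" and rec.extra["Y"] == "0/0"


class TestComputeAcAn:
    @pytest.mark.parametrize("genotypes, alt_index, expected", [
        (["0/1", "1/1", "0/0"], 1, (3, 6)),
        (["./.", "0/1"], 1, (1, 2)),
        (["0/2", "1/2", "2/2"], 2, (4, 6)),
        (["0|1", "1|1"], 1, (3, 4)),       # phased bar treated like slash
        (["./1", "0/0"], 1, (1, 3)),        # half-call: called allele counts
    ])
    def test_counts(self, genotypes, alt_index, expected):
        assert fedvar.compute_ac_an(genotypes, alt_index) == expected

    @pytest.mark.parametrize("bad", [["0"], ["0/1/1"]])
    def test_non_diploid_rejected_naming_sample(self, bad):
        with pytest.raises(ValueError, match="sample 1"):
            fedvar.compute_ac_an(["0/0"] + bad, 1)


class TestAssignBin:
    @pytest.mark.parametrize("start, width, expected", [
        (0, 62_500, 0),
        (62_500, 62_500, 1),          # left-closed boundary
        (62_499, 62_500, 0),
        (112241765, 62_500, 112241765 // 62_500),  # == 1795
    ])
    def test_floor_division(self, start, width, expected):
        assert fedvar.assign_bin(start, width) == expected

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            fedvar.assign_bin(0, 0)


class TestIngestVcf:
    def test_fixture_ingest_counts_and_bins(self, ingested_fixture):
        _fed, platform, handle = ingested_fixture
        assert handle.row_count == 4
        assert handle.bin_width == 62_500
        rows = fedvar.export_rows(platform, handle.table_name)
        for row in rows:
            assert row["bin_id"] == row["start_position"] // 62_500

    def test_header_only_vcf_gives_empty_table(self, federation, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text("##fileformat=VCFv4.2\n"
                        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        handle = fedvar.ingest_vcf(str(path), federation.platform("gcp_like"),
                                   "empty_table")
        assert handle.row_count == 0

    def test_triallelic_site_splits_into_two_rows(self, federation, tmp_path):
        path = tmp_path / "tri.vcf"
        path.write_text("##fileformat=VCFv4.2\n"
                        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                        "1\t100\trsX\tA\tT,G\t.\tPASS\tAC=1,2;AN=10\n")
        handle = fedvar.ingest_vcf(str(path), federation.platform("gcp_like"),
                                   "tri_table", keep_genotypes=False)
        assert handle.row_count == 2

    def test_duplicate_table_name_rejected(self, ingested_fixture, fixture_vcf):
        _fed, platform, handle = ingested_fixture
        with pytest.raises(DuplicateTableError):
            fedvar.ingest_vcf(fixture_vcf, platform, handle.table_name)

    def test_missing_file_rejected(self, federation):
        with pytest.raises(IngestError):
            fedvar.ingest_vcf("/nonexistent.vcf",
                              federation.platform("gcp_like"), "nope")

    def test_gzip_vcf_readable(self, federation, fixture_vcf, tmp_path):
        gz = tmp_path / "fixture.vcf.gz"
        gz.write_bytes(gzip.compress(open(fixture_vcf, "rb").read()))
        handle = fedvar.ingest_vcf(str(gz), federation.platform("aws_like"),
                                   "gz_table")
        assert handle.row_count == 4

    def test_round_trip_preserves_vcf_tuples(self, ingested_fixture):
        """Export reproduces every (chrom, POS, ID, REF, ALT) of the input."""
        _fed, platform, handle = ingested_fixture
        rows = fedvar.export_rows(platform, handle.table_name)
        got = {(r["chromosome_name"], r["start_position"] + 1, r["rsid"],
                r["reference_bases"], r["alternate_bases"]) for r in rows}
        want = {(chrom, pos, rsid, ref, alt)
                for _d, rsid, chrom, pos, ref, alt in FIXTURE_VARIANTS}
        assert got == want

    def test_fixture_allele_counts(self, ingested_fixture):
        _fed, platform, handle = ingested_fixture
        rows = fedvar.export_rows(platform, handle.table_name)
        got = {r["rsid"]: (r["ac"], r["an"]) for r in rows}
        assert got == FIXTURE_EXPECTED_COUNTS

    def test_partition_counts_sum_to_row_count(self, federation, tmp_path):
        spec = fedvar.SimSpec(n_samples=4, n_variants=300, seed=11)
        vcf, _ = fedvar.simulate_cohort(spec, tmp_path)
        platform = federation.platform("gcp_like")
        handle = fedvar.ingest_vcf(vcf, platform, "cohort", bin_width=10_000)
        stats = platform.conn.execute(
            "SELECT SUM(row_count) FROM _partition_stats WHERE table_name=?",
            ("cohort",)).fetchone()
        assert stats[0] == handle.row_count == 300

    def test_ac_an_match_cyvcf2(self, tmp_path):
        """Independent oracle: cyvcf2's per-site counts on a simulated VCF."""
        cyvcf2 = pytest.importorskip("cyvcf2")
        spec = fedvar.SimSpec(n_samples=12, n_variants=60, seed=5)
        vcf, _ = fedvar.simulate_cohort(spec, tmp_path)
        ours = {r.rsid: (r.ac, r.an, r.start_position)
                for r in fedvar.variant_store.iter_vcf_records(vcf)}
        for v in cyvcf2.VCF(vcf):
            alts = sum(1 for g in v.genotypes for a in g[:2] if a == 1)
            called = sum(1 for g in v.genotypes for a in g[:2] if a >= 0)
            assert ours[v.ID] == (alts, called, v.start)


class TestIngestAnnotation:
    def test_headered_tsv(self, federation, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("chromosome_name\tstart_position\tend_position\tgene\n"
                        "chr1\t100\t200\tTP53\n"
                        "chr1\t150\t300\tTP53\n"
                        "chr2\t5\t10\tEGFR\n")
        platform = federation.platform("gcp_like")
        handle = fedvar.ingest_annotation(str(path), platform, "ann")
        assert handle.row_count == 3
        rows = fedvar.export_rows(platform, "ann")
        assert rows[0]["attributes"]["gene"] in ("TP53", "EGFR")

    def test_headerless_bed_gets_default_attr_names(self, federation, tmp_path):
        path = tmp_path / "ann.bed"
        path.write_text("chr1\t100\t200\tfoo\nchr1\t300\t400\tbar\n")
        handle = fedvar.ingest_annotation(
            str(path), federation.platform("gcp_like"), "bed")
        rows = fedvar.export_rows(federation.platform("gcp_like"), "bed")
        assert handle.row_count == 2
        assert rows[0]["attributes"] == {"attr_1": "foo"}

    def test_empty_interval_rejected_with_line_number(self, federation, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\tok\nchr1\t100\t100\tx\n")
        with pytest.raises(RowValidationError, match="line 2"):
            fedvar.ingest_annotation(str(path),
                                     federation.platform("gcp_like"), "bad")

    def test_attribute_values_preserved_verbatim(self, federation, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("chromosome_name\tstart_position\tend_position\tnote\n"
                        "chr17\t7571719\t7590868\tgene=TP53\n")
        fedvar.ingest_annotation(str(path), federation.platform("gcp_like"),
                                 "verbatim")
        rows = fedvar.export_rows(federation.platform("gcp_like"), "verbatim")
        assert rows[0]["attributes"]["note"] == "gene=TP53"


class TestPartitionExport:
    def test_one_file_per_populated_partition(self, ingested_fixture, tmp_path):
        _fed, platform, handle = ingested_fixture
        paths = fedvar.export_partition_files(platform, handle.table_name,
                                              tmp_path / "parts")
        # four variants on four chromosomes -> four partitions
        assert len(paths) == 4
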