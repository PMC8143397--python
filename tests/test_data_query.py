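"""Cross-platform joins: planning, transfer integrity, oracle equivalence."""

import pytest

import fedvar
from fedvar.data_query import (
    pack,
    plan_transfer,
    resolve_gene,
    unpack,
    unpack_and_materialize,
)
from fedvar.errors import (
    AmbiguousGeneError,
    DecryptionError,
    GeneNotFoundError,
    MustTransferFirstError,
    TransferIntegrityError,
)
from fedvar.platform import temp_tables
from fedvar.variant_store import ANNOTATION_LAYOUT, VARIANT_LAYOUT


def build_federated_scene(tmp_path, seed, n_variants=2000, gene_count=3,
                          records_per_gene=6):
    """Variants on one platform, annotations + gene model on the other."""
    fed = fedvar.Federation(seed=seed)
    aws = fed.register_platform("aws_like")
    gcp = fed.register_platform("gcp_like")
    spec = fedvar.SimSpec(n_samples=8, n_variants=n_variants, seed=seed)
    vcf, _ = fedvar.simulate_cohort(spec, tmp_path / f"s{seed}")
    ann, genes = fedvar.simulate_annotation(
        gene_count, records_per_gene, seed=seed,
        out_dir=tmp_path / f"s{seed}", ensure_symbols=["TP53"])
    fedvar.ingest_vcf(vcf, aws, "kg")
    fedvar.ingest_annotation(ann, gcp, "annot")
    fedvar.ingest_gene_model(genes, gcp, "genes")
    return fed


def single_engine_join_oracle(fed, symbol):
    """Brute-force full join of both complete tables, region-restricted."""
    variants = fedvar.export_rows(fed.platform("aws_like"), "kg")
    annotations = fedvar.export_rows(fed.platform("gcp_like"), "annot")
    gene = resolve_gene(fed.platform("gcp_like"), symbol, "genes")
    out = []
    for v in variants:
        if v["chromosome_name"] != gene.chromosome_name:
            continue
        if not (v["start_position"] < gene.end_position
                and v["end_position"] > gene.start_position):
            continue
        for a in annotations:
            if (a["chromosome_name"] == v["chromosome_name"]
                    and max(v["start_position"], a["start_position"])
                    < min(v["end_position"], a["end_position"])):
                row = {k: v[k] for k in VARIANT_LAYOUT if k != "bin_id"}
                row["annotation_start_position"] = a["start_position"]
                row["annotation_end_position"] = a["end_position"]
                row.update(a["attributes"])
                out.append(row)
    return out


class TestResolveGene:
    @pytest.fixture
    def gene_model(self, federation, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("symbol\tchromosome_name\tstart_position\tend_position\n"
                        "TP53\t17\t7571719\t7590868\n"
                        "DUP\t1\t100\t200\n"
                        "DUP\t2\t100\t200\n")
        platform = federation.platform("gcp_like")
        fedvar.ingest_gene_model(str(path), platform, "genes")
        return platform

    def test_symbol_resolves_to_region(self, gene_model):
        gene = resolve_gene(gene_model, "TP53", "genes")
        assert (gene.chromosome_name, gene.start_position,
                gene.end_position) == ("17", 7571719, 7590868)

    def test_lowercase_input_is_uppercased(self, gene_model):
        assert resolve_gene(gene_model, "tp53", "genes") == \
            resolve_gene(gene_model, "TP53", "genes")

    def test_unknown_symbol(self, gene_model):
        with pytest.raises(GeneNotFoundError):
            resolve_gene(gene_model, "NOSUCHGENE", "genes")

    def test_duplicate_symbol_is_ambiguous(self, gene_model):
        with pytest.raises(AmbiguousGeneError) as info:
            resolve_gene(gene_model, "DUP", "genes")
        assert len(info.value.candidates) == 2


class TestEstimateAndPlan:
    def test_estimate_counts_exact_and_bounded(self, ingested_fixture):
        fed, platform, handle = ingested_fixture
        rows, nbytes = fedvar.estimate_subset(
            platform, handle, fedvar.Selector.region("12", 0, 200_000_000))
        assert rows == 1
        assert 0 < nbytes <= handle.byte_size
        empty = fedvar.estimate_subset(
            platform, handle, fedvar.Selector.region("12", 0, 1))
        assert empty == (0, 0)

    def test_smaller_side_moves(self):
        plan = plan_transfer({"gcp_like": (10, 3_100_000),
                              "aws_like": (999, 238_592_000_000)})
        assert plan.moving_side == "gcp_like"
        assert plan.receiving_side == "aws_like"

    def test_move_larger_flag_inverts(self):
        plan = plan_transfer({"gcp_like": (10, 3_100_000),
                              "aws_like": (999, 238_592_000_000)},
                             move_larger=True)
        assert plan.moving_side == "aws_like"

    def test_tie_breaks_lexicographically(self):
        plan = plan_transfer({"b": (1, 10), "a": (1, 10)})
        assert plan.moving_side == "a"

    def test_two_party_only(self):
        with pytest.raises(ValueError):
            plan_transfer({"a": (1, 1)})


class TestPackUnpack:
    RECORDS = [
        {"chromosome_name": "17", "start_position": i, "end_position": i + 10,
         "bin_id": 0, "attributes": {"gene": "TP53", "score": f"{i}"}}
        for i in range(1000)
    ]

    def test_compression_shrinks_repetitive_rows(self):
        payload, receipt = pack(self.RECORDS, ANNOTATION_LAYOUT)
        assert receipt.wire_bytes < receipt.raw_bytes

    def test_round_trip_identity(self):
        payload, receipt = pack(self.RECORDS, ANNOTATION_LAYOUT)
        records, layout, checksum = unpack(payload)
        assert records == self.RECORDS
        assert checksum == receipt.checksum

    def test_empty_record_list_round_trips(self):
        payload, receipt = pack([], ANNOTATION_LAYOUT)
        records, _layout, _ck = unpack(payload)
        assert records == [] and receipt.raw_bytes == 0

    def test_corruption_detected_and_nothing_materialized(self, federation):
        payload, _ = pack(self.RECORDS, ANNOTATION_LAYOUT)
        corrupted = payload[:-10] + bytes([payload[-10] ^ 0xFF]) + payload[-9:]
        platform = federation.platform("aws_like")
        with pytest.raises(TransferIntegrityError):
            unpack_and_materialize(platform, corrupted, "bad", suffix="ee")
        assert temp_tables(platform) == []

    def test_encryption_round_trip_and_wrong_key(self):
        payload, _ = pack(self.RECORDS, ANNOTATION_LAYOUT,
                          encrypt=True, key="secret")
        records, _l, _c = unpack(payload, key="secret")
        assert records == self.RECORDS
        with pytest.raises(DecryptionError):
            unpack(payload, key="wrong")

    def test_encrypt_without_key_refused(self):
        with pytest.raises(ValueError):
            pack(self.RECORDS, ANNOTATION_LAYOUT, encrypt=True)


class TestOverlapJoin:
    @pytest.fixture
    def joined_platform(self, federation, tmp_path):
        platform = federation.platform("aws_like")
        vcf = tmp_path / "v.vcf"
        vcf.write_text("##fileformat=VCFv4.2\n"
                       "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                       "1\t101\trsIn\tA\tT\t.\t.\t.\n"    # [100, 101)
                       "1\t151\trsEdge\tA\tT\t.\t.\t.\n"  # [150, 151)
                       "2\t101\trsChr2\tA\tT\t.\t.\t.\n")
        fedvar.ingest_vcf(str(vcf), platform, "v")
        ann = tmp_path / "a.bed"
        ann.write_text("1\t50\t150\tblock\n")
        fedvar.ingest_annotation(str(ann), platform, "a")
        return platform

    def test_containment_joins(self, joined_platform):
        rows, _ = fedvar.overlap_join(joined_platform, "v", "a",
                                      fedvar.Selector.region("1", 0, 1000))
        assert [r["rsid"] for r in rows] == ["rsIn"]
        assert rows[0]["attr_1"] == "block"

    def test_half_open_abutment_does_not_join(self, joined_platform):
        rows, _ = fedvar.overlap_join(joined_platform, "v", "a",
                                      fedvar.Selector.region("1", 150, 151))
        assert rows == []

    def test_chromosome_mismatch_does_not_join(self, joined_platform):
        rows, _ = fedvar.overlap_join(joined_platform, "v", "a",
                                      fedvar.Selector.region("2", 0, 1000))
        assert rows == []

    def test_cross_platform_join_refused(self, ingested_fixture, tmp_path):
        fed, gcp, handle = ingested_fixture
        aws = fed.platform("aws_like")
        ann = tmp_path / "a.bed"
        ann.write_text("12\t112241000\t112242000\tx\n")
        fedvar.ingest_annotation(str(ann), aws, "remote_ann")
        with pytest.raises(MustTransferFirstError):
            fedvar.overlap_join(gcp, handle, aws.tables["remote_ann"],
                                fedvar.Selector.region("12", 0, 2 * 10**8))


class TestDataQueryPipeline:
    def test_matches_single_engine_oracle(self, tmp_path, multiset):
        fed = build_federated_scene(tmp_path, seed=2)
        oracle = single_engine_join_oracle(fed, "TP53")
        result = fedvar.data_query(
            fed, fedvar.Selector.gene("TP53"), "aws_like.kg",
            "gcp_like.annot", gene_model_target="gcp_like.genes")
        assert multiset(result.rows) == multiset(oracle)

    def test_move_larger_gives_identical_multiset(self, tmp_path, multiset):
        fed = build_federated_scene(tmp_path, seed=4)
        default = fedvar.data_query(
            fed, fedvar.Selector.gene("TP53"), "aws_like.kg",
            "gcp_like.annot", gene_model_target="gcp_like.genes")
        inverted = fedvar.data_query(
            fed, fedvar.Selector.gene("TP53"), "aws_like.kg",
            "gcp_like.annot", gene_model_target="gcp_like.genes",
            move_larger=True)
        assert multiset(default.rows) == multiset(inverted.rows)
        assert default.plan.moving_side != inverted.plan.moving_side

    def test_empty_region_still_creates_and_drops_temp(self, tmp_path):
        fed = build_federated_scene(tmp_path, seed=5)
        result = fedvar.data_query(
            fed, fedvar.Selector.region("1", 0, 1), "aws_like.kg",
            "gcp_like.annot")
        assert result.rows == []
        assert result.receipt.temp_handle is not None
        for platform in fed.platforms.values():
            assert temp_tables(platform) == []

    def test_cleanup_after_injected_join_failure(self, tmp_path, monkeypatch):
        import importlib
        fed = build_federated_scene(tmp_path, seed=6)

        def boom(*args, **kwargs):
            raise RuntimeError("injected join failure")

        monkeypatch.setattr(importlib.import_module("fedvar.data_query"),
                            "overlap_join", boom)
        with pytest.raises(RuntimeError, match="injected"):
            fedvar.data_query(fed, fedvar.Selector.gene("TP53"),
                              "aws_like.kg", "gcp_like.annot",
                              gene_model_target="gcp_like.genes")
        for platform in fed.platforms.values():
            assert temp_tables(platform) == []

    def test_targets_on_one_platform_rejected(self, tmp_path):
        fed = build_federated_scene(tmp_path, seed=7)
        gcp = fed.platform("gcp_like")
        with pytest.raises(ValueError):
            fedvar.data_query(fed, fedvar.Selector.gene("TP53"),
                              "gcp_like.annot", "gcp_like.annot")

    def test_ledger_conservation_and_raw_equals_subset(self, tmp_path):
        fed = build_federated_scene(tmp_path, seed=8)
        result = fedvar.data_query(
            fed, fedvar.Selector.gene("TP53"), "aws_like.kg",
            "gcp_like.annot", gene_model_target="gcp_like.genes")
        moving = result.plan.moving_side
        receiving = result.plan.receiving_side
        outs = [e for e in result.ledger_entries if e.kind == "transfer_out"]
        ins = [e for e in result.ledger_entries if e.kind == "transfer_in"]
        assert len(outs) == len(ins) == 1
        assert outs[0].platform_name == moving
        assert ins[0].platform_name == receiving
        assert outs[0].wire_bytes == ins[0].wire_bytes == \
            result.receipt.wire_bytes
        # raw bytes = canonical serialized size of the moved subset
        from fedvar.platform import run_selector_query
        platform = fed.platform(moving)
        handle = platform.tables["kg" if moving == "aws_like" else "annot"]
        subset = run_selector_query(platform, handle, result.plan.selector)
        from fedvar.variant_store import serialize_row
        expected_raw = sum(
            len(serialize_row(r, handle.layout).encode()) + 1
            for r in subset.rows)
        assert result.receipt.raw_bytes == expected_raw
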