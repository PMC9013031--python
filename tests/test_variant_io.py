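import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_call
from oracles import apply_edit
from panelconcord.variant_io import (
    DepthRule,
    PanelConfigError,
    VariantCall,
    VariantFormatError,
    VariantValidationError,
    builtin_panel,
    infer_variant_class,
    load_panel_spec,
    normalize_variant,
    read_variant_table,
    restrict_to_common_genes,
    write_variant_table,
)

HEADER = (
    "sample_id\tassay_id\tgene\tchrom\tpos\tref\talt\tvariant_class\t"
    "allele_frequency\tread_depth\tactionability_tier\n"
)


def _write(tmp_path, rows):
    path = tmp_path / "calls.tsv"
    path.write_text(HEADER + "".join(rows))
    return path


def _row(pos=100, ref="A", alt="G", af="0.25", vclass="substitution", tier="none"):
    return f"S1\tTO\tSHG001\tchr1\t{pos}\t{ref}\t{alt}\t{vclass}\t{af}\t500\t{tier}\n"


class TestReadVariantTable:
    def test_three_rows(self, tmp_path):
        path = _write(tmp_path, [_row(100), _row(200), _row(300)])
        calls = read_variant_table(path)
        assert len(calls) == 3
        assert [c.pos for c in calls] == [100, 200, 300]

    def test_header_only(self, tmp_path):
        assert read_variant_table(_write(tmp_path, [])) == []

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tgene\nS1\tSHG001\n")
        with pytest.raises(VariantFormatError, match="chrom"):
            read_variant_table(path)

    def test_af_out_of_range_reports_row(self, tmp_path):
        path = _write(tmp_path, [_row(100), _row(200, af="1.7")])
        with pytest.raises(VariantValidationError, match="row 3"):
            read_variant_table(path)

    def test_six_base_substitution_rejected(self, tmp_path):
        path = _write(tmp_path, [_row(ref="ACGTTA", alt="TTTTTT")])
        with pytest.raises(VariantValidationError, match="substitution"):
            read_variant_table(path)

    def test_invalid_rows_raise_not_skip(self, tmp_path):
        path = _write(tmp_path, [_row(100), _row(pos=0)])
        with pytest.raises(VariantValidationError):
            read_variant_table(path)


class TestValidation:
    def test_ref_equals_alt(self):
        with pytest.raises(VariantValidationError, match="not a variant"):
            make_call(ref="A", alt="A")

    def test_tier_range(self):
        with pytest.raises(VariantValidationError):
            make_call(tier=7)

    def test_class_consistency(self):
        with pytest.raises(VariantValidationError, match="inconsistent"):
            VariantCall(
                sample_id="S1", gene="G", chrom="chr1", pos=5, ref="A", alt="AT",
                variant_class="deletion", allele_frequency=0.1, read_depth=10,
            )

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "substitution"),
            ("ACG", "TTT", "substitution"),
            ("A", "AT", "insertion"),
            ("AT", "A", "deletion"),
            ("AC", "TG" * 5, "delins"),
        ],
    )
    def test_infer_class(self, ref, alt, expected):
        assert infer_variant_class(ref, alt) == expected


class TestNormalize:
    def test_shared_prefix_trimmed(self):
        call = make_call(pos=100, ref="AT", alt="AG")
        norm = normalize_variant(call)
        assert (norm.chrom, norm.pos, norm.ref, norm.alt) == ("chr1", 101, "T", "G")

    def test_snv_unchanged(self):
        call = make_call(pos=100, ref="A", alt="G")
        assert normalize_variant(call) is call

    def test_indel_anchor_retained(self):
        call = make_call(pos=50, ref="CAAA", alt="CAA")
        norm = normalize_variant(call)
        assert (norm.pos, norm.ref, norm.alt) == (50, "CA", "C")
        assert norm.variant_class == "deletion"

    allele = st.text(alphabet="ACGT", min_size=1, max_size=5)

    @given(ref=allele, alt=allele, pos=st.integers(1, 10_000))
    def test_idempotent_and_edit_preserving(self, ref, alt, pos):
        if ref == alt or (len(ref) == len(alt) and len(ref) > 5):
            return
        call = make_call(pos=pos + 20, ref=ref, alt=alt)
        norm = normalize_variant(call)
        assert normalize_variant(norm) == norm
        # the represented allele change must be identical on a 20-bp context
        context_start = call.pos - 10
        context = "T" * 10 + call.ref + "T" * 10
        edited_raw = apply_edit(context, context_start, call.pos, call.ref, call.alt)
        edited_norm = apply_edit(context, context_start, norm.pos, norm.ref, norm.alt)
        assert edited_raw == edited_norm


class TestRoundTrip:
    alleles = st.sampled_from(
        [("A", "T"), ("C", "G"), ("AT", "A"), ("A", "ATG"), ("ACGT", "TTTA"), ("GG", "TC")]
    )
    call_st = alleles.flatmap(
        lambda pair: st.builds(
            make_call,
            chrom=st.sampled_from(["chr1", "chr2", "chrX"]),
            pos=st.integers(1, 10**8),
            ref=st.just(pair[0]),
            alt=st.just(pair[1]),
            af=st.floats(0, 1, allow_nan=False),
            depth=st.integers(0, 10**5),
            tier=st.sampled_from([None, 1, 2, 3, 4, 5]),
            gene=st.sampled_from(["SHG001", "TOG001", "TNG001"]),
            assay=st.sampled_from(["TO", "TN"]),
        )
    )

    @settings(max_examples=50)
    @given(calls=st.lists(call_st, max_size=10))
    def test_write_then_read_identity(self, calls, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "calls.tsv"
        write_variant_table(calls, path)
        assert read_variant_table(path) == calls

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_variant_table([], path)
        assert path.read_text() == HEADER
        assert read_variant_table(path) == []

    def test_assay_id_preserved(self, tmp_path):
        calls = [make_call(assay="TO"), make_call(pos=200, assay="TN")]
        path = tmp_path / "both.tsv"
        write_variant_table(calls, path)
        assert [c.assay_id for c in read_variant_table(path)] == ["TO", "TN"]


class TestRestrictToCommonGenes:
    def test_shared_gene_retained(self, panel_to, panel_tn):
        assert len(panel_to.genes) == 215
        assert len(panel_tn.genes) == 114
        assert len(panel_to.genes & panel_tn.genes) == 92
        call = make_call(gene="SHG042")
        assert restrict_to_common_genes([call], panel_to, panel_tn) == [call]

    def test_private_gene_removed(self, panel_to, panel_tn):
        call = make_call(gene="TOG001")
        assert restrict_to_common_genes([call], panel_to, panel_tn) == []

    def test_all_shared_keeps_length_and_order(self, panel_to, panel_tn):
        calls = [make_call(gene=f"SHG{i:03d}", pos=100 + i) for i in range(1, 11)]
        assert restrict_to_common_genes(calls, panel_to, panel_tn) == calls

    def test_symmetric(self, panel_to, panel_tn):
        calls = [make_call(gene=g, pos=100 + i)
                 for i, g in enumerate(["SHG001", "TOG001", "TNG001", "SHG092"])]
        assert restrict_to_common_genes(calls, panel_to, panel_tn) == \
            restrict_to_common_genes(calls, panel_tn, panel_to)


class TestPanelSpec:
    def test_tn_fixture_depth_rule(self, panel_tn):
        assert panel_tn.matched_normal
        assert panel_tn.reporting_cap is None
        assert panel_tn.depth_rule.threshold(0.6) == 200
        assert panel_tn.depth_rule.threshold(0.3) == 250
        assert panel_tn.depth_rule.threshold(0.1) == 500
        # stated endpoints belong to the middle tier
        assert panel_tn.depth_rule.threshold(0.5) == 250
        assert panel_tn.depth_rule.threshold(0.2) == 250

    def test_to_fixture_cap(self, panel_to):
        assert not panel_to.matched_normal
        assert panel_to.reporting_cap == 14

    def test_missing_genes_errors(self, tmp_path):
        path = tmp_path / "panel.yaml"
        path.write_text("name: X\nmatched_normal: false\n")
        with pytest.raises(PanelConfigError, match="genes"):
            load_panel_spec(path)

    def test_unknown_depth_rule_form(self, tmp_path):
        path = tmp_path / "panel.yaml"
        path.write_text(
            "name: X\nmatched_normal: false\ngenes: [A]\ndepth_rule:\n  bogus: 1\n"
        )
        with pytest.raises(PanelConfigError, match="depth_rule"):
            load_panel_spec(path)

    def test_fixed_rule_not_tiered(self):
        rule = DepthRule(fixed=100)
        assert not rule.tiered
        assert rule.threshold(0.9) == 100

    def test_unknown_builtin(self):
        with pytest.raises(ValueError):
            builtin_panel("XX")


class TestVcfDialect:
    def test_minimal_vcf(self, tmp_path):
        path = tmp_path / "calls.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tG\t.\t.\tGENE=SHG001;AF=0.25;DP=500\n"
        )
        calls = read_variant_table(path, dialect="vcf")
        assert len(calls) == 1
        assert calls[0].pos == 100
        assert calls[0].gene == "SHG001"
        assert calls[0].allele_frequency == pytest.approx(0.25)
        assert calls[0].read_depth == 500
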