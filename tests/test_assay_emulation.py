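import numpy as np
import pytest

from panelconcord.assay_emulation import (
    AssayReport,
    SuppressedCall,
    depth_threshold_for_cellularity,
    emulate_tumor_normal_assay,
    emulate_tumor_only_assay,
    write_assay_report,
)
from panelconcord.synthetic_data import (
    NormalEvidence,
    NormalTable,
    SimulationConfig,
    TruthSet,
    TruthVariant,
    simulate_cohort,
)
from panelconcord.variant_io import SampleMeta


def _meta(group="FF", cellularity=0.6):
    return SampleMeta(
        sample_id="S0001",
        group=group,
        library_concentration=10.0,
        q_value=0.8,
        tumor_cellularity=cellularity,
    )


def _truth(variants):
    return TruthSet(sample_id="S0001", variants=variants)


def _somatic(i, af=0.30, gene="SHG001", tier=None):
    return TruthVariant(gene, "chr1", 1000 + i, "A", "G", "somatic", af,
                        actionability_tier=tier)


def _germline(i, gene="SHG002"):
    return TruthVariant(gene, "chr2", 2000 + i, "C", "A", "germline", 0.5)


def _normal_for(truth, het_origins=("germline",), depth=500):
    table = NormalTable()
    for tv in truth.variants:
        alt = depth // 2 if tv.origin in het_origins else 0
        table.add(NormalEvidence("S0001", tv.chrom, tv.pos, tv.ref, tv.alt,
                                 normal_depth=depth, normal_alt_reads=alt))
    return table


class TestDepthThreshold:
    @pytest.mark.parametrize("cellularity,expected", [
        (0.60, 200), (0.30, 250), (0.10, 500), (0.51, 200), (0.50, 250), (0.20, 250),
    ])
    def test_tiers(self, panel_tn, cellularity, expected):
        assert depth_threshold_for_cellularity(cellularity, panel_tn) == expected

    def test_fixed_rule_errors(self, panel_to):
        with pytest.raises(ValueError, match="not tiered"):
            depth_threshold_for_cellularity(0.6, panel_to)


class TestTumorOnly:
    def test_cap_applied(self, panel_to):
        truth = _truth([_somatic(i, af=0.30) for i in range(20)])
        report = emulate_tumor_only_assay(truth, _meta(), panel_to,
                                          np.random.default_rng(0))
        assert len(report.reported) == 14
        capped = [s for s in report.suppressed if s.reason == "reporting_cap"]
        assert len(capped) == 6

    def test_under_cap_all_reported(self, panel_to):
        truth = _truth([_somatic(i, af=0.30) for i in range(5)])
        report = emulate_tumor_only_assay(truth, _meta(), panel_to,
                                          np.random.default_rng(1))
        assert len(report.reported) == 5

    def test_cap_ranking_prefers_actionable(self, panel_to):
        tiers = [1] * 7 + [2] * 7 + [None] * 6
        truth = _truth([_somatic(i, af=0.30, tier=t) for i, t in enumerate(tiers)])
        report = emulate_tumor_only_assay(truth, _meta(), panel_to,
                                          np.random.default_rng(2))
        assert all(c.actionable for c in report.reported)
        assert all(s.call.actionability_tier is None
                   for s in report.suppressed if s.reason == "reporting_cap")

    def test_germline_not_removed(self, panel_to):
        # a 0.5-AF heterozygote at depth ~3000 survives sampling essentially always
        for seed in range(100):
            truth = _truth([_germline(seed)])
            report = emulate_tumor_only_assay(truth, _meta(), panel_to,
                                              np.random.default_rng(seed))
            assert len(report.reported) == 1

    def test_off_panel_gene_suppressed(self, panel_to):
        truth = _truth([_somatic(0, gene="TNG001")])
        report = emulate_tumor_only_assay(truth, _meta(), panel_to,
                                          np.random.default_rng(3))
        assert report.reported == []
        assert report.suppressed[0].reason == "gene_not_on_panel"

    def test_matched_normal_spec_rejected(self, panel_tn):
        with pytest.raises(ValueError, match="matched-normal"):
            emulate_tumor_only_assay(_truth([]), _meta(), panel_tn,
                                     np.random.default_rng(4))

    def test_partition_invariant(self, panel_to):
        truth = _truth([_somatic(i, af=0.01 + 0.02 * i) for i in range(10)]
                       + [_somatic(50, gene="TNG001")])
        report = emulate_tumor_only_assay(truth, _meta(), panel_to,
                                          np.random.default_rng(5))
        reported_keys = {c.key for c in report.reported}
        suppressed_keys = {s.call.key for s in report.suppressed}
        assert reported_keys.isdisjoint(suppressed_keys)
        assert reported_keys | suppressed_keys == {tv.key for tv in truth.variants}


class TestTumorNormal:
    def test_germline_subtracted(self, panel_tn):
        truth = _truth([_germline(0)])
        report = emulate_tumor_normal_assay(truth, _meta(), panel_tn,
                                            _normal_for(truth),
                                            np.random.default_rng(0))
        assert report.reported == []
        assert report.suppressed[0].reason == "germline_subtracted"

    def test_somatic_reported(self, panel_tn):
        truth = _truth([_somatic(0, af=0.30)])
        report = emulate_tumor_normal_assay(truth, _meta(), panel_tn,
                                            _normal_for(truth),
                                            np.random.default_rng(1))
        assert len(report.reported) == 1
        assert report.matched_normal

    def test_missing_normal_row_names_variant(self, panel_tn):
        truth = _truth([_somatic(0, af=0.30)])
        with pytest.raises(KeyError, match="chr1:1000"):
            emulate_tumor_normal_assay(truth, _meta(), panel_tn, NormalTable(),
                                       np.random.default_rng(2))

    def test_tumor_only_spec_rejected(self, panel_to):
        with pytest.raises(ValueError, match="tumor-only"):
            emulate_tumor_normal_assay(_truth([]), _meta(), panel_to, NormalTable(),
                                       np.random.default_rng(3))

    def test_low_cellularity_low_depth_reduces_sensitivity(self, panel_tn):
        # cellularity 0.10 -> required mean depth 500; at assay depth 250 nearly
        # everything fails the depth rule, at 600 most variants clear it
        def run(mean_depth, seed):
            hits = 0
            for i in range(200):
                truth = _truth([_somatic(i, af=0.08)])
                report = emulate_tumor_normal_assay(
                    truth, _meta(cellularity=0.10), panel_tn, _normal_for(truth),
                    np.random.default_rng([seed, i]), mean_depth=mean_depth,
                )
                hits += len(report.reported)
            return hits

        assert run(mean_depth=250, seed=10) < run(mean_depth=600, seed=11)

    def test_depth_rule_reason_recorded(self, panel_tn):
        truth = _truth([_somatic(0, af=0.30)])
        report = emulate_tumor_normal_assay(
            truth, _meta(cellularity=0.10), panel_tn, _normal_for(truth),
            np.random.default_rng(5), mean_depth=100,
        )
        assert report.reported == []
        assert report.suppressed[0].reason == "below_depth_rule"


class TestReportInvariants:
    def test_panel_privacy(self, panel_to, panel_tn, default_bundle):
        for report in default_bundle["to_reports"].values():
            assert all(c.gene in panel_to.genes for c in report.reported)
        for report in default_bundle["tn_reports"].values():
            assert all(c.gene in panel_tn.genes for c in report.reported)

    def test_cap_never_exceeded(self, default_bundle, panel_to):
        for report in default_bundle["to_reports"].values():
            assert len(report.reported) <= panel_to.reporting_cap

    def test_unknown_suppression_reason_rejected(self):
        from conftest import make_call
        with pytest.raises(ValueError):
            SuppressedCall(make_call(), "because")

    def test_write_assay_report(self, tmp_path, panel_to):
        truth = _truth([_somatic(i, af=0.30) for i in range(3)])
        report = emulate_tumor_only_assay(truth, _meta(), panel_to,
                                          np.random.default_rng(6))
        path = tmp_path / "report.tsv"
        write_assay_report([report], path)
        lines = path.read_text().splitlines()
        assert lines[0].endswith("suppression_reason")
        assert len(lines) == 1 + len(report.reported) + len(report.suppressed)


class TestNullCase:
    def test_no_noise_no_discordance(self, panel_to, panel_tn):
        """With no artifacts, no germline, no cap pressure and deep sequencing,
        the two assays agree perfectly on shared genes."""
        from panelconcord.concordance import match_calls
        from panelconcord.variant_io import restrict_to_common_genes

        rng = np.random.default_rng(7)
        for trial in range(20):
            truth = _truth([_somatic(i, af=0.5, gene=f"SHG{(i % 92) + 1:03d}")
                            for i in range(8)])
            to_rep = emulate_tumor_only_assay(
                truth, _meta(cellularity=1.0), panel_to, rng, mean_depth=50_000)
            tn_rep = emulate_tumor_normal_assay(
                truth, _meta(cellularity=1.0), panel_tn, _normal_for(truth), rng,
                mean_depth=50_000)
            res = match_calls(
                restrict_to_common_genes(to_rep.reported, panel_to, panel_tn),
                restrict_to_common_genes(tn_rep.reported, panel_to, panel_tn),
            )
            assert res.only_a == [] and res.only_b == []
            assert res.concordance_rate == 1.0
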