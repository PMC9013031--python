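"""End-to-end glue: simulate -> emulate -> compare -> attribute -> report.

Everything downstream of the simulator is deterministic; the simulator and
the assay emulators consume disjoint counter-based substreams of the config
seed, so the whole run is byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np

from . import assay_emulation, attribution, concordance, stats_report, synthetic_data
from .assay_emulation import AssayReport, write_assay_report
from .concordance import ComparisonResult, match_calls
from .synthetic_data import NormalTable, SimulationConfig
from .variant_io import PanelSpec, SampleMeta, builtin_panel, restrict_to_common_genes

__all__ = ["run_pipeline", "compare_reports"]

# substream tags so simulation and the two emulators never share draws
_TO_STREAM = 101
_TN_STREAM = 102


def compare_reports(
    to_reports: Mapping[str, AssayReport],
    tn_reports: Mapping[str, AssayReport],
    panel_to: PanelSpec,
    panel_tn: PanelSpec,
    normal: NormalTable,
) -> tuple[dict[str, ComparisonResult], list[attribution.AttributionRecord]]:
    """Match per-sample reports on the shared gene set and attribute discordance."""
    results: dict[str, ComparisonResult] = {}
    records: list[attribution.AttributionRecord] = []

    def lookup(sample_id, key):
        try:
            return normal.lookup(sample_id, key)
        except KeyError:
            return None

    for sample_id in sorted(to_reports):
        rep_a = to_reports[sample_id]
        rep_b = tn_reports[sample_id]
        calls_a = restrict_to_common_genes(rep_a.reported, panel_to, panel_tn)
        calls_b = restrict_to_common_genes(rep_b.reported, panel_to, panel_tn)
        res = match_calls(calls_a, calls_b)
        results[sample_id] = res
        records.extend(
            attribution.attribute_comparison(
                res.only_a, res.only_b, rep_a, rep_b, lookup
            )
        )
    return results, records


def run_pipeline(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the default dual-assay pipeline on a simulated cohort.

    Returns a dict with the cohort, per-sample assay reports, comparison
    results, attribution records and the summary report bundle; writes all
    stages as TSV/JSON under ``out_dir`` when given.
    """
    config = config or SimulationConfig()
    panel_to = builtin_panel("TO")
    panel_tn = builtin_panel("TN")

    metas, truths, normal = synthetic_data.simulate_cohort(config)

    to_reports: dict[str, AssayReport] = {}
    tn_reports: dict[str, AssayReport] = {}
    for idx, meta in enumerate(metas):
        truth = truths[meta.sample_id]
        rng_to = np.random.default_rng([config.seed, idx, _TO_STREAM])
        rng_tn = np.random.default_rng([config.seed, idx, _TN_STREAM])
        to_reports[meta.sample_id] = assay_emulation.emulate_tumor_only_assay(
            truth, meta, panel_to, rng_to,
            mean_depth=config.to_mean_depth, depth_cv=config.depth_cv,
        )
        tn_reports[meta.sample_id] = assay_emulation.emulate_tumor_normal_assay(
            truth, meta, panel_tn, normal, rng_tn,
            mean_depth=config.tn_mean_depth, depth_cv=config.depth_cv,
        )

    results, records = compare_reports(to_reports, tn_reports, panel_to, panel_tn, normal)

    meta_by_id = {m.sample_id: m for m in metas}
    to_only_calls = [c for res in results.values() for c in res.only_a]
    spectra = attribution.count_transition_spectrum(
        to_only_calls, strata=lambda c: meta_by_id[c.sample_id].group
    )
    report = stats_report.build_report(results, metas, records, spectra)
    report["tests"] = _run_tests(results, metas)

    bundle = {
        "config": config,
        "metas": metas,
        "truths": truths,
        "normal": normal,
        "to_reports": to_reports,
        "tn_reports": tn_reports,
        "results": results,
        "attributions": records,
        "spectra": spectra,
        "report": report,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _run_tests(results: Mapping[str, ComparisonResult], metas) -> dict:
    """Cohort-level tests: group Fisher, AF rank test, quality correlations."""
    meta_by_id = {m.sample_id: m for m in metas}
    tests: dict[str, dict] = {}

    counts = {g: [0, 0] for g in ("FF", "FFPE_H", "FFPE_L")}  # concordant, discordant
    for sample_id, res in results.items():
        grp = meta_by_id[sample_id].group
        counts[grp][0] += len(res.both)
        counts[grp][1] += len(res.only_a) + len(res.only_b)
    table = [[counts[g][0] for g in counts], [counts[g][1] for g in counts]]
    try:
        fisher = stats_report.fisher_exact_rxc(table)
        tests["group_concordance_fisher"] = {
            "table": table, "p_value": fisher.p_value, "method": fisher.method,
        }
    except ValueError as exc:
        tests["group_concordance_fisher"] = {"table": table, "error": str(exc)}

    af_only_a = [c.allele_frequency for r in results.values() for c in r.only_a]
    af_both = [
        (a.allele_frequency + b.allele_frequency) / 2.0
        for r in results.values()
        for a, b in r.both
    ]
    if af_only_a and af_both:
        rt = stats_report.rank_test(af_only_a, af_both, paired=False)
        tests["af_only_a_vs_both"] = {
            "median_only_a": float(np.median(af_only_a)),
            "median_both": float(np.median(af_both)),
            "p_value": rt.p_value,
            "method": rt.method,
        }

    per_sample = [
        (meta_by_id[sid].library_concentration, meta_by_id[sid].q_value,
         res.concordance_rate)
        for sid, res in results.items()
        if res.defined
    ]
    if len(per_sample) >= 3:
        conc = [r for _, _, r in per_sample]
        for label, column in (("library_concentration", 0), ("q_value", 1)):
            xs = [row[column] for row in per_sample]
            try:
                sr = stats_report.spearman_correlation(xs, conc)
                tests[f"concordance_vs_{label}"] = {
                    "r": round(sr.statistic, 3), "p_value": sr.p_value,
                }
            except ValueError as exc:
                tests[f"concordance_vs_{label}"] = {"error": str(exc)}
    return tests


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    synthetic_data.write_cohort(
        out_dir, bundle["metas"], bundle["truths"], bundle["normal"]
    )
    write_assay_report(
        (bundle["to_reports"][m.sample_id] for m in bundle["metas"]),
        out_dir / "to_report.tsv",
    )
    write_assay_report(
        (bundle["tn_reports"][m.sample_id] for m in bundle["metas"]),
        out_dir / "tn_report.tsv",
    )
    with (out_dir / "attribution.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "chrom", "pos", "ref", "alt", "missing_from",
                    "category", "evidence"])
        for rec in bundle["attributions"]:
            v = rec.variant
            w.writerow([v.sample_id, v.chrom, v.pos, v.ref, v.alt,
                        rec.missing_from, rec.category, rec.evidence])
    with (out_dir / "spectra.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["stratum", "CT_GA", "other"])
        for stratum in sorted(bundle["spectra"]):
            ch = bundle["spectra"][stratum]
            w.writerow([stratum, ch.get("CT_GA", 0), ch.get("other", 0)])
    stats_report.write_report(bundle["report"], out_dir)
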