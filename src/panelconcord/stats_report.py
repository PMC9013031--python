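"""Statistical tests and summary-report generation.

The exact 2xk contingency test is implemented by full enumeration of tables
with fixed margins (Freeman-Halton for k=3); the two-sided p-value is the
sum of probabilities of all tables no more probable than the observed one.
Rank tests and the Spearman correlation are thin, contract-checked wrappers
around scipy.  ``build_report`` assembles the downstream summary bundle and
a block of reference worked examples that recompute headline rates from
canned count partitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .attribution import AttributionRecord, LOW_AF_THRESHOLD
from .concordance import ComparisonResult, concordance_from_counts, stratified_summary
from .variant_io import SampleMeta

__all__ = [
    "StatResult",
    "fisher_exact_rxc",
    "rank_test",
    "spearman_correlation",
    "REFERENCE_PARTITIONS",
    "worked_examples",
    "build_report",
    "write_report",
]

#: AF bin edges used in the attribution histogram (reference lines at 5%/15%).
AF_BINS = ((0.0, 0.05, "<5%"), (0.05, 0.15, "5-15%"), (0.15, 1.01, ">15%"))


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# exact contingency test


def _log_table_prob(row0: Sequence[int], col_totals: Sequence[int], r0: int, n: int) -> float:
    # P(T | margins) = prod_j C(c_j, a_j) / C(N, r0)
    logp = -(gammaln(n + 1) - gammaln(r0 + 1) - gammaln(n - r0 + 1))
    for a, c in zip(row0, col_totals):
        logp += gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
    return float(logp)


def fisher_exact_rxc(table: Sequence[Sequence[int]]) -> StatResult:
    """Two-sided exact test of independence for a 2x2 or 2x3 count table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (the Freeman-Halton extension for k=3).
    """
    arr = np.asarray(table, dtype=object)
    if arr.shape[0] != 2 or arr.shape[1] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 2x3 table, got shape {arr.shape}")
    arr = np.asarray(table, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative integers")
    row_totals = arr.sum(axis=1)
    col_totals = arr.sum(axis=0)
    if (row_totals == 0).any() or (col_totals == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")

    r0 = int(row_totals[0])
    n = int(arr.sum())
    k = arr.shape[1]
    log_obs = _log_table_prob(arr[0], col_totals, r0, n)

    # enumerate first-row vectors summing to r0 within the column margins
    total_p = 0.0
    eps = 1e-9

    def recurse(j: int, remaining: int, row0: list[int]) -> None:
        nonlocal total_p
        if j == k - 1:
            if remaining <= col_totals[j]:
                logp = _log_table_prob(row0 + [remaining], col_totals, r0, n)
                if logp <= log_obs + eps:
                    total_p += math.exp(logp)
            return
        tail_capacity = int(col_totals[j + 1 :].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(col_totals[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, row0 + [a])

    recurse(0, r0, [])
    return StatResult(
        name="fisher_exact" if k == 2 else "freeman_halton",
        statistic=math.exp(log_obs),
        p_value=min(1.0, total_p),
        n=tuple(int(c) for c in col_totals),
        method="exact enumeration, two-sided (sum of P <= P_obs)",
    )


# ---------------------------------------------------------------------------
# rank tests and correlation

_EXACT_N_MAX = 25


def rank_test(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> StatResult:
    """Two-sided rank test between two samples.

    Unpaired runs the Mann-Whitney rank-sum form (exact enumeration for
    combined n <= 25 without ties, normal approximation with tie correction
    otherwise); paired runs the Wilcoxon signed-rank form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank test requires non-empty samples")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        res = sps.wilcoxon(x, y, alternative="two-sided")
        return StatResult(
            name="wilcoxon_signed_rank",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=(int(x.size), int(y.size)),
            method="signed-rank, two-sided",
        )
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = (x.size + y.size) <= _EXACT_N_MAX and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return StatResult(
        name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(x.size), int(y.size)),
        method="exact enumeration" if exact else "normal approximation, tie-corrected",
    )


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with average ranks for ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant input vector")
    res = sps.spearmanr(x, y)
    return StatResult(
        name="spearman",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(x.size),),
        method="rank correlation, t approximation",
    )


# ---------------------------------------------------------------------------
# reference worked examples

#: Canned (both, only_a, only_b) count partitions from a published two-panel
#: comparison, used to demonstrate and regression-test the rate arithmetic.
REFERENCE_PARTITIONS: dict[str, tuple[int, int, int]] = {
    "overall": (51, 99, 31),
    "actionable": (44, 17, 14),
    "vus": (7, 82, 17),
    "replicate_tn": (38, 24, 23),
    "replicate_tn_ffpe_h": (13, 10, 6),
    "replicate_tn_ffpe_l": (25, 14, 17),
}

#: Germline-consistent unmatched calls / all calls unique to the uncapped assay.
REFERENCE_GERMLINE_SHARE = (32, 99)


def worked_examples() -> dict[str, float]:
    """Recompute headline percentages from the canned count partitions."""
    out: dict[str, float] = {}
    for name, (n_both, n_a, n_b) in REFERENCE_PARTITIONS.items():
        conc, disc = concordance_from_counts(n_both, n_a, n_b)
        out[f"{name}_concordance_pct"] = round(100.0 * conc, 1)
        out[f"{name}_discordance_pct"] = round(100.0 * disc, 1)
    g, total = REFERENCE_GERMLINE_SHARE
    out["germline_share_pct"] = round(100.0 * g / total, 1)
    both, only_a, _ = REFERENCE_PARTITIONS["overall"]
    out["assay_a_common_gene_total"] = both + only_a
    return out


# ---------------------------------------------------------------------------
# report bundle


def _af_bin(af: float) -> str:
    for lo, hi, label in AF_BINS:
        if lo <= af < hi:
            return label
    return AF_BINS[-1][2]


def _alteration_table(results: Mapping[str, ComparisonResult]) -> list[dict]:
    n_a = n_b = n_both = 0
    act_a = act_b = act_both = 0
    for res in results.values():
        for pair in res.both:
            n_both += 1
            if pair[0].actionable or pair[1].actionable:
                act_both += 1
        for call in res.only_a:
            n_a += 1
            act_a += int(call.actionable)
        for call in res.only_b:
            n_b += 1
            act_b += int(call.actionable)
    return [
        {"assay": "a", "reported": n_a + n_both, "actionable": act_a + act_both},
        {"assay": "b", "reported": n_b + n_both, "actionable": act_b + act_both},
        {"assay": "both", "reported": n_both, "actionable": act_both},
    ]


def build_report(
    results: Mapping[str, ComparisonResult],
    meta: Sequence[SampleMeta],
    attributions: Sequence[AttributionRecord] = (),
    spectra: Mapping[str, Mapping[str, int]] | None = None,
) -> dict:
    """Assemble the summary bundle for a two-assay cohort comparison.

    Sections: pooled alteration counts with actionable sub-counts, overlap
    (Venn) counts, per-group percentage breakdowns, the attribution-category
    histogram binned at the 5%/15% AF reference lines, the substitution
    spectra, and the reference worked examples.
    """
    n_both = sum(len(r.both) for r in results.values())
    n_a = sum(len(r.only_a) for r in results.values())
    n_b = sum(len(r.only_b) for r in results.values())

    group_table = stratified_summary(results, meta, strata="group")
    group_percent: dict[str, dict[str, float]] = {}
    for _, row in group_table.iterrows():
        total = row["n_total"]
        if total:
            group_percent[row["stratum"]] = {
                "both_pct": round(100.0 * row["n_both"] / total, 1),
                "only_a_pct": round(100.0 * row["n_only_a"] / total, 1),
                "only_b_pct": round(100.0 * row["n_only_b"] / total, 1),
            }

    histogram: dict[str, dict[str, int]] = {}
    for rec in attributions:
        bins = histogram.setdefault(rec.category, {label: 0 for *_, label in AF_BINS})
        bins[_af_bin(rec.variant.allele_frequency)] += 1

    pooled = (
        concordance_from_counts(n_both, n_a, n_b) if (n_both + n_a + n_b) else (None, None)
    )
    return {
        "alteration_counts": _alteration_table(results),
        "venn": {"both": n_both, "only_a": n_a, "only_b": n_b},
        "pooled_concordance_rate": None if pooled[0] is None else round(pooled[0], 3),
        "pooled_discordance_rate": None if pooled[1] is None else round(pooled[1], 3),
        "group_counts": group_table.to_dict(orient="records"),
        "group_percent": group_percent,
        "actionability_counts": stratified_summary(
            results, meta, strata="actionability"
        ).to_dict(orient="records"),
        "attribution_histogram": histogram,
        "spectra": {k: dict(v) for k, v in (spectra or {}).items()},
        "worked_examples": worked_examples(),
    }


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the bundle as JSON plus per-section TSVs and a Markdown digest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    pd.DataFrame(report["group_counts"]).to_csv(
        out_dir / "group_counts.tsv", sep="\t", index=False
    )
    pd.DataFrame(report["alteration_counts"]).to_csv(
        out_dir / "alteration_counts.tsv", sep="\t", index=False
    )
    lines = ["# Two-assay comparison report", ""]
    venn = report["venn"]
    lines.append(
        f"Shared calls: {venn['both']}; unique to assay A: {venn['only_a']}; "
        f"unique to assay B: {venn['only_b']}."
    )
    if report["pooled_concordance_rate"] is not None:
        lines.append(
            f"Pooled concordance {100 * report['pooled_concordance_rate']:.1f}%, "
            f"discordance {100 * report['pooled_discordance_rate']:.1f}%."
        )
    lines.append("")
    lines.append("## Worked examples (canned count partitions)")
    for key, value in sorted(report["worked_examples"].items()):
        lines.append(f"- {key}: {value}")
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
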