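"""Cause attribution for discordant calls and substitution-spectrum counting.

Every variant reported by exactly one of two assays is assigned a single
cause from a fixed five-way taxonomy, resolved in priority order:

1. ``germline``            — the matched-normal pileup is germline-consistent
                             and the absent assay subtracts germline variants;
2. ``reporting_cap``       — the absent assay detected the variant but ranked
                             it below its reporting cap;
3. ``caller_filtered``     — the absent assay suppressed it for depth or
                             AF-floor reasons;
4. ``below_af_threshold``  — reported at AF < 5% with no suppression record
                             in the other assay;
5. ``unexplained``         — catch-all.

The taxonomy is a reconstruction: the upstream assays do not disclose their
filtering internals, so categories 2-4 are defined by this package's
emulation contracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Iterable, Sequence

from .synthetic_data import NormalEvidence
from .variant_io import VariantCall

if TYPE_CHECKING:  # pragma: no cover
    from .assay_emulation import AssayReport

__all__ = [
    "CATEGORIES",
    "LOW_AF_THRESHOLD",
    "AttributionRecord",
    "is_germline_consistent",
    "looks_germline_by_af",
    "classify_discordant",
    "attribute_comparison",
    "count_transition_spectrum",
]

CATEGORIES = (
    "germline",
    "reporting_cap",
    "caller_filtered",
    "below_af_threshold",
    "unexplained",
)

#: Reported-AF boundary under which an unmatched call is considered low-AF.
LOW_AF_THRESHOLD = 0.05

#: Advisory heuristic band for "AF near 50%" germline suspicion.
GERMLINE_AF_BAND = (0.40, 0.60)


@dataclass(frozen=True)
class AttributionRecord:
    """One discordant call with its assigned cause and numeric evidence."""

    variant: VariantCall
    missing_from: str
    category: str
    evidence: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown attribution category {self.category!r}")


def is_germline_consistent(
    call: VariantCall,
    normal: NormalEvidence,
    *,
    min_reads: int = 3,
    min_normal_af: float = 0.25,
) -> bool:
    """True when the matched-normal pileup supports a germline origin.

    Requires at least ``min_reads`` alt reads and a normal AF of at least
    ``min_normal_af``; both thresholds are configurable because the upstream
    vendor's subtraction rule is not disclosed.
    """
    if normal.key != call.key:
        raise ValueError(
            f"normal evidence key {normal.key} does not match call key {call.key}"
        )
    return normal.normal_alt_reads >= min_reads and normal.normal_af >= min_normal_af


def looks_germline_by_af(call: VariantCall) -> bool:
    """Advisory flag: observed AF within the heterozygous band [0.40, 0.60].

    Never used as the primary germline label — only for data sets that lack
    matched-normal evidence.
    """
    lo, hi = GERMLINE_AF_BAND
    return lo <= call.allele_frequency <= hi


def classify_discordant(
    record: VariantCall,
    reporter_report: "AssayReport",
    absent_report: "AssayReport",
    normal: NormalEvidence | None,
    *,
    min_reads: int = 3,
    min_normal_af: float = 0.25,
) -> AttributionRecord:
    """Assign exactly one cause category to a discordant call."""
    key = record.key
    in_reporter = key in reporter_report.reported_keys()
    in_absent = key in absent_report.reported_keys()
    if in_reporter and in_absent:
        raise ValueError(f"not discordant: {key} present in both reports")
    if not in_reporter:
        raise ValueError(f"call {key} is not in the reporting assay's report")

    reason = absent_report.suppression_reason(key)
    if (
        normal is not None
        and absent_is_matched_normal(absent_report, reason)
        and is_germline_consistent(
            record, normal, min_reads=min_reads, min_normal_af=min_normal_af
        )
    ):
        return AttributionRecord(
            variant=record,
            missing_from=absent_report.panel,
            category="germline",
            evidence=f"normal_af={normal.normal_af:.3f} "
            f"normal_alt_reads={normal.normal_alt_reads}",
        )
    if reason == "reporting_cap":
        return AttributionRecord(
            variant=record,
            missing_from=absent_report.panel,
            category="reporting_cap",
            evidence=f"suppressed_by={absent_report.panel} reason=reporting_cap",
        )
    if reason in {"below_af_floor", "below_depth_rule"}:
        return AttributionRecord(
            variant=record,
            missing_from=absent_report.panel,
            category="caller_filtered",
            evidence=f"suppressed_by={absent_report.panel} reason={reason}",
        )
    if reason is None and record.allele_frequency < LOW_AF_THRESHOLD:
        return AttributionRecord(
            variant=record,
            missing_from=absent_report.panel,
            category="below_af_threshold",
            evidence=f"observed_af={record.allele_frequency:.4f}",
        )
    return AttributionRecord(
        variant=record,
        missing_from=absent_report.panel,
        category="unexplained",
        evidence=f"observed_af={record.allele_frequency:.4f} "
        f"suppression_reason={reason or 'none'}",
    )


def absent_is_matched_normal(absent_report: "AssayReport", reason: str | None) -> bool:
    # germline attribution applies only when the other assay subtracts germline
    return reason == "germline_subtracted" or getattr(
        absent_report, "matched_normal", False
    )


def attribute_comparison(
    only_a: Sequence[VariantCall],
    only_b: Sequence[VariantCall],
    report_a: "AssayReport",
    report_b: "AssayReport",
    normal_lookup: Callable[[str, tuple], NormalEvidence | None],
    **thresholds,
) -> list[AttributionRecord]:
    """Classify every discordant call of a two-assay comparison."""
    records: list[AttributionRecord] = []
    for call in only_a:
        normal = normal_lookup(call.sample_id, call.key)
        records.append(classify_discordant(call, report_a, report_b, normal, **thresholds))
    for call in only_b:
        normal = normal_lookup(call.sample_id, call.key)
        records.append(classify_discordant(call, report_b, report_a, normal, **thresholds))
    return records


def count_transition_spectrum(
    calls: Iterable[VariantCall],
    strata: Callable[[VariantCall], str] | None = None,
) -> dict[str, dict[str, int]]:
    """Count C>T/G>A vs other substitution channels, optionally per stratum.

    A call lands in channel ``CT_GA`` iff it is a single-base C>T or G>A
    substitution; all other substitutions (including multi-base ones) and
    indels count as ``other``.
    """
    out: dict[str, dict[str, int]] = {}
    for call in calls:
        stratum = strata(call) if strata else "all"
        channels = out.setdefault(stratum, {"CT_GA": 0, "other": 0})
        channels["CT_GA" if call.is_ct_ga else "other"] += 1
    return out
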