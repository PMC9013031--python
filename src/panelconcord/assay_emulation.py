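"""Apply a panel's detection and reporting rules to a ground-truth sample.

The tumor-only route keeps germline variants (no matched normal to subtract
them) and enforces a finite reporting cap, ranking candidates by
actionability.  The matched tumor-normal route applies a cellularity-tiered
mean-depth requirement and subtracts candidates whose matched-normal pileup
looks germline; it reports without a cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import csv
import numpy as np

from .attribution import is_germline_consistent
from .synthetic_data import (
    NormalTable,
    TruthSet,
    TruthVariant,
    _lognormal_depth,
    observe_variant,
)
from .variant_io import PanelSpec, SampleMeta, VariantCall, TSV_COLUMNS

__all__ = [
    "SUPPRESSION_REASONS",
    "SuppressedCall",
    "AssayReport",
    "depth_threshold_for_cellularity",
    "emulate_tumor_only_assay",
    "emulate_tumor_normal_assay",
    "write_assay_report",
]

SUPPRESSION_REASONS = (
    "below_af_floor",
    "below_depth_rule",
    "germline_subtracted",
    "reporting_cap",
    "gene_not_on_panel",
)


@dataclass(frozen=True)
class SuppressedCall:
    call: VariantCall
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in SUPPRESSION_REASONS:
            raise ValueError(f"unknown suppression reason {self.reason!r}")


@dataclass
class AssayReport:
    """Reported and suppressed calls of one assay run on one sample."""

    sample_id: str
    panel: str
    reported: list[VariantCall] = field(default_factory=list)
    suppressed: list[SuppressedCall] = field(default_factory=list)
    matched_normal: bool = False

    def suppression_reason(self, key: tuple[str, int, str, str]) -> str | None:
        """Reason the variant with this key was withheld, or None."""
        for item in self.suppressed:
            if item.call.key == key:
                return item.reason
        return None

    def reported_keys(self) -> set[tuple[str, int, str, str]]:
        return {c.key for c in self.reported}


def depth_threshold_for_cellularity(cellularity: float, spec: PanelSpec) -> int:
    """Mean-read-depth requirement for a sample of the given tumor cellularity."""
    if not spec.depth_rule.tiered:
        raise ValueError(f"panel {spec.name!r} depth rule is not tiered")
    return spec.depth_rule.threshold(cellularity)


def _make_call(
    tv: TruthVariant, sample_id: str, assay_id: str, af: float, depth: int
) -> VariantCall:
    return VariantCall(
        sample_id=sample_id,
        gene=tv.gene,
        chrom=tv.chrom,
        pos=tv.pos,
        ref=tv.ref,
        alt=tv.alt,
        allele_frequency=af,
        read_depth=depth,
        actionability_tier=tv.actionability_tier,
        assay_id=assay_id,
    )


def _detect(
    truth: TruthSet,
    spec: PanelSpec,
    rng: np.random.Generator,
    mean_depth: float,
    depth_cv: float,
    min_depth: int,
) -> tuple[list[VariantCall], list[SuppressedCall]]:
    """Draw per-variant depth/AF and split truth into candidates vs suppressed."""
    candidates: list[VariantCall] = []
    suppressed: list[SuppressedCall] = []
    for tv in truth.variants:
        if tv.gene not in spec.genes:
            call = _make_call(tv, truth.sample_id, spec.name, 0.0, 0)
            suppressed.append(SuppressedCall(call, "gene_not_on_panel"))
            continue
        depth = _lognormal_depth(mean_depth, depth_cv, rng)
        alt_reads, af = observe_variant(tv.true_af, depth, rng)
        call = _make_call(tv, truth.sample_id, spec.name, af, depth)
        if depth < min_depth:
            suppressed.append(SuppressedCall(call, "below_depth_rule"))
        elif af < spec.af_floor or alt_reads < spec.min_alt_reads:
            suppressed.append(SuppressedCall(call, "below_af_floor"))
        else:
            candidates.append(call)
    return candidates, suppressed


def _cap_rank_key(call: VariantCall) -> tuple:
    # actionability first (tier 1 strongest, VUS last), then AF, then coordinate
    tier = call.actionability_tier if call.actionability_tier is not None else 99
    return (tier, -call.allele_frequency, call.chrom, call.pos, call.ref, call.alt)


def emulate_tumor_only_assay(
    truth: TruthSet,
    meta: SampleMeta,
    spec: PanelSpec,
    rng: np.random.Generator,
    *,
    mean_depth: float | None = None,
    depth_cv: float = 0.3,
) -> AssayReport:
    """Run the tumor-only reporting rules on one sample's truth set.

    Germline variants are *not* removed.  If more candidates survive
    detection than ``spec.reporting_cap`` allows, the top-ranked cap-many
    are reported and the rest suppressed with reason ``reporting_cap``.
    """
    if spec.matched_normal:
        raise ValueError(f"panel {spec.name!r} is matched-normal; tumor-only expected")
    candidates, suppressed = _detect(
        truth, spec, rng, mean_depth or spec.mean_depth, depth_cv, min_depth=0
    )
    if spec.reporting_cap is not None and len(candidates) > spec.reporting_cap:
        ranked = sorted(candidates, key=_cap_rank_key)
        reported = ranked[: spec.reporting_cap]
        suppressed.extend(
            SuppressedCall(c, "reporting_cap") for c in ranked[spec.reporting_cap :]
        )
    else:
        reported = candidates
    return AssayReport(
        sample_id=truth.sample_id,
        panel=spec.name,
        reported=reported,
        suppressed=suppressed,
        matched_normal=False,
    )


def emulate_tumor_normal_assay(
    truth: TruthSet,
    meta: SampleMeta,
    spec: PanelSpec,
    normal: NormalTable,
    rng: np.random.Generator,
    *,
    mean_depth: float | None = None,
    depth_cv: float = 0.3,
) -> AssayReport:
    """Run the matched tumor-normal rules on one sample's truth set.

    Candidates at sites whose matched-normal pileup is germline-consistent
    are suppressed (``germline_subtracted``); there is no reporting cap.
    Raises ``KeyError`` naming the variant if normal evidence is missing.
    """
    if not spec.matched_normal:
        raise ValueError(f"panel {spec.name!r} is tumor-only; matched-normal expected")
    threshold = depth_threshold_for_cellularity(meta.tumor_cellularity, spec)
    candidates, suppressed = _detect(
        truth, spec, rng, mean_depth or spec.mean_depth, depth_cv, min_depth=threshold
    )
    reported: list[VariantCall] = []
    for call in candidates:
        evidence = normal.lookup(truth.sample_id, call.key)
        if is_germline_consistent(call, evidence):
            suppressed.append(SuppressedCall(call, "germline_subtracted"))
        else:
            reported.append(call)
    return AssayReport(
        sample_id=truth.sample_id,
        panel=spec.name,
        reported=reported,
        suppressed=suppressed,
        matched_normal=True,
    )


def write_assay_report(reports: Iterable[AssayReport], path: str | Path) -> None:
    """Serialize reports (reported + suppressed sections) to one TSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS + ("suppression_reason",))
        for report in reports:
            for call in report.reported:
                w.writerow(_row(call) + [""])
            for item in report.suppressed:
                w.writerow(_row(item.call) + [item.reason])


def _row(call: VariantCall) -> list:
    return [
        call.sample_id,
        call.assay_id,
        call.gene,
        call.chrom,
        call.pos,
        call.ref,
        call.alt,
        call.variant_class,
        repr(call.allele_frequency),
        call.read_depth,
        "none" if call.actionability_tier is None else call.actionability_tier,
    ]
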