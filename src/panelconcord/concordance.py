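"""Matching of two call sets and concordance/discordance statistics.

Two reported calls are the same variant iff their normalized genomic keys
``(chrom, pos, ref, alt)`` coincide within a sample; the gene symbol is
annotation, not identity.  The concordance rate of a comparison is

    shared / (shared + only_in_a + only_in_b)

and the discordance rate is its complement.  Stratified rates are pooled:
counts are summed across the stratum's samples before dividing, never
averaged per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variant_io import SampleMeta, VariantCall

__all__ = [
    "UndefinedRateError",
    "ComparisonResult",
    "match_calls",
    "concordance_from_counts",
    "stratified_summary",
]


class UndefinedRateError(ValueError):
    """Raised when a rate is requested for an empty comparison (0/0)."""


@dataclass
class ComparisonResult:
    """Partition of two same-sample call sets into shared and unique calls."""

    both: list[tuple[VariantCall, VariantCall]] = field(default_factory=list)
    only_a: list[VariantCall] = field(default_factory=list)
    only_b: list[VariantCall] = field(default_factory=list)

    @property
    def n_both(self) -> int:
        return len(self.both)

    @property
    def n_total(self) -> int:
        return len(self.both) + len(self.only_a) + len(self.only_b)

    @property
    def defined(self) -> bool:
        """False when no variant was seen by either assay (rates undefined)."""
        return self.n_total > 0

    @property
    def concordance_rate(self) -> float:
        if not self.defined:
            raise UndefinedRateError("no variants in either call set; rate undefined")
        return len(self.both) / self.n_total

    @property
    def discordance_rate(self) -> float:
        return 1.0 - self.concordance_rate

    def counts(self) -> tuple[int, int, int]:
        return (len(self.both), len(self.only_a), len(self.only_b))


def _dedupe(calls: Sequence[VariantCall]) -> dict[tuple, VariantCall]:
    """First occurrence wins; a variant reported twice by one assay counts once."""
    out: dict[tuple, VariantCall] = {}
    for call in calls:
        out.setdefault(call.key, call)
    return out


def _single_sample(calls: Sequence[VariantCall], label: str) -> str | None:
    ids = {c.sample_id for c in calls}
    if len(ids) > 1:
        raise ValueError(f"mixed sample_ids in {label}: {sorted(ids)}")
    return next(iter(ids)) if ids else None


def match_calls(
    calls_a: Sequence[VariantCall], calls_b: Sequence[VariantCall]
) -> ComparisonResult:
    """Partition two same-sample call sets on exact normalized keys.

    Symmetric: ``match_calls(a, b).only_a == match_calls(b, a).only_b``.
    Inputs are deduplicated per key before matching.
    """
    sid_a = _single_sample(calls_a, "calls_a")
    sid_b = _single_sample(calls_b, "calls_b")
    if sid_a is not None and sid_b is not None and sid_a != sid_b:
        raise ValueError(f"mixed sample_ids across call sets: {sid_a!r} vs {sid_b!r}")
    by_a = _dedupe(calls_a)
    by_b = _dedupe(calls_b)
    result = ComparisonResult()
    for key, call in by_a.items():
        if key in by_b:
            result.both.append((call, by_b[key]))
        else:
            result.only_a.append(call)
    result.only_b = [call for key, call in by_b.items() if key not in by_a]
    return result


def concordance_from_counts(
    n_both: int, n_only_a: int, n_only_b: int
) -> tuple[float, float]:
    """(concordance, discordance) from a shared/unique/unique count partition.

    Computed with exact rational arithmetic before the final float conversion.
    """
    for name, n in (("n_both", n_both), ("n_only_a", n_only_a), ("n_only_b", n_only_b)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n}")
    total = n_both + n_only_a + n_only_b
    if total == 0:
        raise UndefinedRateError("all counts zero; concordance undefined")
    conc = Fraction(n_both, total)
    return float(conc), float(1 - conc)


def _pair_actionable(pair: tuple[VariantCall, VariantCall]) -> bool:
    return pair[0].actionable or pair[1].actionable


def stratified_summary(
    results: Mapping[str, ComparisonResult],
    meta: Iterable[SampleMeta],
    strata: str = "group",
) -> pd.DataFrame:
    """Pooled shared/unique counts and concordance per stratum.

    ``strata="group"`` pools by specimen group; ``strata="actionability"``
    splits every variant into actionable vs VUS before counting (a matched
    pair is actionable if either member is).
    """
    if strata not in {"group", "actionability"}:
        raise ValueError(f"unknown stratification {strata!r}")
    meta_by_id = {m.sample_id: m for m in meta}
    missing = sorted(set(results) - set(meta_by_id))
    if missing:
        raise ValueError(f"samples without metadata: {missing}")

    counts: dict[str, list[int]] = {}

    def bump(stratum: str, slot: int, by: int = 1) -> None:
        counts.setdefault(stratum, [0, 0, 0])[slot] += by

    for sample_id, res in results.items():
        if strata == "group":
            stratum = meta_by_id[sample_id].group
            bump(stratum, 0, len(res.both))
            bump(stratum, 1, len(res.only_a))
            bump(stratum, 2, len(res.only_b))
        else:
            for pair in res.both:
                bump("actionable" if _pair_actionable(pair) else "vus", 0)
            for call in res.only_a:
                bump("actionable" if call.actionable else "vus", 1)
            for call in res.only_b:
                bump("actionable" if call.actionable else "vus", 2)

    rows = []
    for stratum in sorted(counts):
        n_both, n_a, n_b = counts[stratum]
        total = n_both + n_a + n_b
        conc = concordance_from_counts(n_both, n_a, n_b)[0] if total else float("nan")
        rows.append(
            {
                "stratum": stratum,
                "n_both": n_both,
                "n_only_a": n_a,
                "n_only_b": n_b,
                "n_total": total,
                "concordance_rate": conc,
            }
        )
    return pd.DataFrame(rows, columns=["stratum", "n_both", "n_only_a", "n_only_b",
                                       "n_total", "concordance_rate"])
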