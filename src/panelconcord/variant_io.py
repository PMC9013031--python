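"""Reading, validation, normalization and writing of short-variant call tables.

The package's native exchange format is a tab-separated table with one reported
variant per row and a fixed header::

    sample_id  assay_id  gene  chrom  pos  ref  alt  variant_class
    allele_frequency  read_depth  actionability_tier

Coordinates are 1-based with VCF-style anchor bases for indels.  A "short
variant" is a base substitution of at most :data:`MAX_SUBSTITUTION_LEN` bases
or an insertion/deletion; longer same-length replacements are rejected at
validation time.  An optional VCF 4.x reader is provided for interoperability.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml

__all__ = [
    "MAX_SUBSTITUTION_LEN",
    "TSV_COLUMNS",
    "VariantCall",
    "SampleMeta",
    "DepthRule",
    "PanelSpec",
    "VariantFormatError",
    "VariantValidationError",
    "PanelConfigError",
    "infer_variant_class",
    "normalize_variant",
    "read_variant_table",
    "write_variant_table",
    "restrict_to_common_genes",
    "load_panel_spec",
    "builtin_panel",
]

#: Maximum length of a multi-base substitution treated as a short variant.
MAX_SUBSTITUTION_LEN = 5

#: Column order of the native TSV dialect.
TSV_COLUMNS = (
    "sample_id",
    "assay_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "allele_frequency",
    "read_depth",
    "actionability_tier",
)

VARIANT_CLASSES = frozenset({"substitution", "insertion", "deletion", "delins"})
SAMPLE_GROUPS = frozenset({"FF", "FFPE_H", "FFPE_L"})

_ALLELE_CHARS = frozenset("ACGTN")


class VariantFormatError(ValueError):
    """A table or config does not have the expected shape (missing columns...)."""


class VariantValidationError(ValueError):
    """A record's field values violate a domain invariant."""


class PanelConfigError(ValueError):
    """A panel-spec config file is malformed."""


def _check_allele(value: str, name: str) -> None:
    if not value or not set(value) <= _ALLELE_CHARS:
        raise VariantValidationError(f"{name} allele {value!r} is not a DNA string")


def infer_variant_class(ref: str, alt: str) -> str:
    """Classify an allele pair as substitution / insertion / deletion / delins."""
    if len(ref) == len(alt):
        return "substitution"
    if len(ref) < len(alt) and alt[: len(ref)] == ref:
        return "insertion"
    if len(alt) < len(ref) and ref[: len(alt)] == alt:
        return "deletion"
    return "delins"


@dataclass(frozen=True)
class VariantCall:
    """One reported short variant.

    ``actionability_tier`` is an ordinal label 1..5 (1 = strongest evidence)
    or ``None`` for a variant of unknown significance; the criteria behind
    the tiers are modeled as a label only.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = ""
    allele_frequency: float = 0.0
    read_depth: int = 0
    actionability_tier: int | None = None
    assay_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantValidationError(f"pos must be >= 1, got {self.pos}")
        _check_allele(self.ref, "ref")
        _check_allele(self.alt, "alt")
        if self.ref == self.alt:
            raise VariantValidationError(
                f"not a variant: ref == alt == {self.ref!r} at {self.chrom}:{self.pos}"
            )
        inferred = infer_variant_class(self.ref, self.alt)
        if not self.variant_class:
            object.__setattr__(self, "variant_class", inferred)
        elif self.variant_class not in VARIANT_CLASSES:
            raise VariantValidationError(
                f"unknown variant_class {self.variant_class!r}"
            )
        elif self.variant_class != inferred:
            raise VariantValidationError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {inferred!r})"
            )
        if self.variant_class == "substitution" and len(self.ref) > MAX_SUBSTITUTION_LEN:
            raise VariantValidationError(
                f"substitution longer than {MAX_SUBSTITUTION_LEN} bases: "
                f"{self.ref}>{self.alt}"
            )
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise VariantValidationError(
                f"allele_frequency {self.allele_frequency} outside [0, 1]"
            )
        if self.read_depth < 0:
            raise VariantValidationError(f"read_depth {self.read_depth} is negative")
        if self.actionability_tier is not None and self.actionability_tier not in range(1, 6):
            raise VariantValidationError(
                f"actionability_tier must be 1..5 or None, got {self.actionability_tier}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic identity key ``(chrom, pos, ref, alt)``."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def actionable(self) -> bool:
        return self.actionability_tier is not None

    @property
    def is_ct_ga(self) -> bool:
        """True for a single-base C>T or G>A substitution."""
        return (self.ref, self.alt) in {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: specimen group, DNA quality and cellularity."""

    sample_id: str
    group: str
    library_concentration: float
    q_value: float
    tumor_cellularity: float
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.group not in SAMPLE_GROUPS:
            raise VariantValidationError(
                f"group must be one of {sorted(SAMPLE_GROUPS)}, got {self.group!r}"
            )
        if not 0.0 <= self.tumor_cellularity <= 1.0:
            raise VariantValidationError(
                f"tumor_cellularity {self.tumor_cellularity} outside [0, 1]"
            )
        if self.library_concentration < 0 or self.q_value < 0:
            raise VariantValidationError("concentration and q_value must be >= 0")


@dataclass(frozen=True)
class DepthRule:
    """Either a fixed mean-depth requirement or one tiered on tumor cellularity.

    Tier boundaries: cellularity > 0.5 -> ``high``; 0.2 <= cellularity <= 0.5
    -> ``mid``; cellularity < 0.2 -> ``low`` (both stated endpoints belong to
    the middle tier).
    """

    fixed: int | None = None
    high: int | None = None
    mid: int | None = None
    low: int | None = None

    def __post_init__(self) -> None:
        tiered = (self.high, self.mid, self.low)
        if self.fixed is None and any(t is None for t in tiered):
            raise PanelConfigError("depth rule needs either 'fixed' or all three tiers")
        if self.fixed is not None and any(t is not None for t in tiered):
            raise PanelConfigError("depth rule cannot be both fixed and tiered")

    @property
    def tiered(self) -> bool:
        return self.fixed is None

    def threshold(self, cellularity: float) -> int:
        if not 0.0 <= cellularity <= 1.0:
            raise ValueError(f"cellularity {cellularity} outside [0, 1]")
        if not self.tiered:
            return int(self.fixed)  # type: ignore[arg-type]
        if cellularity > 0.5:
            return int(self.high)  # type: ignore[arg-type]
        if cellularity >= 0.2:
            return int(self.mid)  # type: ignore[arg-type]
        return int(self.low)  # type: ignore[arg-type]


@dataclass(frozen=True)
class PanelSpec:
    """An assay's gene content and reporting rules.

    ``reporting_cap=None`` means unlimited.  The cap is applied only after
    detection, never before.
    """

    name: str
    genes: frozenset[str]
    matched_normal: bool
    af_floor: float
    depth_rule: DepthRule
    reporting_cap: int | None = None
    min_alt_reads: int = 4
    mean_depth: float = 1000.0

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelConfigError(f"panel {self.name!r} has an empty gene set")
        if not 0.0 <= self.af_floor < 1.0:
            raise PanelConfigError(f"af_floor {self.af_floor} outside [0, 1)")
        if self.reporting_cap is not None and self.reporting_cap < 1:
            raise PanelConfigError("reporting_cap must be positive or unlimited")


# ---------------------------------------------------------------------------
# normalization


def normalize_variant(call: VariantCall) -> VariantCall:
    """Return the canonical minimal representation of ``call``.

    Shared trailing then leading bases are trimmed, keeping at least one base
    in each allele (the VCF anchor for indels) and shifting ``pos`` right by
    the number of leading bases removed.  The operation is idempotent.
    """
    ref, alt, pos = call.ref, call.alt, call.pos
    if ref == alt:
        raise VariantValidationError("not a variant: ref == alt")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (call.ref, call.alt, call.pos):
        return call
    return replace(call, ref=ref, alt=alt, pos=pos,
                   variant_class=infer_variant_class(ref, alt))


# ---------------------------------------------------------------------------
# table I/O


def _parse_tier(text: str, where: str) -> int | None:
    text = text.strip()
    if text.lower() in {"none", "", "."}:
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise VariantValidationError(f"{where}: bad actionability_tier {text!r}") from exc


def _row_to_call(row: dict[str, str], lineno: int) -> VariantCall:
    where = f"row {lineno}"
    try:
        pos = int(row["pos"])
        af = float(row["allele_frequency"])
        depth = int(row["read_depth"])
    except ValueError as exc:
        raise VariantValidationError(f"{where}: {exc}") from exc
    if not 0.0 <= af <= 1.0:
        raise VariantValidationError(
            f"{where}: allele_frequency {af} outside [0, 1]"
        )
    try:
        return VariantCall(
            sample_id=row["sample_id"],
            assay_id=row["assay_id"],
            gene=row["gene"],
            chrom=row["chrom"],
            pos=pos,
            ref=row["ref"].strip().upper(),
            alt=row["alt"].strip().upper(),
            variant_class=row["variant_class"].strip(),
            allele_frequency=af,
            read_depth=depth,
            actionability_tier=_parse_tier(row["actionability_tier"], where),
        )
    except VariantValidationError as exc:
        raise VariantValidationError(f"{where}: {exc}") from exc


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read a variant table; invalid rows raise, they are never skipped."""
    path = Path(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise VariantFormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise VariantFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        return [_row_to_call(row, lineno) for lineno, row in enumerate(reader, start=2)]


def _read_vcf(path: Path) -> list[VariantCall]:
    """Minimal VCF 4.x reader: AF from FORMAT/INFO ``AF``, depth from ``DP``."""
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gene = rec.info.get("GENE", ".")
            if isinstance(gene, tuple):
                gene = gene[0]
            for alt in rec.alts or ():
                af, dp = None, None
                sample_id = samples[0] if samples else "."
                if samples:
                    fmt = rec.samples[samples[0]]
                    af = fmt.get("AF")
                    dp = fmt.get("DP")
                if af is None:
                    af = rec.info.get("AF")
                if dp is None:
                    dp = rec.info.get("DP")
                if isinstance(af, tuple):
                    af = af[0]
                calls.append(
                    VariantCall(
                        sample_id=sample_id,
                        assay_id=str(path.stem),
                        gene=str(gene),
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        allele_frequency=float(af) if af is not None else 0.0,
                        read_depth=int(dp) if dp is not None else 0,
                    )
                )
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls to the native TSV dialect (round-trip safe)."""
    path = Path(path)
    try:
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(TSV_COLUMNS)
            for call in calls:
                writer.writerow(
                    [
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
                )
    except OSError as exc:
        raise OSError(f"cannot write variant table to {path}: {exc}") from exc


def restrict_to_common_genes(
    calls: Sequence[VariantCall], panel_a: PanelSpec, panel_b: PanelSpec
) -> list[VariantCall]:
    """Keep only calls whose gene is covered by both panels; order preserved."""
    common = panel_a.genes & panel_b.genes
    return [c for c in calls if c.gene in common]


# ---------------------------------------------------------------------------
# panel-spec configs


def _read_gene_file(path: Path) -> frozenset[str]:
    symbols = [line.strip() for line in path.read_text().splitlines()]
    return frozenset(s for s in symbols if s and not s.startswith("#"))


def _depth_rule_from_config(raw: object) -> DepthRule:
    if not isinstance(raw, dict):
        raise PanelConfigError(f"depth_rule must be a mapping, got {raw!r}")
    if "fixed" in raw:
        return DepthRule(fixed=int(raw["fixed"]))
    if "tiered" in raw:
        tiers = raw["tiered"]
        try:
            return DepthRule(
                high=int(tiers["high_cellularity"]),
                mid=int(tiers["mid_cellularity"]),
                low=int(tiers["low_cellularity"]),
            )
        except (KeyError, TypeError) as exc:
            raise PanelConfigError(f"malformed tiered depth_rule: {tiers!r}") from exc
    raise PanelConfigError(f"unknown depth_rule form: {raw!r}")


def load_panel_spec(path: str | Path) -> PanelSpec:
    """Load and validate a panel spec from a YAML/JSON config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PanelConfigError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise PanelConfigError(f"{path}: config must be a mapping")
    if "genes" in raw:
        genes = frozenset(raw["genes"])
    elif "genes_file" in raw:
        genes = _read_gene_file(path.parent / raw["genes_file"])
    else:
        raise PanelConfigError(f"{path}: config defines neither 'genes' nor 'genes_file'")
    cap = raw.get("reporting_cap", "unlimited")
    if isinstance(cap, str):
        if cap.lower() != "unlimited":
            raise PanelConfigError(f"{path}: bad reporting_cap {cap!r}")
        cap = None
    try:
        return PanelSpec(
            name=str(raw["name"]),
            genes=genes,
            matched_normal=bool(raw["matched_normal"]),
            af_floor=float(raw.get("af_floor", 0.02)),
            depth_rule=_depth_rule_from_config(raw.get("depth_rule", {"fixed": 0})),
            reporting_cap=cap,
            min_alt_reads=int(raw.get("min_alt_reads", 4)),
            mean_depth=float(raw.get("mean_depth", 1000.0)),
        )
    except KeyError as exc:
        raise PanelConfigError(f"{path}: missing required field {exc}") from exc


def builtin_panel(name: str) -> PanelSpec:
    """Load one of the packaged panel fixtures: ``"TO"`` or ``"TN"``."""
    fname = {"TO": "to_panel.yaml", "TN": "tn_panel.yaml"}.get(name.upper())
    if fname is None:
        raise ValueError(f"no builtin panel named {name!r} (use 'TO' or 'TN')")
    with resources.as_file(resources.files("panelconcord") / "data" / fname) as p:
        return load_panel_spec(p)
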