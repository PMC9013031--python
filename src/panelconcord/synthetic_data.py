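"""Synthetic dual-assay cohort generator.

Produces per-sample ground truth — germline heterozygotes (true AF exactly
0.5), somatic variants (true AF = 0.5 x cellularity x clonal fraction) and
formalin-damage artifacts (low-AF, mostly C>T/G>A) — over a mock gene model
sized like the two panels (92 shared + 123 / 22 private genes), together
with a matched-normal pileup-summary table.  All randomness flows through a
single seed, split into counter-based per-sample substreams so per-sample
output does not depend on generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import csv
import numpy as np
import yaml

from .variant_io import (
    SampleMeta,
    VariantValidationError,
    builtin_panel,
    infer_variant_class,
)

__all__ = [
    "TruthVariant",
    "TruthSet",
    "SimulationConfig",
    "NormalEvidence",
    "NormalTable",
    "build_gene_model",
    "observe_variant",
    "simulate_truth_set",
    "inject_ffpe_artifacts",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

ORIGINS = ("germline", "somatic", "artifact")
_BASES = "ACGT"
_CT_GA = (("C", "T"), ("G", "A"))

GENE_LENGTH = 5_000


@dataclass(frozen=True)
class TruthVariant:
    """A ground-truth variant with provenance label and pre-sampling AF."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str
    true_af: float
    actionability_tier: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise VariantValidationError(f"unknown origin {self.origin!r}")
        if not 0.0 <= self.true_af <= 1.0:
            raise VariantValidationError(f"true_af {self.true_af} outside [0, 1]")
        if self.origin == "germline" and self.true_af != 0.5:
            raise VariantValidationError("germline truth must have true_af == 0.5")
        if self.origin == "artifact" and self.true_af >= 0.10:
            raise VariantValidationError("artifact truth must have true_af < 0.10")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        return infer_variant_class(self.ref, self.alt)

    @property
    def substitution_channel(self) -> str:
        if self.variant_class != "substitution" or len(self.ref) != 1:
            return "na"
        return "CT_GA" if (self.ref, self.alt) in _CT_GA else "other"


@dataclass
class TruthSet:
    """All truth variants of one sample."""

    sample_id: str
    variants: list[TruthVariant] = field(default_factory=list)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}


@dataclass(frozen=True)
class NormalEvidence:
    """Pileup summary of the matched normal at one variant site."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    normal_depth: int
    normal_alt_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.normal_alt_reads <= self.normal_depth:
            raise VariantValidationError(
                f"normal_alt_reads {self.normal_alt_reads} outside "
                f"[0, {self.normal_depth}]"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def normal_af(self) -> float:
        return self.normal_alt_reads / self.normal_depth if self.normal_depth else 0.0


class NormalTable:
    """Lookup of NormalEvidence rows by (sample_id, variant key)."""

    def __init__(self, rows: Iterable[NormalEvidence] = ()) -> None:
        self._rows: dict[tuple, NormalEvidence] = {}
        for row in rows:
            self.add(row)

    def add(self, row: NormalEvidence) -> None:
        self._rows[(row.sample_id, row.key)] = row

    def lookup(self, sample_id: str, key: tuple[str, int, str, str]) -> NormalEvidence:
        try:
            return self._rows[(sample_id, key)]
        except KeyError:
            raise KeyError(
                f"no normal evidence for sample {sample_id} variant "
                f"{key[0]}:{key[1]} {key[2]}>{key[3]}"
            ) from None

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows.values())


@dataclass
class SimulationConfig:
    """Cohort-simulation parameters.  See the README for the full model.

    Artifact rates must be ordered ``FF <= FFPE_H <= FFPE_L``; fixing the
    seed makes the serialized cohort byte-identical.
    """

    n_ff: int = 10
    n_ffpe_h: int = 10
    n_ffpe_l: int = 10
    germline_mean: float = 5.0
    somatic_mean: float = 4.0
    clonal_fraction_beta: tuple[float, float] = (5.0, 2.0)
    artifact_rate: dict[str, float] = field(
        default_factory=lambda: {"FF": 0.0, "FFPE_H": 4.0, "FFPE_L": 12.0}
    )
    ct_fraction: float = 0.8
    artifact_af_beta: tuple[float, float] = (1.0, 40.0)
    to_mean_depth: float = 3000.0
    tn_mean_depth: float = 600.0
    normal_mean_depth: float = 500.0
    depth_cv: float = 0.3
    contamination_rate: float = 0.001
    indel_fraction: float = 0.10
    actionable_prob: dict[str, float] = field(
        default_factory=lambda: {"germline": 0.10, "somatic": 0.50, "artifact": 0.02}
    )
    cellularity_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "FF": (0.3, 0.9),
            "FFPE_H": (0.2, 0.9),
            "FFPE_L": (0.2, 0.9),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [self.artifact_rate.get(g, 0.0) for g in ("FF", "FFPE_H", "FFPE_L")]
        if any(r < 0 for r in rates):
            raise ValueError("artifact rates must be >= 0")
        if not rates[0] <= rates[1] <= rates[2]:
            raise ValueError("artifact rates must satisfy FF <= FFPE_H <= FFPE_L")
        if not 0.0 <= self.ct_fraction <= 1.0:
            raise ValueError("ct_fraction outside [0, 1]")
        if min(self.germline_mean, self.somatic_mean) < 0:
            raise ValueError("Poisson means must be >= 0")
        for grp, (lo, hi) in self.cellularity_range.items():
            if grp != "FF" and lo < 0.20:
                raise ValueError("FFPE cellularity must be >= 0.20")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        for key in ("clonal_fraction_beta", "artifact_af_beta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cellularity_range" in raw:
            raw["cellularity_range"] = {
                g: tuple(v) for g, v in raw["cellularity_range"].items()
            }
        return cls(**raw)


# ---------------------------------------------------------------------------
# gene model


def build_gene_model() -> dict[str, tuple[str, int, int]]:
    """Mock gene model: gene -> (chrom, start, end), 1-based inclusive.

    Covers the union of both packaged panels (shared + private genes) with
    non-overlapping intervals laid out deterministically.
    """
    to_genes = builtin_panel("TO").genes
    tn_genes = builtin_panel("TN").genes
    ordered = sorted(to_genes | tn_genes)
    model: dict[str, tuple[str, int, int]] = {}
    for i, gene in enumerate(ordered):
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 * (i + 1)
        model[gene] = (chrom, start, start + GENE_LENGTH - 1)
    return model


# ---------------------------------------------------------------------------
# sampling primitives


def observe_variant(
    truth_af: float, depth: int, rng: np.random.Generator
) -> tuple[int, float]:
    """Binomial read-sampling of a variant: ``alt_reads ~ Bin(depth, truth_af)``."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    alt_reads = int(rng.binomial(depth, truth_af))
    return alt_reads, alt_reads / depth


def _draw_site(
    rng: np.random.Generator,
    gene_model: Mapping[str, tuple[str, int, int]],
    genes: list[str],
) -> tuple[str, str, int]:
    gene = genes[int(rng.integers(len(genes)))]
    chrom, start, end = gene_model[gene]
    pos = int(rng.integers(start, end + 1))
    return gene, chrom, pos


def _draw_alleles(rng: np.random.Generator, indel_fraction: float) -> tuple[str, str]:
    if rng.random() < indel_fraction:
        anchor = _BASES[int(rng.integers(4))]
        inserted = "".join(_BASES[int(i)] for i in rng.integers(4, size=int(rng.integers(1, 4))))
        if rng.random() < 0.5:
            return anchor, anchor + inserted
        return anchor + inserted, anchor
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[int(rng.integers(4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(4))]
    return ref, alt


def _draw_tier(rng: np.random.Generator, p_actionable: float) -> int | None:
    if rng.random() < p_actionable:
        return int(rng.integers(1, 6))
    return None


def _unique_site(
    rng: np.random.Generator,
    gene_model: Mapping[str, tuple[str, int, int]],
    genes: list[str],
    used: set,
    alleles: tuple[str, str],
) -> tuple[str, str, int]:
    # resample on the (rare) collision of two events at one site
    while True:
        gene, chrom, pos = _draw_site(rng, gene_model, genes)
        if (chrom, pos, *alleles) not in used:
            return gene, chrom, pos


# ---------------------------------------------------------------------------
# truth-set generation


def simulate_truth_set(
    meta: SampleMeta,
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_model: Mapping[str, tuple[str, int, int]] | None = None,
) -> TruthSet:
    """Draw germline and somatic truth variants for one sample."""
    gene_model = gene_model or build_gene_model()
    genes = sorted(gene_model)
    truth = TruthSet(sample_id=meta.sample_id)
    used: set = set()

    ca, cb = config.clonal_fraction_beta
    for origin, count in (
        ("germline", int(rng.poisson(config.germline_mean))),
        ("somatic", int(rng.poisson(config.somatic_mean))),
    ):
        for _ in range(count):
            ref, alt = _draw_alleles(rng, config.indel_fraction)
            gene, chrom, pos = _unique_site(rng, gene_model, genes, used, (ref, alt))
            if origin == "germline":
                af = 0.5
            else:
                clonal = float(rng.beta(ca, cb))
                af = 0.5 * meta.tumor_cellularity * clonal
            truth.variants.append(
                TruthVariant(
                    gene=gene,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    origin=origin,
                    true_af=af,
                    actionability_tier=_draw_tier(rng, config.actionable_prob[origin]),
                )
            )
            used.add((chrom, pos, ref, alt))
    return truth


def inject_ffpe_artifacts(
    truth: TruthSet,
    meta: SampleMeta,
    config: SimulationConfig,
    rng: np.random.Generator,
    gene_model: Mapping[str, tuple[str, int, int]] | None = None,
) -> TruthSet:
    """Append Poisson-distributed low-AF deamination-style artifacts.

    A ``ct_fraction`` share of artifacts are single-base C>T or G>A changes;
    AFs are Beta-distributed and truncated below 0.10.
    """
    lam = config.artifact_rate.get(meta.group, 0.0)
    out = TruthSet(sample_id=truth.sample_id, variants=list(truth.variants))
    if lam == 0:
        return out
    gene_model = gene_model or build_gene_model()
    genes = sorted(gene_model)
    used = out.keys()
    aa, ab = config.artifact_af_beta
    for _ in range(int(rng.poisson(lam))):
        if rng.random() < config.ct_fraction:
            ref, alt = _CT_GA[int(rng.integers(2))]
        else:
            ref, alt = _draw_alleles(rng, 0.0)
            while (ref, alt) in _CT_GA:
                ref, alt = _draw_alleles(rng, 0.0)
        gene, chrom, pos = _unique_site(rng, gene_model, genes, used, (ref, alt))
        af = float(rng.beta(aa, ab))
        while af >= 0.10 or af <= 0.0:
            af = float(rng.beta(aa, ab))
        out.variants.append(
            TruthVariant(
                gene=gene,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                origin="artifact",
                true_af=af,
                actionability_tier=_draw_tier(rng, config.actionable_prob["artifact"]),
            )
        )
        used.add((chrom, pos, ref, alt))
    return out


# ---------------------------------------------------------------------------
# cohort assembly


def _sample_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    # counter-based substream: per-sample output is order-independent
    return np.random.default_rng([config.seed, index])


def _draw_meta(
    sample_id: str, group: str, config: SimulationConfig, rng: np.random.Generator
) -> SampleMeta:
    lo, hi = config.cellularity_range[group]
    cellularity = float(rng.uniform(lo, hi))
    if group == "FFPE_L":
        conc = float(rng.uniform(0.2, 4.9))
    elif group == "FFPE_H":
        conc = float(rng.uniform(5.0, 35.0))
    else:
        conc = float(rng.uniform(5.0, 35.0))
    q_value = float(rng.uniform(0.05, 1.4)) if group != "FF" else float(rng.uniform(0.5, 1.4))
    cancers = ("pancreas", "colorectal", "biliary_tract", "CUP", "NSCLC", "gastric")
    return SampleMeta(
        sample_id=sample_id,
        group=group,
        library_concentration=round(conc, 2),
        q_value=round(q_value, 2),
        tumor_cellularity=round(cellularity, 3),
        cancer_type=cancers[int(rng.integers(len(cancers)))],
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleMeta], dict[str, TruthSet], NormalTable]:
    """Simulate the full cohort: metadata, truth sets and normal evidence.

    The default configuration yields 30 samples in three groups of 10.
    Normal evidence is drawn for every truth variant: germline sites at AF
    0.5, somatic/artifact sites at the cross-contamination rate.
    """
    gene_model = build_gene_model()
    groups = (
        ["FF"] * config.n_ff + ["FFPE_H"] * config.n_ffpe_h + ["FFPE_L"] * config.n_ffpe_l
    )
    metas: list[SampleMeta] = []
    truths: dict[str, TruthSet] = {}
    normal = NormalTable()
    for idx, group in enumerate(groups):
        rng = _sample_rng(config, idx)
        sample_id = f"S{idx + 1:04d}"
        meta = _draw_meta(sample_id, group, config, rng)
        truth = simulate_truth_set(meta, config, rng, gene_model)
        truth = inject_ffpe_artifacts(truth, meta, config, rng, gene_model)
        for tv in truth.variants:
            depth = _lognormal_depth(config.normal_mean_depth, config.depth_cv, rng)
            p = 0.5 if tv.origin == "germline" else config.contamination_rate
            alt_reads = int(rng.binomial(depth, p))
            normal.add(
                NormalEvidence(
                    sample_id=sample_id,
                    chrom=tv.chrom,
                    pos=tv.pos,
                    ref=tv.ref,
                    alt=tv.alt,
                    normal_depth=depth,
                    normal_alt_reads=alt_reads,
                )
            )
        metas.append(meta)
        truths[sample_id] = truth
    return metas, truths, normal


def _lognormal_depth(mean: float, cv: float, rng: np.random.Generator) -> int:
    sigma2 = float(np.log1p(cv * cv))
    mu = float(np.log(mean)) - sigma2 / 2.0
    return max(1, int(round(rng.lognormal(mu, np.sqrt(sigma2)))))


# ---------------------------------------------------------------------------
# serialization (plain TSV, byte-stable)

_META_COLS = ("sample_id", "group", "library_concentration", "q_value",
              "tumor_cellularity", "cancer_type")
_TRUTH_COLS = ("sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
               "origin", "true_af", "substitution_channel", "actionability_tier")
_NORMAL_COLS = ("sample_id", "chrom", "pos", "ref", "alt", "normal_depth",
                "normal_alt_reads")


def write_cohort(
    out_dir: str | Path,
    metas: list[SampleMeta],
    truths: dict[str, TruthSet],
    normal: NormalTable,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with (out_dir / "samples.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_META_COLS)
        for m in metas:
            w.writerow([m.sample_id, m.group, repr(m.library_concentration),
                        repr(m.q_value), repr(m.tumor_cellularity), m.cancer_type])

    with (out_dir / "truth.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRUTH_COLS)
        for m in metas:
            for v in truths[m.sample_id].variants:
                w.writerow([m.sample_id, v.gene, v.chrom, v.pos, v.ref, v.alt,
                            v.variant_class, v.origin, repr(v.true_af),
                            v.substitution_channel,
                            "none" if v.actionability_tier is None else v.actionability_tier])

    with (out_dir / "normal_evidence.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_NORMAL_COLS)
        for row in sorted(normal, key=lambda r: (r.sample_id, r.chrom, r.pos, r.ref, r.alt)):
            w.writerow([row.sample_id, row.chrom, row.pos, row.ref, row.alt,
                        row.normal_depth, row.normal_alt_reads])


def read_cohort(
    in_dir: str | Path,
) -> tuple[list[SampleMeta], dict[str, TruthSet], NormalTable]:
    in_dir = Path(in_dir)
    metas: list[SampleMeta] = []
    with (in_dir / "samples.tsv").open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            metas.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    group=row["group"],
                    library_concentration=float(row["library_concentration"]),
                    q_value=float(row["q_value"]),
                    tumor_cellularity=float(row["tumor_cellularity"]),
                    cancer_type=row["cancer_type"],
                )
            )
    truths: dict[str, TruthSet] = {m.sample_id: TruthSet(m.sample_id) for m in metas}
    with (in_dir / "truth.tsv").open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tier = row["actionability_tier"]
            truths[row["sample_id"]].variants.append(
                TruthVariant(
                    gene=row["gene"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    origin=row["origin"],
                    true_af=float(row["true_af"]),
                    actionability_tier=None if tier == "none" else int(tier),
                )
            )
    normal = NormalTable()
    with (in_dir / "normal_evidence.tsv").open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            normal.add(
                NormalEvidence(
                    sample_id=row["sample_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    normal_depth=int(row["normal_depth"]),
                    normal_alt_reads=int(row["normal_alt_reads"]),
                )
            )
    return metas, truths, normal
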