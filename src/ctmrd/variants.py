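"""Somatic SNV/indel filtering and functional classification.

Tumor/normal variant calls arrive annotated (depths, allele fractions,
population allele frequency, consequence, decision-support verdicts and
splice-impact scores). This module applies the hard-threshold filter
cascade used to nominate ddPCR candidate targets, restricts candidates
to a lymphoid gene panel, and resolves each variant's functional status,
letting splice-impact predictions override the external decision-support
verdict in either direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "GenePanel",
    "Classification",
    "VariantInputError",
    "SNV_FILTER_RULES",
    "apply_snv_filters",
    "restrict_to_panel",
    "classify_variant",
    "read_variant_tsv",
    "write_variant_tsv",
    "write_audit_json",
]

EXTERNAL_CLASSES = frozenset({"functional", "neutral", "vus", "unannotated"})


class VariantInputError(ValueError):
    """Raised when a variant record carries physically impossible values."""


@dataclass
class VariantRecord:
    """One annotated tumor/normal SNV or indel call.

    Depths are read counts; allele fractions live in [0, 1].
    ``gnomad_popmax_af`` is ``None`` when the variant is absent from the
    population database (treated as 0, i.e. maximally rare).
    ``external_class`` is the decision-support verdict supplied as input;
    splice scores (``splice_impact_pct`` on a 0-100 scale,
    ``splice_delta`` in [0, 1]) may be missing for non-splice variants.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_depth: int
    normal_depth: int
    tumor_alt_depth: int
    tumor_ref_depth: int
    tumor_af: float
    tumor_max_af: float
    base_quality: float
    consequence: str = "exonic"
    gene: str = ""
    gnomad_popmax_af: float | None = None
    external_class: str = "unannotated"
    splice_impact_pct: float | None = None
    splice_delta: float | None = None
    is_splice_site: bool = False
    manual_override_vus: bool = False

    def validate(self) -> None:
        label = f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"
        for name in ("tumor_depth", "normal_depth", "tumor_alt_depth",
                     "tumor_ref_depth"):
            if getattr(self, name) < 0:
                raise VariantInputError(f"{label}: negative {name}")
        if self.tumor_alt_depth > self.tumor_depth:
            raise VariantInputError(
                f"{label}: tumor_alt_depth exceeds tumor_depth")
        if self.pos < 1:
            raise VariantInputError(f"{label}: position must be 1-based")
        afs = {"tumor_af": self.tumor_af, "tumor_max_af": self.tumor_max_af}
        if self.gnomad_popmax_af is not None:
            afs["gnomad_popmax_af"] = self.gnomad_popmax_af
        for name, value in afs.items():
            if not (0.0 <= value <= 1.0):
                raise VariantInputError(f"{label}: {name}={value} outside [0,1]")


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols (e.g. a 252-gene lymphoid panel)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene panel must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GenePanel":
        """Load one gene symbol per line; '#' lines are comments."""
        path = Path(path)
        genes = frozenset(
            line.strip() for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#"))
        return cls(name=name or path.stem, genes=genes)


@dataclass
class Classification:
    status: str  # functional | neutral | vus
    rationale: list[str] = field(default_factory=list)


# Each rule maps to a pass-predicate; a record is kept iff all pass.
# Missing gnomAD popmax means the variant is absent from the population
# database and is treated as frequency 0 (keeps novel variants).
SNV_FILTER_RULES: dict[str, callable] = {
    "total_depth": lambda r: r.tumor_depth >= 10 and r.normal_depth >= 10,
    "alt_depth": lambda r: r.tumor_alt_depth >= 3,
    "tumor_af": lambda r: r.tumor_af >= 0.05,
    "max_af": lambda r: r.tumor_max_af < 1,
    "gnomad_popmax": lambda r: (r.gnomad_popmax_af or 0.0) <= 0.001,
    "base_quality": lambda r: r.base_quality >= 20,
    "allele_counts": lambda r: r.tumor_alt_depth > 0 and r.tumor_ref_depth > 0,
}


def apply_snv_filters(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the somatic SNV/indel filter cascade.

    A record is kept iff every rule passes: total depth (tumor AND
    normal) >= 10, tumor alternate-allele depth >= 3, tumor AF >= 0.05,
    maximum tumor AF < 1, gnomAD popmax AF <= 0.001, base quality >= 20,
    and both alternate and reference allele read counts > 0.

    Returns the kept records and a per-rule audit of rejection counts
    (a record failing several rules counts under each).
    """
    audit = {rule: 0 for rule in SNV_FILTER_RULES}
    kept: list[VariantRecord] = []
    for rec in records:
        rec.validate()
        failed = False
        for rule, passes in SNV_FILTER_RULES.items():
            if not passes(rec):
                audit[rule] += 1
                failed = True
        if not failed:
            kept.append(rec)
    return kept, audit


DEFAULT_CONSEQUENCES = frozenset({"exonic", "splicing"})


def restrict_to_panel(
    records: Sequence[VariantRecord],
    panel: GenePanel,
    consequences: Iterable[str] = DEFAULT_CONSEQUENCES,
) -> tuple[list[VariantRecord], dict]:
    """Keep records annotated with an allowed consequence in a panel gene.

    Records with a missing gene symbol are dropped and noted in the
    audit rather than raising.
    """
    allowed = frozenset(consequences)
    kept = []
    audit = {"not_in_panel": 0, "consequence": 0, "missing_gene": []}
    for rec in records:
        if not rec.gene:
            audit["missing_gene"].append(f"{rec.chrom}:{rec.pos}")
            continue
        if rec.gene not in panel.genes:
            audit["not_in_panel"] += 1
            continue
        if rec.consequence not in allowed:
            audit["consequence"] += 1
            continue
        kept.append(rec)
    return kept, audit


def classify_variant(record: VariantRecord) -> Classification:
    """Resolve functional status from the external verdict and splice scores.

    Non-splice-site variants pass the external decision-support class
    through (``unannotated`` becomes ``vus``). For splice-site variants
    the splice predictors override: impact >= 40% or delta score > 0.5
    makes the variant functional regardless of the external class; when
    neither score passes, the external class stands if neutral/VUS and
    is downgraded to VUS otherwise. A manual-override flag forces VUS in
    all cases (for variants with high predicted impact but no apparent
    truncating effect on manual transcript review).
    """
    trail: list[str] = []
    if record.manual_override_vus:
        trail.append("manual override: forced to VUS")
        return Classification("vus", trail)

    external = record.external_class
    if external not in EXTERNAL_CLASSES:
        raise VariantInputError(
            f"unknown external class {external!r} at {record.chrom}:{record.pos}")
    if external == "unannotated":
        external = "vus"
        trail.append("no external verdict: defaulting to VUS")

    if not record.is_splice_site:
        trail.append(f"non-splice variant: external class '{external}' passed through")
        return Classification(external, trail)

    impact_hit = (record.splice_impact_pct is not None
                  and record.splice_impact_pct >= 40)
    delta_hit = (record.splice_delta is not None and record.splice_delta > 0.5)
    if impact_hit or delta_hit:
        trail.append(
            "splice predictor significant "
            f"(impact={record.splice_impact_pct}, delta={record.splice_delta})"
            " -> functional")
        return Classification("functional", trail)

    trail.append("splice predictors below thresholds")
    if external in ("neutral", "vus"):
        trail.append(f"external class '{external}' stands")
        return Classification(external, trail)
    trail.append("external 'functional' contradicted by splice scores -> VUS")
    return Classification("vus", trail)


# ---------------------------------------------------------------------------
# Tabular I/O

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "tumor_depth", "normal_depth",
    "tumor_alt_depth", "tumor_ref_depth", "tumor_af", "tumor_max_af",
    "base_quality", "consequence", "gene", "gnomad_popmax_af",
    "external_class", "splice_impact_pct", "splice_delta", "is_splice_site",
    "manual_override_vus",
]


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.to_dict("records"):
        kwargs = {k: row[k] for k in _TSV_COLUMNS if k in row}
        for opt in ("gnomad_popmax_af", "splice_impact_pct", "splice_delta"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        for flag in ("is_splice_site", "manual_override_vus"):
            if flag in kwargs:
                kwargs[flag] = bool(kwargs[flag])
        if "gene" in kwargs and pd.isna(kwargs["gene"]):
            kwargs["gene"] = ""
        records.append(VariantRecord(**kwargs))
    return records


def write_variant_tsv(records: Sequence[VariantRecord], path: str | Path,
                      classifications: Sequence[Classification] | None = None) -> None:
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    if classifications is not None:
        df["classification"] = [c.status for c in classifications]
        df["classification_rationale"] = [
            "; ".join(c.rationale) for c in classifications]
    df.to_csv(path, sep="\t", index=False)


def write_audit_json(audit: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(audit, indent=2, default=list) + "\n")
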