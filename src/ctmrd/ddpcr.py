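"""Droplet digital PCR quantification for MRD monitoring.

The measurement model: a reaction is partitioned into ~20k droplets of
nominal volume 0.85 nL; each droplet is read positive or negative for
each assay species. Under Poisson loading the mean copies per droplet is
``lambda = -ln(1 - k/N)`` for ``k`` positive droplets out of ``N``, and
concentration follows by dividing by the droplet volume. Replicate wells
of the same reaction are merged by pooling droplet counts before
estimation.

On top of the concentration estimates this module computes variant
allele fractions by three routes (wild-type denominator, partner-assay
denominator for breakpoint assays, copy-number-reference denominator),
the per-assay false-positive rate from normal plasma wells, the
three-criterion positivity call, copies per ml plasma, and the
theoretical limit of detection given the cfDNA copies interrogated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "WellCounts",
    "Quantification",
    "SampleQuant",
    "VolumeSpec",
    "VafResult",
    "PositivityCall",
    "VafRoute",
    "SaturationError",
    "quantify_species",
    "compute_vaf",
    "vaf_confint",
    "estimate_fpr",
    "call_positivity",
    "copies_per_ml",
    "theoretical_lod",
    "quantify_sample",
    "read_wells_csv",
    "write_wells_csv",
]

NEGATIVE_LABEL = "negative"
DROPLET_VOLUME_NL = 0.85  # nominal QX200 droplet volume
WELL_ROLES = frozenset({"patient", "positive_control", "normal_cfDNA", "ntc"})


class SaturationError(ValueError):
    """All droplets positive: the Poisson estimate diverges; dilute."""


class VafRoute(str, Enum):
    WILDTYPE = "wildtype"
    PARTNER = "partner"
    CNR = "cnr"


@dataclass
class WellCounts:
    """Droplet counts for one well.

    ``cluster_counts`` maps a target combination — the frozenset of
    assay species a droplet is positive for, with the empty set meaning
    a negative droplet — to the number of droplets in that cluster.
    """

    well_id: str
    n_droplets: int
    cluster_counts: dict[frozenset[str], int]
    role: str = "patient"

    def __post_init__(self):
        if self.role not in WELL_ROLES:
            raise ValueError(f"{self.well_id}: unknown role {self.role!r}")
        if any(v < 0 for v in self.cluster_counts.values()):
            raise ValueError(f"{self.well_id}: negative cluster count")
        total = sum(self.cluster_counts.values())
        if total != self.n_droplets:
            raise ValueError(
                f"{self.well_id}: cluster counts sum to {total}, "
                f"expected {self.n_droplets}")

    def positives(self, species: str) -> int:
        return sum(c for combo, c in self.cluster_counts.items()
                   if species in combo)

    def single_positives(self, species: str) -> int:
        return self.cluster_counts.get(frozenset({species}), 0)


@dataclass
class Quantification:
    """Merged-well Poisson estimate for one assay species."""

    species: str
    k_positive: int
    n_droplets: int
    lambda_: float
    conc_per_ul: float
    conc_per_20ul: float
    ci95: tuple[float, float]  # on the copies/20µl scale
    n_single_positive: int
    droplet_volume_nl: float = DROPLET_VOLUME_NL

    @property
    def copies_analyzed(self) -> float:
        """Estimated molecules present in the interrogated droplets."""
        return self.lambda_ * self.n_droplets


@dataclass
class VolumeSpec:
    """Volumes linking droplet counts back to plasma.

    ``template_volume_ul`` is the total cfDNA eluate template across the
    merged wells of one reaction.
    """

    elution_volume_ul: float
    plasma_volume_ml: float
    template_volume_ul: float
    droplet_volume_nl: float = DROPLET_VOLUME_NL

    def __post_init__(self):
        for name in ("elution_volume_ul", "plasma_volume_ml",
                     "template_volume_ul", "droplet_volume_nl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class VafResult:
    value: float  # NaN when undefined (no amplifiable reference)
    route: VafRoute
    defined: bool = True
    clamped: bool = False  # numerator exceeded denominator

    def __float__(self) -> float:
        return self.value


@dataclass
class PositivityCall:
    positive: bool
    criteria: dict[str, bool]


def _merge_wells(wells: Sequence[WellCounts], species: str):
    if not wells:
        raise ValueError("no wells to quantify")
    k = sum(w.positives(species) for w in wells)
    n = sum(w.n_droplets for w in wells)
    singles = sum(w.single_positives(species) for w in wells)
    return k, n, singles


def quantify_species(
    wells: Sequence[WellCounts],
    species: str,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
    ci_method: str = "wilson",
) -> Quantification:
    """Poisson concentration estimate for one species over merged wells.

    Merging pools droplet counts: k = total droplets containing the
    species, N = total accepted droplets. The 95% CI is a Wilson score
    interval on the positive fraction, transformed through
    ``lambda(p) = -ln(1-p)`` and the volume scaling (Clopper-Pearson via
    ``ci_method='beta'``).
    """
    k, n, singles = _merge_wells(wells, species)
    if n == 0:
        raise ValueError("merged wells contain no droplets")
    if k >= n:
        raise SaturationError(
            f"{species}: all {n} droplets positive; concentration is not "
            "estimable — dilute the sample and rerun")
    p_hat = k / n
    lam = -math.log1p(-p_hat)
    vol_ul = droplet_volume_nl * 1e-3
    conc_ul = lam / vol_ul
    p_lo, p_hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
    lam_lo = -math.log1p(-min(p_lo, 1 - 1e-15))
    lam_hi = -math.log1p(-min(p_hi, 1 - 1e-15))
    ci = (20.0 * lam_lo / vol_ul, 20.0 * lam_hi / vol_ul)
    return Quantification(
        species=species, k_positive=k, n_droplets=n, lambda_=lam,
        conc_per_ul=conc_ul, conc_per_20ul=20.0 * conc_ul, ci95=ci,
        n_single_positive=singles, droplet_volume_nl=droplet_volume_nl)


def compute_vaf(
    target_q: Quantification,
    wt_q: Quantification | None = None,
    partner_q: Quantification | None = None,
    partner_wt_q: Quantification | None = None,
    cnr_q: Quantification | None = None,
    route: VafRoute | str = VafRoute.WILDTYPE,
) -> VafResult:
    """Variant allele fraction from merged concentrations (copies/20µl).

    * ``wildtype``: target / (target + wild-type) — mutant fraction at
      the mutated locus.
    * ``partner``: target / (partner + partner wild-type) — for
      breakpoint assays and targets without a wild-type assay, the
      denominator is the total genome equivalents measured at the other
      target's locus in the same multiplex.
    * ``cnr``: target / copy-number reference.

    Results are clamped to [0, 1] (flagged). A zero denominator yields
    an undefined-VAF sentinel (NaN, ``defined=False``): no amplifiable
    reference, which is distinct from a measured VAF of 0.
    """
    route = VafRoute(route)
    t = target_q.conc_per_20ul
    if route is VafRoute.WILDTYPE:
        if wt_q is None:
            raise ValueError("wildtype route requires wt_q")
        denom = t + wt_q.conc_per_20ul
    elif route is VafRoute.PARTNER:
        if partner_q is None or partner_wt_q is None:
            raise ValueError("partner route requires partner_q and partner_wt_q")
        denom = partner_q.conc_per_20ul + partner_wt_q.conc_per_20ul
    else:
        if cnr_q is None:
            raise ValueError("cnr route requires cnr_q")
        denom = cnr_q.conc_per_20ul
    if denom == 0:
        return VafResult(value=float("nan"), route=route, defined=False)
    vaf = t / denom
    clamped = vaf > 1.0
    return VafResult(value=min(vaf, 1.0), route=route, clamped=clamped)


def vaf_confint(target_q: Quantification, denom_copies: float,
                alpha: float = 0.05) -> tuple[float, float]:
    """95% CI for a VAF from estimated molecule counts.

    In the rare-event regime the estimated molecule counts behave like
    Poisson counts, so conditionally on the total the mutant count is
    binomial; a Wilson interval on mutant/(total molecules) is applied
    with the effective denominator implied by the VAF route.
    """
    m_t = target_q.copies_analyzed
    n_eff = denom_copies
    if n_eff <= 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(min(m_t, n_eff), n_eff, alpha=alpha,
                                method="wilson")
    return (float(lo), float(hi))


def estimate_fpr(
    normal_wells: Sequence[WellCounts],
    target: str,
    wt: str | None = None,
    partner: str | None = None,
    partner_wt: str | None = None,
    cnr: str | None = None,
    route: VafRoute | str = VafRoute.WILDTYPE,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
) -> float:
    """False-positive rate of a target assay: its apparent VAF in
    normal-plasma cfDNA wells, computed via the target's own route.

    Normal background is typically measured over 9-12 wells; fewer wells
    trigger a warning (less stable FPR), none at all is an error.
    """
    if not normal_wells:
        raise ValueError("FPR requires at least one normal cfDNA well")
    if any(w.role != "normal_cfDNA" for w in normal_wells):
        raise ValueError("FPR wells must have role 'normal_cfDNA'")
    if len(normal_wells) < 9:
        warnings.warn(
            f"FPR estimated from {len(normal_wells)} wells; 9-12 recommended",
            stacklevel=2)
    route = VafRoute(route)
    q = lambda s: quantify_species(normal_wells, s,
                                   droplet_volume_nl=droplet_volume_nl)
    target_q = q(target)
    if target_q.k_positive == 0:
        return 0.0
    res = compute_vaf(
        target_q,
        wt_q=q(wt) if wt else None,
        partner_q=q(partner) if partner else None,
        partner_wt_q=q(partner_wt) if partner_wt else None,
        cnr_q=q(cnr) if cnr else None,
        route=route)
    return res.value if res.defined else 0.0


def call_positivity(
    patient_q: Quantification,
    vaf: float,
    fpr: float,
    normal_q: Quantification,
    min_droplets: int = 3,
    min_single: int = 1,
) -> PositivityCall:
    """Three-criterion MRD positivity call on merged wells.

    Positive iff: the target VAF is strictly above the assay FPR; the
    95% CI of the patient concentration does not overlap the normal
    plasma CI (patient lower bound above normal upper bound); and at
    least ``min_droplets`` positive droplets were seen with at least
    ``min_single`` single-positive droplet (positive for the target
    alone).
    """
    criteria = {
        "vaf_above_fpr": bool(vaf > fpr),
        "ci_nonoverlap": bool(patient_q.ci95[0] > normal_q.ci95[1]),
        "droplet_support": bool(patient_q.k_positive >= min_droplets
                                and patient_q.n_single_positive >= min_single),
    }
    return PositivityCall(positive=all(criteria.values()), criteria=criteria)


def copies_per_ml(copies_measured: float, vol: VolumeSpec) -> float:
    """Convert copies measured in the analyzed wells to copies/ml plasma.

    The eluate fraction actually analyzed is template/elution volume, so
    the scale factor is elution / (template x plasma volume):
    ``copies_per_ml = elution_ul / (template_ul * plasma_ml) * copies``.
    """
    return (vol.elution_volume_ul
            / (vol.template_volume_ul * vol.plasma_volume_ml)
            * copies_measured)


def theoretical_lod(total_cfdna_copies: float) -> float:
    """Theoretical limit of detection: 3 / total cfDNA copies analyzed.

    Three mutant molecules is the minimum detectable signal under the
    positivity rule, so the smallest detectable mutant fraction is 3
    divided by the genome equivalents interrogated.
    """
    if total_cfdna_copies <= 0:
        raise ValueError("total cfDNA copies must be positive")
    return 3.0 / total_cfdna_copies


@dataclass
class TargetReadout:
    """Per-target slice of a sample-level MRD result."""

    target: str
    quant: Quantification
    vaf: VafResult
    vaf_ci95: tuple[float, float]
    fpr: float
    positivity: PositivityCall
    copies_per_ml_plasma: float
    below_lod: bool


@dataclass
class SampleQuant:
    """Full MRD readout for one plasma sample."""

    sample_id: str
    targets: dict[str, TargetReadout]
    reference_quants: dict[str, Quantification]
    total_cfdna_copies: float
    lod: float
    copies_per_ml_map: dict[str, float] = field(default_factory=dict)

    @property
    def mrd_positive(self) -> bool:
        return any(t.positivity.positive for t in self.targets.values())

    @property
    def mean_vaf(self) -> float:
        vals = [t.vaf.value for t in self.targets.values() if t.vaf.defined]
        return float(np.mean(vals)) if vals else float("nan")


def _resolve_route(target_id: str, panel) -> dict:
    """Pick the VAF route for a target given the panel's assay layout."""
    by_id = {t.id: t for t in panel.targets}
    target = by_id[target_id]
    if target.has_wildtype_assay:
        return {"route": VafRoute.WILDTYPE, "wt": target.wildtype_assay}
    for other in panel.targets:
        if other.id != target_id and other.has_wildtype_assay:
            return {"route": VafRoute.PARTNER, "partner": other.id,
                    "partner_wt": other.wildtype_assay}
    if CNR_LABEL in panel.reference_assays:
        return {"route": VafRoute.CNR, "cnr": CNR_LABEL}
    raise ValueError(
        f"{target_id}: no wild-type, partner or CNR assay available")


CNR_LABEL = "CNR"


def quantify_sample(
    sample_id: str,
    patient_wells: Sequence[WellCounts],
    normal_wells: Sequence[WellCounts],
    panel,
    vol: VolumeSpec,
) -> SampleQuant:
    """Compose the full per-sample MRD readout.

    For every target: merged Poisson quantification, VAF via the route
    the panel supports (wild-type, partner, or copy-number reference),
    FPR from the paired normal wells by the same route, the
    three-criterion positivity call against the normal quantification,
    and copies/ml plasma. Total cfDNA copies analyzed are the reference
    assays' molecules plus the targets' molecules in the merged
    reaction; the theoretical LOD is 3 over that total, and targets with
    VAF below it are annotated below-LOD.
    """
    dv = vol.droplet_volume_nl
    quants = {s: quantify_species(patient_wells, s, droplet_volume_nl=dv)
              for s in panel.species}
    ref_quants = {s: quants[s] for s in panel.reference_assays}
    total_copies = (sum(q.copies_analyzed for q in ref_quants.values())
                    + sum(quants[t].copies_analyzed for t in panel.target_ids))
    lod = theoretical_lod(total_copies) if total_copies > 0 else float("nan")

    readouts: dict[str, TargetReadout] = {}
    cpm_map: dict[str, float] = {}
    for s, q in quants.items():
        cpm_map[s] = copies_per_ml(q.copies_analyzed, vol)
    for tid in panel.target_ids:
        ctx = _resolve_route(tid, panel)
        route = ctx["route"]
        kw = {}
        denom = 0.0
        if route is VafRoute.WILDTYPE:
            kw["wt_q"] = quants[ctx["wt"]]
            denom = quants[tid].copies_analyzed + kw["wt_q"].copies_analyzed
        elif route is VafRoute.PARTNER:
            kw["partner_q"] = quants[ctx["partner"]]
            kw["partner_wt_q"] = quants[ctx["partner_wt"]]
            denom = (kw["partner_q"].copies_analyzed
                     + kw["partner_wt_q"].copies_analyzed)
        else:
            kw["cnr_q"] = quants[CNR_LABEL]
            denom = kw["cnr_q"].copies_analyzed
        vaf = compute_vaf(quants[tid], route=route, **kw)
        vaf_ci = vaf_confint(quants[tid], denom)
        fpr = estimate_fpr(
            normal_wells, tid,
            wt=ctx.get("wt"), partner=ctx.get("partner"),
            partner_wt=ctx.get("partner_wt"), cnr=ctx.get("cnr"),
            route=route, droplet_volume_nl=dv)
        normal_q = quantify_species(normal_wells, tid, droplet_volume_nl=dv)
        pos = call_positivity(quants[tid],
                              vaf.value if vaf.defined else 0.0,
                              fpr, normal_q)
        readouts[tid] = TargetReadout(
            target=tid, quant=quants[tid], vaf=vaf, vaf_ci95=vaf_ci,
            fpr=fpr, positivity=pos,
            copies_per_ml_plasma=cpm_map[tid],
            below_lod=bool(vaf.defined and not math.isnan(lod)
                           and vaf.value < lod))
    return SampleQuant(
        sample_id=sample_id, targets=readouts, reference_quants=ref_quants,
        total_cfdna_copies=total_copies, lod=lod, copies_per_ml_map=cpm_map)


# ---------------------------------------------------------------------------
# Well-count CSV dialect: one row per well; one column per cluster
# combination with species joined by '+', 'negative' for the empty set.

def _combo_label(combo: frozenset[str]) -> str:
    return "+".join(sorted(combo)) if combo else NEGATIVE_LABEL


def _parse_combo(label: str) -> frozenset[str]:
    return frozenset() if label == NEGATIVE_LABEL else frozenset(label.split("+"))


def write_wells_csv(wells: Sequence[WellCounts], path: str | Path) -> None:
    combos = sorted({_combo_label(c) for w in wells for c in w.cluster_counts})
    rows = []
    for w in wells:
        row = {"well_id": w.well_id, "role": w.role,
               "n_droplets": w.n_droplets}
        for label in combos:
            row[label] = w.cluster_counts.get(_parse_combo(label), 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_wells_csv(path: str | Path) -> list[WellCounts]:
    df = pd.read_csv(path)
    meta = {"well_id", "role", "n_droplets"}
    combo_cols = [c for c in df.columns if c not in meta]
    wells = []
    for row in df.to_dict("records"):
        counts = {_parse_combo(c): int(row[c]) for c in combo_cols
                  if not pd.isna(row[c])}
        wells.append(WellCounts(
            well_id=str(row["well_id"]), role=row["role"],
            n_droplets=int(row["n_droplets"]), cluster_counts=counts))
    return wells
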