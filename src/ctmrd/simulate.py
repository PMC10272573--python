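"""Synthetic data generation with known ground truth.

Everything the pipeline consumes can be generated here: annotated
variant/SV tables with planted filter violations, multiplexed droplet
partition data under a Poisson co-encapsulation model (optionally with
2D fluorescence amplitudes), normal-plasma background wells, and
longitudinal patient scenarios from diagnosis through clearance to
molecular relapse.

Partitioning model: each assay species s with concentration c_s
(copies/20µl) loads each droplet with Poisson(lambda_s) molecules,
lambda_s = c_s * droplet_volume / 20µl, independently across species and
droplets (ideal partitioning, no droplet-volume dispersion). A droplet's
cluster combination is the set of species with >= 1 molecule; assay
background is an independent per-droplet false-positive flip at a small
per-assay rate (breakpoint assays far below SNV assays, reflecting the
tumor-unique junction sequence).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ddpcr import DROPLET_VOLUME_NL, VolumeSpec, WellCounts
from .svs import SvRecord
from .targets import CandidateTarget, PatientPanel
from .variants import VariantRecord

__all__ = [
    "SimulationConfig",
    "AmplitudeModel",
    "Scenario",
    "Timepoint",
    "simulate_wells",
    "simulate_partition_counts",
    "gate_droplets",
    "simulate_variant_table",
    "simulate_sv_table",
    "simulate_patient_course",
    "relapse_scenario",
    "zero_vaf_scenario",
    "demo_panel",
]

# Per-droplet false-positive flip rates by assay class. Chosen so that a
# merged 12-well normal background against ~5000-6000 genome equivalents
# yields apparent VAFs on the order of 2e-4 (SNV/indel) and 2.5e-5
# (breakpoint assays).
BACKGROUND_RATES = {"snv": 5e-6, "indel": 5e-6, "sv": 5e-7, "reference": 0.0}


@dataclass
class AmplitudeModel:
    """2D fluorescence amplitudes for simulated droplets.

    Each species adds a channel-specific amplitude step scaled by its
    relative assay concentration; a cluster's centroid is the sum of its
    members' steps over the negative baseline, with isotropic Gaussian
    spread and a uniform 'rain' fraction smeared between baseline and
    centroid.
    """

    channels: tuple[str, ...] = ("FAM", "HEX")
    baseline: float = 1000.0
    step: float = 4000.0
    spread: float = 150.0
    rain_fraction: float = 0.0

    def centroid(self, combo: frozenset[str],
                 species_channel: Mapping[str, str],
                 multipliers: Mapping[str, float]) -> np.ndarray:
        pos = np.full(len(self.channels), self.baseline)
        for s in combo:
            ch = self.channels.index(species_channel[s])
            pos[ch] += self.step * multipliers.get(s, 1.0)
        return pos


@dataclass
class SimulationConfig:
    """One multiplexed reaction's generative parameters.

    ``species_concentrations`` are copies/20µl per assay species;
    ``background_rates`` are per-droplet false-positive probabilities
    per species (defaults by assay class via ``species_kinds``).
    """

    seed: int
    species_concentrations: dict[str, float]
    n_droplets_per_well: int = 18000
    droplet_volume_nl: float = DROPLET_VOLUME_NL
    n_wells: dict[str, int] = field(
        default_factory=lambda: {"patient": 3, "normal_cfDNA": 12})
    species_kinds: dict[str, str] = field(default_factory=dict)
    background_rates: dict[str, float] = field(default_factory=dict)
    amplitude: AmplitudeModel | None = None
    species_channel: dict[str, str] = field(default_factory=dict)
    concentration_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(c < 0 for c in self.species_concentrations.values()):
            raise ValueError("concentrations must be >= 0")

    def background_for(self, species: str) -> float:
        if species in self.background_rates:
            return self.background_rates[species]
        kind = self.species_kinds.get(species, "reference")
        return BACKGROUND_RATES.get(kind, 0.0)

    def lambda_per_droplet(self, species: str) -> float:
        conc = self.species_concentrations.get(species, 0.0)
        return conc * (self.droplet_volume_nl * 1e-3) / 20.0


def _positive_probs(config: SimulationConfig,
                    species: Sequence[str]) -> np.ndarray:
    """Per-droplet positive probability per species, background included."""
    probs = []
    for s in species:
        p = 1.0 - math.exp(-config.lambda_per_droplet(s))
        b = config.background_for(s)
        probs.append(p + (1.0 - p) * b)
    return np.asarray(probs)


def simulate_partition_counts(lam: float, n_droplets: int, n_wells: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Positive-droplet counts for single-species wells at loading ``lam``.

    Fast count-level path: k ~ Binomial(N, 1 - e^-lam) per well, the
    exact marginal of the per-droplet model.
    """
    p = 1.0 - math.exp(-lam)
    return rng.binomial(n_droplets, p, size=n_wells)


def simulate_wells(
    config: SimulationConfig,
    with_amplitudes: bool = False,
) -> tuple[list[WellCounts], pd.DataFrame | None]:
    """Draw multiplexed droplet data for every configured well.

    Cluster counts per well are drawn multinomially over the 2^S
    species combinations with probabilities given by independent
    per-species loading (the exact joint law of the per-droplet model).
    Normal-cfDNA and NTC wells carry no patient target molecules — only
    reference species plus per-assay background flips. With
    ``with_amplitudes=True`` a per-droplet 2D amplitude table is also
    returned, with the true combination retained per droplet.
    """
    rng = np.random.default_rng(config.seed)
    species = sorted(config.species_concentrations)
    target_species = [s for s in species
                      if config.species_kinds.get(s, "reference")
                      in ("snv", "indel", "sv")]
    combos = [frozenset(c) for r in range(len(species) + 1)
              for c in itertools.combinations(species, r)]

    def combo_probs(p_pos: np.ndarray) -> np.ndarray:
        probs = np.empty(len(combos))
        for i, combo in enumerate(combos):
            q = 1.0
            for j, s in enumerate(species):
                q *= p_pos[j] if s in combo else (1.0 - p_pos[j])
            probs[i] = q
        return probs

    p_patient = _positive_probs(config, species)
    # Background wells: zero out the target species' true loading,
    # keep reference species (normal genomes) and background flips.
    bg_config = SimulationConfig(
        seed=config.seed,
        species_concentrations={
            s: (0.0 if s in target_species else c)
            for s, c in config.species_concentrations.items()},
        n_droplets_per_well=config.n_droplets_per_well,
        droplet_volume_nl=config.droplet_volume_nl,
        species_kinds=config.species_kinds,
        background_rates=config.background_rates)
    p_background = _positive_probs(bg_config, species)

    wells: list[WellCounts] = []
    amp_rows: list[pd.DataFrame] = []
    for role in sorted(config.n_wells):
        n_wells = config.n_wells[role]
        p_pos = p_patient if role in ("patient", "positive_control") \
            else p_background
        probs = combo_probs(p_pos)
        for i in range(n_wells):
            counts = rng.multinomial(config.n_droplets_per_well, probs)
            cluster_counts = {c: int(k) for c, k in zip(combos, counts)}
            well_id = f"{role}_{i + 1}"
            wells.append(WellCounts(
                well_id=well_id, role=role,
                n_droplets=config.n_droplets_per_well,
                cluster_counts=cluster_counts))
            if with_amplitudes and config.amplitude is not None:
                amp_rows.append(_droplet_amplitudes(
                    well_id, cluster_counts, config, rng))
    amp_df = pd.concat(amp_rows, ignore_index=True) if amp_rows else None
    return wells, amp_df


def _droplet_amplitudes(well_id: str,
                        cluster_counts: Mapping[frozenset[str], int],
                        config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    model = config.amplitude
    frames = []
    for combo, count in cluster_counts.items():
        if count == 0:
            continue
        centroid = model.centroid(combo, config.species_channel,
                                  config.concentration_multipliers)
        pts = rng.normal(centroid, model.spread,
                         size=(count, len(model.channels)))
        if model.rain_fraction > 0 and combo:
            n_rain = rng.binomial(count, model.rain_fraction)
            if n_rain:
                base = np.full(len(model.channels), model.baseline)
                frac = rng.uniform(0.1, 0.9, size=(n_rain, 1))
                pts[:n_rain] = base + frac * (centroid - base)
        df = pd.DataFrame(pts, columns=[f"amp_{c}" for c in model.channels])
        df.insert(0, "well_id", well_id)
        df["true_combination"] = "+".join(sorted(combo)) if combo else "negative"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def gate_droplets(
    amplitudes: pd.DataFrame,
    gates: Mapping[frozenset[str], Sequence[float]],
    role: str = "patient",
    max_radius: float | None = None,
) -> tuple[list[WellCounts], int]:
    """Assign droplets to clusters by nearest configured centroid.

    Replaces the manual 1D/2D threshold setting of vendor software with
    deterministic nearest-centroid gating. Droplets farther than
    ``max_radius`` from every centroid are still assigned to the nearest
    one but counted in the ambiguous tally. Returns per-well counts and
    the ambiguous-droplet count.
    """
    combos = list(gates)
    centroids = np.asarray([gates[c] for c in combos], dtype=float)
    amp_cols = [c for c in amplitudes.columns if c.startswith("amp_")]
    pts = amplitudes[amp_cols].to_numpy()
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    ambiguous = 0
    if max_radius is not None:
        ambiguous = int((np.sqrt(d2.min(axis=1)) > max_radius).sum())
    wells = []
    assigned = amplitudes.assign(_cluster=nearest)
    for well_id, grp in assigned.groupby("well_id", sort=True):
        counts = {c: 0 for c in combos}
        for idx, n in grp["_cluster"].value_counts().items():
            counts[combos[idx]] += int(n)
        wells.append(WellCounts(
            well_id=str(well_id), role=role, n_droplets=len(grp),
            cluster_counts=counts))
    return wells, ambiguous


# ---------------------------------------------------------------------------
# Variant/SV tables with planted filter violations

_CLEAN_SNV = dict(tumor_depth=80, normal_depth=60, tumor_alt_depth=24,
                  tumor_ref_depth=56, tumor_af=0.30, tumor_max_af=0.32,
                  base_quality=35.0, gnomad_popmax_af=None,
                  consequence="exonic", external_class="functional")

# Each plant violates exactly the named rule and passes all others.
_SNV_VIOLATIONS = {
    "total_depth": dict(normal_depth=9),
    "alt_depth": dict(tumor_alt_depth=2, tumor_af=0.05,
                      tumor_depth=40, tumor_ref_depth=38),
    "tumor_af": dict(tumor_af=0.04),
    "max_af": dict(tumor_max_af=1.0),
    "gnomad_popmax": dict(gnomad_popmax_af=0.01),
    "base_quality": dict(base_quality=15.0),
    "allele_counts": dict(tumor_ref_depth=0, tumor_alt_depth=80,
                          tumor_af=1.0, tumor_max_af=0.99),
}

_DEMO_GENES = ("KMT2D", "PIM1", "SOCS1", "BCL2", "MYD88", "CD58",
               "CREBBP", "EZH2", "TNFRSF14", "B2M")


def simulate_variant_table(
    n_pass: int = 10,
    n_fail_per_rule: int = 1,
    seed: int = 0,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """SNV/indel table with known pass/fail truth.

    Plants ``n_pass`` clean records plus ``n_fail_per_rule`` records per
    filter rule, each violating exactly that rule. Returns the records
    and a truth table (variant key, expected outcome, violated rule).
    """
    rng = np.random.default_rng(seed)
    records, truth = [], []
    pos = itertools.count(1_000_000, 997)

    def make(overrides: dict, label: str, rule: str | None):
        base = dict(_CLEAN_SNV)
        base.update(overrides)
        rec = VariantRecord(
            chrom=f"chr{rng.integers(1, 23)}", pos=next(pos),
            ref="C", alt="T", gene=str(rng.choice(_DEMO_GENES)), **base)
        records.append(rec)
        truth.append({"key": f"{rec.chrom}:{rec.pos}", "expected": label,
                      "violated_rule": rule})

    for _ in range(n_pass):
        jitter = dict(_CLEAN_SNV)
        depth = int(rng.integers(30, 120))
        alt = int(rng.integers(max(3, int(0.05 * depth) + 1), depth // 2))
        jitter.update(tumor_depth=depth, tumor_alt_depth=alt,
                      tumor_ref_depth=depth - alt, tumor_af=alt / depth,
                      tumor_max_af=min(0.99, alt / depth + 0.02))
        make(jitter, "pass", None)
    for rule, overrides in _SNV_VIOLATIONS.items():
        for _ in range(n_fail_per_rule):
            make(dict(overrides), "fail", rule)
    return records, pd.DataFrame(truth)


_CLEAN_SV = dict(sv_type="deletion", chrom_a="chr14", chrom_b="chr14",
                 callers=frozenset({"manta", "delly"}),
                 total_paired_reads=60, discordant_reads=20, split_reads=10,
                 affects_coding=True)

_SV_VIOLATIONS = {
    "size": dict(size=999),
    "coding": dict(affects_coding=False),
    "callers": dict(callers=frozenset({"manta"})),
    "low_support": dict(total_paired_reads=20, discordant_reads=2,
                        split_reads=1),
}


def simulate_sv_table(
    n_pass: int = 10,
    n_fail_per_rule: int = 1,
    seed: int = 0,
) -> tuple[list[SvRecord], pd.DataFrame]:
    """SV table with known pass/fail truth, one violated rule per plant."""
    rng = np.random.default_rng(seed)
    records, truth = [], []
    counter = itertools.count(1)

    def make(overrides: dict, label: str, rule: str | None):
        base = dict(_CLEAN_SV)
        size = overrides.pop("size", int(rng.integers(2000, 500_000)))
        base.update(overrides)
        pos_a = int(rng.integers(1_000_000, 50_000_000))
        rec = SvRecord(sv_id=f"sv{next(counter)}", pos_a=pos_a,
                       pos_b=pos_a + size, **base)
        records.append(rec)
        truth.append({"key": rec.sv_id, "expected": label,
                      "violated_rule": rule})

    for _ in range(n_pass):
        make({}, "pass", None)
    for rule, overrides in _SV_VIOLATIONS.items():
        for _ in range(n_fail_per_rule):
            make(dict(overrides), "fail", rule)
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Longitudinal patient scenarios

@dataclass
class Timepoint:
    label: str
    day: int
    true_vaf: dict[str, float]  # per target
    total_copies: float  # genome equivalents per locus in the merged reaction


@dataclass
class Scenario:
    """Timeline of true VAFs and cfDNA input defining a patient course."""

    patient_id: str
    timepoints: list[Timepoint]
    clinical_relapse_day: int | None = None
    normal_total_copies: float = 6000.0
    n_patient_wells: int = 3
    n_normal_wells: int = 12
    n_droplets_per_well: int = 18000

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "patient_id": self.patient_id,
            "clinical_relapse_day": self.clinical_relapse_day,
            "normal_total_copies": self.normal_total_copies,
            "n_patient_wells": self.n_patient_wells,
            "n_normal_wells": self.n_normal_wells,
            "n_droplets_per_well": self.n_droplets_per_well,
            "timepoints": [
                {"label": t.label, "day": t.day, "true_vaf": t.true_vaf,
                 "total_copies": t.total_copies}
                for t in self.timepoints],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        doc = yaml.safe_load(Path(path).read_text())
        tps = [Timepoint(**t) for t in doc.pop("timepoints")]
        return cls(timepoints=tps, **doc)


def demo_panel(patient_id: str = "PatSim") -> PatientPanel:
    """Two-target demo panel: a functional SNV plus a breakpoint assay."""
    targets = [
        CandidateTarget(id="MYD88_L265P", kind="snv", vaf_tumor=0.42,
                        classification="functional"),
        CandidateTarget(id="IGH_BCL2_bp", kind="sv", vaf_tumor=0.38,
                        classification="functional"),
    ]
    panel = PatientPanel(patient_id=patient_id, targets=targets,
                         reference_assays=["MYD88_L265P_wt"])
    from .targets import assign_channels
    return assign_channels(panel)


def relapse_scenario(patient_id: str = "PatSim") -> Scenario:
    """Packaged course: clearance after cycle 1, negative through final
    evaluation, molecular re-emergence at the second follow-up, clinical
    relapse 25 weeks (175 days) after that sample."""
    tp = [
        Timepoint("diagnosis", 0, {"MYD88_L265P": 0.10, "IGH_BCL2_bp": 0.10},
                  6000.0),
        Timepoint("post_cycle_1", 21,
                  {"MYD88_L265P": 0.001, "IGH_BCL2_bp": 0.001}, 1200.0),
        Timepoint("interim", 63, {"MYD88_L265P": 0.0, "IGH_BCL2_bp": 0.0},
                  1200.0),
        Timepoint("final", 126, {"MYD88_L265P": 0.0, "IGH_BCL2_bp": 0.0},
                  1500.0),
        Timepoint("follow_up_1", 490, {"MYD88_L265P": 0.0, "IGH_BCL2_bp": 0.0},
                  1500.0),
        Timepoint("follow_up_2", 855,
                  {"MYD88_L265P": 0.05, "IGH_BCL2_bp": 0.05}, 2000.0),
    ]
    return Scenario(patient_id=patient_id, timepoints=tp,
                    clinical_relapse_day=855 + 175)


def zero_vaf_scenario(patient_id: str = "PatSimNeg") -> Scenario:
    """Course with no circulating tumor signal at any timepoint."""
    tp = [Timepoint(label, day, {"MYD88_L265P": 0.0, "IGH_BCL2_bp": 0.0},
                    copies)
          for label, day, copies in [
              ("diagnosis", 0, 6000.0), ("post_cycle_1", 21, 1500.0),
              ("interim", 63, 1200.0), ("final", 126, 1500.0),
              ("follow_up_1", 490, 1500.0), ("follow_up_2", 855, 1500.0)]]
    return Scenario(patient_id=patient_id, timepoints=tp)


def _copies_to_conc(copies: float, n_wells: int, n_droplets: int,
                    droplet_volume_nl: float) -> float:
    """Copies spread over a merged reaction -> copies/20µl."""
    lam = copies / (n_wells * n_droplets)
    return lam / (droplet_volume_nl * 1e-3) * 20.0


def simulate_patient_course(
    scenario: Scenario,
    panel: PatientPanel | None = None,
    seed: int = 0,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
) -> list[dict]:
    """Generate the full per-timepoint input bundle for one patient.

    Each timepoint yields patient wells (target + reference species at
    concentrations implied by the planted VAF and total genome
    equivalents) and paired normal-cfDNA wells (reference species at the
    scenario's normal input plus assay background). Returns a list of
    dicts with keys label/day/wells/normal_wells/true_vaf/volumes.
    """
    panel = panel or demo_panel(scenario.patient_id)
    kinds = {t.id: t.kind for t in panel.targets}
    kinds.update({r: "reference" for r in panel.reference_assays})
    wt_of = {t.id: t.wildtype_assay for t in panel.targets
             if t.wildtype_assay}
    bundles = []
    for i, tp in enumerate(scenario.timepoints):
        conc = {}
        for t in panel.targets:
            vaf = tp.true_vaf.get(t.id, 0.0)
            conc[t.id] = _copies_to_conc(
                vaf * tp.total_copies, scenario.n_patient_wells,
                scenario.n_droplets_per_well, droplet_volume_nl)
            if t.id in wt_of:
                conc[wt_of[t.id]] = _copies_to_conc(
                    (1.0 - vaf) * tp.total_copies, scenario.n_patient_wells,
                    scenario.n_droplets_per_well, droplet_volume_nl)
        for ref in panel.reference_assays:
            if ref not in conc:  # CNR-style reference sees all genomes
                conc[ref] = _copies_to_conc(
                    tp.total_copies, scenario.n_patient_wells,
                    scenario.n_droplets_per_well, droplet_volume_nl)
        config = SimulationConfig(
            seed=seed * 10_007 + i,
            species_concentrations=conc,
            n_droplets_per_well=scenario.n_droplets_per_well,
            droplet_volume_nl=droplet_volume_nl,
            n_wells={"patient": scenario.n_patient_wells},
            species_kinds=kinds)
        patient_wells, _ = simulate_wells(config)

        normal_conc = {s: 0.0 for s in conc}
        for ref in set(wt_of.values()) | set(panel.reference_assays):
            normal_conc[ref] = _copies_to_conc(
                scenario.normal_total_copies, scenario.n_normal_wells,
                scenario.n_droplets_per_well, droplet_volume_nl)
        normal_config = SimulationConfig(
            seed=seed * 10_007 + 5000 + i,
            species_concentrations=normal_conc,
            n_droplets_per_well=scenario.n_droplets_per_well,
            droplet_volume_nl=droplet_volume_nl,
            n_wells={"normal_cfDNA": scenario.n_normal_wells},
            species_kinds=kinds)
        normal_wells, _ = simulate_wells(normal_config)

        bundles.append({
            "label": tp.label,
            "day": tp.day,
            "wells": patient_wells,
            "normal_wells": normal_wells,
            "true_vaf": dict(tp.true_vaf),
            "true_total_copies": tp.total_copies,
            "volumes": VolumeSpec(
                elution_volume_ul=40.0, plasma_volume_ml=4.0,
                template_volume_ul=8.0 * scenario.n_patient_wells,
                droplet_volume_nl=droplet_volume_nl),
        })
    return bundles
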