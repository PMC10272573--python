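"""Per-patient ddPCR target selection and multiplex panel assembly.

A patient enters plasma monitoring only when the tumor genome offers at
least two candidate targets at >= 10% tumor VAF, one of which is a known
functionally relevant aberration. Selected targets are assembled into an
amplitude-multiplexed panel: up to three assays share a fluorescence
channel, separated by running them at different relative concentrations
so their positive droplet clusters sit at distinct amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "CandidateTarget",
    "PatientPanel",
    "IneligibleError",
    "Ineligible",
    "select_targets",
    "assign_channels",
    "write_panel_yaml",
    "read_panel_yaml",
]

TARGET_KINDS = frozenset({"snv", "indel", "sv"})
DEFAULT_CHANNELS = ("FAM", "HEX")
# Relative assay-concentration ladder separating clusters in one channel.
DEFAULT_LADDER = (0.5, 1.0, 1.5)
MAX_TARGETS_PER_CHANNEL = 3
CNR_ASSAY = "CNR"


class IneligibleError(ValueError):
    pass


@dataclass
class CandidateTarget:
    id: str
    kind: str  # snv | indel | sv
    vaf_tumor: float
    classification: str  # functional | neutral | vus
    has_wildtype_assay: bool = True
    channel: str | None = None
    concentration_multiplier: float | None = None

    def __post_init__(self):
        if self.kind not in TARGET_KINDS:
            raise ValueError(f"{self.id}: unknown target kind {self.kind!r}")
        if not (0.0 <= self.vaf_tumor <= 1.0):
            raise ValueError(f"{self.id}: vaf_tumor outside [0,1]")
        # Breakpoint-junction assays have no wild-type counterpart: the
        # reference genome has no junction to probe.
        if self.kind == "sv":
            self.has_wildtype_assay = False

    @property
    def wildtype_assay(self) -> str | None:
        return f"{self.id}_wt" if self.has_wildtype_assay else None


@dataclass
class Ineligible:
    """Verdict for a patient excluded from plasma analysis."""

    patient_id: str
    reason: str


@dataclass
class PatientPanel:
    patient_id: str
    targets: list[CandidateTarget]
    reference_assays: list[str] = field(default_factory=list)
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self):
        if len(self.targets) < 2:
            raise ValueError("a patient panel needs at least 2 targets")

    @property
    def target_ids(self) -> list[str]:
        return [t.id for t in self.targets]

    @property
    def species(self) -> list[str]:
        """All assay species in the multiplex: targets then references."""
        return self.target_ids + list(self.reference_assays)


def _rank_key(t: CandidateTarget):
    # SV breakpoint junctions first (tumor-unique sequence, highest
    # specificity), then descending tumor VAF, then id for determinism.
    return (0 if t.kind == "sv" else 1, -t.vaf_tumor, t.id)


def select_targets(
    patient_id: str,
    candidates: Sequence[CandidateTarget],
    min_vaf: float = 0.10,
    n_targets: int = 2,
) -> PatientPanel | Ineligible:
    """Pick the patient's ddPCR targets or explain why none can be.

    Eligibility: at least ``n_targets`` candidates at tumor VAF >=
    ``min_vaf``, of which at least one is classified functional. Among
    eligible candidates, SVs rank before SNVs/indels, then higher VAF,
    then id; the top ``n_targets`` form the panel. Reference assays are
    the wild-type counterparts of selected SNV/indel targets, plus a
    copy-number reference when no target has a wild-type assay.
    """
    high_vaf = [c for c in candidates if c.vaf_tumor >= min_vaf]
    if len(high_vaf) < n_targets:
        return Ineligible(
            patient_id,
            f"only {len(high_vaf)} candidate(s) at VAF >= {min_vaf:.0%}; "
            f"need {n_targets}")
    if not any(c.classification == "functional" for c in high_vaf):
        return Ineligible(
            patient_id,
            f"no functionally relevant aberration among candidates at "
            f"VAF >= {min_vaf:.0%}")
    chosen = sorted(high_vaf, key=_rank_key)[:n_targets]
    references = [t.wildtype_assay for t in chosen if t.wildtype_assay]
    if not references:
        references = [CNR_ASSAY]
    panel = PatientPanel(patient_id=patient_id, targets=chosen,
                         reference_assays=references)
    return assign_channels(panel)


def _ladder_for(n: int, ladder: Sequence[float]) -> list[float]:
    if n == 1:
        return [1.0]
    if n == 2:
        return [ladder[0], ladder[-1]]
    return list(ladder[:n])


def assign_channels(
    panel: PatientPanel,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    ladder: Sequence[float] = DEFAULT_LADDER,
) -> PatientPanel:
    """Distribute targets over channels with a concentration ladder.

    Targets go round-robin over the channels in input order (<= 3 per
    channel); within a channel each target gets a distinct relative
    concentration multiplier so simulated cluster amplitudes separate.
    Deterministic given input order.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("at least one channel required")
    capacity = MAX_TARGETS_PER_CHANNEL * len(channels)
    if len(panel.targets) > capacity:
        raise ValueError(
            f"{len(panel.targets)} targets exceed multiplex capacity "
            f"{capacity} ({MAX_TARGETS_PER_CHANNEL} per channel)")
    per_channel: dict[str, list[CandidateTarget]] = {c: [] for c in channels}
    for i, target in enumerate(panel.targets):
        per_channel[channels[i % len(channels)]].append(target)
    for channel, members in per_channel.items():
        for target, mult in zip(members, _ladder_for(len(members), ladder)):
            target.channel = channel
            target.concentration_multiplier = mult
    panel.channels = channels
    return panel


def write_panel_yaml(panel: PatientPanel, path: str | Path) -> None:
    doc = {
        "patient_id": panel.patient_id,
        "channels": list(panel.channels),
        "reference_assays": list(panel.reference_assays),
        "targets": [
            {"id": t.id, "kind": t.kind, "vaf_tumor": t.vaf_tumor,
             "classification": t.classification,
             "has_wildtype_assay": t.has_wildtype_assay,
             "channel": t.channel,
             "concentration_multiplier": t.concentration_multiplier}
            for t in panel.targets],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_panel_yaml(path: str | Path) -> PatientPanel:
    doc = yaml.safe_load(Path(path).read_text())
    targets = [CandidateTarget(**t) for t in doc["targets"]]
    return PatientPanel(
        patient_id=doc["patient_id"],
        targets=targets,
        reference_assays=list(doc.get("reference_assays", [])),
        channels=tuple(doc.get("channels", DEFAULT_CHANNELS)),
    )
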