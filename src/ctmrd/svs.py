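"""Structural-variant retention rules for merged multi-caller call sets.

SVs surviving here are candidate breakpoint assays: large (or
inter-chromosomal) events hitting protein-coding regions, supported by
at least two callers that use discordant read pairs and/or split reads,
and with adequate read support at the breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SvRecord",
    "SvInputError",
    "DEFAULT_SR_CALLERS",
    "apply_sv_filters",
    "annotate_coding_overlap",
    "read_sv_tsv",
    "write_sv_tsv",
]

SV_TYPES = frozenset({"deletion", "duplication", "inversion", "translocation"})

# Callers whose evidence model rests on discordant pairs / split reads.
DEFAULT_SR_CALLERS = frozenset({"manta", "delly", "tiddit"})


class SvInputError(ValueError):
    pass


@dataclass
class SvRecord:
    """One structural-variant call with breakpoints and read support.

    ``size_bp`` is None for inter-chromosomal events (translocations);
    intra-chromosomal records carry ``|pos_b - pos_a|``. Coordinates are
    1-based in I/O.
    """

    sv_id: str
    sv_type: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    callers: frozenset[str]
    total_paired_reads: int
    discordant_reads: int
    split_reads: int
    affects_coding: bool = False
    size_bp: int | None = None
    manually_confirmed: bool | None = None  # None = review not performed

    def __post_init__(self):
        self.callers = frozenset(c.lower() for c in self.callers)
        if self.chrom_a == self.chrom_b and self.size_bp is None:
            self.size_bp = abs(self.pos_b - self.pos_a)

    def validate(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise SvInputError(f"{self.sv_id}: unknown sv_type {self.sv_type!r}")
        for name in ("total_paired_reads", "discordant_reads", "split_reads"):
            if getattr(self, name) < 0:
                raise SvInputError(f"{self.sv_id}: negative {name}")
        if self.discordant_reads + self.split_reads > self.total_paired_reads:
            raise SvInputError(
                f"{self.sv_id}: discordant+split reads exceed total paired reads")

    @property
    def inter_chromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b


def apply_sv_filters(
    records: Sequence[SvRecord],
    sr_callers: Iterable[str] = DEFAULT_SR_CALLERS,
) -> tuple[list[SvRecord], dict[str, int]]:
    """Apply the SV retention rules; returns (kept, per-rule audit).

    Kept iff all hold:

    * size > 1000 bp, or the event is inter-chromosomal (breakpoint
      junctions of translocations have no linear size);
    * the event implicates protein-coding regions;
    * called by >= 2 callers relying on discordant pairs/split reads;
    * NOT low-support: records with total paired reads <= 20 AND
      discordant+split reads <= 15% of total are excluded (both
      conditions must hold to reject);
    * if a manual breakpoint review verdict is present, it must be True.

    Caller labels outside ``sr_callers`` trigger a warning and do not
    count toward the two-caller requirement.
    """
    sr = frozenset(c.lower() for c in sr_callers)
    audit = {"size": 0, "coding": 0, "callers": 0, "low_support": 0,
             "manual_review": 0}
    kept: list[SvRecord] = []
    for rec in records:
        rec.validate()
        unknown = rec.callers - sr
        if unknown:
            warnings.warn(
                f"{rec.sv_id}: caller(s) {sorted(unknown)} not in the "
                "split-read/discordant-pair set; ignored for consensus",
                stacklevel=2)
        failed = False
        if not (rec.inter_chromosomal or (rec.size_bp or 0) > 1000):
            audit["size"] += 1
            failed = True
        if not rec.affects_coding:
            audit["coding"] += 1
            failed = True
        if len(rec.callers & sr) < 2:
            audit["callers"] += 1
            failed = True
        support = rec.discordant_reads + rec.split_reads
        if (rec.total_paired_reads <= 20
                and support <= 0.15 * rec.total_paired_reads):
            audit["low_support"] += 1
            failed = True
        if rec.manually_confirmed is False:
            audit["manual_review"] += 1
            failed = True
        if not failed:
            kept.append(rec)
    return kept, audit


def annotate_coding_overlap(records: Sequence[SvRecord],
                            coding_bed: str | Path) -> None:
    """Set ``affects_coding`` from breakpoint overlap with a coding BED.

    BED intervals are half-open 0-based on disk; record positions are
    1-based. A record affects coding if either breakpoint falls inside a
    coding interval.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    bed = pd.read_csv(coding_bed, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for chrom, grp in bed.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            zip(grp["start"], grp["end"]))
    for rec in records:
        hits_a = trees.get(rec.chrom_a) and trees[rec.chrom_a][rec.pos_a - 1]
        hits_b = trees.get(rec.chrom_b) and trees[rec.chrom_b][rec.pos_b - 1]
        rec.affects_coding = bool(hits_a) or bool(hits_b)


_TSV_COLUMNS = ["sv_id", "sv_type", "chrom_a", "pos_a", "chrom_b", "pos_b",
                "size_bp", "callers", "total_paired_reads",
                "discordant_reads", "split_reads", "affects_coding",
                "manually_confirmed"]


def read_sv_tsv(path: str | Path) -> list[SvRecord]:
    """Read a merged SV table; the caller column is a comma-list."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.to_dict("records"):
        size = row.get("size_bp")
        manual = row.get("manually_confirmed")
        records.append(SvRecord(
            sv_id=str(row["sv_id"]),
            sv_type=row["sv_type"],
            chrom_a=str(row["chrom_a"]), pos_a=int(row["pos_a"]),
            chrom_b=str(row["chrom_b"]), pos_b=int(row["pos_b"]),
            size_bp=None if pd.isna(size) else int(size),
            callers=frozenset(str(row["callers"]).split(",")),
            total_paired_reads=int(row["total_paired_reads"]),
            discordant_reads=int(row["discordant_reads"]),
            split_reads=int(row["split_reads"]),
            affects_coding=bool(row.get("affects_coding", False)),
            manually_confirmed=None if manual is None or pd.isna(manual)
            else bool(manual),
        ))
    return records


def write_sv_tsv(records: Sequence[SvRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        d = asdict(rec)
        d["callers"] = ",".join(sorted(rec.callers))
        rows.append(d)
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
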