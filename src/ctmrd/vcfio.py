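"""VCF ingestion for tumor/normal somatic calls.

Maps a two-sample (tumor, normal) VCF onto ``VariantRecord`` via a
configurable key map, since producers differ in which FORMAT/INFO keys
carry depths, allele fractions and annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .variants import VariantRecord

__all__ = ["VcfKeyMap", "read_vcf"]


@dataclass
class VcfKeyMap:
    """Which VCF keys feed which record fields.

    Sample resolution is by name when given, else tumor is taken as the
    first sample and normal as the second.
    """

    tumor_sample: str | None = None
    normal_sample: str | None = None
    depth_format: str = "DP"
    allele_depth_format: str = "AD"
    af_format: str = "AF"
    max_af_info: str = "MaxAF"
    gnomad_info: str = "GNOMADAF_popmax"
    base_quality_info: str = "QSS"  # per-variant normalized base quality
    consequence_info: str = "Consequence"
    gene_info: str = "Gene"
    external_class_info: str = "ExternalClass"
    splice_impact_info: str = "SpliceImpactPct"
    splice_delta_info: str = "SpliceAI_delta"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VcfKeyMap":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def _scalar(value):
    """INFO values may arrive as tuples/bytes; take the first scalar."""
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    if isinstance(value, bytes):
        value = value.decode()
    return value


def read_vcf(path: str | Path, keymap: VcfKeyMap | None = None) -> list[VariantRecord]:
    """Read tumor/normal calls from a (plain or bgzipped) VCF."""
    from cyvcf2 import VCF

    keymap = keymap or VcfKeyMap()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ValueError("expected a two-sample (tumor, normal) VCF")
    t_idx = (samples.index(keymap.tumor_sample)
             if keymap.tumor_sample else 0)
    n_idx = (samples.index(keymap.normal_sample)
             if keymap.normal_sample else 1)

    records = []
    for var in vcf:
        dp = var.format(keymap.depth_format)
        ad = var.format(keymap.allele_depth_format)
        af = var.format(keymap.af_format)
        if dp is None or ad is None:
            continue
        tumor_depth = int(dp[t_idx][0])
        normal_depth = int(dp[n_idx][0])
        tumor_ref, tumor_alt = int(ad[t_idx][0]), int(ad[t_idx][1])
        if af is not None:
            tumor_af = float(af[t_idx][0])
        else:
            tumor_af = tumor_alt / tumor_depth if tumor_depth else 0.0
        info = var.INFO
        gnomad = _scalar(info.get(keymap.gnomad_info))
        splice_pct = _scalar(info.get(keymap.splice_impact_info))
        splice_delta = _scalar(info.get(keymap.splice_delta_info))
        consequence = _scalar(info.get(keymap.consequence_info)) or "unknown"
        records.append(VariantRecord(
            chrom=var.CHROM, pos=var.POS, ref=var.REF,
            alt=var.ALT[0] if var.ALT else "",
            tumor_depth=tumor_depth, normal_depth=normal_depth,
            tumor_alt_depth=tumor_alt, tumor_ref_depth=tumor_ref,
            tumor_af=tumor_af,
            tumor_max_af=float(_scalar(info.get(keymap.max_af_info))
                               or tumor_af),
            base_quality=float(_scalar(info.get(keymap.base_quality_info))
                               or 0.0),
            consequence=str(consequence),
            gene=str(_scalar(info.get(keymap.gene_info)) or ""),
            gnomad_popmax_af=None if gnomad is None else float(gnomad),
            external_class=str(_scalar(info.get(keymap.external_class_info))
                               or "unannotated"),
            splice_impact_pct=None if splice_pct is None else float(splice_pct),
            splice_delta=None if splice_delta is None else float(splice_delta),
            is_splice_site=str(consequence) == "splicing",
        ))
    return records
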