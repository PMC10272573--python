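# ctmrd

Tumor-informed circulating tumor DNA (ctDNA) monitoring of measurable
residual disease (MRD) in B-cell lymphoma, from whole-genome sequencing
(WGS) variant calls to longitudinal plasma readouts.

The package is aimed at translational researchers building
patient-specific liquid-biopsy assays: WGS of a tumor/normal pair
nominates somatic SNVs, indels and structural-variant (SV) breakpoints;
two high-VAF markers per patient are tracked in serial plasma cfDNA by
multiplex droplet digital PCR (m-ddPCR); and the resulting droplet
counts are turned into absolute concentrations, variant allele
fractions, positivity calls and relapse flags.

## What it computes

**Marker nomination.** Somatic SNV/indel calls pass a hard filter
cascade (tumor and normal depth ≥ 10, tumor alt depth ≥ 3, tumor
AF ≥ 0.05, max AF < 1, gnomAD popmax AF ≤ 0.001, base quality ≥ 20,
both alleles observed), panel/consequence restriction, and functional
classification with splice-prediction overrides. SVs are kept when
> 1000 bp or inter-chromosomal, coding, supported by ≥ 2
split-read/discordant-pair callers, and not low-support (total pairs
≤ 20 **and** support ≤ 15% rejects). Patients with ≥ 2 markers at
≥ 10% tumor VAF, one functionally relevant, get a 2-target multiplex
panel (≤ 3 assays per fluorescence channel on a concentration ladder).

**ddPCR quantification.** For k positive droplets of N (merged wells,
droplet volume 0.85 nL), copies per droplet are λ̂ = −ln(1 − k/N), with
a Wilson 95% CI transformed through λ(p) and reported as copies/20 µl.
VAF is computed by wild-type, partner-assay or copy-number-reference
routes; the per-assay false-positive rate (FPR) is the apparent VAF in
9–12 normal-plasma wells; a target is positive only when VAF > FPR,
patient and normal CIs don't overlap, and ≥ 3 positive droplets with
≥ 1 single-positive are seen. Copies/ml plasma =
elution / (template × plasma volume) × copies; theoretical limit of
detection LOD = 3 / total cfDNA copies analyzed.

**Timelines.** Per-patient longitudinal courses are classified for
clearance after treatment cycle 1, negativity at final evaluation,
molecular relapse (first positive after a negative final) and lead time
to clinical relapse.

**Synthetic data.** A seeded generator produces every pipeline input
with known ground truth: planted-violation variant/SV tables,
multiplexed droplet partitions under Poisson co-encapsulation
(optionally with 2D amplitudes and nearest-centroid gating),
normal-plasma background wells, and longitudinal patient scenarios.

## Worked example

Simulate the packaged relapse course (diagnosis at 10% VAF, clearance
under treatment, re-emergence at the second yearly follow-up) and
classify it:

```bash
mrd timeline --seed 7 --out report/
```

prints

```json
{
  "patient_id": "PatSim",
  "clearance_after_cycle1": true,
  "ctdna_negative_at_final": true,
  "molecular_relapse": "follow_up_2",
  "molecular_relapse_day": 855,
  "lead_time_days": 175,
  "refractory": false,
  "n_timepoints": 6
}
```

— ctDNA cleared after the first treatment cycle, stayed negative
through the end of primary treatment, and re-emerged at the second
follow-up sample 175 days (25 weeks) before the planted clinical
relapse. `report/timeline.tsv` holds one row per timepoint × target;
the diagnosis rows read (abridged):

```
timepoint   target        vaf      fpr   lod        k_positive  target_positive
diagnosis   MYD88_L265P   0.1004   0.0   0.000456   595         True
diagnosis   IGH_BCL2_bp   0.1031   0.0   0.000456   611         True
```

i.e. both assays recover the planted 10% VAF, with a theoretical LOD of
0.046% given the ~6600 cfDNA copies interrogated.

The same stages are available as a library (`ctmrd.apply_snv_filters`,
`ctmrd.select_targets`, `ctmrd.quantify_sample`, ...) and as the other
CLI commands `mrd filter-snv`, `mrd filter-sv`, `mrd select-targets`,
`mrd quantify`, `mrd simulate`.

## Layout

- `src/ctmrd/variants.py` — SNV/indel filter cascade, panel
  restriction, functional classification; `vcfio.py` maps tumor/normal
  VCFs through a configurable key map.
- `src/ctmrd/svs.py` — SV retention rules and coding-BED annotation.
- `src/ctmrd/targets.py` — eligibility, target ranking, channel and
  concentration-ladder assignment.
- `src/ctmrd/ddpcr.py` — Poisson quantification, VAF routes, FPR,
  positivity, copies/ml, LOD, per-sample composition.
- `src/ctmrd/simulate.py` — droplet partition simulator, amplitude
  gating, planted-truth tables, longitudinal scenarios.
- `src/ctmrd/timeline.py` — course classification and reports.

`docs/methods.md` documents the models, defaults, design choices and
limitations.
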