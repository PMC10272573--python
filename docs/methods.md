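# Methods

`ctmrd` models the analytical chain of tumor-informed liquid-biopsy MRD
monitoring in B-cell lymphoma: whole-genome sequencing of a tumor/normal
pair nominates patient-specific somatic markers; a small multiplex ddPCR
panel then tracks those markers in serial plasma samples at far greater
sensitivity than imaging. This note describes the models, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions made where the design was open.

## Variant filtering and classification

Somatic SNV/indel calls are filtered by a conjunction of hard
thresholds: total read depth ≥ 10 in **both** tumor and normal
(interpreting the depth requirement as a conjunction over the pair),
tumor alternate-allele depth ≥ 3, tumor allele fraction ≥ 0.05, maximum
tumor allele fraction < 1, population (gnomAD popmax) allele frequency
≤ 0.001, normalized per-variant base quality ≥ 20, and non-zero read
counts for both alleles. Because the rules are a pure conjunction, the
cascade is order-independent and idempotent — both are asserted as
property tests. A variant absent from the population database is
treated as frequency 0 (absent = rare), the standard somatic-filtering
convention; the alternative (dropping unannotated variants) would
discard exactly the private variants ddPCR monitoring needs. The audit
counts every rule a record violates, so audit totals can exceed the
number of rejected records.

Candidate restriction keeps variants annotated exonic or splicing in a
configurable gene panel (a plain text list; a small demo lymphoid panel
ships with the package — the clinical panel is configuration, not
code).

Functional status starts from an external decision-support verdict
(functional / neutral / VUS) supplied as input. For splice-site
variants, splice-impact predictions override in either direction: a
predicted impact ≥ 40% or a delta score > 0.5 forces functional; when
both scores fail, a functional external verdict is downgraded to VUS —
never to neutral, since the failing scores argue against impact but do
not establish neutrality. A per-variant manual-override flag forces VUS
regardless, modeling variants with high predicted impact but no
truncating effect on manual transcript inspection.

Structural variants are retained when larger than 1000 bp (or
inter-chromosomal, where a junction has no linear size — this keeps the
canonical IGH translocations), implicating protein-coding sequence,
called by at least two of the callers whose evidence model uses
discordant pairs/split reads, and not low-support. The low-support
exclusion is a strict conjunction, exactly as specified: total paired
reads ≤ 20 **and** discordant+split reads ≤ 15% of total. Either
condition alone never rejects, which makes the kept set monotone in
read support. An optional manual-review column, when present, must be
true.

## Target selection and multiplexing

A patient is eligible for plasma monitoring when at least two candidate
markers reach 10% tumor VAF and at least one is a known functionally
relevant lymphoma aberration; both thresholds are parameters with those
defaults. Among eligible candidates the ranking is: breakpoint (SV)
assays first — a junction sequence is tumor-unique, so its assay
background is essentially zero — then descending tumor VAF, then
lexicographic id for determinism. No total order is externally imposed
here; this is the package's own defensible instantiation, and it is
deliberately deterministic so panels are reproducible.

Amplitude multiplexing places up to 3 assays per fluorescence channel
(default channels FAM and HEX), separated by a relative assay
concentration ladder (default 0.5×/1.0×/1.5×) so positive clusters sit
at distinct amplitudes. Wet-lab assay optimization is out of scope; the
ladder exists so the simulator can generate separable clusters.

## Droplet digital PCR quantification

With N accepted droplets of volume v (default 0.85 nL, the nominal
QX200 droplet volume; configurable) and k positive for a species, the
Poisson estimate of mean copies per droplet is

    λ̂ = −ln(1 − k/N),

concentration per µl is λ̂/v and is reported on the copies/20 µl scale.
Replicate wells are merged by pooling counts before estimation, which
is exactly equivalent to treating the union of droplets as one well
(asserted as an identity test). Saturated reactions (k = N) raise an
error instructing dilution rather than applying a continuity
correction: MRD plasma work lives in the rare-event regime, and a
silently corrected saturated estimate would be misleading.

The 95% CI is a Wilson score interval on p̂ = k/N transformed through
λ(p) and the volume scaling. Wilson was preferred because its lower
bound behaves sensibly at the small k typical of MRD (k = 3–10);
Clopper–Pearson is available behind a flag for users who want
guaranteed-conservative coverage. Simulated coverage at λ = 0.05,
N = 20000 sits within 93–97% (asserted over 2000 replicates).

VAF is computed on the copies/20 µl scale by three routes:

* **wild-type**: target / (target + wild-type) at the mutated locus;
* **partner**: target / (partner target + partner wild-type), for
  breakpoint assays and targets without a wild-type counterpart — the
  denominator is the total genome equivalents measured at the *other*
  target's locus in the same multiplex;
* **CNR**: target / copy-number reference.

Ratios are clamped to [0, 1] with a flag; a zero denominator returns an
undefined-VAF sentinel (NaN), which is semantically distinct from a
measured VAF of 0 (no amplifiable reference versus no mutant signal).

A VAF interval is needed for parameter-recovery checks but no standard
formula is imposed by the estimator itself. We use a Wilson interval on
estimated molecule counts: in the rare-event regime the per-species
molecule estimates m = λ̂N are approximately Poisson, so conditional on
the total the mutant count is binomial and a Wilson interval on
m_target / m_denominator applies. Simulated coverage at true VAF 1%
with 6 × 18000 droplets is ≈95%.

The false-positive rate of an assay is its apparent VAF in merged
normal-plasma wells, computed by the assay's own route and per run
(9–12 wells recommended; fewer warns). A sample is called MRD-positive
for a target only if all three criteria hold in merged wells: VAF
strictly above the assay FPR; patient and normal concentration CIs
non-overlapping (patient lower bound above normal upper bound); and at
least 3 positive droplets with at least 1 single-positive droplet — a
droplet positive for the target species and nothing else (the package's
operational definition; co-encapsulation with wild-type molecules makes
pure doubles suspicious at high wild-type load, singles are not).

Copies per ml plasma scale the measured copies by the analyzed eluate
fraction: `elution_µl / (template_µl × plasma_ml) × copies`. The
"copies measured" quantity is the estimated molecules in the analyzed
droplets, λ̂ × N per species; the same quantity, summed over target and
reference species, is the total cfDNA input to the theoretical limit of
detection `LOD = 3 / total copies` — three molecules being the minimum
detectable signal under the droplet-support criterion. Both conventions
are configurable at the call site and stated here because vendor
reports are ambiguous about per-well versus per-reaction totals.

## The synthetic-data generator

The generator emulates ideal Poisson partitioning: each species loads
each droplet independently with Poisson(λ_s) molecules,
λ_s = conc_s × v/20 µl; a droplet's cluster is the set of species
present. Per-well cluster counts are drawn multinomially over the 2^S
combinations — the exact joint law of that model — so no per-droplet
bookkeeping is needed unless 2D amplitudes are requested, in which case
droplets are materialized with Gaussian clusters (configurable centroid
step, spread, rain fraction) and can be re-gated by nearest-centroid
assignment.

Assay background is an independent per-droplet false-positive flip, one
rate per assay class: 5 × 10⁻⁶ for SNV/indel assays and 5 × 10⁻⁷ for
breakpoint assays. Against a typical 5000–6000 genome-equivalent normal
input over 12 wells these rates produce apparent FPRs of order 0.02%
and 0.0025% respectively — the magnitudes reported for optimized assays
of each class — with the SV rate far lower because a junction sequence
does not exist in normal DNA.

What the generator does **not** model: droplet volume dispersion, PCR
efficiency and rain chemistry, probe cross-reactivity (beyond the flip
rate), fluorescence physics, and molecule fragmentation. Passing tests
therefore demonstrate correctness of the estimators and decision logic
under ideal partitioning, not robustness to instrument artifacts.

Planted-truth variant/SV tables contain records violating exactly one
named filter rule each, plus clean records, with the truth emitted
alongside — the oracle for filter-equivalence tests.

### Longitudinal scenarios

The packaged relapse scenario mirrors a clinically anchored sampling
schedule (diagnosis, after cycle 1, interim, final evaluation, two
yearly follow-ups): diagnosis at 10% VAF with 6000 genome equivalents;
0.1% against 1200 copies after cycle 1 (1.2 expected mutant molecules —
below the 0.25% LOD of that sample, so the course shows clearance);
zero through final evaluation and follow-up 1; re-emergence at 5% at
follow-up 2 with clinical relapse planted 175 days (25 weeks) later.
Per-timepoint cfDNA inputs are the package's choice within the
realistic range for lymphoma plasma (hundreds to ~19000 copies/ml),
with lower inputs during and after treatment. A zero-VAF companion
scenario exercises the all-negative path. Problem sizes throughout the
test suite (3 patient + 12 normal wells of 18000 droplets; 400–2000
replicates for coverage studies; 500 replicates for detection curves)
were chosen as the smallest sizes at which the binomial sampling error
is well below the asserted tolerances.

## Timeline classification

Clearance after cycle 1 requires a positive diagnosis sample and a
negative post-cycle-1 sample; a patient negative at diagnosis has
undefined clearance (reported `not_assessed`, never imputed). Molecular
relapse is the first positive timepoint after a negative final
evaluation — a course never negative at final is refractory, not
relapsing — and lead time is the clinical relapse date minus that
timepoint's date. A single positive follow-up sample triggers the flag;
in clinical practice confirmation on a second sample would be prudent,
and the summary exposes the triggering timepoint so users can demand
confirmation.

Reports store measured values untouched; only plots floor zero VAF/FPR
to 0.001% so they remain visible on a log axis.

## Known limitations

* Ideal-partitioning assumption: real droplet volume CVs of a few
  percent bias λ̂ slightly; not modeled.
* The FPR is a point estimate from finite normal wells; at SV-assay
  background levels it is frequently exactly 0, making the
  VAF-above-FPR criterion pass on any signal — the droplet-support and
  CI criteria then carry the specificity burden.
* CNV-based markers, IG rearrangement calling, and panel-sequencing
  concordance analyses are out of scope; upstream callers and
  annotation services are consumed as inputs, never re-implemented.
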