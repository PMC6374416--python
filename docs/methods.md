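# Methods

## Scope and model

`panrec` scores recurrent somatic alterations of a fixed gene panel across
cancer types and integrates them into a pan-cancer target ranking. Three
evidence channels are scored independently and then combined:

1. focal copy-number recurrence (gene-level, GISTIC-style),
2. mutation recurrence (multi-caller vote), and
3. transcript-fusion recurrence (pan-cancer pair counts).

Per gene g and cancer type c the recurrent score
`R(g,c) = 1[SCNA recurrent] + 1[mutation recurrent] + 1[fusion recurrent]`
∈ {0,…,3}; the overall recurrent score is `Σ_c R(g,c)`. The SCNA channel
contributes at most one point per cancer even when a gene has both a
recurrent gain and a recurrent loss there: with three channels and a score
"from 0 to 3", one point per channel is the only consistent reading.

## Focal SCNA scoring

**Cohort hygiene.** Samples with more than 2,000 segments are excluded
(strict inequality: exactly 2,000 is kept). Segments spanning ≥ 50% of a
chromosome arm are treated as broad events and removed from focal scoring;
arm coordinates come from a genome model (chromosome lengths plus
centromeres).

**Gene-level collapse.** SEG records are 1-based inclusive and are converted
to half-open coordinates internally; gene models are BED-like 0-based
half-open. The gene-level logR of a sample is the overlap-length-weighted
mean of the segments intersecting the gene body; a sample with no
overlapping segment gets 0 (diploid) with a coverage note in the log.

**Status and G-score.** Five-level status from the gene-level logR with
thresholds ±0.1 (gain/loss) and ±0.9 (amplification/deep deletion), strict
inequalities at the boundaries. These are the conventional GISTIC2 noise
thresholds; the source data do not print them. Gains and losses are scored
separately: `G = freq × mean|logR| among altered samples`, equivalently the
per-sample mean of altered-sample amplitudes, so G is linear in per-sample
contributions — the property the permutation null exploits.

**Permutation null.** For each permutation, every sample's gene-level
contribution vector (|logR| where altered, else 0, genes in genomic order)
is cyclically shifted by an independent uniform offset; the null G of a gene
is the mean of the shifted contributions. This preserves each sample's
alteration burden and the local autocorrelation of segments while breaking
gene identity, approximating "permute the events along the genome" at gene
resolution. `p = (1 + #{null ≥ observed}) / (1 + K)` with K = 1,000 by
default; Benjamini–Hochberg across the panel per direction. At gene (rather
than locus) resolution, the q ≤ 0.25 rule plays the role of the
peak-region significance filter; this is a documented divergence from
GISTIC2's background model, so printed G-score thresholds from locus-level
analyses should be treated as rank cutoffs, not absolute calibration.

**Four-criteria recurrence call.** An event is a recurrent,
expression-relevant focal SCNA iff (1) q ≤ 0.25, (2) G ≥ 0.1,
(3) the gene is detectable in that cancer type (90th-percentile FPKM ≥ 1,
linear-interpolation quantile), and (4) Pearson p < 0.001 with r > 0 between
log2(FPKM+1) and the gene-level logR. Log base 2 matches the logR units;
zero variance in either vector fails criterion (4) with a reason code.
The overall G-score sums G over passing cancers, per direction.

## Mutation scoring

**Record filter.** Only records whose filter tag consists solely of
PASS/WGA tokens (comma-separated, case-insensitive) are retained:
"PASS", "wga", and "PASS,wga" pass; any third token, or an unrecognized
compound such as "PASS;wga", disqualifies the record.

**Lite callers.** The burden caller estimates a neutral per-base rate from
the panel-wide silent mutation count within each cancer type, scales it by a
neutral non-silent:silent ratio of 3:1 (the standard coding expectation),
and tests each gene's non-silent count with a one-sided binomial tail over
`n_samples × gene length` trials; BH across the panel, flagged at q < 0.1.
If a cohort has no silent mutations the rate falls back to a configurable
floor with a warning. The clustering caller takes the maximum per-residue
mutation count as its statistic and compares it with K uniform
re-placements of the same number of mutations along the protein (empirical
p with the +1 correction, flagged at p < 0.05); genes with fewer than three
positioned mutations are not evaluable and never pass.

Only these two callers are built in; functional-impact and 3D-clustering
methods have no lite stand-ins, and their verdicts enter through the
external flags table (`read_caller_flags`) so the mutation index can span
0–5 as with five configured callers. The recurrence call is index ≥ 2
regardless of how many callers are configured.

**Frequency and M-score.** The mutation frequency denominator is all
retained samples of the cancer type; the numerator counts samples with ≥ 1
non-silent mutation in the gene (silent mutations are excluded from the
frequency, consistent with driver intent). `M = index × frequency`; the
overall M-score sums M over cancers with index ≥ 2 by default (a flag
switches to summing all cancers, since either convention is defensible).

**Annotation.** Category follows a fixed MAF-classification table
(missense; truncating = nonsense, frameshifts, splice site, nonstop,
translation start; inframe; silent; everything else "other" with a log
note). `CCF = clip(VAF × (purity·CN + 2(1−purity)) / (purity·mult), 0, 1)`;
clonal iff CCF ≥ 0.9 — a point-estimate stand-in for a posterior
classification, and deliberately crude (see Limitations). Homozygous iff
multiplicity equals the local total copy number. Timing: a mutation on more
than one copy must predate the copy-number event, so
before_event ⇔ multiplicity > 1 and early ⇔ clonal ∧ before_event; all
other mutations are late. Mutations with missing CCF inputs are labeled not
evaluable and excluded from fraction denominators (fractions over an empty
denominator are missing, not zero).

**Meta-domain hotspots.** Members whose maximum pairwise similarity is
below 20% are excluded. Non-silent mutations inside retained members'
domain spans are pooled onto alignment columns; column c with k of N pooled
mutations is tested against Binomial(N, w_c), where w_c is the fraction of
aligned residues in column c (an exchangeable-occupancy null — simpler than
alignment-trimming schemes but consistent with a consensus alignment); BH
across occupied columns; significant iff p < 0.05 and q < 0.05. For the
synthetic panel, `DomainAlignmentMap.from_panel` builds identity alignments
(all members of a domain share its length).

## Fusions

Events are deduplicated per (sample, 5′ gene, 3′ gene). Pair identity is the
ordered (5′, 3′) tuple — orientation is biologically meaningful — with an
unordered aggregation reported alongside. A pair is recurrent at ≥ 2 events
across all cancer types; a gene earns the fusion point in a cancer type iff
it participates in a recurrent pair with at least one event in that type
(recurrence is defined pan-cancer but the score is assigned per cancer;
this reconciliation is the package's choice). Tiers are opaque confidence
labels in 1–4.

## Expression analyses

Detectability: 90th-percentile FPKM ≥ 1 per gene and cancer type;
lineage-restricted means detectable somewhere but not everywhere, with the
count of detectable types reported so users can apply their own cutoff.
Co-expression: Pearson r on log2(FPKM+1) per cancer type; the pan-cancer
statistic is the mean per-cancer r rather than a pooled correlation, which
would be confounded by lineage (Simpson's paradox); ties break by gene id.
Pre-ranked GSEA uses the classic weighted statistic (hits weighted by
|statistic|^p with p = 1, misses by −1/(N−n)); the null is K permutations
of the gene labels; NES = ES / mean |null ES| of the same sign; p has the
+1 correction; BH across sets; sets smaller than 5 after intersection are
skipped.

## Report formatting

Cohort ratios are printed as percents by truncating to two decimals and
stripping a trailing zero (minimum one decimal): 63/73 → 86.3,
68/73 → 93.15, 154/192 → 80.2, 81/400 → 20.25. This single rule reproduces
every printed convention the package targets; ordinary rounding to either
one or two decimals cannot.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes; its
defaults are the study conditions used throughout the tests.

| knob | default | what it emulates |
|---|---|---|
| panel | 73 genes: 12 writers, 6 writer_readers, 37 readers, 18 erasers | a histone-acetylation modulator panel with domain annotations (BRD 110 aa, HAT 170 aa, deacetylase 300 aa) |
| genome | 8 × 120 Mb chromosomes, centromere at 40% | a compact genome for arm/focal logic |
| cohort | 4 cancer types × 150 samples | per-cancer TCGA-like sample groups |
| background segments | Poisson(60)/sample, length log-uniform 0.5–20 Mb, logR ~ N(0, 0.15); plus Poisson(1)/sample whole-arm events, logR ~ N(0, 0.2) | segmental background + broad events for the focal filter |
| planted SCNAs | focal 0.5–5 Mb covering the gene in U(30–60%) of samples, logR ~ N(±0.6, 0.1) | recurrent focal driver events |
| expression | log2(FPKM+1) = baseline N(3,1) + lineage offset N(0,0.7) + 1.0 × logR + N(0,0.5), clipped at 0 | lineage signatures plus a copy-number dosage effect |
| mutations | Poisson(1.5/Mb × gene length)/sample; drivers ×15 with the excess all non-silent and half placed at one hotspot codon in the first domain | background vs positively selected genes |
| classification mix | background 50% missense / 25% silent / 15% truncating / 5% inframe / 5% other; driver excess 80/20 missense/nonsense | a neutral 3:1 non-silent:silent ratio, matching the burden caller's calibration |
| CCF mixture | clonal w.p. 0.7 at CCF 1.0, else Beta(2,2); clonal mutations have multiplicity 2 w.p. 0.75 (local CN 2 w.p. 0.3, else 3), otherwise multiplicity 1 at CN 2 | clonal > 65%, early > 50%, heterozygous ~ 75% — the fractions reported for this gene family |
| reads | purity U(0.3,0.9) per sample; VAF = CCF·mult·p/(p·CN+2(1−p)); alt ~ Binomial(120, VAF) | fixed 120× depth keeps CCF estimable |
| fusions | Poisson(0.04)/sample, random panel × partner pairs, tiers (0.75, 0.125, 0.075, 0.05) | fusions as rare events with the observed tier mix |
| filter tags | PASS 92%, wga 3%, "PASS,wga" 1%, other 4% | the record filter has real work to do |

Random streams are keyed by (seed, cancer-type index), so adding a cancer
type never perturbs earlier ones. Panel genes are spaced ≥ 6 Mb apart so a
planted focal event (≤ 5 Mb) never covers two panel genes — real cohorts do
show proximity co-alteration, which the generator deliberately avoids to
keep planted-truth labels unambiguous. Purity is drawn per sample (the CCF
model assumes one purity per tumor). Driver mutation totals are
multiplier × background (so moment checks hold), decomposed into a 1×
background-classified part and a (multiplier−1)× all-non-silent excess, with
the hotspot fraction applied to the excess.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: SNP-array probe noise and segmentation artifacts,
mutational signatures and trinucleotide context, subclonal copy-number
structure, co-amplified gene neighborhoods, recurrent fusion partners with
biological meaning, and between-sample purity/ploidy estimation error
(purity is known exactly to the CCF estimator).

## Numerical conventions and scaling

Empirical p-values always use the +1 correction and a 1e-15 tolerance on
"≥ observed" comparisons. BH is `statsmodels.stats.multitest.multipletests`.
Quantiles use linear interpolation. Percent strings use exact decimal
arithmetic. Tests run the default study conditions at modest problem sizes —
the null-calibration check uses 20 cohorts of 73 × 4 × 150 with K = 1,000,
the recovery checks 5 such cohorts — chosen so the full suite completes in a
few minutes on one core while keeping every statistical margin
well-separated from its threshold.

## Known limitations

* The permutation null works at gene resolution; it does not estimate peak
  boundaries or arm-level significance, and lite G-scores are on a
  comparable but not identical scale to locus-level implementations.
* The clonality rule (point CCF ≥ 0.9) ignores estimation uncertainty: at
  120× depth a truly clonal mutation with VAF ≈ 0.3 is misclassified
  subclonal ~20% of the time. Measured clonal/subclonal agreement with the
  generator's truth is ~0.86; a posterior-interval classifier would be
  needed to push this above 0.9 at this depth.
* The burden caller's 3:1 non-silent:silent scaling is a fixed constant, not
  a covariate model; genes with unusual codon composition would be
  mis-calibrated on real data.
* The hotspot null weights columns by occupancy only; conservation-based
  trimming is not implemented.
* Plate ordering in barcode deduplication is lexicographic on the plate
  string; alphanumeric plates have no other documented order.
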