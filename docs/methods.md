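# Methods

`msatprof` implements a complete microsatellite instability (MSI) / loss of
heterozygosity (LOH) profiling pipeline for paired tumor–normal
fragment-analysis data, from sized peak tables to patient classification,
cohort mutation-profile statistics, and survival association analysis.

## Data model and locus catalog

The unit of observation is a *locus–sample pair*: one microsatellite locus
amplified from a patient's tumor and matched normal tissue, sized on a
capillary sequencer, and summarized as a list of (fragment size in bp, peak
height) pairs per tissue.

The bundled default catalog defines 66 loci: 61 microsatellites inside 19
colorectal-cancer-related genes, partitioned 26 tumor-suppressor (TS) / 20
oncogene / 9 mismatch-repair (MMR: MLH1, MSH2, MSH6, PMS2) / 6 DNA-repair
(DNAR: MGMT) by gene class and 53 intron / 1 exon / 5 noncoding / 2 3′-UTR
by region, with repeat units of 38 dinucleotide / 8 trinucleotide / 13
tetranucleotide loci plus one pentanucleotide (TP53-1, AAAAT) and one
mononucleotide run; plus the five Bethesda reference markers (BAT25, BAT26,
D2S123, D5S346, D17S250). The literature on this panel reports the group
denominators (26/20/9/6, 53/1/5/2, 38/8/13) but not a complete per-locus
table, so the shipped catalog is a reconstruction consistent with every
reported denominator and with the locus names in common use; it is a
plain TSV and fully user-replaceable — all downstream computation reads
group membership from the catalog, never from constants. One documented
inconsistency exists in the source material between two sets of repeat-unit
counts (38/8/13 vs 35/6/12); the catalog follows the set used by the
frequency denominators.

## Genotyping (normal tissue)

Fragment sizes from sizing software carry sub-bp jitter while true alleles
live on an integer lattice, so peaks are first merged into 1-bp bins
(heights summed, size = height-weighted mean rounded to integer;
`size_bin_bp`, default 1.0). Binning in integer bp rather than repeat units
prevents 1-bp sizing jitter at dinucleotide loci from creating phantom
alleles.

Two filters then run, in order:

1. **Noise floor** — peaks strictly below `min_rel_height` × (tallest peak)
   are discarded (default 0.10, conventional for capillary STR data).
2. **Stutter** — a peak exactly one repeat unit *below* a strictly taller
   retained peak, with relative height ≤ `stutter_ratio` (default 0.15), is
   PCR slippage stutter and is discarded. Stutter is modeled only at −1
   repeat; +1 artifacts are left to the noise floor. Anchoring is single
   pass against the noise-retained peak set, so removal order cannot
   matter.

The surviving peaks are the germline alleles: one → homozygous, two →
heterozygous (*informative*, the precondition for LOH assessment), zero →
`LOW_SIGNAL`, more than two → `FAILED`. Failed loci are treated as not
assayed: they leave every numerator and shrink the effective Bethesda panel
rather than counting as stable.

Genotyping is scale-invariant (all thresholds are relative heights) and
idempotent with respect to binning; both properties are enforced by
property-based tests.

## MSI calling

MSI is detected as **de novo alleles**: after applying the same noise and
stutter filters to the tumor peaks — with the normal alleles serving as
additional stutter anchors, so stutter of an LOH-diminished allele cannot
surface as a novel peak — any retained tumor peak whose binned size is not
a germline allele is a novel allele, and one or more novel alleles make the
locus MSI. A germline allele *slipped* by whole repeat units (the old size
absent, a shifted size present) is automatically a novel allele under this
rule. No cap is placed on the shift distance: the "slipped by a few base
pairs" phenotype is a special case, and distant novel alleles are equally
real.

## LOH calling

At loci heterozygous in the normal, allelic imbalance is quantified by the
ratio of tumor to normal allelic ratios. With normal allele heights (n₁,
n₂) and tumor heights (t₁, t₂) at the same binned sizes (a missing tumor
allele contributes height 0):

    R = (t₁/t₂) / (n₁/n₂),  r = min(R, 1/R)

r is the retained fraction of the diminished allele; LOH is called when
**r < 0.65, strictly** — i.e. strictly more than 35% of one allele's
relative signal is lost — including complete loss (r = 0). The folded
ratio is computed from height products in both orientations so that the
boundary case r = 0.65 is exactly symmetric and never drifts across the
threshold by a rounding ulp. Homozygous loci, and tumors with no retained
signal at either allele position, are non-informative for LOH (but still
enter MSI assessment and MSI denominators).

**One event per locus–sample pair, MSI precedence.** MSI and LOH are
mutually exclusive verdicts: the published event arithmetic (217 + 909 =
1126) admits no double counting, and an allelic ratio is not meaningful
once novel alleles are present. A pair with both phenomena is recorded as
MSI with LOH marked non-informative, and the evidence string says so.

## Patient classification

- **Bethesda MSI class**: ≥ 2 of the five B5 loci unstable → MSI-H, exactly
  1 → MSI-L, 0 → MSS (the standard Bethesda convention, and the exact
  analog of the LOH rule below). For survival groupings, the comparison is
  MSI-H vs MSI-L+MSS; an "any unstable locus vs none" variant is available
  as an option.
- **Bethesda LOH class**: ≥ 2 B5 loci with LOH → LOH-H, 1 → LOH-L, 0 →
  non-LOH.
- **MMR class**: MMR-deficient iff ≥ 1 MSI call at a locus inside an MMR
  gene; the grouping is marker-based, not immunohistochemical.

Failed loci reduce the effective panel; with fewer than two assayable B5
loci the class is missing, and missing classes are dropped pairwise from
downstream tests. Per-patient event tallies run over tumor-related-gene
loci only; B5 markers feed the panel classes exclusively.

## Cohort profiling

All frequencies follow one convention:

    frequency = n_events / (n_loci_in_group × n_samples)

where `n_loci_in_group` is the number of *catalog* loci in the group (all
26 TS loci, for instance), not the number of loci that happened to mutate —
this is the reading that reproduces every published denominator.
Denominators use the full sample count; pairs non-informative for LOH are
*not* subtracted, again matching the published arithmetic. This
overstates LOH trial counts statistically, which is documented here as a
faithful-reproduction choice; the `EventCounts`/`GroupFrequency` types
accept any denominator, so an informative-pair analysis is a one-line
variant.

Per-locus occurrence rates divide by `n_samples` alone. The pattern
partition splits all events into MSI vs LOH shares and labels each locus
MSI-only / LOH-only / both / none. Spectrum summaries report events per
patient, with the mean taken over *affected* patients (≥ 1 event), so that
e.g. 217 events in 48 affected patients give 4.52. Group-frequency
comparisons use a 2×2 chi-square on [events, trials−events] with a Fisher
fallback (below).

## Statistics

- **Contingency tests**: Pearson chi-square without continuity correction;
  when any expected count is below 5, Fisher's exact (2×2, via
  scipy.stats) or an exact conditional test for small 2×K tables computed
  by multivariate-hypergeometric enumeration with the probability-based
  two-sided rule (scipy provides no exact test beyond 2×2). The method
  used is always reported alongside the p-value.
- **Survival**: Kaplan–Meier product-limit curves and the K-group log-rank
  chi-square test (lifelines). "5-year" analyses administratively censor
  follow-up at 60 months; the truncation is a mode switch because source
  analyses of this kind label outcomes "5-year" without stating the
  truncation, and both modes are provided.
- **Cox regression**: proportional-hazards partial likelihood with Efron
  tie handling (lifelines' default; the less biased of the standard
  choices). Constant and linearly dependent covariates are dropped before
  the fit and flagged in the result — the same degrees-of-freedom
  reduction standard survival software applies. Categorical covariates are
  binary-encoded against the first sorted level; the coding is visible in
  the output names and configurable by recoding the input frame.
- **Marker scans**: for each locus (event vs no event) or panel class
  (high vs rest) and each stratum (all patients, stage II, stage III,
  chemotherapy-treated), a two-arm log-rank p per endpoint (OS, PFS).
  Strata with fewer than two patients per arm are skipped with a flag. Raw
  p-values are reported by default, matching field practice for this kind
  of exploratory per-locus scan; Benjamini–Hochberg adjustment is
  available behind a flag, with the caveat that few per-locus findings of
  this size survive it. Every reported p carries the n actually used after
  pairwise deletion of missing clinical fields.

## Synthetic cohort generator

The generator emulates the study design the pipeline expects: paired
normal/tumor peak tables over the 66-locus catalog for `n_patients`
(default 256), plus a clinical table and a complete ground-truth record.

Per locus–sample pair: a germline genotype is drawn on the locus's
repeat-unit lattice (heterozygous with probability `het_rate`, default
0.70 — a typical dinucleotide-marker heterozygosity); peaks are emitted
for each allele with −1-repeat stutter at relative height
`stutter_ratio_gen` (0.10), multiplicative log-normal height noise (CV
0.05) and Gaussian sizing jitter (SD 0.06 bp). Somatic events are then
drawn mutually exclusively: MSI with per-locus probability `msi_prob`
(default 0.0139 uniformly — the overall rate corresponding to 217 events
over 61 × 256 pairs), else LOH among heterozygous loci with probability
calibrated so the expected overall LOH rate across all pairs equals
`target_loh_rate` (default 0.0582, the 909-event rate): p = target /
((1 − msi_prob) × het_rate). An MSI event adds or (with probability
`slip_fraction` = 0.5) replaces an allele at ±1–3 repeat units, redrawn to
avoid germline sizes; an LOH event scales one allele's height by a
retained fraction drawn uniformly from [0, 0.6] — below the 0.65 detection
threshold by construction, so default-condition events are detectable with
margin. A stress mode draws retained fractions above the threshold
(verifying zero sensitivity there, the threshold semantics), and another
generates coincident MSI+LOH to probe the precedence rule.

Survival times are exponential with median OS 80 months, the hazard scaled
by exp(Σ log-HR) over configured marker effects, with uniform censoring on
[36, 120] months; PFS uses a 1.3× hazard, capped at OS. Clinical
covariates are drawn independently at typical colorectal-cohort marginals
(57.5% male, 34.5% smoking, 22.4% drinking, 51.2% chemotherapy, stage
II/III 57.7/42.3%, 54.7% colon, age ≈ N(67.4, 8) clipped to [40, 90]).

Everything derives from one seeded PCG64 stream in a fixed iteration
order, and all writers use fixed numeric formats, so identical config +
seed yields byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: electrophoresis artifacts beyond −1 stutter
(pull-up, off-ladder alleles, size drift), population allele-frequency
structure, correlated events across loci within a patient, and clinical
covariates correlated with each other or with marker status. In
particular, because default per-locus event probabilities are uniform and
independent, the simulated per-affected-patient mean MSI burden (~1.5) is
far below the published 4.52, which reflects concentration of MSI in a few
MMR-deficient hypermutators; cohorts with that structure can be generated
via `msi_prob_per_locus` overrides and marker effects, but it is not the
default condition.

## Problem sizes used in the test suite

The suite verifies printed-arithmetic reproduction exactly; end-to-end
recovery on ten cohorts of 256 patients × 66 loci (seeds 1–10) at ≥ 95%
sensitivity/specificity and ≥ 95% Bethesda-class agreement, with per-seed
MSI totals inside the central 99% binomial band around the 217-event
anchor; log-rank null calibration at 1000 replicates of 100 subjects per
arm (rejection rate in [0.03, 0.07] at α = 0.05); Cox recovery of a known
log(2) hazard at n = 500 within 3 SE; and Fisher p-values against a direct
hypergeometric-enumeration oracle on every 2×2 table with total n ≤ 40 (up
to row/column/transpose symmetry, 18,215 canonical tables). The
law-of-large-numbers check on the generator runs 5000 patients over a
10-locus catalog subset; per-locus rates are required to behave exactly as
a binomial at 3 SE predicts (at most the one >3-SE outlier expected among
20 simultaneous checks, none beyond 4 SE, pooled rates within 3 SE).

## Known limitations

- The LOH imbalance ratio uses the two germline allele positions only; a
  tumor that both shifts and loses an allele is MSI by precedence, and its
  allelic loss is not separately quantified.
- The exact 2×K test enumerates tables and is restricted to small totals
  (n ≤ 500); larger sparse tables fall back to chi-square with the method
  flagged.
- Patient-level clinical findings of the source cohort (its Tables of
  association and survival p-values) are not reproducible from printed
  data; the pipeline's statistical machinery is instead validated by
  calibration and parameter-recovery simulation.
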