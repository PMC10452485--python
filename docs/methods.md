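# Methods

## The assay model

A patient-specific panel of somatic mutations, selected at diagnosis, is
amplified at each follow-up time-point in three biological replicates and
sequenced to a target depth of 500,000× per amplicon. For one mutation in
one replicate, reads are assigned to the wild-type or mutant allele by
exact match against the allele's sequence context (the variant ± 15 bp);
the replicate's MRD ratio is

    r = mut_reads / (mut_reads + wt_reads)

i.e. the standard allele-fraction definition. The pipeline then proceeds
per mutation and time-point:

1. **Artifact removal.** From the three replicate ratios, compute the mean
   m and sample SD s (n−1 denominator); remove every ratio strictly above
   m + 1·s; average the retained replicates into the corrected mean. The
   rule is a single pass (no re-iteration after removal). The minimum
   ratio can never exceed m + s, so at least one replicate always
   survives and the corrected mean never exceeds the raw mean.
2. **Calibration.** For each mutation independently, nine healthy-donor
   replicates (three triplicates of three donors) define the background:
   LOD = mean + 3·SD and LOQ = mean + 10·SD of the control ratios (sample
   SD again). LOD/LOQ scale linearly with the controls (scale
   equivariance) and LOQ ≥ LOD ≥ control mean by construction.
3. **Per-mutation call.** corrected mean < LOD → eliminated (below_LOD);
   ≥ LOQ → quantifiable; in between → detected. A mutation whose *own*
   LOD exceeds 1×10⁻⁴ is flagged `lod_excluded`: its background is too
   noisy for ultrasensitive tracking and it never contributes to the
   patient-level value, whatever its ratio.
4. **Patient-level value.** The MRD value at a time-point is the maximum
   corrected mean over eligible mutations (not eliminated, not
   LOD-excluded); the sample is positive iff at least one mutation is
   eligible. The 2×10⁻⁴ assay sensitivity is a reporting annotation — a
   positive value below it is flagged `below_assay_floor` — not an extra
   threshold; the operative thresholds are the per-mutation LOD/LOQ.

Boundary conventions follow the wording of the rules: "above m + s" and
"below LOD" are strict, so ties resolve toward retention and detection.
The same n−1 SD estimator is used for artifact removal and calibration.

At baseline, FFPE tissue variant tables are cleaned of formalin-induced
deamination artifacts: a C>T or G>A call with VAF < 0.20 **and**
transformed p-value > −2 is removed unless its COSMIC flag rescues it.
The transformed p-value is a caller-supplied score consumed as-is; both
thresholds compare strictly, with boundary values retained. The filter is
restricted to the tissue compartment (plasma is not formalin-exposed; the
filter raises on plasma input). MRD biomarkers are then the filtered
variants carrying the described-in-lymphoma annotation flag; both flags
are input columns, not live database queries, for offline
reproducibility. Paired genotypes merge on normalized
(chrom, pos, ref, alt) keys (shared-prefix/suffix trimming for indels;
no positional tolerance).

## Concordance statistics

PET/CT response maps Deauville 1–3 to negative and 4–5 to positive
(partial metabolic response and progression both positive). Clinical
truth is an input adjudication column, as in practice it comes from later
imaging and follow-up, outside the computational pipeline. Per-method
confusion matrices use sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP); between-method concordance is the fraction of records where
the PET group (as boolean) equals molecular positivity, and is symmetric
in the two methods. MRD values across PET groups are compared with a
two-sided Mann–Whitney U test (average ranks for ties; scipy's automatic
exact/asymptotic policy). cfDNA concentration is dichotomized at 5 ng/mL
— values exactly at the boundary go to "low", since the rule is stated as
strictly higher/lower — and tested against clinical factors with a
chi-square of independence, Yates-corrected for 2×2 tables and
uncorrected for wider tables. Pearson correlations (paired tissue/plasma
VAFs) use the standard t-approximation for p-values.

## The synthetic cohort generator

The generator exists so every stage is testable without patient data. It
emulates:

* **Subtype mix and spectra.** Patients draw a subtype (defaults
  FL 25/78, DLBCL-like 34/78, PMBCL 12/78, PCNSL 7/78) and then gene hits
  as independent Bernoulli draws at the subtype's recurrent-gene
  frequencies (e.g. KMT2D 0.64 in FL, 0.32 in DLBCL; STAT1 0.83 in
  PMBCL; MYD88 0.80 in PCNSL).
* **VAF structure.** Tissue VAF ~ Beta with mean 0.26 (shape α = 2,
  configurable); plasma VAF = 0.7 × tissue + N(0, 0.12), clipped to
  [0, 1]. The attenuation reflects the lower mean plasma VAF (≈0.18 vs
  0.26); the noise level is chosen so the induced paired-VAF correlation
  is clearly positive but moderate, as observed cohorts show, rather than
  near-perfect. Plasma calls below a 0.03 reporting floor are dropped.
* **ctDNA shedding.** A per-patient Bernoulli flag (DLBCL 0.82, PMBCL
  0.86, PCNSL 0.43, FL 0.56) gates plasma detectability, so a realistic
  fraction of plasma samples is empty; a small per-mutation probability
  (0.08) makes a clone plasma-only.
* **Deamination artifacts.** Each tissue sample receives up to 4
  candidate C>T/G>A artifacts (each injected with probability 0.30) with
  VAF ~ U(0.01, 0.19) and transformed p-value ~ U(−1.9, 0); 15% carry
  the COSMIC flag and are therefore rescued by the filter. Genuine
  somatic calls draw p-values in (−12, −3), so the filter's removal set
  equals the injected-artifact set minus the rescued members exactly —
  the basis of the parameter-recovery test.
* **Counts.** Mutant reads per replicate ~ Binomial(depth, f + e) with
  depth 500,000 and per-mutation background e = 2×10⁻⁵ by default; a 5%
  "noisy site" fraction gets e = 10⁻³ so the LOD-exclusion path is
  exercised. This is the minimal sufficient structure: the pipeline
  consumes ratios, so no per-cycle PCR lineage or read-level error
  profile is simulated (no quality scores, indel errors, strand bias, or
  molecular-tag read families). Healthy-control replicates use the same
  binomial model at f = 0.
* **Follow-up.** Responders' circulating fraction decays to 0 after the
  first on-treatment sample (2% of baseline at the first point);
  relapsers (probability 0.3) rebound to 10⁻² at the last time-point.
  Deauville scores follow the true disease state with a configurable
  PET false-positive rate (default 3/23 ≈ 0.13, matching the imaging
  specificity the confusion analysis reproduces) and false-negative rate
  (default 0).

Randomness: one master seed; per-patient streams derive from
`SeedSequence((seed, stage, patient_index))`, so identical configurations
reproduce byte-identical outputs and partial regeneration is stable.

What passing on synthetic data does **not** show: real amplicon data have
position-dependent, over-dispersed error (the binomial model is
equi-dispersed), UMI family structure, and correlated replicate failures;
cohort-level quantities (detection rates per subtype, the observed VAF
correlation of 0.375–0.459, gene frequencies) depend on the real
patients and are covered here only as convergence properties of the
generator at its configured rates.

## Numerical choices and degenerate inputs

* Replicates with zero total reads are dropped with a warning; a
  triplicate with fewer than three usable replicates skips the outlier
  rule (plain mean); an all-empty measurement is an error.
* Artifact removal and the brute-force oracle use the same direct
  formulas (mean = Σr/3, SD = √(Σ(r−m)²/2)), and the minimum ratio is
  retained explicitly, so constant triplicates are safe against float
  rounding of the m + s boundary.
* Calibration requires ≥ 2 control ratios; correlation requires ≥ 3
  pairs and non-zero variance; Deauville scores outside 1–5, plasma
  input to the FFPE filter, mismatched patient IDs in a merge, and an
  LOQ multiplier below the LOD multiplier are rejected with explicit
  errors.
* Read matching tries the forward orientation first and the reverse
  complement only as a fallback, so a context pair that is its own
  reverse complement stays decidable; a read matching both contexts in
  one orientation is unmatched.

## Problem sizes

The test suite simulates cohorts of 10–500 patients (500 only for
frequency-recovery checks with artifact injection disabled), 200-run
detection experiments at depth 500,000, and an exhaustive 36³-point grid
of small replicate counts for oracle equivalence; the acceptance script
uses 200 seeded runs and a 250-patient cohort. These sizes give stable
statistics (binomial SEs well inside the asserted bands) while keeping a
full run in the low seconds.

## Known limitations

* The "three types of reads" generated per molecular-tagged primer in
  the wet-lab assay are not modeled; the simulator emits matched counts
  directly and `match_reads` handles plain sequence strings.
* Whether patient-level positivity should additionally require LOQ (vs
  LOD) is a design choice; LOD is used, per the elimination rule.
* The deamination filter is tissue-only; applying it to plasma would
  require a separate decision about non-FFPE error modes.
* No survival or relapse-prediction modeling, no UMI consensus, no
  variant calling from raw baseline reads, and no figure rendering
  beyond tabular reports.
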