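# Methods

This note documents the models, rules and numerical choices behind
`mfhet`, in the order the pipeline applies them.

## Cohort model and variant identity

A cohort is patients → lesions → samples; multifocality requires at least
two lesions per patient and every lesion at least one sample.  Variant
identity is the genomic key *(chrom, pos, ref, alt)* after left-trim
normalisation (shared suffix removed, then shared prefix, keeping one base
and advancing the position).  Protein change is annotation only: two
different substitutions in the same gene remain two variants.  Genomic
identity was chosen over protein identity because the two sequencing
platforms' callers pad indel alleles differently, and genomic
normalisation gives a deterministic cross-platform match.  Coordinates are
1-based inclusive (VCF convention).  Silent variants are parsed but
excluded from every analysis stage, which operate on non-silent coding
mutations only.

## Cross-platform confirmation

Each variant discovered in ≥ 1 sample of a patient is assayed in **all**
samples of that patient on the validation platform.  Per assay:

* validated ⟺ AF<sub>val</sub> ≥ `af_confirm_min` (default **0.05**), or
  `af_rescue_min` ≤ AF<sub>val</sub> < `af_confirm_min`
  (default **0.01**) with another sample of the same patient carrying the
  variant at ≥ `af_confirm_min` (the supporting sample is recorded; a
  sample never supports itself);
* thresholds are inclusive and AFs are compared as real numbers, no
  rounding;
* "detected at discovery" means any reported discovery call with AF > 0
  (discovery calls come from an upstream caller, so the call itself is the
  detection);
* `CONFIRMED` = validated ∧ detected at discovery; `PRESENT` = validated ∧
  not detected at discovery in that sample; `ASSAY_FAILED` (assay not run
  or unreadable) makes no claim and is excluded from denominators.

Concordance: Spearman's ρ over assays with both AFs observed (optionally
restricted to validated assays; the default uses all pairs, since the
restriction is not determined by the procedure itself).  The ROC treats
validated-vs-not as the label and the discovery AF (0 when absent) as the
score; this construction is a package choice — other label/score
assignments are defensible.  The AUC's 95% CI uses the Hanley–McNeil
asymptotic standard error.

## Oncogenicity rule cascade

Rules fire in tier order; the first firing tier wins and the
lowest-numbered rule within it is recorded.

| tier | rule | condition |
|---|---|---|
| ONCOGENIC | R1 | non-synonymous substitution or in-frame indel in an oncogene at a recurrent hotspot |
| | R2 | non-synonymous substitution with catalogue recurrence ≥ `cosmic_recurrent_min` (default **2**) |
| | R3 | variant in ≥ 2 distinct *patients* of the analysed cohort |
| | R4 | nonsense / frameshift in a tumour suppressor |
| PUTATIVE | R5 | unreported (catalogue count 0) substitution in a cancer gene within ± `hotspot_window_aa` (default **3**) residues of a catalogue-recurrent position |
| | R6 | cohort cluster: window of span ≤ 3 residues containing ≥ `cluster_min_mutations` (default **3**, i.e. "more than two") distinct substitution positions of that gene |
| POSSIBLE | R7 | catalogue count exactly 1 |
| | R8 | within ±3 residues of a position flagged as a catalogued mutation cluster |

Choices made where the rule set is under-specified: R1's "recurrent
hotspot" is operationalised as an exact protein change with catalogue
count ≥ 2 in an oncogene (no separate hotspot list exists); R3 counts
distinct patients, not samples, so multi-sample patients do not
self-inflate; R6 counts distinct residues (not distinct genomic variants)
and applies the window to any gene; R5's "known cancer gene" is any gene
with a role other than `not_cancer_gene`; R8 is inert unless the
recurrence table carries an `in_cosmic_cluster` column, because no
catalogue cluster definition is available to derive one.  Unparseable
protein changes skip the position-based rules but still allow R4 (which
needs only the variant class).  The collapsed binary "oncogenic" flag is
category ≠ UNKNOWN.  Cohort tallies count per-patient unique variants (a
hotspot carried by k patients contributes k), with the distinct-key count
also reported.

## Heterogeneity grouping

Presence of a variant in a sample = validation status `CONFIRMED` or
`PRESENT`; an `ASSAY_FAILED` cell falls back to the discovery detection
(`assay_failed_uses_discovery`, default on), so a screen-detected variant
is not dropped when its validation assay could not be run.  Variants with
no present cell are removed; patients left without variants cannot be
grouped and are excluded with a warning.

* `HOMOGENEOUS` ⟺ every variant present in every sample of every lesion;
* lesion-common ⟺ present in ≥ 1 sample of every lesion
  (`common_requires_every_sample=True` switches to the stricter
  every-sample reading);
* `HETEROGENEOUS` ⟺ no lesion-common variant; `INTERMEDIATE` otherwise.

The asymmetric default (strict for homogeneous, lesion-level for common)
follows the two definitions' natural readings; a patient whose every
variant is lesion-common but not sample-complete is therefore
INTERMEDIATE.  Both behaviours sit behind the config flag because the
grouping is declaredly operational rather than model-derived.

AF comparison: restricted to INTERMEDIATE patients (the only ones with
both sets).  Per variant, the AF is the median over samples where it is
present (validation AF, discovery fallback); pooled medians are reported
over all such per-variant values, and the test is a paired two-sided
Wilcoxon signed-rank over per-patient (median private, median common)
pairs.  Covariate associations: Kruskal–Wallis across the three groups
and rank-sum across the shared-oncogenic split (patients with no
oncogenic variant at all are excluded from that split) for continuous
covariates; Fisher's exact test on the groups × levels table for
categorical ones; all two-tailed, raw p-values (no multiplicity
correction, mirroring how such covariate scans are usually reported;
a Benjamini–Hochberg column can be added by the caller).

## Structural comparison

Rearrangements match when class (orientation-derived: deletion-type +/−,
tandem-duplication-type −/+, inversion-type ++/−−, inter-chromosomal),
chromosome pair and strands agree and both breakpoints lie within
`rearrangement_bp_tolerance` (default **500 bp** — capillary-validated
breakpoints are near-exact, so the tolerance mainly absorbs mapping
jitter).  Matching is greedy 1-to-1 by smallest breakpoint-distance sum
with genomic-order tie-break, anchored on the lexicographically first
lesion so results are invariant to input order.  Greedy matching can in
principle under-match adversarially overlapping candidates closer than
the tolerance; for breakpoints separated by more than twice the tolerance
it is exact (property-tested).

Copy-number comparison works on total (not allele-specific) integer
profiles.  The gain/loss baseline is round(ploidy), so tetraploid lesions
are not called whole-genome gained.  Adjacent same-direction segments are
merged into maximal aberration intervals first, making calls invariant to
re-segmentation of the same underlying profile.  An aberration is common
when every lesion has a same-direction aberration with reciprocal overlap
≥ `scna_reciprocal_overlap_min` (default **0.5**).  Focal-region calls
take the direction covering the largest part of the region, neutral when
none overlaps.

**Minimum-event distance.**  Profiles are intersected per chromosome onto
the common breakpoint grid (non-alignable grids are an error).  One event
adds +1 or −1 to one contiguous run of segments; segments at copy 0
cannot change (no resurrection), which both bars gains from 0 (the target
is then unreachable, reported as `inf`) and splits the chromosome into
independent blocks.  Because gain and loss events act on disjoint segment
sets, the difference profile decomposes into positive and negative parts,
and the minimum count per part is the total rise of its step function
(linear scan); the chromosome distances sum.  This equals the shortest
path in the explicit event graph, verified against an independent A*
search on randomized instances.

## Synthetic cohort generator

The generator emulates the statistical structure of a two-platform
multi-region breast-cancer study; defaults are the emulated study's
conditions:

| parameter | default | note |
|---|---|---|
| patients | 36 | fixed group composition 11 : 13 : 12 (homogeneous : intermediate : heterogeneous), largest-remainder apportionment shuffled by the RNG — cohorts enrol fixed group counts rather than iid draws |
| lesions/patient | 2 w.p. 22/36, 3 w.p. 10/36, 4 w.p. 4/36 | the published split records only 2 vs > 2 (22 vs 14); the 3/4 subdivision is the package's choice |
| samples/lesion | 1–3 (p = 0.45/0.35/0.20) | gives ≈ 4.7 samples/patient, matching 171 samples over 36 patients |
| mutation counts | log-normal draws, σ = 0.6, clipped to [1, 27]; medians 2.5 (homogeneous), 1.5 + 1.5 (intermediate truncal + private), 2 per lesion (heterogeneous) | calibrated to a cohort median of ≈ 3 with homogeneous < heterogeneous (≈ 2.5 vs ≈ 4.5) |
| CCF | truncal 1.0 in all samples; intermediate-private `private_subclone_ccf` = **0.5** in one lesion; heterogeneous lesions clonal (1.0) for their private set | heterogeneous patients get a guaranteed distinct driver per lesion (convergent evolution), which raises the realised oncogenic fraction somewhat above the 0.44 per-draw target |
| purity | U(0.4, 0.9) per sample | cellularity-selected cohorts exclude low-purity samples |
| depths | Poisson, means 178 (discovery) and 1344 (validation) | the two platforms' median coverages |
| read model | beta-binomial, overdispersion ρ = 0.01 (`binomial` and `none` also available) | mild FFPE-like overdispersion; expectation purity × CCF / 2 (diploid heterozygous) |
| background error | 0.001 | validation reads at variant-absent sites |
| discovery caller | AF ≥ 0.05 and ≥ 4 alt reads | emulates screen sensitivity; variants discovered nowhere are recorded as undiscovered truth |
| assay failures | 7% of (variant, sample) validation assays | emulates design failures / exhausted DNA |
| oncogenic fraction | 0.44 per non-forced draw (hotspot 50% / truncating TSG 30% / catalogue singleton 20%) | planted rules R1/R2, R4, R7; passengers in non-cancer genes, residues ≥ 7 aa apart to avoid accidental clusters |
| inter-lesion distance | N(1.5, 1) / N(2.5, 1) / N(4, 1) cm by group, 10/36 missing | heterogeneous lesions planted further apart |
| CN / rearrangements | shared truncal events plus lesion-private events (more private in heterogeneous patients), breakpoints jittered ≤ 200 bp across lesions; event regions kept a segment apart so truncal and private aberrations never merge | |

Identical seed and config give byte-identical outputs (single
`numpy.random.default_rng` stream, deterministic file writers).

What the generator does **not** emulate — and what passing recovery tests
therefore do not show about real data: discovery-platform false-positive
calls (so the validation rate of detected calls is ≈ 100%, and the ROC
separates perfectly, unlike real screens where ~10% of calls fail
validation); copy-number-aware allele fractions; within-lesion subclonal
structure beyond a single CCF level; germline contamination; sequence
context and FFPE artefact spectra.  Truth-recovery accuracy on these
cohorts measures the pipeline's logic, not robustness to artefacts the
model does not contain.

## Statistical procedures

All tests are two-tailed and report whether the exact or asymptotic
branch ran.  Spearman: average-rank ties; p by full permutation
enumeration for n ≤ 10 (vectorised over a cached permutation array),
t-approximation above; constant vectors are an error.  Wilcoxon
signed-rank: zeros dropped (Wilcoxon's original treatment; the all-zero
case returns p = 1); exact distribution for n ≤ 25 without ties, normal
approximation with continuity correction otherwise.  Rank-sum: exact for
pooled n ≤ 25 without ties, tie-corrected normal approximation otherwise.
Kruskal–Wallis: chi-square approximation with tie correction; identical
constant groups return p = 1.  Fisher: hypergeometric two-sided for 2×2;
for r×k with total ≤ 50 an exact fixed-margin enumeration (sum of
probabilities of tables no more probable than the observed one);
chi-square above.  Note that exact conditional tests are conservative at
small counts — the two-sided 2×2 Fisher test's true size at nominal 0.05
is ≈ 0.033 at 25 observations per group, approaching 0.05 only as counts
grow — so calibration checks are run at group sizes (150) where
discreteness no longer dominates.

## Known limitations

* The heterogeneity grouping is threshold-free but operational; it does
  not infer clonal phylogenies or cancer-cell-fraction deconvolution, and
  a single low-AF validated variant can move a patient between groups.
* Rearrangement "common" calls depend on the breakpoint tolerance, which
  stands in for an unspecified matching criterion.
* The minimum-event distance treats total copy number only; allele-specific
  events and whole-genome doubling are out of scope.
* Real supplementary per-sample tables (controlled-access) can be analysed
  by the same file readers, but no such data ship with the package.
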