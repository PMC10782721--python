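# Methods

## The confirmation cascade

A candidate heteroplasmy is a (donor, tissue, position, minor allele) seen
in at least one per-library call.  Confirmation requires, in order:

1. **Complete replicate reproducibility.** The minor allele must be called
   in *every* platform-A library of the donor/tissue group.  A replicate
   missing only because of the minor-read-count floor may be rescued: the
   site is re-called with the fall-back count of 2, but rescue is
   read-count-only — a site failing the MAF threshold or lacking reads on
   one strand is refused.
2. **Both-strand evidence** in every replicate (rescued ones included).
3. **Genotype quality > 41 in every replicate.**  The stricter
   per-replicate reading was chosen over a group-level one because the
   cascade is a validation-style filter; a single low-confidence replicate
   should block confirmation.
4. **Cross-platform concordance:** a matching call (same position, same
   minor allele) in every platform-B library of the group.  MAF agreement
   is reported but not gated.  A group with no platform-B library is marked
   unevaluable, never confirmed.  Platform-B presence is required at the
   standard thresholds; strand evidence on B is recorded but not gated.
5. **Dual-pipeline concordance:** an independently coded second analysis
   path (P2) recomputes MAFs from the raw strand counts with its own
   grouping order and plain-loop arithmetic, and must see the allele in
   every group library.  P2 shares only the numeric threshold values with
   the primary path, so a code-path artefact in either pipeline breaks
   concordance.

Removing a replicate from the manifest can only keep or enlarge the
confirmed set; adding one can only keep or shrink it (monotonicity, tested).

### Genotype quality

The upstream vendor's GQ formula is unpublished, so GQ is re-specified here
as a one-sided Phred-scaled binomial likelihood ratio: the likelihood of the
observed minor count at its maximum-likelihood MAF versus the likelihood
under homoplasmy plus a site error rate (default 2e-4 per strand and
substitution type), clamped to 0 when the observed MAF does not exceed the
error rate and capped at 99.  The GQ = 41 gate therefore filters at an
equivalent operating point, not bit-identically to the original software —
a deliberate, documented substitution.  The score is monotone in the minor
count at fixed depth (property-tested over k = 0..100).

### Strand bias

No published definition exists for the workflow's SB score; it is
implemented as the -log10 two-sided Fisher-exact p-value of the 2x2
minor/major x forward/reverse table, symmetric under strand relabelling,
with an undefined sentinel (None) for an all-zero table.

### Thresholds

| parameter | default | meaning |
|---|---|---|
| analysis threshold (AT) | 0.001 | MAF floor for detection |
| interpretation threshold (IT) | 0.001 | MAF floor for reporting |
| min_read_count | 10 | minor-read floor in routine calling |
| fallback_read_count | 2 | floor used only in replicate rescue |
| gq_min | 41 | Phred gate in the cascade |
| site_error_rate | 2e-4 | error model behind GQ |

AT and IT are kept distinct (both applied to final counts) so sensitivity
analyses can separate detection from reporting.  The minor allele is capped
at MAF 0.5; at an exact 50/50 tie the rCRS base is designated major.
Indels and length heteroplasmy (homopolymer C-tracts) are out of scope.

## rCRS annotation

Coordinates are 1-based rCRS (NC_012920.1) throughout; the packaged FASTA
is the byte-exact reference sequence (MD5
`c68f52674c9fb33aef52dcf399755519`, the digest every GRCh38 sequence
dictionary lists for chrM).  The locus map ships as a BED-like table
(0-based half-open internally, converted at the API surface).  The control
region is 16024-16569 plus 1-576; HVS-I is 16024-16365 and HVS-II 57-372 —
the only boundary convention under which the printed hotspot-table labels
(five HVS-I, six HVS-II, 16390 and 16519 outside both) are reproduced, as
the source tables do not state one.  Coding classification uses the rCRS
codon context (not per-donor haplotypes): light-strand genes (MT-ND6,
light-strand tRNAs) are reverse-complemented before translation with the
vertebrate mitochondrial code; an incomplete terminal codon is completed
with A, mirroring post-transcriptional polyadenylation.  Where genes
overlap (ATP8/ATP6, ND4L/ND4), the first gene in map order provides the
codon frame.  At a 50/50 allele mix, or where a cohort's major allele is a
common non-reference variant (e.g. 16093C, 16286T, 16519C), annotation
works from the stated major/minor pair; strict mode warns when the major
allele is not the rCRS base.

## The synthetic-data generator

The generator emulates the *statistical shape* of a replicated two-tissue
deep-sequencing study; it does not simulate reads, alignment, PCR chimeras
or NUMT co-amplification (the emulated workflow excludes NUMTs
experimentally, and no read-level artefact model is attempted).

Defaults (one seed drives everything; per-library substreams are derived
deterministically so any library is reproducible in isolation):

- **Design:** 11 donors x 2 tissues; two technical-replicate donors
  (16 and 13 libraries), nine longitudinal donors (3 time points x 2
  replicates x 2 tissues), one platform-B library per donor/tissue group;
  159 libraries in total.
- **Coverage:** gamma-Poisson (negative-binomial) depth, mean 7,746x,
  dispersion 20, log-normal per-position multipliers shared across
  libraries (amplicon unevenness), including a systematic ~3x dip in a
  240 bp window around position 3586.  Uneven amplicon coverage is why
  depth is overdispersed rather than Poisson.
- **Noise:** per-substitution-type mean error 2e-4 per strand (transitions
  4x transversions), with per-position log-normal multipliers (sigma 0.5)
  drawn once per platform.  This puts a small number of site-channels
  genome-wide near or above the 0.1% MAF threshold — the regime the
  confirmation cascade must defeat — while keeping platform A and B noise
  independent.  The real study's per-position noise spectrum is
  unpublished; these rates are explicit stand-ins, and conclusions from
  passing tests are about the cascade's logic under this model, not about
  any particular instrument.
- **Truth:** about six PHPs per sample; 45% of a donor's events are
  germline-shared (present in both tissues with independent log-normal MAF
  jitter, sigma 0.2), the rest tissue-specific somatic.  Positions come
  from a 50/50 mixture of the packaged control-region hotspot table
  (weighted by relative substitution rate) and the uniform genome; MAFs
  are log-uniform on [0.001, 0.5]; the minor allele is the transition
  partner of the rCRS base except for a 1/131 transversion fraction
  (matching one transversion among 131 events).  The placeholder position
  3107 (N) receives no reads.

What the generator does **not** capture: realistic error auto-correlation
along amplicons, mapping artefacts, donor haplotype backgrounds (all
libraries are rCRS-major except planted PHPs), contamination, and
platform-specific homopolymer behaviour.  Results on synthetic data
therefore validate the pipeline's decision logic and statistical
calibration, not wet-lab performance.

## Landscape statistics

- "Low-level" is fixed at MAF < 1%; cut-off comparisons use >= at the
  boundary; the default cut-off ladder is 0.1 / 0.5 / 1 / 3 / 10%.
- Hotspot rows pool MAFs over both tissues; an even pool's median is the
  midpoint of the central pair (the source tables are silent on this).
- The linkage test measures, per tissue, how many donors share both
  positions of a pair, against a null that independently permutes each
  position's donor labels within the tissue (equivalently redraws its
  donor set at fixed size).  The cited precedent describes no test, so an
  assumption-light, seedable permutation scheme was chosen.  Empirical
  p-values use the add-one rule and are BH-adjusted across pairs; with the
  default 100+ permutations the discreteness of the p-values makes BH
  discoveries under the null rare, which the calibration check exercises.
- A longitudinal "loss" verdict requires zero minor reads at a later time
  point *and* depth above a detectability floor (the depth at which the
  first time point's MAF would still yield at least the fall-back count of
  expected minor reads); coverage dropouts are reported as unevaluable,
  never as losses.
- Blood:buccal ratios flag potential leukocyte-contamination echoes at a
  configurable fold threshold (default 17); a zero buccal MAF yields an
  infinite-ratio sentinel.

## Problem sizes used in the checks

The statistical acceptance checks run on deliberately small study plans —
one or two donors with three platform-A replicates and one platform-B
library per group, 25-50 noise seeds, 40 planted PHPs for recovery, 200
seeds x 200 permutations for linkage calibration.  These sizes give the
binomial and permutation arguments enough resolution while keeping the
whole suite fast on a single CPU; the cohort-scale results of the emulated
study (62 positions, 131 events, printed hotspot medians) are not
recomputable from synthetic data and are consumed as fixture inputs only.

## Known limitations

- GQ and SB are re-specifications, not re-implementations, of proprietary
  scores; the 41 gate is an equivalent operating point.
- The simulated platform-B run reuses the study's library plan rather than
  modelling a pooled re-run; cross-platform concordance therefore tests
  independence of noise, not library identity.
- Pathogenicity prediction, haplogroup assignment and population-incidence
  estimates are explicitly out of scope.
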