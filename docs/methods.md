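# Methods

## The question and the procedure

For each patient with a primary tumor and a matched metastasis, the package
asks whether the two lesions are clonally related.  Under linear
progression, the metastasis is seeded by the dominant primary clone and the
two samples share the mutations acquired before divergence (the *trunk*)
plus similar chromosome-level copy-number changes.  Under polyclonal
progression, the metastasis descends from a genetically distinct minor
clone: few or no shared mutations, dissimilar copy-number profiles.

The procedure is deliberately rule-based, mirroring how such cohorts are
analysed in practice:

1. **SCNA categorisation.**  Integer total copy number and an LOH flag map
   each segment to one of five categories: 0 → homozygous loss, 1 → one copy
   loss, 3 → one copy gain, ≥4 → high copy gain, and 2 with LOH →
   copy-neutral LOH.  The copy-number class takes precedence over the LOH
   flag.  These thresholds are the standard diploid reading; they are not
   dictated by any array-processing software and are kept in one function so
   they can be adapted.  The per-sample **total SCNA number** sums the four
   copy-number categories only — copy-neutral LOH is tallied separately.
   This convention is verified against all 30 rows of the bundled reference
   table: each published total equals the sum of its four copy-number
   columns.  Burden counts segments (events), not bases; the reference
   table's magnitudes (hundreds to thousands per sample) are event counts.

2. **Binned profiles and clustering.**  Segments are rasterised onto
   fixed-size bins (default 1 Mb, conventional for array-resolution CNV
   work; chromosome extents are taken from the segment table itself).  A
   bin's value is the per-base mean of (copy number − 2) with uncovered
   bases counting as diploid; a parallel layer holds the fraction of the bin
   covered by LOH segments, appended to the feature vector at weight 1.0
   (configurable) so that copy-neutral LOH — invisible in total copy
   number — still separates samples.  Distances are Euclidean by default
   (manhattan and correlation are available); no metric is canonical for
   this task, Euclidean on binned states is the common choice.  Clustering
   is agglomerative with complete linkage by default (average and single
   are available and give the same pair calls on well-separated data).

   The agglomerator is implemented in the package rather than delegated,
   because the downstream call depends on the exact merge sequence and
   therefore on a defined tie-break: among cluster pairs at the minimal
   distance, the lexicographically smallest (creation-index, creation-index)
   pair merges first.  Leaves are numbered in input order and merge *k*
   creates cluster *n+k*.  The implementation uses the Lance–Williams
   update; tests verify its merge sequence against an independently coded
   re-agglomerator that recomputes all inter-cluster distances from the raw
   matrix at every step, and cross-check cluster compositions against
   `scipy.cluster.hierarchy.linkage` on tie-free input.

3. **Pair adjacency.**  A pair is *grouped* when its two leaves are
   dendrogram siblings — the first merge involving either of them merges
   exactly the two singletons.  This is a strict criterion; a relaxed
   mutual-nearest-neighbour variant is provided for sensitivity analysis but
   never enters the classification.

4. **Mutation concordance.**  Mutations match on the full identity key
   (chromosome, position, ref, alt); within-sample duplicates collapse.
   The shared percentage uses the Jaccard denominator,
   100·S/(n_P + n_M − S).  The reference table that motivates this statistic
   prints percentages without defining the formula; the Jaccard form is
   adopted because for every one of its 15 pairs an integer shared count S
   reproduces the printed percentage within ±0.05 — a property the
   test-suite re-verifies by enumeration, and which simpler denominators
   (min, mean, n_P) do not satisfy across all rows.  Raw counts include all
   seven retained effect classes (non-synonymous, synonymous, stop
   gain/loss, frameshift and non-frameshift indels, splicing); gene-level
   statistics — driver concordance, per-gene frequencies — use non-silent
   classes only, since they concern functional mutations.  Indels
   participate in key matching through their "-" alleles; inputs are assumed
   consistently left-normalised upstream.

5. **Hypermutation.**  The hypermutator phenotype shows up as an
   order-of-magnitude burden gap (819–971 vs ≤113 in the reference
   metastases).  Default strategy: absolute threshold 500 (the midpoint of
   that gap on a log scale); alternative: 5× the cohort median.  Both
   reproduce the reference cohort's four flags.  Flagged samples are
   screened for *missense* (non-synonymous only) mutations in the
   mismatch-repair panel (MLH1, MLH3, MSH2, MSH6, PMS2, PMS6, ERCC2, ERCC5,
   ERCC6, MUTYH, RAD9A, EXO1, SLX4, ATR, BLM) and the polymerase panel
   (POLN, POLL, POLQ, POLH, POLE, POLD1, POLG); both panels are replaceable
   by plain text files.  MSI itself is a wet-lab assay and out of scope —
   hypermutation here is purely a count-threshold phenotype.

6. **Statistics.**  Two-sample *t*-tests are provided in Welch
   (Welch–Satterthwaite df) and pooled variants, plus a paired *t*; the
   statistic and df are computed explicitly and the two-sided p comes from
   the *t* survival function.  The LOH–hypermutation association uses Welch
   by default: with the reference cohort's highly unequal group variances
   the pooled variant gives a p-value two orders of magnitude larger, and
   only Welch matches the published association (2.8e-09 at two significant
   figures — reproduced by the test-suite).  Zero-variance inputs are
   handled as limiting cases (p = 1 for equal means; p → 0, flagged
   degenerate, otherwise) rather than errors.  The paired burden comparison
   within grouped pairs is computed and reported; the test-suite asserts
   only its qualitative outcome (non-significant), because a standard paired
   *t* on the bundled counts gives ≈0.32 and the exact subset/variant behind
   the published rounded figure is not reconstructable.  All p-values are
   validated against an arbitrary-precision incomplete-beta oracle (mpmath)
   to relative error < 1e-8.

7. **Classification.**  `related` = grouped AND ≥1 shared driver;
   `distinct` = ungrouped AND 0 shared drivers; anything else =
   `discordant_evidence`.  The third label exists because the two evidence
   streams, though they agreed perfectly in the reference cohort, can
   disagree on noisy data; forcing a binary call would hide exactly the
   cases worth inspecting.  The shared percentage is reported as evidence
   but does not enter the rule — one reference pair shares 52.1% of its
   mutations yet no driver mutation and was grouped remotely, and the
   classifier follows the driver criterion while attaching a high-sharing
   warning to such calls.

## The synthetic cohort generator

The generator emulates the reference cohort's statistical structure, not its
sequences.  Defaults (all configurable on `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_pairs` | 15 | reference cohort size |
| `fraction_related` | 8/15 | reference grouped fraction; planted count is `round(n_pairs·fraction)` |
| `trunk_mutations_mean` | 40 | Poisson mean of shared mutations; with the private mean this puts related pairs' shared percentage in the observed 30–55% band |
| `private_mutations_mean` | 30 | per-sample Poisson mean; non-hypermutated totals land in the observed 34–113 range |
| `hypermutator_probability` | 4/15 | reference incidence among metastases |
| `hypermutator_multiplier` | 30 | multiplies the private mean so hypermutators land in the observed 800–1000 range, an order of magnitude above both default thresholds |
| `loh_baseline_mean` / `loh_hypermutator_mean` | 15 / 150 | observed LOH count magnitudes (0–80 vs 145–164) |
| `loh_dispersion_baseline` / `_hyper` | 1.5 / 50 | negative-binomial size; baseline LOH is strongly overdispersed (0–80), hypermutator LOH tightly grouped |
| `scna_bins` | 500 | 100 kb bins on the toy genome; enough resolution to host 150 LOH bins plus ~100 events |
| `scna_event_rate` | 0.2 | per-bin alteration probability; gives cross-sample distances well above within-pair distances |
| `scna_noise_rate` | 0.02 | per-bin resampling rate in related metastases; adjacency recovery is near-perfect here and degrades smoothly as it rises toward 1 (full independence) |

Related pairs copy a base per-bin profile (copy-number states drawn from
{0,1,3,4,5} on altered bins, LOH bins drawn on neutral bins) into the
metastasis with per-bin resampling noise; hypermutator metastases top up
their LOH bins toward the hypermutator mean, and get one planted missense
mutation in each screening panel.  Mutation keys are drawn *without
replacement from the whole toy genome* (5 × 10 Mb), so unrelated samples
share zero keys by construction and truth labels are exact rather than
probabilistic.  Related pairs always carry 1–3 planted trunk drivers; a
config switch (`plant_discordant_drivers`) adds same-gene different-position
driver pairs to exercise discordance logic.  All randomness flows through a
single `numpy` generator in a fixed draw order: identical configs give
byte-identical output files.  `recovery_experiment` runs the full pipeline
on replicate cohorts (replicate *r* uses seed `seed + r`) and scores
classification accuracy, adjacency sensitivity/specificity and hypermutator
flag accuracy against the planted truth; at the strong-signal defaults with
30-pair cohorts and 20 replicates all of these are ≥0.95 (hypermutator
flags exact), and they fall to chance as the trunk mean goes to 0 and the
SCNA noise rate to 1.

What the generator does **not** model: allele frequencies and subclonal
structure (the clone tree is exactly two levels, trunk/private), mutation
hotspots and context biases, germline CNV, segmentation artefacts, and any
quantitative calibration of SCNA similarity to real arrays.  Passing
recovery tests therefore show that the pipeline's logic is correct and its
signal thresholds coherent under the cohort's published magnitudes — not
that real array noise would be handled at any particular accuracy.

## Numerical and interface choices

* Coordinates are 1-based closed intervals at every interface; bin
  arithmetic is half-open internally.  A segment contributes to a bin
  proportionally to overlap length; the per-base brute-force oracle in the
  tests pins this definition.
* Parsers are strict TSV-with-header; a column map renames dialects onto the
  canonical columns rather than guessing.  A bad row aborts with its line
  number — rows are never silently dropped.  Write→read is the identity
  (property-tested).
* Dendrograms export to Newick with branch lengths derived from merge
  heights; correlation distance on a constant profile is defined as the
  maximal 1 instead of NaN.
* Problem sizes in the test-suite and the recovery experiment (30-pair
  cohorts, 500-bin toy genome, 20 replicates, 200 oracle matrices at n ≤ 8,
  500 t-test oracle draws) were chosen to exercise every code path at the
  reference cohort's scale while keeping the whole suite around fifteen
  seconds.

## Known limitations

* The clustering criterion is topology-only; no bootstrap or height-based
  confidence accompanies a "grouped" call.
* Burden counting is segment-based; if upstream segmentation granularity
  differs wildly between samples, totals are not comparable (base-pair
  weighted burden is not implemented).
* The classifier trusts its two inputs symmetrically; there is no
  probabilistic model of clonality and no attempt to resolve
  `discordant_evidence` calls automatically.
* Chromosome extents are inferred from the data, so bins beyond the last
  segment of a chromosome are silently absent; supply explicit lengths via
  the library API if exact genome tiling matters.
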