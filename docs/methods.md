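# Methods

## Genotype calling

Calls are made per (cell, site) from reference (`r`) and variant (`a`) read
counts. Coverage below `min_coverage = 10` reads makes the site NA: with
fewer than ten reads one cannot distinguish a wild-type site from a mutant
site whose variant allele happened not to be sampled, so no genotype is
asserted and NA is propagated (never imputed). At covered sites
VAF = a/(r+a) and the site is MUT when `a >= min_alt_reads` (default 2)
**and** `VAF >= min_vaf` (default 0.05), else WT. The coverage threshold is
the study design's qualification cut; the MUT thresholds are this package's
choice where the calling rule at covered sites was otherwise unspecified:
requiring two variant reads rejects single-read PCR/sequencing errors, and
the 5% VAF floor keeps sensitivity at the low single-cell VAFs that
amplicon expression data show while discarding trace contamination. All
comparisons are inclusive (`>=`), and both knobs are exposed in
`CallerParams`. A cell is *qualified* with `min_informative_sites >= 1`
non-NA site — the weakest rule consistent with qualification being about
usable data; the threshold is exposed because stricter panels may want
more.

## Clone reconstruction and exclusions

Clones are cells of one donor with identical mutation combinations over the
donor's *detected* sites (sites MUT-called in at least one of that donor's
qualified cells). Scoping NA exclusion to donor-detected sites (rather than
the whole panel) is deliberate: a cell uncallable at a site never mutated
in its donor carries no ambiguity about the donor's clonal structure. Cells
NA at a detected site are excluded and counted; cells WT at every detected
site form the WT clone, excluded from clonal analyses but counted, so the
partition identity `qualified = assigned + WT-excluded + NA-excluded` holds
per donor and is asserted by the pipeline. Clone ids are deterministic
(`donor:sorted-signature`), and cross-donor clone *families* are formed by
exact signature equality; a family present in two or more donors is
*shared*. Within-donor analyses never merge donors, and origin is evaluated
per donor even when a family spans donors.

## Classification and origin

Mutation classes are detection-based over the qualified cells of the whole
cohort: detected in any HD-group cell ⇒ CH, detected only in MDS-group
cells ⇒ MDS; sites never detected are unclassified and omitted. A site
detected only in HD donors is CH by this rule (clonal hematopoiesis by
construction) and is additionally flagged `hd_only` for transparency. Clone
class: any MDS-class site in the signature makes an MDS clone regardless of
coexisting CH mutations; carrying both classes flags a double-mutant clone.
Origin: HSC iff the clone's realized populations contain all six mature
lineages {n, m, E, M, B, T}; the CD34+ `H` population is ignored both ways
because sorted HPCs cannot discriminate the two origins. With a limited
number of cells per population an HSC-derived clone can be missed in a
lineage, so HSC counts are a lower bound on real data; the tests quantify
this only where the simulator guarantees recoverability (below).

## The synthetic cohort generator

The generator emulates the study's data shape and is the ground-truth
surface for every downstream test. Defaults are the study's conditions:
7 HD-group donors and 14 MDS patients; an 18-variant panel (3 CH-class,
15 MDS-class) over the six recurrently mutated genes; 7 populations with
18–26 cells each per donor; long-tailed negative-binomial coverage with
mean 100 against the 10-read threshold; heterozygous expressed VAF 0.5 with
Gaussian per-cell-site jitter (sd 0.08, clipped to [0.05, 0.95]) matching
the broad single-cell VAF spread of amplicon expression data; allelic
dropout 0.2 per mutant cell-site (the mutation-detection failure rate
implied by single-cell validation experiments of this assay class is on the
order of 20%, conflating dropout and coverage — the default is a realistic
free parameter, not a calibrated claim); false positives at 0.001 per
cell-site, emitting a spurious variant fraction Uniform(0.05, 0.5).

Per donor a nested hierarchy is grown from the WT root; each clone adds one
mutation to its parent, so child signatures strictly contain their
parents', and no CH mutation is acquired below an MDS-bearing clone (CH
before MDS on every descent path). CH sites are planted in at least one
donor of each group when both exist; MDS sites only in MDS donors — this
makes the intended class identical to the class the detection dichotomy
recovers, in every configuration. HD donors draw fewer clones
(`hd_clones_per_donor`, default 0–2, so some healthy donors carry none, as
observed in real marrow). True origins are drawn per clone with HSC
probability 0.27 for CH-only clones and 0.10 for MDS clones — the fractions
the lineage-tracing analysis reports — and HPC clones emit into a random
proper subset of 1–5 lineages; `H` emission is an independent coin flip
because the origin rule ignores `H`. CH-only clones are upweighted in cell
sampling (`ch_size_advantage`, default 2) to reproduce the larger observed
size of CH clones; `wt_fraction` (default 0.4) keeps a WT clone present so
the WT-exclusion logic is always exercised.

One simulator property is load-bearing for testing: every clone receives at
least one cell in each population it emits in. Realized population sets
therefore equal the truth emission sets, so on a *noiseless* configuration
(dropout, false positives and jitter zero, coverage dispersion raised to
100 so that P(coverage < 10) ≈ 1e-40) the pipeline recovers partitions,
classes and origins exactly — the basis of the exact-recovery tests. Real
data offer no such guarantee; passing those tests shows the reconstruction
logic is correct, not that noisy data are fully recoverable. Under noise
the tests assert only what survives: conservation of cells, the
combinatorial clone bound, no co-clustering of conflicting definite
genotypes, and the reappearance of the configured dropout rate as WT calls
at true-mutant sites. MDS donors get a blast percentage Uniform(1, 20) so
both blast strata (1–9%, >9%) are populated. All randomness flows from one
`numpy` Generator seeded by `SimConfig.seed`; identical configs give
byte-identical tables. The requested clone count is clipped into
`[s, 2^s − 1]` for `s` distinct donor sites, since each clone must be a
distinct nonempty signature.

## Statistics

Shannon diversity uses the natural log by default (the index is used
comparatively, so the base only rescales; it is exposed as an option).
Clone size is reported both as absolute cells and as the within-donor
fraction of mutant (clone-assigned) cells; comparisons default to the
fraction because donors contribute unequal cell numbers. The Mann–Whitney U
test uses exact enumeration whenever the pooled sample is tie-free and
n₁+n₂ ≤ 25, else the tie-corrected normal approximation (midranks); the
t test is Welch's by default with the pooled-variance form behind a flag.
Two identical constant samples return p = 1 (method `degenerate`) — no
evidence of a difference rather than an error. No multiple-testing
correction is applied, matching per-panel testing; donors with no
qualified cells raise an undefined-statistic signal instead of
contributing 0. Blast percentages below 1% fall outside both named strata
and map to NA.

## Numerical and design notes

- Integer read counts are enforced at I/O with the offending row reported;
  unknown ids fail referential-integrity checks before any computation.
- Tables are plain delimited text with headers, column order free, unknown
  columns preserved; re-running the pipeline on its own outputs is rejected
  by schema (never silently misread).
- The run manifest records checksums, parameters, the seed and every
  exclusion count, so each analytic exclusion has an audit trail.
- Test problem sizes (tens of donors, hundreds-to-thousands of cells,
  20–100 simulated cohorts, 2000 null replicates) were chosen as the
  smallest sizes at which the checked properties are sharp: exhaustive
  where the domain is finite (the (ref, alt) grid, 127 population subsets,
  full permutation enumeration at n₁+n₂ ≤ 10) and Monte-Carlo elsewhere
  with tolerances stated in the tests.

## Known limitations

- Classification is detection-based, so a single false-positive call in an
  HD cell can promote an MDS site to CH; at the default false-positive rate
  this is rare but visible in large cohorts, and mirrors the fragility of
  the dichotomy on real data.
- Dropout can split or merge recovered clones; no statistical correction of
  clone assignments is attempted (explicitly out of scope).
- The simulator models per-site read counts only — no UMIs, no doublets, no
  expression of non-target genes, no PCR chemistry — and its dropout /
  false-positive defaults are plausible rather than calibrated.
- Origin inference underestimates HSC clones when few cells per population
  are sampled; the generator's guarantee removes this effect from tests but
  not from real data.
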