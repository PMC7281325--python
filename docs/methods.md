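# Methods

## The measurement model

Each SILAC mix combines a heavy- and a light-labeled cell population and
yields, per quantified phosphosite, a normalized heavy/light intensity
ratio. The design uses four mixes per time point, one per biological
contrast (A: resistant vs parental untreated; B: resistant vs parental,
both treated; C: treatment response of the resistant line; D: treatment
response of the parental line), over three time points labeled T1/T2/T3.
The channel assignment is label-swapped between the untreated and treated
pairs — the resistant line is heavy in A and light in B — so systematic
label biases cancel in aggregate and the analysis must re-orient ratios per
contrast. `ComparisonDesign` records, per contrast and time point, which
experiment column supplies the ratio and whether the heavy channel carries
the contrast's sample; `orient_ratio` inverts H/L to L/H when it does not.

Oriented ratios r are mapped to signed fold changes: +r for r ≥ 1, −1/r for
r < 1. The value +1 denotes no change; the representation never takes
values in (−1, 1). The sign convention at exactly r = 1 is +1 by choice;
downstream logic treats |1| as unchanged, so the choice is inert.

## Marker classification

Signed fold changes are thresholded at an **inclusive** cutoff (default
1.5: |FC| ≥ 1.5 counts as regulated; the cutoff value is the standard SILAC
regulation threshold of the assay, and inclusiveness is our choice since
the assay convention does not specify strictness). Per time point the four
calls combine as: with d the direction of A if regulated, else of B, the
site is a resistance marker in direction d iff (A or B regulated in
direction d, neither regulated opposite) and (C unchanged, missing, or
regulated in direction d) and (D not regulated in direction d). D regulated
opposite to d raises the *de novo* annotation — the parental line's
sensitivity-associated response is lost in the resistant line — and is
deliberately an annotation, not an exclusion: the set-difference term of
the formula removes only same-direction D regulation.

Numerical/degenerate choices:

* Missing C or D calls count as unchanged — sites with incomplete time
  points must remain classifiable, since real datasets retain markers with
  missing quantification at individual time points.
* Both A and B missing makes the time point uninformative
  (`insufficient_data`), distinct from `none`.
* A and B regulated in opposite directions is a conflict and yields `none`;
  the prose "A or B" does not address conflicts, so we resolve them
  conservatively.

Aggregation over time requires a direction-consistent consensus:
`overlap_level` is the largest number of time points sharing one
resistance direction (discordant time points never count), with stringency
tiers at ≥ 2 of 3 and 3 of 3; the 3/3 set is nested in the ≥2/3 set by
construction. Marker tables are ordered by |consensus fold change|
descending, then site key, for reproducible output; the consensus fold
change is the mean over contributing time points of the A-contrast signed
FC (B's when A does not support the consensus).

**Cutoff monotonicity.** The regulated-site sets shrink as the cutoff
rises, but the classification subtracts veto sets (opposite-direction C,
same-direction D) that shrink too — so raising the cutoff can *add*
markers when noise activates a veto at a low cutoff. Full
count-monotonicity in the cutoff is therefore not a theorem of the
formula; it holds exactly when the C/D contrasts are quiescent (the
planted-truth situation), and empirically for the ≥2/3 tier on the default
noisy dataset. The test suite pins both statements separately.

## Class-1 filtering

Only sites with localization probability strictly greater than 0.75
(class-1) are analyzed. The filter is idempotent and monotone in the
threshold; the retained fraction is reported per table (about 74% under
the generator's defaults, matching the share typical of phosphoproteome
enrichment of this kind).

## Differential expression

The transcriptome arm takes a log2 expression matrix (genes × samples) over
2 cell lines × 2 treatments × ≥ 2 replicates. Probe-level matrices are
collapsed to genes by the arithmetic mean of probe rows. Per contrast
(untreated or treated, resistant minus parental) each gene gets a
pooled-variance two-sample t statistic. With two replicates per group the
plain t has 2 degrees of freedom and essentially no power after multiple
testing, so the pipeline moderates: each gene's variance is shrunk toward
the median gene variance with prior weight d0 (default 4), and the
reference distribution gains d0 degrees of freedom — a lightweight
analogue of empirical-Bayes moderated statistics. The plain t (d0 = 0) is
retained as the library default because it is exactly calibrated under
normality; the null-uniformity and FDR-calibration tests use it.

BH adjustment is the standard step-up with enforced monotonicity
(delegated to `statsmodels`; an independent brute-force implementation
serves as the test oracle). A gene is **drug-independent regulated** iff
q < 0.05 and |fold change| > 2 (both strict) in *both* contrasts with the
same sign; the rule is symmetric in the contrasts and splits into up/down
sets.

## Network integration and enrichment

Markers and selected genes merge into an undirected `networkx` graph keyed
by gene symbol: phosphoprotein nodes carry per-site A-contrast signed FC
vectors with missing time points as explicit nulls, mRNA nodes carry the
transcript fold change, shared symbols become `both` nodes, and a
user-supplied symbol list flags kinases. Edges come from a file (symbol,
symbol, score) rather than live database retrieval, for offline
testability; edges touching absent symbols are dropped with a warning.
GraphML and Cytoscape-JSON exports JSON-encode attributes so round trips
are lossless and element order is deterministic.

Enrichment is the upper-tail hypergeometric test P(X ≥ k) for overlap k of
the selected n within a universe of N containing K annotated symbols, BH
corrected across terms; terms with no annotated universe member are
skipped. The default universe is the set of measured symbols (all sites and
genes entering the analysis); a whole-proteome universe can be supplied
instead by passing it explicitly.

## The synthetic generator

`SimulationConfig` defaults define the emulated study: 5000 sites × 3 time
points × 4 mixes, planted categories resistance_up/down (1% each),
treatment_response_only (1%), de_novo_reversal (0.5%), remainder null;
effect size 3.0 on the ratio scale; log10-normal multiplicative ratio noise
(sd 0.05); 5% missingness per site-per-experiment (completely at random —
real missingness is intensity-dependent, which this does not model);
class-1 target share 0.74; expression: 2000 genes, biological duplicates,
16 up + 20 down planted drug-independent genes (the first up gene is a
TEAD2-like exemplar at 2.24-fold) and 20 treatment-only genes, gaussian
log2 noise sd 0.1. Planted effects are constant across time points by
default; `partial_marker_fraction` moves that share of markers to exactly
2 of 3 time points to exercise the overlap tiers.

Design choices worth knowing:

* **Noise placement.** Noise multiplies the *oriented* (sample/reference)
  ratio before conversion to the stored H/L value. Biologically the
  variation lives on the measured ratio either way; placing it on the
  oriented scale makes the label-swap invariance structural (a swapped
  regeneration stores exact reciprocals), which is the property the paired
  design is meant to guarantee and which the tests verify bit-for-bit on
  marker lists.
* **Localization probabilities.** Planted (non-null) sites are always
  class-1 — the generator plants *detectable* markers; a marker silently
  removed by the localization filter would make ground truth meaningless —
  and the null-site class-1 probability is adjusted so the expected overall
  share equals `class1_fraction`. Probabilities are drawn once per site and
  reused across time points.
* **Seeding.** One master seed spawns independent sub-streams for the
  phosphosite and expression arms, so changing `n_genes` never perturbs
  site-level data. Identical config and seed give byte-identical files.
* **Ground-truth evaluation** grades marker recovery at the direction
  level: de-novo-reversal sites count toward their resistance direction
  (they are markers; the de novo flag is a separate annotation). Precision
  is reported as NaN with zero support when nothing is predicted.

What passing on synthetic data does **not** show: robustness to
intensity-dependent missingness, ratio compression, peptide-to-site
aggregation artifacts, batch effects between time points, or probe-level
normalization issues — none of which the generator emulates.

## Problem sizes and runtime

The test suite and the acceptance script use the generator's default scale
(5000 sites, 2000 genes), chosen to match the emulated study's order of
magnitude while keeping any single check within seconds on one CPU. The
exhaustive set-logic check enumerates all 4^4 = 256 call combinations; the
hypergeometric oracle covers every (N ≤ 30, K, n, k) instance.

## Known limitations

* The DE stage is a documented stand-in, not a re-implementation of
  published empirical-Bayes machinery; its moderation is a single-parameter
  shrinkage toward the median variance.
* Multiplicity variants of a site are distinct identities; no
  site-to-peptide collapsing rule is applied.
* Enrichment supports flat gene-set collections (GMT); no ontology
  topology or term-redundancy reduction.
* The generator's time-point labels are abstract (T1/T2/T3); it does not
  model unequal noise or effect attenuation across time.
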