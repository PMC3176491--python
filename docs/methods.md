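# Methods

## Score model and network construction

An S-score quantifies the deviation of a double mutant's growth from
the neutral expectation; it is treated here as a dimensionless,
symmetric pair attribute with no error model of its own. Matrices may
contain both orientations of a pair; if they disagree the mean is
stored (the same averaging rule used when merging matrices from
several studies, so one symmetrization policy governs all duplication).
Gene identifiers are taken verbatim — ORF/name mapping is an annotation
concern and deliberately outside I/O.

Sign classification uses symmetric percentile cutoffs rather than a
fixed score value, which makes the construction invariant to monotone
rescaling of the assay and guarantees (up to ties) equally many
negative and positive edges. The estimator is nearest-rank: with `n`
stored scores and tail mass `X` percent, `k = ceil(X/100 · n)` and the
cutoffs are the k-th smallest and k-th largest score. Comparisons are
inclusive on both sides, so ties at a cutoff are admitted; in the
degenerate case where the two cutoffs coincide and a score satisfies
both, the edge is classified negative (a fixed, documented tie-break —
note it breaks the N/P mirror symmetry only in this measure-zero case).

The gene filter removes genes with fewer than 2 supra-threshold edges.
It is a **single pass** computed on the thresholded network: the
wording "did not achieve two or more interaction scores beyond the
threshold" references scores, not the post-filter network, so
surviving genes are not re-examined after edge removal and may end up
with degree below 2. An iterate-to-fixpoint mode is available behind
`ThresholdConfig.iterate_filter` for sensitivity analysis.

## Triplet census

Triangles are listed by the standard edge-iterator method and verified
against an exhaustive triple loop. Within a triplet the three edges
are ordered ascending by S-score into positions i, ii, iii; ties are
broken lexicographically by the sorted gene-pair labels so position
codes are deterministic. The class label is the sign multiset.

Participation averages (fraction of participating edges that are
negative; mean triplets per N and per P edge) are computed over edges
in at least one triplet, not over all edges — the only definition under
which the per-sign means, the edge-slot identity (3 × triplet count)
and the sign fraction are mutually consistent.

Per-gene sign polarity uses a two-sided exact binomial test of the
gene's N/(N+P) split against 0.5, Bonferroni-corrected across tested
genes. No test is named in the source analyses; the exact binomial is
the minimal null for sign skew.

## Null model

The ensemble preserves each node's negative and positive degree
exactly: double-edge switches are attempted within the N edge set and
within the P edge set (q attempts per edge per class, default
q = 100), rejecting any switch that would create a self-loop or place
a second edge on a pair already occupied by either sign — so a pair
holds at most one edge, matching the input structure where each pair
has one S-score.

One subtlety matters for correctness: the per-sign attempts are
**interleaved in a random schedule**, not run as two sequential
phases. Each individual switch kernel is symmetric, hence doubly
stochastic, so any interleaving leaves the uniform distribution over
reachable configurations invariant; running all N switches before all
P switches does not (the P configuration would be equilibrated
conditional on the final N configuration only, which over-weights
states in proportion to the inverse of their compatible-P count). The
sequential variant measurably biased small-network ensemble means; the
interleaved sampler matches exact enumeration over all reachable
states on small test networks (uniform over the reachable set is the
correct target because the proposal is symmetric and rejections act as
self-loops).

z = (observed − mean)/SD per class, with the SD over `n_random`
independent draws (n−1 denominator; default n_random = 1000, ensemble
sizes are configurable everywhere). SD = 0 (rigid degree sequences)
flags z undefined rather than infinite. Each draw's random stream is
derived from the user seed and the draw index through numpy's
SeedSequence, so runs are reproducible and order-independent.

Reading z against normal quantiles (z ≥ 2 ≈ p 0.05 two-sided) assumes
approximately normal null counts. This holds for dense networks with
per-class counts well above 1 and **fails at very sparse counts** —
see "Calibration" below.

## Annotation channels

Six term channels (complex, pathway, phenotype, GO function / process
/ location) and three pair channels (physical, genetic, homology).
Genetic-interaction tables keep only manually curated synthetic-lethal
and synthetic-growth-defect rows. GO annotations are propagated to all
ancestors, then terms annotating fewer than 2 or more than 40 genes
(inclusive) of the analysis universe are removed globally; frequency
is counted over the post-filter gene set, per channel (the closure is
idempotent, so re-running the filter is a no-op). The finer term
refinement applied in some earlier integrated-network studies is not
reproduced beyond closure + frequency window; this is a known
limitation. The phenotype term 'viable' is uninformative (nearly
universal) and removed. Homology is consumed as a precomputed pair
list (blastp E ≤ 0.01 is the conventional recipe; running it is not a
package concern).

## Enrichment analyses

*Position codes.* One 3-bit code per (triplet, channel); bit k is set
iff the pair at position k shares the channel's feature. All 8
patterns are retained. For channels whose sharing relation is
transitive (single-complex membership), two-bit codes are impossible;
for multi-membership channels they are not, so observed {110, 101,
011} counts are emitted as a diagnostic, and an optional collapse mode
maps any ≥2-bit code to 111 for comparison with analyses that assume
transitivity. Both exact patterns and position aggregates
("any-bit-at-iii") are supported, since published figures can be read
either way.

*Fisher cross-tabulation.* 2×2 table {in class, not} × {code matches,
not}; two-sided exact p (verified against hypergeometric enumeration
to 1e-10); odds ratio with Haldane 0.5 correction on zero cells. The
Bonferroni family is all testable records emitted by one scan — the
family size is recorded with the results.

*Edge-context fold changes.* For each sign, each channel, the fraction
of edges sharing the feature in each triplet context relative to
same-sign edges outside any triplet; two-sided Fisher vs the baseline,
Bonferroni across emitted comparisons, significance at corrected
p < 0.01 (a printed "p > 0.01" in the source figure legend is an
evident typo for the significance threshold).

*Profile correlation.* Spearman (average ranks on ties) between the
two genes' S-score vectors over partners measured for both, excluding
the two genes themselves; edges with fewer than 10 common partners are
skipped by default (configurable; small synthetic matrices use 5).
Summaries report mean ± SD per edge-sign role within a class, with the
standard error alongside.

*Positional gene-set enrichment.* The gene set occupying a node role
(NPP positive node = gene on both P edges; NNP spanned node = gene on
both N edges), deduplicated across triplets; per term a one-sided
hypergeometric p against the analysis universe, Bonferroni across
terms, and fold enrichment (set fraction / universe fraction).

## Synthetic data generator

The generator emulates a pooled E-MAP's gross statistics — 100 genes
and 78% missing values by default, scaled down from the thousands of
genes of a real compendium so every experiment runs in seconds — and
plants the four arrangements the motif analysis targets:

| structure | default | scores | plants |
|---|---|---|---|
| complexes | 5 cliques of 4 | N(+6, 1) within | PPP |
| bridges | 3 complex pairs (the triangle 0-1-2), 2 liaison genes each side, complete bipartite | N(−6, 1) | NNP per bridge; NNN across the mutually bridged triple |
| pathways | 5 redundant pairs | N(−6, 1) within | the N edge of NPP |
| regulators | 5 genes, each positively linked to all members of 2 pathways | N(+6, 1) | NPP with the regulator at the positive node |

Background pairs draw from N(0, 1); the missing mask is uniform over
non-planted pairs with the per-pair probability scaled so overall
missingness hits the target (planted pairs are exempt by default —
disable `keep_planted` for realism studies). Structural means of ±6
against unit noise separate planted from background scores by several
standard deviations, so percentile tails sized to the planted-edge
fraction capture the structure cleanly. At the default scale the
planted positive edges are ~4.6% of measured pairs, hence the recovery
experiment's default tail mass is X = 5 — at compendium scale (hundreds
of thousands of scored pairs) the same structures occupy well under 1%
and the conventional X = 1 applies. An optional block-missingness mode
restricts measured pairs to within gene blocks, emulating the
fragmented coverage of pooled screens (each study screens a few
hundred genes); the default mask is uniform and does not reproduce
that row-column structure.

What passing recovery shows: thresholding, filtering, census, null
model and positional enrichment jointly recover planted structure at
these effect sizes and this sparsity. What it does not show: behaviour
under correlated noise, batch structure, asymmetric measurement
error, or score distributions with heavy tails — none of which the
generator models.

## Calibration and its limits

With no planted structure the pipeline should not report enrichment.
The calibration experiment (`null_calibration`) generates
background-only matrices at the default conditions, runs the identical
pipeline (X = 5, minimum degree 2), and counts replicates in which all
four class z-scores stay within ±3 (SD = 0 classes count as within
bounds iff observed equals the null mean; networks too small or too
sparse to randomize carry no structure and count as within bounds).

Measured: ~90–94 of 100 replicates, not ~99. The shortfall is a
property of the z statistic at desk-scale density, not of the sampler
(which matches exact enumeration, and disabling the degree filter
leaves the rate unchanged): per-class null triplet counts are
approximately Poisson with mean 0.2–0.7, so an unstructured network
carries ≥2 chance triangles of one class in roughly 5–10% of
replicates, and (obs − mean)/SD then exceeds 3 even though nothing is
wrong. Two secondary effects add to this: chance triangles survive the
degree filter preferentially (a triangle is self-supporting under a
minimum-degree-2 rule), and a single observed triangle over a
near-zero-SD ensemble produces a large z. At real-compendium scale,
null counts are in the hundreds, normality is adequate, and the issue
vanishes — but users interpreting z-scores from small or heavily
thresholded networks should treat |z| < 3–4 on single-digit counts as
noise, or use empirical ensemble quantiles instead of the normal
reading.

## Problem sizes

Default experiment sizes — 100-gene matrices, n_random = 500 (recovery)
or 150 (calibration), q = 50 swap attempts per edge, 100 calibration
replicates, 5000 draws for the exact-enumeration check on a 7-node
network — were chosen so the full test suite and the acceptance script
each complete in minutes on one CPU while keeping Monte-Carlo standard
errors well inside the asserted margins.

## Known limitations

- Score symmetrization hides systematic orientation effects (logged,
  not modelled).
- The GO frequency window is applied per channel; a joint filter
  across the three GO branches would change term survival near the
  window edges.
- The randomization chain's reachable set can in principle be a proper
  subset of all graphs with the given signed degree sequence (the
  cross-sign occupancy constraint can disconnect the switch space);
  expectations are therefore defined over the reachable set, which is
  also what exact enumeration verifies.
- Analytic expected counts are not provided; the null is Monte Carlo
  only.
- No 4-node or higher-order motifs.
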