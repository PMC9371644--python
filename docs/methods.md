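# Methods

## Scope and model

`tadshift` analyses perturbation Hi-C experiments in which a chemical
treatment (a condensate-disrupting alcohol, or a transcription inhibitor)
transiently weakens a subset of TAD boundaries. The package's analytical
chain is: matrix balancing → insulation scoring → boundary calling →
per-boundary differential testing → compartment analysis → boundary
clustering and trans-contact aggregation → nascent-transcription
(PRO-seq) pausing analytics. A synthetic-data generator with known ground
truth defines the conditions under which every stage is benchmarked.

## Insulation score and boundary calling

For bin *i* and window *w* bins, the raw insulation is the mean balanced
contact count over the square of pairs spanning *i*:
`s_raw(i) = mean{ M[u,v] : i−w ≤ u < i < v ≤ i+w }`. The reported score
is `log2(s_raw(i) / mean_chrom(s_raw))`, with the mean taken per
chromosome (not genome-wide) so per-chromosome coverage differences
cancel. Bins within *w* bins of a chromosome end are masked, as are bins
the balancer masked. A raw value of zero is floored at half the smallest
positive `s_raw` on that chromosome before the log, so contact-free
junctions remain finite and callable.

Defaults: window 480 kb (12 bins at 40 kb) — a common choice spanning a
typical TAD; balanced input (raw-count scoring retained as an option);
boundary = local minimum strictly below both flanking valid scores with
prominence ≥ 0.1 log2 units; plateau minima resolve to the leftmost bin.
Cross-sample boundary tables are built on a fixed reference boundary set
(the pooled control by default); a union-merge mode collapsing calls
within one bin to the lower-scoring bin is also provided.

Balancing is symmetric Sinkhorn/ICE iteration: biases are updated by
`sqrt(row_sum / mean_row_sum)` until all unmasked row sums agree to
relative tolerance 1e−5 (error with iteration count on non-convergence);
rows with no nonzero entries are masked.

## Differential boundary insulation

Insulation scores are log-ratios and are treated as Gaussian. Per
boundary, a Gaussian identity-link GLM `score ~ condition` is fitted; the
condition coefficient Δ (treated − control) is tested two-sided via its
t statistic. For a two-group design this is exactly the pooled two-sample
t-test, which is what the vectorized production path computes; an
explicit GLM route (statsmodels) is kept and asserted to agree to ten
significant digits. Directionality is imposed as a sign gate: HDS
requires BH q < 0.05 *and* Δ > 0 (weakening moves the negative minimum
toward zero). Boundaries with fewer than two finite replicates per
condition, or zero pooled variance, are flagged and excluded from the
FDR. No variance moderation is applied by default — with two replicates
per condition the test has 2 df and is exact under the Gaussian model;
shrinkage alternatives are intentionally out of scope.

## Compartments

Per chromosome at 500-kb bins: expected counts per diagonal are the
diagonal means over valid bin pairs; the observed/expected matrix is
converted to a Pearson correlation matrix over valid, variable bins; PC1
is the leading eigenvector. Because the eigenvector sign is arbitrary,
the caller supplies an orientation anchor (gene density on real data, the
planted profile in simulations) and PC1 is flipped to correlate
positively with it; A = PC1 > 0. PCA is per-chromosome, avoiding
artifacts from stitching chromosomes. The differential-compartment test
reuses the Gaussian replicate test per bin, BH-corrected; a "switched"
bin is significant and changes the sign of its condition-mean PC1. This
per-bin construction is a reconstruction chosen for internal consistency
with the boundary test.

## Spatial analyses

Boundaries with midpoints strictly closer than 1 Mb to an annotated
centromere are removed (a boundary exactly 1 Mb away is retained).
Clustering is a single sweep per chromosome merging consecutive HDS
boundaries whose midpoint gap is ≤ the threshold (default 2 Mb — not a
biologically derived constant, so the cluster summary statistics are
always reported for comparison against data). Clusters need ≥ 2 members;
the rest are singletons.

Trans aggregation scales each sample's interchromosomal total to 1e6
(CPM), assigns each 4-Mb bin its HDS-boundary count and a group
(0/1/2/3+ by default), and reports the mean CPM over interchromosomal
bin pairs whose both ends fall in the same group (a one-sided mode is
available; the choice is genuinely open and both are exposed). Bins with
zero trans coverage are excluded from grouping, which makes group means
invariant to adding empty chromosome pairs. A confounder table reports
the distribution of *total* boundary counts per HDS-count group.

Housekeeping genes are the intersection of per-tissue top-fraction
expression lists (default top 1% on real-size tables; 5% on the small
demo so the top list is larger than the housekeeping set). Enrichment is
the density ratio (housekeeping genes per Mb inside cluster spans vs
outside), with genes assigned by midpoint containment and the cluster
genomic fraction reported alongside.

## PRO-seq

The pause window is TSS−50 to TSS+300 in the direction of transcription
and the body runs from TSS+300 to the TES; the pausing index is the
pause/body density ratio, undefined when the body has fewer than 10 reads
or is shorter than 100 bp (reason codes `low_body` / `too_short`). These
window choices follow common pausing-index practice and are configurable,
since no single canonical definition exists. Differential pausing sums
pause and body counts over replicates and applies Fisher's exact test to
the 2×2 (pause/body × control/treated) table per gene, BH-corrected,
classifying genes by the sign of the PI change at q < 0.05 —
replicate-aware count models are out of scope. Transcript discovery is
annotation-driven (known gene intervals), a deliberate simplification of
de-novo transcript calling. Region enrichments use midpoint overlap and
are normalized by region span in Mb.

## The simulator

Cis expectation per chromosome:
`E[i,j] ∝ (1+|i−j|)^−α · τ^[same TAD] · Π π_eff(b)` over boundaries *b*
strictly between *i* and *j*, scaled so the expected per-chromosome total
equals the configured depth; counts are Poisson on the upper triangle,
mirrored. A boundary's permeability π ∈ (0,1] becomes
`π + w_c(1−π)` for HDS boundaries under a condition with weakening
factor `w_c` — multiplicative recovery toward full permeability, with
the schedule (control 0, 5 min 0.5, 30 min 0.25, 3 h 0) modelling
treatment and washout. Trans maps are Poisson around
`λ · ε^[both bins in the cluster set]` with ε relaxing toward 1 under
treatment. PRO-seq reads per gene are Poisson with mean proportional to
expression; a fraction `f_pause` lands uniformly in the pause window and
the rest uniformly over the body. Expression tables are log-normal per
tissue, with designated housekeeping genes drawn high-mean/low-variance
in every tissue and preferentially placed (p = 0.8) inside cluster
regions. Every (condition, replicate, data-kind) triple has its own
random stream derived from the master seed, so adding samples never
perturbs existing draws.

Poisson (not negative-binomial) noise is the default: it is the simplest
model that exercises the Gaussian replicate test, and the insulation
statistic averages enough matrix cells that extra dispersion would change
power, not correctness. The demo conditions — 2 chromosomes × 20 Mb,
40-kb bins, 10 boundaries per chromosome with permeabilities 0.10–0.50,
20% HDS arranged as one two-boundary cluster per chromosome inside a
single 4-Mb bin, α = 1, τ = 1.5, 1e6 cis contacts per chromosome per
replicate, ε = 2, 1e6 PRO-seq reads — were fixed once as a realistic
desk-scale configuration. Problem sizes throughout the benchmark battery
(200 null runs × 5,000 boundaries; 6 genomes for the power study; 100
random matrices/placements for the oracles) are the package's own choice
of what yields stable estimates in a few minutes on one CPU.

## What the synthetic benchmarks do and do not show

Passing recovery tests demonstrates the *implementation* is correct and
the statistics calibrated under the generative model. Real Hi-C has
features the generator omits: coverage and mappability bias beyond what
balancing removes, loops and stripes, negative-binomial overdispersion,
replicate batch effects, centromeric/repeat artifacts, and treatment
effect sizes far subtler than the planted permeability shifts (real
insulation shifts are small; the planted w = 0.5 weakening is chosen to
make the power benchmark's ground truth unambiguous). Observed headline
fractions on real data (what share of boundaries is condensate-sensitive,
cluster descriptives, fold-enrichments) are properties of the data, not
of this software, and are not reproduced by the demo.

## Numerical and design notes

* Coordinates are 0-based half-open everywhere; BED dialects on disk;
  triplet TSV is the canonical contact interchange (an indexed binary
  container adds a dependency without helping testability at this scale).
* Contact matrices are dense in memory — at 40-kb/500-kb/4-Mb bins a
  chromosome is at most a few thousand bins.
* Degenerate inputs: empty TAD partition = single-TAD genome; chromosome
  shorter than 2w+1 bins gives an all-masked track with a warning, not an
  error; empty boundary tables propagate as empty results.
* Tie-breaks are deterministic: plateau minima to the leftmost bin;
  union-merge keeps the lower score.
* The pipeline manifest hashes each stage's parameters together with its
  upstream signatures, so changing one parameter re-runs exactly the
  affected suffix of the stage graph.

## Known limitations

Boundary identity across conditions relies on a fixed reference set
called on the control, so boundaries absent from the control are
invisible. The differential-compartment and differential-pausing tests
are deliberately simple (per-bin t, summed-count Fisher) and do not model
replicate overdispersion. Trans aggregation reports means, not
significance — permutation nulls for specific chromosome pairs are out
of scope. The simulator does not generate read-level data, loops, or
polymer-physics structure.
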