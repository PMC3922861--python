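# Methods

## Scope and model

`regscreen` operationalizes a multi-evidence screen for candidate
transcriptional regulators of cellulase and hemicellulase genes. The premise
is biological: regulators of an induced enzyme system are often themselves
induced and co-regulated with their targets (the "double-lock" pattern), so
candidates can be ranked by how many independent expression-derived evidence
streams they satisfy. The pipeline starts from a normalized log2 signal
matrix — probe-level preprocessing, array QC and paired designs are out of
scope — and treats every stage as a pure function of its typed inputs, so
stages can be run, tested and replaced independently.

## Differential induction

Each (substrate, time) cell is an independent two-group comparison of
induced samples against the uninduced controls at the same time point.
This mirrors how induction experiments are analyzed in practice: controls
are shared across substrates, and a joint linear model would add coupling
the design does not require.

Per gene, Δ = mean(induced) − mean(control) on the log2 scale and
s² = pooled two-group variance with d = nᵢ + n꜀ − 2 df. Variances are
shrunk with an empirical-Bayes prior fitted by moment matching on the log
variances: if s² ~ s₀²·F(d, d₀), then log s² has mean log s₀² + ψ(d/2) −
ψ(d₀/2) − log(d/d₀) and variance ψ′(d/2) + ψ′(d₀/2); the sample moments of
log s² across genes give (d₀, s₀²) via a Newton inversion of the trigamma
function. The moderated statistic is t = Δ / (s̃ √(1/nᵢ + 1/n꜀)) with
s̃² = (d₀s₀² + d·s²)/(d₀ + d) and two-sided p from t on d₀ + d df.

Numerical choices:

* Genes with zero sample variance are floored to the smallest positive
  variance observed so the log-moment estimator stays finite.
* When the observed spread of log variances is no larger than the sampling
  spread ψ′(d/2), the prior df estimate diverges; d₀ = ∞ is handled exactly
  (posterior variance = s₀², normal p-values — the pooled-variance z
  statistic). This is the correct limit for homoscedastic data, not an
  error state.
* Fully noise-free data (all s² = 0, possible only in simulation) get
  p = 0 for any nonzero fold change and p = 1 otherwise.
* Contrast cells with fewer than two replicates on either side are reported
  with NaN statistics and call 0, never silently dropped.

Calls use raw p < 0.01 plus |log2FC| > 0.4, reported as +1/−1/0. Raw
p-values gate the default call; a Benjamini–Hochberg column is emitted for
users who want FDR control but never drives the call. Induction breadth is
the number of substrates with a +1 call at any time point; breadth ≥ 3 is
the induction criterion downstream.

## Profiles and fuzzy c-means

Clustering operates on per-(substrate, time) mean log2 fold changes versus
control — the representation displayed in induction heat maps — standardized
row-wise (z-score, sample sd). Constant rows (zero variance, typically
uninduced genes in noise-free simulations) are dropped and reported.

Fuzzy c-means minimizes J_m = ΣᵢΣⱼ u{ᵢⱼ}^m ‖xᵢ − vⱼ‖² under row-stochastic
memberships, by the standard alternating updates. Parameters: fuzzifier
m = 1.25 (crisp enough for hard assignment, soft enough to expose borderline
genes; m → 1 recovers k-means), tolerance 1e-5 on max |ΔU|, 300 iterations,
3 seeded restarts keeping the lowest J_m. The cluster count c is a required
choice (default 6 matches the synthetic generator; real genomes need larger
c and the package reports J_m for comparing choices — no automatic validity
index is applied). Degenerate geometry is handled explicitly: a point
coinciding with a centroid takes full membership on the first such centroid;
a centroid left with zero membership mass keeps its previous position; hard
assignment breaks membership ties toward the lower cluster index.

Reference clusters: clusters are ranked by how many of the user-supplied
reference (characterized cellulase/hemicellulase) genes they hold, and the
smallest prefix covering ≥ 90% of the references is flagged; all
non-reference genes in flagged clusters form the co-clustered set. The 90%
coverage default reflects that a few characterized enzymes always fall
outside the main clusters.

## Enrichment

Class over-representation in a gene set uses the exact hypergeometric upper
tail P(X ≥ k) with fold (k/n)/(K/N); over-representation is the default
(one-sided) because the screen asks whether regulatory domain classes are
concentrated in the co-clustered set. Multiple classes get a BH-adjusted
column alongside the raw p, which remains primary. Conventions at the
boundary: k = 0 gives p = 1; an empty class gives fold 0.

## Genome scan

Scaffold gene order is the start-coordinate sort (strand ignored — observed
co-regulated regions mix strands). Two rules:

* **Windowed regions**: maximal chains of same-cluster genes with
  successive-member rank gaps ≤ 5 that place ≥ 3 members inside some window
  of 9 consecutive genes. "Distance of five genes" is read as a rank
  difference between successive members (≤ 4 interleaved genes); the window
  predicate is monotone in the member set, so maximal chains are well
  defined, and both thresholds are parameters for users who prefer the
  alternative readings. A chain may extend past the triggering window via
  the gap rule; the trigger guarantees a locally dense core.
* **Adjacent patches**: maximal runs of ≥ 3 rank-consecutive same-cluster
  genes. Every such patch is also found by the windowed rule under the
  default parameters (containment property, tested).

Correctness of both scans is established against brute-force enumeration on
randomized scaffolds rather than against hand-picked cases. Coordinates are
1-based inclusive internally (GFF3 convention); BED input/output converts at
the boundary.

## Correlation screen and proteome flags

Pearson correlation (Spearman optional) of condition-level expression
against the specific protein production rate across ≥ 3 chemostat-like
conditions; |r| ≥ 0.5 passes, with the sign recorded. The threshold is
deliberately permissive — at n = 6 conditions the null tail
P(|r| ≥ 0.5) = 2·P(t₄ ≥ 0.5√(4/0.75)) = 0.3125 — so a correlation pass is
weak evidence on its own and is never sufficient for selection. Genes with
zero expression variance get undefined r and never pass. Proteome support
enters only as user-supplied per-gene flags (+1 protein up under
high-production conditions, −1 down, 0 none); the mass-spec analysis itself
is out of scope.

## Candidate integration

Five boolean criteria per gene: induction breadth ≥ 3; co-clustering with
the references; correlation pass; proteome flag ≠ 0; co-localization
(membership in a detected region or patch, OR a CAZy/sugar-transporter gene
as direct rank-neighbor). "Fulfilling several criteria" is operationalized
as a configurable count threshold, default 3 of 5, behind a regulatory-class
gate (the gene must carry a configured regulatory domain class, e.g. the
Zn2-C6 TF domains). Score is the weighted criterion sum (uniform default);
ranking breaks ties by criteria count then gene id, making reports
byte-reproducible. The gate and threshold are config-first because the
original selection of this kind is partly editorial; the defaults encode
the stated criteria without attempting to reproduce manual curation.

## Synthetic studies

The generator emulates the targeted study design: induced cultures on four
substrates sampled at 0/6/17 h with four biological replicates against a
shared uninduced control; expression = gene baseline (log2 ~ N(8, 1.5),
fixed choice — signal distributions are not dictated by the screen) +
planted cluster effect + N(0, noise_sd²). Cluster effects are step
functions of time ("early": full amplitude from 6 h; "late": only at the
last time point), amplitude 2.0 log2 units, residual sd 0.5 — values chosen
once as a realistic strong-induction regime for 4-replicate arrays.
Defaults: 2,000 genes on 20 scaffolds, six clusters of 60 genes, 20 planted
5-gene regions hosting 20 regulator genes, 2.5% of the genome tagged with
the regulatory domain class, a 6-condition chemostat block where regulators
and reference genes track the production rate (slope 1 log2 unit per rate
sd, noise 0.25).

Genome layout: genes tiled at fixed 1 kb length with 500 bp gaps,
alternating strand. Planted regions occupy consecutive ranks with a 6-rank
buffer, and the remaining cluster members are spread with spacing wider
than the scan's member gap, so the planted regions are the only
co-localized same-cluster structure and region recovery is exact under
perfect labels. Truth structure (layout, labels, annotations) is a function
of the config alone; the seed varies only the noise realizations, so two
seeds of one config share identical ground truth. Sub-generators per block
are derived deterministically from the seed.

What the generator does **not** emulate — and what passing tests therefore
do not show: probe-level artifacts and normalization residue, correlated
noise between replicates, genes with partial or graded cluster membership,
unequal gene lengths/intergenic distances, annotation errors, and the
editorial component of real candidate selection. Recovery rates on
synthetic data are upper bounds for real arrays.

## Problem sizes and determinism

Test and acceptance computations use desk-scale sizes chosen to exercise
every code path with tight statistical bands: 10,000 genes for calibration
checks, 600 genes / six clusters for cluster recovery, 1,000 random
scaffolds for scan-oracle equivalence, and the 2,000-gene default study for
end-to-end recovery. All randomness flows through explicit seeds; repeated
runs with one seed produce checksum-identical output trees, and every
output file re-parses through the package's own readers.

## Known limitations

* The screen's real-data headline counts depend on the original microarray
  and genome annotation and are not reproducible from this package alone;
  the package reproduces the method, with correctness established by
  oracles and planted-truth simulations.
* P-values are used unadjusted in the default call, matching the screen's
  published cutoffs; users wanting FDR control should gate on the emitted
  BH column.
* Cluster numbering is not comparable across runs or to any published
  numbering (fuzzy c-means labels are permutation-arbitrary).
* The correlation screen assumes condition-level expression summaries; it
  does not model within-condition replicate structure.
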