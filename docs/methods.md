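# Methods

`mrscreen` identifies candidate transcriptional master regulators (MRs) —
TFs whose activity plausibly drives a case-vs-control expression program —
by running two independent routes from expression data to TF→gene pairs and
keeping only TFs that survive a selection criterion under *both* routes.
This note records the models, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Study layout

Samples are organised in six cells: two strains (`case`, `control`, e.g. a
spontaneously diabetic rat model versus its control strain) crossed with
three growth periods (`P1`–`P3`, each pooling adjacent time points).  All
gene-symbol handling is case-insensitive; original casing is preserved for
display only.

## Network screening (knowledge-based route)

A reference collection of known regulatory networks is scored per cell.
Each network is a DAG of TF→target edges; its fit to the data is the
log-likelihood of the linear Gaussian network without intercepts,

    l(G) = Σ_i −(m/2) · (1 + ln 2π σ_i²),

where node *i* is regressed on its graph parents by no-intercept ordinary
least squares over the cell's m samples and σ_i² is the ML residual
variance (denominator m; a parentless node's fit is the zero function, so
σ² is its mean square).  Because the model has no intercept, every gene is
standardised to zero mean and unit variance (denominator m) within the
scored cell first; without centring, a mean-shifted root gene would make
the no-intercept likelihood meaningless.  Whether standardisation should
be global or per cell is a genuinely open choice; per cell is used because
each cell is scored independently.

The likelihood grows with graph size, so it is calibrated into the **graph
consistency probability (GCP)**: N_r random DAGs with the same node and
edge counts are scored on the same data and GCP is the fraction scoring
*strictly* higher (ties do not count).  GCP is an empirical p-value: under
a null of no structure it is uniform on [0,1] (verified by a
Kolmogorov–Smirnov calibration test), and a network is "active" in a cell
when GCP < α.  Defaults: N_r = 2000, α = 0.05.  The random-DAG sampler
draws a uniform topological order and then a uniform set of
order-respecting edges — the simplest distribution satisfying the
node/edge-count constraint, documented so results are reproducible.

Numerical edge cases: a node with σ² ≈ 0 (an exact fit, e.g. a duplicated
gene) would contribute +∞ and bias GCP to zero; instead such nodes are
excluded from both the observed and every random total, so both sides sum
over the same node set.  Underdetermined regressions (parents ≥ samples)
are solved by pseudoinverse and flagged.  Network nodes absent from the
matrix are dropped with their incident edges; a network reduced below two
nodes is skipped.  Null-draw scoring reuses the cell's gene–gene covariance
(σ² = S_ii − S_iP S_PP⁻¹ S_Pi), which is algebraically identical to the
per-node OLS route and is verified against an independently coded
term-by-term log-density oracle at 1e−9 relative tolerance.

Seeds: one master seed; the RNG for network j in cell i is
`SeedSequence(master, spawn_key=(i, j))`, so serial and parallel execution
agree bit-exactly.

## Modified path-consistency inference (data-driven route)

Per cell, an undirected association skeleton is inferred from the complete
graph by partial-correlation tests of increasing order ℓ.  Edges are
visited in lexicographic pair order; conditioning subsets of size ℓ are
drawn in lexicographic order from the adjacency of each endpoint in turn,
and the adjacency structure is updated immediately after each removal
(classic PC scheduling, no order permutation).  Partial correlations are
computed by inversion of the sub-correlation matrix; conditional
independence is judged by the Fisher z test, p = 2(1 − Φ(√(n−ℓ−3)·|z|)),
at a configurable α (default 0.05 — the underlying study leaves this
unstated).  The algorithm stops naturally when no edge has ℓ eligible
neighbours; `max_order` optionally caps ℓ for large gene sets.

**The modification.**  Expression profiles are often near-duplicated, and
the induced multicollinearity makes some partial correlations numerically
unevaluable (singular or ill-conditioned submatrix, condition number above
`cond_limit` = 1e10, or |r| ≥ 1 − 1e−12).  Classic PC would abort; here
the pair is instead declared *dependent*: the edge is kept without a test,
flagged `kept-multicollinear`, and no further subsets are tried for that
edge at that order.  The edge is re-eligible at higher orders — the most
conservative reading that still guarantees natural termination.  A full
audit log records every removal (pair, order, separating set, statistic,
p) and every skipped test.

An oracle-covariance mode accepts a population correlation matrix and
treats |r| < `zero_tol` (1e−8) as zero; on any faithful linear-Gaussian
DAG this provably recovers the d-separation skeleton, which the tests
verify by brute-force enumeration.  Constant genes are dropped at ingest
(no correlation is defined); a cell with a single sample returns the
complete graph with every test skipped and a warning.

Only the skeleton is built — no collider orientation.  Edge semantics for
selection: a skeleton edge with exactly one endpoint in the TF list is
read as TF→gene; a TF–TF edge yields both orientations (configurable).

## Signatures and the two selection criteria

The **expression signature** of a period is the set of genes whose
case-vs-control difference over the period's pooled samples passes a
Benjamini–Hochberg FDR threshold (default 0.05) on Welch two-sample
t-tests (robust default for unequal variances; Student t would also be
defensible).  Signatures use raw values; standardisation is internal to
screening.  TF→gene pairs from both routes are kept only when the gene is
in the cell's period signature.  TF expression change is deliberately not
required — MR activity need not show up as the TF's own differential
expression.

**Specificity**: a TF qualifies when it emerges (≥ 1 extracted pair) in at
least one case cell and in no control cell.  "At least one case period" is
the union reading; the per-period TF lists in published analyses are
non-overlapping, so the intersection reading would be empty.

**Coverage**: per cell, the number of signature genes each TF regulates is
tabulated, and outlyingly well-covered TFs are found by an iterated
one-sided Smirnov–Grubbs maximum test at α = 0.05: G = (max − mean)/sd
(sample sd), critical value ((N−1)/√N)·√(t²/(N−2+t²)) with t the upper
α/N Student quantile at N−2 df; an outlying maximum is selected, removed,
and the test repeated while ≥ 3 values remain.  Ties at the maximum are
selected together (the statistic depends only on the values, which keeps
the selection order-invariant).  Cells with fewer than 3 covered TFs
select nothing.  The criterion's candidate set is the union of case-cell
selections minus the union of control-cell selections — the only rule
consistent with published counts where most screening-route coverage TFs
appear in both strains.

**Merge**: the final candidates are the union of the four pairwise
intersections of {screening, inference} × {specificity, coverage} —
equivalently, TFs passing at least one criterion under both routes — with
a 2×2 overlap matrix reported, plus all case-cell pairs of the final TFs.
Pairs are counted as pairs; the unique-gene count is reported separately
because one gene may be regulated by two final TFs.

**Hierarchy**: the final TF→gene pairs form a directed network layered by
breadth-first level from the zero-in-degree roots (or, in cyclic graphs,
all nodes of minimal in-degree).  Levels are banded into top/middle/bottom
thirds by level rank; master regulators are expected in the top band.

## The synthetic benchmark

The generator plants a linear Gaussian SEM because both the likelihood
score and partial-correlation testing are exactly correct under it:
recovery failures are then attributable to the pipeline, not to model
mismatch.  The demo scenario: 25 TFs, of which 5 are planted MRs assigned
round-robin to the periods; each MR regulates a 10-gene regulon whose
edges (coefficient 1.0) are active only in case cells of its period, and
whose targets are mean-shifted there by 2.5 noise-SD; 20 background
regulon sets of 4 genes are active in both strains in every cell, with
half of each set's genes mean-shifted in case cells of all periods
(staggered so every background TF gets ~half differential targets); 10
genes are unregulated noise; 50 samples per cell.  Root TFs are standard
normal, samples i.i.d.

The sample size was chosen by a design-time power analysis: conditioning a
TF–target edge on ℓ co-targets of the same hub shrinks the population
partial correlation toward b/√(1+(ℓ+1)b²) (≈ 0.45 at ℓ = 3, b = 1), so
Fisher z tests at n = 20 prune true hub edges aggressively; n = 50 retains
them reliably.  For the same reason the demo pipeline configuration caps
the PC order at 2 — in regulon-structured data, orders 0–2 already remove
chance correlations and common-cause shortcuts, while deeper orders mainly
re-test true hub edges against ever-larger co-target subsets and erode
power.  The library defaults are unconstrained order and N_r = 2000; the
demo configuration uses N_r = 200, which resolves GCP to 0.005, ample for
an α = 0.05 cut at the demo's network sizes.

The recovery harness draws 10 independent scenario seeds, runs the full
pipeline, and pools true/false positives: recall = pooled TP / planted,
precision = pooled TP / reported.  Residual misses are dominated by a
structural property of the procedure, not a bug: an MR's regulon network
has a ~5% chance per control cell of a spurious GCP hit (GCP is a
p-value), which places the MR in a control cell and defeats specificity;
the coverage criterion usually, but not always, rescues it.

What the benchmark does **not** emulate: probe-level noise, normalisation
artefacts, correlated samples, non-Gaussian expression, overlapping
regulons, or realistic network densities.  Passing it shows the pipeline's
logic and numerics are sound under its own assumptions, not that the
procedure has any particular power on real microarray data.

## Bundled case-study tables

The published selection tables of the GK/WKY diabetic-rat analysis (both
specificity TF lists, both per-cell coverage tables, and the final
candidate regulons) ship as plain TSV data.  They exercise the
criterion/merge logic deterministically: the overlap matrix, the final
five-TF set and the 54 regulated-gene pairs are recomputed from these
inputs, not stored as expected outputs.  The upstream expression data and
the licence-encumbered reference-network collection are not
redistributable, so the headline cardinalities that depend on them (active
network counts, signature sizes) are out of scope.

## Known limitations

* PC output depends on the calculation order of pairs; the fixed
  lexicographic schedule makes runs reproducible but is one member of the
  equivalence class of valid schedules.  An order-permutation sensitivity
  analysis is possible but not the default.
* GCP makes no multiple-testing correction across networks (by design:
  the per-network threshold is the published procedure).
* Grubbs-based coverage selection assumes approximately normal count
  spreads; with < 3 covered TFs per cell it abstains.
* The hierarchy's root convention for cyclic graphs (minimal in-degree)
  is one reasonable choice among several.
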