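# Methods

This note documents the models, estimators, numerical choices and
limitations of `pou-trajectory`, in the order the pipeline runs them.

## Substitution model

Amino-acid evolution is a reversible CTMC over the 20 states. Given
symmetric exchangeabilities S and equilibrium frequencies π, the
generator is Q_ij = S_ij π_j (i ≠ j), diagonal set so rows sum to zero,
rescaled so −Σ_i π_i Q_ii = 1: one unit of branch length is one expected
substitution per site at stationarity. The LG tables (Le & Gascuel
2008) ship as a PAML-style text file (`data/lg.dat`); a Poisson model
is available for tests, custom models load from the same .dat layout,
and a "+F" variant (observed frequencies) can be requested explicitly.

Rate heterogeneity across sites uses the discrete-gamma scheme: k
equal-probability categories of Γ(α, 1/α), each represented by its
conditional **mean** (not median), renormalized to average exactly 1.
Defaults: k = 4, α estimated from the data (see below). Category means
are computed from regularized incomplete-gamma differences, which the
tests check against adaptive quadrature.

Transition matrices P(t) = exp(Qt) come from the symmetric
eigendecomposition of diag(π)^{1/2} Q diag(π)^{−1/2} — numerically
stable for reversible generators and cheap to re-evaluate at many t.
Tiny negative entries from round-off are clipped and rows renormalized.

## Likelihood and ancestral reconstruction

Column likelihoods follow Felsenstein pruning with per-column scaling
(log-scale accumulators per node), mixing rate categories with equal
weights: L(col) = (1/k) Σ_c Σ_x π_x L_root^c(x). Gaps and 'X' are
missing data — the leaf partial is all ones. Gap-only columns are
flagged and carried through.

Marginal ancestral posteriors at node v combine the inside partial
(data below v) with an outside message (data above v, including π),
per category, with category-specific scale factors; the per-node MAP
peptide takes the argmax, ties broken toward the alphabetically first
single-letter code and logged (ties can change downstream substitution
calls). Each node also carries a per-column `map_defined` flag — true
when at least one leaf below the node has an observed residue — and
substitution calling skips undefined columns.

Branch lengths are optimized coordinate-wise: for each edge the outside
message is cached, so a bounded Brent search (bounds [1e−8, 20],
xatol 1e−6) costs one 20×20 transition matrix and one matrix product
per candidate length. Sweeps repeat until the total log-likelihood
improves by less than 1e−6 (max 50 sweeps, warning + best-so-far
otherwise). α is profiled by a bounded 1-D search on [0.05, 50]
(hitting the upper bracket is logged: it means rate-homogeneous data).
Branch sweeps and α alternate for two rounds, then one final sweep
series re-optimizes lengths under the final α.

**Identifiability.** With a reversible model and the stationary prior at
the root, the likelihood depends on the two root-child branch lengths
only through their sum. Recovery experiments therefore assess that sum
as a single parameter. Relatedly, the per-branch ML error at realistic
alignment sizes is irreducibly noisy: on the fixed 8-leaf recovery tree
with 3,000 columns the per-branch sampling CV is ~8–12%, so recovery is
summarized by the per-seed *mean* relative error over identifiable
branches (observed 4–9%, versus a 15% bound), not by the worst branch.

## Reconciliation and rooting

LCA reconciliation: each gene node maps to the species-tree LCA of the
species below it; a node is a duplication iff it maps to the same
species node as one of its children. Losses per gene edge (u, v):
depth(M_v) − depth(M_u), minus 1 when u is a speciation. Losses above
the gene-tree root are not counted. Gene trees must be binary;
polytomies are rejected.

Rooting by duplication–loss evaluates every edge of the unrooted tree
as a candidate root and keeps the minimum of unweighted D + L (ties:
fewer duplications, then first edge in deterministic preorder, logged).
A user-supplied rooted topology can be passed through unchanged
(`rooting: keep`), with reconciliation used only for annotation — the
workflow for manually corrected topologies. Midpoint rooting places the
root halfway along the longest leaf-to-leaf path; the tests verify both
against exhaustive search.

## Trajectory calling

Substitutions are MAP-versus-MAP comparisons between parent and child
peptides — matching the most-likely-peptide-per-node convention — on
the union of branches from the root to each family ancestor, each
branch counted once in tree-wide totals (per-path sums are also
reported, since shared backbone branches are counted by both
conventions). Consequences of the MAP convention: multiple hits at one
column on one branch are invisible, and low-confidence states
(MAP posterior < 0.5 at either endpoint, configurable) are flagged but
still counted, since no posterior filter is applied by default.

Region annotation (domain intervals, helix intervals, DNA-contact
columns, the final dipeptide of the homeodomain) is user-supplied input,
1-based inclusive; the shipped POU fixture encodes the four text-named
contact positions (60, 64, 91, 134), plausible helix spans, and the
136–137 dipeptide default. The final-dipeptide motif flag uses
aliphatic = {A,G,I,L,P,V} followed by charged = {K,R,H,D,E}.
Per-column conservation is log2(20) minus the Shannon entropy of
gap-excluded residue frequencies (bits), the quantity a sequence logo
draws as column height.

## Functional-divergence tests

Both estimators are model-free moment estimators in the spirit of Gu's
site-rate correlation framework; Θ is clamped to [0, 1] (clamping is
logged), Z = Θ/SE, p is the two-tailed normal tail, and pairwise tables
carry both raw and Holm-adjusted p.

**Type I** (site-rate profile shift). Each cluster's profile is the
per-column count of MAP changes over the cluster's branches, divided by
total cluster branch length (≥3 leaves required). The raw between-
cluster correlation r_AB is attenuated by sampling noise, so it is
rescaled by the geometric mean of split-half reliabilities (branches
interleaved by length rank, Spearman–Brown corrected):
Θ = 1 − r_AB / sqrt(rel_A · rel_B). SE comes from the Fisher-style
large-sample form (1 − r²)/√(n−3), inflated by the reliability factor.
With structureless profiles (zero reliability) the estimator is
undefined; this is inherent — there is no rate signal to compare.

**Type II** (radical excess between family ancestors). Among columns
where the two family-ancestor MAP peptides differ, let F be the radical
fraction. Its null expectation is **not** the single-step radical
fraction: over a path of length t, multiple hits mix the endpoint pair
toward the stationary cross-class fraction (≈0.58 under LG, versus
≈0.45 for single steps), so using a single-step baseline inflates Θ for
fast-evolving pairs (measured 20% false-positive rate under a matched
null). The baseline used is therefore model-implied at the observed
divergence: p0 = P(classes differ | states differ) for a stationary
pair at the ML pairwise distance between the two ancestor peptides
(gamma-mixed). Θ = (F − p0)/(1 − p0); SE by the binomial delta method
on F with a continuity-corrected variance. Measured operating
characteristics under the canonical scenario (below): power 84% at
ρ = 5, false-positive rate 6% at ρ = 1 (50 seeds each). A
consensus-of-tips variant (`tip_based=True`) is kept for sensitivity
analysis.

## Simulators and what they do (not) emulate

Sequences evolve by exact CTMC simulation — exponential waiting times
per column per branch — so the truth log records every realized change,
including the multiple hits that MAP-versus-MAP calling undercounts.
One gamma category is drawn per column for the whole tree, matching the
inference model's site-rate assumption. The root is drawn from π.

Neofunctionalization shifts multiply a branch's cross-class rates by
ρ ≥ 1 and renormalize each row so the total substitution rate is
unchanged: composition shifts toward radical changes without altering
the expected number of changes; an optional rate multiplier m ≥ 1
models release of purifying selection separately. The canonical
scenario (`neofunctionalization_scenario`) fixes the study conditions
used across tests: two five-leaf paralog clades, conserved stem 0.1
substitutions/site, shifted stem 0.5 carrying m = 1.5 and the bias ρ,
200 columns, LG+Γ(0.8, k=4) — the conserved-copy/diverged-copy
asymmetry of the neofunctionalization model.

Gene families arise by birth–death along a binary species tree (one
gene entering above the root; stem length 1.0). The truth record
reports *observable* duplication and loss counts: the event log
projected onto the pruned gene tree the way a most-parsimonious
reconciliation sees it (a duplication counts if both daughters have
surviving descendants and their ranges overlap in the species tree; one
loss per species branch the surviving tree skips). Raw event counts are
reported alongside. This projection is computed set-based,
independently of the reconciliation module, and serves as its
cross-check.

What the simulators do **not** emulate: insertions/deletions (gaps are
only introduced by masking in tests), codon-level selection,
among-branch model heterogeneity beyond the shift branches, and
alignment error. Passing tests on simulated data therefore validate the
inference machinery under the model's own assumptions, not robustness
to misalignment or indel-rich histories.

## Problem sizes and determinism

Test and acceptance experiments run at desk scale: enumeration-oracle
checks on trees with ≤5 leaves and ≤6 columns (200 random cases),
recovery on a fixed 8-leaf tree with 3,000 columns and 10 seeds,
divergence operating characteristics over 50 seeds of the canonical
scenario, reconciliation over 100 simulated families. All randomness
flows through explicit integer seeds (`rng_for(seed, stream)` derives
per-stream generators); inference itself is deterministic given inputs.

## Reproducing the published POU counts

The tree-wide trajectory totals of the original POU analysis (173
changes; 117 in helices; 95 radical; 87 POU_HD / 86 POU_S with 66 and
51 in helices) can be recomputed by placing the study's supplementary
alignment and reconciled tree (plus a family-membership table) under
`data/external/` and running the acceptance suite; the shipped
annotation fixture provides the structural regions. Exact equality is
not guaranteed: the upstream reconstruction service's gap handling and
fitted α are not published, and helix boundaries are figure-derived, so
the comparison is tolerance-based (±10% per count, ±5 percentage points
on the radical fraction).

## Known limitations

- Marginal (not joint) reconstruction; no Bayesian reconstruction.
- MAP-based substitution calling undercounts multiple hits (documented
  above); expected-count calling is not implemented.
- The type-I estimator needs ≥3 leaves per cluster and non-degenerate
  profiles; the type-II SE is binomial and ignores reconstruction
  uncertainty in the ancestor peptides (the low-confidence flags exist
  to audit this).
- Duplication-loss rooting optimizes unweighted D + L by default;
  weighted mixtures are available via `dup_weight`/`loss_weight` but are
  untuned.
- Polytomies are rejected rather than resolved.
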