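# Methods

## Process model

A gene family evolves inside a rooted, binary, ultrametric species tree
*S* whose branch lengths are absolute time; time is 0 at the extant
leaves and increases rootward. A pre-root *stem* edge (default duration
10 % of the tree height, configurable) provides the origination point:
the process starts with a single lineage at the stem tip. On a species
edge a gene lineage experiences duplication (δ), loss (μ) and lateral
transfer (τ), all per lineage per time unit. A duplication keeps both
daughter lineages on the edge. A transfer keeps one daughter on the donor
edge and places the other on a recipient edge drawn **uniformly over the
other species edges alive at that instant**; when the donor is the only
live edge (the stem), the effective transfer rate is zero. A loss ends
the lineage, and pruning the extinct subtree suppresses the resulting
out-degree-1 vertex. Lineages split deterministically at speciation
vertices and become extant gene copies at species leaves.

Edge substitution rates are i.i.d. Gamma with mean *m* and coefficient of
variation *cv* (shape 1/cv², scale m·cv²). An observed gene-tree edge of
duration *t* and substitution length *l* therefore contributes the
density GammaPDF(l/t; 1/cv², m·cv²)/t. Sequences evolve by JC69 by
default (GTR via eigendecomposition of the reversible rate matrix;
rate matrices normalised to one expected substitution per unit length;
no among-site rate variation — the relaxed clock acts on edges, not
sites).

## Discretization

Probabilities are computed on a time-sliced grid *S″*. Step 1 inserts an
out-degree-1 vertex on every edge at every species-vertex time it spans,
cutting the tree into slices bounded by speciation times (plus the stem
slice). Step 2 subdivides each slice into `resolution` equal parts and
places grid points at the `resolution − 1` interior boundary times,
**the same times on all edges crossing the slice**. Each interior point
carries a quadrature weight Δ = slice width / (resolution − 1), so the
per-edge weights sum exactly to the edge duration; species vertices and
slice-boundary points carry Δ = 0 and never host duplication or transfer
events — an event is never placed exactly at a speciation time. With
`resolution = 1` no interior event points exist (a degenerate but legal
grid); the default is 10, and the bundled studies use 3 for speed. The
quadrature error vanishes as the resolution grows; a refinement test
(5 → 10 → 20 → 40) verifies first-order convergence of the density.

## Extinction, propagation and the gene-tree density

Within a slice with *k* live edges the extinction probabilities satisfy

    dE_e/dt = μ − (δ+μ+τ) E_e + δ E_e² + τ/(k−1) Σ_{f≠e} E_f E_e

(τ terms dropped for k = 1), with E = 0 at leaves and the product of the
child-edge values at speciation vertices. The single-lineage propagation
probability p11 — exactly one surviving descendant on the same species
path, every side lineage extinct — decays at rate
(δ+μ+τ) − 2δE_e − τ/(k−1)·Σ_{f≠e}E_f: a duplication whose extra copy
dies, or a transfer whose emigrant dies, is invisible. p11 composes
multiplicatively along edges and picks up the sibling edge's extinction
probability when passing down through a speciation. Both quantities are
integrated per slice with a fixed-step RK4 scheme whose substep count is
derived from the requested tolerance (default 1e-6); the deterministic
fixed-step form was chosen over an adaptive integrator because it is
branch-free, trivially reproducible and fast inside the MCMC loop, and it
is validated against the linear birth–death closed form to better than
1e-4 and against Monte-Carlo extinction frequencies of the independent
forward simulator to 3 standard errors at 10⁵ replicates.

The density p(G, l | θ, S) is a postorder dynamic programme over
(gene vertex, grid point): speciation terms pair the children across the
two child edges in both orders; duplications contribute 2δ (unordered
children); transfers contribute τ/(k−1) symmetrised over which child
emigrates and summed over recipients; each gene edge contributes p11
times the relaxed-clock length density for the implied duration, each
interior event point its weight Δ, and the root is summed over placements
reachable from the stem tip. A parent and child are never mapped to the
same time. Per-vertex max-normalisation keeps the DP in floating range;
the retained (scaled) tables drive exact conditional realization sampling
in preorder, and a max-product variant with backtrace gives the MAP
realization. An exhaustive enumerator over all valid realizations —
guarded to ≤ 9 gene vertices and small grids — reproduces the density as
a score sum and serves as the oracle for both the density and the
samplers.

One approximation is inherited from the realization formalism: between
gene vertices a lineage stays on one species path, so histories in which
a transfer's resident copy dies and the emigrant survives (a "silent"
edge jump with no surviving branching) are not representable. The
forward simulator does generate such histories; at the transfer rates
used here they are rare, and the calibration study bounds their effect.

## MCMC

The chain targets P(D|G,l)·p(G,l|θ,S)·p(θ); the normalising constant
P(D|S) is never evaluated. Priors are uniform and independent with
bounded supports (δ, μ, τ ∈ [0,10]; m ∈ (0,10]; cv ∈ (0,5]). The move
mixture is 30 % topology (rooted NNI, plus SPR for 30 % of topology
moves, with the exact length-split Hastings factor), 40 % single-edge
multiplicative log-normal length updates, 30 % single-parameter
multiplicative log-normal updates (Hastings factor x′/x); all weights and
scales are configuration options. Tables are re-used across moves: rate
moves re-solve the ODEs, clock moves re-build only the length densities,
length moves update one density row, topology moves re-run only the two
dynamic programmes. The initial gene tree is UPGMA on JC-corrected
distances — chosen over neighbour joining because it directly yields the
rooted binary start the chain needs, with lengths from the distance fit;
θ starts at the configured value (bounds midpoints by default). Site
patterns are compressed once per family.

Traces are thinned (TSV output: iteration, θ, the two log densities,
canonical topology, full newick). The MAP gene tree is the most frequent
post-burn-in topology, ties broken by higher mean joint log density.
Burn-in is chosen by the max-ESS rule; diagnostics report per-scalar
Geweke z (first 10 % vs last 50 %, Bartlett-window spectral variances),
ESS, and split-R̂ across chains (zero-variance degenerate case defined
as 1). Realizations are sampled post hoc, by default one draw per
post-burn-in trace entry whose topology equals the MAP topology (a
`draws_per_sample` knob and an all-topologies variant exist; the latter
feeds the "sampled trees" highway tally).

## Distances and evaluation

The topological distance between two realizations pairs their transfer
vertices by minimum-total gene-tree path length (Hungarian matching);
the temporal distance reuses that matching and measures the gap between
the event time intervals (zero when they overlap), so refining the grid
can only decrease it. When transfer counts differ, each unmatched
transfer contributes the gene-tree diameter (topological) or the species
root height (temporal) — a convention of this package, flagged in the
output metadata, since the distances are otherwise undefined for unequal
counts. Posterior expectations weight draws uniformly.

Evaluation against simulated truth mirrors the usual study design:
families whose MAP topology differs from the truth are flagged and
skipped; for the rest we report the posterior fraction with the correct
transfer count, the posterior probability of the true transfer vertex
(matched by leaf clade), recovery of the true From / To / (From, To)
species edges at posterior ≥ 0.5 (inclusive threshold), and the four
expected distances. Highway summaries count, per ordered species-edge
pair, the families whose per-pair posterior probability reaches the
threshold, separately for MAP-topology and all-topology realization
sets.

## The simulator and what passing tests show

The simulator is grid-free: exponential waiting times in continuous time
with the piecewise-constant contemporaneous-edge count, exact event
times, and recorded donor/recipient edges per transfer. It shares no
numerical machinery with the ODE/DP side, which is what makes the
extinction cross-validation meaningful. `require_transfer` resamples
until a transfer survives; this conditions the process and is recorded
through the attempt count.

Study conditions in the bundled tests and acceptance script (chosen as
typical for small prokaryotic gene families and fixed before running):
species trees of height 1 with 5–6 leaves and stem 0.1; rates
δ = μ = 0.2–0.3, τ = 0.3–0.6 per time unit; m = 1 substitution/site/time,
cv = 0.5; 200–400 sites; grid resolution 3; chains of 2·10⁴–10⁵
iterations thinned by 50–100. Synthetic data reproduce the generative
model exactly, so passing tests demonstrate internal correctness and
calibration of the inference — not robustness to model violations real
data carry (alignment error, rate heterogeneity across sites, incomplete
lineage sorting, unsampled donors outside the species tree).

## Known limitations

* Transfer donors must be lineages of the given species tree; extinct or
  unsampled donors are outside the model.
* The gridded likelihood ignores silent transfer jumps along gene edges
  (see above).
* Gene edge lengths of exactly zero have zero density for cv ≤ 1;
  alignments should carry some signal on every branch.
* μ is weakly identified from single small families (loss events leave
  no sequence signal); the calibration criteria therefore target δ and τ.
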