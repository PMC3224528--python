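# Methods

`regraft` answers a specific comparative-genomics question: given a
single-gene protein alignment and a tree in which a query clade (for
example, the euglenophyte copies of a Calvin-cycle enzyme) occupies some
position, how strongly does the data constrain that position?  The
package implements the full inference chain — substitution model,
site-wise likelihoods, exhaustive clade re-grafting, multiscale-bootstrap
topology tests, bootstrap support, and indel-synapomorphy scanning —
together with a simulator that generates data with exactly the structure
the chain assumes.

## Substitution model

Sequences evolve under a reversible continuous-time Markov chain on the
20 amino acids.  The generator is built from the published WAG
exchangeability matrix *S* (bundled as data) and stationary frequencies
*π*: `Q_ij = S_ij π_j` for `i ≠ j`, diagonal set so rows sum to zero, and
the whole matrix scaled so the expected rate `−Σ π_i Q_ii` is one — branch
lengths are therefore in expected substitutions per site.  With `+F` the
frequencies are replaced by the observed residue proportions of the data,
with an add-one pseudocount so every frequency stays strictly positive
(the symmetric eigendecomposition used for `exp(Qt)` requires `π > 0`).

Among-site rate variation is the standard `+I+Γ` mixture: a proportion
`p_inv ∈ [0, 1)` of sites with rate 0 and `n_cat` (default 4) equal-weight
discrete-gamma classes with shape `α`.  Class rates are the conditional
means of the Gamma(α, α) distribution within inter-quantile slices (the
mean-of-slice convention, the dominant one among ML programs), computed
through the incomplete-gamma identity rather than quadrature, and
rescaled by `1/(1 − p_inv)` so the mixture mean rate is exactly one.

Transition probabilities come from one symmetric eigendecomposition in
the `π^{1/2}` inner product; `P(t·r)` for every branch and rate class
reuses the same factors.  Entries are clipped to `[0, 1]` after
exponentiation.

## Likelihood engine

Site likelihoods use Felsenstein pruning with partials of shape
`(n_class, 20, n_sites)`.  The invariant class is simply the rate-0 class
run through the same code path: its transition matrix is the identity, so
a column contributes through it exactly when its non-missing states
agree.  This reproduces the usual "+I" bookkeeping with the convention
that gaps do not break constancy.  Gaps and `X` are missing data (partial
of ones).  Underflow is controlled by per-node renormalisation with
accumulated per-site log scalers, not by log-space arithmetic.

Trees are stored with a trifurcating root purely as a data-structure
convention; reversibility makes the likelihood independent of where that
trifurcation sits, which is asserted in tests (the pulley principle).
Zero-length input branches are floored at `1e-8` before likelihood work
to keep transition matrices non-singular.

Besides the upward (subtree) partials the engine maintains *outside*
partials — for the edge above node `v`, the probability of all data
outside `v`'s subtree conditional on the state at `v`'s parent.  With
both directions cached, the likelihood as a function of a single branch
length is cheap, which is what branch-length optimization and placement
evaluation exploit.

Branch lengths are optimized by bounded scalar search (`[1e-8, 10]`),
round-robin over edges: each round does one postorder pass, then a
preorder sweep that refreshes outside partials along the way so each
1-D problem is solved against the current lengths above it.  Sibling
subtree partials can be one update stale within a round, so the exact
total log-likelihood is re-checked at the end of every round and a
non-improving round is rolled back — the reported lnL never decreases.
Model parameters (`α` on a log scale in `[0.02, 100]`, `p_inv` in
`[0, 0.99]`) are fitted by the same bounded scalar search, alternated
with branch rounds; ties keep the incumbent value.  Default tolerances
(1e-4 on lnL for branches, 1e-3 joint) are package decisions, exposed in
the configuration.

## Tree search and bootstrap

The search is deliberately modest: pairwise maximum-likelihood distances
(two-taxon likelihood on the 20×20 pair-count matrix, symmetrised so the
estimate is exactly symmetric; pairs with no shared sites get a cap,
default 5.0), neighbor joining (scikit-bio, negative estimates floored at
0), then nearest-neighbor-interchange hill climbing: all NNI neighbours
scored with inherited lengths, best improving move accepted, branch
lengths re-optimized after each acceptance, ties broken toward the
smallest (edge, variant) index.  This is weaker than SPR-based searches
but predictable and fast at the package's target scale (tens of taxa).

Bootstrap support resamples alignment columns with replacement and
re-runs the same search per replicate; support of an edge is the
percentage of replicate trees containing its bipartition.  Replicate `r`
draws its RNG from the substream `(master_seed, r)`, so replicates are
order-independent.

## Clade placement

`prune_clade` removes a (necessarily monophyletic) query clade, sums the
two branch lengths flanking the attachment point into one backbone edge,
and reports that edge as the "original" placement.  Backbone edges are
identified by their canonical split — the side of the bipartition not
containing the alphabetically first backbone taxon — which is stable
across rootings and is the identifier used in all reports.

`enumerate_placements` builds one candidate tree per backbone edge
(`2m − 3` of them for `m` backbone leaves): the edge is bisected, each
half keeping half its length, and the intact clade subtree is attached by
a new pendant branch (default 0.1).  The clade's internal structure is
never re-rooted, matching the design in which only the query branch
moves while the rest of the topology stays fixed.

Candidates are evaluated in one of two modes.  `all_branches` re-optimizes
every branch length per candidate — the conservative default for final
analyses.  `graft_only` holds backbone lengths fixed and optimizes only
the pendant branch; because the backbone's directional partials are
computed once, each candidate costs a handful of 20×20 matrix products
per site, and the whole enumeration runs in seconds at 56 taxa.  The two
modes agree to machine precision when the pendant length is pinned,
which is tested.

## Topology tests

All tests operate on the site log-likelihood matrix (topologies × sites)
by resampling estimated log-likelihoods (RELL) — no refitting inside the
bootstrap.

* **BP**: fraction of replicates in which a topology attains the maximum
  resampled lnL; argmax ties go to the lowest row index (deterministic;
  tie rates are nonzero on short matrices).
* **KH**: the per-site lnL difference between two topologies is centred
  at its mean and resampled; one-sided p with mid-p tie handling, so two
  identical site vectors give exactly 0.5.  The report tests each
  candidate against the ML topology.
* **SH**: replicate sums centred per topology at their own mean; each
  topology's lnL deficit is compared with the distribution of
  max-over-topologies centred deviations.  SH ≥ KH conservativeness is
  verified empirically.
* **AU**: multiscale bootstrap at scales `r ∈ {0.5, 0.6, …, 1.4}`
  (resample size `round(r·n)`), default `B = 10,000` replicates per
  scale.  `BP(r)` is transformed to `z(r) = Φ⁻¹(1 − BP(r))` and fitted by
  weighted least squares to `z(r) = d√r + c/√r` with weights
  `B φ(z)² / (BP(1 − BP))`; the p-value is `1 − Φ(d − c)`.  BP values are
  clamped to `[1/(2B), 1 − 1/(2B)]` as a continuity correction; a curve
  entirely on one boundary gets the boundary p-value (0 or 1), and a
  topology with fewer than two off-boundary scales is flagged
  untestable.  An exhaustive mode enumerates every resample with its
  multinomial weight (for small matrices), used as the exactness oracle.

The 5% level is a reporting convention: the report carries a
`rejected` flag at `α = 0.05` but all p-values are emitted.

## Simulator

`simulate_alignment` draws a rate class per site (invariant with
probability `p_inv`), a root state from `π`, and walks the tree with
`P(length · rate)`.  `simulate_hgt_dataset` builds the full fixture: a
backbone of named monophyletic groups joined by a random skeleton, the
query clade grafted at a random internal edge of the donor group, and
planted deletions (an interval overwritten with gaps) shared by the
query clade plus the donor group, and privately by one other group.

Default dimensions mirror a realistic single-gene matrix: 56 taxa (14
outgroup; 12 + 7 + 3 + 3 + 5 + 4 + 5 across seven ingroup groups; a
3-taxon query clade), 327 columns, `α = 0.8`, `p_inv = 0.1`, internal
branches around 0.1 and terminals around 0.15 expected
substitutions/site.  What the generator does *not* emulate: indels are
overwritten post hoc rather than evolved under an indel process (enough
to exercise the scanner, not a model of indel evolution),
site-heterogeneous profile mixtures, alignment error, and compositional
heterogeneity across lineages.  Passing tests therefore demonstrate
algorithmic correctness and calibration under the assumed model, not
robustness to real-data violations of it.

## Indel scanner

Per-taxon maximal gap runs are clustered by boundary agreement within
`boundary_slack` columns (default 1) at both ends; clusters spanning at
least `min_len` columns (default 2) are classified per named taxon group
as fully present, fully absent, or mixed, and only blocks with at least
one present and one absent group are reported, with a per-group
conformity fraction.  Both thresholds are package decisions — published
indel figures of this kind are assembled by eye and state no tolerance.
Blocks are labelled "deletion-like" when the gap carriers are the
minority, "insertion-like" otherwise, and can be reported in the residue
numbering of a designated reference taxon (1-based, the convention of
published alignment figures).

## Verification sizes

The test-suite experiments use sizes chosen to exercise the statistics
meaningfully on a desk machine: the likelihood oracle on 100 random
4-taxon instances; enumeration completeness on 50 random trees up to 30
taxa against independent dendropy surgery; AU calibration on 200 null
fixtures (56 × 327, `graft_only`, generating model fixed, `B = 1000`);
transfer recovery on 20 fixtures; `α`/`p_inv` recovery at 56 × 5000 with
the tree fixed at truth; pairwise-distance recovery at t = 0.5 with
20,000 sites.  The acceptance script repeats the same computations with
100 calibration runs.

## Known limitations

* The NNI-only search can be trapped by local optima that SPR escapes;
  for publication-grade trees on real data a dedicated ML program is the
  right tool, with this package consuming its tree.
* `graft_only` evaluation conditions on backbone branch lengths; when the
  backbone lengths are themselves poorly estimated, `all_branches` is the
  safer (much slower) choice.
* The AU fit uses a fixed scale grid; curves that are degenerate on most
  scales (near-certain or near-impossible topologies) fall back to
  boundary p-values rather than extrapolation.
* Bootstrap and RELL p-values inherit Monte-Carlo noise of order
  `1/√B`; B is configurable everywhere.
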