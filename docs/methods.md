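# Methods

`microdelim` implements an integrative molecular species-delimitation
pipeline for DNA barcode data, together with the downstream evolutionary
analyses that typically follow it: diversification-rate model selection on
the delimited lineages and bioclimatic niche-overlap statistics.  This
note records the models, the conventions that were genuinely open choices,
the synthetic-data generators' assumptions, and known limitations.

## Genetic distances

Pairwise distances use the Kimura two-parameter (K2P) model with pairwise
deletion: for each pair, sites where either sequence carries a gap, `N` or
any non-ACGT IUPAC code are excluded, and with transition fraction `P` and
transversion fraction `Q` over the remaining `n` sites,

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)].

Pairs that saturate the logarithm are flagged with the sentinel `+inf` and
behave as "above any threshold" in clustering.  Pairwise (not complete)
deletion matches barcoding practice and keeps a per-pair effective site
count, which is reported so downstream code can flag pairs with few
comparable sites.  Haplotype collapsing uses exact string equality:
sequences differing only in missing data are deliberately *not* merged,
because merging through `N`s can chain otherwise distinct haplotypes.
The implementation agrees with `ape::dist.dna(model="K80",
pairwise.deletion=TRUE)` to 1e-8 (cross-checked in the test suite).

## Threshold clustering

Fixed-threshold delimitation (default cutoff 3.2% K2P) takes the connected
components of the graph with an edge wherever `d <= cutoff` — single
linkage, i.e. transitive closure.  The linkage is not dictated by the
method's common description; single linkage is the standard "cluster at
threshold" reading and the one under which barcode-gap datasets resolve
exactly.  Complete linkage is available behind a flag.

## Automatic barcode gap discovery

The ABGD-style procedure assumes intraspecific divergence stays below a
prior `P` and looks for a wide gap in the sorted pairwise distances
crossing that prior: the first ascent from `d[i]` to `d[i+1]` with
`d[i+1] > P` and `d[i+1] - d[i] > X d[i]` (X = minimum relative gap
width) is the barcode gap; the group is split by single linkage at the
gap midpoint and the procedure recurses into each subgroup.  This local
relative-width rule is a fully specified variant of the reference tool's
windowed slope heuristic; on data with a genuine gap the two behave
identically.  Prior scans use a geometric series of priors (the reference
tool's convention).  As with the reference method, priors placed *inside*
the intraspecific distance distribution oversplit, because sampling gaps
among intraspecific distances can satisfy the relative-width rule; a
scan's stability summary makes this visible.

## Statistical parsimony (TCS-style) connection limit

Haplotypes are connected while their mutational difference stays within
the largest step count `j_max` whose parsimonious (homoplasy-free)
connection probability reaches the confidence level (default 95%);
connected components are the delimited entities.  The probability model
assumes equal rates across sites, no recombination and a four-state
symmetric substitution process: for `j` observed differences over `L`
sites, per-site divergence is estimated by the multiple-hit correction
`mu = -(3/4) ln(1 - 4j/(3L))`, a differing site arose from exactly one
substitution with probability

    c = mu e^(-mu) / [(3/4)(1 - e^(-4 mu/3))],

and `P(j) = c^j`.  `P(j)` decreases in `j`; `j_max` is the largest `j`
with `P(j) >= confidence`.  For a 607 bp barcode at 95% this gives a
9-step limit, matching the familiar behaviour of TCS on barcode-length
data.  Only connectivity is computed — intermediate (unsampled) haplotypes
are never reconstructed, since delimitation depends on component
membership alone.  Alignment gaps are treated as missing, not as a fifth
state.

## GMYC

The generalized mixed Yule-coalescent model splits an ultrametric tree at
a threshold age `T`: branching older than `T` follows a generalized
diversification process, branching younger than `T` follows independent
within-species coalescents, one per branch crossing `T`.  Interval `i`
has total event rate

    R_i = lambda_d n_d,i^p_d + lambda_c sum_j n_j,i^p_c

and the log-likelihood sums each event's log-rate minus `sum_i R_i x_i`.

Conventions, each of which materially affects behaviour:

* **Event counts.** Diversification events use the forward-Yule count
  (lineages just before the split).  Coalescent events use the merging
  pair's count — the count on the *younger* side — so a group's basal
  node scores `n = 2`.  This makes the coalescent class identical to the
  backward Kingman factorization with rate function `lambda n^p`; with
  forward counts the basal event of every group would score `n = 1`,
  which systematically biases the fitted exponent downward and destroys
  cluster detection.
* **Single lineages.** A group is one lineage between the threshold and
  its basal node; one lineage cannot coalesce, so that segment carries
  zero rate.  A tip that never joins a multi-specimen group stays in the
  diversification class to the present (treating such pendants as
  zero-rate "populations of one" hands every candidate threshold free
  waiting time and inflates the test's false-positive rate on Yule trees
  to ~10-15%; with this convention it is ~3%).
* **Exponent ranges.** `p_d` is searched in [-2, 1] (per-lineage
  speciation at most linear in `n`, density-dependent slowdowns allowed)
  and `p_c` in [0, 2] (between uniform and the Kingman-like `n^2`
  scaling).  The canonical process sits at the upper boundary of each
  class.  Wider ranges are not merely unnecessary: with `p` free up to 3
  a *single* class can mimic the two-phase pattern of a clustered tree
  and the threshold model collapses to one entity on ~20% of clearly
  structured trees.
* **Threshold placement** is discrete, over observed branching times.
  The null model fits the whole tree as one class.  The multiple-threshold
  mode greedily gives the interior of one cluster its own, younger
  threshold per accepted step (the cluster's upper structure reverts to
  the diversification class), while the likelihood improves by more than
  1e-4.  Each threshold counts 3 degrees of freedom (threshold + its
  class's rate and exponent) in likelihood-ratio tests, which reproduces
  df = 6 for a two-extra-threshold comparison.

For a fixed classification both rates profile out in closed form
(`lambda = events / sum(x n^p)`), leaving two independent bounded 1-D
searches over the exponents (coarse grid, then Brent refinement), so the
full threshold sweep on a 50-tip tree takes well under 0.1 s.

Under the generative model (10 species x 5 tips, within-species depths 20x
below the species boundaries), the single-threshold fit recovers the exact
species partition and rejects the one-class null in 50/50 replicates,
while rejecting on 3% of pure Yule trees.  Rate recovery is consistent
when the exponents are pinned at their generative values; with free
exponents, `lambda` and `p` trade off on small trees and the marginal
error of `lambda` alone is larger — an identifiability property of the
generalized family, not an optimizer failure.

## Conservative consensus and cross-validation

The consensus of several method partitions is the partition-lattice join:
specimens share a consensus lineage whenever a chain of co-membership
edges from *any* input partition connects them.  The join is the only
order-independent formalization of "the most comprehensive grouping
predicted by any method", and deliberately risks lumping rather than
splitting.  Cross-validation against morphospecies names classifies each
name as `match` (one lineage, held alone), `split` (several lineages,
none shared), `lumped` (one lineage shared with other names) or `mixed`,
and counts molecularly distinct lineages hidden inside split names.
Incongruent cases are reported as flags, never edited.

## Diversification models

Five models are fitted to the branching times (node ages) of an
ultrametric tree, all under the same inter-event factorization (root
starts two lineages; the final interval carries only a waiting term; no
conditioning constant on survival or tip count, so log-likelihoods are
comparable only within this convention):

* `pureBirth`: constant rate, closed-form MLE `r1 = (N-2) / sum(n x)`.
* `bd`: Nee-style birth-death conditional likelihood in net rate
  `r1 = b - d` and extinction fraction `a = d/b`, sharing the pure-birth
  constant so `a = 0` reproduces `pureBirth` exactly (validated against
  the formula used by `ape::birthdeath` in the tests); optimized over
  `(log r, logit a)` with an `a = 0` boundary fallback.
* `DDL` (`lambda = r1 (1 - n/k)`, `k > N` enforced) and `DDX`
  (`lambda = r1 n^-xp`): rate profiles out, leaving a bounded 1-D search
  over `k` (log-offset parametrization) or `xp` in [-5, 5].
* `yule2rate`: `r1` above a shift age `st`, `r2` below; `st` is searched
  over branching times (ties resolved to the oldest), with closed-form
  rates per regime.  An eventless young regime is admissible — its rate
  MLE is the `lambda -> 0` supremum, with neither event terms nor waiting
  penalty — which is how a very recent, still eventless slowdown
  (the protracted-speciation signature) is expressed.

AIC = 2P - 2 lnL; model tables rank by AIC with ties broken by fewer
parameters.  Because the shift search and the density-dependent fits gain
likelihood on genuinely constant-rate trees by selection, raw AIC
comparisons over-favour rate-variable models (an RV model is strictly
best on roughly a third of pure-birth trees).  The rate-constancy test
therefore uses a parametric bootstrap: the statistic
`AIC(best rate-constant) - AIC(best rate-variable)` is recomputed on
pure-birth trees simulated at the fitted rate with the same tip count,
and the p-value is the add-one-smoothed exceedance fraction.  At the
default study conditions (N = 45, 100-200 bootstrap trees) the measured
size is 2-6% at alpha = 0.05 and power against a 10-fold recent rate
drop is ~87%.

`truncate_recent_history(tree, fraction)` slices the tree at
`fraction x depth` before the present; every lineage crossing the slice
becomes a tip (recent cherries merge), leaving an ultrametric tree of
depth `(1 - fraction) x depth`.  On recent-burst trees (two-rate, burst
confined to the youngest ~3% of history) the preferred model class flips
from rate-variable to rate-constant — pure birth back inside the
conventional dAIC <= 2 equivalence band — in ~79% of replicates after a
5% truncation.

LTT data are emitted as step points on the relative time axis (root = -1,
present = 0), starting at (-1, 2).

## Niche statistics

On habitat-suitability grids normalized to sum to one over valid cells:
Schoener's `D = 1 - 1/2 sum |p1 - p2|`, Warren's
`I = 1 - 1/2 sum (sqrt(p1) - sqrt(p2))^2`, and a relative-rank statistic
`RR` = the proportion of valid cell pairs whose suitability ordering
agrees between grids (a pair tied in both grids agrees trivially; tied in
exactly one counts 1/2).  `RR` is computed exactly up to 2000 valid cells
and by seeded uniform pair-sampling above (200k pairs by default, within
~0.01 of exact on tested grids).  The exact estimator of the reference
niche-comparison tool is unpublished, so `RR` is a documented dialect:
Kendall-style concordance scaled to [0, 1].  Niche breadth is Levins'
standardized measure `B = (1/sum p^2 - 1)/(n - 1)`.  All statistics are
invariant to positive rescaling of raw scores but not to monotone
transforms, so raw- versus logistic-scale inputs are not interchangeable.

## Synthetic data

The generators produce inputs with exactly the structure each stage
assumes; every output embeds its parameters and seed, and regeneration is
bit-identical.

* **Trees.** Pure-birth trees conditioned on the tip count draw
  inter-event intervals `Exp(n r)` plus one final waiting interval, so
  the youngest branching age is strictly positive; the mean root age
  matches the analytic `sum 1/(i r)` expectation.  Two-rate trees are
  simulated backward from the present so the rate shift sits at an exact
  age (a forward placement at the expected depth lets fast-growing
  replicates finish before ever experiencing the shift).  The target
  relative shift age is converted to an absolute age via the two-regime
  expected depth; the realized fraction varies.  Birth-death trees run a
  forward Gillespie simulation with extinct lineages pruned, retrying on
  whole-tree extinction.
* **Species + coalescent trees.** A Yule species tree with a Kingman
  genealogy per species.  `separation` is a hard guarantee: each
  genealogy is rescaled so its basal age is `(youngest speciation age /
  separation) x U(0.5, 1)` — every cluster is unambiguously shallower
  than every species boundary, mirroring the hard-bound contract of the
  planted-gap generator.  Unrescaled (naturally varying) coalescent
  depths occasionally reach the species boundary and make the inference
  problem ambiguous by construction, which is a different, harder regime
  than the one these fixtures are meant to pin down.
* **Sequences.** K80 evolution with exact branch transition
  probabilities (no per-site rate variation, no indels).
* **Planted barcode gaps.** A star phylogeny (stems carrying `inter_min`
  expected substitutions per site, tip fans `intra_max / 8`) keeps the
  rejection rate low; realized K2P distances are then checked against
  the contract (all intra <= `intra_max`, all inter >= `inter_min`) and
  the draw repeated on violation, so the returned dataset satisfies the
  gap *exactly*, not just in expectation.
* **Morphospecies labels** start from true lineages and apply a requested
  number of lumps (two lineages, one name) and splits (one lineage, two
  names), disjointly, with an edit log.
* **Suitability grids** are Gaussian bumps with controllable center
  separation; overlap decreases monotonically with separation.

What passing tests do *not* show: real barcode data have rate variation
across sites, indels, chimeras and uneven sampling; real coalescent
histories include migration and variable effective sizes; real
suitability surfaces are not unimodal.  The fixtures certify the
machinery under each method's own assumptions, not robustness to their
violation.

## Numerical choices and degenerate inputs

Ultrametricity is enforced at a relative tip-age tolerance of 1e-6
(overridable), loose enough for trees written by Bayesian dating
software.  Zero-length intervals from tied node ages are handled
naturally (zero waiting contribution; simultaneous events see each
other's pre-split counts).  Saturated distances propagate as `+inf` and
never join clusters.  The ABGD recursion stops when single linkage at the
detected cutoff fails to split a group (chaining), guaranteeing
termination.  All optimizers are deterministic (bounded Brent and
Nelder-Mead from fixed starts); every stochastic routine takes an
explicit seed.

## Problem sizes used in the checks

The shipped verification suite runs the delimitation stack on 40-specimen
planted-gap alignments (607 bp), GMYC on 50-tip trees (50 clustered + 100
Yule replicates), the rate-shift test at N = 45 with 100-simulation
bootstraps (200 size trials, 100 power trials), and the truncation
experiment on 100 40-tip replicates — sizes chosen to estimate each rate
to a few percent while keeping the whole suite in minutes.
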