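# Methods

This note documents the statistical models and numerical choices behind
`sibpop`, the defaults that matter, and what the bundled simulations do and
do not establish.

## Data model and coordinates

Genotypes are diploid codominant calls: per (individual, locus) an unordered
pair of positive integer allele codes, 0 reserved for missing; a call is
either fully typed or fully missing (half-typed GENEPOP codes are demoted to
missing on read). Allele codes are opaque labels — no stepwise mutation
semantics are assumed anywhere outside the simulator.

All spatial computation happens on a planar km grid. Lon/lat input is
projected with a spherical Lambert azimuthal equal-area projection centered
on the sample centroid; over regional extents (hundreds of km) the
distance distortion is far below the 50-km thinning threshold and the
kriging length scales. Distances are Euclidean on that plane.

Missing-data policy (the field's sources rarely state theirs): all
frequency-based statistics use pairwise-complete deletion per locus;
individuals with > 50 % missing loci are flagged (`flag_high_missing`) but
never auto-dropped.

## Spatial thinning

Sampling intensity is homogenized before analysis because heterogeneous
effort distorts spatial genetic structure. Locations are clustered by
agglomerative hierarchical clustering (Lance–Williams recurrence; complete
linkage by default) and the tree is cut at the threshold distance
(default 50 km), so resulting clusters are separated by more than the
threshold. Clusters above the cap (default 10) are subsampled uniformly at
random with the stage seed. Points are pre-sorted canonically (x, y, id)
before linkage so merge-height ties, and hence the partition, do not depend
on input order.

## Admixture model

The clusterer is the standard admixture mixture: individual *i* carries
mixing proportions q_i over K clusters, cluster k carries allele-frequency
vectors p_kl per locus, and each observed allele copy is an independent draw
from Σ_k q_ik p_kl. Estimation is block-coordinate EM. Two departures from a
bare maximum-likelihood fit:

- **Ancestry prior.** Rows of Q get a symmetric Dirichlet(α) prior with
  α = 2 (the smallest integer giving an interior posterior mode), and EM
  maximizes the resulting penalized likelihood. The point estimate of a pure
  ML fit degenerates on unstructured data — it assigns confident memberships
  to sampling noise — whereas posterior-averaging samplers report q ≈ 1/K
  there. The weak prior restores that behavior (panmictic simulations:
  aligned mean |q − 0.5| ≈ 0.1 instead of ≈ 0.2; strongly drifted demes keep
  memberships ≥ 0.95). The penalized objective is asserted non-decreasing at
  every iteration; the reported log-likelihood is the unpenalized one.
  α is exposed on `ClusterConfig` (α = 1 recovers pure ML).
- **Replicates as restarts.** Replicate variability comes from seeded random
  restarts (default 10), mirroring the role of MCMC replicates. Replicate
  seeds spawn deterministically from the stage seed.

K = 1 is handled exactly (Q ≡ 1, frequencies = observed frequencies).
Convergence: Δ(penalized objective) < tol (default 1e-6) or 500 iterations.
Cluster allele frequencies are plain ML (independent across clusters); the
correlated-frequency prior of the Bayesian programs is intentionally not
modeled.

**Label alignment.** Replicates are aligned by greedily permuting each
replicate's columns to maximize the similarity statistic
G(Q, Q′) = 1 − ‖Q − Q′‖_F / √(2n) against the running mean, restarted over
random visit orders (default up to 200 for K ≤ 3); for small K each
per-replicate search enumerates all K! permutations, so K = 2 is exact. The
aligned element-wise mean (rows renormalized) is the consensus Q.

**K diagnostics.** For each K the replicate mean and sd of the converged
objective are reported together with ΔK = |L̄(K+1) − 2 L̄(K) + L̄(K−1)| / sd(K),
defined only at interior K with sd > 0. The package reports diagnostics and
never auto-selects K — plateau reading is a judgment call left to the user.

## Kriging and isocline selection

Membership values are interpolated with a thin-plate spline: minimize
Σ (y_i − s(x_i))² + λ · J(s), J the bending energy. The system is solved in
the polynomial null space via QR + eigendecomposition, so the whole λ path
costs one O(n³) factorization. λ is selected by generalized cross-validation,
GCV(λ) = n‖y − ŷ‖² / (n − tr A(λ))², minimized over a 45-point log grid
spanning eight decades around the mean eigenvalue; λ = 0 gives exact
interpolation and is available by request. Affine fields and constants are
reproduced exactly for any λ (the polynomial part is unpenalized). Membership
surfaces are clipped to [0, 1] at evaluation. Exact duplicate coordinates are
jittered by a seeded 1e-6 km before fitting; collinear point sets are
rejected with advice to jitter.

An individual belongs to a cluster's subpopulation center iff that cluster's
surface, evaluated at the individual's own coordinates, is ≥ the threshold
(default 0.70; boundary values retained, with a 1e-9 tolerance for floating-
point rounding). This value rule replaces polygonizing the 0.70 contour and
point-in-polygon testing: it is equivalent up to contour topology and far
more robust. The exported 200 × 200 surface grid (bounding box + 5 % margin)
is for plotting only — selection always uses exact evaluation. Because the
spline is linear in the data and the polynomial part absorbs constants, the
two clusters' surfaces are exactly complementary before clipping.

## The bifurcation process

Each node: fit K = 2 replicates → align → consensus Q → krige both columns →
select by isocline. Recursion is depth-first; each node's seed derives from
(run seed, lineage name) so a subtree's result is independent of sibling
execution order, and identical seeds reproduce byte-identical trees.

Stopping and reporting rules:

- A branch ends when its bifurcation retains nobody at the isocline, when a
  retained group is smaller than `min_group` (default 10 — too small to
  krige or to report as a center), at `max_depth` (default 8), or when a
  single isocline swallows the entire node (no progress).
- A node with no children is a terminal center holding its retained members.
- When exactly one side retains a viable group, the parent is itself
  reported as a center holding its retained members not claimed by deeper
  descendants — the natural reading when one lineage continues subdividing
  while its sibling dissolves.
- Per-round attrition (individuals outside both isoclines, as a percentage
  of the round's starting samples) is reported per node.

## Diversity and divergence

Per group, averaged over typed loci with equal weights: A (alleles/locus),
Ae = 1/Σp² (effective alleles), A95 (alleles at frequency ≥ 0.05), Ho
(observed heterozygote fraction), He = 1 − Σp² (gene diversity), and
F_IS = 1 − Ho/He computed from the across-locus means. He is deliberately the
plain (biased) gene diversity so the F_IS identity holds exactly; an
unbiased 2n/(2n−1) option sits behind a flag. Note some published tables
print F_IS values inconsistent with their own rounded Ho/He (per-locus
aggregation and unpublished rounding); those cells cannot be reproduced from
the printed inputs by any estimator and are not targeted.

**Θ_ST** is the Weir–Cockerham (1984) variance-components estimator,
computed per allele and locus (components a, b, c from sample sizes, allele
frequencies, and heterozygote-carrier frequencies) and combined as
Σa / Σ(a+b+c) over all alleles and loci. Small negative estimates are a
known property of the estimator and are not clipped.

**Jost's D** per locus uses Nei–Chesser-corrected heterozygosities with
ñ the harmonic mean sample size: Hs′ = (2ñ/(2ñ−1)) Hs,
Ht′ = Ht + Hs′/(2ñr), D = (Ht′ − Hs′)/(1 − Hs′) · r/(r−1), clipped to
[0, 1]; monomorphic loci are excluded and the multilocus value is the
arithmetic mean over polymorphic loci (source programs disagree here; the
mean is the simplest defensible choice and is documented as such).

**Hardy–Weinberg test**: Monte-Carlo exact — observed allele copies are
reshuffled into random diploid pairings and genotype arrays are ranked by
their conditional probability given allele counts; p = (hits + 1)/(reps + 1),
so p > 0 always. **Gametic disequilibrium**: genotypic log-likelihood-ratio
statistic against independence, null by permuting one locus's genotypes among
individuals. Both skip monomorphic loci and are calibrated by simulation
(p approximately uniform under the null). Bonferroni correction is applied
across the relevant test family.

**AMOVA genetic distance** between individuals: per locus
d² = ½ Σ_a (x_a − y_a)² on allele dosage vectors — 0 for identical genotypes
up to 4 for opposite homozygotes — summed over shared typed loci and
rescaled by (total/shared); pairs with no shared locus raise or get NaN per
configuration.

**Mantel correlogram**: equal-width distance classes over [0, max distance]
(default 80). Per class, r = −cor(genetic distance, class indicator) over
unordered pairs, negated so positive r means positive spatial
autocorrelation. Significance by permuting individual labels (999 default),
one-tailed in the observed direction; progressive Bonferroni multiplies the
k-th tested class's p by k. Classes in the upper half of the distance range
are tested only while every individual still has a pair in the class, and
classes with < 2 pairs are skipped. Per-class r values are cross-checked in
the test suite against an independent R implementation of the Mantel
statistic.

## KDE center polygons

Individuals are assigned to their maximum-membership group (ties to the
lowest column index, flagged). Each group's density is a bivariate normal
kernel with the reference bandwidth h = σ n^(−1/6), σ = √((var x + var y)/2),
evaluated on a 200 × 200 grid (10 % + 3h margin). The v-level region
(v ∈ {25, 50, 75} %) is the smallest-area set of cells containing fraction v
of the gridded mass — the home-range convention, not a density-height
quantile — polygonized by marching squares and cleaned with a zero buffer.
Levels nest by construction; the enclosed mass is within grid resolution
(≈ 2 %) of nominal.

## Synthetic data

Two generators define the test conditions; all randomness flows from the
config seed and identical configs are byte-identical.

- **Hierarchical (Balding–Nichols)**: ancestral frequencies per locus are
  symmetric-Dirichlet (10 alleles default, matching microsatellite allele
  counts); each branch of a bifurcating deme tree draws child frequencies
  from Dirichlet(p(1−F)/F), so branch drift F is controlled exactly.
  Genotypes are Hardy–Weinberg within terminal demes. Demes sit on a nested
  spatial layout (root separation 800 km, halved per level — regional-scale
  geography) with individuals scattered Gaussian σ = 30 km, optionally
  clumped into leks of uneven intensity. Truth labels (deme, lineage path,
  lek) ride along.
- **Stepping-stone (Wright–Fisher)**: demes on a lattice (50 km spacing)
  founded from a common pool, evolving with nearest-neighbor migration m,
  stepwise mutation (rate 5e-4) on a reflecting 20-state allele ladder, and
  multinomial drift (2N gene copies, N = 100 default); defaults m = 0.01,
  200 generations give strong local autocorrelation with IBD decay.

What the simulations do **not** emulate: continuous (non-deme) space, real
marker ascertainment, null alleles and genotyping error beyond simple
missingness, temporal sampling, and the mixed IBD-plus-hierarchy regime of
real landscapes. Passing the recovery tests therefore shows the pipeline is
correct and well-calibrated under its own assumptions, not that any
particular real dataset will yield clean centers.

## Problem sizes and numerical notes

The bundled analyses run at desk scale by design: bifurcation recovery uses
4 demes × 50 individuals × 15 loci; the panmixia null 200 individuals;
calibration 200 datasets of n = 40 (399 permutations each) and 100 Mantel
null seeds (n = 30, 199 permutations); the IBD check a 10 × 2 lattice with
15 samples/deme and 999 permutations. The kriging solve is dense
O(n³) — comfortable to a few thousand points; beyond that, thin the sample
first (as the method itself prescribes). Permutation matrices for the
correlogram are materialized in float32 blocks (reps × pairs) to bound
memory.

## Known limitations

- The EM consensus Q is a point-estimate stand-in for posterior-mean
  memberships; very weak structure (pairwise F ≲ 0.05 at 15 loci) sits near
  its detection floor and may bifurcate inconsistently across seeds.
- The 0.70 isocline, min_group = 10, and the binary (K = 2 per round)
  subdivision are method constants inherited from the procedure's design,
  not estimated from data; sensitivity to them is the user's to explore.
- The thin-plate-spline + GCV smoother approximates the "default kriging"
  behavior of the R tooling this workflow grew out of; exact defaults of
  that tooling are version-dependent. A Matérn ordinary-kriging variant is
  not currently implemented.
- Jost's D multilocus averaging and the He estimator are documented
  conventions; other programs make different choices and will differ in the
  third decimal.
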