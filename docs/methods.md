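# Methods

This note documents the statistical machinery, the defaults and the
design decisions of `cophylospace`, in the spirit of a model-description
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genetic distances

**p-distance.** For a specimen pair, the proportion of compared sites
that differ. A site is compared when both sequences carry an
unambiguous base (`A/C/G/T`) there; gaps, `N` and IUPAC ambiguity codes
are excluded *pairwise* (per pair of sequences), not by deleting whole
columns. Pairwise deletion is the default of the common distance
implementations for ITS-type alignments, where indel-rich regions would
otherwise discard most columns; complete deletion is available via
`deletion='complete'`. Treating ambiguity codes as missing rather than
partially matched is the simplest defensible rule; it is recorded in
the API contract rather than silently applied. A pair with zero
comparable sites is an error naming the pair, never a silent 0 or NaN.

**TN93.** The Tamura–Nei (1993) closed form with the two transition
classes P₁ (A↔G), P₂ (C↔T) and transversions Q estimated per pair from
the compared sites, and base frequencies likewise estimated per pair
(`frequencies='global'` switches to alignment-wide frequencies, which
is what `ape::dist.dna` uses; the test suite cross-checks that mode
against ape). When any logarithm argument is ≤ 0 the pair is
*saturated*: the distance is mathematically inestimable. Such pairs are
flagged in `TN93Result.inestimable` and converting to a distance matrix
raises, so saturation cannot leak downstream as NaN. Where both are
defined, TN93 ≥ p-distance elementwise (the correction only inflates).

**Geographic distance.** Haversine on a sphere of radius 6,371,000 m.
At sampling extents of order 10⁶ m the sphere-vs-ellipsoid discrepancy
(≲0.5%) is far below the scale resolution of the spatial eigenvector
basis, which only consumes the rank order and rough magnitudes of the
distances.

**Summaries.** Matrix summaries (mean, SD, range over unique pairs) use
the sample standard deviation (ddof = 1). The spatial extent of a
dataset is the maximum pairwise geographic distance.

## Ordination

**PCoA.** Gower double-centering of −½·D∘D followed by a symmetric
eigendecomposition; coordinates are eigenvectors scaled by √λ.
Eigenvalues within 10⁻¹⁰·λ₁ of zero are treated as zero. Non-Euclidean
inputs produce negative eigenvalues; the default (`correction='none'`)
reports them but excludes those axes from the coordinates, matching
common db-RDA practice. Lingoes (add 2c to squared off-diagonal
distances, c = −λ_min) and Cailliez (add c to off-diagonal distances,
c from the 2n×2n companion eigenproblem) corrections are available for
users who need all axes retained.

**MEM basis.** Distances above the truncation threshold *t* are
replaced by 4*t* and the result is run through PCoA; positive-eigenvalue
eigenvectors are kept as unit-norm, centered spatial variables, MEM 1
being the broadest scale. The default *t* is the longest edge of a
minimum spanning tree over the points — the smallest threshold that
keeps the sampling graph connected. There are at most n−1 MEMs. The
basis matches R `vegan::pcnm` (eigenvalues and vectors up to sign),
which the test suite checks directly.

**db-RDA.** The response distance matrix is embedded by PCoA (positive
axes, √λ scaling); predictors are column-centered and reduced to an
orthonormal basis by SVD, dropping collinear columns with a warning.
R² is the projected fraction of total inertia,
pseudo-F = (R²/m)/((1−R²)/(n−m−1)), and the permutation test permutes
response rows. A model with m ≥ n−1 predictors is refused as saturated.

**Permutation p-values.** Everywhere in the package,
p = (#{stat_perm ≥ stat_obs} + 1)/(n_perm + 1) (with ≤ for PACo, whose
evidence direction is reversed). This Monte-Carlo convention cannot
produce p = 0 and makes p uniform on {1/(B+1), …, 1} under the null.
Observed-vs-permuted comparisons use a 10⁻¹² slack so exact ties (e.g.
a permutation reproducing the identity) count as exceedances.

**Forward selection.** Greedy: at each step every remaining MEM is
scored by the permutation p-value of its partial pseudo-F given the
already-selected block; the same permutation draws are shared by all
candidates within a step (this is what makes 999-permutation selection
affordable, and it only couples candidates within a step, not the
sequential decisions). Ties on p are broken by larger added R², then
lower MEM index, making selection deterministic given the seed. Entry
stops when the best candidate's p exceeds α (default 0.05, 999
permutations). Permutations are of the raw response rows; Blanchet-style
double stopping on adjusted R² is deliberately not applied — only the
α rule — since variance partitioning downstream already penalises
overfitted spatial blocks through adjusted R². An empty selection is a
legal outcome and yields a partner-only partition with genuinely (not
structurally) zero spatial fractions.

**Variance partitioning.** With A, B, AB the adjusted R² of the partner
block, the spatial block and their union: a = AB − B, b = A + B − AB,
c = AB − A, d = 1 − AB; a+b+c+d = 1 by construction. a, b, c may be
slightly negative — an expected adjusted-R² artifact, reported raw in
machine output; `VariancePartition.clamped()` provides the
zero-floored display version used in the human-readable table.

**Explanatory axes.** How a partner *distance matrix* becomes db-RDA
*predictors* is a genuinely open convention. The default uses all
positive-eigenvalue PCoA axes (the information-complete choice);
`rule='cum95'` (axes covering 95% of positive inertia) and `rule=k`
(first k axes) are provided because the partner fraction is materially
sensitive to this choice and users comparing against other software may
need to match its convention.

## PACo

X = PCoA coordinates of the algal matrix, Y = of the fungal matrix
(positive axes, shared implementation with the ordination module); the
narrower configuration is zero-padded. Y is superimposed on X by
least squares: both centered, Y scaled by s = trΣ/‖Y_c‖² and rotated by
R = UVᵀ from svd(Y_cᵀX_c) = UΣVᵀ. The asymmetric (Y-onto-X) convention
is the default, with the direction configurable for the reverse
analysis; symmetric scaling is not offered. Reflections are allowed
because PCoA axis signs are arbitrary. m² = Σ rᵢ², with per-specimen
rᵢ² = ‖xᵢ − T(yᵢ)‖².

The null randomises the row pairing of Y (Fisher–Yates via the seeded
generator); the observed pairing is not excluded from the draws. The
test is one-sided with small m² as evidence of congruence:
p = (#{m²_perm ≤ m²_obs} + 1)/(n_perm + 1), 10,000 permutations by
default. Permuted statistics use the closed form
m² = ‖X_c‖² − (trΣ_perm)²/‖Y_c‖², which folds in the optimal scale and
avoids refitting. Per-specimen residuals can be grouped by categorical
traits (growth form, presence of apothecia, …) with group counts,
means, medians and the share of specimens above the overall median.

## Synthetic data generator

The generator provides ground truth for every stage; its defaults *are*
the study conditions used by the acceptance checks: n = 40 specimens,
600-site alignments, substitution rate 0.05 per site over the (unit)
tree depth, 600 km bounding box, full co-speciation and full spatial
signal unless a parameter is swept.

**Co-phylogeny.** The fungal lineage diversifies by a Yule process
(per-lineage rate 1; depth rescaled to 1 at the end). The algal pool
diversifies on the same timeline by background speciation events at the
same *total* rate as the fungal process. A per-lineage pool rate would
make the two lineage counts a Pólya urn whose total event count has
infinite expectation (occasional pool explosions); coupling the pool's
total rate to the fungal process keeps pool diversity comparable to the
sampled radiation and event counts bounded. At each fungal speciation,
with probability `p_cospeciation` the partner algal lineage
co-speciates (each fungal daughter tracks its own algal daughter);
otherwise one daughter inherits the parent's partner and the other
attaches to an extant algal lineage drawn uniformly — so low
co-speciation yields few, shared algal lineages, which is also how
zero algal distances arise (specimens sharing a photobiont lineage).
After every speciation, each other fungal lineage re-attaches to a
uniform algal lineage with probability `switch_rate`; at
`switch_rate = 1` the final association is an i.i.d. uniform draw,
i.e. the exact exchangeable null of the PACo permutation test, which is
what the calibration checks use. Unpartnered pool lineages are pruned;
with full co-speciation and no switching the induced algal tree equals
the fungal tree in topology and node times.

**Sequences.** Jukes–Cantor, simulated exactly: a uniform random root
sequence, per-branch site-change probability ¾(1 − e^(−4μb/3)), changed
sites uniform over the other three bases. The default μ = 0.05 puts
pairwise p-distances on the 0–0.2 scale typical of ITS datasets (the
suite asserts this). Estimating with TN93 on JC-generated data is an
intentional, harmless model mismatch at these divergences.

**Locations.** A 2-D Brownian motion diffuses along the fungal tree;
tip positions are min–max rescaled to the bounding box and mixed with
uniform positions as σ·BM + (1−σ)·uniform, then converted to lon/lat
around a fixed mid-latitude origin (172°E, 43°S). σ = 1 makes fungal
genetic distance spatially structured; σ = 0 severs genetics from
geography.

**Determinism.** Every output is a pure function of the scenario:
per-stage generators are spawned from one `SeedSequence`, and the
pipeline derives per-stage seeds from the master seed by fixed offsets,
so reports are byte-identical across reruns.

**What the generator does not emulate.** Indel evolution and alignment
uncertainty (alignments are gap-free by construction, though the
readers and distance rules fully support gaps/ambiguities), rate
variation across sites and lineages, tripartite symbioses,
within-thallus photobiont mixtures, and non-random sampling designs.
Passing tests therefore demonstrate correctness of the statistical
machinery and qualitative parameter recovery under a clean generating
model — not robustness to alignment error or model misspecification in
field data.

## Problem sizes and numerical choices

The calibration checks use the sizes at which the relevant asymptotics
already hold while each check stays in the seconds-to-minutes range:
db-RDA null calibration with 1000 replicates at n = 30 (99 permutations
each), PACo null with 500 independent-tree replicates at n = 16, power
with 50 replicates at n = 40 (199 permutations), and parameter sweeps
with 8 paired seeds per setting. Eigenvalue zero-tolerance is
10⁻¹⁰·λ₁ throughout; predictor rank uses the SVD with the standard
machine-epsilon threshold; MST tie-breaks inherit scipy's deterministic
sparse-graph implementation, so results are reproducible given input
order.

## Known limitations

- Exact reproduction of published partner fractions from other studies
  depends on their (often unstated) explanatory-axis retention and
  forward-selection conventions; the defaults here are the
  information-complete choices, and the alternatives are exposed.
- Negative-eigenvalue handling defaults to axis dropping; with strongly
  non-Euclidean distance matrices the corrections can change fractions
  noticeably.
- Forward selection with raw-data permutations is mildly liberal when
  the selected block already explains much of the response; with many
  candidate MEMs some false entries are expected (the variance
  partition's adjusted R² compensates downstream).
- The PACo m² is not comparable across datasets of different size or
  diversity; only its permutation p-value is.
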