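# Methods

This note documents the models, parameter choices, and numerical
conventions behind `commstruct`, and what the synthetic-data generator
does and does not emulate.

## Distances

Phylogenetic distances are cophenetic (patristic): the branch-length path
between two tips of a rooted tree, read with dendropy. Trees need not be
ultrametric (a warning is logged if they are not); every metric below is
defined for arbitrary nonnegative distances. Functional distances are
Gower dissimilarities on continuous traits: the mean over traits of
|xᵢ − xⱼ| / rangeₖ with the observed per-trait range, bounded in [0, 1],
equally weighted, and invariant to affine rescaling of any single trait.
Traits are used raw; an opt-in log10 transform exists for body mass.
Missing trait values are rejected rather than pairwise-deleted — with a
small trait set, silent deletion would change what the distance measures
from pair to pair.

## Alpha structure: MPD, MNTD, and SES

MPD is the mean of pairwise distances among the species present at a
site; MNTD the mean of each species' distance to its nearest co-occurring
neighbor. Both default to abundance weighting: MPD weights each ordered
pair by fᵢfⱼ (self-pairs excluded, since the metric is defined among
distinct species and δᵢᵢ = 0 terms would only dilute it), MNTD weights
each species' nearest-neighbor distance by fᵢ. Communities with fewer
than two species return NaN (logged) rather than raising — a survey can
legitimately contain monospecific sites.

The null model preserves each site's richness and abundance vector:
species identities are redrawn uniformly without replacement from the
pool (all species with nonzero total abundance across the matrix — the
only pool observable from the data), and the observed abundances are
reassigned in random order. SES = (obs − null mean) / null SD with the
sample SD over the null replicates; the rank p is
(count of null ≤ obs + 1)/(n_null + 1). When the null SD is 0 (e.g. a
site containing the whole pool with equal abundances) the SES is
undefined and flagged, and the run continues. The default replicate count
is 999 for both alpha and beta nulls, keeping p-value resolution uniform
across stages.

Sign convention: SES(MPD) = −NRI, SES(MNTD) = −NTI; positive means
overdispersion, negative clustering.

## Beta structure: D′pw and D′nn

D′pw is the full double sum Σᵢ Σⱼ δᵢⱼ fᵢ fⱼ over the two communities'
species with within-community relative abundances; species shared between
the communities contribute their δ = 0 terms (the double sum is
unrestricted). D′nn sums each community's abundance-weighted
nearest-neighbor distances into the other community; with relative
abundances the normalizing denominator is 1. The default is this literal
(unhalved) two-term form; `convention="halved"` divides by two, matching
the comdistnt convention of phylocom/picante, so results can be compared
against either reading. The two differ by an exact factor of 2. Both
metrics are symmetric in the two communities and scale linearly with the
distance matrix.

Null standardization shuffles species labels of the distance matrix
(exactly equivalent to shuffling tree tips or trait rows, and cheaper)
and recomputes all pairwise values per replicate; per-pair SES uses the
same standardized-effect form as the alpha metrics.

Region contrasts group upper-triangle site pairs by sorted region pair
(within-west, west–center, ..., within-east) and delegate the one-way
ANOVA to scipy and the Tukey HSD adjustment to statsmodels. Pairwise
beta values are not independent; the grouped ANOVA is a descriptive
summary, as is conventional in this literature. When a Tukey group has
zero variance the studentized range is 0/0: a zero mean difference is
reported as p = 1, a nonzero one as p = 0.

Partial Mantel: Pearson correlation of the upper-triangle vectors after
residualizing both on the control matrix (ordinary least squares); the
permutation p permutes rows/columns of the first matrix jointly
(one-tailed, ≥ observed), with all permuted vectors built by one fancy
indexing operation.

## Phylogenetic signal

Independent contrasts follow Felsenstein's pruning algorithm. Because the
recursion is linear in the trait vector, the whole computation is
captured once per tree as an (n−1) × n matrix and applied to all 1000
trait shuffles in a single product — this is what keeps the
randomization test fast. Polytomies are resolved deterministically
(children ordered by smallest descendant tip label, folded pairwise with
zero-length branches), so a tree with n tips always yields n − 1
contrasts. At a zero-length resolution node the standardization
denominator vanishes; the contrast is then taken as the raw difference
and the ancestral value as the plain mean, keeping the computation
defined where reference implementations error out.

The randomization test ranks the observed contrast variance within the
shuffle distribution; significance is the extreme 2.5% of ranks in either
tail (25 ranks per tail at 1000 shuffles — two-tailed α = 0.05), low tail
= signal, high tail = antisignal. The reported p is the doubled smaller
tail rank probability, capped at 1.

Blomberg's K uses the standard phylogenetic variance–covariance
formulation: observed MSE0/MSE with the GLS phylogenetic mean, divided by
its Brownian expectation (tr V − n/Σ V⁻¹)/(n − 1). K is invariant to
affine trait transforms and to global branch-length rescaling. Both the
PIC-randomization p and K are reported for every trait.

## Temperature predictors, NMDS, envfit

Season windows (Northern-Hemisphere wintering defaults, configurable):
autumn Sep–Nov, winter Dec–Feb, spring Mar–May, autumn–winter Sep–Feb,
winter–spring Dec–May, annual all 12. Means are arithmetic means of the
window months. "Fluctuation" is not standardized terminology; here it is
the sample SD (ddof = 1) of the window's monthly means, with max − min
range as an option.

NMDS delegates stress minimization to scikit-learn's nonmetric MDS
(precomputed dissimilarities, Kruskal stress-1, 16 random starts by
default, best kept, coordinates centered). envfit regresses the centered,
unit-variance predictor on the centered ordination coordinates: direction
= unit vector of the coefficients, r² = squared multiple correlation,
p = permutation probability of r² under site-label shuffles, and the
display arrow is direction × √r², so weak predictors draw short arrows.
One ordination is fitted per beta metric.

## MCC tree

Clade credibility is each clade's frequency across the tree set; the tree
maximizing the summed log credibilities of its clades is selected (first
in input order on ties). Node heights on the selected tree are replaced
by the mean height of the clade across the trees containing it, with
height = distance to the furthest descendant tip, and branch lengths
rebuilt from the averaged heights. Tips carry a derived height (parent
height minus terminal edge) so terminal branches of non-ultrametric
singletons round-trip exactly; internal edges off a node's longest path
do not survive height-based reconstruction — the inherent lossiness of
mean-heights annotation, shared with TreeAnnotator, which also motivates
clamping occasional negative rebuilt branches to zero. Intended use is
ultrametric (dated) tree sets.

## Synthetic surveys

The generator emulates a 42-site coastal survey spanning longitudes
111–117° E (regions west [111, 113), center [113, 115), east [115, 117),
half-open to make the minute-based boundaries deterministic) over a
60-species pool on a unit-depth Yule tree. Four latent traits evolve by
Brownian motion (rate σ² = 1) and are mapped through base · exp(cv · z)
onto positive morphological scales (wing, beak, tarsus in mm; mass in g).
Site richness is uniform on 10–25; abundances are lognormal
(meanlog 1, sdlog 1) counts ≥ 1.

Assembly mechanisms:

- **filtering** — inclusion probability ∝ exp(−(z − optimum)²/(2σ_f²))
  on the first latent trait, with the site optimum tracking the gradient
  across the trait's 10–90% quantile range; σ_f = 0.15, about 15% of the
  pool trait SD. Abundances at filtering sites are additionally scaled by
  the filter weight: a filter that limits colonization also depresses the
  abundance of poorly matched species. Because the trait is Brownian,
  trait filtering clusters communities on the tree only as strongly as
  the trait's phylogenetic signal allows — the filter must be narrow for
  the clustering signature to be reliable.
- **neutral** — uniform draws.
- **competition** — sequential assembly rejecting candidates whose
  nearest cophenetic distance to any resident falls below 0.5 (half the
  tree depth); if the pool is exhausted first, remaining slots are filled
  from the rejects at random so richness is preserved.

The paperlike scenario assigns filtering to western sites, competition to
eastern sites, and a probabilistic blend in the center (filtering
probability declining eastward), so composition turns over smoothly
along the gradient rather than jumping between two internally unordered
clusters — without that smoothness an ordination has no gradient to
correlate with temperature.

Monthly temperatures are a cosine seasonal cycle peaking in July with
winter amplitude declining linearly from 8 °C (west) to 2 °C (east),
site offsets of 15 ± 1.5 °C that carry no gradient, and 0.3 °C monthly
noise. Annual, autumn and spring means of a symmetric cycle cancel the
amplitude, so MAT/MAuT/MST are noise-only while the fluctuation
predictors track the gradient; MWT inherits amplitude through the winter
trough and is the one mean predictor that can be informative — matching
the intended contrast in which fluctuation, not mean temperature, drives
the geography.

What the generator does **not** emulate: spatial autocorrelation of
sites, detection error in counts, migration linking communities,
correlated trait evolution, and realistic within-year temperature
autocorrelation. Tests passing on these simulations show the statistical
machinery is correct and the mechanisms are recoverable under the
modelled conditions; they do not show that real waterbird communities
behave this way.

## Problem sizes and reproducibility

The test and acceptance runs use deliberately modest problem sizes — 199
null replicates for scenario SES summaries, 999 for the headline Mantel
and null defaults, 100–500 replicates for calibration experiments — the
package's own choice of sizes at which the checked quantities are already
stable. Every stochastic stage takes an explicit seed (or numpy
Generator) and is bit-reproducible; the pipeline writes a manifest with
SHA-256 digests of all outputs so a rerun with the same config is
verifiable byte for byte.

## Known limitations

- The grouped ANOVA on pairwise beta values ignores their
  non-independence (descriptive, as noted).
- NMDS is a local optimizer; results are reproducible for a fixed seed
  and start count but not guaranteed globally optimal.
- MCC mean-heights reconstruction is faithful only for ultrametric tree
  sets (above).
- The richness null conditions on the surveyed pool; in real data the
  regional pool may be larger, which would shift SES toward clustering.
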