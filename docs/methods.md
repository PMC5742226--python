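# Methods

This note documents the statistical procedures, parameter defaults, and
numerical choices implemented in `rupestre`, and the decisions taken where
several defensible conventions exist.

## 1. Data model

Sites carry a substrate (quartzite or canga/ironstone) and a physiognomy
(open or forest), combining to four habitat classes: FC, FQ, OC, OQ (first
letter physiognomy, second substrate). Incidence matrices are binary
(sites × species); abundance inputs are binarized with a warning. Taxon
labels are sanitized to lowercase with underscores, and infraspecific
epithets are stripped so that subspecies collapse to their species.
Morphospecies determined only to genus are kept as distinct terminals;
uncertain determinations ("cf.", "aff.") are *not* merged into their
nominate species, since synonymy cannot be established from a checklist
alone. Site filters remove plots with unknown or disturbed vegetation and
limestone substrates, then drop species left with no occurrences.

## 2. Megatree construction and dating

Species are grafted onto a genus/family backbone tree: a species tip is
attached under its genus node when present, otherwise as a polytomy child
of its family node, otherwise reported unplaced. Backbone tips that
received no species are pruned; named unifurcations are retained because
they carry calibration information.

Node ages are assigned by even interpolation between calibrations
(the classic branch-length-adjustment approach). Calibrated nodes are
processed oldest first. For each path from a calibrated node down to the
next node with a known age (a deeper calibration or a tip at age 0), the
$m$ intermediate nodes are spaced evenly:

$$a_k = a_{top} - (a_{top} - a_{bot}) \cdot \frac{k}{m+1}, \quad k = 1..m$$

Ages assigned this way become fixed and constrain all later paths, making
the procedure deterministic and order-independent among equal-age
calibrations. Branch lengths are parent age minus child age; the result is
ultrametric to within 1e-9 relative error by construction, and calibration
inputs that conflict (child older than parent) raise an error before any
dating occurs.

## 3. Phylogenetic structure

Patristic distances are computed coherently from node depths:
$d_{ij} = \delta_i + \delta_j - 2\,\delta_{\mathrm{MRCA}(i,j)}$, accumulated
in a single post-order pass.

MPD and MNTD per site are standardized against a *tip-shuffle* null:
shuffling the labels of the distance matrix uniformly is equivalent to
drawing $|S|$ tips uniformly at random from the pool, so the null is
implemented as vectorized uniform $k$-subset draws (blocked to bound
memory at ~2×10⁷ floats per block). Defaults: 999 shuffles, sample
standard deviation (ddof = 1), significance at $|$index$| > 1.96$. The
index is undefined (NaN) when the null standard deviation is zero (e.g. a
site containing the whole pool). Species absent from the tree are dropped
globally — from every site and from the pool — rather than per site, so
all sites face the same null pool.

## 4. Beta diversity

Species occurring at exactly one site are removed before dissimilarity
computation (they carry no information about shared composition and
inflate distances between species-poor sites). On binary data Bray–Curtis
equals the Sørensen dissimilarity $1 - 2a/(2a + b + c)$. Clustering uses
Ward.D2 linkage on the dissimilarities. NMDS minimizes Kruskal stress-1
with isotonic regression for the monotone fit and Guttman-transform
updates; the first start is the principal-coordinates configuration,
followed by seeded random restarts (default 20), convergence tolerance
1e-7 on stress, 300 iterations per start. Stress is reported on the final
(centered) configuration; a warning is emitted when no start converged.

## 5. Habitat statistics

Per habitat, the mean NRI (and NTI) is tested against zero with a
one-tailed one-sample t test (alternative: mean > 0, i.e. clustering).
Two-way ANOVA of each index on substrate and physiognomy uses *sequential*
(Type I) sums of squares with substrate entered first — the convention of
classical `aov`-style analyses — so with unbalanced designs the order
matters and is documented output. Pairwise habitat contrasts use the
Tukey–Kramer studentized-range statistic
$q = |\bar{y}_i - \bar{y}_j| / \sqrt{\tfrac{MSE}{2}(1/n_i + 1/n_j)}$ with
the error degrees of freedom from the ANOVA. Shapiro–Wilk per group and
median-centered Levene tests are reported as advisories, not gates.

## 6. Clade representation (nodesig)

For a site of richness $n$ drawn from a pool of $N$ tips, the count of
site members descending from a node with $K$ pool descendants is
Hypergeometric$(N, K, n)$ under the uniform null. The default mode
computes exact tails (`sf(x−1)` and `cdf(x)`); a Monte-Carlo mode
estimates them from uniform draws with the $(c+1)/(r+1)$ correction so no
estimate is exactly zero. The decision is two-tailed at $\alpha/2 = 0.025$
per tail. At the habitat level a clade is flagged when significant in at
least $\lceil \text{sites}/2 \rceil$ of the habitat's sites; crown ages
from the dated tree are attached and rows are sorted youngest-first within
habitat. Unnamed internal nodes receive a stable signature
`[ancestor:first..last:count]` built from the nearest named ancestor and
the descendant tip range.

## 7. Synthetic data generator

The generator emulates the *assembly structure* of a habitat-mosaic
survey, not any particular flora:

- **Tree**: a Yule (pure-birth) process conditioned on the tip count, with
  exponential waiting times at rate equal to the current lineage count,
  rescaled to a fixed root age.
- **Communities**: per habitat, a focal seed taxon anchors a distance-decay
  weight $w_s = e^{-\lambda\, d(s, s_0)}$; each site draws its richness
  uniformly from a configured range and samples species without
  replacement with those weights. $\lambda = 0$ reduces exactly to uniform
  assembly; the planted focal clade (the clade closest to a configured
  fraction of the pool) is recorded as ground truth.
- **Singletons**: after assembly, additional single-occurrence species are
  injected from the unused pool to reach a target singleton fraction
  $t = (r \cdot n_{occ} - s_{nat}) / (1 - r)$, clipped to the available
  pool, emulating the long occupancy tail of floristic data.

What it does **not** emulate: spatial autocorrelation between sites,
substrate-specific species pools, abundance structure, or taxonomic
(genus/family) signal in community membership.

Defaults mirror a realistic campo-rupestre-scale survey chosen as this
package's reference problem size: 2920 species, 140 My root age, 47 sites
(FC 5, FQ 9, OC 11, OQ 22), per-site richness 20–503, filtering strengths
{FC 0, FQ 0.02, OC 0.02, OQ 0.1}, focal clade ≈10 % of the pool,
singleton rate 0.1. All are configurable.

## 8. Pipeline and reproducibility

`run_pipeline` executes stages in order (inputs → summary → beta diversity
→ phylogenetic structure → habitat statistics → clade representation →
manifest), writes one table per product, and records SHA-256 hashes of all
outputs plus per-stage seeds in `manifest.json`. Stage seeds are derived
from the global seed as the first 4 bytes of
`sha256("{seed}:{stage}")` reduced mod 2³¹, so stages are independently
reproducible and adding a stage never perturbs existing ones. A `FAILED`
marker file names the failing stage on error.

## 9. Numerical notes and limitations

- Boolean incidence vectors are cast to integers before matrix products;
  NumPy's boolean matmul is logical, not counting.
- Null-model and Monte-Carlo loops are blocked to bound peak memory; block
  sizes trade memory for speed and do not affect results.
- The even-interpolation dating is only as good as its calibrations;
  paths with no internal calibration are spaced uniformly, which
  compresses or stretches real branch-length variation.
- The hypergeometric nodesig null ignores phylogenetic non-independence
  between nested nodes; nested clades are tested marginally, as in the
  original formulation, and no multiplicity correction is applied beyond
  the half-of-sites tabulation rule.
- Type I ANOVA results depend on factor entry order under imbalance;
  substrate-first is fixed and stated rather than configurable, to keep
  outputs comparable across runs.
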