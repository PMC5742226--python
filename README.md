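# rupestre

Community-phylogenetics toolkit for habitat mosaics: build a dated megatree
for a regional species pool, quantify the phylogenetic structure of site
assemblages against tip-shuffle null models, ordinate sites by composition,
and locate the clades that drive habitat differences.

The package was motivated by analyses of tropical mountain vegetation —
open and forested communities on quartzite and ironstone (canga)
substrates — but every component works on any incidence matrix plus a
phylogeny.

## What it computes

**Phylogenetic structure per site.** For a site with species set $S$ and a
patristic distance matrix $d$ on the regional pool:

- Mean pairwise distance $\mathrm{MPD} = \binom{|S|}{2}^{-1} \sum_{i<j} d_{ij}$
- Mean nearest-taxon distance $\mathrm{MNTD} = |S|^{-1} \sum_i \min_{j \ne i} d_{ij}$

Both are standardized against a null of drawing $|S|$ tips uniformly from
the pool (999 label shuffles by default):

$$\mathrm{NRI} = -\frac{\mathrm{MPD}_{obs} - \overline{\mathrm{MPD}}_{null}}{\sigma(\mathrm{MPD}_{null})}, \qquad
\mathrm{NTI} = -\frac{\mathrm{MNTD}_{obs} - \overline{\mathrm{MNTD}}_{null}}{\sigma(\mathrm{MNTD}_{null})}$$

Positive values indicate phylogenetic clustering, negative values
overdispersion; $|$index$| > 1.96$ is flagged significant.

**Clade representation (nodesig).** For every internal node with $K$
descendant tips in a pool of $N$, the number of the site's $n$ species
falling inside the clade is Hypergeometric$(N, K, n)$ under the uniform
null. Exact tail probabilities decide over-/under-representation at
$\alpha/2$ per tail; a Monte-Carlo mode is available for cross-checking.
Habitat summaries flag clades significant in at least half of a habitat's
sites and attach crown ages from the dated tree.

**Beta diversity.** Singleton species are removed, Bray–Curtis (≡ Sørensen
on incidence data) dissimilarities are clustered with Ward.D2 linkage, and
sites are ordinated with non-metric multidimensional scaling (Kruskal
stress-1, isotonic regression, multiple restarts).

**Habitat statistics.** One-tailed one-sample t tests of mean NRI/NTI per
habitat, sequential (Type I) two-way ANOVA of the indices on substrate and
physiognomy, Tukey–Kramer pairwise contrasts, and Shapiro–Wilk/Levene
assumption advisories.

**Megatree construction.** Species are grafted onto a genus/family backbone
(genus node first, then family polytomy), and node ages are assigned by the
even-interpolation dating algorithm: calibrated ages are fixed, and
uncalibrated nodes on each path between fixed ages are spaced evenly,
processing calibrations oldest-first so earlier assignments constrain later
paths.

**Synthetic data.** A Yule-tree simulator plus a distance-decay community
assembler: site membership is drawn with weights $e^{-\lambda\, d(s,
s_0)}$ toward a focal seed taxon, so $\lambda = 0$ gives uniform assembly
and larger $\lambda$ plants phylogenetic clustering with a known focal
clade. A configurable singleton rate emulates the long occupancy tail of
real floristic surveys.

## Worked example

```python
import numpy as np
from rupestre import SyntheticConfig, simulate_tree, simulate_communities
from rupestre.phylo_structure import cophenetic, ses
from rupestre.beta_diversity import bray_curtis, nmds

cfg = SyntheticConfig(
    seed=0, n_species=120, root_age=140.0,
    habitat_sites={"FC": 4, "OQ": 8}, richness_range=(10, 30),
    filtering_strength={"FC": 0.0, "OQ": 0.1},
    focal_clade_fraction=0.15, singleton_rate=0.0,
)
tree = simulate_tree(cfg.n_species, cfg.root_age, seed=cfg.seed)
matrix, meta, truth = simulate_communities(tree, cfg)

pat = cophenetic(tree)
results = ses(matrix, pat, "MPD", n_null=999, seed=1)
for r in results[:3]:
    print(f"{r.site_id}: NRI = {r.index:.2f} "
          f"(obs MPD {r.obs:.1f}, null {r.null_mean:.1f} ± {r.null_sd:.1f}, {r.significant})")

ord_ = nmds(bray_curtis(matrix), dims=2, n_starts=5, seed=2)
print(f"NMDS stress: {ord_.stress:.3f}")
```

Output:

```
FC01: NRI = -0.77 (obs MPD 245.7, null 240.3 ± 7.1, ns)
FC02: NRI = 1.17 (obs MPD 228.5, null 240.6 ± 10.3, ns)
FC03: NRI = -0.67 (obs MPD 243.2, null 240.2 ± 4.4, ns)
NMDS stress: 0.090
```

Mean NRI over the unfiltered forest-canga (FC) sites is −0.35 — consistent
with random assembly — while the strongly filtered open-quartzite (OQ)
sites average 20.84, recovering the planted clustering.

## Command line

```bash
rupestre simulate --seed 1 --n-species 200 --outdir landscape/   # synthetic inputs
rupestre summary  --matrix landscape/matrix.csv --metadata landscape/metadata.csv
rupestre beta     --matrix landscape/matrix.csv --outdir beta/
rupestre ses      --matrix landscape/matrix.csv --tree landscape/tree.nwk --out ses.csv
rupestre nodesig  --matrix landscape/matrix.csv --tree landscape/tree.nwk \
                  --metadata landscape/metadata.csv --out nodesig.csv
rupestre run      --config run.yaml     # full pipeline with manifest
```

`rupestre run` takes a YAML config (see `RunConfig.from_yaml`) pointing at
either real inputs (matrix, metadata, backbone, ages) or a synthetic
configuration, and writes all tables plus a `manifest.json` with SHA-256
hashes and per-stage seeds.

## Layout

| module | contents |
| --- | --- |
| `rupestre.data_core` | incidence matrices, site metadata, name sanitation, filters |
| `rupestre.megatree` | backbone grafting, even-interpolation node dating, dated trees |
| `rupestre.phylo_structure` | patristic distances, MPD/MNTD, NRI/NTI null models |
| `rupestre.beta_diversity` | Bray–Curtis, Ward.D2 clustering, NMDS |
| `rupestre.habitat_stats` | t tests, Type I two-way ANOVA, Tukey–Kramer, assumption checks |
| `rupestre.clade_representation` | per-node hypergeometric tests, habitat tabulation |
| `rupestre.synthetic_data` | Yule trees, distance-decay community generator |
| `rupestre.pipeline` / `rupestre.cli` | staged runner, manifest, click CLI |

See `docs/methods.md` for the statistical details and parameter defaults.
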