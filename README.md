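# rootscape

Root system architecture (RSA) phenotyping and clustering for seedling
root scans, built for diversity-panel studies in which hundreds of
genotypes are imaged on blue germination paper at several days after
germination and genotyped with a SNP chip.

The package covers the full analysis path:

1. **Imaging** — segment the root from the blue paper by a single HSV hue
   threshold (H > 175° is background, with an automatic Lab-lightness
   fallback for oversaturated frames), thin the mask to a medial skeleton,
   and extract closed shape outlines.
2. **Traits** — the full ARIA-style trait set per plant: total/primary root
   length (TRL, PRL), depth and width (DEP, WID), convex and network areas
   (CVA, NWA), solidity and its inverse (SOL, SOL2), length distribution
   (LED = TRLUpper/TRLLower), lateral root branches and angles (LRB, LRA),
   rhizosphere area (RHZO), volume, centroid depth profiles, and growth
   rates across imaging days.
3. **Phenotype statistics** — Tukey-fence outlier removal, then the
   random-effects model

   y_ik = μ + g_i + b_k + e_ik

   per trait and day, with g ~ N(0, σg²) the genotype effect, b the block
   (growth chamber) effect, and e ~ N(0, σe²).  `RootTraitModel.fit()`
   returns variance components, BLUPs (shrunken genotype means), the
   genotype F test, and broad-sense heritability on an entry-mean basis,
   H² = σg² / (σg² + σe²/r) with r replications.  Tukey HSD and VIF
   (collinearity) diagnostics round out the stage.
4. **iRoot ideotypes** — direction-aware rank sums over named trait sets
   (nutrient foraging, drought tolerant, umbrella, beard, maximum); lower
   rank sums are better.
5. **Clusters** — genotype-based (Ward linkage on allele-sharing distance
   from MAF-filtered SNPs, with BIC-guided cluster-count selection, PCA,
   and pairwise Hudson FST between clusters), phenotype-based (complete
   linkage on 13 z-scored trait BLUPs), and shape-based (elliptic Fourier
   mean shapes → convolutional autoencoder latents → k-means), each
   relabeled A..H by the stage's ordering rule, plus cross-tabulations
   against metadata and ideotype ranks.
6. **Synthetic study generator** — rendered root images with known
   geometry, phenotypes with known variance components, Balding–Nichols
   SNP panels with known subpopulations, and silhouette shape families,
   so every stage is testable offline against ground truth.

## Worked example

Fit the random-effects model to a simulated 292-genotype panel with 14
replications (σg² = 1, σe² = 2), the design for which the analytic
entry-mean heritability is 1 / (1 + 2/14) = 0.875:

```python
from rootscape import RootTraitModel, SyntheticStudyConfig, simulate_phenotypes

config = SyntheticStudyConfig(
    n_genotypes=292, n_replicates=14, days=(9,),
    sigma_g2=1.0, sigma_e2=2.0, seed=7,
)
table, truth = simulate_phenotypes(config)
results = RootTraitModel(table, "value", day=9).fit()
print(results.summary())
```

```
Root trait random-effects model
==============================================
trait: value    day: 9    n obs: 4088
genotypes: 292    replications (median): 14
----------------------------------------------
mu               9.975
sigma_g^2      0.95896
sigma_b^2   0.00063979
sigma_e^2       2.0845
H^2 (entry-mean)   0.8656
genotype F(291, 3795) = 7.438, p = 6.61e-211
==============================================
```

The estimated components (σ̂g² = 0.96, σ̂e² = 2.08) recover the simulation
truth, H² lands near the analytic 0.875, and the F test confirms a real
genotype effect.  `results.blups` holds the shrunken genotype means used
downstream by the ideotype scoring and phenotype clustering:

```python
from rootscape import score_categories, DEFAULT_CATEGORIES
import pandas as pd

blups = pd.DataFrame({"value": results.blups})  # one trait here; use 13 in a study
```

A full synthetic study (images → traits → BLUPs → iRoot → GBC/PBC/SBC →
cross-tabs) runs from one config:

```sh
rootstudy run config.yaml --out study_run
```

and writes every stage output plus a `MANIFEST.json` with checksums; the
same config and seed reproduce identical files.

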