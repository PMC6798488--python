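# nucmorph

Quantitative nuclear histomorphometry for H&E tissue images of ductal
carcinoma in situ (DCIS), and more generally for any cohort of segmented
nuclei masks paired with grayscale intensity images.

Pre-invasive breast cancer is risk-stratified by gene-expression assays
such as the Oncotype DX DCIS score (0–100, categorized low < 39,
intermediate 39–54, high 55–100), which are expensive and
tissue-destructive. Computational pathology offers a complementary route:
measure the *morphology* of the cancer nuclei — their shape, chromatin
texture, orientation coherence, and spatial arrangement — directly from
digitized slides, and ask whether those measurements separate the risk
categories. `nucmorph` implements that measurement-and-evaluation
pipeline as a tested, reusable library for image analysts and
computational pathology researchers.

## What it computes

From each image (nuclei label mask + grayscale intensity), **241 named
features** in five families:

| family | count | prefix | content |
|---|---|---|---|
| Global Graph | 51 | `graph_` | Voronoi cell area/perimeter/chord, Delaunay triangle/edge, MST edge statistics; neighbor counts in radii 10–50 px, k-NN distances (k = 3, 5, 7), sliding-window density |
| Shape | 100 | `shape_` | per-nucleus enclosing-circle ratios, radial-distance statistics, smoothness, Hu moments 1–7, boundary fractal dimension, Fourier descriptors 1–10, eccentricity; aggregated by mean/sd/median/min-max ratio |
| Cell Orientation Entropy (CORE) | 39 | `core_` | 13 second-order (Haralick-family) statistics of orientation co-occurrence among CCG neighbors, aggregated by mean/sd/range |
| Cell Cluster Graph (CCG) | 25 | `ccg_` | local subgraph connectivity: components, density, eccentricity/diameter/radius, clustering coefficients, edge-length statistics |
| Haralick Texture | 26 | `har_` | 13 GLCM statistics of within-nucleus gray levels (64 levels, distance 1, 4 directions), aggregated by mean/sd |

Throughout, `disorder = 1 − 1/(1 + sd/mean)` is the bounded
coefficient-of-variation statistic, and the Bhattacharyya distance uses
the Gaussian closed form
`D = ¼(μ_a−μ_b)²/(σ_a²+σ_b²) + ½ ln((σ_a²+σ_b²)/(2σ_aσ_b))`.

On top of feature extraction the package provides:

* **four feature rankers** — |point-biserial correlation|, Wilcoxon
  rank-sum p-value (exact enumeration for both classes ≤ 10, else
  tie-corrected normal approximation), and greedy mRMR (mutual-information
  difference and quotient variants);
* the **balanced-subsampling cross-validation protocol**: 100 rounds of
  equal-per-class training draws, in-fold top-3 selection, LDA /
  ridge-regularized QDA / linear SVM, Mann–Whitney AUC, and per-round mean
  Bhattacharyya distance of the selected features on the test split;
* **consensus clustering**: top-2 PCA projection, then 50 agglomerative
  clusterings of 80% patient resamples aggregated into a consensus matrix
  and a final 2-cluster cut;
* a **synthetic tissue generator** (elliptical nuclei, hard-core /
  parent–offspring placement, wrapped-normal orientation, tunable texture
  noise) so the whole pipeline is testable against known ground truth.

Rankers and clustering are exposed as scikit-learn-compatible estimators
(`TopFeatureSelector`, `ConsensusCluster`, `RidgeQDA`) and compose with
sklearn pipelines.

## Worked example

```python
import numpy as np
from nucmorph import (TissueParams, generate_tissue, extract_features,
                      CVConfig, run_cv)
from nucmorph.features import FEATURE_NAMES
import pandas as pd

# one synthetic field with strongly disordered nuclear orientations
tissue = generate_tissue(TissueParams(n_nuclei=120, field_size=500,
                                      orientation_disorder=0.9, seed=1))
feats = extract_features(tissue.label_mask, tissue.intensity)
print(len(feats), round(feats["core_mean_info_measure1"], 3))

# CV on a table with three planted discriminative features
rng = np.random.default_rng(7)
X = pd.DataFrame(rng.normal(size=(50, 241)), columns=list(FEATURE_NAMES))
y = np.array(["high"] * 25 + ["low"] * 25)
for f in ("core_mean_info_measure1", "ccg_edge_length_skewness",
          "graph_voronoi_area_sd"):
    X.loc[y == "high", f] += 2.0
res = run_cv(X, y, CVConfig(train_per_class=15, ranking="mrmr_mid",
                            classifier="svm_linear", positive_class="high",
                            seed=11))
print(round(res.mean_auc, 3), "+/-", round(res.sd_auc, 3))
```

prints

```
241 0.288
0.963 +/- 0.062
```

i.e. the disordered field yields the full 241-feature vector with a high
orientation-co-occurrence information measure, and the planted two-sigma
effect is recovered by mRMR + linear SVM at a mean AUC of 0.96 over the
100 cross-validation rounds.

The same stages are scriptable from a shell via the `nucmorph` CLI
(`synth`, `extract`, `cv`, `cluster` subcommands, YAML config).

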