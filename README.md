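# contourcode

Analysis toolkit for how visual cortical neurons (area V4) encode the
geometry of natural contours.  Given contour stimuli (ordered point lists
with a figure–ground label), spike-count tables, and grating-patch
response grids, the package quantifies four contour features inside each
neuron's classical receptive field (CRF), estimates feature tuning with
permutation significance, measures the mutual information between
features and responses, and embeds the population with nonmetric MDS.
A bundled synthetic generator produces stimulus sets with controlled
feature statistics and Poisson model neurons with known tuning, so every
stage is testable by parameter recovery.

Intended users: visual neurophysiologists and computational
neuroscientists replicating or extending contour-coding analyses.

## The quantities at the core

* **CRF**: mean grating responses on a 5×5 position grid are fitted with
  an axis-aligned 2-D Gaussian; the CRF extent is the open 2-SD ellipse
  ((x−cx)²/sx² + (y−cy)²/sy² < 4).  All local feature computations are
  gated by this extent.
* **Closure** ∈ [0,1]: the fraction of 100 radial lines from the CRF
  centre whose first intersection with the contour lies inside the
  extent.
* **Curvature** ∈ (−1,1): circles are fitted to the contour inside
  sliding square windows (scales 1, 3/4, 2/4, 1/4, 1/10 of the patch,
  10-px steps, ≥10 gated points, 80th-percentile error cut, ≤20 kept);
  each raw curvature c = 1/r is squashed by c′ = 2/(1+e^(−a·c)) − 1
  (a = 20) and signed +1/−1 for convex/concave with respect to the
  figure side.
* **Symmetry** ∈ [0,1]: contour points blurred by a 2-px Gaussian; the
  greatest fold-overlap ratio across 24 axes (7.5° apart) through the
  stimulus centre, min–max normalised across the stimulus set.
* **Orientation** ∈ [0,180): the axial (doubled-angle) mean of local
  orientations from point pairs 5 px apart along the gated contour.
* **Tuning**: maps of mean spikes per feature bin, normalised by their
  maximum, fitted with f(x) = a·exp(−(x−b)²/c²) (closure, symmetry;
  0 ≤ a,b,c ≤ 1, strength a/c) or f(θ) = a·cos(θ−c)+d (curvature,
  orientation; strength a).  Significance: the original fit error must
  beat the bottom 1% of the errors of 1,000 shuffled maps.
* **Mutual information**: the plug-in estimator
  I(X;Y) = Σ p(x,y)·log₂ p(x,y)/(p(x)p(y)) on equal-width bins with
  nbin = ⌈1 + log₂ n⌉ per axis, permutation significance at p < 0.05,
  and per-neuron greatest/least-MI ratios against the even split 0.25.
* **Population map**: row-max-normalised response matrix, Euclidean
  dissimilarities, nonmetric MDS minimising Kruskal's Stress-1, with
  NS preference (R_nat − R_sil)/(R_nat + R_sil), equal-count axis
  groups, 30-neuron moving-window profiles and axis regressions.

## Worked example

Simulate a small stimulus set and one closure-tuned Poisson neuron, then
recover its tuning:

```python
import numpy as np
from contourcode import (CRFModel, StimulusSetConfig, generate_contours,
                         NeuronModel, FeatureKernel, simulate_responses,
                         fit_tuning, build_tuning_map,
                         permutation_test_tuning)
from contourcode.pipeline import feature_tables

stimuli = generate_contours(StimulusSetConfig(
    n_patches=60, pool_size=600, seed=0, min_flatness=0.25))
neuron = NeuronModel(
    "v4_sim", crf=CRFModel(center=(34, 34), sd=(12, 12)),
    kernels={"closure": FeatureKernel(kind="gaussian", peak=0.8,
                                      width=0.25)},
    gain=10.0, baseline=1.0, trials=20)
features = feature_tables(stimuli, {"v4_sim": neuron.crf})
responses = simulate_responses([neuron], stimuli.stimuli, features, seed=1)

tm = responses.trial_means().loc["v4_sim"]
geoms = stimuli.geometry_of()
pp = features.per_pair.set_index("stimulus_id")
closure = np.array([pp.at[geoms[s], "closure"] for s in tm.index])
tuning_map = build_tuning_map("closure", closure, tm.to_numpy(float))
fit = fit_tuning(tuning_map)
test = permutation_test_tuning("closure", closure, tm.to_numpy(float),
                               n_perm=1000, seed=0)
print(f"closure tuning: optimum={fit.optimal:.2f}, "
      f"strength a/c={fit.strength:.2f}, rmse={fit.rmse:.3f}")
print(f"permutation test: significant={test.significant}, p={test.p:.4f}")
```

Output:

```
closure tuning: optimum=0.79, strength a/c=3.37, rmse=0.061
permutation test: significant=True, p=0.0010
```

The fitted optimum (0.79) recovers the planted kernel peak (0.8) within
one bin of the 10-bin closure map; the permutation p-value sits at the
floor attainable with 1,000 shuffles.

## Command line

```bash
contourcode simulate --out data/            # synthetic study (contours,
                                            # responses, ground truth)
contourcode validate data/                  # file checks
contourcode crf --grid grid.csv             # receptive-field fit
contourcode analyze --dir data/ --out out/  # tuning + MI + MDS
```

## Acceptance script

`scripts/acceptance.py` regenerates the synthetic stimulus set at the
default configuration (210 patches including mirror pairs), measures the
four contour features of every generated contour under the reference
central CRF, and reports the maximum absolute pairwise Pearson
correlation among them — the stimulus-design independence bound the
analyses rely on.  Run it from the repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
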