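# morphodetail

How much anatomical detail does a statistical shape model need?
`morphodetail` is a research pipeline for measuring the effect of
fine-surface-detail preservation on (a) statistical-shape-model quality and
(b) unsupervised shape categorisation, built around the left atrial
appendage (LAA): clinicians separate LAAs into *chicken-wing-like* (long,
sharply bent) and *non-chicken-wing-like* morphologies, and the blood-pool
surface carries trabeculae — fine ridges and recesses from the pectinate
muscles — that conventional shape analyses smooth away.

Because patient-derived LAA surface meshes are not publicly available, the
package ships a first-class synthetic anatomy generator and runs the whole
study on synthetic cohorts whose fine detail carries class signal by
construction.

## The pipeline

1. **Synthetic cohort** — watertight genus-0 LAA-like meshes: bent tube
   with lobes, plus trabecular detail (template-patterned clefts and
   band-limited texture); class labels CW/NCW with a 21/85 prevalence
   typical of clinical series.
2. **Reduced-detail variants** — oriented surface points thinned by a
   factor R ∈ {2, 4, 8, 16} and reconstructed watertight at a matched
   octree-style depth d ∈ {8, 7, 6, 5}; R = 1 keeps the originals.  All
   shapes normalized to a common volume of 6,000 mm³.
3. **Rigid registration** — moment-based coarse alignment, ICP (2,000
   samples/iteration, rejection distance 10 mm → 0.5 mm), multiview
   refinement until all pairs put 80% of samples within 0.5 mm (achievable
   for low-variability cohorts).
4. **Correspondence + PCA** — multiscale particle correspondence (e.g.
   1,024 particles from 128), then a point-distribution model:
   mean shape, modes, eigenvalues λᵢ, per-shape scores.
5. **Model evaluation** — compactness C(n_m) = Σ_{i≤n_m} λᵢ,
   leave-one-out generalisation Ĝ(n_m) and specificity Ŝ(n_m)
   (mean per-particle distances, mm), per reduction level.
6. **Clustering** — retain the PCs covering 85% of variance in the
   full-detail dataset, cluster the scores (complete linkage, correlation
   distance), pick k by silhouette, and score against the ground-truth
   labels with adjusted mutual information
   AMI = (MI − E[MI]) / (½(H(U) + H(V)) − E[MI]),
   with exact hypergeometric E[MI].

The headline comparison is the AMI of the full-detail ("trabeculated")
dataset versus the 4×-reduced ("simplified") one.

## Worked example

```python
import numpy as np
from morphodetail import (CohortSpec, ExperimentConfig, run_experiment,
                          report_summary)

config = ExperimentConfig(
    cohort=CohortSpec(n_shapes=14, mesh_resolution=1.0, master_seed=0),
    factors=(1, 4), n_particles=256, n_init_particles=32,
    specificity_draws=300, register=False, master_seed=5)
report = run_experiment(config)
print(report_summary(report))
```

prints (a 14-shape desk-scale cohort, ~40 s):

```
 factor  n_modes  compactness  generalisation_mm  specificity_mm  k  silhouette    ami
      1        6       0.8609             0.5537          0.5897  7      0.6013 0.2748
      4        6       0.9406             0.4436          0.5731  4      0.5470 0.1901
```

Read: removing trabecular-scale detail (factor 4) makes the shape model
*better by every classical score* — more variance in the same number of
modes (compactness 0.86 → 0.94), lower unseen-shape error (generalisation
0.55 → 0.44 mm) and more plausible samples (specificity 0.59 → 0.57 mm) —
while the agreement of the unsupervised categorisation with the true
class labels drops (AMI 0.27 → 0.19).  Single desk-scale cohorts are
noisy; the effect is established as a median over seeds in the test
suite.  Model-quality metrics and
downstream scientific utility pull in opposite directions; that tension
is the point of the package.

The same pipeline is available from the shell:

```
morphodetail experiment --seed 1 --out results/
morphodetail generate --out-dir cohort/ --n-shapes 20 --seed 0
morphodetail meshinfo cohort/shape_000.ply
```

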