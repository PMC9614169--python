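# tkp — tridimensional kidney perfusion modelling

Nephron-sparing surgery for small renal tumors increasingly uses **segmental
renal artery clamping**: instead of occluding the main renal artery, the
surgeon clamps only the segmental arteries feeding the tumor region,
converting global renal ischemia to regional ischemia.  Doing this safely
requires knowing, voxel by voxel, *which artery supplies which part of the
parenchyma* — information a plain CT angiogram does not give.

`tkp` implements the computational core of a tridimensional kidney perfusion
model for surgeons and imaging researchers working from segmented contrast
CT.  Starting from label volumes (kidney, sinus/collecting system, binary
artery mask, tumor), it:

1. **labels the artery tree** — thins the vessel mask to a skeleton, roots
   it at the hilum, and groups every lobar branch and its descendants under
   its parent segmental artery (branches "of the same color");
2. **partitions the parenchyma into perfusion territories** — each voxel is
   assigned to the closest lobar artery or branch in physical millimetres
   (a vascular Voronoi partition by distance transform), then lobar
   territories merge into segmental territories;
3. **simulates clamping** — the predicted ischemic region of a clamped
   segment set is the union of their territories, compared to an observed
   region with the **dice coefficient** `2|A∩B| / (|A|+|B|)` (dice > 0.7 =
   high similarity);
4. **derives the clamp plan** — target segmental arteries (territories the
   tumor enters or abuts), feeding lobar arteries, tumor-parenchyma
   **contact surface area** (area-element mesh estimator; spherical-cap
   check `CSA = 2πrh`), and the R.E.N.A.L nephrometry components;
5. **reproduces the cohort statistics** — per-level odds ratios with Wald
   95% CIs (`OR = bc/ad`, `CI = exp(ln OR ± 1.96·SE)`,
   `SE = √(1/a+1/b+1/c+1/d)`) and Pearson chi-square tests from the bundled
   131-patient contingency tables.

Because no imaging data ships with the package, a **synthetic kidney
phantom** (ellipsoidal kidney, hilar sinus wedge, seeded bifurcating artery
tree obeying Murray's law, spherical tumor) generates every structure with
known ground truth, so the whole pipeline runs and validates out of the box.

## Worked example

```python
import tkp
from tkp.pipeline import build_perfusion_model
from tkp.planning import build_plan_report

bundle = tkp.generate_phantom(n_segmental=3, branch_depth=2,
                              tumor_radius=14.0, rng_seed=11)
tree, tmap = build_perfusion_model(bundle.kidney, bundle.sinus_ucs,
                                   bundle.vessels, bundle.truth.root_hint)
report = build_plan_report(tmap, bundle.kidney, bundle.sinus_ucs,
                           bundle.tumor, abut_margin_mm=1.0)
```

Running `python examples/surgical_plan.py` (the script above) prints:

```
target segmental arteries : [1, 2, 3] (clamp these 3)
feeding lobar arteries    : [1, 2, 3, 5] (4 branches reach the tumor)
contact surface area      : 13.31 cm^2 (mesh)
R/E/N/L components        : R=1 (diameter 2.8 cm), E=2 (36% exophytic), N=2 (4.6 mm to sinus), L=2 (crosses_polar_line)
nephrometry total         : 7 (4 = simplest, 12 = most complex)
```

The 2.8 cm tumor straddles all three segmental territories, so selective
clamping needs all three arteries; four lobar branches reach within 1 mm of
it; the contact surface area and nephrometry total grade its complexity.
`examples/phantom_pipeline.py` closes the loop against ground truth — the
clamped segment's predicted ischemic region overlaps the phantom's true
territory at dice 0.9937 — and `examples/cohort_odds_ratios.py` prints the
cohort odds-ratio table (e.g. tumors ≤ 4 mm from the sinus carry OR 9.78,
95% CI 2.53–37.80, for needing 3–5 feeding lobar arteries).

A thin CLI mirrors the stages (`tkp phantom | tree | territories | clamp |
plan | dice | stats | run`); see `tkp --help`.

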