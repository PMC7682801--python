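# cardiomorph

Statistical shape analysis of the left ventricle for two-group
cardiovascular cohorts, together with the standard closed-form vascular
indices that accompany such studies.

## What problem this solves

Conventional cardiac MR reporting reduces the left ventricle to a handful of
global numbers (mass, volumes, mean wall thickness).  Subtle but systematic
differences in *where* the myocardium sits — e.g. a diffuse concentric
thickening without any change in length or cavity diameter — can be
invisible to those summaries.  The established remedy is a **statistical
shape atlas**: corresponded surface meshes x_j ∈ ℝ^{3N} are rigidly aligned,
their mean x̄ is the cohort's average anatomy, and PCA of the shape
covariance yields orthonormal modes of variation v_i with eigenvalues λ_i.
Each subject gets a per-mode score in SD units,

    s_ij = v_iᵀ(x_j − x̄) / √λ_i ,

and group differences are tested mode-by-mode (unpaired t-test), then
re-tested after forced-entry OLS adjustment for blood pressure to ask
whether a shape difference is merely a blood-pressure footprint.

`cardiomorph` implements that pipeline end-to-end for anyone studying
exposure-related LV remodelling (the motivating use case is a history of
hypertensive pregnancy vs normotensive pregnancy in midlife):

- **`cardiomorph.synthetic`** — a seeded generator of two-group cohorts of
  corresponded half-ellipsoid LV meshes with a planted, purely
  wall-thickness group effect, plus calibrated clinical covariates and raw
  vascular measurements; every downstream stage is testable against ground
  truth.
- **`cardiomorph.mesh`** — the corresponded mesh data model, short-axis
  contour stacks, reconstruction of meshes from contours, and per-mesh
  measurements (thickness map, cavity volume, myocardial mass).
- **`cardiomorph.atlas`** — rigid landmark alignment (centre of mass, basal
  plane → +z, LV→RV direction → +x) and the PCA atlas as a
  statsmodels-style pair: `ShapeModel(meshes).fit()` returns a
  `ShapeAtlasResults` with eigenvalues, explained fractions, SD-unit
  scores, `summary()`, ±k·SD shape synthesis and projection of held-out
  meshes.
- **`cardiomorph.modestats`** — per-mode two-group t-tests, forced-entry
  OLS adjustment (unstandardised β reported), two-sample sample-size
  arithmetic and Monte-Carlo empirical power of the whole pipeline.
- **`cardiomorph.vascular`** — aortic compliance (ΔA/A_min) and
  distensibility (compliance/PP), global aortic means, carotid–femoral
  pulse wave velocity, capillary density, Du Bois BSA indexing.
- **`cardiomorph.pipeline`** — "Table 1" group comparison with automatic
  test selection (Shapiro–Wilk → t or Mann–Whitney; χ² for categories),
  blood-pressure adjustment sweeps with a persistence flag, subgroup
  dose–response summaries, sensitivity re-runs, and `run_pipeline` which
  writes a fully deterministic report directory.

A thin CLI mirrors the stages:
`cardiomorph simulate|atlas|modes-test|indices|report`.

## Worked example

Simulate a cohort of 200 + 200 with the default calibration (a 0.3 mm
concentric wall-thickness effect in the exposed group), fit the atlas and
test the modes:

```python
from cardiomorph import (CohortConfig, simulate_cohort, cohort_frame,
                         build_atlas, compare_modes, adjust_mode,
                         thickness_mode_selector, append_indices)

cfg = CohortConfig(n_per_group=200, seed=0)
meshes, records = simulate_cohort(cfg)
frame = append_indices(cohort_frame(records))
atlas = build_atlas(meshes, prealigned=False, subject_ids=frame["subject_id"])
print(atlas.summary().head(7))

mode = thickness_mode_selector(atlas, frame)          # -> 5
comp = compare_modes(atlas.scores_sd, frame["group"], n_modes=6,
                     group_order=("normotensive", "hypertensive"))
print(comp.table)
```

```
 mode  eigenvalue_mm2  explained_fraction  cumulative_fraction
    1       3465.9169              0.3815               0.3815
    2       2765.2488              0.3044               0.6859
    3       1870.9944              0.2060               0.8919
    4        600.2279              0.0661               0.9579
    5        128.5884              0.0142               0.9721
    6         45.9977              0.0051               0.9771
    7          1.9721              0.0002               0.9774

 mode  mean_normotensive  mean_hypertensive       t  df      p
    1             0.0007            -0.0007  0.0148 398 0.9882
    2             0.0687            -0.0687  1.3760 398 0.1696
    3             0.0969            -0.0969  1.9446 398 0.0525
    4             0.0461            -0.0461  0.9216 398 0.3573
    5            -0.2949             0.2949 -6.1663 398 0.0000
    6             0.0198            -0.0198  0.3960 398 0.6923
```

The nuisance modes (length, diameter, apex position/tilt) dominate the
variance; the planted thickening surfaces as the small-variance mode 5
(1.4% of shape variance), and only that mode separates the groups — the
exposed group sits +0.29 SD higher.  The difference survives adjustment for
office systolic blood pressure:

```python
adjust_mode(atlas.scores_sd[:, mode-1], frame["group"],
            covariates=frame[["sbp_office"]]).summary()
#  term   beta     se    p covariates   n
# group 0.5389 0.1035  0.0 sbp_office 400
```

(β is the adjusted group difference in SD units of the mode score.)  The
vascular calibration is carried along in the same table:

```
              functional_capillary_density  global_compliance
hypertensive                       105.643              0.242
normotensive                       116.117              0.256
```

`docs/methods.md` describes the model, the generator's study conditions and
the numerical choices in detail.

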