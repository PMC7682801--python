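# Methods

## The model

`cardiomorph` implements a point-distribution statistical shape model of the
left ventricle and the cohort statistics that are usually run on top of one.
Each subject's LV is a corresponded two-surface mesh: `2 · n_long · n_circ`
nodes in a fixed `(surface, longitudinal level, circumferential index)`
ordering, so node *k* refers to the same anatomical location in every
subject.  After rigid alignment, the meshes are stacked as shape vectors
x_j ∈ ℝ^{3N} (concatenated coordinates, mm), and the sample covariance of the
centred vectors (divisor n−1) is eigendecomposed:

- mean shape x̄ — the cohort "average anatomy";
- modes v_i (orthonormal eigenvectors) — directions of anatomic variation;
- eigenvalues λ_i (mm²), sorted descending, with explained fractions
  f_i = λ_i / Σλ;
- subject scores in SD units, s_ij = v_iᵀ(x_j − x̄)/√λ_i, which by
  construction have sample mean 0 and SD 1 per mode.

PCA runs on raw coordinates with **no size normalisation**: ventricular
length is a legitimate anatomical mode and must not be scaled away.  When
3N > n the eigendecomposition goes through the n×n Gram matrix (exact and
cheaper); eigenvalues below 10⁻¹⁰·λ₁ (or below coordinate round-off for an
all-identical cohort) are truncated.

**Alignment** is landmark-based and rigid, with no iterative Procrustes
refinement and no scaling: node centroid to the origin; the least-squares
basal plane (through the basal-level nodes of both surfaces) rotated so its
normal — oriented apex→base — is +z; the LV→RV centroid direction, projected
into the basal plane, rotated to +x.  The rotation is proper by
construction.  Alignment fails, by design, when the LV→RV direction is
parallel to the basal normal.

**Mode signs.** Eigenvectors are sign-ambiguous, so each mode is oriented so
that moving +1 SD from the mean *increases* mean wall thickness, computed
from the linearised (directional-derivative) thickness change — the finite
+1 SD step is not odd in the vector and would mis-orient thickness-neutral
modes.  Modes with no linearised thickness response are oriented by the
sign of their largest-magnitude component, which is stable under
eigensolver perturbation.  This makes ±3 SD renders and the sign of group
differences reproducible across runs.

## Mode statistics

Group contrasts on mode scores use the unpaired equal-variance Student
t-test (two-sided), reported mode-by-mode for the first 20 modes with raw
p-values; Bonferroni correction is available but off by default, matching
how per-mode shape panels are conventionally displayed.  Welch's correction
is behind a flag.

Covariate adjustment is forced-entry OLS: score ~ group + covariates, all
terms retained, group coded 0 = normotensive, 1 = hypertensive, and the
*unstandardised* group coefficient β (SD units of the score) reported with
its SE and p.  With no covariates this reduces exactly to the group mean
difference, and its p equals the equal-variance t-test p.  The adjustment
sweep runs one model per blood-pressure characterisation (office/ambulatory
× systolic/diastolic) and flags an effect as persistent only when every
variant keeps p < 0.05.

Sample-size arithmetic uses the two-sample normal approximation
n = 2σ²(z_{1−α/2} + z_{power})²/δ² per group, floored at 2.  The worked
design example (δ = 4.8 g, 80% power at α = 0.01 → 70/group) requires
σ ≈ 8.3 g; that σ is not derivable from first principles here and is an
explicit package assumption.  `empirical_power` closes the loop by running
the whole simulate → align → atlas → t-test chain over replicate cohorts and
measuring the rejection rate of the thickness-linked mode.

A caveat measured during development: because the tested directions are
estimated by PCA from the same cohort, the score t-test is not exactly
calibrated; at n = 70/group and 3N ≈ 2700 the null rejection rate at
α = 0.05 is ≈ 0.052 and power is attenuated by the score–latent correlation
(≈ 0.98 under the default conditions).  Both effects are properties of
atlas-score testing itself, not of this implementation.

## The synthetic cohort generator

The generator exists so that every pipeline stage can be tested against
ground truth.  Each ventricle is a half-ellipsoid shell truncated at the
basal (equatorial) plane: the endocardium has basal radius `r_endo_base`
and long-axis length `length`; the epicardium is the endocardium offset
outward by `wall_thickness` along the surface normal, so ground-truth
thickness is exactly the parameter at every node (a uniform offset was
chosen over a confocal ellipsoid precisely for this testability).  Six
parameters span the variation — length, mid-wall basal radius, wall
thickness, two apex-offset components, apical tilt — mirroring the axes LV
atlases report as their leading modes.  Correspondence is by construction
(fixed grid ordering); no point matching is performed.

Two geometric choices matter and were made deliberately:

- **Concentric thickness.** Diameter is parameterised at the mid-wall
  (`r_endo = r_mid − t/2`).  Thickening then preserves the mid-wall while
  the cavity shrinks and the epicardium expands — physiologically the
  concentric-hypertrophy pattern, and geometrically it makes the thickness
  direction approximately orthogonal to the diameter direction in node
  space.  Had diameter been parameterised at the endocardium, the two
  directions would overlap with cosine ≈ 0.64 and PCA would smear the
  thickness effect across mixed modes, making a thickness-specific mode
  impossible to emulate.
- **Base-anchored tilt.** Apical tilt is a depth-progressive rotation
  (angle ∝ depth), not a rigid rotation — a rigid rotation would be
  removed entirely by alignment and could not act as a shape parameter.
  Apex offset is likewise a base-anchored shear.

Per-node isotropic Gaussian noise (default 0.3 mm) emulates contouring
jitter.  Randomness uses one seed per cohort with counter-derived
per-subject substreams, so enlarging a cohort never reshuffles earlier
subjects and identical configs are bitwise reproducible.

### Default study conditions

Defaults emulate a two-group (normotensive- vs hypertensive-pregnancy
history) midlife cohort of 70 per group.  Values printed in the emulated
study's results are used directly; the rest are field-realistic choices
made once:

| quantity | normotensive | hypertensive | source |
|---|---|---|---|
| wall thickness (mm) | 5.2 (SD 0.8) | 5.5 | printed group means (common SD chosen between the printed 0.7/0.9) |
| LV mass index (g/m²) | 45.9 (SD 6.5) | 51.4 / 49.6 / 49.4 by subgroup (SD 7.1) | printed subgroup means |
| functional capillary density (/mm²) | 115.2 | 103 / 102 / 111 by subgroup | printed |
| anatomic capillary density (/mm²) | 127 | +12 over functional | chosen (post-cuff maximisation exceeds resting) |
| global aortic compliance | 0.258 (SD 0.05) | 0.240 | printed |
| office SBP/DBP (mmHg) | 116/72 | 126/78 | 10 mmHg systolic offset from the design paragraph; absolute levels chosen |
| awake ambulatory SBP/DBP | 117/73 | 120/75 | chosen (reported as not significantly different) |
| central PP (mmHg) | 38 | 42 | chosen |
| PWV (m/s) | 6.8 | 7.4 | chosen |
| age / BMI / chol:HDL | 42 / 25.5 / 3.3 | 42 / 25.8 / 3.5 | similar age and BMI; slightly higher lipid ratio |
| antihypertensive use | 0% | 9% | printed |
| preterm normotensive delivery | 20% | — | chosen (deliberate recruitment) |
| subgroup mix GH/latePET/earlyPET | — | 40/35/25% | chosen |

The group effect is concentrated purely in wall thickness
(`thickness_effect = 0.3 mm`); all nuisance parameters (length SD 6 mm,
mid-wall radius SD 2 mm, apex offset SD 2.5 mm, tilt SD 4°) are drawn
identically in both groups.  Office SBP is weakly correlated (ρ = 0.1)
with the within-group thickness residual: weak, because the emulated study
reports that the shape difference *persists* after blood-pressure
adjustment, which a strong within-group coupling plus the 10 mmHg offset
would contradict.  Aortic site areas taper distally (520/410/330/260 mm²)
and share the subject's latent compliance plus per-site noise; capillary
fields are 6 draws around a subject latent (between-subject SD 19, field
SD 12).

With the printed thickness effect (standardised ≈ 0.37), a single default
cohort detects the thickness mode at p < 0.05 only ~55% of the time — the
marginal significance of a single run is a property of the emulated design,
not a bug.

### What the generator does not emulate

Idealised ellipsoid geometry (no trabeculation, no regional wall-thickness
variation, no papillary muscles); Gaussian parameter variation (the real
cohort's distributional family is unknown); no imaging point-spread or
segmentation bias; covariates are conditionally Gaussian and the
vascular measurements share no latent physiology beyond the group label.
Passing tests therefore demonstrate correctness of the *pipeline machinery*
and its statistical calibration — not that real anatomies satisfy the
half-ellipsoid model.  In particular the absolute myocardial mass of the
synthetic shells (≈60 g for typical parameters) is below clinical values,
because a truncated half-ellipsoid omits the myocardium above the equator;
the `lv_mass_index` cohort column is therefore generated as a calibrated
covariate rather than derived from the mesh.

## Mesh measurements and reconstruction

- **Thickness** is the paired-node distance — deterministic on the
  correspondence grid; a stated approximation for oblique walls (no
  normal-ray casting).
- **Cavity volume** closes the endocardial surface with a planar basal lid
  and sums the divergence theorem over consistently outward-wound
  triangles (1 mL = 1000 mm³); a 48×20 grid is within 0.6% of the analytic
  half-ellipsoid volume and halving the grid step changes it by < 0.5%.
- **Myocardial mass** is (epi − endo) enclosed volume × 1.05 g/mL.
- **Reconstruction** from short-axis contour stacks: contours are resampled
  at equal polar angles about their centroids with the angular datum
  pointing at the RV centroid's basal-plane projection (the basal slice
  fixes the datum for the whole stack, which keeps mesh columns straight
  when apical slices wobble); the surface is interpolated along z with a
  not-a-knot cubic spline in *squared* radius — exact for ellipsoidal
  anatomy — with the apex closure found as the root of a quadratic fit to
  r²(z); endocardial nodes sit at equally spaced z levels, and each
  epicardial node is found by casting the endocardial outward normal onto
  the spline epicardial surface, so paired nodes measure thickness.
  Round-trip error (slice at 10 mm → reconstruct) is < 0.4 mm RMS on a
  noise-free ellipsoid, and shrinks with slice spacing.
- Slice planes start at the basal plane and descend at the acquisition
  spacing; planes whose endocardial ring falls below a 3 mm mean radius are
  dropped (the apical cap is never contoured in practice).  Contour
  validation rejects open or macroscopically self-intersecting polygons and
  epi/endo crossings, while tolerating round-off-scale slivers from noise.

## Group tables and the pipeline

`compare_groups` operationalises the classic test-selection rule:
Shapiro–Wilk at α = 0.05 in *both* groups routes a continuous variable to
Student's t, otherwise Mann–Whitney (medians [IQR] reported); categorical
variables get Pearson χ² without continuity correction (Yates behind a
flag).  The visual-histogram step of the usual protocol is necessarily
dropped.  Constant variables are kept in the table but skipped with a note.
Missing data are complete-case per analysis, with per-analysis n reported.

Subgroup analysis compares each exposed subgroup against the normotensive
reference by t-test (subgroups with < 2 subjects keep their mean, skip the
test) and reports a descriptive dose–response check: "graded" requires the
three exposed subgroup means to be strictly monotone in severity order
*and* the extreme subgroups to differ by more than twice the SE of that
difference — under identically drawn subgroups this fires rarely, as it
should.

`run_pipeline` chains simulate (or load) → slice → reconstruct → align →
atlas → mode tests → BP-adjustment sweeps → vascular indices → group table
→ subgroup and sensitivity re-runs, writing a report directory whose CSV
tables are byte-identical for identical config + seed (the log carries the
seed and a config hash; output paths are excluded from the hash).  Named
sensitivity filters (exclude preterm-normotensive deliveries, exclude
antihypertensive users, exclude current smokers) re-test on strict subsets.

## Vascular indices

All closed-form: compliance = (A_max − A_min)/A_min; distensibility =
compliance / central PP (so distensibility × PP = compliance exactly);
global aortic values are available-case means over the four sites (AA, PDA,
distal descending, abdominal), with missingness flagged.  PWV uses the
subtracted-distance convention — both paths are measured from the sternal
notch, so v = (d_fem − d_car)/(t_fem − t_car); this is the combination rule
implied by notch-referenced distances.  Capillary density is the mean of
exactly 6 fields (a relaxed available-case mode exists behind a flag).
BSA is Du Bois by default (Mosteller behind a flag).

## Problem sizes used in the shipped tests

Unit tests run on 16×6 to 24×10 grids with 10–40 subjects; the Monte-Carlo
calibration checks use the full study conditions (70/group, 32×12 grid)
with 1000 null replicates and 500 power replicates; the acceptance script
uses 500 replicates per rate.  These sizes were chosen so the whole suite
completes in a few minutes while keeping binomial standard errors below
0.01 on the calibrated rates.

## Known limitations

- Paired-node thickness under-reads obliquely sheared walls.
- The atlas-score t-test inherits the mild PCA-overfitting miscalibration
  discussed above; permutation tests would remove it but are out of scope.
- The basal plane is taken as the most basal contoured level, and the
  figshare-style deposit adapter returns raw shape vectors when no grid
  metadata is present (mesh-based measurements then unavailable).
- One-/two-sided conventions: all reported p-values are two-sided.
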