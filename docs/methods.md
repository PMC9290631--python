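# Methods

## Scope and overall design

`gmshore` reconstructs a two-group gray-matter microstructure analysis —
PPMS vs. RRMS multiple sclerosis phenotypes — as a closed, synthetic
pipeline: cohort simulation → per-voxel DTI/3D-SHORE index computation →
regional moment features → factorial ANCOVA → Fisher-score/LOOCV
consensus SVM. Because no cohort of this design is publicly deposited,
every quantitative claim a test makes is about the synthetic world the
generator defines; the demographics and all structural constants (group
sizes, acquisition scheme, ROI list, feature counts, SVM cost and cost
grid) are taken from the published study design.

## Acquisition model

The default scheme has 7 b=0 volumes, 32 directions at b = 700 s/mm² and
64 at b = 2000 s/mm² (103 measurements). Direction sets are built
deterministically: Fibonacci-hemisphere initialization followed by 200
sweeps of antipodally-symmetric electrostatic repulsion (minimum pairwise
angles ≈ 24.5° / 17.0° for the 32- and 64-direction sets). q-space radii
use the narrow-pulse convention q = √(b/4π²τ).

## Synthetic voxel model

Each gray-matter voxel is a two-compartment Gaussian mixture:

* a "tissue" tensor, axially symmetric with axial/radial diffusivities
  1.0/0.5 × 10⁻³ mm²/s (mild anisotropy, as in cortical/deep GM);
* a faster quasi-free compartment, isotropic 1.8 × 10⁻³ mm²/s;
* baseline volume fractions 0.8/0.2, jittered per voxel
  (SD 0.05, clipped to [0.05, 0.95]);
* per-subject multiplicative diffusivity variation (SD 3%);
* per-ROI orientation fields fixed across subjects (a property of the
  synthetic anatomy), varied across voxels.

Magnitude noise is Rician, built from two Gaussian channels with
σ = s0/SNR (default SNR 30 at b0). Group effects enter as per-ROI
multiplicative shifts: the default world gives the progressive group a
10% hippocampal diffusivity increase (i.e. a restriction deficit:
RTOP/RTAP/RTPP fall, MD/MSD rise) and a 15% thalamic volume reduction.
These defaults are deliberately strong (subject-level Cohen's d ≈ 3) so
that recovery is a property of the method, not of luck; they are the
ground truth the ANCOVA and the SVM selection are tested against.
Morphometry baselines (volumes ≈ 7.7/3.6/5.0/4.0 cm³ for thalamus/
caudate/putamen/hippocampus, thicknesses 1.6–3.0 mm, eTIV 1.5 L) are
generic adult values with ~8% SDs.

Demographics: ages and disease durations are truncated normals at the
published group means/SDs clipped to the published ranges (rejection
sampling, hence exact range compliance); EDSS is rounded to 0.5 steps;
the sex split matches the published female/male counts proportionally.
Sex is generated for demographic tests but unused downstream, matching
the described models.

What the generator does **not** emulate: white-matter lesions, partial
volume with CSF/WM at ROI borders, registration error, motion/eddy
artifacts, scanner drift, spatial noise correlation, or hemispheric
asymmetry (ROIs are generated hemisphere-merged). A green recovery test
therefore establishes the correctness of the estimation and selection
machinery, not clinical performance.

## DTI stage

Weighted log-linear least squares (weights = squared signal) on the b=0
and b=700 measurements only; the b=2000 shell is excluded by design and
the fit is bit-identical with or without it. FA/MD use the standard
eigenvalue formulas; FA of the zero tensor is defined as 0.

## 3D-SHORE stage

Basis: φₙₗₘ(q**u**) = κ(ζ,n,l) (q²/ζ)^{l/2} e^{−q²/2ζ} Lₙ₋ₗ^{l+1/2}(q²/ζ) Yₗₘ(**u**),
l even, enumerated shell-wise (50 coefficients at radial order 6),
orthonormal over q-space. Defaults and their rationale:

* **τ = 0.025 s** — a typical clinical diffusion time; indices are
  reported together with τ so values are comparable within a run.
* **N_max = 6** — the standard radial order for two-shell data.
* **λ_N = λ_L = 1e-8** on diagonal roughness penalties (n(n+1))² and
  (l(l+1))² — the two-shell scheme samples only three radii, so the
  radial subspace is underdetermined and a (minimal) penalty is
  mandatory; fitting with both penalties zero on such a scheme raises.
* **ζ = 1/(8π²τ·median MD)** per voxel block — with this scale an
  isotropic Gaussian voxel at the typical diffusivity is exactly the
  first basis function, which is why matched isotropic oracles are
  reproduced to machine precision.
* Signals are normalized by the mean of the b=0 volumes before fitting.

Indices are computed from the fitted coefficients via q-space identities
(no explicit propagator reconstruction): RTOP = ∫E d³q; RTPP = ∫E(q·axis)dq;
RTAP = plane integral of E, using ∮Yₗₘ over a great circle = 2πPₗ(0)Yₗₘ(axis);
MSD = −∇²E(0)/4π² (only l = 0 contributes). All radial integrals reduce
to dimensionless constants precomputed once by 400-node Gauss–Legendre
quadrature and rescaled analytically in ζ. GFA is std/rms of the
constant-solid-angle ODF (radial Hankel transform of the basis,
precomputed numerically) sampled on a fixed 724-direction
Fibonacci-antipodal sphere. PA is sin θ between the coefficient vector
and its l = 0 projection (the best isotropic approximant in an
orthonormal basis), mapped through the standard scaling sigmoid
t^{3ε}/(1 − 3t^ε + 3t^{2ε}) with ε = 0.4. The RTAP/RTPP reference axis
is the voxel's DTI principal eigenvector — well defined even in the
low-anisotropy GM regime and standard practice.

**Accuracy envelope (measured).** The index formulas themselves agree
with brute-force q-space quadrature to ~1e-13. End-to-end accuracy
against closed-form Gaussian propagators is limited by representation:
with two shells at b ≤ 2000 and order 6, the error grows monotonically
with the tensor's eigenvalue ratio λ₁/λ₃ — ≤0.5% at ratio ≤ 2 (the GM
regime), ~6% at 2.5, up to ~40% at ratio ≈ 20. Higher radial order
(8, 10) and other penalty weights do not improve the worst case; the
limit is the acquisition, not the solver. Consequently the
RTAP·RTPP = RTOP factorization of a separable Gaussian holds only to
~2% for mild prolates in the fitted representation.

## Regional features

Six moments per (index, ROI): sample mean and median; SD with the n−1
denominator; bias-uncorrected skewness g₁ and excess kurtosis g₂ (a
constant sample defines all three as 0); the mode of a continuous sample
is the center of the most populated histogram bin (Freedman–Diaconis
width, Sturges when the IQR is 0, ties toward the lowest bin, bin count
capped at 2¹⁶ against outlier-driven blowup). Voxels are pooled across
hemispheres before moment computation (the synthetic anatomy is
generated hemisphere-merged); pooling-before versus averaging-after
differs for the non-linear moments, and pooling was chosen as the
convention. Volumes are divided by the subject's eTIV; thicknesses are
raw mm. Any NaN feature aborts table assembly — a complete-case design,
no imputation. Column identity 8·6·11 + 4 + 7 = 539 is asserted at
construction.

## Statistics

Demographics: pooled-variance two-sample t-test (it reproduces the
published p-values from the printed summaries, and "unpaired two-sample
t-test" classically means the pooled form) and Pearson chi-square
without continuity correction.

ANCOVA: per index, the long table of subject × ROI × moment observations
is fitted with fixed effects DISEASE × ROI × FEAT (all interactions)
plus age, disease duration, and EDSS as covariate main effects;
morphometry uses DISEASE × ROI. Factors are sum-to-zero coded and each
term is tested with a Type III F (full-vs-reduced RSS), which matches
`statsmodels anova_lm(typ=3)` to 1e-8 in the test oracle. Rows within a
subject are treated as independent — the classical factorial reading of
this design. *Caveat:* this ignores within-subject correlation across
ROIs/moments, so the factorial p-values are anticonservative for
correlated features; the null-calibration test passes because the
synthetic null generates independent rows. Post-hoc disease contrasts
within each ROI(×FEAT) cell are covariate-adjusted differences of
predicted means (PPMS − RRMS, covariates at their sample means),
Bonferroni-multiplied by the family size (66 for the three-way grid, 11
for morphometry), significance at 0.05 with the usual star convention.
Covariate-by-factor interactions are not modeled (unstated in the
design; main effects only).

## SVM selection

Step 1 computes, per LOOCV fold, Fisher scores on the training subjects
only, ranks all features (stable sort, ties by column order), and for
each cutoff n trains a linear SVC (libsvm SMO, C = 0.4662 by default)
on the top-n features after standardization with training-fold
statistics (zero-variance features map to 0 with a warning); the
held-out subject is classified by the same transform. Rankings cannot
depend on n, so one ranking per fold is stored and the N × M
"tested models" accounting is exposed as a replicated view (identical
ordering, counts × N). Step 2 scans n upward, updating on
accuracy ≥ incumbent AND variance ≤ incumbent (variance = sample
variance of the fold 0/1 outcomes); note that on a cohort where
accuracy saturates at 1.0 the tie-accepting rule walks n_opt to N —
literal rule behavior. Step 3 counts occurrences in the first n_opt
positions across folds; ties break by better mean ranking position,
then lexicographic name (determinism). The final report evaluates the
selected features by LOOCV: confusion matrix with true PPMS/RRMS rows,
accuracy, sensitivity/precision with RRMS as the positive class (this
convention reproduces the published worked-example precision from its
confusion counts), specificity, and a ROC with trapezoid AUC from the
held-out decision values. `optimize_cost` scans the literal 100-point
linear grid from 0.0005 to 512 (the published default cost 0.4662 does
not lie on that grid; reported, not resolved) with ties to the smallest
cost. The whole procedure is deterministic given a feature table: the
fold order is the row order and no RNG is used.

Leak-freedom is tested two ways: corrupting a held-out row cannot change
that fold's ranking, and selection on a pure-noise cohort stays at
chance accuracy.

## Numerical and degenerate-input choices

* Fisher score: 0/0 → 0; positive/0 → +inf (ranked first).
* t-test with zero pooled variance: p = 1 for equal means else p = 0.
* Non-finite SHORE coefficients → NaN indices with a logged warning,
  never an exception; a failed voxel is NaN in *all* eight maps.
* b ≤ 10 s/mm² counts as b = 0; bvecs off unit norm by >1e-6 at b > 0
  are renormalized on read with a warning.
* All tables are TSV with `.` decimals; floats print with %.17g so the
  feature table round-trips bit-exactly.

## Known limitations

* Index accuracy degrades with anisotropy (see envelope above); for
  white-matter-like tensors this pipeline underestimates RTOP/RTAP.
* The factorial ANCOVA ignores subject-level random effects (above).
* The synthetic world's effect sizes are strong by construction; the
  pipeline's published-scale performance numbers (70% accuracy etc.)
  are properties of the unavailable clinical cohort and are not
  reproduced here — only the worked-example arithmetic on the printed
  confusion counts is checked.
* `robust_mode` is histogram-based and bin-width sensitive; it is
  compared bin-exactly, not as a density estimate.
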