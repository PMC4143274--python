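# Methods

## The scientific question and the modeled quantities

After a mild-to-moderate ischemic stroke or TIA, cognitive state a year later
may be driven less by the new infarct than by the brain's preexisting
white-matter condition. The package operationalizes that question with five
observed quantities per subject: age and education (demographics), the
volume of chronic white-matter lesions (WML, FLAIR-hyperintense), a
single "NAWM integrity" factor summarizing the diffusivity of
normal-appearing white matter, and a global cognitive score (standardized
scale, mean 100, SD 15). A sixth, the acute ischemic lesion volume (ILV),
distinguishes the two competing path models:

* **Model 1** (with ILV): education → cognition; age → WML; age → integrity;
  WML → cognition; integrity → cognition; WML → ILV; ILV → cognition.
* **Model 2** (without ILV): the same minus ILV and its two paths.

Age is deliberately not given a direct path to cognition: the cognitive
score is age-normalized, and adding the direct path would over-adjust the
age-mediated effects of interest.

## Synthetic phantoms

The phantom is intentionally minimal geometry with exactly known labels:
an axis-aligned brain ellipsoid (semi-axes 0.94 of the half-extent), a
central ellipsoidal CSF compartment (0.28 of the brain axes), an outer
gray-matter band (elliptical radius > 0.85), a white-matter interior, and
spherical lesions at user-specified voxel centers. Spheres must lie fully
inside the brain and may not overlap each other; both conditions are
validated and violations rejected. Sphere volumes are analytically
checkable by voxel enumeration.

Signals: FLAIR and b0 intensities are per-class truncated Gaussians
(default bounds ±1.5 within-class SD). The truncation is a deliberate
modeling choice: an unbounded Gaussian puts a fixed ≈2.3% of reference
tissue above any mean + 2 SD threshold however clean the image, which no
amount of averaging removes; real parenchymal intensity spread is bounded,
and the truncated model lets a clean phantom be exactly separable while the
separate acquisition-noise dial (Gaussian, or Rician as the magnitude of a
complex Gaussian) restores realistic tails when wanted. Defaults: white
matter and gray band FLAIR 300 ± 10, CSF 120 ± 10 (arbitrary units); lesion
FLAIR offset +4 reference SD.

Diffusion: each class carries a diagonal tensor profile (eigenvalue mean ±
jitter SD, mm²/s) — white matter (1.2, 0.78, 0.55)·10⁻³, WML
(1.6, 1.1, 0.97)·10⁻³ (both at typical adult values), near-isotropic gray
matter and CSF, and restricted-diffusion acute ischemia
(0.40, 0.35, 0.30)·10⁻³. The 15-direction series (Fibonacci-sphere
gradients, b = 1000 s/mm²) follows S = S₀·exp(−b·gᵀDg) exactly before
noise, so acute lesions are DWI-hyperintense and chronic WML are not —
the physical basis of the DWI conjunction rule. Everything is a pure
function of (spec, seed); identical specs give bit-identical volumes.

What the phantom does **not** emulate: cortical folding, partial-volume
mixing at tissue boundaries, anatomically realistic periventricular lesion
placement, multi-shell diffusion, motion/eddy artifacts, bias fields.
Passing phantom tests therefore demonstrates correctness of the
computational chain, not expected accuracy on clinical images.

## Simulated cohorts

Cohort tables are drawn from a user-specified recursive path model:
exogenous variables from a unit-variance multivariate normal with the
requested correlations, each endogenous variable as its parents' weighted
sum plus independent Gaussian noise, generated in topological order. With
auto-computed residual SDs every variable has unit variance, so the edge
weights are the model-implied standardized coefficients, and the implied
correlation matrix is available in closed form for convergence checks.
Skewed variables (lesion volumes) are exponentiated and rescaled back to
the target mean/SD — monotone, so rank statistics are unaffected. Default
path weights for the study-like generator: age → WML 0.306,
age → integrity 0.370, WML → cognition −0.231, integrity → cognition
−0.176, education → cognition 0.328, with corr(age, education) = −0.10.

## Tensor estimation and maps

Ordinary least squares on log-signals: one shared pseudo-inverse of the
(directions × 6) design solves every voxel at once. Multiple b0 volumes are
averaged first; a non-positive b0 marks the voxel invalid; at least one b0
and six non-collinear gradients are required (design rank checked).
Negative eigenvalues, possible under noise, are clamped to zero and the
voxel flagged. Eigenvalues are sorted descending, which defines
Da = λ₁ and Dr = (λ₂+λ₃)/2 unambiguously; MD is computed as
(Da + 2·Dr)/3 so the identity holds bitwise;
FA = √(3/2)·‖λ−λ̄‖/‖λ‖ with FA ≡ 0 for an all-zero tensor. Maps are
computed on unsmoothed fits. Nonlinear (Rician-aware) estimators,
eddy/motion correction and tractography are out of scope; the OLS
log-linear estimator is the deterministic, closed-form baseline and is
validated against a per-voxel nonlinear least-squares fit in the tests.

## Segmentation

The two-cluster FLAIR step runs k-means (k = 2) on the absolute deviation
of intensity from the robust parenchymal mode (the median over the brain),
with fixed quantile-based initialization (25th and 99.5th percentile) —
dark CSF and bright lesions then share the "outlier" cluster, which raw
two-means on intensity cannot achieve. The parenchymal cluster's mean and
SD are the reference statistics; a near-constant image is rejected as
degenerate.

Thresholds are strict everywhere: lesion candidates are brain voxels with
FLAIR > mean + k·SD (default k = 2); the acute/chronic split uses the same
rule on DWI (default multiplier 2, reference = non-hyperintense
parenchyma) — a candidate that is also DWI-hyperintense is acute ischemia,
otherwise chronic WML. Connected components (26-connectivity) smaller than
`min_lesion_voxels` are dropped per class; the default is 0, and small
positive values emulate the known miss of tiny low-contrast infarcts. The
NAWM mask is the parenchymal cluster at FA strictly > 0.2 minus all
detected lesion voxels (the gray band fails the FA cut; WML would pass it,
hence the explicit subtraction). ICV is the brain-mask volume; relative
volumes are 100·volume/ICV. The manual-correction step of semi-automatic
practice is replaced by optional caller-supplied masks (the functions
accept explicit reference/lesion masks).

## Integrity factor

Per-subject mean NAWM eigenvalues are z-scored (they share units but not
scales) and collapsed onto their first principal component; scores are
standardized to mean 0, SD 1. **Sign convention:** the score is oriented to
correlate positively with mean diffusivity, so a higher "integrity" score
means *worse* microstructure, and its expected path to cognition is
negative. The name invites the opposite reading; the orientation is chosen
so coefficient signs match the convention used throughout the package.
Rotated factor solutions and additional components are out of scope.

## Path analysis

The covariance matrix (not the correlation matrix) is analyzed and
standardization applied post-fit, the conventional ML-SEM choice. Free
parameters: one coefficient per edge, every variance (log-parameterized to
enforce positivity), and the explicitly freed covariances; df =
p(p+1)/2 − #free. For the five-variable Model 2 the freed parameters are
the age↔education covariance and the WML↔integrity *residual* covariance;
the latter is required to obtain df = 3 and reflects the strong empirical
association between lesion burden and surrounding-tissue integrity beyond
their shared age dependence. Model 1 under the same parameterization has
df = 6; its spec is user-editable if another parameterization is wanted.

Fitting minimizes F = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with the analytic
gradient (dF/dΣ = Σ⁻¹(Σ−S)Σ⁻¹ chained through the parameterization),
L-BFGS-B from a closed-form start (per-equation regression solved directly
from S) plus four deterministically jittered restarts, then a Newton
polish on the gradient; convergence is declared at gradient norm < 1e−8,
and non-PD trial points are repelled by a large penalty. χ² = (n−1)·F,
p from χ²(df). The CFI baseline is the independence model (diagonal Σ,
free variances), for which F has a closed form. AGFI and RMSEA are
undefined at df = 0 except that an exactly fitting saturated model reports
RMSEA 0. Model comparison counts the conventional criteria — χ² p > 0.05,
CFI > 0.95, GFI > 0.95 (Jöreskog form), AGFI > 0.95, RMSEA < 0.08 — and
breaks ties by CFI; an exact tie is reported as such. Latent variables,
mean structures, FIML and bootstrap SEs are out of scope.

## Statistical battery

Volumes are log₁₀(v + ε) transformed with ε = one voxel volume (default
8 mm³), keeping the many zero-infarct subjects finite and rank order
intact. Correlations are Pearson, or Spearman when a variable is declared
ordinal (the caller decides; NIHSS is the intended ordinal example), with a
strict p < 0.005 flag against multiple comparisons. The regression battery
standardizes outcome and predictors, reports per-predictor unadjusted β
and then one multiple regression on the predictors passing p < 0.05,
refusing collinear sets (condition number > 1e8). ANOVA is one-way across
infarct-location groups, dropping groups with n < 2 with a warning. The
ANCOVA is a linear model with the presence indicator plus log WML volume,
using the Type-II F for the group term.

## Numerical choices and problem sizes

Deterministic seeds everywhere: phantoms and cohorts are pure functions of
(spec, seed); the pipeline derives per-subject seeds from its master seed
and writes uncompressed NIfTI so reruns are checksum-identical. Default
test and acceptance problem sizes are chosen for tight statistical checks
at interactive runtimes: phantoms of 40×40×32 voxels at 2 mm, cohorts of
n = 142 (the study scale), large-n recovery at n = 10⁵, χ² calibration
over 500 replicates at n = 5000, and 100–200-replicate preference/reversal
simulations.

## Known limitations

* The segmentation's two-cluster construction is a documented stand-in for
  the semi-automatic clinical method it mirrors; with acquisition noise the
  2-SD rule still tags a small parenchymal tail, controlled by the
  component-size filter rather than by manual correction.
* The ILV-bearing Model 1 reproduces the intended structure but its df
  depends on the chosen free-parameter set; only the five-variable model's
  df = 3 is pinned down by the documented parameterization.
* Phantom realism is deliberately limited (see above), so quantitative
  claims transfer to clinical data only qualitatively.
* GFI/AGFI variants differ between SEM packages; the Jöreskog ML form is
  used here.
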