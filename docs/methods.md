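# Methods

## Signal model

Each voxel's diffusion-weighted signal is a two-compartment mixture,

S(b)/S0 = f·e^(−b·D\*) + (1−f)·e^(−b·D),

with the perfusion fraction `f` (dimensionless, stored as a fraction),
the vascular pseudo-diffusion coefficient `D*` and the tissue diffusion
coefficient `D` (both stored in mm²/s). The flow-related parameter `fD*`
is always the product of the stored `f` and `D*`, never an independent
quantity. Report layers (group tables, map files) convert to the
conventional display units — percent for `f`, 10⁻³ mm²·s⁻¹ for
diffusivities — so that a silent 10³ unit error cannot arise inside the
computation.

Assumptions inherited from the emulated acquisition:

* **No CSF compartment.** The acquisition suppresses cerebrospinal fluid
  with an inversion-recovery preparation; the model and the phantom simply
  contain none. Differences in relaxation rates between compartments under
  inversion recovery are not modelled.
* **Gaussian tissue diffusion** up to b = 900 s/mm²; no kurtosis or
  multi-exponential tissue term.
* **Isotropy at the trace level.** Directional acquisitions are combined
  into the trace as the geometric mean of the three directional signals
  (equivalently, the arithmetic mean of log-signals/ADCs — the standard
  trace-weighted convention; for mono-exponential directional decays the
  trace is exactly the mono-exponential with the mean diffusivity). The
  measurement convention behind the emulated protocol is not recorded, so
  the geometric mean was chosen and is used consistently.

## Segmented two-step fit

1. **Tissue stage.** Ordinary least squares of ln S on b over b > 200 s/mm²
   with a *free* intercept. The slope gives `D`; the back-transformed
   intercept is the tissue amplitude (≈ 1 − f), which seeds stage 2. A
   fixed unit intercept would bias `D` by the perfusion fraction, which is
   why the intercept is free even though only `D` is reported from this
   stage.
2. **Perfusion stage.** With `D` fixed, (f, D\*) minimize the sum of
   squared residuals over all b-values using `scipy.optimize.least_squares`
   (bounded trust-region reflective, a Levenberg–Marquardt-class method)
   with an analytic Jacobian. Bounds: f ∈ [0, 1],
   D\* ∈ [D, 0.1 mm²/s]. Initialization: f₀ = clip(1 − amplitude,
   0.01, 0.3), D\*₀ = 10·D. Tolerances: xtol 10⁻⁸, ftol/gtol 10⁻¹⁴,
   at most 500 function evaluations.

**The D\* upper bound (0.1 mm²/s) is the identifiability limit of the
default scheme**: the first nonzero b-value is 10 s/mm², so for
D\* ≥ 1/b₁ = 0.1 mm²/s the vascular compartment has decayed essentially
completely before the first diffusion-weighted sample and larger values
only fit noise. Admitting larger pseudo-diffusivities (e.g. a 0.5 bound)
demonstrably corrupts Monte-Carlo moments: the SD of fitted fD\* inflates
until fD\* loses its precision advantage over f and D\*, contradicting the
fit's well-documented behaviour. The bound is configurable (`dstar_max`).

**Validity flags instead of value cut-offs.** A fit is non-physical
(`valid=False`) when f sits at a bound, D\* sits at the upper bound, the
stage-1 D is non-positive (e.g. a flat curve), or the optimizer did not
converge. Such voxels are NaN in maps and such replicates are excluded
(and counted) in simulation moments. No ad-hoc parameter-value cut-off is
ever applied — the same motivation that favours ROI-averaged fitting for
quantitative statistics. A separate `weakly_identified` diagnostic marks
fits with D\*/D < 2, where the compartments barely separate.

### Intrinsic bias of the segmented estimator

Even without noise the two-step fit is biased: the vascular term
f·e^(−b·D\*) has not fully decayed just above the b = 200 threshold, and
the stage-1 log-linear regression absorbs part of it into the slope. The
noiseless relative error scales as e^(−300·(D\*−D)) and is independent of
f and D. Numerically: ≈ 8% at D\* = 9.6×10⁻³ mm²/s, ≈ 0.8% at the
gray-matter resting point (D\* = 17×10⁻³), below 10⁻⁴ only for
D\* ≳ 32×10⁻³. The test suite therefore verifies the exact (≤ 10⁻⁴)
round trip on a grid in the separable regime (D\* ≥ 35×10⁻³) and asserts
the < 1% bias at the gray-matter truth separately. Any analysis of tissues
with small D\* should expect this truncation bias; an iterated or joint
fit would remove it but is deliberately out of scope, since the two-step
procedure *is* the method under study.

### Sampling distribution of D\*

At moderate SNR the sampling distribution of fitted D\* is strongly
right-skewed: the median is essentially unbiased (e.g. 17.8 vs a true
17×10⁻³ at SNR 100) while the mean overshoots by tens of percent because
occasional noise realizations are best fitted by a fast-decaying vascular
term. This is a property of the estimator, not an implementation artifact:
it persists under every variant examined (tighter or looser D\* bounds,
unbounded Levenberg–Marquardt with physicality screening, exclusion of
bound-hitting fits). Consequently *mean-based* recovery of D\* to within
10% is reached only around SNR ≈ 200 under the study conditions, whereas
f and D reach it by SNR 100. `fD*` inherits a milder version of the skew;
its relative SD is nonetheless consistently the smallest of the three
perfusion parameters because errors in f and D\* anti-correlate.

## Monte-Carlo simulations

* **Noise model.** Gaussian noise of SD σ_b is added to the *normalized*
  signal at every b-value (σ = 1/SNR in S/S0 units); values are clipped
  below at 10⁻⁶ to keep log fits defined. A Rician option exists but is
  off by default, matching the Gaussian design of the emulated study.
* **SNR sweep.** Truth f = 4%, D = 0.7×10⁻³, D\* = 17×10⁻³ (rounded
  gray-matter baseline values); constant σ = 1/SNR across b; default grid
  10–400. Reference replicate count 10,000 per SNR; tests use 300–1,000
  (desk scale — moments stabilise well before that for f and D).
* **Parameter sweeps.** f from 0.2% to 20% (step 0.2%) with
  D\* = 17×10⁻³ fixed, or D\* from 0.8 to 30×10⁻³ (step 0.2×10⁻³) with
  f = 4% fixed; D = 0.7×10⁻³ throughout; reference 30,000 replicates per
  point, grid and count overridable for desk-scale runs.
* **Experimental noise profile.** The measured SNR of the emulated
  protocol falls from 107.4 at b = 0 to 34.2 at b = 900 s/mm². The shape
  between the endpoints is not recorded; linear interpolation in b is used
  and configurable.
* **SNR estimator.** From ≥ 3 repeated acquisitions: per voxel and
  b-value, SNR = mean over repeats / SD over repeats; zero-SD voxels are
  excluded; the profile is the mean over masked voxels.
* Replicate streams are driven by a single `numpy` Generator per sweep;
  identical seed + configuration reproduces results bit-for-bit.

## Synthetic study generator

The phantom is a 64×64 single slice (1 voxel ≈ 1 grid unit): a circular
head of radius 28 whose outer ribbon (width 7) is gray matter and whose
core is white matter; the posterior sector (last 12 rows of the head) is
the activated "visual" region, giving four tissues ≥ 20 voxels each. The
activation indicator doubles as a surrogate t-map (t = 10 inside, 0
outside), and binary tissue probability maps accompany it, so ROI
reconstruction by thresholding + probability assignment recovers the
generator's masks exactly.

Defaults mirror the emulated study: 8 subjects, 5 blocks per condition
alternating stimulation/baseline and starting with stimulation, 16
b-values in 3 orthogonal directions acquired once each, per-direction
Gaussian noise following the experimental SNR profile. Per-tissue,
per-condition truths default to the published group means ± SDs (e.g.
activated gray matter f: 3.55 ± 0.59% at rest, 5.34 ± 0.81% under
stimulation; D\*: 17.27 ± 10.17 vs 30.50 ± 18.35 ×10⁻³ mm²/s). Subject
parameters are drawn independently per condition from truncated normals
(f ∈ (0.001, 0.25), D ∈ (0.1, 3)×10⁻³, D\* ∈ (2, 90)×10⁻³); only
marginal summary SDs are available, so no baseline–stimulation correlation
is imposed — paired tests remain valid, merely conservative. A master seed
spawns one stream per subject; identical specs reproduce identical studies.

What the phantom does **not** emulate: partial-volume mixing at tissue
borders beyond the voxel grid, susceptibility artifacts, eddy-current
distortion, motion, Rician noise floors, anisotropic diffusion, and any
CSF contribution. Passing tests therefore demonstrate correctness of the
fitting and statistics pipeline under the stated noise model, not
robustness to those real-data effects.

## Group analysis

Per subject and condition, each ROI value is the arithmetic mean of the
ROI-averaged block fits (block-to-subject aggregation is not recorded in
the emulated design; the arithmetic mean is the natural choice). The group
table reports across-subject mean ± SD per condition, the percent
variation computed from the *group means* (100·(stim − base)/base), and a
one-tailed paired Student t-test. The test direction defaults to a fixed
`increase`, under which the null distribution of p is exactly uniform;
`direction='observed'` instead tests in the direction of the observed
group-mean change, which matches how one-tailed p-values are convention-
ally reported for both increases and decreases, at the cost of folding
the null p onto (0, 0.5]. Gray-vs-white-matter contrasts per condition
use the same paired test across subjects in the direction of the observed
difference. All rounding happens in the report layer only.

Degenerate paired inputs: identically zero differences return the t → 0
limit p = 0.5; a nonzero constant difference (zero variance) raises a
degenerate-input error.

## Unit conversion

CBV[ml/100ml] = λ_H2O · f[%] and CBF[ml/100ml/min] = c · fD\*[10⁻³ mm²/s]
with c = 60·6·λ_H2O·100/(L·⟨l⟩)·10⁻³ derived at run time from
λ_H2O = 0.78, L = 2 mm, ⟨l⟩ = 0.108 mm (c = 130.0 for these defaults; an
invariant asserts the derivation, the constant is never hard-coded).
Means and SDs convert by the same linear factor; percent variations and
p-values are invariant and carried over. One published table cell
(activated white matter CBV under stimulation, printed 3.85) does not
follow from its own conversion rule (0.78 × 4.69 = 3.66); the package
reports the computed value and documents the discrepancy rather than
forcing agreement. The conversion as a whole is a rough estimate — it
assumes a single capillary topology for all tissues.

## Problem sizes used by the test and acceptance suites

Chosen as the package's own desk-scale defaults: SNR-sweep checks at
1,000 replicates per SNR; the precision-ordering check at 3,000
replicates under the experimental profile; the grid-search oracle on 100
seeded curves (f grid 0–0.3 step 0.001 × D\* grid 1–60×10⁻³ step
0.1×10⁻³); null-calibration over 500 seeds of a reduced study (24×24
slice, 4 subjects, 1 block per condition) against a Kolmogorov–Smirnov
uniformity test; and one full default-scale study (64×64, 8 subjects, 5
blocks per condition) for end-to-end effect recovery, compared to the
generator's drawn truth within a delta-method 3·SE Monte-Carlo interval.

## Known limitations

* The segmented fit's truncation bias and the skewed D\* sampling
  distribution, both quantified above.
* The experimental-noise interpolation (linear in b) is an assumption.
* Independent per-condition subject draws understate within-subject
  pairing; recovered p-values are conservative relative to a correlated
  generator.
* No spatial regularization, Bayesian fitting, or simultaneous
  three-parameter fitting; no multi-slice geometry; no DICOM ingestion.
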