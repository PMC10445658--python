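# Methods

`trfdr` re-implements, as a tested pipeline, the analysis chain of a
combined time-resolved fluorescence (TRF) and diffuse reflectance (DR)
raster-scanning system for breast-tumor margin assessment: thirteen optical
parameters per 1 mm pixel, a three-class decision-tree classifier evaluated
patient-wise, and the diagnostic and model-comparison statistics computed
from the pooled predictions.  Because the clinical spectra behind the
published results were never deposited, the package ships a synthetic
cohort generator with known ground truth; the published confusion and
transition matrices themselves are vendored and re-analysed exactly.

## TRF forward model and lifetime extraction

Each spot measurement carries eleven pulse replicates of the fluorescence
decay at 39 emission wavelengths (380–570 nm, 5 nm steps), sampled at
0.1 ns over a 50 ns window.  Replicates are averaged, and the mean trace at
each wavelength is fitted with

    y(t) = A · [exp(−t/τ) ⊛ IRF](t) + c,

a mono-exponential decay convolved with a Gaussian instrument response
(default FWHM 0.5 ns, centred at 1 ns).  A single reported lifetime per
biomolecule motivates the mono-exponential choice.  The fit uses variable
projection: at any trial τ the amplitude A and baseline c are the linear
least-squares solution, so the optimisation reduces to a one-dimensional
search over τ (coarse logarithmic scan over 0.05–20 ns, then bounded Brent
refinement).  There is no random element, and the trace is normalised by
its peak before fitting, so fits are deterministic and scale-equivariant up
to the Brent termination tolerance (~1e−8 relative).  The simulator and the
fitter share the same discrete convolution, so noiseless round trips are
exact to optimizer precision.

"Intensity" is defined as the time integral of the fitted decay, A·τ
(robust to IRF width; a peak-amplitude definition would only rescale the
band ratios).  Per fluorophore — collagen 380–440 nm, NADH 450–500 nm, FAD
520–570 nm, inclusive band edges on the 5 nm grid — intensities are
band-averaged and normalised to the fitted NADH intensity at exactly
460 nm, giving the collagen/NADH and FAD/NADH ratios; lifetimes are
band-averaged fitted τ.  Band-averaging of lifetimes mirrors the intensity
rule; the source analysis specifies averaging for intensities only, and the
symmetric treatment is our choice.  A non-positive 460 nm denominator or a
non-positive band lifetime marks the record invalid; invalid records are
excluded and counted, never silently zeroed.

## DR forward model, look-up table, and spectral inversion

Only the 0.64 mm source–detector bundle is analysed (it is the only one
that is background-corrected); the 0.32 and 1.5 mm bundles are stored
untouched.  Processing: subtract the water-blank spectrum (negatives
clipped to zero and counted; records with >10% clipped channels are
invalid), then normalise to the stored 99% reflectance standard so that a
measurement identical to the standard reads 0.99.

Reflectance is modelled with the spatially resolved steady-state diffusion
approximation for a semi-infinite medium, extrapolated-boundary dipole
solution, with the absorption-independent diffusion coefficient
D = 1/(3 μs′) and source depth z0 = 1/μs′ (internal-reflection parameter
A = 3.25 for a relative refractive index of 1.4).  This variant keeps the
source/image geometry independent of μa, which guarantees that reflectance
decreases strictly monotonically in μa — the property the look-up-table
inversion relies on.  At 0.64 mm the diffusion approximation is physically
marginal; it serves here as a self-consistent forward/inverse test bed, not
as a claim about real tissue.

The look-up table (LUT) is filled by evaluating the forward model on a
simulated ink/microsphere phantom grid (default 128×128 nodes, log-spaced,
μa ∈ [0.001, 1.0] mm⁻¹, μs′ ∈ [0.08, 6.0] mm⁻¹) and interpolated
bilinearly; interpolation is exact at nodes and accurate to ≲0.1% off-grid
at the default density.

A single separation yields one reflectance per wavelength, which cannot
determine two coefficients per wavelength.  The inversion is therefore
spectrally constrained over 450–650 nm:

    μa(λ) = w_oxy·B_oxy(λ) + w_deoxy·B_deoxy(λ) + w_base,
    μs′(λ) = a · (λ/500 nm)^(−b),

where B_oxy and B_deoxy are hemoglobin-like template curves: a steep blue
(Soret-tail) edge plus the 542/576 nm double peak, and a broader blue
shoulder plus the 556 nm peak, respectively, each normalised to unit
maximum over a fixed 450–650 nm reference window.  The steep, shaped blue
edges are what make absorption spectrally separable from smooth power-law
scattering at a single distance: with flat, featureless absorption the
problem is nearly degenerate and μa is only weakly identifiable (see
Limitations).  The five coefficients are fitted by bounded trust-region
least squares with residuals scaled by the measured reflectance — the
inverse-variance weighting for multiplicative detector noise — from five
fixed start points (lowest cost wins, ties to the earlier start), making
the inversion deterministic.  Bounds (w_oxy, w_deoxy ≤ 0.35 mm⁻¹,
w_base ∈ [0.001, 0.25] mm⁻¹, a ∈ [0.2, 4] mm⁻¹, b ∈ [0.1, 3]) are chosen so
any admissible curve stays inside the default LUT domain; fits that leave
the LUT domain under non-default configurations are flagged invalid.  The
eight DR parameters are the normalized reflectance read directly at 520 and
560 nm plus the fitted μa and μs′ curves evaluated at 540, 560 and 576 nm.

## Classification and cross-validation

The 13 parameters mix units (dimensionless ratios, ns, mm⁻¹), so each
feature set (TRF-only 5, DR-only 8, combined 13) is standardized before
PCA; components are retained until cumulative explained variance reaches
98%.  A greedy binary decision tree (Gini impurity, midpoint thresholds) is
grown on the component scores with three stopping rules: at least 3
instances per leaf, no splitting of subsets smaller than 5, and stop when
the node majority reaches 95%.  Equal-gain splits resolve to the lowest
feature index then the lowest threshold, and leaf-majority ties follow the
fixed class order (adipose, fibroglandular, tumor), so training is fully
deterministic.  The tree is implemented in this package because the
95%-majority stopping rule is not expressible in standard library trees;
its splits are verified against exhaustive enumeration in the tests.

Evaluation is leave-one-patient-out: one fold per held-out patient, with
the scaler, PCA and tree all refitted on the training fold only (a
`global` PCA scope is available as the documented alternative, since the
original description is ambiguous about the fitting scope; fold-internal
fitting avoids leakage and is the default).  Out-of-fold predictions are
pooled; every record is predicted exactly once, including patients whose
class is absent from a fold's training data.  Pooled tumor-class leaf
frequencies give the one-vs-rest ROC; AUC is the trapezoid over all
distinct score thresholds, equal to the pair-ordering probability
P(s⁺>s⁻) + ½P(tie).

## Diagnostics

Confusion matrices use the fixed class order; sensitivity is the per-class
diagonal fraction and specificity the one-vs-rest true-negative fraction.
Percentages are rounded half-up to one decimal.  Cross-model transition
tables count (model A prediction, model B prediction) pairs over the
tumor-actual pixels; the net gain is the count moving into minus the count
moving out of correct tumor classification.  Two paired symmetry tests are
reported side by side: Bowker's χ² over the off-diagonal pairs with
n_ij + n_ji > 0 (df = number of included pairs, so an all-zero pair drops
from the df), and the binary McNemar test with continuity correction,
(|b−c|−1)²/(b+c) on 1 df, after collapsing to correct/incorrect for tumor.
Both are given because the two published comparison p-values are not
mutually consistent under a single variant; on the vendored tables the
DR-vs-combined comparison is significant under binary McNemar (p ≈ 0.018)
but not under the symmetric 3×3 Bowker test (p ≈ 0.06).

## Synthetic cohort generator

The generator's default cohort reproduces the study conditions: 80
patients contributing 761 adipose, 77 fibroglandular and 347 tumor pure
spectra (allocated round-robin so each patient contributes several
classes), a water blank, a 99% standard spectrum (a smooth lamp-shaped
curve), and per-pulse trace noise at SNR 50 with 1% multiplicative
reflectance noise.  Class models assign each tissue type mean fluorophore
amplitudes/lifetimes and mean optical spectra, with lognormal
between-patient effects on amplitudes, chromophore weights and scattering
prefactor (σ = 0.35 / 0.25 / 0.16), truncated-normal effects on lifetimes
(6–12% relative) and scattering power (sd 0.12), and smaller within-patient
spot-level effects (σ = 0.10, 3% on lifetimes).  Lifetimes and amplitudes
sit in the physiological ballpark (collagen slowest, FAD fastest;
collagen-rich stroma, NADH-elevated tumor); absorption rises with blood
content from adipose to tumor, and μs′(500 nm) spans ≈1.1–1.9 mm⁻¹.  No
real-tissue parameter values were available to validate against, so these
defaults are illustrative: their spreads were set so that the end-to-end
pipeline lands in the broad performance region reported for the original
system (tumor sensitivity/specificity in the 70s–90s, DR stronger than TRF,
combined strongest), not fitted to tissue data.  What passing tests show is
that the pipeline recovers known inputs and behaves statistically correctly
— not that real tissue would yield these numbers.

The generator does not emulate: fluorophore band overlap (bands are
disjoint by construction, which the band-orthogonality tests exploit),
bi-exponential decays, wavelength-dependent IRF, spatial correlation
between neighbouring pixels, mixed-composition pixels (available but off by
default), or Mie-theory scattering spectra.

## Numerical choices

* Decay fit: τ search bounded to [0.05, 20] ns; 80-point coarse log grid;
  Brent `xatol` 1e−9; convergence requires an interior τ and positive
  amplitude.
* Inversion: `scipy.optimize.least_squares` (trf), xtol/ftol/gtol 1e−12,
  five fixed multi-starts.
* LUT: bilinear `RegularGridInterpolator`; linear extrapolation during
  optimisation only, with a final in-domain check.
* Degenerate inputs: all-zero traces return an unconverged fit; empty
  bands, zero-variance features, single-patient cohorts, mismatched
  wavelength grids and malformed scan files raise typed errors naming the
  offending field.
* Determinism: every stochastic stage derives its generator from
  `SeedSequence(seed, spot_index)`; identical seeds give bit-identical
  cohorts, and the tree/PCA/fit stages contain no randomness at all.

## Problem sizes used in the shipped checks

The test suite exercises cohorts of 2–40 patients (30–380 spectra), 200
Monte-Carlo decay fits and 100 noisy inversions; the acceptance script runs
the full 80-patient, 1185-spectrum default cohort end to end, which
completes in minutes on a single CPU.

## Known limitations

* At a single 0.64 mm separation, μa of weakly absorbing, spectrally flat
  tissue (adipose-like) is poorly identifiable: small reflectance errors
  move the fit along a near-degenerate valley traded against the scattering
  power law.  Recovery tests therefore target the blood-bearing classes;
  adipose DR classification rests mainly on r520/r560 and μs′.
* The diffusion dipole model at 0.64 mm is outside its formal validity
  range; all inverse-problem guarantees are relative to this forward model,
  not to photon-transport reality.
* The decision tree's printed-study hyperparameters are fixed; no
  rebalancing is applied to the 10:1 adipose/fibroglandular imbalance, so
  fibroglandular sensitivity is structurally weak, as in the original
  analysis.
* The published AUCs (0.842/0.887/0.911), the real-data PCA variance
  percentages (99.2/98.5/98.9) and the published summary metric rows that
  are inconsistent with the printed matrices require the undeposited
  per-record data; they are carried as documentation-only context and
  never asserted.
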