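# Methods

## Overview

`bbbsim` simulates the complete measurement chain of low-leakage DCE-MRI:
a labelled head object with known pharmacokinetic ground truth generates a
high-resolution 4D signal; an acquisition model degrades it with k-space
sampling, rigid head motion, composite-k-space motion artefacts and noise;
and an analysis pipeline recovers Patlak parameter maps and per-tissue
summaries.  Because the generating parameters are known exactly, every
difference between estimate and truth is attributable to the measurement
process, not to pharmacokinetic model error.

## Forward model

**Kinetics.**  Brain tissues follow the Patlak model
`C_t[t] = v_P c_p[t] + PS ∫₀ᵗ c_p dt′`, valid in the slow-leakage regime at
low temporal resolution.  The integral uses the cumulative trapezoidal rule
on the frame times — the de-facto standard quadrature for Patlak
implementations at ~1 min temporal resolution — and the *same* quadrature is
used by the fitting stage, so on undegraded data the OLS fit is exact by
construction (verified in tests to 1e-10 relative).

**Arterial input.**  The default AIF is the Weinmann population
biexponential, `c_p(τ) = D (a₁ e^{−m₁τ} + a₂ e^{−m₂τ})` with
a₁ = 3.99, a₂ = 4.78 kg/L, m₁ = 0.144, m₂ = 0.0111 min⁻¹ and
D = 0.1 mmol/kg, giving a plasma peak of ≈0.88 mM.  Any smooth AIF
exercises the downstream computation identically, and the same AIF object
is used for synthesis and fitting, so parameter recovery is AIF-agnostic.
Injection occurs at the start of the first post-contrast frame; frames are
stamped at their temporal midpoints.

**Signal.**  Relaxation rates vary linearly with concentration
(`1/T_i = 1/T_i0 + r_i C`), with defaults r₁ = 3.9 and r₂* = 4.5 mM⁻¹s⁻¹
(representative gadoterate values at 1.5 T; both configurable).  The
spoiled gradient-echo equation then yields the signal.  Tissues without a
BBB (muscle, skin, meninges, skull marrow, eyes) do not follow Patlak
kinetics; they use empirical enhancement-multiplier templates (exponential
saturation `1 + a(1 − e^{−τ/τ₀})` or power law `1 + a(τ/τ_ref)^b`) applied
to their pre-contrast signal, with amplitudes several-fold above brain
enhancement — the property that makes extra-cerebral tissue the dominant
source of ringing artefacts inside the brain.  Blood vessels are modelled
as plasma: `v_P = 1 − Hct` (Hct = 0.45) and `PS = 0`.

Ground-truth parameters are piecewise-constant per tissue class, so each
frame of the high-resolution object is a lookup of a per-class signal
curve; this keeps synthesis O(volume) per frame and memory bounded.

## Phantom

The synthetic head is a nested-ellipsoid object with 16 tissue classes:
skin and adipose shells, a three-layer skull (outer table, diploe, inner
table), meninges, subarachnoid CSF, a cortical grey-matter ribbon, a white
matter interior, lateral ventricles with periventricular WMH caps, deep
grey-matter nuclei, one basal-ganglia stroke lesion (~8 mm), tubular
vessels crossing the brain surface (a superior sagittal sinus and two
penetrating vessels), eyes, and a lower muscle block with a vertebral
column.  Geometry is parametric and seeded: internal structures get a small
random displacement so different seeds give different anatomies, while the
same seed is exactly reproducible.

The phantom reproduces the *phenomenology* that matters for artefact
studies — strongly enhancing extra-cerebral tissue adjacent to brain, sharp
tissue interfaces, small lesions, vessels — but not real anatomy: it is
smoother and more symmetric than a head (consequences below), its tissue
boundaries are perfectly sharp, and in-vivo texture within tissues is
absent.  Passing tests therefore demonstrate correctness of the measurement
model and pipeline, not anatomical realism.

T2*₀ values per tissue are not part of the reference ground-truth table and
are shipped as assumptions (≈60 ms brain, shorter in bone/air-adjacent
classes, configurable).  The table is a CSV fixture; external labelled
atlases can be plugged in through the NIfTI label reader using the same
class IDs.

## Acquisition model

Per frame: (1) the starting position (uniform ±5° rotations, ±2.5 mm
translations, identical for all frames) and the per-frame trajectory
transform position the object by resampling the high-resolution volume
(trilinear by default; Lanczos-3 windowed sinc available) — resampling
rather than k-space phase ramps so rotation and interpolation effects are
captured; (2) the object is masked to the acquired FOV along the
frequency- and partition-encode axes (band filter / slab excitation); (3)
its unitary centred 3D FFT is truncated to the acquired matrix by central
block extraction (DC at `floor(N/2)`), scaled so image intensity is
resolution-invariant; (4) when motion-artefact simulation is on, a second
k-space is formed at the previous frame's position and a composite is
assembled — phase-encode planes below a uniform-random split fraction come
from the previous position, the rest from the current one, ordered
sequentially along the slowest (partition) axis; (5) complex Gaussian noise
of standard deviation σ is added to both channels and the magnitude of the
inverse FFT is the acquired frame (Rician noise; Rayleigh in background,
verified against the closed-form mean/std ratio 1.913).

The unitary FFT convention makes σ identical in k-space and image domain,
so SNR calibration is unambiguous: σ = (mean pre-contrast NAWM signal at
acquired resolution) / SNR_target, with SNR_target = 91.5 by default.
Source and acquired FOV must agree, which makes central extraction exact;
the simulator does not model phase-encode wrap-around since the source grid
itself bounds the object.

**Motion trajectories.**  Random walks in the 6 rigid parameters with
severity-dependent step scales, classified by mean frame-to-frame
displacement of brain tissue: low < 0.5 mm, moderate 0.5–1.5 mm,
high > 1.5 mm (thresholds configurable).  The default scales place the
three classes near 0.16, 0.74 and 2.3 mm respectively.  Rotations are about
the FOV centre, Euler order ZYX, so trajectories are portable between
grids.

## Analysis pipeline

**Realignment.**  Frames are rigidly realigned to frame 0, either by
intensity registration (Powell search over 6 DOF maximising normalised
cross-correlation, two passes — Gaussian-smoothed then raw images — with a
soft trust region of ±15°/±12 mm around the initialisation) or in *oracle*
mode, which inverts the known simulation transforms and isolates
interpolation effects from registration error.  On the smooth,
near-axisymmetric phantom the NCC optimum for rotations is genuinely
displaced by up to ~1° (axial rotation is nearly unobservable), while
translations are recovered to well under a tenth of a voxel; real heads
have richer structure, so registration accuracy here is a lower bound along
rotational axes.

**Concentration.**  Voxel enhancement relative to the pre-contrast mean is
converted to concentration by inverting the SPGR equation at the nominal
flip angle with a regional T10 map (piecewise-constant per propagated
tissue label).  The T2* factor is neglected in the inversion — standard
practice — while the forward model retains it; the resulting bias is ≈−0.5%
in PS and v_P at brain concentrations (quantified in tests) and grows with
concentration.  Enhancement beyond the SPGR ceiling cannot be inverted;
such voxels are clamped and flagged.  A linear small-signal fast path is
available for diagnostics.

**Fitting.**  OLS of C_t on {c_p, ∫c_p} without intercept (the Patlak
equation has no offset), excluding the first three post-contrast frames by
default, vectorised over voxels through one shared pseudo-inverse.
Negative estimates are preserved — they are a real feature of degraded
data.  Segmentation is propagated by registering the high-resolution
pre-contrast image to acquired frame 0 (or by the oracle transform),
resampling each class mask with cubic interpolation into a soft
probability, and labelling each voxel by the argmax class (background where
the best probability is below 0.5).

**Summaries and post-processing.**  Four estimators per tissue: mean/median
over the parameter maps, and a single Patlak fit of the mean/median ROI
signal curve.  Optional post-processing: morphological erosion with a
1-voxel spherical kernel, and a 4th-order Bessel magnitude low-pass applied
separably per axis to the acquired k-space (cutoff 0.7 Nyquist by default;
unity at DC so the image mean is preserved; order 0 selects a flat
response).  The Bessel order/cutoff and the 0.5 background-probability
threshold are package choices where no reference value exists.

## Monte Carlo and problem sizes

The Monte-Carlo driver repeats simulate→analyse→summarise with a fresh
starting position, trajectory and noise per run (child seeds of one master
seed; fully reproducible and permutation-invariant) and reports median and
IQR of per-tissue relative errors.  The packaged demo default is 25 runs.

Problem sizes were chosen so the full loop runs on a laptop-class budget:
the demo phantom is 96³ at 1 mm (acquired 48×40×12 at 2×2.4×8 mm,
preserving the reference protocol's voxel-shape anisotropy and equal FOV);
the test suite uses 48³ at 2 mm; Monte-Carlo experiments use 64³ at 1.5 mm
with an acquired grid of 32×24×16 (3×4.5×6 mm).  The slice dimension of the
Monte-Carlo grid is deliberately finer than the demo's 8 mm: with only 12
partitions the eroded white-matter mask collapses onto the periventricular
zone, a degenerate geometry that the erosion experiment presumes away (it
requires tissue extent well beyond one voxel).  The full-scale reference
matrix (256×192×46) is supported behind the same interfaces.

**Noise-calibration measurement.**  The spatial-SNR check reconstructs the
pre-contrast frame on a grid matched to the source, so that tissue is
exactly piecewise-constant and the spatial standard deviation inside the
eroded NAWM mask measures the injected noise alone.  At coarse acquired
grids the phantom's sharp boundaries add Gibbs/partial-volume variance
inside the mask that in-vivo white matter (the context in which a spatial
SNR of 91.5 is measured) does not exhibit; the matched-grid measurement is
the configuration in which the number being calibrated is the number being
measured.

## Numerical choices and degenerate inputs

- FFTs: orthonormal, centred via fftshift/ifftshift, DC at `floor(N/2)`;
  even/odd lengths handled by that single convention and tested.
- Trapezoidal AIF integral shared between synthesis and fitting (exactness
  of the no-noise fit is a designed invariant, not an accident).
- Rank-deficient Patlak designs (all-zero AIF) and fewer than 3 usable
  frames raise; per-voxel failures in maps are flagged, never fatal.
- Registration failures fall back to identity with a warning; empty eroded
  masks yield NaN summaries, recorded but not fatal.
- Labels are uint16 with background 0; world coordinates are defined by a
  centred affine (FOV centre at the origin) so grids of equal FOV align.

## Known limitations

- No parallel imaging, partial Fourier, non-Cartesian sampling, coil
  sensitivities, B0/B1 effects or scanner drift; motion is piecewise-static
  between two positions per frame rather than continuous.
- The phantom's symmetry makes axial-rotation registration ill-conditioned;
  quantitative registration claims are restricted to translations.
- The T2*-neglect bias in the concentration inversion (~0.5% at brain
  concentrations) is inherent to the standard analysis, and is the floor of
  the "ideal-condition" recovery error.
- Extra-cerebral enhancement amplitudes are plausible templates, not fits
  to in-vivo curves; conclusions about artefact *magnitude* outside the
  brain should not be read quantitatively.
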