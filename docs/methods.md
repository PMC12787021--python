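# Methods

This note documents the models, numerical choices, and known limitations
of `qnmr1d`. It is the companion to the API documentation: everything
here is implemented and tested in the package; no empirical claim is made
that the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

A target resonance is modelled as an asymmetric pseudo-Voigt profile on
the frequency axis (Hz):

    V(f) = A · [ η·L(f; c, w(f)) + (1−η)·G(f; c, w(f)) ]
    w(f) = 2·FWHM / (1 + exp(a·(f−c)/FWHM))

where `L` and `G` are amplitude-normalised Lorentzian and Gaussian shapes
sharing centre `c` and width `w`, `η ∈ [0, 1]` is the Lorentzian weight,
and `a` is a dimensionless skew (a = 0 recovers the symmetric profile,
|a| ≤ 0.5). The side-dependent sigmoidal width is this package's declared
convention for asymmetry — peaks near presaturation regions in 1D-NOESY
wine spectra show mild skew, and the sigmoid keeps the apex height and
position stable. Note the skew argument is normalised by the FWHM: an
un-normalised offset in ppm would make the asymmetry numerically
invisible at realistic linewidths.

Symmetric peak areas use the closed form
`A·w·[η·π/2 + (1−η)·(1/2)√(π/ln 2)]`; asymmetric areas use adaptive
quadrature over ±50 FWHM. The two routes agree to ≤ 1e-6 relative on a
parameter grid (tested).

## Preprocessing

* Zero-fill to SI = 131072 real points ("128 k"), FFT with the first FID
  point halved (removes the DC offset of the rectangle rule), intensities
  scaled by the dwell time so a line's frequency-domain integral in Hz
  equals its time-domain oscillator amplitude.
* Exponential line broadening, default 0.25 Hz; adds exactly LB to every
  Lorentzian width while preserving integrals.
* Zero-order auto-phasing: coarse 2° grid minimising the squared negative
  intensities (with a tiny reward for positive signal that breaks the
  degenerate ±90° solution on nearly-pure-absorption spectra), bounded
  scalar refinement, then a TMSP-flank refinement that nudges the phase so
  the mean real intensity beside the TMSP peak approaches zero. The
  refinement is kept only when it does not raise the negativity cost by
  more than 2%: with a well-resolved TMSP line the flank mean is dominated
  by the peak's own Lorentzian tails, and "fixing" it would trade a real
  offset for dispersion leakage (this failure mode measurably corrupted
  peak areas in testing). First-order phase is exposed but defaults to
  zero: pulse-acquire and 1D-NOESY wine spectra are near-pure zero-order.
* ppm calibration: the dominant maximum in a search window (default
  1.02–1.07 ppm) is located with three-point parabolic interpolation and
  shifted to the target (default 1.046 ppm, the central ethanol
  ¹³C-satellite line). If no peak rises 5 robust-σ above the local median
  the spectrum is returned unshifted and flagged. The operation is
  idempotent.

## Baseline, denoising, picking, fitting

* **airPLS**: Whittaker smoother with second-difference penalty λ
  (default 1e5 per ROI, configurable) and the adaptive reweighting scheme
  — zero weight above the baseline, exponential up-weighting below.
  Stopping matters more than λ: iterating to strict convergence on noisy
  data concentrates exploding weights on the few most negative noise
  excursions and drags the baseline tens of σ below the signal. The
  iteration therefore stops when the L1 norm of negative residuals falls
  below max(1e-6·‖y‖₁, 0.02·n·σ), with σ the noise estimate from the
  designated peak-free window (default 9.5–10.0 ppm; required, never
  inferred). Noiseless inputs still converge fully; the weight exponent is
  capped at 30.
* **Wavelet denoising**: Daubechies-8 by default (Symlets by
  configuration), decomposition depth ⌊log₂ n⌋ − 4 (minimum 3), soft
  universal threshold σ√(2 ln n) with σ from the MAD of the finest detail
  coefficients. Peak maxima of noiseless signals move < 1 point.
* **Second-derivative picking**: candidates are local minima of a
  Savitzky–Golay (window 9, cubic) second derivative lying below −3× its
  robust noise scale, whose intensity also exceeds max(snr_min, 3)·σ —
  the method is not applicable below S/N 3, so weaker features are never
  returned. The smoothed derivative is deliberate: the bare
  central-difference stencil fires on single-point ripples left by
  wavelet reconstruction. On 200 seeded replicates of a three-peak region
  at S/N 10 the picker returns exactly three candidates ≥ 95% of the time
  (tested).
* **Fitting**: one profile per candidate, joint bounded least squares
  (trust-region reflective; ftol/xtol 1e-12, finite evaluation budget).
  Initialisation: amplitude from the signal height, FWHM 1 Hz, η 0.7,
  a 0. Bounds: η ∈ [0,1], |a| ≤ 0.5, centre inside the ROI, FWHM ≤ 6 Hz
  per ROI by default — wine resonances stay well below this, and an
  unbounded width lets the optimizer absorb baseline leftovers into broad
  phantom peaks that steal area from genuine lines. Non-convergence is
  reported, not raised.
* **Lineshape QC**: the fitted TMSP FWHM must be strictly below 1 Hz.

## Pattern matching

Each signature expands into first-order multiplet lines (d: δ ± J/2;
dd: δ ± (J₁±J₂)/2; q: 1:3:3:1 at ±J/2, ±3J/2; "m" multiplets carry
explicit, empirically chosen line lists flagged approximate — the methine
multiplets of 3-methylbutan-1-ol and shikimic acid have no first-order
decomposition here). Assignment minimises

    score = Σ |Δδ|/δ_tol + Σ |ΔJ|/J_tol,   δ_tol = 0.01 ppm, J_tol = 0.3 Hz

subject to every line within tolerance, couplings measured as
fitted-centre differences converted to Hz, peaks assigned injectively
across the sub-signals of one pattern, and line order preserved.
Candidate lists in a narrow ROI are short, so the search is exhaustive
and provably equals brute force (tested against an independent
enumeration oracle up to 8 candidates). Ties break toward larger total
area; a second valid assignment within 10% of the best score sets the
`ambiguous` flag. Partial matches (e.g. one of catechin's two doublets)
quantify over the matched proton weights only and are flagged.

## PULCON conventions

* The "absolute integral" I follows the point-sum convention
  (fitted area in intensity·Hz × SI/SW), matching K = SW/SI in the factor
  formula.
* Per-standard factors combine by arithmetic mean after the QR gate
  (< 5%, strict) passes; Citrate1/Citrate2 are the two halves of the
  citrate AB system and their integrals and proton counts are summed
  before the formula.
* In the concentration formula the correction factor CF multiplies and
  the dilution factor divides, with f_dil defined as the wine volume
  fraction in the tube (0.8 for 800 µL wine + 100 µL spiking solution +
  100 µL buffer; 1/f_dil restores the undiluted concentration). This
  convention is fixed by the algebraic self-consistency requirement that
  quantifying the QR's own standard with its own factor returns the
  preparation concentration exactly (tested to 1e-9).
* Receiver gain is recorded and cross-RG quantification is refused unless
  an explicit override ratio is supplied; RG is held fixed per pulse
  program in the intended acquisition scheme.
* QC recovery uses an inclusive ±8% boundary (a recovery of exactly 8%
  deviation passes); the QR (< 5%) and TMSP (< 1 Hz) gates are strict.

## Validation statistics

Equations (3)–(5)-style quantities (precision, bias, linear uncertainty)
operate in percent; the dynamic model and LOQ rule operate in fractional
units with threshold 0.60 — the only pairing under which published (α, β)
pairs reproduce their published LOQs. Specifics:

* s_r² is the mean of within-series variances; S_RW uses the balanced
  design only (unbalanced designs are rejected). The estimator is
  unbiased for σ²_between + σ²_within; a 500-seed simulation at 2%/1%
  components recovers 5 (%²) within 5% (tested).
* µ(u_prec) over levels is the arithmetic mean (the weighting is not
  specified by the OIV procedure; arithmetic is this package's choice).
* u_MTD = MAD/√3 is offered as a helper under a rectangular-distribution
  reading, clearly an interpretation.
* The trueness inequalities are strict at equality.
* The dynamic model's inflection pair (x₁, x₂) and stabilised subset for
  β are explicit arguments — never inferred — with a helper proposing the
  two lowest levels with decreasing CV.
* Dynamic-model LOQs are reported raw and rounded to the nearest 5 mg/L.
  One published parameter set (fumaric acid: α = 1.46, β = 0.08) is not
  consistent with its published LOQ of 5 mg/L under the 60% rule (closed
  form ≈ 2.5); the reference table carries the published value unchanged.

## Synthetic data: what it does and does not emulate

The generator renders first-order multiplets with pseudo-Voigt lineshapes
(defaults FWHM 1 Hz, η 0.7, a 0 — typical 500 MHz wine values; chosen
once and documented, since lineshape parameters of real wine peaks vary
by matrix), polynomial baseline drift, white Gaussian noise (frequency
domain for rendered spectra; time domain for synthetic FIDs, which are
restricted to η = 1 because only Lorentzian lines have exact exponential
time-domain counterparts), and a signal scale proportional to molar
concentration × proton count — the proportionality PULCON relies on.
Validation sets draw per-series and per-replicate Gaussian components
with deterministic sub-streams per (level, series).

Not emulated: solvent-suppression phase artefacts, ¹³C satellites of
arbitrary compounds, strong-coupling (second-order) multiplet distortion,
pH- or temperature-dependent shift drift beyond a constant offset, and
matrix-dependent lineshape changes. Passing tests therefore demonstrate
the correctness of the processing chain and its statistics on idealised
spectra of known composition, not robustness to every distortion of real
wine spectra; the correction-factor machinery exists precisely because
real matrices deviate from ideal response.

## Problem sizes in tests

The test suite and acceptance checks run spectra at 65536–131072 points
(the production spectrum size), 50-seed noisy ensembles at S/N 50 for the
recovery checks, 200 replicates for the picker property, and 500 seeds
for the S_RW property — sizes chosen to make the statistical assertions
sharp while keeping the whole suite around a minute on one core.

## Known limitations

* First-order multiplets only; "m" patterns require user-supplied line
  lists.
* First-order phase correction is a configurable constant, not optimised.
* The airPLS noise-aware stop assumes the designated noise window is
  representative of the ROI noise.
* Pattern matching assumes peaks were resolved by the deconvolution;
  fully coincident lines are not disambiguated.
* The bundled profile's ROI boundaries were chosen for clean synthetic
  spectra and ordinary wine compositions; unusual matrices may need
  per-ROI recalibration (supported via `local_calibration`).
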