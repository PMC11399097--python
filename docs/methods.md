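# Methods

`trwaxs` analyzes microsecond time-resolved wide-angle X-ray scattering
(TR-WAXS) recorded as MHz pulse trains: bursts of 175 X-ray pulses at 564 kHz
(1.77 µs spacing, ~308 µs window) repeating at 10 Hz, with every other train
optically excited ("light") and the rest unexcited ("dark"). The measured
quantity is the difference scattering ΔS(q, t) = S_light(q, t) − S_dark(q, t),
a ~10⁻³–10⁻⁵ relative perturbation of a large static background. This note
records the models, the defaults and their rationale, the numerical choices,
and what the synthetic studies do and do not demonstrate.

## Geometry and reduction

Momentum transfer follows q = 4π sin θ/λ with 2θ the scattering angle; the
photon-energy/wavelength conversion uses hc = 12,398.42 eV·Å, and real-space
resolution is d = 2π/q. Azimuthal integration assigns each pixel's q at its
center and averages unmasked pixels into half-open q bins; bins without usable
pixels are flagged, never silently zeroed. A single rectangular detector with
a user mask stands in for multi-panel layouts; panel calibration is out of
scope. The default analysis grid is 170 linear points on 0.08–1.5 Å⁻¹; a wider
reduction window up to 2.1 Å⁻¹ is configurable.

**Train filter.** Intermittent jet instability changes the *shape* of the
scattering curve, so each train's pulse-averaged profile is Pearson-correlated
against the run average of trains with the same light/dark flag; trains below
0.99995 are discarded. The reference is refined greedily (drop the worst
offender, recompute the average, repeat): in small runs a single distorted
train biases the run average enough to fail clean trains, whereas with
thousands of trains per run the refinement changes nothing. NaN correlations
(degenerate profiles) count as failing. The report carries both train- and
image-level retention counts.

**Differencing and normalization.** Two pairing strategies exist. The default
quantitative route subtracts each light train from its neighbouring dark train
in raw units: train-level common-mode gain (jet thickness, beam intensity)
drifts slowly, so adjacent pairs share most of it. Window-sum normalization
(divide each curve by its summed intensity over the q window) removes
multiplicative gain *exactly* and mirrors the published reduction ordering
(filter → average per class → normalize → subtract), but it also injects a
background-shaped admixture proportional to the net window difference signal —
a first-order distortion of ΔS regardless of how small the signal is relative
to the background. It is therefore offered as an option rather than the
quantitative default. Residual train gain that survives pairing is constant
within a train, hence exactly dark-shaped when decomposed on the sequential
model; downstream fits co-project the dark curve as a nuisance component to
absorb it. Two datasets (e.g. two sample concentrations) merge by a
scale-and-offset least-squares alignment followed by a weighted average with
weights equal to the light-frame counts.

## Kinetic decomposition

ΔS(q, t) is modeled as Σᵢ BSᵢ(q) Cᵢ(t): time-independent basis spectra of the
states of an irreversible sequential scheme weighted by their closed-form
concentrations. For A → B: C_A = e^(−k_A t), C_B = 1 − C_A. For A → B → C:
C_A = e^(−k_A t), C_B = k_A/(k_B − k_A)·(e^(−k_A t) − e^(−k_B t)),
C_C = 1 − C_A − C_B, which keeps Σᵢ Cᵢ = 1 exactly and all concentrations in
[0, 1]. Near-degenerate rates (relative gap < 10⁻⁷) switch to the analytic
limit C_B = k_A t e^(−k_A t); the generic formula agrees with the limit to
better than Δ·t/2 relative, so sub-10⁻⁶ agreement is expected only through
k·t ≲ 2 — which covers the physically informative region around the
intermediate's peak.

The fit is a variable projection: an outer Nelder–Mead simplex over
*log*-rates (enforcing positivity) with the basis spectra solved exactly by
linear least squares at every evaluation. The target is the sum of squared
per-(q, t) residuals — the quantity the inner linear solve minimizes. A 3×3
multiplicative multistart grid (×0.1, ×1, ×10 around the initial rates,
defaults 1/(2 µs) and 1/(100 µs)) guards against local minima; termination
uses xatol 10⁻⁸ in log-rate space and a function tolerance scaled to the
initial residual (an absolute ftol is meaningless in squared-count units). No
sign constraint is placed on basis spectra (difference spectra are signed); a
per-q weight hook exists but the default fit is unweighted. The three-state
model is selected over the two-state one only when it lowers the residual by
more than 5% relative — a margin calibrated so that on two-state truth the
nested three-state fit is promoted in at most ~2 of 20 noisy replicates.

## Theoretical scattering

Candidate and native structures are scored through the vacuum Debye formula
I(q) = Σᵢⱼ fᵢ fⱼ sin(q rᵢⱼ)/(q rᵢⱼ) with constant effective electron counts
per element (H 1, C 6, N 7, O 8, P 15, S 16). No solvation shell or excluded
volume term is included — the deliberate fidelity gap of this package: the
downstream quantities are *difference* profiles and their low-q
radius-of-gyration behaviour, which the vacuum calculation captures, not
solvent-accurate absolute curves. An exact O(N²) path and a pair-distance
histogram path (bin width 10⁻⁵ Å, occupied bins only) agree to better than
10⁻⁶ relative; the histogram path engages automatically above 400 atoms.
R_g is the f-weighted RMS distance from the f-weighted centroid, and a
self-consistent Guinier fit (window q·R_g < 1) reproduces it to a few percent
on compact models.

## Absolute scale, candidate scoring and photoactivation yield

The experimental dark curve is matched to the theoretical native dark curve by
the scalar c_abs minimizing Σ_q (S_dark,exp·c_abs − S_dark,theory)²; the same
scale is applied to the difference curves. Each candidate structural pair is
scored on q < 0.16 Å⁻¹ (the R_g-change regime) by projecting a coefficient c
minimizing Σ_q (c·ΔS_exp,scaled − ΔS_model)², i.e. c = Σ e·m / Σ e². The
goodness score is reported as R² = 1 − SS_res/Σ m², oriented so 1 is perfect
and the conventional R² > 0.9 selection threshold is meaningful; the raw
residual ratio with the experimental-curve denominator is also emitted for
transparency. Candidates are selected when R² > 0.9 **and** c lies in the
photoactivation-yield window 15 ± 5% (closed interval [0.10, 0.20]), ranked by
R² with ties broken by |c − 0.15| and then model id — pure set semantics, so
selection is idempotent and order-independent.

In this projection convention c multiplies the *experimental* curve, so the
experimental input must be expressed per unit projected yield for c to read
out the yield itself. The pipeline therefore feeds the screen the measured
final-state spectrum divided by the square of the independently estimated
yield: once to convert the measured (yield-scaled) signal to full conversion,
and once more so that the required-yield coefficient of a correct pair equals
the yield. The yield estimate itself never depends on this convention: it is
the least-squares scale of a saturated (full-photoconversion) reference
difference curve onto the measured signal — the analysis analog of
calibrating against a steady-state saturation experiment — with the dark
shape co-fitted as a nuisance and a seeded residual bootstrap (default 1,000
resamples) for the uncertainty interval.

## Synthetic data: what it emulates, and what it does not

The generator runs the analysis model in reverse. Dark-train pulses have
expectation g·S_dark(q); light-train pulses add the kinetic signal
yield·Σ BSᵢ(q)Cᵢ(t) before the shared train gain g. Defaults define the study
conditions: 60 light/dark train pairs of 175 pulses at 564 kHz; yield 0.15;
rates (0.1, 0.01) µs⁻¹ — a ~10 µs first step resolved by the 1.77 µs grid and
a ~100 µs final step spanning the train; train gain g with 10⁻³ standard
deviation and AR(1) correlation 0.9 across trains (slow drift is what makes
adjacent-train subtraction effective); Poisson counts on per-bin integrated
intensities (per-pixel in image mode); 10¹⁰ expected photons per pulse over
the window. The photon budget is deliberately generous per pulse so the
*averaged* null-signal noise floor lands at the 10⁻⁵–10⁻⁴ relative scale of
real MHz-train data while simulating thousands rather than millions of
frames. Corrupted trains receive a smooth random cubic shape distortion,
decorrelated from the background's own shape and scaled in profile-variance
units so that the default strength (0.05) reliably trips the 0.99995 filter.

Basis spectra come from toy structure pairs: a compact four-helix Cα bundle
whose terminal 20 residues are resampled along a compact-to-extended morph,
giving candidates with radius-of-gyration increases sweeping ~4–18 Å, Debye
difference profiles, and a designated "true" final state near ΔR_g = 6 Å. By
default the basis spectra are rescaled to a peak amplitude of 10⁻³ of the
background peak (the relative scale of real data); the structural-screen
configuration instead keeps the Debye absolute relation between background
and basis spectra (`relative_signal=None`), because absolute-scale screening
requires commensurate units.

What passing these studies shows: the reduction, decomposition, scaling and
selection algebra is correct; rates, yield and unfolding extent are recovered
without bias at realistic noise; filtering detects shape-level corruption at
the published threshold. What it does not show: performance against detector
gain artifacts, panel geometry errors, solvent/hydration-shell scattering,
radiation damage, or model ensembles whose candidate curves are not spanned
by the toy morph — none of which the generator emulates.

## Problem sizes

Tests and the acceptance script run desk-scale problems: 170 q-points ×
175 pulses, 4–120 trains per run, 100-seed calibration loops at 12 train
pairs, 10–20-seed loops where a full kinetic fit is needed. These sizes make
every statistical assertion cheap to reproduce while keeping estimator errors
(rates ~3–5%, yield ±0.5–1 percentage point) small against the tolerances
being checked.
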