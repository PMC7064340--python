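# Methods

This note documents the models, the numerical choices and the known limits
of the `khoomei` package, which reproduces the acoustics of the "focused
state" of Sygyt-style Tuvan overtone singing with a fully synthetic
pipeline: tract geometry → transmission-line acoustics → formant merging →
source/filter synthesis → spectrogram analysis.

## Tract geometry

A midsagittal tract is represented by two traced contours (inner and
outer, glottis first, cm). The centerline is found by iterative bisection:
starting from the midpoint of the glottal end, the algorithm advances in
fixed arc steps (default 0.25 cm) and slides each candidate point along
the local normal (Brent root-finding) until it is equidistant from the two
contour polylines (shapely point–polyline distances). The cross-distance
`D(x)` is the sum of the two polyline distances; `x` is cumulative arc
length. Points within 0.5 cm of either end are flagged low-confidence
because the perpendicular is ill-defined where the contours terminate.

Cross-distance converts to area by the circular-section rule
`A(x) = k D(x)^alpha` with `k = pi/4`, `alpha = 2` (elements of `D`
treated as diameters). Other (k, alpha) pairs exist in the literature with
no agreed-on values; only the circular rule is implemented. Area functions
are resampled to uniform sections (default 44) by piecewise-linear
interpolation before any acoustic computation.

**Accuracy limit.** The recovered cross-distance matches the generating
tube within 2% only where the diameter varies slowly. Near steep
constriction/expansion complexes the nearest-polyline distance differs
from the perpendicular cross-distance by up to ~10% — a property of offset
curves, not of the extraction; the tests cover both regimes explicitly.

## Transmission-line acoustics

The tract is a chain of uniform tube sections (1-D plane waves, CGS
units). Each section contributes an ABCD chain matrix built from its
per-unit-length series impedance `z` and shunt admittance `y`:

- ideal terms: `z = j w rho / A`, `y = j w A / (rho c^2)`,
  with `c = 35000 cm/s`, `rho = 1.14e-3 g/cm^3` (warm moist air);
- viscous / thermal boundary-layer losses (square-root frequency laws)
  on `z` and `y` respectively;
- yielding walls as a per-area mass–resistance–stiffness shunt branch,
  defaults `r = 1600 dyn s/cm^3`, `m = 1.5 g/cm^2`, `k = 3e5 dyn/cm^3`
  (the classic values of the transmission-line literature);
- lip radiation as a piston-in-baffle load (parallel radiation resistance
  and inertance).

Matrix entries are computed branch-safely via `cosh` and `sinh(u)/u`
(both even in `u = sqrt(zy) l`). The default transfer function is the
volume-velocity gain `U_lips/U_glottis` (ideal flow source at the
glottis); a `radiated_pressure` variant multiplies by the radiation load,
adding its ~+6 dB/oct characteristic. Formant frequencies are insensitive
to the choice; synthesis of "microphone-like" audio uses the radiated
variant. Grid default 10–8000 Hz at 2 Hz (1 Hz for convergence studies).
On this model a lossless uniform closed–open tube reproduces the
quarter-wave series `(2i-1)c/4L` exactly, and full losses shift and
broaden the peaks to realistic formant bandwidths (F1/F2/F3 of a uniform
3 cm^2 tube: ~37/34/63 Hz at −3 dB).

Formants are prominent local maxima of the gain curve (default prominence
1 dB, minimum separation 80 Hz, parabolic refinement of the peak
frequency); peaks closer than the separation are merged into one, keeping
the taller (ties toward lower frequency) and flagging it merged.

## Sensitivity functions and formant merging

The sensitivity of formant `F_i` to fractional area change is the
classical energy form: with the interior pressure/flow state propagated
from the lip termination at `F_i`, each section's kinetic minus potential
acoustic energy, normalized by the total, predicts
`dF/F ≈ sum_n S(n) dA(n)/A(n)`. Against central finite differences on
random smooth tracts the prediction agrees to a few percent in the
near-lossless regime; yielding-wall loading (which mostly affects F1)
degrades the agreement to ~10–20%, as expected for a rigid-wall
perturbation result.

The focused state is produced by iterative perturbation: at each step the
two tracked formants and their sensitivities define a 2×N linear model,
and the minimum-norm fractional-area update that would move both formants
onto the target is applied at a fractional step (default 0.1), smoothed
along the tract (3-section moving average), capped at |dA/A| ≤ 0.15 per
iteration and clipped to [0.05, 8] cm^2 (physiological floor and ceiling —
without the ceiling the optimizer balloons the tract to nonphysiological
~17 cm^2 cross-sections). A naive sum of independent single-formant
updates was found to stall when F2 and F3 approach (their sensitivity
functions nearly cancel); the joint least-squares solve converges in
~20–40 iterations. Formants are tracked across iterations by frequency
continuity; the loop stops when both tracked formants are within `tol`
(default 1%) of the target, or when the response shows one isolated peak
at the target (which also makes the operation idempotent). Failure is
reported as a non-converged result carrying the iteration trace, never an
exception. A single-formant variant (`steer_formant`) moves one formant
(used for the secondary 3–3.5 kHz focus some singers add).

From the default neutral design, targeting 1800 Hz (the 12th harmonic of
a 150 Hz drone) merges F2 and F3 into one peak within 1% of the target in
~31 iterations (~3 s on one CPU).

## Designed tracts (synthetic data)

The designed neutral tract is parametric: length 17.5 cm, baseline
3 cm^2, a cosine taper out of the glottis, Gaussian log-area bumps for
the uvular constriction (CP: 1.6 cm^2 at 6 cm — the position is only
qualitatively "near the uvula", 6–8 cm is plausible and 6 cm gives the
strongest CP control), the alveolar-ridge constriction (CO: 0.8 cm^2 at
14 cm, where the retroflex tongue tip constricts), a sublingual expansion
(4.5 cm^2 at 15.8 cm) and a narrow mouth opening (0.6 cm^2, Sygyt being
sung nearly closed). Default feature width sigma = 1 cm. The defaults give
five well-separated formants (F3 − F2 ≈ 960 Hz), an essentially neutral
vowel, with F1–F5 within ~10% of a published neutral-design reference.

Two articulatory control claims are reproduced on the converged focused
tract: widening CO monotonically splits the merged peak (gap 0 → ~190 Hz
for ×1.0 → ×2.5), i.e. the oral constriction controls F2–F3 proximity;
rescaling CP moves the merged-formant frequency by ≥ 50 Hz. In the
*neutral* regime the CO → gap relation is weak and non-monotone in this
geometry (minimum near the 0.8 cm^2 default); the proximity control is a
focused-state phenomenon here.

Synthetic sagittal profiles are built by offsetting a straight or
circular-arc centerline by ±D/2 along its normals, returning the exact
ground truth for extraction tests. Song scenarios are seeded and
bit-reproducible: `sygyt` places one normal→focused transition (default
ramp 50 ms, in the reported 40–60 ms range) with the focus drawn from
1.5–2 kHz and snapped to a harmonic of f0; `sygyt_double` adds a constant
secondary focus in 3–3.5 kHz.

## Source/filter synthesis

The glottal source is a harmonic comb (default 40 harmonics, −12 dB/oct
tilt — a standard modal-voice approximation; no jitter by default,
vibrato as sinusoidal FM in cents). Static synthesis is additive with
per-harmonic amplitudes `source(k) × |H(k f0)|`, sine phases,
peak-normalized; linearity (output dB = source dB + filter dB within
1 dB) is verified spectrally. Dynamic synthesis proceeds in 10 ms hops
with 20 ms Hann windows at 50% overlap-add: per frame the normal and
focused tracts are interpolated geometrically in area
(`A_a^(1-w) A_b^w`, positivity-preserving) according to the scenario's
focus weight, the filter is re-evaluated at the harmonic frequencies
(cached on a 64-level weight grid), and harmonic phases accumulate
continuously so constant-weight passages equal the static path. Default
rate 44.1 kHz (96 kHz available).

## Spectral analysis

Spectrograms use 4096-sample Hamming windows at 95% overlap by default
(hop = 204 samples at 96 kHz), magnitude in dB re the global maximum with
a −120 dB floor. Edge frames whose window extends beyond the signal are
treated as undefined. Per frame: f0 is the strongest peak below 500 Hz
with a subharmonic-consistency correction (radiated spectra rise with
frequency, so the strongest low peak can be h2–h4; a consistent peak at
1/2, 1/3 or 1/4 of it is preferred) and quadratic bin refinement;
harmonics are local peaks within ±f0/2 of each k·f0 (missing ones NaN);
the formant trend is a 10× polyphase-FIR upsampling of the harmonic-level
sequence whose peaks serve as formant estimates (skipped below 4 usable
harmonics).

The focus statistic integrates linear spectral magnitude over the band
(default 1–2 kHz) and over 0–fmax (default 8 kHz) and squares the ratio:
`eR = (∫band P / ∫full P)^2 ∈ [0, 1]`. An alternative `power` variant
integrates `P^2` and does not square the ratio; both are available
because the two published descriptions of the statistic differ, and the
squared-ratio form is the default. Transition detection is a Schmitt
trigger with hold: an entry fires at an upward threshold crossing whose
next `min_hold` (default 100 ms) stays above `threshold − hysteresis` and
reaches `threshold + hysteresis`; exits are symmetric. The API default
threshold is 0.35; for this package's synthetic material the appropriate
threshold is ~0.10 (see below).

## What the synthetic focused state does and does not reproduce

The emulation reproduces, on fully synthetic audio: the merged F2/F3
peak at the target overtone; the focused overtone becoming the single
strongest spectral component (0 dB re max in the focused clip) with
flanking overtones suppressed by 15–20 dB (real singers show 15–35 dB);
a sharp eR(1,2) jump at the transition (~4.5× contrast, recovered within
one spectrogram hop for step transitions); and recovery of f0, focus
frequency (±100 Hz) and transition times from the audio alone.

It does **not** reach the absolute eR(1,2) levels (≥ 0.5) measured on
real singers: the synthetic focused state's median eR plateaus near 0.18
across the entire physiological design space (CO 0.3–1.2 cm^2, mouth
0.3–1.0 cm^2, area floor 0.05–0.3 cm^2). The reason is a source–filter
budget, not a tuning failure: eR ≥ 0.5 requires ≥ 71% of the integrated
spectral magnitude in 1–2 kHz, i.e. roughly 38 dB of volume-velocity
filter gain at 1800 Hz relative to the sub-500 Hz drone region, while a
realistically lossy tract resonance delivers at most ~27–31 dB
(|H| → 1 at low frequency is forced by flow continuity, and viscous plus
radiation losses bound the merged peak's height). Real Sygyt sources are
produced with pressed phonation and carry far more high-harmonic energy
than the −12 dB/oct modal approximation; with that source the same
filter would reach the measured levels. The package states the achievable
contrast (focused ≈ 0.18 vs normal ≈ 0.04) and tests against it; raising
the source richness (e.g. tilt −6 dB/oct) is the one-line change that
closes the gap, deliberately not made the default so the source stays a
standard modal model.

## Numerical and testing choices

- All randomness (scenario draws, test tracts) flows through seeded
  `numpy.random.default_rng`; generators are bit-reproducible.
- Formant-frequency measurements in tests refine peaks on local 0.05 Hz
  grids; finite-difference oracles use central differences at 1%
  perturbations and skip shifts below 0.02 Hz as unmeasurable.
- The lossless response has true poles; gains are clamped for dB
  arithmetic, and sensitivity/finite-difference validation is done with
  small damping so the peaks are smooth.
- Problem sizes: 44 tube sections, 2–3 s clips at 44.1 kHz, 2048–4096
  sample analysis windows — the full test suite runs in well under a
  minute and each analysis driver in seconds.

## Limitations

- No side-branch resonators (piriform sinuses), no 3-D acoustics, no
  nonlinear source–filter coupling, no glottal-pulse time-domain model,
  no subharmonic (Kargyraa-style) sources.
- MRI processing is out of scope; geometry starts from traced contours.
- The designed tract is parametric, not traced from measured anatomy;
  conclusions about specific singers require their measured area
  functions.
- The eR limitation described above: absolute focused-state eR levels
  require a richer-than-modal source.
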