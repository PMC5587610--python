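# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate — the things a user
needs to interpret the pipeline's output and the test suite's evidence.

## Homodyne lifetime model and estimator

Both the simulator and the estimator use the single-harmonic
(fundamental-frequency) homodyne model

    I(θ) = A · [1 + m · M(τ) · cos(θ − φ)],   tan φ = ωτ,
    M = (1 + ω²τ²)^(−1/2),   ω = 2πf,  f = 1600 Hz.

Real instruments of this kind chop the excitation with a square wave and
gate an image intensifier; the product of two square waves contains
higher harmonics whose size depends on duty cycle and gate width. The
package deliberately models only the fundamental: first-harmonic
analysis is the standard treatment for phase-shift lifetime estimation,
and using the same model in the simulator and the estimator keeps the
round trip exactly invertible, which is what makes the verification
chain conclusive. Chopper duty cycle and gate width therefore never
enter the model. The consequence: agreement on synthetic data does not
bound harmonic-contamination errors on real instruments — the
`modulation_lifetime` diagnostic (lifetime from the demodulation ratio,
requires knowing m) is provided precisely to flag such model violations
in real data, since the two lifetime estimates coincide only under the
ideal model.

The ten phase steps cover 0°–162° in 18° increments (half a modulation
period). Over half a period the cosine/sine basis is **not** orthogonal,
so the three-parameter fit (a, b, c) is solved through the exact normal
equations rather than Fourier quadrature sums, which would be biased
here. Per-pixel validity requires a fitted phase in the open interval
(0°, 90°) — boundaries are marked invalid, never clamped — and a DC
amplitude above 10 % of the stack's 99th-percentile amplitude (the
percentile reference is robust to hot pixels).

## Stern–Volmer conversion

PO2 = (1/τ − 1/τ₀)/k_q per pixel. Noise can push tensions slightly
negative near zero oxygen; values in (−1, 0) mmHg are clipped to zero
and counted, values below −1 mmHg indicate a calibration mismatch and
are invalidated instead. The 1 mmHg split separates "statistically zero"
from "physically wrong".

Replicate averaging is performed in the PO2 domain (tissue maps
averaged pixel-wise across the three repeats; vessel PO2 averaged per
vessel across repeats). Because the τ → PO2 map is convex, averaging in
the lifetime domain would give systematically different values for
non-constant fields; the test suite asserts this inequality so the
choice stays visible.

## Curvature flattening and boundary detection

How the curved optical section is flattened is an open design point; the
package uses the smallest assumption set: per row, the chorioretinal
interface is located via the argmax of the axially box-smoothed signal
(5 px window), band edges are refined by a 10 %-of-row-max threshold
crossing, a quadratic is fit to interface-position versus row, and rows
are realigned by sub-pixel linear interpolation of the fitted trend.
Detected edges use a half-pixel convention — a binary edge between
pixels j−1 and j is reported at j − 0.5 — because the expected position
of a uniformly distributed true boundary inside the crossing cell is the
cell midpoint; integer indices would carry a systematic half-pixel bias
that propagates into the depth scale and hence (quadratically) into
QO2. Retinal depth is normalized per 10-row bin, not globally, since
thickness varies across a section.

## Anisotropic smoothing

The 6 × 4 px (vertical × axial, 18 µm each) moving-average filter is
mask-aware: windows are truncated at borders and invalid pixels and
renormalized by the in-window valid count, so band-edge tPO2 is never
diluted by out-of-band zeros. For an even window of size s the span is
−s//2 … s−1−s//2 about each pixel; the resulting half-pixel centroid
offset is a pure translation of the depth axis and cancels in QO2
(which depends on curvature and layer width only).

## Three-layer diffusion model and QO2 fitting

Model: Dk·d²P/dx² = Q(x) on the outer retina (x from the chorioretinal
interface, expressed as a fraction of the outer thickness L = half the
retinal thickness), Q = q₂ in layer 2 (x₁ < x < x₂, photoreceptor inner
segments), zero in layers 1 and 3, Dirichlet boundary tensions, tension
and flux continuous at x₁ and x₂. The closed form is piecewise
linear–quadratic–linear; the six segment coefficients come from a 6×6
linear solve. An independent finite-difference solver (2000 nodes,
cell-averaged source so the layer boundaries are represented with
sub-cell accuracy) is kept in the package purely as a numerical
cross-check; agreement is max |ΔP| ~ 5·10⁻⁵ mmHg over random
physiological parameter sweeps.

Fitting minimizes squared residuals over (P_C, P_L, x₁, x₂, q₂) with
`scipy.optimize.least_squares` (trf) under box constraints;
x₂ = x₁ + (1 − x₁)·s₂ keeps the ordering constraint smooth, and q₂ ≥ 0
is a bound. Initialization: P_C from the profile maximum, P_L from the
sample nearest 50 % depth, x₁ = 0.2, x₂ = 0.4, q₂ from the largest
positive discrete second difference (the consuming layer is convex).
Three seeded, jittered restarts guard against local minima. A fit is
excluded from the mean QO2 when it fails to converge or ends on an
active constraint; q₂ = 0 is treated as a legitimate "no consumption"
answer, not an active bound. QO2 is reported averaged over the whole
outer retina, QO2 = 100·q₂·(x₂ − x₁) (density 1 g/mL), which makes the
reported value depend on Dk only through the fit itself.

**Filter-aware fitting.** The consuming layer is only ~5 px wide at the
default geometry while the axial filter arm spans 4 px, so the filter
materially blunts the profile curvature — fitting the sharp-kink model
to smoothed data underestimates QO2 by ~15 %. The pipeline therefore
fits the *box-averaged* model: the moving-window mean of the closed-form
profile, evaluated exactly from its piecewise antiderivative, with the
window width equal to the filter's axial extent in fractional units
(profile continuation beyond 50 % depth is taken constant at P_L).
Samples whose window crosses the chorioretinal band edge have truncated,
asymmetric windows that the symmetric-box model does not describe; they
are left out of the fit. With this, the end-to-end noise-free QO2 error
is below 1 %.

## OEF

Hill form S = PO2ⁿ/(PO2ⁿ + P50ⁿ) for the rat oxyhemoglobin dissociation
curve; content C = capacity·S + solubility·PO2 with the dissolved term
included by default (set solubility to 0 to drop it).
OEF = (C_A − C_V)/C_A, computed per animal from that animal's PO2_A and
PO2_V and only then averaged across a cohort — a cohort-mean OEF is the
mean of per-animal OEFs, not the OEF of the mean tensions.

## Constants and defaults

| constant | default | units | note |
|---|---|---|---|
| R0 τ₀ / k_q | 637 µs / 381 | s, mmHg⁻¹s⁻¹ | literature placeholder |
| G2 τ₀ / k_q | 251 µs / 281 | s, mmHg⁻¹s⁻¹ | literature placeholder |
| P50 / n | 36 / 2.7 | mmHg, – | rat Hill curve, placeholder |
| Hb capacity | 0.2 | mL O2/mL blood | placeholder |
| O2 solubility | 3·10⁻⁵ | mL O2·mL⁻¹·mmHg⁻¹ | placeholder |
| Dk | 1.97·10⁻¹⁰ | mL O2·cm⁻¹·s⁻¹·mmHg⁻¹ | placeholder, ×60 internally |
| pixels | 3 (y) × 4.5 (z) | µm | from the 10 px = 30 µm bins and the 6×4 px = 18 µm filter |

All placeholders emit `CalibrationDefaultWarning` when used and are
echoed into every run log. They are *not* measured values for any
specific instrument; quantitative use requires supplying the
instrument's own calibration.

## The synthetic scene

The default scene is the healthy-rat operating point used throughout
the tests: 350 × 120 px image (1.05 mm of retina vertically), retinal
thickness 230 µm, a quadratic interface trace with ~8 px sag, two
arteries at 41 mmHg and one vein at 25 mmHg (circular cross-sections,
radius 8 px, placed at quarter-depth), inner tissue at 23 mmHg with a
4 mmHg Gaussian elevation (σ = 45 µm) next to arteries tapering to zero
at 50 % depth, and an outer profile generated by the three-layer model
with P_C = 60 mmHg, P_L = 23 mmHg, x₁ = 0.2, x₂ = 0.4 and
QO2 = 0.57 mL O2/100 g/min. Acquisition: 10 phases, 1.6 kHz, modulation
depth 0.8, 3 replicates per channel, amplitude 1000 counts, additive
Gaussian camera noise (σ configurable; 20 counts = 2 % of amplitude in
the noisy verification runs — ICCD read noise dominating at low light
motivates Gaussian rather than Poisson noise, and it keeps the oracles
analytic).

What the simulator does **not** emulate: optical scattering and the
instrument PSF (the real effect that blunts tPO2 curvature and lowers
measured QO2 in vivo), photobleaching, eye motion, blood-column depth
within vessels, and square-wave harmonics (above). Passing tests
therefore demonstrate the correctness and internal consistency of the
*analysis* — estimator exactness, model inversion, bookkeeping,
determinism — not robustness of the measurement to those physical
effects.

## Problem sizes and determinism

Verification runs use the full 350 × 120 × 10-phase × 3-replicate ×
2-channel stack set (a realistic section's worth of data), 35 depth
profiles, 100 random parameter draws for the oracle sweep and 35-profile
noisy ensembles; these sizes were chosen so every check runs in seconds
while exercising realistic dimensions. All randomness (camera noise and
fit restarts) flows from a single configured seed, and identical
config + seed reproduces every output file byte for byte (no timestamps
are written).
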