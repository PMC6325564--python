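# Methods

`nemaswim` turns bright-field movies of a single swimming *C. elegans* (or
synthetic stand-ins with exact ground truth) into a biomechanical profile per
animal — body length L, swimming speed U, beating frequency f, period-averaged
propulsive force ⟨F_P⟩ and mechanical power ⟨P⟩ — plus curvature kymographs,
head-normalized curvature profiles, movie inclusion criteria, and the group
comparison statistics used in behavioral phenomics. This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## The synthetic gait generator

No raw recordings are deposited with the study this pipeline is modeled on,
so the generator is a first-class, tested component: it defines the study
conditions under which every downstream claim is validated.

The gait is **curvature-first**. A traveling curvature wave

    κ(σ, t) = κ₀ · A(σ) · S(σ) · sin(2π(σ·L/λ − f·t)),   σ = s/L ∈ [0, 1]

is integrated along the body to tangent angles θ(σ) (cumulative trapezoid) and
then to coordinates by stepping exactly ds = L/(n−1) per segment using midpoint
angles. Consequences that the tests rely on: the body is inextensible to
machine precision, and the analytic κ is the exact ground truth for the
finite-difference kymograph (a y(x)-sinusoid construction would have neither
property). The mean tangent is pinned opposite the travel direction — the wave
runs head→tail, so the animal leads with its head — and the centroid is pinned
to a straight track advancing at the prescribed U.

* **Envelope** A(σ): linear decay from 1 at the head to 0.5 at the tail
  (configurable), reproducing the head-dominant beat of real animals; it is
  also what makes head/tail assignment identifiable.
* **Suppression window** S(σ): multiplicative factor on σ ∈ [0.5, 0.8]
  emulating regional loss of neuromuscular function in the SMA-model gait;
  the `defective` preset uses factor 0.15, the `smn1_*` presets 0.35.
* **Presets**: one per genotype × stage, parameterized to the published group
  means and SDs of length (0.39–0.70 mm), speed (0.16–0.28 mm/s) and frequency
  (1.7–2.6 Hz). Cohorts draw per-worm values from truncated normals at the
  published SDs, with mild shape jitter (envelope tail ±0.05, wavelength
  fraction ±0.05, lognormal 8% on κ₀) so that normalized profiles vary between
  individuals as they must for position-wise statistics to be meaningful.
* **Amplitude and wavelength defaults**: λ = 1.5 L (swimming wavelengths
  exceed the body length; ~0.6 L is a crawling value) and κ₀·L = 6, a
  realistic head-curvature amplitude that keeps shapes free of
  self-intersection (a validation check rejects self-intersecting frames).
* **Timebase**: 30 frames/s, 4 s default duration (≥ 4 beat cycles, the
  inclusion threshold); generation refuses < 4 cycles unless a deliberate
  QC-reject case is requested (`allow_short`).

**What the generator does *not* emulate**: hydrodynamic self-consistency of
the prescribed translation (see force balance below), body-wave asymmetries
between dorsal/ventral bends, omega turns and reversals, multi-worm scenes,
3-D out-of-plane motion, and illumination gradients. Passing round-trip tests
therefore demonstrates that the *measurement chain* is unbiased under these
idealized conditions, not that segmentation would survive arbitrary real-world
imaging artifacts.

Rendering rasterizes each centerline as a union of disks of local half-width
a(σ) (0.025 mm mid-body, piecewise-linear taper over the terminal 10% to 25%
of the mid-body width — the thin, translucent ends are what motivates trimming
5% of the body from curvature profiles), subtracts the band from a bright
background (200 − 120 intensity), Gaussian-blurs (1 px) and adds Gaussian
noise (SD 8). The pre-blur mask is stored as segmentation ground truth.
Rendering is bit-reproducible from its seed.

## Tracking

Segmentation is Otsu's inter-class-variance threshold per frame (bright-field
worm histograms are strongly bimodal; a fixed threshold can be supplied),
keeping the largest dark connected component above a minimum area, with
morphological closing and hole filling. The centerline is the topological
skeleton pruned to its longest end-to-end path (double BFS), **extended along
the end tangents to the mask boundary** — the skeleton of a band stops about
one body radius short of each tip, which would otherwise bias L by ~5% —
then Gaussian-smoothed (2 px) and resampled to n = 100 points at uniform
spacing. The resampler interpolates only on the source polyline and iterates
the parameter positions until consecutive chords are equal to 1 part in 10⁹,
so downstream arclength derivatives see a uniform grid. Local half-width is
read from the Euclidean distance transform along the path.

Orientation: each frame is flipped to minimize end-to-end displacement against
the previous frame; globally, the head is the end with the larger
time-averaged terminal (15%) curvature. When the two ends differ by a ratio
< 1.1 the assignment is flagged low-confidence and can be overridden. Isolated
extraction failures (< 3 consecutive frames) are linearly interpolated;
longer runs or > 20% failures abort the movie.

Coordinates are image pixels converted to mm, origin top-left, y downward,
frames 0-indexed; all physics is done in mm, s, mPa·s.

## Kinematics

* **Curvature** κ = dθ/ds of the tangent angle, computed at the n−2 interior
  points after Savitzky–Golay smoothing of θ along the body (window 5% of
  body length, order 2 — exact for constant curvature, so a circular arc of
  radius R yields κ = 1/R to < 1%). Positive κ = counterclockwise bending.
* **Frequency** f: dominant peak of the Hann-windowed power spectrum of the
  mid-body (σ ∈ [0.3, 0.5]) curvature signal, refined by parabolic
  interpolation on log power; requires peak ≥ 10× the median spectral floor,
  else `NoOscillation`. A zero-crossing cycle counter provides a cross-check
  and the successive cycle periods used by QC. T = 1/f identically.
* **Wave speed**: the phase of the dominant frequency component per body
  position, amplitude-weighted and regressed linearly on arclength; the slope
  gives λ = 2π/|dφ/ds| and wave speed = λf. Phase-fit residual > 0.6 rad or
  λ > 10 L (a standing wave has both) returns a flagged absent value.
* **Speed** U: mean magnitude of the centroid velocity, central differences
  on a 5-frame-smoothed track with the edge-padded frames excluded from the
  mean (raw differentiation at 30 fps amplifies pixel noise).
* **Curvature profile**: time-averaged |κ| vs σ, trimmed to σ ∈ [0.05, 0.95],
  normalized by the head-most retained value (exactly 1 by construction).
  The stated procedure this reimplements reads "average in time, then take
  the magnitude", but that order annihilates a zero-mean wave (the package
  asserts this as a test), which is incompatible with the nonzero published
  profiles; both orders are implemented and **magnitude-first is the
  default**, being the order that reproduces a flat ≈ 1 profile for a
  uniform-envelope wave. Group profiles average per-worm normalized profiles
  and renormalize. "Amplitude" appears in the profile vocabulary of the field
  but has no canonical definition here and is not reported.

## Resistive-force-theory dynamics

At Re ≪ 1 each slender segment experiences drag linear in its velocity
components, dF = −(C_N u_N n̂ + C_T u_T t̂) ds. Because the animal is
self-propelled and force-free, period-averaged thrust balances drag, letting
muscle output be estimated from the drag integral:

    F_P(t) = ∫ (C_N u_N + C_T u_T) ds ,    P(t) = ∫ (C_N u_N² + C_T u_T²) ds .

* **Coefficients**: the source study cites Lighthill's refinement without
  printing formulas. The default `lighthill` model is
  C_T = 2πμ/(ln(2λ/a) − ½), C_N = 4πμ/(ln(2λ/a) + ½); the `gray_hancock`
  alternative is the original ratio-2 simplification (same C_T, C_N = 2C_T).
  Both are exposed because the choice is unverifiable; all results record
  which was used. λ is the *measured* undulation wavelength (body length as
  fallback), a the median tracked mid-body half-width (L/25 fallback).
* **Viscosity** μ = 1.0 mPa·s by default (aqueous buffer, room temperature);
  every force and power is exactly linear in μ.
* **Units**: with μ in mPa·s, lengths in mm, velocities in mm/s, C·u·ds is
  directly nN and C·u²·ds directly pW — no hidden conversion factors.
* **F_P(t) definition**: the integral as written is sign-ambiguous. Per
  frame, segment forces are projected on the instantaneous swimming
  direction; F_P(t) is the summed forward-pushing (thrust) part, the opposing
  part is reported as drag, and the full vector sum as the net force. Period
  averages use the largest integer number of beat periods (partial remainder
  discarded); with no detectable period the full record is averaged and
  flagged.
* **Force-free closure**: RFT force is linear in velocity and rigid
  translation superposes, so the speed at which the net period-mean force
  vanishes has a closed form (`balanced_speed`), and `calibrate_kappa0`
  inverts it for amplitude. With wall effects excluded (deliberately — no
  boundary-element or chamber-wall corrections), the balanced speed saturates
  near 0.08–0.19 mm/s across the preset geometries, *below* the published
  speeds of 0.16–0.28 mm/s: unmodified RFT under-predicts swimming speed for
  this animal, a known limitation. Presets therefore prescribe the published
  speeds (the condition being emulated), accepting that those kinematics are
  only approximately force-free; the closure property (period-mean |net
  force| ≤ 10% of ⟨F_P⟩ — measured ≈ 1%) is validated on a gait translating
  at its balanced speed, the regime where the closure is meaningful.

## Inclusion criteria (QC)

A movie is rejected for (i) fewer than four beating cycles (duration × f,
with a 0.05-cycle numerical tolerance so a truly-4-cycle record is not
rejected by estimator jitter; exactly four passes), (ii) wall interaction —
any body point within one body radius (configurable) of the chamber boundary,
(iii) irregular beating — successive cycle-period CV > 0.3 (configurable) or
failed frequency estimation. The CV threshold and wall margin are declared
surrogates for judgements the original criteria leave unspecified. Missing
chamber geometry skips the wall check with a warning. Acceptance is monotone
in added clean cycles.

## Group statistics

Metrics are compared with the tie-corrected Kruskal–Wallis omnibus test and
Dunn's pairwise rank test (hand-implemented on pooled ranks with the tie
variance term, verified against a hand computation) under Holm–Šidák
adjustment. The procedure name "dunnett" is accepted but mapped to Dunn with
a warning: Dunnett's test is parametric and incompatible with rank data, and
the two names are used interchangeably in parts of the literature this
mirrors. Curvature profiles are compared position-by-position with Welch
t tests (variances differ between genotypes) under Holm–Šidák correction
across positions; positions constant in both groups (the head, 1 by
construction) get p = 1. Percent changes are computed from group means at
full precision; display rounding is half-up (62.5 → 63, matching the
published rounding) and isolated from stored values. Calibration is verified
by simulation: omnibus type-I error within [0.03, 0.07] at α = 0.05 over 1000
replicates, and family-wise any-rejection ≤ 0.07 over 500 same-preset null
cohort replicates.

## Problem sizes and numerical choices

Tests and the acceptance script use 2–4 s records at 30 fps with n = 100
body points (64 for the null-calibration cohorts), rendered at 5 µm/px;
the tracker sweep covers 3 lengths × 3 frequencies. These sizes were chosen
so every claim is exercised end-to-end while the whole suite stays fast;
mesh convergence (n = 100 → 400 changes ⟨F_P⟩ and ⟨P⟩ by < 2%) and a
fine-grid quadrature oracle justify the defaults. Degenerate inputs fail
loudly by design: repeated centerline points, straight worms in profile
normalization, single-frame stacks, and uniform frames raise typed errors
naming the offending field or frame.

## Known limitations

RFT here has no wall corrections although the emulated chamber is 1 mm deep,
so absolute forces/powers are best read comparatively across groups; the
skeleton-based centerline is one of several defensible midline definitions
(a contour-midline variant could differ near the tips); suppression windows
have sharp edges; and the generator's per-worm jitter is independent across
parameters, ignoring the allometric correlations of real cohorts.
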