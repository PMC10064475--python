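# Methods

## Model

The package implements the classical energy model of first-order motion:
linear spatiotemporal filtering, squaring, and opponency. A stimulus is a
spatiotemporal luminance volume I(x, y, t) in [0, 1]; the model is entirely
luminance-driven (color inputs are reduced to luminance with Rec.601
weights at ingest, and the generators emit luminance directly — e.g. the
classically yellow/blue stepping feet become bright/dark bars). This is an
assumption of the model class, not an approximation we control: chromatic
motion pathways are out of scope.

Each direction channel θ_k = 360·k/K is an oriented quadrature pair in
x–y–t built from separable components:

* **Spatial**: Gabor quadrature pair with carrier wave vector along θ_k.
  The even (cosine) kernel is DC-corrected by projecting out the Gaussian
  envelope — this keeps the correction local instead of adding a constant
  pedestal — and both kernels are unit L2 norm. The odd kernel is exactly
  antisymmetric under 180° rotation, the even exactly symmetric, so a
  static image excites opposite channels identically.
* **Temporal**: causal biphasic filters
  f_n(t) = (t/τ)^n e^(−t/τ) [1/n! − (t/τ)²/(n+2)!], n = 3 (fast) and
  n = 5 (slow), sampled at integer frame lags and unit-normed.
* **Combination**: even·fast − odd·slow and odd·fast + even·slow, each
  divided by √2 so the 3-D kernels are unit-norm (the components are
  orthogonal, so the combined norm is exactly √2). Squaring and summing
  the pair gives the channel energy; direction selectivity follows from
  the ~90° phase relation between the fast and slow temporal responses.

Opponency is full-circle: O_k = E_k − E_{k+K/2}, computed so the
antisymmetry O_k = −O_{k+K/2} is exact in floating point. The readout is a
rectified population vector sum over opponent channels; the decoded angle
is the atan2 of the resultant and the magnitude its norm. Resultants that
cancel only to round-off (≤ 1e−12 of the total rectified weight) are
snapped to zero and flagged undefined rather than reported as a spurious
direction.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| K | 8 | channels | finest bank for which opposite pairing and 90°-rotation symmetry are cheap to verify; 45° spacing bounds decoding error at ±22.5° |
| λ (spatial wavelength) | 8 | px | comfortably above Nyquist, small enough that 128 px frames hold many cycles |
| σ (spatial envelope) | 3 | px | ~1-octave bandwidth; a 15-tap kernel truncates the Gaussian beyond 2.3 σ, keeping quadrature-energy phase ripple ≈ 0.3 % (< the 1 % contract) |
| kernel size | 15 | px | smallest odd support holding λ = 8, σ = 3 |
| τ (temporal constant) | 0.75 | frames | with 16 taps the support holds both biphasic lobes (the slow filter's sign change sits at t/τ ≈ 6.5) and the tail falls below 1 % of peak (measured 0.04 % / 0.48 %) |
| temporal taps | 16 | frames | see τ; also the warm-up latency of the stream |
| magnitude floor (ring phase) | 0.1 | fraction of annulus max | excludes background pixels whose direction is noise-dominated |
| color-wheel percentile | 99 | % | robust per-frame display max; a fixed absolute scale mode exists for cross-condition comparison |

The bank's preferred speed at these defaults is ≈ 1 px/frame (measured on
matched gratings; response falls to < 5 % at speed 0 and < 50 % at 4× the
preferred speed). All parameters are overridable through `RunConfig` /
flat YAML; a multi-scale bank (list of wavelengths, energies summed per
direction) is available but off by default — a single scale keeps the
quantitative checks sharp.

## Conventions and numerics

* **Coordinates.** Image convention: x rightward, y downward; "clockwise"
  always means clockwise as displayed. Trigonometry is done in a y-up
  frame and converted at the boundary by one involutive function
  (`geometry.screen_from_math`), which is tested on its own.
* **Boundaries.** Spatial filtering uses symmetric-mirror ("reflect")
  padding, so frame size is preserved and no spurious edge energy appears;
  temporal filtering is causal and valid-only — output starts once the
  16-frame buffer is warm, and no future frame ever leaks in.
* **Precision.** All accumulation is float64; the brute-force 3-D
  correlation oracle in the tests matches the streaming separable engine
  to ~1e−14 on random input.
* **Stimulus rendering** evaluates analytic patterns at continuous
  coordinates per frame (no template shifting), so sub-pixel speeds are
  exact; rectangles are anti-aliased by pixel-coverage fractions. Gabor
  elements are added on mid-gray and clipped to [0, 1].
* **Ring phase** uses magnitude-weighted circular statistics. Per-frame
  measurements are pooled by summing resultant vectors weighted by each
  frame's total magnitude weight. An annulus with no pixel above the floor
  yields the undefined signal (`None`), never a number.
* **Degenerate flows.** atan2(0, 0) is never trusted: zero-magnitude
  pixels carry NaN angles and render neutral (black).

## Synthetic stimuli and what they do (not) show

The generators emulate the demonstration conditions: drifting and
counterphase sinusoidal gratings (probes), the stepping feet (opposite-
polarity bars, 20×8 px, 1 px/frame over square-wave stripes of period
16 px), solid textured annuli (product of an n-fold angular modulation and
a radial carrier under a Gaussian radial envelope, so pure rotation moves
only the angular phase and pure expansion only the radial one), rings of
oriented Gabor micropatterns, and a fixational-eye-movement emulation
(global random-walk translation with reflect borders, increment RMS =
requested amplitude).

Ring geometry in the shipped conditions is sized so the ring plus its 3 σ
envelope stays inside a 128×128 frame for the whole sequence: the rotating
annulus sits at radius 24 px (12-fold texture ≈ matches the bank's
passband; 3°/frame ≈ 1.3 px/frame tangentially), the expanding Gabor ring
grows 28 → 51 px over 24 frames, the plain expanding annulus 20 → 47 px
over 28 frames.

These stimuli are noise-free, rigid, and spectrally matched to the bank.
Passing tests therefore show that the *model pipeline* is correct and that
the illusions follow from its structure (e.g. the ±45° illusory phases are
pure aperture-problem geometry); they do not show robustness to sensor
noise, broadband natural textures, occlusion, or photometric
nonlinearities of a real camera feed. Camera input is supported through
the same frame interface but is not exercised in tests.

## Design choices where the design was open

* **Opponency and readout.** Full-circle signed opponency with a rectified
  vector-sum readout — the conventional population decoding; rectification
  uses each direction's positive evidence exactly once since opponent
  pairs are exact negations.
* **Normalization.** Divisive contrast normalization
  (O / (ε + local mean E), Gaussian pool of 2 σ_spatial, ε = 1e−3) exists
  but is **off** by default: the stepping-feet contrast dependence — the
  point of that demonstration — requires output strength to track
  stimulus contrast. No rectification or temporal smoothing is applied
  before decoding.
* **Stepping-feet strength measure.** Mean decoded-flow magnitude in a
  3 px-dilated box around each foot, per frame. At full background
  contrast the two feet's series are strongly anti-correlated and modulate
  at the stripe period; reducing background contrast by 75 % roughly
  halves the modulation depth ((max−min)/(max+min)).
* **Gabor-element tilt parameter** is defined as the rotation of the
  carrier *wave vector* away from the local outward radial direction
  (clockwise positive). With this definition an expanding ring of
  elements tilted +φ decodes to a ring phase near +φ, which makes the
  illusion's geometry explicit.
* **Time-reversal symmetry** of the opponent code (reversal swaps opposite
  channels) is exact only in the ideal-quadrature limit; discretely it
  holds to ~1e−6 for channel-energy aggregates over interior pixels and
  frames of a drifting grating, which is how it is tested. Per-pixel
  instantaneous equality is not a property of causal discrete filters, and
  no such claim is made.

## Known limitations

* Single luminance channel; no second-order (contrast-defined) motion, no
  chromatic motion.
* One spatial scale by default: stimuli far from the bank's passband
  (very coarse or very fine texture) produce weak, noisy flows.
* The 16-frame causal warm-up delays output; short clips lose that many
  frames.
* Video containers besides GIF require an imageio backend with ffmpeg;
  PNG frame directories are the canonical interchange format.
* The color-wheel hue anchor is a display convention (config), not a
  calibrated quantity.
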