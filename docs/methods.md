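# Methods

## The parameter: a background-normalized band difference

Every quantity in the pipeline derives from one scalar per spectrum. The
*target value* is the mean intensity over four mid-wavelength bins
(710, 720, 730, 740 nm, where a cy5.5-like NIRF probe emits) minus the mean
over four low-wavelength bins (640, 650, 660, 670 nm, dominated by tissue
autofluorescence). Two properties make this a good probe detector:

* it is **linear** in the spectrum, so the target of an ROI-mean spectrum
  equals the mean of per-pixel targets — ROI averaging and parametrization
  commute, and the choice between them is immaterial;
* any **spectrally flat** component cancels exactly, whatever its
  brightness, so broadband autofluorescence (skin, food particles, fur) is
  suppressed rather than thresholded away.

The target value of the probe ROI is divided by the target value of a
background ROI (skull) to give the *probe-to-background ratio*. The ratio is
invariant to global intensity scale (exposure, lamp power) and is kept
signed: a probe dimmer than background in the mid band gives a negative
ratio, which is reported numerically and clamped to zero only when mapped
to the synthesizer. A background target at or below `eps` (default 1e-9
intensity units) is an error, not a silent fallback: the method presumes
reference tissue with a positive mid-minus-low spectral slope, and a flat or
inverted background makes the ratio meaningless. Bins are keyed by
wavelength, not channel index, and are configurable so probes other than
cy5.5 can be mapped by moving the mid bins onto their emission band.

## Sonification: two-oscillator FM

The ratio is used directly (scale 1, clamp at 0) as the modulation index
*I* of simple frequency modulation,
`s[n] = A sin(2π f_c n/sr + I sin(2π f_m n/sr))`. Defaults: carrier 220 Hz,
modulator 110 Hz (a 2:1 harmonic ratio — harmonic timbres are easier to
compare by ear), 1 s notes at 44.1 kHz, peak amplitude 0.8, 10 ms
raised-cosine fades to avoid clicks. Sideband amplitudes follow the Bessel
law: the component at `f_c + k·f_m` has magnitude `A·|J_k(I)|`, so the
number of audible sidebands grows with *I* (Carson's rule) and a stronger
probe is heard as a richer timbre at fixed pitch. This law is also the
module's numerical oracle: rendered DFT magnitudes must match
`scipy.special.jv` to within 1% of the largest sideband in an alias-safe
configuration (`f_c` = 2000 Hz, `f_m` = 100 Hz, fades off, integer-periodic
over 1 s — every component then falls exactly on a DFT bin).

Two measured descriptors summarize timbre. The *spectral centroid*
(magnitude-weighted mean frequency) rises with *I* at the musical defaults
because sidebands that would fall below 0 Hz fold back upward; in a
symmetric alias-free configuration the centroid stays at the carrier, which
is why the brightness comparison uses the defaults and the sideband count
uses the analysis configuration. The *sideband count* is the number of
components at `f_c ± k·f_m` (k ≠ 0) above 1% of the spectral peak.

Synthesis contains no randomness: identical inputs give bit-identical
buffers, and WAVs are written as mono 16-bit PCM with round-to-nearest
quantization (round-trip error ≤ 1/32767).

## Parametric images

Per-pixel ratios are min-max rescaled to [0, 1] (recording the window; a
constant map rescales to all zeros and renders cold blue rather than
erroring) and mapped through an explicit HSV rainbow, hue = 240°·(1 − v)
with full saturation and value, quantized round-half-up to 8-bit RGB. The
formula — not a named library palette — keeps rendered images
bit-reproducible. An optional 1st–99th percentile clip is available for
noisy maps, off by default. Overlays blend the rainbow over a grayscale
photograph where the rescaled map exceeds a threshold.

For detection scoring, `otsu_mask` smooths the ratio map with an isotropic
Gaussian (default σ = 1.5 px, the scale of the smallest lesions of
interest — the spatial-pooling analog of probing with a small ROI) and
applies Otsu's threshold; masks are compared to ground truth with the Dice
coefficient.

## The phantom: study conditions in closed form

The generator emulates one imaging session on an 18-channel 640–810 nm
grid (128×128 px by default):

* **background**: log-linear autofluorescence, `B·exp(slope·(λ − 640))`
  with B = 100 and slope = +0.01/nm. The slope is positive so the
  background's mid-minus-low target value `d = B·Δe` is positive — the
  ratio's denominator presumes reference tissue whose emission rises across
  the acquisition window; a decaying background would make the method's
  normalization undefined by its own contract;
* **tumor**: a Gaussian emission bump `A·exp(−(λ − 720)²/(2·25²))` added
  uniformly inside an ellipse (center (64, 80), semi-axes (12, 9) px,
  A = 300). The peak sits at 720 nm, inside the mid bins, because the bins
  define what "signal" means to this method — not at the in vitro cy5.5
  emission maximum;
* **noise**: additive zero-mean Gaussian (sd = 5), clipped at zero. Gaussian
  rather than Poisson keeps the closed-form expected ratio exact; a Poisson
  flag exists for robustness checks. All randomness is seeded.

Because every ingredient is analytic, the expected ratio is closed-form:

    expected_ratio = 1 + A·Δg / (B·Δe),

with Δg and Δe the mid-minus-low bin-mean differences of the unit bump and
unit background. Defaults give 3.123, in the range reported for clearly
visible tumors in vivo. A noise-free phantom must reproduce it to 1e-9
relative; at default noise the mean over 50 seeds stays within 5%, and
background-vs-background ratios stay in [0.8, 1.2].

Two scenario transforms:

* `extravasation_control` adds a small, very bright spot (5× tumor
  amplitude) at a tail position — a positive control whose ratio (~11.6)
  dominates every other ROI;
* `masked_tumor_config` builds the weak-signal regime: a 32×32 close-up
  field around a suspicious area with a tiny (3, 2)-px tumor, amplitude set
  so the expected ratio is 1.8, and noise raised so the best single-band
  per-pixel contrast is 1.8 noise-sd — below the ~2 sd rule of thumb for
  visual detection. The scenario isolates what band averaging buys: the
  ratio pools eight bins and the probe ROI pools 13 px, so the measured
  ratio still separates cleanly from background even though no single band
  shows the lesion.

What the phantom does **not** emulate: depth-dependent photon transport
(scattering/absorption), detector fixed-pattern noise, motion, or textured
autofluorescence artifacts. Tests passing on phantoms therefore demonstrate
the correctness of the processing chain under its stated model, not in vivo
performance.

## Statistics

Per-ROI ratios are tabulated as (subject, ROI, role, replicate, ratio);
replicates are averaged within subject before testing to avoid
pseudo-replication. Groups (probe vs background roles) are compared with the
two-sided Wilcoxon rank-sum test: exact null by enumeration when the
combined sample is ≤ 12 without ties (the switch point balances runtime and
fidelity and is configurable), otherwise the normal approximation with
midranks, tie correction and continuity correction. If every value is
identical the test is degenerate: p = 1 with a warning flag. A paired
signed-rank mode is provided since per-animal pairing of tumor and own
background is an equally plausible design; unpaired is the default. Exact
p-values are property-tested against exhaustive enumeration of all
labelings, the asymptotic branch against a 2000-replicate null simulation
(type-I error within [0.03, 0.07] at n = 10 per group).

## Numerical and interface conventions

* Coordinates are 0-based (row, col); rectangles half-open; polygon
  membership by pixel centers (row+0.5, col+0.5) under the even-odd rule;
  circles select pixels whose integer coordinates lie within the radius.
* Cubes travel as multi-page TIFF (page = channel, dtype preserved) with a
  JSON sidecar carrying `wavelengths_nm`; channel semantics live in the
  sidecar, so 17- and 18-channel cubes both work.
* Integer cubes are promoted to float64 at extraction; no rescaling.
* All CLI commands are deterministic given a seed; exit code 2 signals
  usage/data errors; unknown config keys are rejected.

## Known limitations

* Global histogram thresholding (Otsu) cannot segment the masked-tumor
  close-up: with per-pixel ratio SNR capped near 2.1 by the visually-masked
  construction, the smoothed lesion peaks at ~4.5σ while occupying ~2% of
  the field, and Otsu's between-class criterion prefers splitting the
  background noise distribution (Dice ~0.1). An oracle threshold on the
  same smoothed map reaches Dice ~0.85–0.9, so the information is present;
  reliable small-lesion segmentation needs a detection-theoretic threshold
  (e.g., a noise-calibrated false-positive rate), which is outside the
  present scope. At default contrast the same detector yields Dice ≈ 0.99.
* The ratio-to-index mapping is linear with a clamp; no psychoacoustic
  (loudness/pitch) scaling is attempted.
* The FM note is a fixed 1 s event per probe; no real-time or interactive
  audio.
* Group comparisons are single tests; no multiplicity correction is
  applied.
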