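# Methods

## The model in brief

`deformsense` formalizes deformation perception as template matching on
the spatial pattern of motion-direction responses. The processing chain
is: (1) spatiotemporal filtering of a narrow strip at the bar's edge;
(2) half-wave rectification; (3) divisive normalization — together the
V1 motion-energy stage; (4) Gaussian spatial pooling; (5) opponent
cosine weighting over direction; (6) rectification; (7) normalization —
the MT direction-selective stage. A higher-order unit then scores the
position × direction response map against the separable template
`K(x, θ) = sin(2πfx + φ)·cos(θ − α)` by zero-mean normalized
cross-correlation, maximized over a 32-phase grid, and the score is
linked to report proportions through `p = a·exp(b·NCC)`.

## Conventions

* Image coordinates: x rightward, y **downward** (row order); the bar's
  midline is x = 0.
* Direction labels: 0° = leftward, 90° = downward, 180° = rightward,
  270° = upward, in 15° steps. The kernel's preferred direction α = 0°
  (leftward) matches this convention.
* Each energy channel is labelled with the motion direction of its
  drifting carrier; the 24 orientations with signed temporal frequency
  give 24 distinct directions.
* Luminance is linear cd/m² throughout; no display gamma is modelled.

## Stimuli

**Deforming bar.** Both edges of the 0.6° × 5.0° bar are displaced by
the same travelling sinusoid (constant-width undulation); a single-edge
mode exists. Deformation amplitude is 0.04 **degrees** — an amplitude in
cycles/deg would be dimensionally inconsistent — at 1 Hz, with
deformation frequencies 0.1–6.4 cpd. Edges are anti-aliased by linear
coverage blending over one pixel. Bar/background luminances default to
38/76 cd/m².

**Moiré stimulus.** A static bar occludes a sinusoidal grating tilted
0.5–16° from vertical (6.4/12.9/25.8 cpd, 1 Hz drift, Michelson
contrast 0.75, mean 74.5 cd/m²), windowed by a horizontal Gaussian
contrast envelope (SD 0.62°) centred on the bar. A square-wave carrier
is available behind a flag. The intersections of the bar's edge with
the grating crests translate vertically at `tf/(sf·sinθ)` deg/s — the
moiré signal that drives the illusory deformation.

**Rendering resolution.** Default 200 px/deg, so the finest filter
wavelength (0.04°) spans 8 px and the 0.04° amplitude is resolved with
sub-pixel precision; the display such stimuli were designed for
(~27 px/deg) is far too coarse for model analysis. Clips default to
180 frames at 60 Hz (3 s presentations), but every analysis preset
renders 12 frames: the model consumes a single 6-frame window (below),
and nothing downstream depends on clip length beyond that.

## V1 stage

Filters are square spatiotemporal Gabors whose support equals their
spatial wavelength (0.08° for the deforming bar; 0.16/0.08/0.04° for
the 6.4/12.9/25.8 cpd moiré conditions, matching the analysis-strip
width). The spatial envelope is an isotropic Gaussian of SD = size/4
(no envelope is otherwise specified); the temporal window is flat over
6 frames (~100 ms) with carrier temporal frequency 0.4 Hz. Carrier
phases are {0, π} as printed in the source design; a quadrature pair
{0, π/2} is available (`FilterBankSpec.quadrature`). Kernels are DC
subtracted, so uniform fields elicit exactly zero.

Two deliberate consequences of this design are worth stating:

* **Static structured patterns are not nulled.** With a flat temporal
  window and a slow carrier, a stationary edge drives the near-vertical
  channels tonically. This is intended: it is precisely the non-zero
  baseline along the edge that makes the V1 energy maps noisier
  templates than the MT direction maps, which is the model's central
  contrast. Direction maps of static clips are time-invariant and
  spatially flat — carrying no pattern for the kernel to match — but
  not numerically zero after normalization.
* **Less than one temporal carrier cycle** fits inside the 6-frame
  window (0.4 Hz × 100 ms). Direction selectivity therefore rests on a
  small one-way phase ramp, which suffices: all 24 matched drifting
  sinusoids are identified to within one 15° step.

**Tiling.** Filters tile the strip vertically without overlap by
default. The analyses require 64 (respectively 32/128) positions over
the 4.97°-tall strip, one or two more than the natural non-overlapping
count; the bank therefore accepts a target position count and places
filters at `round(linspace)` offsets, shrinking the stride marginally
below the filter size. Downstream pooled counts (29/61/125) depend on
these totals.

**Temporal window of analysis.** `apply_filters` averages raw inner
products over the valid temporal offsets it is given; every preset
passes a *single* 6-frame window (`n_temporal_offsets=1`). The
deformation travels along the bar, so the alternating left/right
direction pattern drifts vertically at `tf/f_d`; averaging raw
responses across a long clip superimposes all phases of that drift and
cancels exactly the spatial structure the higher-order unit monitors.
A full-clip average remains available via configuration for stimuli
without travelling structure.

**Normalization.** `E(o) = Σ_φ R_max·⌊r⌋₊ / (Σ ⌊r⌋₊ + σ)` per position,
with maximum attainable response `R_max = 1` and semi-saturation
`σ = 0.1` (the source design defers these constants to prior work
without printing values; both are configuration-exposed). Responses are
bounded by `R_max`, increase monotonically and saturate with contrast,
and zero input maps to zero output.

## MT stage

Pooling combines 4 adjacent positions at stride 1 with Gaussian weights
(SD 1.2 position units, centred on the window, renormalized to sum
to 1). Direction tuning computes `L(α) = Σ_o cos(dir(o) − α)·E(o)`: the
cosine's negative lobe subtracts energy in opposing directions
(opponency), making the pre-rectification drive antisymmetric under
α → α + 180°. Rectification and normalization reuse the V1 constants.

## Higher-order kernel and ZNCC

Kernel positions are the pooled-filter centres in degrees from the
strip top. The printed component equations were reconstructed to their
standard forms: spatial part `sin(2πfx + φ)` (the printed `sin(2fx+φ)`
omits 2π), direction part `cos(θ − α)` (the printed `cos(2π(θ−α))`
would have period 1 rad, incompatible with a 24-direction design), and
ZNCC with the conventional `sqrt(ΣΔK²·ΣΔI²)` denominator (the printed
denominator of summed zero-mean terms is identically zero, while the
quantity is explicitly the *zero-mean NCC*). Normalization is joint
(global) over the whole grid, not per axis. Constant fields score 0.
The phase grid `{k·0.0625π}` for k = 0..31 tiles [0, 2π) exactly; the
kernel frequency sweep covers 0.1–6.4 cpd in octaves.

## Psychometric link and synthetic observer

The two-parameter family `p = a·exp(b·NCC)` is fitted by unweighted
least squares on per-condition proportions (a binomial-weighted option
and a three-parameter offset variant exist behind flags). The nonlinear
fit is seeded by log-linear regression of `log(p + 1e−3)` on the NCC —
deterministic and robust against local minima. r² = 1 − SSres/SStot on
the proportion scale; constant proportions leave r² undefined and are
flagged rather than silently propagated.

The synthetic observer draws per-condition reports from
Binomial(n, clip(a·exp(b·NCC), 0, 1)) with a seeded generator. Its
defaults (a = 0.1, b = 2.5, generating kernel 0.1 cpd, pooled trial
counts 140/240/240 per condition for the three designs, matching
observers × sessions × repetitions) place report probabilities in
roughly the 0.1–0.95 range psychophysical data span. What it emulates
is the *link* between model score and report under binomial noise; it
does not emulate observer-specific lapses, learning, criterion drift,
or between-observer variance, so recovery tests validate the fitting
machinery and the link's identifiability — not human behaviour.

Trial schedules expand each factorial design (7 frequencies × 10
repetitions × 2 sessions; 3 × 7 × 5 × 4; 2 × 9 × 5 × 4), shuffling
within session from the run seed; totals are 140/420/360 per observer.

## Problem sizes and determinism

Preset runs render at 200 px/deg, 12 frames, and analyse one 6-frame
window per condition; a full 7-condition run takes a few seconds on one
core. The acceptance script runs the deforming-bar preset, the
12.9-cpd moiré orientation series, and 100 observer-recovery
replications at 1000 trials/condition. Pipelines are fully
deterministic; only the observer simulation and schedule shuffling
consume randomness, all derived from the single run seed.

## Known limitations

* No speed tuning in the MT stage — only direction parameters are
  assessed; no second-order (contrast-defined) channels, so
  contrast-based moiré structure is invisible to the model by
  construction.
* Single spatial scale per condition (filter size tied to strip width);
  no multi-scale pyramid.
* `valid`-only filter placement (no padding): responses near the strip
  ends reflect slightly different stimulus support than the interior.
* The phase pair {0, π} makes raw responses sign-redundant rather than
  a quadrature energy pair; phase-insensitivity arises only through
  full-wave rectification, and scores inherit a mild dependence on
  stimulus phase within the analysis window (absorbed by the kernel's
  32-phase search).
* Pooled-proportion fitting only; per-observer fits and the attendant
  inferential statistics are out of scope.
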