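# deformsense

How do human observers see a bar *deform* — rather than merely move?
`deformsense` implements a computational account of dynamic-deformation
perception: local motion is first measured by V1-like spatiotemporal
energy filters, integrated into MT-like direction-selective responses,
and the *spatial pattern* of those direction responses is then monitored
by a higher-order unit whose template is sinusoidal in space and
cosine-tuned in direction. The template's match to the response map —
a zero-mean normalized cross-correlation (ZNCC) — predicts how often
observers report the bar as deforming.

The package is for vision scientists who want to synthesize the relevant
stimuli, run the model, and link its scores to (real or simulated)
psychophysical reports.

## The model

1. **Stimuli.** Either a vertical bar (0.6° × 5.0°) whose contour is
   sheared by a travelling sinusoid
   `Δ(y, t) = A · sin(2π·f_d·y ± 2π·tf·t)` (deformation frequency `f_d`
   in cycles/deg, amplitude `A = 0.04°`, 1 Hz), or a static bar in front
   of a drifting grating tilted slightly from vertical — the moiré
   configuration in which a solid bar *appears* to deform.
2. **V1 stage.** A strip near the bar's right edge is analysed by 24
   oriented spatiotemporal Gabor filters (15° steps, two carrier phases
   0/π, 6-frame support, 0.4 Hz), half-wave rectified and divisively
   normalized: `E(o) = Σ_φ R_max·⌊r(o,φ)⌋₊ / (Σ_{o',φ'} ⌊r(o',φ')⌋₊ + σ)`.
3. **MT stage.** Energies are pooled over 4 adjacent positions (Gaussian,
   SD 1.2), weighted by `cos(dir(o) − α_d)` in an opponent fashion over
   24 preferred directions, rectified, and normalized again.
4. **Higher-order unit.** `K(x, θ) = sin(2π·f·x + φ) · cos(θ − α)` with
   `α = 0°` (leftward); the score is `max_φ ZNCC(K, map)` over 32 phases
   (0.0625π steps).
5. **Psychometric link.** Report proportions follow `p = a·exp(b·NCC)`,
   fitted by least squares; sweeping the kernel frequency `f` and
   comparing r² identifies which spatial band of the direction pattern
   drives the percept.

## Worked example

```python
from deformsense import RunConfig, run_experiment_preset

bundle = run_experiment_preset(RunConfig(experiment="exp1", seed=1))
print(bundle.sweeps["direction"].table.round(3))
```

```
   kernel_f_cpd     r2      a      b
0           0.1  0.983  0.102  2.513
1           0.2  0.949  0.119  2.147
2           0.4  0.045  0.231  0.534
3           0.8  0.008  0.269 -0.265
4           1.6  0.029  0.279 -0.673
5           3.2  0.201  0.360 -5.723
6           6.4  0.071  0.184 11.640
```

This renders the seven deforming-bar conditions (deformation frequency
0.1–6.4 cpd), runs them through the model, simulates a Bernoulli
observer from the direction-map NCC scores, and refits the exponential
link for kernels of each spatial frequency. The r² column peaks at the
lowest kernel frequencies (0.983 at 0.1 cpd) and collapses above
0.4 cpd: it is the *coarse* spatial pattern of direction responses that
carries the deformation percept. Running the same sweep against the V1
energy maps gives a lower best r² (0.976 here) — the direction-selective
stage, which resolves the aperture problem, explains the reports better.

The same applies from the shell:

```bash
deformsense run --preset exp1 --seed 1 --out results/exp1
deformsense render-bar --sf 0.8 --amp 0.04 --bar-lum 38 --bg-lum 76 --out clip.tif
deformsense mt --clip clip.tif --out dmap.csv
deformsense ncc --map dmap.csv --fs 0.1,0.2,0.4,0.8,1.6,3.2,6.4 --out profile.csv
```

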