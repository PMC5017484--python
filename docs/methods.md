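# Methods

## Problem and model

A scarified acorn's cross-section is assessed for viability from its
colour: healthy cotyledon tissue is bright and yellow-green, while
mummified (fungus-spoiled) tissue forms dark, weakly saturated blobs.
The package reduces each section image to seven scalar features — the
masked averages `Fav^C` of hue, saturation, value, red, green, blue and
grey over the circular section mask — and classifies the seed as
germinating or non-germinating. Partly spoiled seeds are grouped with
spoiled: container sowing cannot tolerate their ~50% germination rate,
and the germination reference is binary anyway.

Averaging over the mask and dividing by its pixel area `A_E` makes the
features independent of acorn size; normalising each image against the
white reference patch makes them largely independent of illumination.
Those two invariances are what the test suite checks most heavily,
because they are what the method's portability to a working
scarification line rests on.

## Normalisation

The reference patch is cut from the white-fiberboard holder, so its
chromaticity is neutral and its channel means track the illuminant.
The correction is two linear steps executed in one pass per image:

* white balance: `R *= mean_G/mean_R`, `B *= mean_G/mean_B`, green
  unchanged. Green anchors the balance because the brightness target is
  defined on the green mean. The patch means are equal afterwards by
  construction.
* brightness: all channels times `Gain = GreenT / mean_G` with
  `GreenT = 0.824`. The target sits below full scale so that clipping
  is rare; outputs are clipped to [0, 1] and a warning is logged when
  more than 0.1% of samples clip.

The procedure equalises components across a sequence; it is not
colorimetric colour restoration. It is idempotent (a normalised image
re-normalises to itself within 1e-6) and invertible with respect to
multiplicative drift: across a drifting sequence,
`Gain × applied_gain × cast_G` is constant.

## Segmentation

Stage one thresholds the grey image (Otsu by default; a fixed threshold
can be supplied) and takes the bounding box of the largest dark
connected component, padded by a 5% margin. Stage two runs Canny
(σ = 2) and a circular Hough transform over an integer radius grid
inside the ROI. Candidates need edge support on at least 30% of their
perimeter; among qualifying candidates the *perimeter-weighted* vote is
maximised. The weighting matters: the cotyledon–pericarp boundary is
also a near-complete circle, and perimeter-normalised votes alone
sometimes prefer it; weighting by radius selects the outer circle, the
mask that circumscribes cotyledons plus adjacent pericarp. Ties break
deterministically (larger radius, then smaller y, then x). Coordinates
are 0-based, x rightward, y downward; the mask is all pixels within
`radius` of the centre, and its pixel count is the `A_E` used by the
features — the two can never disagree.

Automatic detection can always be replaced by `override_circle`
(recorded as `method="manual"` in the artefacts), mirroring operator
fine-tuning of masks on a real line.

## Features

`rgb2hsv` (hexcone, hue in [0,1), hue = saturation = 0 for achromatic
pixels) and the exact luma weights 0.299/0.587/0.114 produce the
planes. Decisions that are fixed here, since any choice is defensible:

* undefined hue at zero saturation enters the average as offset value
  0.5, because the sum runs over every mask pixel unconditionally;
* the hue average is the arithmetic mean of the *offset* plane, not a
  circular mean — the 0.5 offset exists precisely so that acorn hues
  occupy a monotonic stretch of the scale and linear averaging plus a
  single threshold work;
* bit depth is metadata: 8- and 12-bit sources are mapped to unit-range
  floats before any arithmetic.

## Discrimination

The threshold sweep evaluates all 256 grid points `k/255`. A sample is
positive when its feature is **strictly greater** than the threshold
("below threshold" is the negative side; equality had to be fixed one
way for determinism). Ties on accuracy keep the smallest threshold.
The sweep is vectorised but contractually identical to brute force —
the suite asserts exact agreement of ACC and Thr against an explicit
loop on randomised label sets.

Gaussian naive Bayes uses empirical class priors, per-class per-feature
maximum-likelihood means and variances (variance floored at 1e-9), and
argmax of log-posterior with ties going to non-germinating — the
conservative call, since sowing a spoiled seed wastes a container
cell. The 240/160 train/test split is a seeded random partition by
default (`sequential` takes the first 240 ids); the split used by the
original study is not recoverable, so agreement is asserted as
train-vs-test stability rather than as row-identical membership.

## Synthetic scenes: what they emulate and what they do not

The generator composites, in order: holder background (shared by the
reference patch), pericarp annulus (default 12% of the radius), two
cotyledon half-discs split by a dark chord (an arc when the
size-asymmetry option is set), seeded dark ellipses for mummification,
then per-channel multiplication by `colour_cast × illumination_gain`,
additive Gaussian noise, and clipping. Defaults emulate the study
conditions: 400 scenes, 183 germinating, a step change of illumination
mid-sequence (drift profiles: constant, step, ramp), per-scene colour
cast jitter of ±8%, and geometric jitter of circle centre and radius.
Non-germinating seeds draw a mummified cover of 30–60% of the section,
germinating seeds at most 5% — the binary collapse of the three
nursery fractions.

Parameter choices worth recording:

* **Exposure headroom.** The holder reflectance is ~0.52, i.e. the
  brightest material sits near half scale. That emulates raw 12-bit
  acquisition, where exposure is set so highlights never clip; it is
  the property that keeps the reference patch linear under a combined
  gain × cast excursion up to ~1.9×, and hence lets normalisation hit
  the 0.824 target to 1e-3 everywhere in that range.
* **Noise.** Additive Gaussian, σ = 0.003 (~12 DN of a 4096-level
  12-bit scale), a realistic read-noise figure for a machine-vision
  CCD. Saturation is the feature most sensitive to this choice:
  `S = (max − min)/max` is biased upward by noise on dark pixels, and
  the bias scales with the normalisation gain, so under extreme gain
  ratios (≳3×) the saturation average can shift by more than the 0.02
  invariance budget even though the linear features move by < 1e-3.
  Within the acquisition drift band the generator emulates (gain
  0.5–1.2, cast 0.9–1.1) all seven features are invariant to < 0.013.
* **Tissue colours.** No quantitative colour statistics exist for
  healthy vs. mummified tissue; the defaults (cotyledon
  (0.44, 0.40, 0.20), pericarp (0.16, 0.10, 0.06), mummification
  (0.09, 0.08, 0.075)) are free parameters chosen so that, after
  normalisation, germinating sections average V > 0.5 and the classes
  are separable — they are not claims about real acorns.

Consequences for interpretation: the synthetic classes are cleanly
separable, so sweep and naive-Bayes accuracies on generator output sit
near 100%, unlike the low-80% figures real images produce. Passing
tests therefore demonstrate the *contracts* (normalisation reaches its
target, features are illumination- and size-invariant, the sweep is
exactly optimal on its grid, NB generalises across the split), not
field accuracy. The generator has no specular moisture reflections, no
cracked cotyledons, no pericarp cutting defects, and no texture — the
known failure modes of the real system are out of its vocabulary.

## Problem sizes and numerics

Default synthetic frames are 360 × 300 with a 100-pixel patch and
~110-pixel section radius (unit tests use a 220 × 180 variant). Study
runs use 400 scenes with ground-truth masks standing in for the manual
mask revision step; automatic Hough detection is validated separately
on 50-scene batches (≥ 95% of fits within 5 px). All arithmetic is
float64 on unit-range values; determinism comes from
`numpy.random.default_rng` seeded per scene, with dataset-level seeds
spawning per-scene seeds below 2³¹.
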