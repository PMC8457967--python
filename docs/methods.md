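# Methods

## Segmentation model

The foreground model is deliberately minimal: three scalar cuts on three
chroma planes, applied per pixel and refined morphologically. It assumes
a fixed overhead camera, stable lighting, yellow-brown plumage against
largely achromatic litter/walls, and feeders/drinkers whose colour
differs from plumage mainly in its red-green balance. No illumination
normalisation or white balancing is applied; thresholds are only valid
for the conditions they were learned under.

### Colour conventions

The cut values are meaningless without fixed conversion conventions, so
the package pins them:

* **Cb** — full-range BT.601, `Cb = 128 − 0.168736 R − 0.331264 G + 0.5 B`
  on 8-bit RGB. Grays map to exactly 128; on 8-bit inputs the plane
  spans [0.5, 255.5]. (The studio-swing variant used by some libraries
  spans [16, 240] and would shift every learned cut.)
* **b\*** — CIELAB via sRGB gamma expansion and the D65 white point, the
  de-facto camera assumption.
* **Q** — the NTSC YIQ quadrature row `(0.211456, −0.522591, 0.311135)`
  on RGB in [0, 1], left on its native ±0.5226 scale. The row is applied
  directly (rather than through a library YIQ call) because the exactly
  zero-sum coefficients keep grays at zero chroma to float precision,
  which the achromatic-invariance contract requires.

All planes are computed in floating point; nothing is quantised before
thresholding. Scale and offset are irrelevant to the method as long as
training and inference agree.

### Threshold learning

Each cut is a two-class problem: given component values from the class
expected below the cut and the class expected above, maximise
`score(T) = #{lower < T} + #{upper > T}`. The score is piecewise
constant, so the search runs over midpoints of consecutive distinct
pooled values plus one candidate beyond each extreme. Ties are broken
deterministically: the candidate whose surrounding data-value interval
is widest wins (the maximal-margin cut), and among equally wide
intervals the lowest. The score attained is verified in the tests
against a brute-force scan of every candidate.

A sample data point is a single pixel's component value; the default is
100 per class and channel, drawn uniformly without replacement (seeded)
from the pooled pixels of labelled square patches (default 20×20 px).

### Orientation of the pixel rule, and the `eq2_verbatim` switch

The body-side orientations are fixed by the physics: plumage has low Cb
and high b*, litter is achromatic (Cb ≈ 128, b* ≈ 0), and the
feeder/drinker plastic sits on the high-Q side of plumage. The pixel
rule is therefore `Cb < T_Cb ∧ b* > T_b ∧ Q < T_Q`. An inverted form of
the two litter tests (`Cb > T_Cb ∧ b* < T_b`) circulates in print for
this family of methods; under the orientations above it selects litter,
not birds, so it is treated as a sign slip — but it is preserved behind
the `eq2_verbatim` flag so both readings can be audited.

### Morphological refinement

Order: (1) remove 8-connected components with area < `min_object_area`;
(2) closing, then (3) opening, with a disk of radius `se_radius`;
(4) fill enclosed holes (4-connected background) of area ≤
`max_hole_area`. Defaults `se_radius=3`, `min_object_area=50`,
`max_hole_area=200` are sized for birds of roughly 20×12 px at the
384×216 working resolution and scale quadratically (areas) / linearly
(radius) with the frame. A parameter of 0 disables its stage. Opening
can split a blob with a neck thinner than the structuring element, so
refinement may raise the component count; what it never does is invent
foreground outside the closure of surviving material (tested).

## Occupancy and activity

An analysis period is a clock hour sampled at one frame per minute
(n = 60). Occupancy is the per-pixel sum of the refined masks; the
activity index is the fraction of pixels with counts in [10, 49],
inclusive at both ends. The band excludes pixels never visited and
pixels occupied ≥ 50/60 of the hour, the latter reflecting birds
resting or huddling in place rather than moving. Periods with fewer
frames than expected are analysed but flagged; the band is not
rescaled. Heat maps are rendered by pure array colormap lookup on a
fixed 0..n_frames scale (plus a gradient colour bar), which makes
re-rendering byte-stable.

## Environment statistics

Sensor readings are averaged per (date, clock-hour) window, half-open
`[start, start+1h)`. A period missing any of the three fields entirely
is dropped (complete-record rule). THI is computed on the period means
(mean-then-THI, not the mean of per-reading THIs).

Kendall's τ_a is the concordance sum over ordered pairs divided by
n(n−1); τ_b divides C − D by the tie-corrected pair counts. τ_b is the
reporting default because real period means contain ties (the bundled
trial tables do); both variants are computed. p-values: exact
enumeration of rank arrangements for tie-free samples with n ≤ 10
(direct enumeration to n = 8, the rank-distribution recursion beyond);
the normal approximation uses the tie-corrected variance of S = C − D
(undefined, hence NaN, for n < 3 or a constant series); an exact
request that is infeasible (ties, or n > 10) falls back to seeded
permutation resampling with ≥ 10⁵ draws and flags the result.

Pairing for correlation is by (date, period), with listwise deletion of
incomplete pairs.

## Synthetic data

The generator emulates the intended scene, not its photometry: per-pixel
black/white litter speckle, a white wall strip, one feeder and one
drinker disk, and ellipse birds (semi-axes 10×6 px by default) textured
with two plumage colours, all with Gaussian colour jitter (σ = 6 by
default). The feeder/drinker colours are chosen plumage-like in Cb and
b* but separated in Q — the separation difficulty the Q cut exists for.
Bird centres follow a reflected Gaussian random walk (σ = 6 px/frame by
default); scene texture is frozen within a period (static litter), so a
frozen flock reproduces identical frames. Default working resolution is
384×216, a 1/10-scale stand-in for a 4K overhead camera, so suites run
in seconds; default flock size is 20 birds, a density comparable to the
intended pens at that scale.

Environment series come from a Gaussian copula with correlation ρ and
uniform marginals over winter-trial ranges (THI 51–62, NH₃ 9–50 ppm);
temperature is back-solved at fixed RH = 60% so the THI invariant holds
on the generated summaries. Since monotone marginals preserve ranks,
the population τ is (2/π)·arcsin ρ, giving a closed-form target for
recovery tests.

What passing synthetic tests shows: the learning, thresholding,
morphology, accumulation and correlation machinery is correct and
recovers known ground truth under the stated scene assumptions. What it
does not show: robustness to real-footage effects the generator omits —
occlusion and bird deformation, lighting drift, shadows, soiled litter
approaching plumage colour, camera noise structure. Thresholds for real
pens must be learned from real labelled patches.

## Numerical choices and edge cases

* Threshold candidates are data-driven midpoints (not an integer grid):
  b* and Q are real-valued under the conventions above.
* Empty mask sequences accumulate to zero counts with n_frames = 0; the
  activity index of an empty band query on them is 0.
* `correlate_periods` requires ≥ 2 complete pairs; `kendall_tau`
  requires n ≥ 2; τ_b is NaN when either series is constant.
* Connectivity: 8-connectivity for foreground components, 4 for the
  background during hole filling (standard blob-analysis choice).
* All stochastic components (patch sampling, scene generation, copula
  draws, permutation p-values) take explicit integer seeds.

## Known limitations

* A global colour threshold cannot separate birds that are touching;
  the occupancy analysis never needs instances, only foreground.
* The activity index depends on the camera geometry through the band:
  counts are per-pixel, so changing resolution or mounting height
  changes what [10, 49] means; re-learn thresholds and keep geometry
  fixed within a study.
* The correlation stage is associational; n = 24 periods gives wide
  confidence bands and no causal reading.
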