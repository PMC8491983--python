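# Methods

## Image model and stain separation

Brightfield H-DAB slides obey Beer-Lambert absorbance to good
approximation: per channel, `OD(c) = -log10((I(c)+1)/256)` with the `+1`
offset keeping OD finite for pure-black pixels (max ~2.408) and white
(255) at exactly zero. Per-pixel stain amounts are the solution of
`OD = concentrations @ M` for a 3x3 matrix `M` of unit-norm stain OD
vectors: hematoxylin `(0.650, 0.704, 0.286)`, DAB `(0.269, 0.568,
0.778)`, and their normalized cross product as a residual axis. Melanin
has a broad brown absorbance and loads almost entirely onto the DAB
vector, so the "brown" channel deliberately pools DAB and melanin — the
pipeline never tries to separate them spectrally; that is the control
slide's job. Negative unmixed concentrations are clipped to zero for the
blue/brown channels; the residual stays signed as a lack-of-fit
indicator. An RGB-ratio heuristic (`brown = OD_B - OD_R`,
`blue = OD_G - OD_B`, clipped) is available behind
`QuantConfig(use_deconvolution=False)` for stains that depart badly from
the reference vectors; deconvolution is the default.

Channels are mapped to 8-bit for thresholding by a linear scale of
`[0, clip_max]` onto `[0, 255]` (half-away-from-zero rounding,
saturation above). `clip_max` defaults to 2.0 OD units, a typical
chromogen saturation level; one bin is therefore ~0.0078 OD.

## Thresholding

Three classical 256-bin histogram methods, one per mask type, each with
foreground `value > t` and ties broken toward the smallest maximizing
`t` so masks are bit-reproducible:

- **Triangle** (tissue): line from the histogram peak to the farthest
  nonzero bin on the longer tail; `t` maximizes the perpendicular
  distance to that line. A single-bin histogram returns that bin, which
  makes an all-white region yield an empty tissue mask.
- **MaxEntropy** (brown): maximizes the sum of the class entropies of
  the below- and above-threshold distributions over all splits with
  mass on both sides. Chosen for the chromogen because it behaves well
  with small foreground fractions.
- **Moments** (nuclei): the two representative levels of the
  moment-preserving binary image are the roots of the quadratic whose
  coefficients preserve the first three gray-level moments; `t` is the
  smallest bin where the cumulative distribution reaches the
  below-threshold fraction.

Degenerate inputs: histograms with fewer than two nonzero bins raise for
the direct threshold functions; inside the mask builders, a region whose
nonzero bins span fewer than `min_dynamic_range` bins (default 8, i.e.
< 0.063 OD of total contrast) is treated as *blank* and returns an empty
mask with a warning. This matters for chromogen-free slides: without the
guard, MaxEntropy would dutifully place a cut inside the scanner-noise
floor and mark a few percent of background pixels as foreground. A blank
control region is a legal input, hence a warning rather than an error.

## Quantification

The ROI polygon (0-based pixel coordinates, `x` = column) is rasterized
by the closed-polygon pixel-center rule (boundary pixels count as
inside). The tissue mask is Triangle on inverted mean-RGB grayscale
within the ROI; nucleus and brown masks are computed within
`ROI AND tissue`.

The slide pair is registered by the integer translation maximizing the
overlap of the two tissue masks within `max_shift_px` (default 32); no
overlap at any shift falls back to the identity with a warning. Two
deduction modes:

- **pixel** (default): corrected PD-L1 mask =
  `brown_stained AND NOT translate(brown_control)`; always a subset of
  the uncorrected mask. The melanin mask is the translated control mask.
- **count**: no registration; brown-positive *cells* are counted on each
  slide independently and
  `n_pdl1 = max(0, n_brown_stained - n_brown_control)`. This mode is a
  fallback for unregistrable pairs and is systematically conservative:
  a PD-L1+ cell that also touches pigment or background is counted once
  on the stained slide but still contributes to the control count, so
  it is effectively deducted twice. The unit tests assert coarse
  tracking and the downward direction of the error, not pixel-mode
  accuracy.

Cells are 8-connected components of the nucleus mask with at least
`min_area_px` (default 10) pixels; no watershed splitting of touching
nuclei is attempted — the scoring tolerances absorb occasional merges,
and heavily confluent tissue is a stated limitation. Each cell's
footprint is its component dilated by `dilation_px` (default 2 at a
20x-equivalent scale) to capture the membranous rim around the nucleus.
A cell is PD-L1+ if its footprint contains at least `min_overlap_px`
corrected-mask pixels, melanin+ by the same rule on the melanin mask;
PD-L1 takes precedence on dual overlap because control-attributable
brown has already been deducted.

`min_overlap_px` defaults to **10 pixels**, not 1. With two physically
distinct sections, scanner noise independently flips near-threshold
background pixels on each slide, so pixel-wise deduction always leaves a
~1–2% residue of isolated stained-only pixels; at a 1-px criterion every
~100-px footprint would score positive. Ten pixels demands a coherent
stained patch (true rims overlap footprints by ~60 px at default
geometry) while the false-positive probability per cell drops below
1e-3. The trade-off: very small or faint stained patches (< 10 px after
deduction) are missed, and melanin calls on barely-touching granules are
not made.

The score is `percent_pdl1 = 100 * n_pdl1 / n_total` over **all**
nucleated cells in the ROI (CPS-like; no tumor-vs-immune distinction),
with call `positive` iff the percentage reaches `cutoff_percent`
(default 5, boundary inclusive) *and* at least `min_cells` (default 100)
cells were evaluable; fewer cells give `indeterminate`, and with zero
cells the percentage is reported as missing, never as 0. Setting
`min_cells=None` disables the guard.

## Synthetic slide pairs

The renderer emulates a pair of consecutive sections: a centered tissue
ellipse (semi-axes 0.42 of each image dimension) on white glass;
fine-grained tissue texture *shared by both slides* — cytoplasmic
hematoxylin 0.08 OD plus half-normal(0.04) variation, and a diffuse
nonspecific brown background, half-normal(0.05 OD), the very signal an
IgG control exists to measure; non-overlapping disc nuclei (radius 4 px,
hematoxylin 0.8 OD x U(0.9, 1.1)) placed by rejection sampling with a
clearance that keeps dilated footprints off neighbouring rims, so
component counting is exact; a DAB annulus (width 3 px, 1.0 OD x
U(0.85, 1.15)) on `round(pdl1_fraction * n_cells)` randomly chosen
cells; melanin granules (radius 2–4 px, 1.5 OD x U(0.85, 1.15)) drawn
until `melanin_area_fraction` of the tissue is covered, at identical
positions on both slides (an optional jitter displaces the control copy
to stress registration). RGB is the forward Beer-Lambert transform with
the same H-DAB vectors the pipeline inverts, plus i.i.d. Gaussian
scanner noise (sd 2.0 on the 8-bit scale) drawn independently per slide.
All randomness derives from one seed via spawned generator streams, so
the cell layout is identical across melanin settings at a fixed seed.

What the renderer does **not** model — and hence what passing tests do
not establish about real slides: nucleus shape/texture variation and
touching nuclei, section-to-section tissue deformation (the pair is
perfectly consecutive up to translation), stain variation away from the
reference vectors, membrane-vs-cytosol staining patterns, scanner
shading and compression artifacts, and photorealistic chromatin or
stromal texture. Results on synthetic pairs demonstrate the *mechanism*
(separation, thresholding, deduction, counting), not clinical accuracy.

## Synthetic cohorts

Patient records are drawn per a study-level parameter object. The binary
physician/digital calls come from the joint 2x2 distribution implied by
the two marginal positivity probabilities (defaults 60/156 and 95/156)
and the overall agreement (99/156): `p11 = (agree + p_phys + p_dig -
1)/2`, validated against the Frechet bounds with the violated bound
named on error. Best overall response is Bernoulli with a rate per joint
cell (defaults 0.604 / 0.400 / 0.272 / 0.334 for both+/digital-only/
physician-only/both−, jointly consistent with digital-arm rates of
0.505 and 0.323). Survival is exponential per digital call
(median-parameterized, rate `ln 2 / median`; PFS 9.9 vs 4.6 months, OS
40.0 vs 13.0 — the 40 stands in for a median not reached within the
follow-up horizon), with one uniform censoring time per patient on
`(0, 2 x 26.4)` months so the median follow-up is 26.4. PFS and OS are
drawn independently (no enforced PFS <= OS). Eight binary covariates are
independent Bernoulli draws at registry-like prevalences; LDH and BRAF
status carry a small missingness rate so complete-case handling is
exercised. Percentages for the two raters share a per-patient latent
severity, giving positively correlated physician/digital percent values
consistent with each call.

## Outcome statistics

Concordance is the 2x2 cross-classification with percent agreement
rounded to one decimal and discordance defined as its exact complement
(they always sum to 100). The combined classifier pools the two
discordant patterns into `single_positive`. Response tables use the
Pearson chi-square without continuity correction (Yates available by
flag) and exclude patients with no evaluable response. Kaplan-Meier,
log-rank and Cox are backed by `lifelines`; the median survival
convention is the smallest `t` with `S(t) <= 0.5`, propagated as an
explicit "not reached" token (`None` / `"not_reached"`) when the curve
never gets there. Cox uses the Efron tie approximation, Wald confidence
intervals, complete-case rows per model with the exclusion count
reported, and raises naming the covariate on separation/degeneracy. All
p-values are two-sided.

## Numerical and reproducibility choices

Ties in every threshold search go to the smallest candidate. FFT
cross-correlation scores are rounded to integers before the argmax
(overlap counts are integral) to kill floating-point jitter, with the
smallest `(dy, dx)` winning ties. Identical inputs and configuration
give bit-identical results end to end; batch outputs are sorted by
sample id and embed a SHA-256 configuration hash and the package
version.

## Problem sizes used in the test suite

Synthetic pairs are 512 x 512 px with 150 cells (20 x 192 px / 20-cell
pairs for the I/O round-trip tests); the fraction-recovery sweep uses 20
pairs per condition across true fractions {0, 0.02, 0.05, 0.10, 0.25,
0.50}; cohort-level checks use n = 10,000 for marginal calibration and
100 seeded cohorts of n = 1,560 for the qualitative-ordering rate. These
sizes keep a full run of suite plus acceptance script to a few minutes
on one CPU while leaving binomial/KM standard errors well inside the
asserted tolerances.

## Known limitations

- No tumor-cell/immune-cell discrimination: the score is CPS-like by
  design, so it reads systematically higher than a physician's TPS.
- Touching nuclei are counted as one cell (no watershed).
- Count-mode deduction is biased low on pigmented tissue (see above).
- The registration model is a rigid integer translation; real
  consecutive sections can shear and fold.
- The blank-region guard means genuinely ultra-faint staining
  (< ~0.06 OD of histogram contrast) is reported as no signal.
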