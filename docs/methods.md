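# Methods

## The measurement model

A photoconvertible calcium-integrator experiment produces two-channel
(green/red) volumetric images taken after an illumination episode. The
quantity of interest per cell is the red-to-green fluorescence ratio
(RGR): converted (red) protein is produced in proportion to the
coincidence of 400-nm light and elevated calcium, while the green pool
is depleted by the same conversion, so the ratio is a monotone readout
of the cell's activity during illumination.

The recorded channels mix that signal with instrument nuisances. Writing
`g_sig` for a cell's true green emission and `r_conv` for its converted
red emission, the package models the recorded somatic means as

```
g = g_sig + dark_g + noise
r = r_conv + rho * g_sig + beta(hemisphere) + dark_r + noise
```

with `dark_*` the PMT dark currents, `rho` the fraction of green
emission leaking through the red filter, and `beta` an additive red
offset from cranial-window autofluorescence that differs between
hemispheres (each window meets the optical axis at its own angle).
Inverting this model is the correction chain:

```
g_corr = g - dark_g
r_corr = r - dark_r - beta(h) - rho * g_corr
RGR    = r_corr / g_corr
```

Dark currents are the mean of laser-off frames per channel. `rho` and
`beta` come from cells imaged *before* photoconversion, where
`r_conv = 0` and the red-on-green regression has slope `rho` and
intercept `beta`. By default one slope is shared across hemispheres
(the spectral leak is a property of sensor and filters) with one
intercept per hemisphere, fitted jointly as a single OLS with
hemisphere dummies; a flag fits fully independent per-hemisphere lines.
Plain OLS is used rather than a robust variant; cells with internally
studentized residuals above 4 are reported in the diagnostics but not
removed. Corrections are applied to per-cell means, not per pixel —
for cells of uniform interior the two are algebraically identical, and
means are what every downstream quantity consumes.

Cells whose corrected green is non-positive are flagged and excluded
from ratio computation (a near-zero denominator makes the ratio
meaningless); they are counted in the QC output rather than clipped.

A paired RGR variant, `(r_post - r_pre) / g_post`, serves acquisitions
in which red puncta exist before conversion: subtracting the same
cell's pre-conversion red removes any residual additive red term —
the hemisphere offset cancels in the difference, so no separate `beta`
handling is needed there.

## Extraction geometry

Volumes are collapsed into depth slabs by averaging every 3 adjacent
z-slices and skipping the next 2 (defaults; both configurable). With a
3-µm z-step a slab spans 6 µm — about one somatic diameter — so
consecutive slabs share almost no cells and each slab's cells can be
treated as distinct without explicit 3-D deduplication. Trailing groups
with fewer slices than the group size are dropped rather than padded:
averaging fewer slices would silently change the noise level of the last
slab. A cell's depth is its slab's mean slice depth.

Cell masks normally come from a dedicated segmentation tool and are
imported as integer-label TIFFs. The built-in fallback labeler
(Gaussian smoothing, global threshold at a quantile of the nonzero
pixels, 8-connected components, area filter) is deterministic and is
held only to count-level agreement with ground truth, since masks are a
replaceable input. Pre/post acquisitions are matched by
mutual-nearest-neighbour centroids under a distance cap.

## Population metrics and statistics

Region (or field-of-view — `group_by` switches the aggregation level)
summaries report n, median, mean, sample variance, and the 25–75 and
5–95 percentile bands with linear interpolation; the 5–95 range is the
heterogeneity measure used to compare expression strategies. Two
regions' distributions are separated by the sensitivity index

    d' = (mean_A - mean_B) / sqrt(0.5 * (var_A + var_B))

computed with sample (ddof = 1) variances — the convention choice for
empirical distributions of hundreds of cells; a `ddof` argument makes it
switchable. Two identical constant groups give d' = 0; distinct
constants give signed infinity with a warning.

Group comparisons are two-tailed throughout: Wilcoxon rank-sum (the
statistic reported is the sum of group A's pooled ranks, midranks for
ties, exact p for small tie-free samples), Student two-sample t (Welch
by flag), paired t, and one-way ANOVA. Degenerate zero-variance inputs
with equal means report statistic 0, p = 1 instead of NaN. No
multiple-comparison correction is applied by default; a
Benjamini–Hochberg helper exists for users who want one.
Behaviour–activity association is a simple linear regression of
per-mouse regional activity medians on the behaviour score, tested with
the F-statistic against the constant-only model (for one predictor,
F = t² of the slope).

## Fitted models

**Ratio decay.** Trajectories normalised to each cell's level
immediately after conversion are fitted (via nonlinear least squares on
the across-cell medians) with `y(t) = 2^(-t / t_half)`: amplitude fixed
at 1 and offset at 0, because normalisation pins y(0) = 1. Both can be
freed — useful because a measured one-week loss slightly below the
pure-exponential prediction suggests a small floor. R² is reported
against the constant-mean model; the half-life's standard error comes
from the fit covariance.

**Dose response.** The sensitivity-vs-dose curve is fitted with a plain
least-squares polynomial (cubic by default; degree 1 and 2 serve the
normalised green and red channel trends) and the optimum located by
evaluating the fit on a dose grid (1 dose-unit spacing by default) over
the observed range.

**Stimulus-response integral.** For dynamic-indicator traces, each
grating appearance contributes `sum(F_resp / 2) - sum(F_base)`, where
F_resp spans the 4-s stimulus window and F_base the 2 s immediately
before it (the /2 equates the window lengths frame-for-frame);
appearances lacking a full pre-window are skipped with a warning, and
the per-cell response is the sum over all appearances.

## Dose units

One dose unit is 1 mW/mm² × 1 s = 1 mJ/mm². Protocol figures quoted in
the field for these experiments (e.g. "~6 per full-power 1-s cycle",
"optimum near 300", "1150 maximum") are numerically consistent with
this milli-joule scale given the stated powers and apertures (200 mW
over a 6.5-mm circle ≈ 6.03 mW/mm²), even where they are printed with a
J/mm² label — a ×10³ inconsistency this package does not attempt to
adjudicate; it follows the printed numeric scale. Whole-cycle counts for
a target dose use the ceiling of target/per-cycle: 1150 at ~6 per cycle
→ 192 cycles.

## The synthetic generator

The generator exists so every stage can be validated against known
ground truth. Cells are non-overlapping spheres (a ≥3-µm placement
margin keeps rendered masks separable) of uniform interior intensity —
somatic means are what the pipeline quantifies, so interior texture is
irrelevant. The phenomenological conversion model is

    c(dose, a) = a * c_max * (1 - exp(-dose / tau_d))

(defaults c_max = 0.5, tau_d = 150 dose units) with an additional
saturating green bleach `1 - k * tau_g * (1 - exp(-dose / tau_g))`
(tau_g = 300). `k` is calibrated so that, for a uniform-[0,1] activity
population, the mean green signal at dose 300 is exactly 60% of its
unconverted level — anchoring the simulated dose scale to the operating
point at which the green channel has lost 40%. Converted protein emits
1.5 red counts per green count it replaces. The model makes no claim
about the sensor's actual photophysics; it is monotone in dose and
activity, zero at dose 0, and calibrated only to those anchors, which
is all the pipeline's validation requires.

Noise is Gaussian with variance `shot_scale * signal + read_sd²` (the
standard PMT shot + read model); depth attenuation is `exp(-rate * z)`
applied at each cell's centroid depth, identical in both channels by
default (so the ratio is depth-flat, matching the observed flatness
over superficial cortex) with an optional channel-specific red
coefficient to emulate the 20–30% ratio decay reported for deeper
tissue. Decay cohorts default to 73 cells observed on days
0,1,2,3,5,7,10,15 with half-life 1.04 days and 20% lognormal per-cell
scatter (the boxplot spread of the characterisation data is roughly
±20% of the median; chosen once). Grating traces are rectangular
responses on a constant baseline with additive Gaussian noise —
adequate for validating the response integral's window bookkeeping,
not a calcium-indicator kinetics model.

What passing tests on synthetic data do **not** show: robustness to
segmentation errors on real morphology, motion artefacts, non-uniform
illumination or vignetting (no flat-field model), indicator kinetics,
or any nonlinearity between firing rate and conversion. Inputs are
assumed motion-registered.

## Reproducibility and problem sizes

All randomness flows from explicit seeds; the pipeline fans one global
seed into per-stage child seeds via `numpy.random.SeedSequence.spawn`,
so stages re-run independently yet reproducibly, and identical configs
produce byte-identical tables. Default problem sizes (60-cell scenes on
12 × 300 × 300 voxel volumes, 73-cell decay cohorts) were chosen as the
smallest at which estimator scatter is comfortably below the effects
being validated; the whole suite and the acceptance script each run in
well under a minute.
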