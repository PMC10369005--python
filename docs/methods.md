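# Methods

This note records the models, conventions and design choices behind
`coxradius`, in the order the pipeline runs.

## Radial coordinate and annuli

All features live on a signed Euclidean distance from the GTV surface,
computed from two exact distance transforms (outside and inside the
mask, anisotropy-aware) shifted by half the smallest voxel dimension so
that boundary voxels sit within half a voxel of zero. Negative distances
are inside the GTV. Annuli are half-open 1 mm bins `[k, k+1)` assigned
by voxel-center distance: density curves on [−5, 20) mm, dose curves on
[5, 40) mm (the scan defaults to the [5, 20) mm subrange; both ranges
are configurable).

At coarse voxel sizes some annuli are geometrically unreachable: with
2 mm isotropic voxels no voxel center can fall within 1 mm of the
surface, so the innermost bins on either side of the boundary are empty
for every patient. Empty annuli take the value of the nearest non-empty
annulus before smoothing and are flagged in the curve metadata. This
keeps curves defined everywhere for the scanner; the cost is that
adjacent heat-map rows become partially redundant near the boundary.

## Density and dose metrics

Density metrics come from a 2D cross-histogram of density (10 HU bins
over [−1024, 200] HU; the bin width is not part of the method, 10 HU
makes binned statistics match voxelwise ones to < 3 HU) against
distance, restricted to lung voxels so density is not a surrogate for
adjacent organs. Per annulus: mean, 90th percentile (linear
interpolation between order statistics), and SD (population convention,
used consistently for density and dose). Dose metrics are computed per
annulus directly from the respiratory-blurred EQD2 volume inside the
body mask: SD, fraction of volume strictly below 30 Gy EQD2 (a reported
threshold for controlling microscopic disease), and mean (for
visualisation).

Blurring precedes EQD2 conversion: the physical dose is averaged over
10 equal-weight phases of a sinusoidal cranio-caudal trajectory whose
peak-to-peak amplitude is the patient's motion amplitude (equal time
sampling reproduces the dwell-time weighting of a 4D-CT), with linear
interpolation and edge replication. EQD2 uses the linear-quadratic
conversion `D (D/n + α/β) / (2 + α/β)` with α/β = 10 Gy.

All curves are smoothed with a normalised Gaussian, σ = 1.5 mm,
reflective boundaries (annulus thickness is below typical slice
thickness; reflective padding avoids edge attenuation on short curves).

## Survival primitives

The Cox fitter maximises the Efron tie-corrected partial likelihood by
Newton iterations with step-halving on likelihood decrease, a
trust-region cap of 5 on the largest coefficient step, convergence when
the relative log-likelihood change drops below 1e-9, and at most 100
iterations. Monotone likelihoods (separation) are reported through a
`converged=False` flag — in the scan such cells become p = 1
(conservative) rather than errors. The likelihood evaluation is fully
vectorised (suffix cumulative sums for risk sets, segment sums for tie
groups), which is what makes 500-resample bootstraps of ~375-cell scans
affordable; with no ties it reduces exactly to the Breslow formulas.
Agreement with an independent reference implementation is enforced to
1e-4 on hundreds of random datasets in the test suite.

Harrell's C counts a pair as comparable when the earlier observed time
is an event (or, at a shared time, exactly one subject fails); tied risk
scores count 1/2. Clinical covariates enter as ln(tumour volume), motion
amplitude (cm), age (years), and reference-coded sex (female) and lobe
(lower); model-facing density is rescaled to 100 HU units. Continuous
covariates are centered for numerical stability (Cox coefficients are
unaffected).

## The scan and region selection

For each cell the reduced model is `clinical + density(a) + dose(b)`
and the full model adds the product; the LRT has 1 df. Significant
cells (p < α = 0.05) form 8-connected components (connectivity is not
fixed by the method; 8 is the permissive choice). Average thickness per
axis is component area divided by extent along the other axis, and both
axes must reach 3 mm (a bounding-extent alternative is available behind
a flag). The region box used for value extraction is the per-axis
min–max extent of the component, so extraction covers every significant
annulus; per-patient region values are means of the smoothed curves
over the box intervals.

Candidate models are validated with a patient-level bootstrap
(default 500 resamples, unstratified by event status). Stability uses
the 2.5–97.5 percentile interval of the interaction coefficient across
resamples; an interval spanning both signs is unstable. The optimism
correction subtracts the median of (C on the resample − C of the same
refit on the original data) from the apparent C. The performance gate
compares *optimism-adjusted* C-indices of the candidate and clinical
models: comparing raw or in-resample concordances would hand the larger
model a mechanical advantage from its three extra parameters, and with
that biased rule spurious regions survive on null cohorts at an
unacceptable rate.

Interpretation outputs: contrast curves
`log HR(x; v) = (β_density + β_int v)(x − x_ref)` at the 10th/50th/90th
percentile of the centered dose value, with delta-method CIs from the
coefficient covariance block and the cohort median density as x_ref
(HR = 1 at a typical patient); and Kaplan–Meier stratification at the
median density crossed with the outer dose tertiles (middle tertile
discarded), log-rank per dose stratum. External validation either
scores the frozen training linear predictor by concordance on the new
outcomes (rank-based, so invariant to monotone transforms) or refits
the same terms.

Bootstrapping is applied to the final candidate models, not to the
whole selection pipeline inside each resample; a full-pipeline
bootstrap would also refit region selection per resample and is noted
as the stricter (and far costlier) alternative.

## The synthetic cohort

Each patient: a dense ellipsoidal tumour core (~0 HU, semi-axes within
±15% of a radius drawn from 6–14 mm, giving ~1–11 cc volumes) in lung
parenchyma at −800 HU with 40 HU independent voxel noise plus a 40 HU
spatially correlated texture field (5 mm correlation length, standing in
for vessels, septa and density gradients). The texture component is
load-bearing: with white noise only, annulus summaries average the noise
away and collapse onto a handful of patient-level factors, making every
heat-map row a near copy of its neighbours. The delineated GTV
contour over-covers the core by 2 mm, so a thin parenchyma rim inside
the contour still counts as lung and density stays measurable at small
negative distances — as in real segmentations, where identified density
regions extend slightly inside the contour. The peritumoral halo adds a
patient-level HU offset (mean +150, between-patient SD 100 HU) to the
lung shell within a per-patient width (mean 3 mm, ±33%); the width
variation matters because a fixed-width halo would make every density
annulus a single rescaled copy of one patient factor, and no annulus
could then be distinguished from its neighbours.

The plan delivers 60 Gy in 5 fractions: prescription dose inside the
PTV (GTV + 5 mm) plus a smooth Gaussian random field (6 mm correlation
length) normalised to an in-PTV SD of 4 Gy, both decaying outside the
PTV as exp(−d/8 mm); per-patient heterogeneity amplitude (±50%) and
fall-off scale (±20%) create the between-patient variance in the
incidental-dose metrics. Motion amplitudes are uniform on 0–1.2 cm
(median ≈ 0.6 cm, typical of lung SABR); age ~ N(75, 8) clipped to
45–92, 49% male, 65% upper lobe.

Outcomes follow an exponential-baseline proportional-hazards model.
The density and dose features entering the hazard are means of the
smoothed p90-density and dose-SD curves over the planted intervals
(density [0, 3] mm, dose [5, 16] mm by default), computed by the same
extraction code the analysis uses — recoverability is a property of the
pipeline, not of a shortcut. Features are centered at cohort means
(density in 100 HU units) before applying coefficients. Defaults:
baseline 0.01/month with a 60-month administrative horizon and
0.005/month random censoring (≈ 45–50% events — low clinical event
rates carry too little information for cohorts of a few hundred, so the
generator is calibrated for informative desk-scale studies); interaction
log-HR 1.0 per (100 HU·Gy), a deliberately strong planted effect so
recovery studies probe localisation rather than marginal power; density
main effect 1.6 per 100 HU, tied to the interaction coefficient so that
the density effect cancels in the lowest dose-SD tertile and roughly
doubles in the highest — the signature pattern (density stratifies
outcome only under heterogeneous incidental dose) this method exists to
detect; dose main effect 0.1/Gy; clinical effects dominated by tumour
volume (1.1 per ln(cc), i.e. a hazard ratio ≈ 3 per e-fold, the size of
volume effect reported for local relapse after lung SABR; lobe 0.3, sex
0.2, motion 0.2, age 0.01). Regional failure is
generated from the clinical covariates only unless a dedicated model is
supplied. A single root seed determines the cohort bit-for-bit.

What the generator does *not* emulate: realistic beam arrangements,
4D-CT phase reconstruction, image artifacts (emphysema, fibrosis),
anatomy outside the lung (the body mask is the full grid), and
non-proportional hazards. Passing recovery tests therefore shows the
machinery is sound under its stated model, not that the clinical effect
sizes or false-positive rates transfer to real cohorts.

## Numerical and degenerate-input conventions

Distance bins at 2 mm spacing leave the |d| < 1 mm annuli empty (see
above). Annuli whose values are imputed for the majority of patients are
excluded from hypothesis testing in the scan (cells flagged untested,
p = 1): an imputed value is a copy of a neighbouring annulus, and
testing copies counts the same evidence several times — in particular it
manufactures cluster area for the region-size rule out of rows that hold
no data. The curves themselves stay filled and defined everywhere, so
region boxes and value extraction are unaffected. Densities outside the
histogram range are clipped into the edge bins so counts are conserved. Dose columns of the
fraction-below-30-Gy metric are exactly zero near the target at SABR
doses; the corresponding scan cells are degenerate (constant covariate)
and are flagged non-converged with p = 1 — mirroring the fact that this
metric carries no information where everything is far above threshold.
Curves with all annuli empty, empty masks, masks filling the grid, a
non-positive administrative horizon, and non-nested LRT inputs are
errors. Negative LRT statistics from numerical noise are clamped to
zero with a warning.

## Study sizes used by the tests

The acceptance-style studies run at 48³ voxels of 2 mm, n = 300 (null
calibration, 20 seeds), n = 400 (planted-interaction recovery, 20
seeds) and n = 200 (transfer), sizes at which every stage is exercised
end-to-end while the full suite stays comfortably runnable on one CPU.
A known property of the null calibration: per-map significant-cell
fractions have heavy seed-to-seed variance because annulus values share
patient-level factors (halo offset, fall-off scale), so a single chance
association can light up much of one map; the [0.02, 0.09] calibration
band refers to the mean over maps and seeds. With non-zero density and
dose main effects, single-annulus models are misspecified proxies of
the true interval features, which inflates the interaction test; null
calibration is therefore assessed on cohorts with no imaging–outcome
association, and this sensitivity is a limitation to keep in mind when
interpreting real-data maps.

A second known limitation: bootstrapping only the final candidate model
corrects refit optimism but not *selection* optimism — the candidate was
already the most significant cluster among roughly two thousand scanned
cells, and that advantage survives the correction. Under the null study
conditions above, a stable region with a small positive adjusted-C gain
is still retained in roughly one cohort in five or six. The strict
alternative — re-running scanning and region selection inside every
bootstrap resample — would remove this at several hundred times the
cost; the package implements the final-model bootstrap and reports the
residual false-retention rate rather than hiding it.
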