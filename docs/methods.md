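# Methods

`flimplate` implements the analysis chain of a time-gated FLIM-FRET
multiwell plate assay: decay fitting with reference reconvolution,
membrane-selective cell segmentation, global-binning population-fraction
estimation, and plate-level screening statistics, validated end to end
on a synthetic plate generator with known ground truth.

## The measurement model

A gated-intensifier FLIM system records, for each excitation pulse, the
photons arriving in a boxcar window of width *w* opened at a programmable
delay *d* after the pulse; scanning the delay yields a stack of 2-D count
frames indexed by gate. The per-pixel expectation at gate *k* is

    E[y_k] = B * ∫_{d_k}^{d_k+w} [ IRF ⊗ I ](t) dt / Z,

where `I(t) = Σ_i β_i exp(-t/τ_i)` is the emission decay,
`IRF` the instrument response, *B* the pixel's photon budget and *Z* the
normalisation over the acquired schedule. Counts are Poisson. Throughout
the package the mixture weights β_i are **amplitude fractions** — equal
to molecular population fractions when the radiative rate is shared —
and all times are picoseconds.

Defaults (all configurable in `SimulationConfig`): 16 contiguous gates
of 500 ps spanning 0–8000 ps; Gaussian IRF of 150 ps FWHM centred 500 ps
after the first gate opening; donor lifetime τ_D = 2950 ps (a CFP-like
donor), FRET lifetime τ_F = 766 ps, reference lifetime τ_ref = 50 ps (a
DASPI-like dye); 500 expected photons per cell pixel. The gate count,
width and budget are not constrained by published instrument settings;
they are realistic choices for a gated optical intensifier and are
exposed in the config.

## Reference reconvolution

Rather than deconvolving an explicitly measured IRF, the fit expresses
every model decay through the gated measurement of a reference dye with
known short mono-exponential lifetime. From
`R = IRF ⊗ (1/τ_ref) e^{-t/τ_ref}` follows the operator identity
`IRF = R + τ_ref dR/dt`, and hence, for a mixture,

    I_model(t) ∝ Σ_i β_i [ τ_ref R(t) + (1 − τ_ref/τ_i) (R ⊗ e^{-t/τ_i})(t) ].

The discrete convolution `R ⊗ e^{-t/τ}` treats R as piecewise linear and
integrates each segment exactly — a first-order exponential recurrence,
evaluated as an IIR filter.

**Coarse gates.** When the reference is recorded on gates as wide as
their spacing (the default), its sub-gate time structure is lost but its
cumulative distribution is known *exactly* at every gate boundary. The
engine therefore (i) interpolates that cumulative with a monotone cubic
(PCHIP) and differentiates to a non-negative density on a ~10 ps
internal grid, (ii) evaluates the reconvolution there, and (iii) maps
the model back through the same boxcar gate-integration operator that
produced the data. One irreducible error source remains: gates that open
while the reference still has mass in flight ("rise gates") depend on
the unknowable within-gate shape of the IRF. Gates opening after
essentially all reference mass has arrived (cumulative ≥ 0.999) follow
the pure-decay model exactly, so fitting is restricted to those gates.
With the default schedule this excludes the first two of sixteen gates
(~19% of photons) and leaves a mono-exponential lifetime bias of
≈ −0.2% at 10⁴ photons. A small systematic remains in bi-exponential
fraction estimates (β₁ high by ≈ 0.02 at 10⁶ pooled photons) because the
two components weight the residual within-gate placement uncertainty of
the reference peak differently; this is below the package's validation
tolerance and is flagged here rather than hidden.

For references sampled finely (spacing at or below the internal
resolution) the identity is evaluated directly on the reference's own
grid — this path reproduces a brute-force numerical IRF convolution to
< 10⁻³ maximum relative deviation.

## Fitting

All fits minimise the Neyman-weighted squared residual
`Σ_k (y_k − m_k)² / max(y_k, 1)`.

* `fit_monoexp` — Levenberg–Marquardt over (log τ, log A); τ initialised
  deterministically from the log-linear tail slope of the last half of
  the gates, amplitude from the total counts. Convergence: relative
  parameter change below 10⁻⁶ within the iteration cap; all-zero decays
  return a non-converged result with τ undefined.
* `fit_pixelwise` — per-pixel mono-exponential lifetime image, with
  pixels below the photon threshold (default 200 photons summed over the
  schedule) left undefined. For throughput the amplitude is profiled out
  analytically (variable projection) on a dense logarithmic lifetime
  grid (180 points, 250–9000 ps) and the χ² minimum is polished by
  parabolic interpolation in log τ; this agrees with the LM path to well
  below shot noise and is verified against it in the tests.
* `fit_roi_binned` — sums counts over all ROI pixels per gate, then fits
  once; invariant to pixel permutation by construction.
* `fit_global_binned` — two-step global analysis. Step 1 pools all
  conditions and fits the bi-exponential model with τ₁ fixed (in the
  assay, τ₁ comes from a mono-exponential fit of the positive-control
  wells — the non-FRETing donor lifetime, including any residual FRET
  those wells contain); this yields the shared FRET lifetime τ₂. Step 2
  fixes both lifetimes and fits the long-lifetime fraction β₁ per
  condition, clamped to [0, 1] with a boundary flag; β₂ = 1 − β₁ always.
  τ₂ is declared unidentifiable when the pooled two-component fit fails
  a likelihood-ratio test against the single-exponential (Δχ² < 9), when
  β₁ sits at the single-component boundary, or when τ₂ collapses onto τ₁
  within a 50 ps guard; in that case the per-condition fits report the
  mono-exponential interpretation (β₁ = 1, flagged). τ₂ uncertainty is
  reported as the SD of per-replicate-row refits.
* The donor is modelled as mono-exponential throughout; a real CFP donor
  is multi-exponential, and the same simplification a practitioner would
  make (approximating it as mono-exponential) is built into both the
  generator and the fitter.
* A constant additive background term is available in principle through
  the mixture interface but is off by default; the generator emits no
  background light.

## Segmentation

The size-tuned nonlinear top-hat scores each pixel by
`max(0, stat_close(disc r≤inner) − stat_distant(annulus inner<r≤outer))`.
The statistic pair is configurable. The default is median/median: the
close median requires the object to fill over half the inner disc and
the distant median requires the annulus to be mostly background, so the
transform responds to objects of roughly 0.7–1.8× the inner radius — a
genuinely size-tuned detector. A max distant statistic is stricter
(any object pixel in the annulus vetoes the score) and is only suitable
for blobs smaller than the inner disc; it is available but not the
default for cell-scale objects. Neighbourhoods are clipped at image
borders (no invented padding); a border pixel whose clipped annulus is
empty uses a 0 baseline.

Pipeline: top-hat → threshold → morphological closing then opening
(disc, radius 1) → 8-connected labelling → discard objects smaller than
`min_object_size` → membrane mask per object as the exact set difference
`mask AND NOT erode(mask, disk(erosion_depth))`, with out-of-image
treated as background. Defaults at the synthetic 64×64 scale:
inner 5 px, outer 12 px, threshold 100 counts, minimum size 100 px,
erosion depth 3 px (the membrane width). An empty result carries a
"no cells found" flag that propagates to white wells in plate maps.

## The synthetic plate generator

Each field of view contains non-overlapping elliptical cells (semi-axes
6–8.5 px at 64×64, membrane ring 3 px wide formed by disc erosion of the
filled ellipse). Membrane pixels carry a FRETing donor fraction set by
the well's condition: positive controls (myristoylation-deficient Gag,
no membrane binding) at `f_min` = 0.05; vehicle negative controls at
`f_max` = 0.8; dosed wells follow a four-parameter Hill curve
`f(d) = f_min + (f_max − f_min)/(1 + (d/EC50)^h)` with EC50 = 0.1 µM and
h = 1 linking the NMT-inhibitor dose to membrane binding. Cytoplasm
carries a constant dose-independent dimerisation fraction (0.15). Small
bright debris discs (2–3 px radius, pure FRET decay, brightness equal to
the cells) are scattered outside cells with an expected count
proportional to the membrane FRETing fraction — debris is a product of
VLP formation, so aggregating wells carry it and inhibited wells do not.
This reproduces the assay's observed phenomenology: debris biases plain
intensity thresholding while membrane-selective ROIs both exclude it and
avoid diluting the membrane signal with cytoplasm, widening the assay
window at low dose.

The generator emulates Poisson photon counting only. It does **not**
model camera read noise or intensifier gain noise, optical sectioning,
photobleaching, cell-to-cell expression variability, spatial plate
gradients, or multi-exponential donors. Passing tests therefore
demonstrate correctness of the estimators and pipeline under the stated
photon-counting model, not robustness to every artefact of real plate
data — drift QC, for example, is exercised on injected gradients, since
the generator is spatially unbiased by design.

All randomness descends from a single seed through spawned
`SeedSequence` children (one per well), so datasets are bit-identical
under a fixed seed and independent of well iteration order.

## Plate statistics

* Per-well aggregation pools pixel/ROI values across FOVs
  (`pixel_pooled`, default) or averages per-FOV means (`fov_mean`).
* Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with sample SDs; arms default to
  per-well mean lifetimes over replicate wells (per-ROI or per-pixel
  arms can be passed instead). Substituting a saturating dose column for
  a failed control arm is supported by passing that column's values.
* Percent inhibition = 100 (τ_med − τ_low)/(τ_high − τ_low): lifetime
  rises with inhibition, so the low dose anchors 0%. Out-of-range values
  are reported unclamped with a flag.
* Drift QC: OLS slope of well means ordered column- or row-wise, with an
  optional flag when the fitted drift across the span exceeds a fraction
  of the assay window.
* Dose–response tables pool repeat wells per dose; a rising
  four-parameter Hill fit against log dose gives EC50, flagged
  unidentifiable for flat responses, with an optional residual-bootstrap
  CI. EC50 estimated from the effective-lifetime readout is an
  *apparent* EC50: the fitted single-exponential lifetime is a nonlinear
  function of the FRETing fraction, which shifts the curve's midpoint
  (about 1.5–2× low under the default conditions). The population-
  fraction readout β₁ is linear in the ground-truth fraction and
  recovers the generator's EC50 without that distortion; both are
  computed.

## Problem sizes

The validation studies run at desk scale by choice: 64×64 pixel fields
(downsampled from a full-frame sensor), one FOV per well, 96-well
plates, 10³–10⁶ photons per decay, 400–1000 fit repetitions per
calibration point. These sizes give standard errors comfortably inside
every tolerance asserted in the test suite while keeping the whole suite
in a few minutes on one core.

## Known limitations

* Rise gates are excluded from fitting under coarse contiguous gating;
  schedules whose reference never clears the 0.999 cumulative threshold
  fall back to all-gate fitting with the gated model (approximate).
* Gapped (non-contiguous) coarse gate schedules use a midpoint
  approximation for the reference rather than the exact cumulative
  construction.
* The β₁ estimate carries a ≈ +0.02 systematic at coarse gating (see
  above).
* Touching cells are not split (no watershed); segmentation accuracy is
  validated against the generator's well-separated cells.
* The Hill fit reports a residual-bootstrap CI, not a profile-likelihood
  interval.
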