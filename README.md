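# flimplate

Time-gated FLIM-FRET multiwell plate analysis: decay fitting with
reference reconvolution, membrane-selective segmentation, global-binning
population-fraction estimation, and screening-assay statistics.

## The problem

Fluorescence lifetime imaging (FLIM) turns FRET into a quantitative,
concentration-independent readout of protein–protein interaction: when a
donor fluorophore transfers energy to a nearby acceptor, its excited-state
lifetime drops. An automated FLIM plate reader imaging, say, an HIV-1 Gag
aggregation assay produces one time-gated image stack per field of view —
a 2-D photon-count frame for each gate delay after the excitation pulse —
across a 96-well plate in which an inhibitor dose series modulates how
much Gag binds and aggregates at the plasma membrane.

Turning those stacks into assay numbers takes a chain of steps, each of
which this package implements as tested, reusable code:

1. **Decay fitting with reference reconvolution** (`flimplate.fitting`).
   Each decay is fitted by weighted Levenberg–Marquardt NLLS to
   `I(t) = I₀ [β₁ e^{−t/τ₁} + β₂ e^{−t/τ₂}]` (or its one-component
   special case), with the instrument response accounted for through the
   gated measurement of a short-lifetime reference dye: using
   `IRF = R + τ_ref dR/dt`, the model is expressed directly in terms of
   the measured reference `R`. Pixel-wise fitting yields lifetime images
   thresholded at a minimum photon count; ROI-binned fitting pools the
   time-resolved data over a region first.
2. **Membrane segmentation** (`flimplate.segmentation`). A size-tuned
   nonlinear top-hat transform (configurable rank statistics over a
   close disc and a distant annulus), threshold, morphological
   smoothing, size sieve, and per-object erosion produce whole-cell and
   membrane-only masks — selecting the plasma membrane where the FRET
   signal lives.
3. **Global binning** (`fit_global_binned`). With the non-FRETing donor
   lifetime τ₁ fixed from positive-control wells, the shared FRET
   lifetime τ₂ is fitted to the globally binned decay and the
   long-lifetime (non-FRETing) population fraction β₁ is estimated per
   dose — the monomer/oligomer ratio behind the lifetime shift.
4. **Plate statistics** (`flimplate.plate`). Per-well aggregation, plate
   maps with missing-well flags, row/column drift QC, percent
   inhibition, dose–response tables with Hill/EC50 fits, and the
   screening quality factor `Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|` (> 0.4 is
   considered a usable assay).

Because raw plate data of this kind are rarely shared, the package
includes a first-class synthetic generator (`flimplate.simulate`): plates
of gated stacks containing elliptical cells whose membrane pixels carry a
dose-dependent mixture of FRETing and non-FRETing donor decays, convolved
with a Gaussian IRF, gate-integrated, and Poisson-sampled — with every
ground-truth parameter recorded in a manifest. All validation runs
against this generator.

## Worked example

```python
from flimplate import (
    DoseResponseModel, SegmentationParams, SimulationConfig,
    default_dose_response_layout, generate_plate, z_prime,
)
from flimplate.pipeline import analyse_plate, control_arm_values

layout = default_dose_response_layout()          # 96 wells: controls + 9-dose series
dataset = generate_plate(layout, SimulationConfig(), DoseResponseModel(), seed=1)
analysis = analyse_plate(dataset, SegmentationParams())

for mode in ("pixel", "membrane"):
    pos = control_arm_values(analysis.well_results[mode], layout, "positive_control")
    neg = control_arm_values(analysis.well_results[mode], layout, "negative_control")
    m = z_prime(pos, neg)
    print(f"{mode}: Z' = {m.z_prime:.3f}, window = {abs(m.mu_pos - m.mu_neg):.0f} ps")
```

prints (seed 1):

```
pixel: Z' = 0.751, window = 831 ps
membrane: Z' = 0.843, window = 976 ps
```

i.e. both readouts comfortably clear the Z′ > 0.4 screening threshold,
and membrane-selective ROI analysis widens the assay window over plain
intensity thresholding (here by a factor 1.17) because it excludes
FRETing cell debris and undiluted cytoplasm from the aggregating wells.

The numbered drivers under `analysis/` run the full study and write
tables under `results/`:

```bash
python analysis/01_simulate_plate.py           # plate -> scratch/plate/
python analysis/02_analyse_plate.py            # Z', windows, drift, dose tables
python analysis/03_global_binning.py           # tau2, beta1 per dose, EC50
python analysis/04_characterisation_inhibition.py  # 3-dose plates, % inhibition
python analysis/05_precision_study.py          # bias and 1/sqrt(N) precision
```

`03_global_binning.py`, for example, reports for the seed-1 plate a
shared FRET lifetime τ₂ = 719 ± 6 ps (SD across the 8 replicate rows),
β₁ rising from 0.31 at 0.001 µM to 0.96 at 10 µM inhibitor, and an EC50
of 0.092 µM from the β₁ readout against a ground truth of 0.1 µM.

A thin CLI wraps the same pipeline:
`flimplate simulate|segment|fit|report|run --help`.

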