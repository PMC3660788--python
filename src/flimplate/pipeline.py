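"""End-to-end orchestration: simulate -> segment -> fit -> report.

`analyse_plate` is the shared analysis core used by the pipeline, the
numbered analysis drivers and the acceptance checks: for every field of
view it segments the photon image, fits lifetimes pixel-wise (intensity
threshold only) and per membrane/whole-cell ROI, and aggregates the
three readouts into per-well statistics.  `run_pipeline` wraps it with
file I/O, metrics tables and a provenance record.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import (
    ReconvolutionEngine,
    fit_global_binned,
    fit_monoexp,
    fit_pixelwise,
    fit_roi_binned,
)
from .io import (
    RunConfig,
    config_hash,
    read_layout_csv,
    run_config_to_dict,
    write_plate,
)
from .plate import (
    PlateLayout,
    WellResult,
    default_dose_response_layout,
    dose_response_table,
    drift_check,
    plate_map,
    well_aggregate,
    z_prime,
)
from .segmentation import SegmentationParams, segment_cells
from .simulate import PlateDataset, generate_plate

__all__ = [
    "PlateAnalysis",
    "analyse_plate",
    "control_arm_values",
    "run_pipeline",
    "effective_lifetime_of_fraction",
    "fraction_for_lifetime_effect",
    "dose_for_fraction",
]

ANALYSIS_MODES = ("pixel", "cell", "membrane")


@dataclass
class PlateAnalysis:
    """Per-well results for the three analysis modes plus pooled decays.

    ``well_results[mode]`` maps well id -> :class:`WellResult` where
    mode is 'pixel' (intensity-thresholded pixel-wise fits), 'cell'
    (whole-cell ROI-binned fits) or 'membrane' (membrane-only ROI
    fits).  ``membrane_decays``/``cell_decays`` hold the per-well
    ROI-binned photon counts per gate, for global analysis.
    """

    well_results: dict = field(default_factory=dict)
    membrane_decays: dict = field(default_factory=dict)
    cell_decays: dict = field(default_factory=dict)
    n_cells_by_well: dict = field(default_factory=dict)


def analyse_plate(
    dataset: PlateDataset,
    seg_params: SegmentationParams,
    fit_threshold: float = 200.0,
    aggregate_method: str = "pixel_pooled",
) -> PlateAnalysis:
    """Segment and fit every field of view of a plate dataset."""
    reference = dataset.reference
    engine = ReconvolutionEngine(reference)
    out = PlateAnalysis(well_results={m: {} for m in ANALYSIS_MODES})
    fovs_by_well: dict[str, list] = {}
    for (well, fov), stack in dataset.stacks.items():
        fovs_by_well.setdefault(well, []).append(stack)
    all_wells = list(dataset.manifest.get("wells", {})) or list(fovs_by_well)
    for well in all_wells:
        stacks = fovs_by_well.get(well, [])
        pixel_vals, cell_vals, mem_vals = [], [], []
        mem_decay = None
        cell_decay = None
        n_cells = 0
        for stack in stacks:
            image = stack.photon_image()
            li = fit_pixelwise(stack, reference, fit_threshold, engine=engine)
            pixel_vals.append(li.defined_values())
            seg = segment_cells(image, seg_params)
            n_cells += seg.n_cells
            fov_cell, fov_mem = [], []
            for cmask, mmask in zip(seg.cell_masks, seg.membrane_masks):
                cfit = fit_roi_binned(stack, reference, cmask, engine=engine)
                if cfit.converged:
                    fov_cell.append(cfit.tau_ps)
                if mmask.any():
                    mfit = fit_roi_binned(stack, reference, mmask, engine=engine)
                    if mfit.converged:
                        fov_mem.append(mfit.tau_ps)
                    decay = stack.binned_decay(mmask)
                    mem_decay = decay if mem_decay is None else mem_decay + decay
                cdecay = stack.binned_decay(cmask)
                cell_decay = cdecay if cell_decay is None else cell_decay + cdecay
            cell_vals.append(fov_cell)
            mem_vals.append(fov_mem)
        out.well_results["pixel"][well] = well_aggregate(well, pixel_vals, aggregate_method)
        out.well_results["cell"][well] = well_aggregate(well, cell_vals, aggregate_method)
        out.well_results["membrane"][well] = well_aggregate(well, mem_vals, aggregate_method)
        out.n_cells_by_well[well] = n_cells
        if mem_decay is not None:
            out.membrane_decays[well] = mem_decay
        if cell_decay is not None:
            out.cell_decays[well] = cell_decay
    return out


def control_arm_values(
    well_results: dict, layout: PlateLayout, role: str
) -> np.ndarray:
    """Per-well mean values of all non-flagged wells with a given role."""
    by_id = layout.by_id()
    vals = [
        res.mean_tau
        for wid, res in well_results.items()
        if wid in by_id and by_id[wid].role == role and not res.no_cells_flag
    ]
    return np.asarray(vals, dtype=float)


def _well_results_frame(analysis: PlateAnalysis, layout: PlateLayout) -> pd.DataFrame:
    by_id = layout.by_id()
    rows = []
    for mode, results in analysis.well_results.items():
        for wid, res in results.items():
            spec = by_id.get(wid)
            rows.append(
                {
                    "well": wid,
                    "mode": mode,
                    "role": spec.role if spec else "",
                    "dose_uM": spec.dose_uM if spec else float("nan"),
                    "mean_tau_ps": res.mean_tau,
                    "sd_tau_ps": res.sd_tau,
                    "n_values": res.n_values,
                    "n_fovs": res.n_fovs,
                    "no_cells": res.no_cells_flag,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate -> segment -> fit -> report and write the artifact tree.

    Returns the metrics dictionary; everything is deterministic given
    ``config.seed``.  Artifacts: the simulated dataset (TIFF + JSON),
    per-well fit tables (CSV), plate maps (CSV), assay metrics (JSON)
    and a provenance record.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.layout_csv:
        layout = read_layout_csv(config.layout_csv)
    else:
        layout = default_dose_response_layout(
            rows=config.simulation.rows, cols=config.simulation.cols
        )
    dataset = generate_plate(
        layout, config.simulation, config.dose_response, seed=config.seed
    )
    write_plate(dataset, out_dir / "data")
    analysis = analyse_plate(
        dataset, config.segmentation, config.fit_threshold, config.aggregate_method
    )
    _well_results_frame(analysis, layout).to_csv(out_dir / "well_fits.csv", index=False)

    metrics: dict = {"seed": config.seed, "z_prime": {}, "dose_response": {}}
    for mode in ANALYSIS_MODES:
        results = analysis.well_results[mode]
        pos = control_arm_values(results, layout, "positive_control")
        neg = control_arm_values(results, layout, "negative_control")
        grid = plate_map(results, layout)
        pd.DataFrame(grid).to_csv(out_dir / f"plate_map_{mode}.csv", index=False)
        try:
            am = z_prime(pos, neg)
            metrics["z_prime"][mode] = {
                "z_prime": am.z_prime,
                "mu_pos_ps": am.mu_pos,
                "sigma_pos_ps": am.sigma_pos,
                "mu_neg_ps": am.mu_neg,
                "sigma_neg_ps": am.sigma_neg,
            }
        except ValueError as exc:
            metrics["z_prime"][mode] = {"error": str(exc)}
        try:
            table, hill = dose_response_table(results, layout, n_bootstrap=0)
            table.to_csv(out_dir / f"dose_response_{mode}.csv", index=False)
            metrics["dose_response"][mode] = {
                "ec50_uM": hill.ec50_uM if hill else float("nan"),
                "identifiable": bool(hill.identifiable) if hill else False,
            }
        except ValueError as exc:
            metrics["dose_response"][mode] = {"error": str(exc)}
    drift = drift_check(analysis.well_results["pixel"], layout, "dose", axis="column")
    metrics["drift_slope_ps_per_well"] = drift.slope

    # global binning on the membrane-pooled decays: tau1 from the
    # positive controls, shared tau2 across the series, beta1 per dose
    metrics["global_binning"] = _global_binning_metrics(dataset, analysis, layout)

    provenance = {
        "config_hash": config_hash(config),
        "config": run_config_to_dict(config),
        "seed": config.seed,
        "flimplate_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, sort_keys=True, indent=1)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, sort_keys=True, indent=1)
    return metrics


def effective_lifetime_of_fraction(
    fret_fraction: float,
    config,
    reference=None,
) -> float:
    """Noise-free effective single-exponential lifetime of a membrane mixture.

    Maps a FRETing donor fraction to the lifetime a mono-exponential
    reconvolution fit reports for the corresponding two-component decay
    (donor + FRET lifetimes from ``config``) — the assay's ground-truth
    dose-to-readout transfer function.
    """
    from .simulate import expected_gate_counts, simulate_reference

    if reference is None:
        reference = simulate_reference(config, rng=None)
    f = float(fret_fraction)
    decay = expected_gate_counts(
        [(1.0 - f, config.tau_donor_ps), (f, config.tau_fret_ps)], 1e6, config
    )
    fit = fit_monoexp(decay, reference)
    if not fit.converged:
        raise RuntimeError("noiseless effective-lifetime fit failed")
    return fit.tau_ps


def fraction_for_lifetime_effect(
    effect: float,
    f_low: float,
    f_high: float,
    config,
    reference=None,
) -> float:
    """FRETing fraction whose effective lifetime sits at ``effect`` of the way
    from the ``f_low`` to the ``f_high`` lifetime.

    Used to plate a "medium" dose at a known position of the assay's
    ground-truth lifetime window (e.g. 0.75 for a 75%-inhibition well).
    """
    from scipy.optimize import brentq

    from .simulate import simulate_reference

    if reference is None:
        reference = simulate_reference(config, rng=None)
    tau_low = effective_lifetime_of_fraction(f_low, config, reference)
    tau_high = effective_lifetime_of_fraction(f_high, config, reference)
    target = tau_low + effect * (tau_high - tau_low)

    def g(f):
        return effective_lifetime_of_fraction(f, config, reference) - target

    lo, hi = sorted((f_low, f_high))
    return float(brentq(g, lo, hi, xtol=1e-5))


def dose_for_fraction(fret_fraction: float, model) -> float:
    """Invert the Hill link: the dose at which the membrane FRETing
    fraction equals ``fret_fraction`` (must lie strictly between f_min
    and f_max)."""
    f = float(fret_fraction)
    if not (model.f_min < f < model.f_max):
        raise ValueError("fraction must lie strictly between f_min and f_max")
    return float(
        model.ec50_uM * ((model.f_max - model.f_min) / (f - model.f_min) - 1.0)
        ** (1.0 / model.hill)
    )


def _global_binning_metrics(dataset, analysis: PlateAnalysis, layout: PlateLayout) -> dict:
    from .plate import fit_hill_curve

    by_id = layout.by_id()
    pos_decay = None
    decays_by_dose: dict[float, np.ndarray] = {}
    for wid, decay in analysis.membrane_decays.items():
        spec = by_id.get(wid)
        if spec is None:
            continue
        if spec.role == "positive_control":
            pos_decay = decay if pos_decay is None else pos_decay + decay
        elif spec.role in ("dose", "negative_control"):
            dose = float(spec.dose_uM)
            decays_by_dose[dose] = decays_by_dose.get(dose, 0) + decay
    if pos_decay is None or len(decays_by_dose) < 2:
        return {"error": "not enough data for global binning"}
    tau1_fit = fit_monoexp(pos_decay, dataset.reference)
    if not tau1_fit.converged:
        return {"error": "positive-control mono-exponential fit failed"}
    keys = {dose: f"dose_{dose:.6g}" for dose in decays_by_dose}
    result = fit_global_binned(
        {keys[d]: v for d, v in decays_by_dose.items()},
        dataset.reference,
        tau1_fit.tau_ps,
    )
    beta1_by_dose = {
        d: result.condition_fits[keys[d]].beta1 for d in sorted(decays_by_dose)
    }
    # EC50 from the population-fraction readout: beta1 is linear in the
    # ground-truth FRETing fraction, unlike the effective lifetime
    doses = np.array([d for d in beta1_by_dose if d > 0])
    betas = np.array([beta1_by_dose[d] for d in beta1_by_dose if d > 0])
    hill = fit_hill_curve(doses, betas)
    return {
        "tau1_ps": tau1_fit.tau_ps,
        "tau2_ps": result.tau2_ps,
        "tau2_unidentifiable": bool(result.tau2_unidentifiable),
        "beta1_by_dose": [[d, b] for d, b in beta1_by_dose.items()],
        "ec50_uM_beta1": hill.ec50_uM if hill.identifiable else float("nan"),
        "ec50_identifiable": bool(hill.identifiable),
    }
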