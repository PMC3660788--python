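"""Synthetic time-gated FLIM plate generator with known ground truth.

Emulates a gated-intensifier FLIM plate reader imaging a Gag-aggregation
FRET assay: each frame contains elliptical cells whose plasma-membrane
pixels carry a dose-dependent mixture of FRETing (short-lifetime) and
non-FRETing (long-lifetime) donor decays, the cytoplasm carries a small
dose-independent dimerisation fraction, and optional small bright debris
blobs carry the pure FRETing decay.  Decays are convolved with a Gaussian
instrument response, integrated over boxcar gates, and corrupted by
Poisson counting noise.  A matching reference-dye measurement (short
known lifetime, same gate schedule) is generated for reconvolution
fitting.

Conventions: mixture fractions are amplitude fractions of the decay law
``I(t) = I0 * sum_i beta_i exp(-t / tau_i)`` (equal to molecular
population fractions for a shared radiative rate); all times are in
picoseconds; pixel indexing is row-major and 0-based.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import ellipse as _ellipse
from skimage.morphology import dilation, disk, erosion

from .core import GatedStack, ReferenceDecay, validate_gate_schedule

__all__ = [
    "BACKGROUND",
    "CYTOPLASM",
    "MEMBRANE",
    "DEBRIS",
    "DoseResponseModel",
    "SimulationConfig",
    "GroundTruthCell",
    "CellField",
    "PlateDataset",
    "fret_fraction_at_dose",
    "render_cell_field",
    "add_debris",
    "decay_gate_fractions",
    "simulate_gated_stack",
    "simulate_reference",
    "generate_plate",
    "well_mixtures",
    "expected_gate_counts",
    "amplitude_weighted_lifetime",
]

# compartment codes in label images
BACKGROUND = 0
CYTOPLASM = 1
MEMBRANE = 2
DEBRIS = 3


@dataclass(frozen=True)
class DoseResponseModel:
    """Hill-curve link from inhibitor dose to the FRETing donor fraction.

    The inhibitor blocks membrane binding, so the FRETing fraction falls
    from ``f_max`` (no drug, maximal aggregation) towards ``f_min``
    (residual FRET) with increasing dose.

    Parameters
    ----------
    ec50_uM
        Dose producing the half-maximal drop, in micromolar.
    hill
        Hill slope (> 0).
    f_max, f_min
        FRETing donor fraction at zero and saturating dose.
    """

    ec50_uM: float = 0.1
    hill: float = 1.0
    f_max: float = 0.8
    f_min: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_min <= self.f_max <= 1.0):
            raise ValueError("need 0 <= f_min <= f_max <= 1")
        if not (self.ec50_uM > 0 and self.hill > 0):
            raise ValueError("ec50_uM and hill must be > 0")


def fret_fraction_at_dose(dose_uM: float, model: DoseResponseModel) -> float:
    """Ground-truth FRETing donor fraction at an inhibitor dose.

    ``f(d) = f_min + (f_max - f_min) / (1 + (d / ec50)^hill)``; equals
    ``f_max`` at zero dose and is monotonically non-increasing in dose.
    """
    if dose_uM < 0:
        raise ValueError("dose must be >= 0")
    if dose_uM == 0:
        return model.f_max
    return model.f_min + (model.f_max - model.f_min) / (
        1.0 + (dose_uM / model.ec50_uM) ** model.hill
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All tunable parameters of the synthetic plate generator.

    Defaults describe a 96-well plate imaged at 64 x 64 pixels per field
    of view with 16 contiguous 500 ps gates spanning 0-8000 ps, a CFP-like
    donor (tau_donor = 2950 ps), a FRETing donor species (tau_fret =
    766 ps), a DASPI-like reference (tau_ref = 50 ps) and a Gaussian IRF
    of 150 ps FWHM centred 500 ps after the first gate opening.
    """

    rows: int = 8
    cols: int = 12
    fovs_per_well: int = 1
    frame_shape: tuple[int, int] = (64, 64)
    gate_delays_ps: tuple[float, ...] = tuple(float(k) * 500.0 for k in range(16))
    gate_width_ps: float = 500.0
    tau_donor_ps: float = 2950.0
    tau_fret_ps: float = 766.0
    tau_ref_ps: float = 50.0
    irf_fwhm_ps: float = 150.0
    irf_center_ps: float = 500.0
    internal_dt_ps: float = 10.0
    photon_budget: float = 500.0  # expected photons per cell pixel over the schedule
    reference_photon_budget: float = 5e6
    cytoplasm_fret_fraction: float = 0.15
    cells_per_fov: int = 5
    cell_axes_px: tuple[float, float] = (6.0, 8.5)  # semi-axis range
    membrane_width_px: int = 3
    debris_per_frame: float = 3.0  # expected count at FRETing fraction 1.0
    debris_radius_px: tuple[int, int] = (2, 3)
    debris_brightness: float | None = None  # None -> photon_budget
    no_cell_fraction: float = 0.0

    def __post_init__(self) -> None:
        validate_gate_schedule(np.asarray(self.gate_delays_ps), self.gate_width_ps)
        for name in ("tau_donor_ps", "tau_fret_ps", "tau_ref_ps"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.photon_budget < 0:
            raise ValueError("photon_budget must be >= 0")
        if not (0.0 <= self.no_cell_fraction <= 1.0):
            raise ValueError("no_cell_fraction must be in [0, 1]")


@dataclass
class GroundTruthCell:
    """One simulated cell: geometry plus per-compartment masks/brightness."""

    center: tuple[float, float]
    axes: tuple[float, float]
    membrane_width: int
    cytoplasm_mask: np.ndarray
    membrane_mask: np.ndarray
    brightness: dict = field(default_factory=dict)

    def full_mask(self) -> np.ndarray:
        return self.cytoplasm_mask | self.membrane_mask


@dataclass
class CellField:
    """Cells plus compartment/instance label images for one frame."""

    cells: list[GroundTruthCell]
    compartment_labels: np.ndarray  # BACKGROUND/CYTOPLASM/MEMBRANE/DEBRIS
    cell_labels: np.ndarray  # 0 = background, k = cell k
    packing_warning: bool = False
    n_debris: int = 0


def _filled_ellipse(center, axes, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _ellipse(center[0], center[1], axes[0], axes[1], shape=shape)
    mask[rr, cc] = True
    return mask


def render_cell_field(
    n_cells: int,
    frame_shape: tuple[int, int],
    rng: np.random.Generator,
    axes_range: tuple[float, float] = (6.0, 8.5),
    membrane_width: int = 3,
    min_gap_px: int = 2,
    max_tries_per_cell: int = 200,
) -> CellField:
    """Place non-overlapping elliptical cells with membrane rings.

    Each cell is a filled ellipse; its membrane is the ring of
    ``membrane_width`` pixels obtained by subtracting the disc-eroded
    ellipse, and the remainder is cytoplasm.  Placement is rejection
    sampling; if a cell cannot be placed within the retry budget the
    field is returned with fewer cells and ``packing_warning`` set.
    """
    h, w = frame_shape
    lo, hi = axes_range
    if 2 * hi + 2 > min(h, w):
        raise ValueError("frame too small to hold a cell at the configured axes")
    occupied = np.zeros(frame_shape, dtype=bool)
    comp = np.zeros(frame_shape, dtype=np.uint8)
    cell_labels = np.zeros(frame_shape, dtype=np.int32)
    cells: list[GroundTruthCell] = []
    warning = False
    selem = disk(membrane_width)
    for _ in range(n_cells):
        placed = False
        for _try in range(max_tries_per_cell):
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            cy = rng.uniform(a + 1, h - a - 1)
            cx = rng.uniform(b + 1, w - b - 1)
            filled = _filled_ellipse((cy, cx), (a, b), frame_shape)
            grown = dilation(filled, disk(min_gap_px))
            if not (grown & occupied).any():
                placed = True
                break
        if not placed:
            warning = True
            break
        interior = erosion(filled, selem)
        membrane = filled & ~interior
        occupied |= filled
        comp[interior] = CYTOPLASM
        comp[membrane] = MEMBRANE
        label = len(cells) + 1
        cell_labels[filled] = label
        cells.append(
            GroundTruthCell(
                center=(cy, cx),
                axes=(a, b),
                membrane_width=membrane_width,
                cytoplasm_mask=interior,
                membrane_mask=membrane,
            )
        )
    return CellField(cells, comp, cell_labels, packing_warning=warning)


def add_debris(
    field: CellField,
    n_debris: int,
    rng: np.random.Generator,
    radius_range: tuple[int, int] = (2, 4),
    max_tries: int = 50,
) -> CellField:
    """Scatter small bright discs (pure-FRET debris) outside the cells."""
    h, w = field.compartment_labels.shape
    placed = 0
    for _ in range(n_debris):
        for _try in range(max_tries):
            r = int(rng.integers(radius_range[0], radius_range[1] + 1))
            cy = rng.uniform(r, h - r - 1)
            cx = rng.uniform(r, w - r - 1)
            blob = _filled_ellipse((cy, cx), (r, r), (h, w))
            if not (blob & (field.compartment_labels > 0)).any():
                field.compartment_labels[blob] = DEBRIS
                placed += 1
                break
    field.n_debris += placed
    return field


# ---------------------------------------------------------------------------
# decay model on the gate schedule
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=512)
def _gate_fractions_cached(
    betas: tuple[float, ...],
    taus: tuple[float, ...],
    delays: tuple[float, ...],
    width: float,
    irf_fwhm: float,
    irf_center: float,
    dt: float,
) -> tuple[float, ...]:
    delays_arr = np.asarray(delays)
    t_max = delays_arr[-1] + width + 6 * irf_fwhm
    t = np.arange(0.0, t_max + dt, dt)
    sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if sigma > 0:
        irf = np.exp(-0.5 * ((t - irf_center) / sigma) ** 2)
        irf /= irf.sum() * dt
    else:  # delta-like IRF at irf_center
        irf = np.zeros_like(t)
        irf[int(round(irf_center / dt))] = 1.0 / dt
    decay = np.zeros_like(t)
    for b, tau in zip(betas, taus):
        decay += b * np.exp(-t / tau)
    model = np.convolve(irf, decay)[: t.size] * dt
    # cumulative integral for boxcar gate windows
    cum = np.concatenate([[0.0], np.cumsum((model[1:] + model[:-1]) * 0.5 * dt)])
    start = np.interp(delays_arr, t, cum)
    stop = np.interp(delays_arr + width, t, cum)
    integrals = np.clip(stop - start, 0.0, None)
    total = integrals.sum()
    if total <= 0:
        raise ValueError("decay model has no support on the gate schedule")
    return tuple(integrals / total)


def decay_gate_fractions(
    components: Sequence[tuple[float, float]],
    config: SimulationConfig,
) -> np.ndarray:
    """Expected fraction of detected photons in each gate for a mixture.

    ``components`` is a sequence of ``(beta, tau_ps)`` amplitude
    fractions and lifetimes.  The IRF-convolved decay is integrated over
    each boxcar gate and normalised so the fractions sum to one over the
    schedule (the photon budget is defined over the acquired gates).
    """
    betas = tuple(float(b) for b, _ in components)
    taus = tuple(float(tau) for _, tau in components)
    if any(tau <= 0 for tau in taus):
        raise ValueError("all lifetimes must be > 0")
    if abs(sum(betas) - 1.0) > 1e-6:
        raise ValueError(f"mixture fractions must sum to 1, got {sum(betas)}")
    return np.asarray(
        _gate_fractions_cached(
            betas,
            taus,
            tuple(float(d) for d in config.gate_delays_ps),
            float(config.gate_width_ps),
            float(config.irf_fwhm_ps),
            float(config.irf_center_ps),
            float(config.internal_dt_ps),
        )
    )


def simulate_gated_stack(
    label_image: np.ndarray,
    mixtures: Mapping[int, Sequence[tuple[float, float]]],
    config: SimulationConfig,
    rng: np.random.Generator,
    brightness: Mapping[int, float] | None = None,
) -> GatedStack:
    """Simulate one gated stack from a compartment label image.

    Parameters
    ----------
    label_image
        Integer compartment codes per pixel; code 0 (background) emits
        nothing unless given a mixture and brightness.
    mixtures
        Per-compartment decay mixture ``{code: [(beta, tau_ps), ...]}``;
        fractions must sum to 1 per compartment.
    brightness
        Expected total photons per pixel per compartment over the gate
        schedule; defaults to ``config.photon_budget`` for every
        compartment in ``mixtures`` (debris uses
        ``config.debris_brightness`` when set).
    """
    label_image = np.asarray(label_image)
    delays = np.asarray(config.gate_delays_ps)
    expected = np.zeros((delays.size,) + label_image.shape, dtype=float)
    for code, components in mixtures.items():
        mask = label_image == code
        if not mask.any():
            continue
        if brightness is not None and code in brightness:
            bright = float(brightness[code])
        elif code == DEBRIS and config.debris_brightness is not None:
            bright = float(config.debris_brightness)
        else:
            bright = float(config.photon_budget)
        fractions = decay_gate_fractions(components, config)
        expected[:, mask] = bright * fractions[:, None]
    counts = rng.poisson(expected).astype(np.uint16)
    return GatedStack(counts, delays.copy(), config.gate_width_ps)


def expected_gate_counts(
    components: Sequence[tuple[float, float]],
    budget: float,
    config: SimulationConfig,
) -> np.ndarray:
    """Noise-free expected per-gate counts for a single mixed decay."""
    return budget * decay_gate_fractions(components, config)


def simulate_reference(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReferenceDecay:
    """Simulate the gated reference-dye measurement.

    A mono-exponential decay at ``tau_ref_ps`` under the same IRF and
    gate schedule as the samples; Poisson noise at
    ``reference_photon_budget`` total photons (skipped when ``rng`` is
    None, yielding the noise-free expectation).
    """
    expected = expected_gate_counts(
        [(1.0, config.tau_ref_ps)], config.reference_photon_budget, config
    )
    counts = expected if rng is None else rng.poisson(expected).astype(float)
    return ReferenceDecay(
        counts,
        np.asarray(config.gate_delays_ps),
        config.gate_width_ps,
        config.tau_ref_ps,
    )


def amplitude_weighted_lifetime(components: Sequence[tuple[float, float]]) -> float:
    """Amplitude-weighted mean lifetime ``sum(b tau) / sum(b)`` of a mixture."""
    betas = np.array([b for b, _ in components], dtype=float)
    taus = np.array([tau for _, tau in components], dtype=float)
    return float((betas * taus).sum() / betas.sum())


# ---------------------------------------------------------------------------
# whole-plate generation
# ---------------------------------------------------------------------------


@dataclass
class PlateDataset:
    """In-memory synthetic plate: stacks keyed by (well_id, fov)."""

    stacks: dict
    reference: ReferenceDecay
    manifest: dict
    layout: "object"


def well_mixtures(
    membrane_fret_fraction: float, config: SimulationConfig
) -> dict[int, list[tuple[float, float]]]:
    """Per-compartment decay mixtures for a given membrane FRETing fraction."""
    f_mem = float(membrane_fret_fraction)
    f_cyt = float(config.cytoplasm_fret_fraction)
    tau_d, tau_f = config.tau_donor_ps, config.tau_fret_ps
    return {
        CYTOPLASM: [(1.0 - f_cyt, tau_d), (f_cyt, tau_f)],
        MEMBRANE: [(1.0 - f_mem, tau_d), (f_mem, tau_f)],
        DEBRIS: [(1.0, tau_f)],
    }


def generate_plate(
    layout,
    config: SimulationConfig,
    model: DoseResponseModel,
    seed: int,
    out_dir=None,
) -> PlateDataset:
    """Generate a full synthetic plate with ground-truth manifest.

    For every non-empty well in ``layout`` one :class:`GatedStack` per
    FOV is produced.  Membrane pixels carry the FRETing fraction implied
    by the well's role/dose through ``model``; cytoplasm carries the
    residual dimerisation fraction; debris density scales with the
    membrane FRETing fraction (debris is a product of VLP formation).
    A fraction of wells may be flagged "no cells" to emulate autofocus
    failures.  When ``out_dir`` is given the dataset is also written to
    disk (TIFF stacks + JSON sidecars + manifest).
    """
    from .plate import PlateLayout  # local import avoids a cycle at module load

    if not isinstance(layout, PlateLayout):
        raise TypeError("layout must be a PlateLayout")
    ss = np.random.SeedSequence(seed)
    ref_rng = np.random.default_rng(ss.spawn(1)[0])
    reference = simulate_reference(config, ref_rng)
    stacks: dict = {}
    wells_manifest: dict = {}
    active = [wl for wl in layout.wells if wl.role not in ("excluded", "empty")]
    child_seeds = ss.spawn(len(active) + 1)[1:]
    for wl, child in zip(active, child_seeds):
        rng = np.random.default_rng(child)
        if wl.role == "positive_control":
            f_mem = model.f_min
        elif wl.role == "negative_control":
            f_mem = fret_fraction_at_dose(0.0, model)
        else:
            f_mem = fret_fraction_at_dose(wl.dose_uM, model)
        no_cells = config.no_cell_fraction > 0 and rng.random() < config.no_cell_fraction
        entry = {
            "condition": wl.condition,
            "role": wl.role,
            "dose_uM": wl.dose_uM,
            "membrane_fret_fraction": f_mem,
            "cytoplasm_fret_fraction": config.cytoplasm_fret_fraction,
            "no_cells": bool(no_cells),
            "fovs": [],
        }
        if not no_cells:
            mixtures = well_mixtures(f_mem, config)
            for fov in range(config.fovs_per_well):
                cell_field = render_cell_field(
                    config.cells_per_fov,
                    config.frame_shape,
                    rng,
                    axes_range=config.cell_axes_px,
                    membrane_width=config.membrane_width_px,
                )
                n_debris = int(rng.poisson(config.debris_per_frame * f_mem))
                add_debris(cell_field, n_debris, rng, config.debris_radius_px)
                stack = simulate_gated_stack(
                    cell_field.compartment_labels, mixtures, config, rng
                )
                stack.meta.update({"well": wl.well_id, "fov": fov})
                stacks[(wl.well_id, fov)] = stack
                entry["fovs"].append(
                    {
                        "fov": fov,
                        "n_cells": len(cell_field.cells),
                        "n_debris": cell_field.n_debris,
                        "packing_warning": cell_field.packing_warning,
                    }
                )
        wells_manifest[wl.well_id] = entry
    manifest = {
        "seed": int(seed),
        "config": _config_to_jsonable(config),
        "dose_response_model": asdict(model),
        "wells": wells_manifest,
    }
    dataset = PlateDataset(stacks, reference, manifest, layout)
    if out_dir is not None:
        from . import io as _io

        _io.write_plate(dataset, out_dir)
    return dataset


def _config_to_jsonable(config: SimulationConfig) -> dict:
    out = {}
    for key, value in asdict(config).items():
        if isinstance(value, tuple):
            value = list(value)
        out[key] = value
    return out
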