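"""On-disk formats: TIFF stacks with JSON sidecars, layouts, configs.

Gated stacks are multi-page TIFF (one page per gate, 16-bit unsigned
counts) with a JSON sidecar carrying the gate schedule and provenance;
lifetime images are 32-bit float TIFF; references and manifests are
JSON; plate layouts are CSV; run configurations are YAML and round-trip
losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import GatedStack, ReferenceDecay
from .plate import PlateLayout
from .segmentation import SegmentationParams
from .simulate import DoseResponseModel, PlateDataset, SimulationConfig

__all__ = [
    "RunConfig",
    "read_gated_stack",
    "write_gated_stack",
    "read_reference",
    "write_reference",
    "read_layout_csv",
    "write_layout_csv",
    "write_plate",
    "read_plate",
    "write_lifetime_image",
    "load_run_config",
    "save_run_config",
    "config_hash",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_gated_stack(stack: GatedStack, path) -> Path:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(stack.counts)
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed the uint16 range")
    tifffile.imwrite(path, counts.astype(np.uint16))
    sidecar = {
        "gate_delays_ps": [float(d) for d in stack.gate_delays_ps],
        "gate_width_ps": float(stack.gate_width_ps),
        **{k: v for k, v in stack.meta.items()},
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
    return path


def read_gated_stack(path) -> GatedStack:
    """Read a multi-page TIFF stack; the JSON sidecar is required."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing gate-schedule sidecar {sidecar_path} for stack {path}"
        )
    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None]
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    delays = np.asarray(meta.pop("gate_delays_ps"), dtype=float)
    width = float(meta.pop("gate_width_ps"))
    if counts.shape[0] != delays.size:
        raise ValueError(
            f"{path}: {counts.shape[0]} TIFF pages but {delays.size} gate delays"
        )
    return GatedStack(counts, delays, width, meta=meta)


def write_lifetime_image(tau_map: np.ndarray, path, sidecar: dict | None = None) -> Path:
    """Write a lifetime map (ps) as 32-bit float TIFF with optional sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(tau_map, dtype=np.float32))
    if sidecar is not None:
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, sort_keys=True, indent=1)
    return path


def write_reference(reference: ReferenceDecay, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "counts": [float(c) for c in reference.counts],
        "gate_delays_ps": [float(d) for d in reference.gate_delays_ps],
        "gate_width_ps": float(reference.gate_width_ps),
        "tau_ref_ps": float(reference.tau_ref_ps),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
    return path


def read_reference(path) -> ReferenceDecay:
    with open(path) as fh:
        payload = json.load(fh)
    return ReferenceDecay(
        np.asarray(payload["counts"], dtype=float),
        np.asarray(payload["gate_delays_ps"], dtype=float),
        float(payload["gate_width_ps"]),
        float(payload["tau_ref_ps"]),
    )


def write_layout_csv(layout: PlateLayout, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    layout.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_layout_csv(path, rows: int = 8, cols: int = 12) -> PlateLayout:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"well", "row", "col", "condition", "dose_uM", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
    return PlateLayout.from_frame(df, rows=rows, cols=cols)


def write_plate(dataset: PlateDataset, out_dir) -> Path:
    """Write a synthetic plate dataset: stacks, reference, manifest, layout."""
    out_dir = Path(out_dir)
    (out_dir / "stacks").mkdir(parents=True, exist_ok=True)
    for (well, fov), stack in dataset.stacks.items():
        write_gated_stack(stack, out_dir / "stacks" / f"{well}_fov{fov}.tif")
    write_reference(dataset.reference, out_dir / "reference.json")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(dataset.manifest, fh, sort_keys=True, indent=1)
    write_layout_csv(dataset.layout, out_dir / "layout.csv")
    return out_dir


def read_plate(out_dir) -> PlateDataset:
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    reference = read_reference(out_dir / "reference.json")
    layout = read_layout_csv(out_dir / "layout.csv")
    stacks = {}
    for tif in sorted((out_dir / "stacks").glob("*.tif")):
        stack = read_gated_stack(tif)
        stacks[(stack.meta["well"], int(stack.meta["fov"]))] = stack
    return PlateDataset(stacks, reference, manifest, layout)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dose_response: DoseResponseModel = field(default_factory=DoseResponseModel)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    fit_threshold: float = 200.0
    aggregate_method: str = "pixel_pooled"
    layout_csv: str | None = None
    log_level: str = "INFO"


def _dataclass_to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _dataclass_to_plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _dataclass_to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_dataclass_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _build_dataclass(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        default = f.default if f.default is not dataclasses.MISSING else None
        if isinstance(value, list):
            value = tuple(value) if isinstance(default, tuple) or default is None else value
        kwargs[f.name] = value
    return cls(**kwargs)


def run_config_to_dict(config: RunConfig) -> dict:
    return _dataclass_to_plain(config)


def run_config_from_dict(data: dict) -> RunConfig:
    return RunConfig(
        seed=int(data.get("seed", 0)),
        simulation=_build_dataclass(SimulationConfig, data.get("simulation", {})),
        dose_response=_build_dataclass(DoseResponseModel, data.get("dose_response", {})),
        segmentation=_build_dataclass(SegmentationParams, data.get("segmentation", {})),
        fit_threshold=float(data.get("fit_threshold", 200.0)),
        aggregate_method=str(data.get("aggregate_method", "pixel_pooled")),
        layout_csv=data.get("layout_csv"),
        log_level=str(data.get("log_level", "INFO")),
    )


def save_run_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(run_config_to_dict(config), fh, sort_keys=True)
    return path


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return run_config_from_dict(data or {})


def config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(run_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
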