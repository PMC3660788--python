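"""Simulate the standard 96-well Gag-aggregation dose-response plate.

Generates gated FLIM stacks for one plate — positive controls
(myristoylation-deficient Gag) in column 1, a nine-point NMT-inhibitor
dose series (10 to 0.001 uM, half-decade steps) in columns 2-10,
vehicle-only negative controls in column 11 — together with the
reference-dye measurement and a ground-truth manifest, and writes them
under scratch/plate/.
"""

from pathlib import Path

from flimplate.io import write_plate
from flimplate.plate import default_dose_response_layout
from flimplate.simulate import DoseResponseModel, SimulationConfig, generate_plate

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "plate"


def main() -> None:
    config = SimulationConfig()
    model = DoseResponseModel()
    layout = default_dose_response_layout()
    dataset = generate_plate(layout, config, model, seed=SEED)
    write_plate(dataset, OUT)
    n_wells = len(dataset.manifest["wells"])
    n_cells = sum(
        f["n_cells"] for w in dataset.manifest["wells"].values() for f in w["fovs"]
    )
    print(f"wrote {len(dataset.stacks)} gated stacks ({n_wells} wells, "
          f"{n_cells} cells total) to {OUT}")
    print(f"donor tau {config.tau_donor_ps} ps, FRET tau {config.tau_fret_ps} ps, "
          f"EC50 {model.ec50_uM} uM, membrane FRET fraction "
          f"{model.f_min}-{model.f_max}")


if __name__ == "__main__":
    main()
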