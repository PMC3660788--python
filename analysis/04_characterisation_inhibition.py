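"""Three-dose assay-characterisation plates and percent inhibition.

Builds three separately seeded plates dosed at low (~EC20), medium and
high (~EC80) inhibitor concentrations, with the medium dose placed at
75% of the ground-truth lifetime effect, analyses each with membrane-ROI
fitting, and reports the percent inhibition of the medium dose relative
to the low/high anchors per plate.  Writes results/inhibition.json.
"""

import json
from pathlib import Path

import numpy as np

from flimplate.pipeline import (
    analyse_plate,
    dose_for_fraction,
    fraction_for_lifetime_effect,
)
from flimplate.plate import percent_inhibition, three_dose_layout
from flimplate.segmentation import SegmentationParams
from flimplate.simulate import DoseResponseModel, SimulationConfig, generate_plate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEEDS = (31, 32, 33)


def main() -> None:
    config = SimulationConfig(rows=4, cols=6)
    model = DoseResponseModel()
    span = model.f_max - model.f_min
    f_low = model.f_max - 0.2 * span   # ~EC20
    f_high = model.f_max - 0.8 * span  # ~EC80
    f_med = fraction_for_lifetime_effect(0.75, f_low, f_high, config)
    doses = [dose_for_fraction(f, model) for f in (f_low, f_med, f_high)]
    print(f"doses (uM): low {doses[0]:.3f}, medium {doses[1]:.3f}, high {doses[2]:.3f}"
          f"  (medium at 75% of the lifetime effect)")

    per_plate = []
    for seed in SEEDS:
        layout = three_dose_layout(doses[0], doses[1], doses[2], rows=4, cols=6)
        dataset = generate_plate(layout, config, model, seed=seed)
        analysis = analyse_plate(dataset, SegmentationParams())
        groups: dict[str, list] = {}
        for w in layout.wells:
            res = analysis.well_results["membrane"].get(w.well_id)
            if res is not None and not res.no_cells_flag:
                groups.setdefault(w.condition, []).append(res.mean_tau)
        pct, _ = percent_inhibition(
            float(np.mean(groups["gag_medium"])),
            float(np.mean(groups["gag_low"])),
            float(np.mean(groups["gag_high"])),
        )
        per_plate.append(round(pct, 1))
        print(f"plate (seed {seed}): low {np.mean(groups['gag_low']):.0f} ps, "
              f"medium {np.mean(groups['gag_medium']):.0f} ps, "
              f"high {np.mean(groups['gag_high']):.0f} ps -> inhibition {pct:.0f}%")

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "inhibition.json", "w") as fh:
        json.dump(
            {"ground_truth_effect_pct": 75.0, "inhibition_pct_per_plate": per_plate,
             "doses_uM": [round(d, 4) for d in doses]},
            fh, indent=1,
        )
    print(f"inhibition across plates: {per_plate} % (ground truth 75%)")


if __name__ == "__main__":
    main()
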