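#!/usr/bin/env python
"""Foot-process width morphometry: control vs effacement.

Simulates junction positions whose gaps follow lognormal width distributions
(control mean 0.25 µm vs effaced 0.60 µm, CV 0.3), compares one 20-site
draw per group with a t test, and estimates the detection power of the
20-sites-per-group design over 100 replicates. Tables land in results/.
"""

from pathlib import Path

import pandas as pd

from podoquant.experiments import morphometry_power
from podoquant.morphometry import compare_widths, sample_sites, widths_from_junctions
from podoquant.pipeline import comparison_text
from podoquant.scenes import generate_morphometry_dataset


def main():
    Path("results").mkdir(exist_ok=True)
    groups = {}
    rows = []
    for seed, (grp, mean) in enumerate((("control", 0.25), ("effaced", 0.60))):
        gt = generate_morphometry_dataset(60, ("lognormal", {"mean": mean, "cv": 0.3}),
                                          seed=100 + seed)
        widths = widths_from_junctions(gt.junction_positions, group_label=grp)
        sites = sample_sites(widths, 20, seed=5)
        groups[grp] = sites
        rows += [{"group": grp, "site_id": w.site_id, "width_um": w.width} for w in sites]
    pd.DataFrame(rows).to_csv("results/foot_process_widths.csv", index=False)
    comp = compare_widths(groups["control"], groups["effaced"],
                          group_labels=("control", "effaced"))
    print(comparison_text(comp).strip())

    power = morphometry_power(0.25, 0.60, cv=0.3, sites_per_group=20,
                              n_replicates=100, seed=5)
    pd.DataFrame([power]).to_csv("results/morphometry_power.csv", index=False)
    print(f"power at α=0.05, 20 sites/group, 100 replicates: {100 * power['power']:.0f}%")


if __name__ == "__main__":
    main()
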