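#!/usr/bin/env python
"""Parameter recovery of the positional ratio across depth fractions.

For each true depth fraction f in 0.1 … 0.9, one loop scene is measured with
30 perpendicular lines, noiseless and at SNR 10 (amplitude 1000, Gaussian
sd 100). The table of group-mean ratios and absolute errors lands in
results/ratio_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from podoquant.experiments import ratio_recovery_sweep

FRACTIONS = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))


def main():
    rows = []
    for label, sd, seed in (("noiseless", 0.0, 1), ("snr10", 100.0, 2)):
        sweep = ratio_recovery_sweep(FRACTIONS, noise_sd=sd, lines_per_scene=30, seed=seed)
        for f, v in sweep.items():
            rows.append({"condition": label, "true_f": f, **v})
    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/ratio_recovery.csv", index=False)
    for label in ("noiseless", "snr10"):
        sub = df[df["condition"] == label]
        print(f"{label}: max |mean ratio − f| = {sub['abs_error'].max():.4f} "
              f"over f ∈ [0.1, 0.9] ({int(sub['n_accepted'].sum())} accepted lines)")


if __name__ == "__main__":
    main()
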