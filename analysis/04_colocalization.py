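#!/usr/bin/env python
"""Boundary colocalization versus junctional fraction.

Renders cell scenes with the target's junctional share q swept over
0 … 1 at a fixed geometry/noise seed and computes the boundary-band Pearson
R against the purely junctional partner channel. Writes
results/coloc_q_sweep.csv and reports whether R rises monotonically with q
(the signature of junctional recruitment).
"""

from pathlib import Path

import pandas as pd

from podoquant.experiments import coloc_q_sweep

Q_VALUES = (0.0, 0.25, 0.5, 0.75, 1.0)


def main():
    sweep = coloc_q_sweep(Q_VALUES, noise_sd=50.0, seed=7)
    df = pd.DataFrame({"junction_fraction": list(sweep), "pearson_r": list(sweep.values())})
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/coloc_q_sweep.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    rs = list(sweep.values())
    mono = all(a < b for a, b in zip(rs, rs[1:]))
    print(f"boundary-band R strictly increasing in q: {mono}")


if __name__ == "__main__":
    main()
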