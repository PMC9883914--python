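#!/usr/bin/env python
"""Nucleotype-ratio drift across spore bottlenecks, with and without mixing.

Each spore samples a few hundred nuclei from its parent culture, so the
nucleotype ratio performs a Wright-Fisher-like random walk across
generations: variance grows, lineages diverge and eventually fix one
nucleotype.  Nuclear mixing (hyphal fusion) counteracts the drift.  This
driver tabulates the across-lineage ratio variance per generation and the
long-run fixation fraction at several bottleneck sizes and mixing rates.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from heterokaryon import spore_bottleneck

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 77


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for n_spore in (60, 200, 1000):
        for mixing in (0.0, 0.1, 0.5):
            traj = spore_bottleneck(
                ratio_r=2 / 3, n_nuclei_per_spore=n_spore, n_generations=100,
                n_lineages=2000, mixing_rate=mixing, seed=SEED,
            )
            var = traj.var(axis=0)
            fixed = float(np.mean((traj[:, -1] == 0) | (traj[:, -1] == 1)))
            rows.append(
                (n_spore, mixing, round(float(var[1]), 6), round(float(var[-1]), 6),
                 round(fixed, 4))
            )
    frame = pd.DataFrame(
        rows,
        columns=["n_nuclei_per_spore", "mixing_rate", "variance_gen1",
                 "variance_gen100", "fixed_fraction_gen100"],
    )
    frame.to_csv(RESULTS / "04_drift_summary.csv", index=False)
    print(frame.to_string(index=False))
    print(
        "\nWithout mixing the ratio variance keeps growing and small bottlenecks"
        " begin fixing a single nucleotype within 100 generations; even 10%"
        " mixing holds the variance near its single-generation level."
    )


if __name__ == "__main__":
    main()
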