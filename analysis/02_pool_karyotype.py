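#!/usr/bin/env python
"""Pooled-DNA karyotype analysis: SNP filter, AF spectrum, ratio MLE, PCA.

Reads the simulated dataset (regenerating it if 01 has not been run),
applies the pooled-sample filter (coverage 85-135, both alleles >= 10,
repeats excluded), detects the spectrum modes, estimates the nucleotype
ratio by mixture MLE, mirrors the MAT-locus coverage estimate, and runs a
PCA over additional pooled samples simulated at 1:1 and 2:1 ratios.
"""

import runpy
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from heterokaryon import (
    NucleotypeModel,
    PoolFilterParams,
    af_spectrum,
    detect_modes,
    estimate_ratio_mle,
    filter_pool_snps,
    make_genome,
    make_nucleus_population,
    mat_coverage_ratio,
    pca_shared_snps,
    read_repeat_bed,
    read_vcf,
    simulate_pool_counts,
    snp_density,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def main() -> None:
    if not (DATA / "pool.vcf").exists():
        runpy.run_path(str(ROOT / "analysis" / "01_simulate_data.py"), run_name="__main__")
    RESULTS.mkdir(exist_ok=True)

    table = read_vcf(str(DATA / "pool.vcf"))
    repeats = read_repeat_bed(str(DATA / "repeats.bed"))
    filtered = filter_pool_snps(table, "pool", PoolFilterParams(), repeats)
    spectrum = af_spectrum(filtered, "pool")
    modes = detect_modes(spectrum)
    est = estimate_ratio_mle(filtered, "pool")

    # MAT-locus coverage mirror: per-base depths proportional to nucleotype counts
    rng = np.random.default_rng(17)
    d1 = rng.poisson(110 * est.ratio_r, 2000).mean()
    d2 = rng.poisson(110 * (1 - est.ratio_r), 2000).mean()
    p1, p2 = mat_coverage_ratio(d1, d2)

    rows = [
        ("n_sites_raw", table.n_sites),
        ("n_sites_filtered", filtered.n_sites),
        ("snp_per_kb_raw", round(snp_density(table.n_sites, 4_000_000), 3)),
        ("modes_percent", ";".join(f"{m:.1f}" for m in modes)),
        ("mle_ratio_r", round(est.ratio_r, 4)),
        ("karyotype", est.karyotype),
        ("mat_coverage_mat1", round(p1, 4)),
        ("mat_coverage_mat2", round(p2, 4)),
    ]
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        RESULTS / "02_pool_karyotype.csv", index=False
    )

    # PCA across pooled samples of two ratio groups sharing one genome
    genome = make_genome(10, 100_000, 1.0, seed=900)
    tables = {}
    for name, ratio, seed in [
        ("balanced_a", 0.5, 901), ("balanced_b", 0.5, 903),
        ("skewed_a", 2 / 3, 905), ("skewed_b", 2 / 3, 907),
    ]:
        model = NucleotypeModel(ratio_r=ratio, error_rate=0.0, mean_depth=100.0)
        pop = make_nucleus_population(genome, model, 30, seed=seed)
        tables[name] = simulate_pool_counts(pop, model, seed=seed + 1, sample_name=name)
    pca = pca_shared_snps(tables)
    pca.coordinates.assign(explained_pc1=pca.explained_variance[0]).to_csv(
        RESULTS / "02_pool_pca.tsv", sep="\t"
    )

    print(pd.DataFrame(rows, columns=["quantity", "value"]).to_string(index=False))
    print("\nPCA coordinates:")
    print(pca.coordinates.round(2).to_string())


if __name__ == "__main__":
    main()
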