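#!/usr/bin/env python
"""Generate the synthetic study dataset all downstream analyses consume.

A scaled-down dikaryon-like isolate: 40 contigs of 100 kb (4 Mb total) at
0.78 SNPs/kb with ~46% repeat content, 30 nuclei at a 2:1 nucleotype ratio,
three implanted 6-SNP recombination tracts, pooled DNA at mean depth 110,
ten single nuclei with mild dropout/contamination, and RNA for four hosts
(two with nucleotype-equalizing expression weights, two with neutral ones).

Raw VCF/BED/TSV/FASTA files go to scratch/simdata/ (bulky, regenerable);
a small summary table goes to results/.
"""

from pathlib import Path

import pandas as pd

from heterokaryon import (
    NucleotypeModel,
    make_genome,
    make_nucleus_population,
    simulate_nucleus_counts,
    simulate_pool_counts,
    simulate_rna_counts,
    write_mat_labels,
    write_repeat_bed,
    write_vcf,
)
from heterokaryon.synthdata import write_ground_truth, write_rdna_fasta

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "scratch" / "simdata"
RESULTS = Path(__file__).resolve().parents[1] / "results"

HOST_WEIGHTS = {
    "Medicago": (1.0, 2.0),
    "Chives": (1.0, 2.0),
    "Nicotiana": (1.0, 1.0),
    "Tomato": (1.0, 1.0),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    genome = make_genome(
        n_contigs=40, contig_length=100_000, snp_per_kb=0.78,
        repeat_fraction=0.4619, low_freq_site_fraction=0.1, seed=SEED,
    )
    model = NucleotypeModel(ratio_r=2 / 3, error_rate=0.002, mean_depth=110.0,
                            depth_dispersion=0.05)
    # tracts span 12 SNPs in full site-index space: with ~46% of sites inside
    # repeats (and thus masked from the nucleus analysis), a tract still leaves
    # a run of >= 5 consecutive analyzable SNPs most of the time
    population = make_nucleus_population(
        genome, model, n_nuclei=30, n_recomb_tracts=3, tract_len_snps=12, seed=SEED + 1
    )
    lengths = genome.contig_lengths()

    pool = simulate_pool_counts(population, model, seed=SEED + 2)
    write_vcf(pool, str(OUT / "pool.vcf"), lengths)
    nuclei = simulate_nucleus_counts(
        population, model, contamination_rate=0.01, dropout_rate=0.05, seed=SEED + 3
    )
    write_vcf(nuclei, str(OUT / "nuclei.vcf"), lengths)
    rna = simulate_rna_counts(population, model, HOST_WEIGHTS, seed=SEED + 4)
    for host, reps in rna.items():
        for j, t in enumerate(reps, start=1):
            write_vcf(t, str(OUT / f"rna_{host}_rep{j}.vcf"), lengths)

    write_repeat_bed(genome.repeat_intervals, str(OUT / "repeats.bed"))
    write_mat_labels(population.mat_labels(), str(OUT / "mat_labels.tsv"))
    write_rdna_fasta(genome, str(OUT / "rdna.fasta"))
    write_ground_truth(str(OUT / "truth.json"), population, model, HOST_WEIGHTS)

    summary = pd.DataFrame(
        [
            ("total_length_bp", genome.total_length),
            ("n_contigs", len(genome.contigs)),
            ("n_snp_sites", genome.n_sites),
            ("repeat_length_bp", genome.repeat_intervals.total_length()),
            ("n_nuclei", population.n_nuclei),
            ("n_mat1_nuclei", sum(m == "MAT-1" for m in population.mats)),
            ("n_recomb_tracts", len(population.recombined_tracts)),
            ("n_hosts", len(HOST_WEIGHTS)),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "01_dataset_summary.csv", index=False)
    print(f"wrote dataset to {OUT}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
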