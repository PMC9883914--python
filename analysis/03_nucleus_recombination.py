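#!/usr/bin/env python
"""Single-nucleus concordance: discordant SNPs, recombination blocks, similarity.

Runs the full pipeline (intersect with the filtered pooled SNP set,
heterozygosity + 500 bp proximity + depth filters, MAT-grouped discordance,
>=5-consecutive-SNP block calling) on the simulated single-nucleus data and
compares the called blocks against the implanted ground-truth tracts.
"""

import json
import runpy
from pathlib import Path

import pandas as pd

from heterokaryon import (
    analyze_nuclei,
    discordance_percentage,
    read_mat_labels,
    read_repeat_bed,
    read_vcf,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def main() -> None:
    if not (DATA / "nuclei.vcf").exists():
        runpy.run_path(str(ROOT / "analysis" / "01_simulate_data.py"), run_name="__main__")
    RESULTS.mkdir(exist_ok=True)

    pool = read_vcf(str(DATA / "pool.vcf"))
    nuclei = read_vcf(str(DATA / "nuclei.vcf"))
    labels = read_mat_labels(str(DATA / "mat_labels.tsv"))
    repeats = read_repeat_bed(str(DATA / "repeats.bed"))
    truth = json.loads((DATA / "truth.json").read_text())

    res = analyze_nuclei(pool, nuclei, labels, repeats=repeats)
    d = res.discordance
    pct = discordance_percentage(d.n_discordant, d.n_total)

    block_rows = []
    for b in res.blocks:
        contig_pos = res.sites.loc[res.sites["contig"] == b.contig, "pos"].to_numpy()
        block_rows.append(
            (b.contig, int(contig_pos[b.first_site_index]),
             int(contig_pos[b.last_site_index]), b.n_snps, ",".join(sorted(b.nuclei)))
        )
    blocks_frame = pd.DataFrame(
        block_rows, columns=["contig", "first_pos", "last_pos", "n_snps", "nuclei"]
    )
    blocks_frame.to_csv(RESULTS / "03_recombination_blocks.tsv", sep="\t", index=False)
    res.similarity.round(4).to_csv(RESULTS / "03_nucleus_similarity.tsv", sep="\t")

    summary = pd.DataFrame(
        [
            ("n_snps_analyzed", d.n_total),
            ("n_discordant", d.n_discordant),
            ("discordance_percent", round(pct, 2)),
            ("n_blocks_called", len(res.blocks)),
            ("n_tracts_implanted", len(truth["recombined_tracts"])),
            ("n_sites_het_excluded", res.n_het_excluded_sites),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "03_discordance_summary.csv", index=False)
    print(summary.to_string(index=False))
    print("\ncalled blocks:")
    print(blocks_frame.to_string(index=False))
    print("\nimplanted tracts (bp coordinates; indices are pre-filter):")
    print(pd.DataFrame(truth["recombined_tracts"]).to_string(index=False))
    print(
        "\nDiscordant SNPs decompose into the implanted tracts plus the"
        " low-frequency nucleotype-internal variants, which are discordant"
        " within one MAT group by construction. Called block spans should"
        " match the implanted tracts' bp ranges after repeat masking."
    )


if __name__ == "__main__":
    main()
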