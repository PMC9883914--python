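import numpy as np
import pandas as pd
import pytest

from heterokaryon import NucleotypeModel, VariantTable, make_genome, make_nucleus_population


def table_from_rows(rows, sample="S"):
    """Build a single-sample VariantTable from (contig, pos, ref, alt, dp, ro, ao) rows."""
    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in rows],
        columns=["contig", "pos", "ref", "alt"],
    )
    dp = np.array([r[4] for r in rows])
    ro = np.array([r[5] for r in rows])
    ao = np.array([r[6] for r in rows])
    return VariantTable.from_counts(sites, {sample: (dp, ro, ao)})


@pytest.fixture
def toy_table():
    """Six pooled-count sites exercising every pool-filter predicate."""
    rows = [
        ("c1", 100, "A", "T", 80, 40, 40),
        ("c1", 200, "A", "T", 90, 81, 9),
        ("c1", 300, "A", "T", 100, 50, 50),
        ("c1", 400, "A", "T", 140, 70, 70),
        ("c2", 100, "A", "T", 100, 91, 9),
        ("c2", 200, "A", "T", 100, 89, 11),
    ]
    return table_from_rows(rows)


@pytest.fixture
def balanced_population():
    """Balanced dikaryon: 10 nuclei, ~200 clean sites, no tracts or repeats."""
    genome = make_genome(4, 50_000, 1.0, repeat_fraction=0.0, low_freq_site_fraction=0.0, seed=42)
    model = NucleotypeModel(ratio_r=0.5, error_rate=0.0, mean_depth=50.0)
    population = make_nucleus_population(genome, model, n_nuclei=10, seed=43)
    return genome, model, population
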