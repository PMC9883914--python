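"""Genotype calling, het/proximity filters, discordance, blocks, similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heterokaryon import (
    HetFilterParams,
    NucleotypeModel,
    analyze_nuclei,
    call_nucleus,
    discordance_percentage,
    exclude_heterozygous_neighborhoods,
    find_discordant_snps,
    find_recombination_blocks,
    make_genome,
    make_nucleus_population,
    similarity_matrix,
    simulate_nucleus_counts,
    simulate_pool_counts,
)
from heterokaryon.nucleus_genotypes import ALT, MISSING, REF, NucleusCallSet

from conftest import table_from_rows
from _oracles import brute_blocks, brute_discordant_flags


def _callsets(calls_matrix, mats, contigs=None):
    calls_matrix = np.asarray(calls_matrix)
    n_sites = calls_matrix.shape[1]
    contigs = contigs or ["c1"] * n_sites
    sites = pd.DataFrame(
        {
            "contig": contigs,
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": "A",
            "alt": "T",
        }
    )
    return [
        NucleusCallSet(f"N{i}", mat, calls_matrix[i], sites)
        for i, mat in enumerate(mats)
    ], sites


class TestCallNucleus:
    @pytest.mark.parametrize(
        "dp,ro,ao,expected_call,expected_het",
        [
            (20, 18, 2, REF, False),   # AO/DP = 0.1 is not > 0.1
            (20, 12, 8, MISSING, True),  # both fractions above threshold
            (9, 9, 0, MISSING, False),   # below min_depth
            (20, 2, 18, ALT, False),
        ],
    )
    def test_het_rule_and_majority_call(self, dp, ro, ao, expected_call, expected_het):
        t = table_from_rows([("c1", 1, "A", "T", dp, ro, ao)], "N")
        cs, het = call_nucleus(t, "N", HetFilterParams())
        assert cs.calls[0] == expected_call
        assert (len(het) == 1) == expected_het


class TestProximityExclusion:
    def test_distance_arithmetic_inclusive_at_threshold(self):
        sites = pd.DataFrame(
            {"contig": ["c1"] * 3, "pos": [600, 1400, 1501], "ref": "A", "alt": "T"}
        )
        keep = exclude_heterozygous_neighborhoods(sites, [("c1", 1000)], 500)
        assert keep.tolist() == [False, False, True]

    def test_het_sites_scoped_per_contig(self):
        sites = pd.DataFrame(
            {"contig": ["cB"] * 2, "pos": [1000, 1100], "ref": "A", "alt": "T"}
        )
        keep = exclude_heterozygous_neighborhoods(sites, [("cA", 1000)], 500)
        assert keep.all()

    def test_no_het_sites_retains_everything(self):
        sites = pd.DataFrame({"contig": ["c1"], "pos": [5], "ref": "A", "alt": "T"})
        assert exclude_heterozygous_neighborhoods(sites, [], 500).all()


class TestDiscordance:
    def test_both_alleles_within_a_mat_group(self):
        cs, _ = _callsets([[REF], [ALT], [ALT], [ALT]], ["MAT-1", "MAT-1", "MAT-2", "MAT-2"])
        assert find_discordant_snps(cs).flags.tolist() == [True]

    def test_canonical_dikaryon_pattern_concordant(self):
        cs, _ = _callsets([[REF], [REF], [ALT], [ALT]], ["MAT-1", "MAT-1", "MAT-2", "MAT-2"])
        assert find_discordant_snps(cs).n_discordant == 0

    def test_missing_calls_excluded_from_group_test(self):
        cs, _ = _callsets([[REF], [MISSING], [ALT], [ALT]], ["MAT-1", "MAT-1", "MAT-2", "MAT-2"])
        assert find_discordant_snps(cs).n_discordant == 0

    @pytest.mark.parametrize("n_disc,n_total,expected", [(503, 9947, 5), (0, 10, 0), (7, 7, 100)])
    def test_percentage(self, n_disc, n_total, expected):
        assert round(discordance_percentage(n_disc, n_total)) == expected


class TestBlocks:
    def _blocks(self, flags, contigs=None, **kw):
        n = len(flags)
        sites = pd.DataFrame(
            {
                "contig": contigs or ["c1"] * n,
                "pos": np.arange(1, n + 1) * 100,
                "ref": "A",
                "alt": "T",
            }
        )
        return find_recombination_blocks(sites, np.array(flags, bool), **kw)

    def test_run_of_five_is_one_block(self):
        blocks = self._blocks([0, 1, 1, 1, 1, 1, 0])
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.first_site_index, b.last_site_index, b.n_snps) == (1, 5, 5)

    def test_interrupted_runs_below_threshold_give_no_block(self):
        assert self._blocks([1, 1, 1, 1, 0, 1, 1, 1, 1]) == []

    def test_single_snp_contig_skipped(self):
        assert self._blocks([1], min_run=1) == []

    def test_blocks_never_span_contigs(self):
        contigs = ["c1"] * 5 + ["c2"] * 5
        blocks = self._blocks([1] * 10, contigs=contigs)
        assert len(blocks) == 2
        assert {b.contig for b in blocks} == {"c1", "c2"}

    def test_increasing_min_run_never_adds_blocks(self):
        rng = np.random.default_rng(5)
        flags = (rng.random(200) < 0.4).tolist()
        counts = [len(self._blocks(flags, min_run=k)) for k in range(1, 9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_nuclei=st.integers(2, 8),
        n_sites=st.integers(1, 50),
        min_run=st.integers(1, 6),
    )
    def test_flags_and_blocks_match_bruteforce(self, seed, n_nuclei, n_sites, min_run):
        rng = np.random.default_rng(seed)
        calls = rng.choice([REF, ALT, MISSING], size=(n_nuclei, n_sites))
        mats = ["MAT-1"] * 2 + [
            "MAT-1" if rng.random() < 0.5 else "MAT-2" for _ in range(n_nuclei - 2)
        ]
        contigs = [f"c{rng.integers(1, 4)}" for _ in range(n_sites)]
        contigs.sort()
        cs, sites = _callsets(calls, mats, contigs)
        res = find_discordant_snps(cs)
        assert res.flags.tolist() == brute_discordant_flags(calls.tolist(), mats)
        got = sorted(
            (b.contig, b.first_site_index, b.last_site_index)
            for b in find_recombination_blocks(sites, res.flags, min_run=min_run)
        )
        assert got == brute_blocks(contigs, res.flags.tolist(), min_run=min_run)


class TestSimilarity:
    def test_identical_callsets_score_one(self):
        cs, _ = _callsets([[REF, ALT, REF], [REF, ALT, REF]], ["MAT-1", "MAT-1"])
        assert similarity_matrix(cs).iloc[0, 1] == 1.0

    def test_one_mismatch_of_four(self):
        cs, _ = _callsets(
            [[REF, ALT, REF, REF], [REF, ALT, REF, ALT]], ["MAT-1", "MAT-1"]
        )
        assert similarity_matrix(cs).iloc[0, 1] == pytest.approx(0.75)

    def test_no_cocalled_sites_gives_nan(self):
        cs, _ = _callsets([[REF, MISSING], [MISSING, ALT]], ["MAT-1", "MAT-1"])
        assert np.isnan(similarity_matrix(cs).iloc[0, 1])

    def test_within_mat_similarity_exceeds_between(self, balanced_population):
        genome, model, pop = balanced_population
        nuc = simulate_nucleus_counts(pop, model, seed=70)
        pool = simulate_pool_counts(pop, model, seed=71)
        res = analyze_nuclei(pool, nuc, pop.mat_labels())
        sim = res.similarity.to_numpy()
        mats = np.array(pop.mats)
        same = np.equal.outer(mats, mats) & ~np.eye(len(mats), dtype=bool)
        diff = ~np.equal.outer(mats, mats)
        assert np.nanmean(sim[same]) > np.nanmean(sim[diff])


class TestPipeline:
    def test_clean_data_without_tracts_yields_zero_discordance(self, balanced_population):
        genome, model, pop = balanced_population
        nuc = simulate_nucleus_counts(pop, model, seed=80)
        pool = simulate_pool_counts(pop, model, seed=81)
        res = analyze_nuclei(pool, nuc, pop.mat_labels())
        assert res.discordance.n_discordant == 0
        assert res.blocks == []

    def test_implanted_tracts_recovered_with_exact_boundaries(self):
        genome = make_genome(5, 60_000, 1.0, seed=90)
        model = NucleotypeModel(ratio_r=0.5, error_rate=0.0, mean_depth=40.0)
        pop = make_nucleus_population(
            genome, model, 8, n_recomb_tracts=2, tract_len_snps=6, seed=91
        )
        nuc = simulate_nucleus_counts(pop, model, seed=92)
        pool = simulate_pool_counts(pop, model, seed=93)
        res = analyze_nuclei(pool, nuc, pop.mat_labels())
        got = sorted((b.contig, b.first_site_index, b.last_site_index) for b in res.blocks)
        want = sorted(
            (t.contig, t.first_site_index, t.last_site_index)
            for t in pop.recombined_tracts
        )
        assert got == want
        for b in res.blocks:
            truth = {
                t.nucleus_id
                for t in pop.recombined_tracts
                if (t.contig, t.first_site_index) == (b.contig, b.first_site_index)
            }
            assert set(b.nuclei) == truth

    def test_short_tracts_are_not_called(self):
        genome = make_genome(5, 60_000, 1.0, seed=94)
        model = NucleotypeModel(ratio_r=0.5, error_rate=0.0, mean_depth=40.0)
        pop = make_nucleus_population(
            genome, model, 8, n_recomb_tracts=2, tract_len_snps=4, seed=95
        )
        nuc = simulate_nucleus_counts(pop, model, seed=96)
        pool = simulate_pool_counts(pop, model, seed=97)
        res = analyze_nuclei(pool, nuc, pop.mat_labels(), min_run=5)
        assert res.blocks == []
        assert res.discordance.n_discordant == 8  # tract sites stay discordant
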