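"""The synthetic dikaryon generator: structure, determinism, count laws."""

import numpy as np
import pytest

from heterokaryon import (
    NucleotypeModel,
    make_genome,
    make_nucleus_population,
    simulate_nucleus_counts,
    simulate_pool_counts,
    simulate_rna_counts,
    spore_bottleneck,
)
from heterokaryon.synthdata import MAT1, MAT2, mat_consensus


class TestMakeGenome:
    def test_snp_count_matches_poisson_expectation(self):
        g = make_genome(10, 100_000, 1.0, repeat_fraction=0.0, seed=1)
        assert abs(g.n_sites - 1000) < 3 * np.sqrt(1000)
        assert all(s.alt_carrier in (MAT1, MAT2) for s in g.sites)

    def test_no_repeats_means_no_repeat_flags(self):
        g = make_genome(5, 20_000, 1.0, repeat_fraction=0.0, seed=2)
        assert not any(s.in_repeat for s in g.sites)

    def test_same_seed_reproduces_genome(self):
        a = make_genome(5, 20_000, 1.0, repeat_fraction=0.3, low_freq_site_fraction=0.1, seed=9)
        b = make_genome(5, 20_000, 1.0, repeat_fraction=0.3, low_freq_site_fraction=0.1, seed=9)
        assert a.sites == b.sites
        assert a.rdna_copies == b.rdna_copies

    def test_repeat_coverage_near_requested_fraction(self):
        g = make_genome(20, 100_000, 0.5, repeat_fraction=0.4, seed=4)
        frac = g.repeat_intervals.total_length() / g.total_length
        assert abs(frac - 0.4) < 0.05

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_genome(0, 1000, 1.0)
        with pytest.raises(ValueError):
            make_genome(1, 1000, -1.0)
        with pytest.raises(ValueError):
            make_genome(1, 1000, 1.0, repeat_fraction=1.5)


class TestMakePopulation:
    def test_mat_split_and_consensus(self):
        g = make_genome(4, 25_000, 1.0, seed=5)
        model = NucleotypeModel(ratio_r=0.6)
        pop = make_nucleus_population(g, model, n_nuclei=10, seed=6)
        assert sum(m == MAT1 for m in pop.mats) == 6
        cons = {MAT1: mat_consensus(g, MAT1), MAT2: mat_consensus(g, MAT2)}
        for i, mat in enumerate(pop.mats):
            assert np.array_equal(pop.alleles[i], cons[mat])

    def test_tract_ground_truth_recorded(self):
        g = make_genome(4, 25_000, 1.0, seed=5)
        pop = make_nucleus_population(
            g, NucleotypeModel(ratio_r=0.5), 10, n_recomb_tracts=3, tract_len_snps=6, seed=7
        )
        assert len(pop.recombined_tracts) == 3
        for t in pop.recombined_tracts:
            assert t.last_site_index - t.first_site_index + 1 == 6

    def test_tract_swaps_to_opposite_consensus(self):
        g = make_genome(2, 25_000, 1.0, seed=5)
        pop = make_nucleus_population(
            g, NucleotypeModel(ratio_r=0.5), 6, n_recomb_tracts=1, tract_len_snps=5, seed=8
        )
        (tract,) = pop.recombined_tracts
        i = pop.nucleus_ids.index(tract.nucleus_id)
        other = MAT2 if pop.mats[i] == MAT1 else MAT1
        frame = g.site_frame()
        rows = frame[frame["contig"] == tract.contig].index.to_numpy()
        sel = rows[tract.first_site_index : tract.last_site_index + 1]
        assert np.array_equal(pop.alleles[i, sel], mat_consensus(g, other)[sel])

    def test_ratio_one_gives_all_mat1(self):
        g = make_genome(2, 10_000, 1.0, seed=5)
        pop = make_nucleus_population(g, NucleotypeModel(ratio_r=1.0), 8, seed=9)
        assert all(m == MAT1 for m in pop.mats)

    def test_oversized_tract_rejected(self):
        g = make_genome(2, 2_000, 1.0, seed=5)
        with pytest.raises(ValueError):
            make_nucleus_population(
                g, NucleotypeModel(ratio_r=0.5), 4,
                n_recomb_tracts=1, tract_len_snps=10_000, seed=1,
            )

    def test_low_frequency_sites_hit_expected_pool_frequency(self):
        # fraction 0.2 of one MAT's nuclei at ratio 0.5 -> pooled alt share 0.1
        shares = []
        for seed in range(50):
            g = make_genome(
                2, 20_000, 1.0, low_freq_site_fraction=0.999,
                low_freq_range=(0.2, 0.2000001), seed=seed,
            )
            pop = make_nucleus_population(g, NucleotypeModel(ratio_r=0.5), 10, seed=seed)
            lf = [i for i, s in enumerate(g.sites) if s.alt_carrier == "low_frequency"]
            shares.extend(pop.alt_nucleus_counts()[lf] / pop.n_nuclei)
        assert np.mean(shares) == pytest.approx(0.1, abs=0.005)


class TestPoolCounts:
    def test_balanced_ratio_centres_at_half(self):
        g = make_genome(10, 200_000, 1.0, seed=20)  # ~2000 sites
        model = NucleotypeModel(ratio_r=0.5, error_rate=0.0, mean_depth=100.0)
        pop = make_nucleus_population(g, model, 10, seed=21)
        t = simulate_pool_counts(pop, model, seed=22)
        f = t.alt_frequencies("pool")
        assert np.nanmean(f) == pytest.approx(0.5, abs=0.01)

    def test_counts_conserve_depth_without_error(self):
        g = make_genome(2, 20_000, 1.0, seed=23)
        model = NucleotypeModel(ratio_r=0.5, error_rate=0.0)
        pop = make_nucleus_population(g, model, 10, seed=24)
        t = simulate_pool_counts(pop, model, seed=25)
        assert np.array_equal(t.ro[:, 0] + t.ao[:, 0], t.dp[:, 0])

    def test_error_reads_leave_count_deficit(self):
        g = make_genome(2, 50_000, 1.0, seed=23)
        model = NucleotypeModel(ratio_r=0.5, error_rate=0.05, mean_depth=100.0)
        pop = make_nucleus_population(g, model, 10, seed=24)
        t = simulate_pool_counts(pop, model, seed=25)
        assert np.all(t.ro[:, 0] + t.ao[:, 0] <= t.dp[:, 0])
        assert np.any(t.ro[:, 0] + t.ao[:, 0] < t.dp[:, 0])

    def test_mat2_site_frequency_is_one_minus_ratio(self):
        g = make_genome(10, 100_000, 1.0, seed=26, alt_mat1_prob=0.0)  # all alt on MAT-2
        model = NucleotypeModel(ratio_r=0.7, error_rate=0.0, mean_depth=100.0)
        pop = make_nucleus_population(g, model, 10, seed=27)
        t = simulate_pool_counts(pop, model, seed=28)
        assert np.nanmean(t.alt_frequencies("pool")) == pytest.approx(0.3, abs=0.01)

    def test_same_seed_reproduces_counts(self):
        g = make_genome(2, 20_000, 1.0, seed=29)
        model = NucleotypeModel(ratio_r=0.5)
        pop = make_nucleus_population(g, model, 10, seed=30)
        a = simulate_pool_counts(pop, model, seed=31)
        b = simulate_pool_counts(pop, model, seed=31)
        assert np.array_equal(a.dp, b.dp) and np.array_equal(a.ao, b.ao)


class TestNucleusCounts:
    def test_clean_nuclei_are_homozygous(self, balanced_population):
        genome, model, pop = balanced_population
        t = simulate_nucleus_counts(pop, model, seed=40)
        for j, nucleus in enumerate(t.samples):
            covered = ~t.missing[:, j]
            assert np.all((t.ro[covered, j] == 0) | (t.ao[covered, j] == 0))

    def test_heterozygous_rate_increases_with_contamination(self, balanced_population):
        genome, model, pop = balanced_population
        rates = []
        for c in (0.0, 0.15, 0.3):
            t = simulate_nucleus_counts(pop, model, contamination_rate=c, seed=41)
            het = 0
            total = 0
            for j in range(t.n_samples):
                covered = ~t.missing[:, j] & (t.dp[:, j] > 0)
                minor = np.minimum(t.ro[covered, j], t.ao[covered, j])
                het += int((minor / t.dp[covered, j] >= 0.1).sum())
                total += int(covered.sum())
            rates.append(het / total)
        assert rates[0] < rates[1] < rates[2]

    def test_full_dropout_blanks_every_site(self, balanced_population):
        genome, model, pop = balanced_population
        t = simulate_nucleus_counts(pop, model, dropout_rate=1.0, seed=42)
        assert np.all(t.dp == 0) and np.all(t.missing)


class TestRnaCounts:
    def _pop(self, ratio=2 / 3):
        g = make_genome(10, 100_000, 1.0, seed=50)
        model = NucleotypeModel(ratio_r=ratio, error_rate=0.0, mean_depth=110.0)
        pop = make_nucleus_population(g, model, 30, seed=51)
        return model, pop

    def test_silenced_nucleotype_gives_monoallelic_sites(self):
        model, pop = self._pop()
        (tables,) = simulate_rna_counts(pop, model, {"H": (1.0, 0.0)}, seed=52).values()
        t = tables[0]
        assert np.all((t.ro[:, 0] == 0) | (t.ao[:, 0] == 0))

    def test_equalizing_weights_centre_the_spectrum(self):
        from heterokaryon import af_spectrum, detect_modes

        model, pop = self._pop(ratio=2 / 3)
        out = simulate_rna_counts(pop, model, {"H": (1.0, 2.0)}, seed=53)
        t = out["H"][0]
        modes = detect_modes(af_spectrum(t, t.samples[0]))
        assert len(modes) == 1 and abs(modes[0] - 50) <= 2

    def test_expressed_subset_shared_across_replicates(self):
        model, pop = self._pop()
        out = simulate_rna_counts(pop, model, {"H": (1.0, 1.0)}, n_replicates=3, seed=54)
        first = out["H"][0].sites
        for t in out["H"][1:]:
            assert t.sites.equals(first)

    def test_zero_weights_rejected(self):
        model, pop = self._pop()
        with pytest.raises(ValueError):
            simulate_rna_counts(pop, model, {"H": (0.0, 0.0)}, seed=55)


class TestSporeBottleneck:
    def test_fixed_ratio_is_absorbing(self):
        traj = spore_bottleneck(1.0, 100, 10, 50, seed=60)
        assert np.all(traj == 1.0)

    def test_variance_non_decreasing_without_mixing(self):
        traj = spore_bottleneck(0.5, 100, 20, 10_000, mixing_rate=0.0, seed=61)
        var = traj.var(axis=0)
        assert np.all(np.diff(var) > -1e-5)

    def test_full_mixing_collapses_variance(self):
        traj = spore_bottleneck(0.5, 100, 5, 1000, mixing_rate=1.0, seed=62)
        assert np.all(traj[:, 1:].var(axis=0) < 1e-12)

    def test_trajectories_stay_in_unit_interval(self):
        traj = spore_bottleneck(0.3, 10, 50, 500, mixing_rate=0.2, seed=63)
        assert traj.min() >= 0.0 and traj.max() <= 1.0
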