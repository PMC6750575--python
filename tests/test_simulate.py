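import numpy as np
import pytest

from riverpg.diversity import fis_table
from riverpg.genotypes import BinningConflictError, bin_fragments
from riverpg.simulate import (STUDY_SITE_SIZES, SimulationSpec,
                              balding_nichols_frequencies, sample_genotypes,
                              simulate_admixed_table, simulate_fragment_panel,
                              simulate_study_genotypes, simulate_study_region)


class TestBaldingNichols:
    def test_concentration_limit(self):
        anc = np.array([0.3, 0.5, 0.2])
        fs = balding_nichols_frequencies(anc, 1e-4, 10, seed=0)
        assert np.max(np.abs(fs - anc)) < 0.02

    def test_moment_check(self):
        # Var(p_site) = p(1-p) F for the two-allele case
        anc = np.array([0.6, 0.4])
        F = 0.5
        fs = balding_nichols_frequencies(anc, F, 2000, seed=1)
        expected = anc[0] * (1 - anc[0]) * F
        assert np.var(fs[:, 0]) == pytest.approx(expected, rel=0.2)

    def test_seed_reproducibility(self):
        anc = np.array([0.5, 0.5])
        a = balding_nichols_frequencies(anc, 0.1, 5, seed=7)
        b = balding_nichols_frequencies(anc, 0.1, 5, seed=7)
        assert np.array_equal(a, b)

    def test_degenerate_ancestral_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fs = balding_nichols_frequencies(np.array([1.0, 0.0]), 0.1, 3, seed=0)
        assert np.array_equal(fs, np.tile([1.0, 0.0], (3, 1)))


class TestSampleGenotypes:
    def test_hwe_heterozygosity(self):
        freqs = np.array([[0.5, 0.5]])
        t = sample_genotypes(freqs, 2000, F_IS=0.0, seed=2)
        ho = np.mean(t.calls[:, 0, 0] != t.calls[:, 0, 1])
        assert ho == pytest.approx(0.5, abs=0.03)

    def test_high_inbreeding_limit(self):
        freqs = np.array([[0.5, 0.5]])
        t = sample_genotypes(freqs, 500, F_IS=0.99, seed=3)
        ho = np.mean(t.calls[:, 0, 0] != t.calls[:, 0, 1])
        assert ho < 0.03

    def test_fis_recovery_links_to_diversity(self):
        rng = np.random.default_rng(4)
        freqs = rng.dirichlet(np.ones(5) * 5, size=8)
        t = sample_genotypes(freqs, 500, F_IS=0.3, seed=5)
        _, multi = fis_table(t)
        assert multi["pop1"] == pytest.approx(0.3, abs=0.05)


class TestAdmixedTable:
    def test_alpha_one_mean_q(self):
        cf = np.tile(np.eye(3)[None], (4, 1, 1))
        _, q = simulate_admixed_table(3, 1.0, cf, 1000, seed=6)
        assert np.allclose(q.mean(axis=0), 1 / 3, atol=0.03)

    def test_small_alpha_near_pure(self):
        cf = np.tile(np.eye(2)[None], (4, 1, 1))
        _, q = simulate_admixed_table(2, 0.01, cf, 300, seed=7)
        assert np.mean(q.max(axis=1) > 0.99) > 0.9

    def test_invalid_simplex_rejected(self):
        cf = np.full((2, 2, 3), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_admixed_table(2, 1.0, cf, 10, seed=0)


class TestStudyRegion:
    def test_gamma_rates_are_field_values(self):
        _, net = simulate_study_region(seed=0)
        assert net.gammas == {"large_barge": 0.71, "medium_barge": 0.35,
                              "bus": 0.125}

    def test_single_terrestrial_edge_is_the_highway(self):
        _, net = simulate_study_region(seed=1)
        terrestrial = [e for e in net.edges if e[2] == "terrestrial"]
        assert len(terrestrial) == 1
        u, v, _, length = terrestrial[0]
        assert {u, v} == {"Iquitos", "Nauta"} and length == 95.0

    def test_euclidean_range_matches_study_scale(self):
        geo, _ = simulate_study_region(seed=2)
        from riverpg.transport import euclidean_matrix
        m = euclidean_matrix(geo).values
        iu = np.triu_indices(len(geo), 1)
        assert 13 < m[iu].min() < 20
        assert 115 < m[iu].max() < 135

    def test_network_invariants_and_star_trips(self):
        _, net = simulate_study_region(seed=3)
        # constructor validates invariants; trips radiate from the hub
        for table in net.trips.values():
            assert all(o == "Iquitos" for o, _ in table)

    def test_seed_determinism(self):
        _, a = simulate_study_region(seed=4)
        _, b = simulate_study_region(seed=4)
        assert a.trips == b.trips


class TestFragmentPanel:
    def test_noise_free_round_trip(self):
        rng = np.random.default_rng(8)
        freqs = rng.dirichlet(np.ones(4) * 4, size=3)
        t = sample_genotypes(freqs, 30, seed=9)
        panel = simulate_fragment_panel(t, motif_length=3, size_noise_sd=0.0)
        back = bin_fragments(panel)
        assert np.array_equal(back.calls, t.calls)

    @pytest.mark.parametrize("noise,gap_fraction", [(0.2, 0.5), (0.3, 0.3)])
    def test_noisy_round_trip_recovery(self, noise, gap_fraction):
        # with dense data the between-allele gap shrinks as cluster edges
        # fill in, so heavier noise needs a tighter split threshold
        rng = np.random.default_rng(10)
        freqs = rng.dirichlet(np.ones(5) * 5, size=8)
        t = sample_genotypes(freqs, 125, seed=11)  # 1000 calls
        panel = simulate_fragment_panel(t, motif_length=3, size_noise_sd=noise,
                                        seed=12)
        back = bin_fragments(panel, gap_fraction=gap_fraction)
        assert np.array_equal(back.calls, t.calls)

    def test_excess_noise_rejected_or_conflicts(self):
        t = sample_genotypes(np.array([[0.5, 0.5]]), 20, seed=13)
        with pytest.raises(ValueError, match="size_noise_sd"):
            simulate_fragment_panel(t, motif_length=2, size_noise_sd=1.0)


def test_study_table_shape_and_structure():
    spec = SimulationSpec(seed=42)
    t = simulate_study_genotypes(spec)
    assert t.n_samples == sum(STUDY_SITE_SIZES.values()) == 339
    assert t.n_loci == 8
    sizes = {s: sum(1 for x in t.sample_ids if t.site_of[x] == s) for s in t.sites}
    assert sizes == STUDY_SITE_SIZES
    assert t.group_of["IquitosA"] == "Iquitos"
    assert t.group_of["Nauta"] == "Nauta"
    t2 = simulate_study_genotypes(SimulationSpec(seed=42))
    assert t2 == t


def test_spec_validation():
    with pytest.raises(ValueError):
        SimulationSpec(F=0.0)
    with pytest.raises(ValueError):
        SimulationSpec(F_IS=1.0)


class TestHouseholdClustering:
    def test_clustered_table_valid_and_deterministic(self):
        from riverpg.simulate import sample_family_genotypes
        rng = np.random.default_rng(30)
        freqs = rng.dirichlet(np.ones(4) * 4, size=5)
        a = sample_family_genotypes(freqs, 20, F_IS=0.1, seed=31)
        b = sample_family_genotypes(freqs, 20, F_IS=0.1, seed=31)
        assert a == b
        assert a.n_samples == 20 and a.n_loci == 5
        # offspring alleles are a subset of the sampled parental pool
        assert np.all(a.calls >= 1) and np.all(a.calls <= 4)

    def test_siblings_more_related_than_independent_draws(self):
        from riverpg.simulate import sample_family_genotypes
        # sibling triplets share parents, shrinking within-family diversity;
        # measure via mean allele sharing of consecutive individuals
        rng = np.random.default_rng(32)
        freqs = rng.dirichlet(np.ones(6) * 2, size=6)

        def mean_sharing(t):
            share = []
            for i in range(0, t.n_samples - 2, 3):
                for j in (i + 1, i + 2):
                    share.append(np.mean(t.calls[i] == t.calls[j]))
            return np.mean(share)

        fam = mean_sharing(sample_family_genotypes(freqs, 300, seed=33))
        indep = mean_sharing(sample_genotypes(freqs, 300, seed=34))
        assert fam > indep + 0.05

    def test_spec_switch(self):
        t = simulate_study_genotypes(SimulationSpec(
            seed=1, household_clustering=True,
            n_per_site={"Aucayo": 9, "Nauta": 9}, n_sites=2, n_loci=3))
        assert t.n_samples == 18
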