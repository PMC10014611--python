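"""Two-point likelihood model, rf estimation, and MDS marker ordering."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import smoothdescent as sd
from smoothdescent.mapping import RfMatrix, haldane_cm


def random_phase(p1, p2, n_markers, seed):
    rng = np.random.default_rng(seed)
    return sd.simulate_parents(p1, p2, n_markers, rng)


def informative_two_marker_phase(rng):
    """Random diploid phase whose marker pair carries linkage information
    (at least one parent heterozygous at both loci)."""
    while True:
        H = sd.simulate_parents(2, 2, 2, rng)
        p1, p2 = H.parent1(), H.parent2()
        if (p1[:, 0] != p1[:, 1]).all() or (p2[:, 0] != p2[:, 1]).all():
            return H


class TestPairLikelihood:
    @pytest.mark.parametrize("ploidy", [2, 4, 6])
    @pytest.mark.parametrize("r", [0.0, 0.1, 0.25, 0.5])
    def test_normalises_over_all_genotype_pairs(self, ploidy, r):
        H = random_phase(ploidy, ploidy, 6, seed=ploidy * 10 + 1)
        g_max = ploidy
        total = sum(
            sd.pair_genotype_likelihood(H, 0, 1, g1, g2, r)
            for g1 in range(g_max + 1)
            for g2 in range(g_max + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_no_recombination_keeps_identical_rows_identical(self):
        # same H row at both loci, r=0: the dosages must agree
        H = sd.HomologueMatrix(np.array([[1, 0, 1, 0], [1, 0, 1, 0]]), 2, 2)
        for g1 in range(3):
            for g2 in range(3):
                p = sd.pair_genotype_likelihood(H, 0, 1, g1, g2, 0.0)
                if g1 != g2:
                    assert p == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("ploidy", [2, 4])
    def test_free_recombination_factorises(self, ploidy):
        H = random_phase(ploidy, ploidy, 4, seed=3)
        g_max = ploidy
        joint = np.array(
            [
                [sd.pair_genotype_likelihood(H, 0, 1, g1, g2, 0.5)
                 for g2 in range(g_max + 1)]
                for g1 in range(g_max + 1)
            ]
        )
        m1, m2 = joint.sum(axis=1), joint.sum(axis=0)
        np.testing.assert_allclose(joint, np.outer(m1, m2), atol=1e-9)


class TestEstimateRf:
    def test_same_marker_gives_zero(self):
        H = random_phase(2, 2, 4, seed=4)
        G = sd.DosageMatrix(np.ones((4, 20)))
        assert sd.estimate_rf(G, H, 2, 2) == (0.0, 0.0)

    def test_phase_known_diploid_matches_recombinant_counting(self):
        """Markers heterozygous in parent 1 only: r-hat equals the observed
        recombinant fraction."""
        H = sd.HomologueMatrix(
            np.array([[1, 0, 0, 0], [1, 0, 0, 0]]), 2, 2
        )
        rng = np.random.default_rng(5)
        n = 200
        # locus 1 genotype tells which parent-1 homologue was inherited
        g1 = rng.integers(0, 2, n)
        recomb = rng.random(n) < 0.2
        g2 = np.where(recomb, 1 - g1, g1)
        G = sd.DosageMatrix(np.vstack([g1, g2]).astype(float))
        r_hat, lod = sd.estimate_rf(G, H, 0, 1)
        assert r_hat == pytest.approx(recomb.mean(), abs=0.004)
        assert lod > 10

    @pytest.mark.parametrize("r_true", [0.05, 0.2, 0.4])
    def test_monte_carlo_recovery(self, r_true):
        """Mean r-hat over 50 two-marker diploid populations (n=200)
        recovers the simulated r within 0.02."""
        d = float(haldane_cm(r_true))
        estimates = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            H = informative_two_marker_phase(rng)
            cfg = sd.SimConfig(
                2, 2, n_individuals=200, n_markers=2,
                marker_positions=np.array([0.0, d]), chrom_length=max(d, 1.0),
            )
            b = sd.simulate_population(H, cfg, rng)
            r_hat, _ = sd.estimate_rf(b.G_true, H, 0, 1)
            estimates.append(r_hat)
        assert np.mean(estimates) == pytest.approx(r_true, abs=0.02)

    def test_bias_shrinks_with_sample_size(self):
        """|mean r-hat - r| decreases from n=50 to n=200 (consistency)."""
        d = float(haldane_cm(0.2))
        bias = {}
        for n in (50, 200):
            est = []
            for rep in range(40):
                rng = np.random.default_rng(7000 + rep)
                H = informative_two_marker_phase(rng)
                cfg = sd.SimConfig(
                    2, 2, n_individuals=n, n_markers=2,
                    marker_positions=np.array([0.0, d]), chrom_length=d,
                )
                b = sd.simulate_population(H, cfg, rng)
                est.append(sd.estimate_rf(b.G_true, H, 0, 1)[0])
            bias[n] = abs(np.mean(est) - 0.2)
        assert bias[200] <= bias[50] + 0.005

    def test_too_few_individuals_uninformative(self):
        H = random_phase(2, 2, 2, seed=6)
        G = sd.DosageMatrix(np.ones((2, 5)))
        assert sd.estimate_rf(G, H, 0, 1) == (0.5, 0.0)


def exact_rf_matrix(positions):
    """Noise-free rf/LOD matrices implied by true positions."""
    d = np.abs(positions[:, None] - positions[None, :])
    r = sd.inverse_map_function(d, "haldane")
    lod = np.full_like(r, 10.0)
    np.fill_diagonal(lod, 0.0)
    return RfMatrix(r_hat=r, lod=lod)


class TestOrderMarkers:
    def test_exact_distances_recover_order_up_to_reversal(self):
        positions = np.array([0.0, 3.0, 10.0, 11.0, 25.0, 40.0, 41.0, 55.0])
        gm = sd.order_markers(exact_rf_matrix(positions))
        rho = spearmanr(gm.positions_by_marker(), positions).statistic
        assert abs(rho) > 0.999

    def test_ordering_invariant_to_input_permutation(self):
        positions = np.linspace(0, 60, 20)
        rng = np.random.default_rng(8)
        perm = rng.permutation(20)
        gm = sd.order_markers(exact_rf_matrix(positions[perm]))
        rho = spearmanr(gm.positions_by_marker(), positions[perm]).statistic
        assert abs(rho) > 0.999

    def test_disconnected_graph_raises(self):
        r = np.full((4, 4), 0.5)
        lod = np.zeros((4, 4))
        lod[0, 1] = lod[1, 0] = 5.0
        lod[2, 3] = lod[3, 2] = 5.0
        with pytest.raises(ValueError, match="disconnected"):
            sd.order_markers(RfMatrix(r_hat=r, lod=lod))

    def test_error_free_simulation_recovers_map(self, diploid_clean):
        """Error-free diploid study population: |Spearman| > 0.95 and map
        length within 20% of the true 100 cM."""
        rf = sd.estimate_rf_matrix(diploid_clean.G_true, diploid_clean.H)
        gm = sd.order_markers(rf)
        rho = spearmanr(gm.positions_by_marker(), diploid_clean.positions).statistic
        assert abs(rho) > 0.95
        assert 80 <= gm.length <= 120

    def test_errors_inflate_rf_and_map_length(self, diploid_noisy):
        """Injected errors inflate close-pair r-hat and the estimated map
        relative to the same population's clean genotypes."""
        rf_noisy = sd.estimate_rf_matrix(diploid_noisy.G_observed, diploid_noisy.H)
        pos = diploid_noisy.positions
        close = np.abs(pos[:, None] - pos[None, :]) < 5
        np.fill_diagonal(close, False)
        rf_truth = sd.estimate_rf_matrix(diploid_noisy.G_true, diploid_noisy.H)
        assert rf_noisy.r_hat[close].mean() > rf_truth.r_hat[close].mean()
        gm_truth = sd.order_markers(rf_truth)
        gm_noisy = sd.order_markers(rf_noisy)
        assert gm_noisy.length > gm_truth.length


class TestMapLength:
    def test_single_marker_and_span(self):
        gm = sd.GeneticMap(np.array([0]), np.array([0.0]))
        assert sd.map_length(gm) == 0.0
        gm = sd.GeneticMap(np.arange(3), np.array([0.0, 40.0, 100.0]))
        assert sd.map_length(gm) == 100.0
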