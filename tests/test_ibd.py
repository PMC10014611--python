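"""Naive IBD: configuration combinatorics and the count-ratio probabilities."""

import itertools
from math import comb

import numpy as np
import pytest

import smoothdescent as sd


def brute_force_ibd(h_row, genotype, p1, p2):
    """Independent oracle: enumerate every configuration explicitly."""
    gametes1 = list(itertools.combinations(range(p1), p1 // 2))
    gametes2 = list(itertools.combinations(range(p1, p1 + p2), p2 // 2))
    configs = [a + b for a in gametes1 for b in gametes2]
    possible = [c for c in configs if sum(h_row[h] for h in c) == genotype]
    p = p1 + p2
    if not possible:
        return np.full(p, np.nan), True
    probs = np.array(
        [sum(h in c for c in possible) / len(possible) for h in range(p)]
    )
    return probs, False


class TestConfigurations:
    @pytest.mark.parametrize(
        "p1,p2,expected", [(2, 2, 4), (4, 4, 36), (6, 6, 400), (4, 2, 12)]
    )
    def test_counts_without_double_reduction(self, p1, p2, expected):
        configs = sd.enumerate_configurations(p1, p2)
        assert len(configs) == expected == comb(p1, p1 // 2) * comb(p2, p2 // 2)
        # all distinct, correct size, per-parent indices in range
        assert len({tuple(c) for c in configs}) == expected
        assert configs.shape[1] == (p1 + p2) // 2

    def test_diploid_configurations_are_the_four_parental_pairs(self):
        configs = {tuple(c) for c in sd.enumerate_configurations(2, 2)}
        assert configs == {(0, 2), (0, 3), (1, 2), (1, 3)}

    @pytest.mark.parametrize("p1,p2,expected", [(4, 4, 100), (2, 2, 4), (4, 2, 20)])
    def test_counts_with_double_reduction(self, p1, p2, expected):
        assert sd.count_configurations_with_double_reduction(p1, p2) == expected

    def test_double_reduction_count_matches_multiset_oracle(self):
        def oracle(ploidy):
            if ploidy == 2:
                return 2
            out = set()
            for ms in itertools.combinations_with_replacement(
                range(ploidy), ploidy // 2
            ):
                if all(ms.count(h) <= 2 for h in ms):
                    out.add(ms)
            return len(out)

        for p1, p2 in [(4, 4), (6, 6), (6, 4), (4, 2)]:
            assert (
                sd.count_configurations_with_double_reduction(p1, p2)
                == oracle(p1) * oracle(p2)
            )

    def test_odd_ploidy_rejected(self):
        with pytest.raises(ValueError):
            sd.enumerate_configurations(3, 2)


class TestConfigurationDosage:
    def test_printed_diploid_dosages(self, eq1_phase):
        # marker 1: c1 = {H1, H3} -> 1; c3 = {H2, H3} -> 0
        row = eq1_phase.values[0]
        assert sd.configuration_dosage(row, [0, 2]) == 1
        assert sd.configuration_dosage(row, [1, 2]) == 0

    def test_printed_tetraploid_dosage(self, eq2_phase):
        # marker 1: c1 = {H1, H2, H5, H6} -> 0+1+0+0 = 1
        assert sd.configuration_dosage(eq2_phase.values[0], [0, 1, 4, 5]) == 1


class TestNaiveIBD:
    def test_worked_example_rows(self, eq1_phase):
        expected = np.array(
            [
                [1.0, 0.0, 0.5, 0.5],
                [1.0, 0.0, 0.0, 1.0],
                [0.5, 0.5, 0.0, 1.0],
            ]
        )
        G = sd.DosageMatrix(np.array([[1.0], [0.0], [1.0]]))
        tensor = sd.naive_ibd_population(eq1_phase, G)
        np.testing.assert_array_equal(tensor.probs[:, :, 0], expected)
        assert not tensor.impossible.any()

    def test_missing_genotype_gives_all_missing(self, eq1_phase):
        probs, impossible = sd.naive_ibd_marker(
            eq1_phase.values[0], float("nan"), 2, 2
        )
        assert np.isnan(probs).all() and not impossible

    def test_phase_impossible_genotype_flagged(self):
        # both parents carry only reference alleles: dosage 2 is impossible
        probs, impossible = sd.naive_ibd_marker(np.zeros(4), 2, 2, 2)
        assert impossible and np.isnan(probs).all()

    @pytest.mark.parametrize("p1,p2,n_cases", [(2, 2, 400), (4, 4, 400), (6, 6, 200)])
    def test_matches_enumeration_oracle(self, p1, p2, n_cases):
        rng = np.random.default_rng(12345)
        g_max = (p1 + p2) // 2
        for _ in range(n_cases):
            h_row = rng.integers(0, 2, size=p1 + p2)
            g = int(rng.integers(0, g_max + 1))
            got, got_flag = sd.naive_ibd_marker(h_row, g, p1, p2)
            want, want_flag = brute_force_ibd(h_row, g, p1, p2)
            assert got_flag == want_flag
            np.testing.assert_allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("ploidy", [2, 4])
    def test_per_parent_sums_equal_half_ploidy(self, ploidy):
        rng = np.random.default_rng(7)
        H = sd.simulate_parents(ploidy, ploidy, 40, rng)
        cfg = sd.SimConfig(ploidy, ploidy, n_individuals=20, n_markers=40, seed=7)
        bundle = sd.simulate_population(H, cfg, rng)
        tensor = sd.naive_ibd_population(H, bundle.G_true)
        m = ploidy // 2
        s1 = tensor.probs[:, :ploidy, :].sum(axis=1)
        s2 = tensor.probs[:, ploidy:, :].sum(axis=1)
        informative = np.isfinite(s1)
        assert informative.any()
        np.testing.assert_allclose(s1[informative], m, atol=1e-12)
        np.testing.assert_allclose(s2[np.isfinite(s2)], m, atol=1e-12)

    def test_diploid_truth_outranks_noninherited_within_parent(self):
        # On error-free diploid data the truly inherited homologue never
        # scores below its parent's other homologue.  (Conditioning on the
        # total dosage can rank homologues of *different* parents either
        # way, and for polyploids even within-parent reversals occur when
        # another parent explains the dosage more parsimoniously.)
        rng = np.random.default_rng(99)
        H = sd.simulate_parents(2, 2, 60, rng)
        cfg = sd.SimConfig(2, 2, n_individuals=30, n_markers=60, seed=99)
        bundle = sd.simulate_population(H, cfg, rng)
        tensor = sd.naive_ibd_population(H, bundle.G_true)
        inherited = bundle.I_true.probs > 0.5
        for m in range(60):
            for i in range(30):
                v = tensor.probs[m, :, i]
                if not np.isfinite(v).all():
                    continue
                for sl in (slice(0, 2), slice(2, 4)):
                    inh = inherited[m, sl, i]
                    assert v[sl][inh].min() >= v[sl][~inh].max() - 1e-12

    @pytest.mark.parametrize("ploidy", [2, 4, 6])
    def test_inherited_homologues_never_get_zero_probability(self, ploidy):
        # The true configuration is always dosage compatible on error-free
        # data, so every inherited homologue keeps positive probability.
        rng = np.random.default_rng(5)
        H = sd.simulate_parents(ploidy, ploidy, 50, rng)
        cfg = sd.SimConfig(ploidy, ploidy, n_individuals=25, n_markers=50, seed=5)
        bundle = sd.simulate_population(H, cfg, rng)
        tensor = sd.naive_ibd_population(H, bundle.G_true)
        inherited = bundle.I_true.probs > 0.5
        finite = np.isfinite(tensor.probs)
        assert not (finite & inherited & (tensor.probs <= 1e-12)).any()

    def test_dosage_out_of_range_rejected(self, eq1_phase):
        G = sd.DosageMatrix(np.array([[3.0], [0.0], [1.0]]))
        with pytest.raises(ValueError, match="out of range"):
            sd.naive_ibd_population(eq1_phase, G)
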