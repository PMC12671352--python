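"""Tie-corrected Spearman correlation against published coefficients and
independent oracles (scipy and brute-force enumeration)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from foodrisk import (
    correlation_matrix,
    midranks,
    spearman_pvalue,
    spearman_rho,
)
from foodrisk.errors import DomainError
from reference_values import PRINTED_SPEARMAN

vectors = st.lists(st.floats(min_value=-50, max_value=50,
                             allow_nan=False, allow_infinity=False),
                   min_size=4, max_size=25)

# integer-valued inputs so x -> exp(x/50) is strictly monotone in floats
# (distinct values stay distinct, ties stay tied)
int_vectors = st.lists(st.integers(min_value=-50, max_value=50),
                       min_size=4, max_size=25)


class TestMidranks:
    def test_textbook_tie(self):
        assert midranks([1, 2, 2, 3]).tolist() == [1, 2.5, 2.5, 4]

    def test_strictly_increasing(self):
        assert midranks(np.arange(7.0)).tolist() == list(range(1, 8))

    def test_fixture_chromium_tie(self, brassica):
        # the duplicated Cr value 1.35 spans ranks 8 and 9 -> 8.5 each
        ranks = midranks(brassica.subset("Cecomaf").column("Cr"))
        tied = ranks[brassica.subset("Cecomaf").column("Cr") == 1.35]
        assert tied.tolist() == [8.5, 8.5]

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            midranks([1.0, np.inf])

    @settings(derandomize=True, max_examples=50)
    @given(vectors)
    def test_ranks_sum_to_triangular_number(self, x):
        n = len(x)
        assert midranks(x).sum() == pytest.approx(n * (n + 1) / 2)


class TestSpearmanRho:
    def test_published_coefficients(self, brassica):
        for (site, a, b), printed in PRINTED_SPEARMAN.items():
            sub = brassica.subset(site)
            rho = spearman_rho(sub.column(a), sub.column(b))
            assert rho == pytest.approx(printed, abs=1e-3), (site, a, b)

    def test_matches_scipy_on_every_fixture_pair(self, brassica):
        for site in ("Cecomaf", "Lutendele"):
            sub = brassica.subset(site)
            for a, b in itertools.combinations(sub.metals, 2):
                expected = stats.spearmanr(sub.column(a),
                                           sub.column(b)).statistic
                assert spearman_rho(sub.column(a), sub.column(b)) == (
                    pytest.approx(expected, abs=1e-12)), (site, a, b)

    def test_tied_example_against_hand_computation(self):
        # product-moment of mid-ranks (1, 2.5, 2.5, 4) vs (1, 2, 3, 4)
        rho = spearman_rho([1, 2, 2, 3], [1, 2, 3, 4])
        assert rho == pytest.approx(0.948683, abs=1e-6)

    def test_perfect_monotone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DomainError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @settings(derandomize=True, max_examples=50)
    @given(int_vectors)
    def test_invariant_under_monotone_transform(self, x):
        x = np.asarray(x, dtype=float)
        y = np.linspace(0, 1, len(x))
        try:
            base = spearman_rho(x, y)
        except DomainError:
            return  # constant draw: correlation undefined
        assert spearman_rho(np.exp(x / 50), y) == pytest.approx(
            base, abs=1e-12)

    def test_no_tie_shortcut_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            d = midranks(x) - midranks(y)
            shortcut = 1 - 6 * (d ** 2).sum() / (n * (n * n - 1))
            assert spearman_rho(x, y) == pytest.approx(shortcut, abs=1e-12)


class TestSpearmanPvalue:
    def test_null_center(self):
        assert spearman_pvalue(0.0, 11) == pytest.approx(1.0)

    def test_published_significant_pair(self):
        # Cecomaf Cr-Pb: rho 0.929 over 11 samples is significant
        assert spearman_pvalue(0.929, 11) < 0.05

    def test_small_n_rejected(self):
        with pytest.raises(DomainError):
            spearman_pvalue(0.5, 3)

    def test_enumeration_matches_exact_tail(self):
        # independent oracle: enumerate all 120 rank permutations of n=5
        n, rho_obs = 5, 0.9
        base = np.arange(1, n + 1, dtype=float)
        hits = sum(
            abs(stats.pearsonr(base, np.array(p)).statistic)
            >= rho_obs - 1e-12
            for p in itertools.permutations(base))
        exact = hits / 120
        assert spearman_pvalue(rho_obs, n, method="permutation") == (
            pytest.approx(exact, abs=1e-12))

    def test_permutation_reproducible_under_seed(self):
        a = spearman_pvalue(0.6, 11, method="permutation", seed=5,
                            n_perm=2000)
        b = spearman_pvalue(0.6, 11, method="permutation", seed=5,
                            n_perm=2000)
        assert a == b

    def test_t_approx_tracks_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        rho = spearman_rho(x, y)
        expected = stats.spearmanr(x, y).pvalue
        assert spearman_pvalue(rho, 12) == pytest.approx(expected, abs=1e-9)


class TestCorrelationMatrix:
    def test_published_site_blocks(self, brassica):
        cec = correlation_matrix(brassica, "Cecomaf")
        lut = correlation_matrix(brassica, "Lutendele")
        assert cec.rho.at["Cd", "Hg"] == pytest.approx(0.564, abs=1e-3)
        assert lut.rho.at["Cr", "As"] == pytest.approx(0.910, abs=1e-3)
        assert cec.n == 11 and lut.n == 8

    def test_symmetry_and_unit_diagonal(self, brassica):
        cm = correlation_matrix(brassica, "Cecomaf")
        rho = cm.rho.to_numpy()
        assert np.allclose(rho, rho.T, equal_nan=True)
        assert np.allclose(np.diag(rho), 1.0)
        assert ((cm.rho.abs() <= 1 + 1e-12) | cm.rho.isna()).all().all()
        p = cm.p.to_numpy()
        finite = np.isfinite(p)
        assert ((p[finite] >= 0) & (p[finite] <= 1)).all()

    def test_significance_flags_published_pairs(self, brassica):
        cm = correlation_matrix(brassica, "Cecomaf")
        assert cm.significant.at["Cr", "Pb"]
        assert cm.significant.at["Cr", "As"]
        assert not cm.significant.at["Cr", "Mn"]  # rho 0.187, n 11

    def test_too_few_samples_rejected(self, brassica):
        from foodrisk import ConcentrationTable
        tiny = ConcentrationTable(brassica.data.iloc[:3],
                                  brassica.sites.iloc[:3])
        with pytest.raises(DomainError):
            correlation_matrix(tiny, "Cecomaf")

    def test_long_format_covers_all_pairs(self, brassica):
        cm = correlation_matrix(brassica, "Lutendele")
        long = cm.to_long()
        assert len(long) == 19 * 18 // 2
        assert set(long.columns) == {"metal_a", "metal_b", "rho", "p",
                                     "significant"}
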