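"""Basic-heading PPPs and bilateral index aggregation."""

import numpy as np
import pytest

from spindex import (
    ExpenditureWeights,
    compute_bilateral_set,
    cpd_heading_ppp,
    fisher_index,
    jevons_heading_ppp,
    laspeyres_index,
    match_services,
    paasche_index,
    pls_spread,
)
from spindex.errors import ComputationError, ValidationError

from conftest import make_tableau


class TestJevons:
    def test_proportional_prices(self, rng):
        base = rng.uniform(1, 100, size=6)
        tab = make_tableau(np.vstack([base, 2 * base]))
        ppp = jevons_heading_ppp(tab, "h0").ppp
        assert ppp[1, 0] == pytest.approx(2.0, rel=1e-12)
        assert ppp[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_geometric_mean_of_ratios(self):
        # ratios 2 and 8 -> sqrt(16) = 4
        tab = make_tableau([[1.0, 1.0], [2.0, 8.0]])
        assert jevons_heading_ppp(tab, "h0").ppp[1, 0] == pytest.approx(4.0)

    def test_matches_naive_product_oracle(self, rng):
        prices = rng.uniform(0.5, 500, size=(3, 10))
        tab = make_tableau(prices)
        ppp = jevons_heading_ppp(tab, "h0").ppp
        for j in range(3):
            for k in range(3):
                naive = np.prod((prices[j] / prices[k]) ** (1 / 10))
                assert ppp[j, k] == pytest.approx(naive, abs=1e-12, rel=1e-12)

    def test_reciprocity_and_diagonal(self, rng):
        tab = make_tableau(rng.uniform(1, 10, size=(4, 8)))
        ppp = jevons_heading_ppp(tab, "h0").ppp
        np.testing.assert_allclose(ppp * ppp.T, 1.0, atol=1e-12)
        np.testing.assert_array_equal(np.diag(ppp), 1.0)


class TestCPD:
    def test_equals_jevons_on_complete_tableau(self, rng):
        tab = make_tableau(rng.lognormal(4, 1, size=(4, 30)))
        j = jevons_heading_ppp(tab, "h0").ppp
        c = cpd_heading_ppp(tab, "h0").ppp
        np.testing.assert_allclose(c, j, atol=1e-10, rtol=1e-10)

    def test_identical_prices_give_unity(self):
        row = [3.0, 7.0, 11.0]
        tab = make_tableau([row, row, row])
        np.testing.assert_allclose(cpd_heading_ppp(tab, "h0").ppp, 1.0,
                                   atol=1e-12)

    def test_incomplete_matches_normal_equations_oracle(self, rng):
        m, n = 3, 6
        prices = rng.lognormal(3, 0.8, size=(m, n))
        tab = make_tableau(prices)
        mask = np.ones((m, n), dtype=bool)
        mask[1, 4] = False  # delete one cell
        got = cpd_heading_ppp(tab, "h0", base_region="R0", mask=mask).ppp

        # independent oracle: assemble X'X alpha = X'y explicitly and solve
        rows, cols = np.nonzero(mask)
        y = np.log(prices)[rows, cols]
        p = (m - 1) + n
        X = np.zeros((y.size, p))
        for t, (r, s) in enumerate(zip(rows, cols)):
            if r > 0:
                X[t, r - 1] = 1.0
            X[t, (m - 1) + s] = 1.0
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        alpha = np.concatenate([[0.0], beta[: m - 1]])
        expected = np.exp(alpha[:, None] - alpha[None, :])
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_rank_deficient_design_errors(self):
        # two regions never pricing a common service: effects unidentified
        tab = make_tableau([[1.0, 2.0], [2.0, 4.0]])
        mask = np.array([[True, False], [False, True]])
        with pytest.raises(ComputationError, match="rank"):
            cpd_heading_ppp(tab, "h0", mask=mask)


def _ppps(values, regions=("A", "B")):
    """One-heading-per-value PPP matrices for the 2-region pair (B base A)."""
    from spindex.bilateral import HeadingPPPMatrix
    out = []
    for i, v in enumerate(values):
        m = np.array([[1.0, 1.0 / v], [v, 1.0]])
        out.append(HeadingPPPMatrix(heading=f"h{i}", regions=regions, ppp=m))
    return out


def _w(values):
    return ExpenditureWeights("X", {f"h{i}": v for i, v in enumerate(values)})


class TestAggregation:
    def test_laspeyres_is_weighted_arithmetic_mean(self):
        assert laspeyres_index(_ppps([2.0, 4.0]), _w([0.5, 0.5]), 1, 0) == \
            pytest.approx(3.0)

    def test_laspeyres_proportionality(self, rng):
        w = rng.dirichlet([1, 1, 1])
        lam = 1.37
        assert laspeyres_index(_ppps([lam] * 3), _w(w), 1, 0) == \
            pytest.approx(lam)

    def test_laspeyres_dot_product_oracle(self, rng):
        v = rng.uniform(0.5, 2.0, size=4)
        w = rng.dirichlet(np.ones(4))
        got = laspeyres_index(_ppps(v), _w(w), 1, 0)
        assert got == pytest.approx(float(v @ w), rel=1e-12)

    def test_paasche_is_weighted_harmonic_mean(self):
        got = paasche_index(_ppps([2.0, 4.0]), _w([0.5, 0.5]), 1, 0)
        assert got == pytest.approx(1.0 / (0.25 + 0.125))

    def test_paasche_direct_evaluation_oracle(self, rng):
        v = rng.uniform(0.5, 2.0, size=4)
        w = rng.dirichlet(np.ones(4))
        got = paasche_index(_ppps(v), _w(w), 1, 0)
        assert got == pytest.approx(1.0 / float((1.0 / v) @ w), rel=1e-12)

    def test_harmonic_below_arithmetic(self, rng):
        # same weights on both sides: P <= L always (Jensen)
        v = rng.uniform(0.5, 2.0, size=4)
        w = rng.dirichlet(np.ones(4))
        assert paasche_index(_ppps(v), _w(w), 1, 0) <= \
            laspeyres_index(_ppps(v), _w(w), 1, 0) + 1e-12

    @pytest.mark.parametrize("L,P,expected", [
        (1.1, 1.1, 1.1),
        (2.0, 0.5, 1.0),
    ])
    def test_fisher_known_values(self, L, P, expected):
        assert fisher_index(L, P) == pytest.approx(expected)

    def test_fisher_consistency_identity(self, rng):
        target = 1.3658
        for P in rng.uniform(0.5, 2.0, size=5):
            F = fisher_index(target ** 2 / P, P)
            assert F ** 2 == pytest.approx(target ** 2, rel=1e-12)

    def test_fisher_rejects_nonpositive(self):
        with pytest.raises(ComputationError):
            fisher_index(-1.0, 2.0)

    @pytest.mark.parametrize("L,P,expected", [
        (1.3, 1.3, 0.0),
        (np.e * 0.8, 0.8, 1.0),
    ])
    def test_pls_known_values(self, L, P, expected):
        assert pls_spread(L, P) == pytest.approx(expected)

    def test_pls_orientation_symmetric(self, rng):
        # reversal identity: L_jk = 1/P_kj, so the spread is orientation-free
        L, P = 1.42, 1.17
        assert pls_spread(L, P) == pytest.approx(
            pls_spread(1.0 / P, 1.0 / L), abs=1e-12)

    def test_weight_heading_misalignment_errors(self):
        with pytest.raises(ValidationError):
            laspeyres_index(_ppps([2.0]), _w([0.5, 0.5]), 1, 0)


class TestBilateralSet:
    def test_single_heading_two_regions_collapses_to_jevons(self, rng):
        prices = rng.lognormal(4, 1, size=(2, 12))
        tab = make_tableau(prices)
        weights = {r: ExpenditureWeights(r, {"h0": 1.0}) for r in tab.regions}
        bil = compute_bilateral_set(tab, weights)
        j = jevons_heading_ppp(tab, "h0").ppp
        np.testing.assert_allclose(bil.fisher, j, rtol=1e-12)
        np.testing.assert_allclose(bil.laspeyres, j, rtol=1e-12)

    def test_proportional_system_degenerates(self, noise_free_system):
        # one multiplier per region: every heading PPP is the same ratio,
        # so L = P = F and the spread vanishes regardless of weights
        _, schedules, weights, truth = noise_free_system
        tab = match_services(schedules)
        bil = compute_bilateral_set(tab, weights)
        np.testing.assert_allclose(bil.laspeyres, bil.paasche, rtol=1e-12)
        np.testing.assert_allclose(bil.pls, 0.0, atol=1e-12)
        lam = np.array([truth["lambda"][r] for r in bil.regions])
        np.testing.assert_allclose(bil.fisher, lam[:, None] / lam[None, :],
                                   rtol=1e-10)

    def test_invariant_suite_on_heterogeneous_system(self, rng):
        # per-heading tilts create genuine L-P spread
        from spindex import SyntheticConfig, generate_system
        tilt = {("A", "h1"): 1.3, ("A", "h2"): 0.8, ("B", "h3"): 1.2,
                ("C", "h0"): 0.7}
        cfg = SyntheticConfig(
            region_levels={"A": 1.4, "B": 0.9, "C": 1.0, "D": 1.1},
            headings=("h0", "h1", "h2", "h3"), n_services=40,
            noise_sigma=0.25, heading_tilt=tilt, seed=5)
        schedules, weights, _ = generate_system(cfg)
        tab = match_services(schedules)
        bil = compute_bilateral_set(tab, weights)
        L, P, F = bil.laspeyres, bil.paasche, bil.fisher
        np.testing.assert_allclose(F, np.sqrt(L * P), rtol=1e-12)
        assert np.all(F >= np.minimum(L, P) - 1e-12)
        assert np.all(F <= np.maximum(L, P) + 1e-12)
        np.testing.assert_allclose(F * F.T, 1.0, atol=1e-12)
        np.testing.assert_allclose(L * P.T, 1.0, atol=1e-12)
        np.testing.assert_allclose(bil.pls, bil.pls.T, atol=1e-15)
        assert np.all(bil.pls >= 0)
        assert bil.pls.max() > 0  # the tilts must actually bite
        # mean-value bounds: L and P lie within the span of heading PPPs
        stack = np.stack([h.ppp for h in bil.heading_ppps])
        assert np.all(L >= stack.min(axis=0) - 1e-12)
        assert np.all(L <= stack.max(axis=0) + 1e-12)
        assert np.all(P >= stack.min(axis=0) - 1e-12)
        assert np.all(P <= stack.max(axis=0) + 1e-12)

    def test_region_price_scaling_property(self, rng):
        prices = rng.lognormal(3, 0.5, size=(3, 9))
        headings = ["h0", "h0", "h0", "h1", "h1", "h1", "h2", "h2", "h2"]
        weights = {f"R{i}": ExpenditureWeights(
            f"R{i}", dict(zip(("h0", "h1", "h2"), rng.dirichlet([2, 2, 2]))))
            for i in range(3)}
        bil0 = compute_bilateral_set(make_tableau(prices, headings), weights)
        lam = 1.7
        scaled = prices.copy()
        scaled[2] *= lam  # region R2 uniformly dearer
        bil1 = compute_bilateral_set(make_tableau(scaled, headings), weights)
        # R2's level vs any base scales by lambda; others' levels vs base R2
        # scale by 1/lambda
        np.testing.assert_allclose(bil1.fisher[2, :2], bil0.fisher[2, :2] * lam,
                                   rtol=1e-12)
        np.testing.assert_allclose(bil1.fisher[:2, 2], bil0.fisher[:2, 2] / lam,
                                   rtol=1e-12)

    def test_missing_weights_error_names_region(self, noise_free_system):
        _, schedules, weights, _ = noise_free_system
        tab = match_services(schedules)
        partial = {r: w for r, w in weights.items() if r != "Anhui"}
        with pytest.raises(ValidationError, match="Anhui"):
            compute_bilateral_set(tab, partial)

    def test_cpd_method_matches_jevons_method(self, noisy_system):
        _, schedules, weights, _ = noisy_system
        tab = match_services(schedules)
        a = compute_bilateral_set(tab, weights, method="jevons")
        b = compute_bilateral_set(tab, weights, method="cpd")
        np.testing.assert_allclose(a.fisher, b.fisher, atol=1e-10)
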