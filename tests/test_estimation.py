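import numpy as np
import pytest

from mirmotif import (
    AffineMap,
    FitConfig,
    GridCapError,
    ParsimonyError,
    TDMotif,
    TIMotif,
    SyntheticSpec,
    TimeGrid,
    fit_td,
    fit_ti,
    h_levels,
    hill_factor,
    invert_median_fraction,
    lp_minimax,
    parsimony_check,
    generate_td_dataset,
    generate_ti_dataset,
)
from mirmotif.kinetics import predict_ti, RegulatorTerm, TIParams
from mirmotif.models import TranslationInhibitionModel


def brute_force_minimax(constants, columns, signs, ranges, n=400):
    """Lattice search oracle for the 2-column inner minimax problem."""
    g1, g2 = np.meshgrid(np.linspace(0.0, ranges[0], n),
                         np.linspace(0.0, ranges[1], n), indexing="ij")
    z = np.zeros_like(g1)
    for cst, c1, c2 in zip(constants, columns[0], columns[1]):
        z = np.maximum(z, np.abs(cst + signs[0] * c1 * g1 + signs[1] * c2 * g2))
    return float(z.min())


class TestGridAndInversion:
    def test_h_levels_open_interval(self):
        hs = h_levels(99)
        assert len(hs) == 99
        assert 0.0 < hs[0] and hs[-1] < 1.0
        np.testing.assert_allclose(np.diff(hs), hs[1] - hs[0])

    def test_invert_median_example(self):
        assert invert_median_fraction(2.0, 0.5, 1) == pytest.approx(0.5)

    def test_round_trip(self, rng):
        for _ in range(50):
            med = rng.uniform(0.1, 5.0)
            h = rng.uniform(0.01, 0.99)
            S = int(rng.integers(1, 6))
            u = invert_median_fraction(med, h, S)
            assert hill_factor(med, u, S) == pytest.approx(h, abs=1e-12)

    def test_monotone_in_h(self):
        us = [invert_median_fraction(1.0, h, 2) for h in (0.1, 0.5, 0.9, 0.999)]
        assert us == sorted(us, reverse=True)
        assert us[-1] < 1e-3  # h -> 1 drives u -> 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            invert_median_fraction(0.0, 0.5, 1)
        with pytest.raises(ValueError):
            invert_median_fraction(1.0, 1.0, 1)


class TestParsimony:
    @pytest.mark.parametrize("n_par,q,expected", [
        (4, 19, True),    # 19-point grid admits one inhibitor (n_par = 4)
        (9, 38, True),    # 38 points support 9 parameters
        (5, 19, False),   # but not five parameters on 19 points
    ])
    def test_rule(self, n_par, q, expected):
        assert parsimony_check(n_par, q) is expected

    def test_violation_names_quantities(self):
        motif = TIMotif("P", "G", ("M1", "M2"))  # n_par = 6 > 4.5
        profiles, _ = generate_ti_dataset(SyntheticSpec(motif=motif, seed=0))
        with pytest.raises(ParsimonyError, match=r"n_par = 6.*4\.5"):
            fit_ti(motif, profiles)


class TestLpMinimax:
    def test_zero_columns(self):
        constants = np.array([0.5, -2.0, 1.0])
        rates, z = lp_minimax(constants, [np.zeros(3), np.zeros(3)], (1.0, -1.0))
        assert z == pytest.approx(2.0)

    def test_known_zero_solution(self, rng):
        """Rows built from noiseless dynamics are zeroed at the true rates."""
        gamma0, lam0 = 0.25, 0.6
        mu = rng.uniform(0.5, 3.0, size=10)
        nu = rng.uniform(0.5, 3.0, size=10)
        constants = -(gamma0 * mu - lam0 * nu)
        rates, z = lp_minimax(constants, [mu, nu], (1.0, -1.0))
        assert z == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rates, [gamma0, lam0], atol=1e-7)

    def test_matches_bruteforce_lattice(self, rng):
        for _ in range(3):
            constants = rng.uniform(-1.0, 1.0, size=5)
            columns = [rng.uniform(-1.0, 1.0, size=5) for _ in range(2)]
            rates, z = lp_minimax(constants, columns, (1.0, -1.0))
            ranges = [max(1.0, 2.0 * r) for r in rates]
            n = 400
            z_lattice = brute_force_minimax(constants, columns, (1.0, -1.0), ranges, n)
            tol = sum(
                (r / (n - 1)) * np.max(np.abs(c)) for r, c in zip(ranges, columns)
            )
            assert z <= z_lattice + 1e-9
            assert z_lattice - z <= tol


class TestFitTI:
    def test_noiseless_recovery_and_search_size(self):
        motif = TIMotif("P", "G", ("M1",))
        profiles, truth = generate_ti_dataset(SyntheticSpec(motif=motif, seed=42))
        res = fit_ti(motif, profiles)
        assert res.n_combinations_searched == 495  # 5 site values x 99 h levels
        assert res.err_star < 1e-9
        assert res.params.gamma == pytest.approx(truth.gamma, rel=1e-6)
        assert res.params.lam == pytest.approx(truth.lam, rel=1e-6)
        fit_term, true_term = res.params.inhibitor_terms[0], truth.inhibitor_terms[0]
        assert fit_term.sites == true_term.sites
        assert fit_term.affinity == pytest.approx(true_term.affinity, rel=1e-12)

    def test_optimality_over_grid_spotcheck(self, rng):
        """err_star is minimal over random parameter draws on the model grid."""
        motif = TIMotif("P", "G", ("M1",))
        profiles, _ = generate_ti_dataset(
            SyntheticSpec(motif=motif, seed=7, noise_fraction=0.05))
        res = fit_ti(motif, profiles)
        p = profiles["P"].values
        g = profiles["G"].values
        m = profiles.values_matrix(["M1"])
        med = float(np.median(m[0]))
        hs = h_levels(99)
        for _ in range(100):
            S = int(rng.integers(1, 6))
            u = invert_median_fraction(med, float(hs[rng.integers(99)]), S)
            params = TIParams(float(rng.uniform(0, 1)), float(rng.uniform(0, 1)),
                              (RegulatorTerm("M1", u, S),))
            err = float(np.max(np.abs(predict_ti(params, p, g, m).residuals)))
            assert res.err_star <= err + 1e-12

    def test_scaling_covariance(self):
        """Scaling all profiles by a > 0 scales ERR by a, leaves MODER and rates."""
        motif = TIMotif("P", "G", ("M1",))
        profiles, _ = generate_ti_dataset(
            SyntheticSpec(motif=motif, seed=3, noise_fraction=0.02))
        res = fit_ti(motif, profiles)
        a = 3.7
        scaled = profiles.map_values(AffineMap(a, 0.0))
        res2 = fit_ti(motif, scaled)
        assert res2.err_star == pytest.approx(a * res.err_star, rel=1e-6)
        assert res2.moder == pytest.approx(res.moder, rel=1e-6)
        assert res2.params.gamma == pytest.approx(res.params.gamma, rel=1e-6)
        assert res2.params.lam == pytest.approx(res.params.lam, rel=1e-6)
        # affinity rescales inversely with the profile scale
        assert res2.params.inhibitor_terms[0].affinity == pytest.approx(
            res.params.inhibitor_terms[0].affinity / a, rel=1e-6)

    def test_summary_mentions_key_quantities(self):
        motif = TIMotif("P", "G", ("M1",))
        profiles, _ = generate_ti_dataset(SyntheticSpec(motif=motif, seed=0))
        res = fit_ti(motif, profiles)
        text = res.summary()
        for token in ("gamma", "lambda", "ERR", "MODER", "495"):
            assert token in text


class TestFitTD:
    def test_noiseless_recovery(self):
        motif = TDMotif("G", "M", activators=("A1",))
        grid = TimeGrid.uniform(num=21)  # smallest grid admitting n_par = 5
        profiles, truth = generate_td_dataset(
            SyntheticSpec(motif=motif, seed=5, grid=grid))
        res = fit_td(motif, profiles)
        assert res.err_star < 1e-9
        assert res.params.beta == pytest.approx(truth.beta, rel=1e-6)
        assert res.params.v == pytest.approx(truth.v, rel=1e-6)
        assert res.params.kappa == pytest.approx(truth.kappa, rel=1e-6)
        fit_term = res.params.activator_terms[0]
        true_term = truth.activator_terms[0]
        assert fit_term.sites == true_term.sites
        assert fit_term.affinity == pytest.approx(true_term.affinity, rel=1e-12)

    def test_no_activator_warns(self):
        motif = TDMotif("G", "M", repressors=("R1",))
        grid = TimeGrid.uniform(num=21)
        rng = np.random.default_rng(0)
        from mirmotif import ExpressionProfile, ProfileSet
        profiles = ProfileSet(grid)
        for sid, role in [("G", "mRNA"), ("M", "miRNA"), ("R1", "protein")]:
            profiles.add(ExpressionProfile(sid, role, rng.uniform(0.5, 2.0, 21), grid))
        with pytest.warns(RuntimeWarning, match="activator"):
            fit_td(motif, profiles)

    def test_grid_cap(self):
        motif = TDMotif("G", "M", repressors=("R1",), activators=("A1",))
        grid = TimeGrid.uniform(num=31)
        profiles, _ = generate_td_dataset(SyntheticSpec(motif=motif, seed=1, grid=grid))
        # (5*99)^2 = 245,025 > 1e5 must refuse; default s=60 for k=2 fits the cap
        with pytest.raises(GridCapError):
            fit_td(motif, profiles, FitConfig(s=99))


def test_parsimony_override_allows_fit():
    motif = TIMotif("P", "G", ("M1", "M2"))
    profiles, _ = generate_ti_dataset(SyntheticSpec(motif=motif, seed=2, s=12))
    config = FitConfig(check_parsimony=False, s=12)
    res = fit_ti(motif, profiles, config)
    assert res.err_star < 1e-9
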