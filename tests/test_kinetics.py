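import numpy as np
import pytest

from mirmotif import (
    RegulatorTerm,
    TDParams,
    TIParams,
    hill_factor,
    predict_td,
    predict_ti,
    simulate_td_forward,
    simulate_ti_forward,
    td_commitment,
    ti_commitment,
)


def random_ti_setup(rng, k=1, q=19):
    g = rng.uniform(0.2, 3.0, size=q)
    m = rng.uniform(0.2, 3.0, size=(k, q))
    terms = tuple(
        RegulatorTerm(f"M{i}", affinity=float(rng.uniform(0.1, 2.0)),
                      sites=int(rng.integers(1, 6)))
        for i in range(k)
    )
    params = TIParams(gamma=float(rng.uniform(0.01, 0.8)),
                      lam=float(rng.uniform(0.05, 1.0)),
                      inhibitor_terms=terms)
    return params, g, m


def random_td_setup(rng, n_rep=1, n_act=1, q=19):
    m = rng.uniform(0.2, 3.0, size=q)
    rep_levels = [rng.uniform(0.2, 3.0, size=q) for _ in range(n_rep)]
    act_levels = [rng.uniform(0.2, 3.0, size=q) for _ in range(n_act)]
    mk = lambda i, tag: RegulatorTerm(f"{tag}{i}", affinity=float(rng.uniform(0.1, 2.0)),
                                      sites=int(rng.integers(1, 6)))
    params = TDParams(
        beta=float(rng.uniform(0.01, 0.4)),
        v=float(rng.uniform(0.01, 0.2)),
        kappa=float(rng.uniform(0.1, 1.0)),
        repressor_terms=tuple(mk(i, "R") for i in range(n_rep)),
        activator_terms=tuple(mk(i, "A") for i in range(n_act)),
    )
    return params, m, rep_levels, act_levels


class TestHillAndCommitments:
    def test_hill_examples(self):
        assert hill_factor(0.0, 1.0, 3) == 1.0
        assert hill_factor(1.0, 1.0, 1) == 0.5
        assert hill_factor(1.0, 1.0, 2) == 0.25

    def test_hill_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            hill_factor(-0.1, 1.0, 1)
        with pytest.raises(ValueError):
            hill_factor(1.0, 0.0, 1)

    def test_hill_monotone_decreasing(self, rng):
        for _ in range(100):
            level = rng.uniform(0.1, 5.0)
            u = rng.uniform(0.1, 3.0)
            S = int(rng.integers(1, 5))
            base = hill_factor(level, u, S)
            assert hill_factor(level * 1.01, u, S) < base
            assert hill_factor(level, u * 1.01, S) < base
            assert hill_factor(level, u, S + 1) < base

    def test_ti_commitment(self):
        assert ti_commitment((), []) == 1.0
        term = RegulatorTerm("M1", 1.0, 1)
        assert ti_commitment((term,), [1.0]) == hill_factor(1.0, 1.0, 1)
        t2 = RegulatorTerm("M2", 1.0, 2)
        # factors 0.5 and 0.25 multiply
        assert ti_commitment((term, t2), [1.0, 1.0]) == pytest.approx(0.125)

    def test_ti_commitment_length_mismatch(self):
        with pytest.raises(ValueError):
            ti_commitment((RegulatorTerm("M", 1.0, 1),), [])

    def test_td_commitment_examples(self):
        r = RegulatorTerm("R", 1.0, 1)   # factor 0.5 at level 1
        a = RegulatorTerm("A", 1.0, 2)   # factor 0.25 at level 1
        assert td_commitment((r,), (a,), [1.0], [1.0]) == pytest.approx(0.375)
        # no activators: empty ACT product is 1, so F == 0 structurally
        assert td_commitment((r,), (), [1.0], []) == 0.0
        # strong activation drives F toward REP
        strong = RegulatorTerm("A", 1e6, 1)
        assert td_commitment((), (strong,), [], [1.0]) == pytest.approx(1.0, abs=1e-5)

    def test_commitment_ranges(self, rng):
        for _ in range(100):
            params, g, m = random_ti_setup(rng, k=2, q=5)
            h = ti_commitment(params.inhibitor_terms, list(m))
            assert np.all(h > 0) and np.all(h <= 1)
            tdp, mm_, rep, act = random_td_setup(rng, q=5)
            f = td_commitment(tdp.repressor_terms, tdp.activator_terms, rep, act)
            assert np.all(f >= 0) and np.all(f < 1)


class TestForwardSimulation:
    def test_no_dynamics(self):
        p = simulate_ti_forward(TIParams(0.0, 0.0), np.ones(5), np.zeros((0, 5)), 2.0)
        np.testing.assert_allclose(p, 2.0)

    def test_geometric_decay(self):
        gamma = 0.3
        p = simulate_ti_forward(TIParams(gamma, 0.0), np.ones(6), np.zeros((0, 6)), 1.5)
        np.testing.assert_allclose(p, 1.5 * (1 - gamma) ** np.arange(6), atol=1e-12)

    def test_td_decay_and_structural_zero(self, rng):
        beta = 0.2
        m = np.zeros(6)
        g = simulate_td_forward(TDParams(beta, 0.0, 0.0), m, [], [], 2.0)
        np.testing.assert_allclose(g, 2.0 * (1 - beta) ** np.arange(6), atol=1e-12)
        # kappa > 0 but no activators: F == 0, still pure decay
        m = rng.uniform(0.5, 1.5, size=6)
        v = 0.05
        g2 = simulate_td_forward(TDParams(beta, v, 5.0), m, [], [], 2.0)
        expected = np.empty(6)
        expected[0] = 2.0
        for j in range(5):
            expected[j + 1] = expected[j] * (1 - beta - v * m[j])
        np.testing.assert_allclose(g2, expected, atol=1e-12)

    def test_large_gamma_warns(self):
        with pytest.warns(RuntimeWarning, match="gamma"):
            simulate_ti_forward(TIParams(1.2, 0.0), np.ones(4), np.zeros((0, 4)), 1.0)


class TestPredictors:
    def test_trivial_specializations(self):
        p = np.array([1.0, 2.0, 4.0, 3.0])
        g = np.ones(4)
        pred = predict_ti(TIParams(0.0, 0.0), p, g, np.zeros((0, 4)))
        np.testing.assert_allclose(pred.predicted, p[0])
        np.testing.assert_allclose(pred.residuals, p[1:] - p[0])
        # H == 1, gamma = 0: p^(t_{j+1}) = p(t_1) + lambda * sum g
        lam = 0.5
        pred2 = predict_ti(TIParams(0.0, lam), p, g, np.zeros((0, 4)))
        np.testing.assert_allclose(pred2.predicted, p[0] + lam * np.cumsum(g)[:-1])

    def test_td_trivial(self):
        g = np.array([2.0, 1.0, 3.0])
        pred = predict_td(TDParams(0.0, 0.0, 0.0), g, np.ones(3), [], [])
        np.testing.assert_allclose(pred.predicted, g[0])

    def test_ti_telescoping_identity(self, rng):
        """Forward simulation and cumulative-sum predictor agree exactly."""
        worst = 0.0
        for _ in range(100):
            params, g, m = random_ti_setup(rng, k=int(rng.integers(0, 3)), q=12)
            p = simulate_ti_forward(params, g, m, float(rng.uniform(0.5, 2.0)))
            pred = predict_ti(params, p, g, m)
            scale = np.max(np.abs(p)) or 1.0
            worst = max(worst, np.max(np.abs(pred.residuals)) / scale)
        assert worst < 1e-10

    def test_td_telescoping_identity(self, rng):
        worst = 0.0
        for _ in range(100):
            params, m, rep, act = random_td_setup(rng, q=12)
            g = simulate_td_forward(params, m, rep, act, float(rng.uniform(0.5, 2.0)))
            pred = predict_td(params, g, m, rep, act)
            scale = np.max(np.abs(g)) or 1.0
            worst = max(worst, np.max(np.abs(pred.residuals)) / scale)
        assert worst < 1e-10

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_ti(TIParams(0.1, 0.1), np.ones(4), np.ones(5), np.zeros((0, 5)))


def test_regulator_term_validation():
    with pytest.raises(ValueError):
        RegulatorTerm("M", affinity=-1.0, sites=1)
    with pytest.raises(ValueError):
        RegulatorTerm("M", affinity=1.0, sites=0)
    with pytest.raises(ValueError):
        RegulatorTerm("M", affinity=1.0, sites=6)  # above default S_max = 5
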