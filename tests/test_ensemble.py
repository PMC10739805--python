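import numpy as np
import pandas as pd
import pytest

from emtdyn.circuit import (
    ACTIVATION,
    INHIBITION,
    Edge,
    GeneCircuit,
    KineticParameters,
    circuit_rhs,
    shifted_hill,
)
from emtdyn.ensemble import (
    EnsembleConfig,
    SteadyStateEnsemble,
    classify_states,
    find_steady_states,
    perturb_ensemble,
    run_ensemble,
    sample_parameters,
    z_normalize,
)
from emtdyn.errors import ConfigError, DegenerateEnsembleError


class TestSampling:
    def test_parameter_ranges(self, circuit):
        rng = np.random.default_rng(0)
        cfg = EnsembleConfig(n_models=1)
        for _ in range(300):
            p = sample_parameters(circuit, cfg, rng)
            assert np.all((p.g >= 1) & (p.g <= 100))
            assert np.all((p.k >= 0.1) & (p.k <= 1))
            assert np.all((p.lam_raw >= 1) & (p.lam_raw <= 100))
            assert np.all(np.isin(p.hill_n, np.arange(1, 7)))
            assert np.all(p.b0 > 0)

    def test_inhibitory_effective_fold_change_reciprocal(self, circuit):
        rng = np.random.default_rng(1)
        cfg = EnsembleConfig(n_models=1)
        _, _, sign = circuit.edge_arrays()
        lam = np.vstack(
            [sample_parameters(circuit, cfg, rng).lam_eff for _ in range(500)]
        )
        inh = lam[:, sign < 0]
        act = lam[:, sign > 0]
        assert np.all((inh >= 0.01) & (inh <= 1.0))
        assert np.all((act >= 1.0) & (act <= 100.0))

    def test_degenerate_range_rejected(self, circuit):
        with pytest.raises(ConfigError, match="degenerate"):
            EnsembleConfig(g_min=10, g_max=1).validate()


def _unregulated_params():
    c = GeneCircuit(["A"], [])
    p = KineticParameters(c, g=[2.0], k=[0.5], lam_raw=np.empty(0),
                          hill_n=np.empty(0), b0=np.empty(0))
    return c, p


def _toggle_circuit():
    return GeneCircuit(["A", "B"], [Edge("A", "B", INHIBITION), Edge("B", "A", INHIBITION)])


def _toggle_nullcline_roots(g, k, lam, n, b0):
    """Brute-force oracle: stable fixed points of the symmetric 2-node toggle.

    A* = (g/k) H(B), so fixed points solve B = (g/k) H((g/k) H(B)).  Roots
    are located by sign changes on a fine grid and polished by bisection;
    stability from the 2x2 Jacobian.
    """
    from scipy.optimize import brentq

    scale = g / k

    def a_of_b(b):
        return scale * shifted_hill(b, b0, n, lam)

    def f(b):
        return b - scale * shifted_hill(a_of_b(b), b0, n, lam)

    grid = np.linspace(1e-6, scale * 1.2, 20001)
    vals = np.array([f(b) for b in grid])
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    stable = []
    for b in roots:
        a = a_of_b(b)
        eps = 1e-7
        dh_a = (shifted_hill(a + eps, b0, n, lam) - shifted_hill(a - eps, b0, n, lam)) / (2 * eps)
        dh_b = (shifted_hill(b + eps, b0, n, lam) - shifted_hill(b - eps, b0, n, lam)) / (2 * eps)
        J = np.array([[-k, g * dh_b], [g * dh_a, -k]])
        if np.all(np.real(np.linalg.eigvals(J)) < 0):
            stable.append((a, b))
    return stable


class TestFindSteadyStates:
    def test_monostable_unregulated_node(self):
        c, p = _unregulated_params()
        cfg = EnsembleConfig(n_models=1, n_initial_conditions=100)
        states = find_steady_states(c, p, cfg, np.random.default_rng(0))
        assert len(states) == 1
        assert states[0].levels[0] == pytest.approx(4.0, rel=1e-4)
        assert states[0].multiplicity == 100

    def test_symmetric_toggle_bistable_matches_nullcline_oracle(self):
        g, k, lam_raw, n, b0 = 2.0, 1.0, 100.0, 4, 1.0  # lam_eff = 0.01
        c = _toggle_circuit()
        p = KineticParameters(c, g=[g, g], k=[k, k], lam_raw=[lam_raw, lam_raw],
                              hill_n=[n, n], b0=[b0, b0])
        oracle = _toggle_nullcline_roots(g, k, 1.0 / lam_raw, n, b0)
        assert len(oracle) == 2
        cfg = EnsembleConfig(n_models=1, n_initial_conditions=200)
        states = find_steady_states(c, p, cfg, np.random.default_rng(3))
        assert len(states) == 2
        found = sorted(tuple(s.levels) for s in states)
        expected = sorted(oracle)
        for f_, e_ in zip(found, expected):
            assert np.allclose(f_, e_, rtol=1e-3)
        # mirror images of each other
        assert np.allclose(sorted(found[0]), sorted(found[1]), rtol=1e-3)

    def test_states_satisfy_residual_bound(self, circuit, small_ensemble):
        cfg = small_ensemble.config
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = sample_parameters(circuit, cfg, rng)
            for s in find_steady_states(circuit, p, cfg, rng):
                res = np.max(np.abs(circuit_rhs(s.levels, circuit, p)))
                assert res <= cfg.eps_conv * max(1.0, np.max(np.abs(s.levels)))


class TestRunEnsemble:
    def test_model_ids_and_counts(self, small_ensemble):
        cfg = small_ensemble.config
        ids = small_ensemble.solutions["model_id"]
        assert ids.between(1, cfg.n_models).all()
        assert (small_ensemble.solutions.groupby("model_id").size()
                <= cfg.max_states_per_model).all()
        per_model_mult = small_ensemble.solutions.groupby("model_id")["multiplicity"].sum()
        assert (per_model_mult <= cfg.n_initial_conditions).all()

    def test_seed_determinism_bitwise(self, circuit):
        cfg = EnsembleConfig(n_models=40, seed=5)
        a = run_ensemble(circuit, cfg)
        b = run_ensemble(circuit, cfg)
        pd.testing.assert_frame_equal(a.solutions, b.solutions)
        assert classify_states(a).fractions == classify_states(b).fractions

    def test_mono_and_multistable_models_coexist(self, small_ensemble):
        """Regression fixture of the built ensemble: a substantial share of
        models is monostable and a substantial share multistable."""
        counts = small_ensemble.solutions.groupby("model_id").size()
        mono = (counts == 1).mean()
        assert 0.2 < mono < 0.8
        assert (counts > 1).any()


class TestZNormalize:
    def test_equation_on_simple_column(self, circuit):
        # z on log2 levels with population SD: [1, 2, 4] -> [-1.2247, 0, 1.2247]
        cfg = EnsembleConfig(n_models=3)
        sol = pd.DataFrame({
            "model_id": [1, 2, 3], "multiplicity": [1, 1, 1],
            "SMAD3": [1.0, 2.0, 4.0], "KLF4": [1.0, 2.0, 4.0],
            "PPARG": [1.0, 2.0, 4.0],
        })
        ens = SteadyStateEnsemble(circuit, cfg, sol)
        z = z_normalize(ens)
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        for node in circuit.nodes:
            assert np.allclose(z.solutions[f"z_{node}"], expected, atol=1e-6)
            assert z.solutions[f"z_{node}"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_z_columns_mean_zero_unit_sd(self, small_ensemble):
        for node in small_ensemble.circuit.nodes:
            col = small_ensemble.solutions[f"z_{node}"]
            assert col.mean() == pytest.approx(0.0, abs=1e-9)
            assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_rejected(self, circuit):
        cfg = EnsembleConfig(n_models=2)
        sol = pd.DataFrame({
            "model_id": [1, 2], "multiplicity": [1, 1],
            "SMAD3": [1.0, 2.0], "KLF4": [3.0, 3.0], "PPARG": [1.0, 2.0],
        })
        with pytest.raises(DegenerateEnsembleError, match="KLF4"):
            z_normalize(SteadyStateEnsemble(circuit, cfg, sol))


def _hand_ensemble(circuit, z_rows, mult=None):
    n = len(z_rows)
    sol = pd.DataFrame({
        "model_id": range(1, n + 1),
        "multiplicity": mult or [1] * n,
        "SMAD3": 1.0, "KLF4": 1.0, "PPARG": 1.0,
    })
    for i, node in enumerate(["SMAD3", "KLF4", "PPARG"]):
        sol[f"z_{node}"] = [r[i] for r in z_rows]
    return SteadyStateEnsemble(circuit, EnsembleConfig(n_models=n), sol)


class TestClassifyStates:
    def test_one_solution_per_quadrant(self, circuit):
        # rows are (z_SMAD3, z_KLF4, z_PPARG)
        ens = _hand_ensemble(circuit, [(-1, 0, 1), (1, 0, -1), (-1, 0, -1), (1, 0, 1)])
        f = classify_states(ens)
        assert f.fractions == {"E": 0.25, "M": 0.25, "DN": 0.25, "DP": 0.25}

    def test_matches_quadrant_enumeration(self, circuit):
        rows = [(-2, 0, 1), (0.5, 0, 2), (1, 0, 1), (-1, 0, -1), (2, 0, -3), (-0.1, 0, 0.1)]
        ens = _hand_ensemble(circuit, rows)
        f = classify_states(ens, weighted=False)
        # brute-force quadrant membership by hand: E: zP>0 & zS<=0, etc.
        counts = {"E": 0, "M": 0, "DN": 0, "DP": 0}
        for zs, _, zp in rows:
            if zp > 0 and zs <= 0:
                counts["E"] += 1
            elif zp <= 0 and zs > 0:
                counts["M"] += 1
            elif zp <= 0:
                counts["DN"] += 1
            else:
                counts["DP"] += 1
        for k, v in counts.items():
            assert f.fractions[k] == pytest.approx(v / len(rows))

    def test_multiplicity_weighting(self, circuit):
        ens = _hand_ensemble(circuit, [(-1, 0, 1), (1, 0, -1)], mult=[3, 1])
        f = classify_states(ens)  # weighted by default
        assert f.fractions["E"] == pytest.approx(0.75)
        assert f.fractions["M"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self, small_ensemble):
        for weighted in (True, False):
            f = classify_states(small_ensemble, weighted=weighted)
            assert sum(f.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_marker_rejected(self, small_ensemble):
        with pytest.raises(KeyError):
            classify_states(small_ensemble, e_marker="NOPE")


class TestSymmetryAndPerturbation:
    def test_symmetric_toggle_fraction_symmetry(self):
        """The two single-high states of a symmetric toggle are equally likely
        up to binomial sampling error."""
        c = _toggle_circuit()
        cfg = EnsembleConfig(n_models=600, seed=21)
        ens = run_ensemble(c, cfg)
        za = ens.solutions["z_A"].to_numpy()
        zb = ens.solutions["z_B"].to_numpy()
        w = ens.solutions["multiplicity"].to_numpy(dtype=float)
        tot = w.sum()
        fa = float(w[(za > 0) & (zb <= 0)].sum() / tot)
        fb = float(w[(zb > 0) & (za <= 0)].sum() / tot)
        n_sol = len(ens.solutions)
        se = np.sqrt(2 * fa * (1 - fa) / n_sol)
        assert abs(fa - fb) <= 3 * se

    def test_perturbation_shifts_mean_z_monotonically(self, circuit):
        cfg = EnsembleConfig(n_models=150, seed=13)
        control = run_ensemble(circuit, cfg)
        for node in circuit.nodes:
            oe = perturb_ensemble(circuit, cfg, node, "OE", control=control)
            de = perturb_ensemble(circuit, cfg, node, "DE", control=control)
            zc = control.solutions[f"z_{node}"].mean()
            assert oe.ensemble.solutions[f"z_{node}"].mean() >= zc
            assert de.ensemble.solutions[f"z_{node}"].mean() <= zc

    def test_perturbation_input_validation(self, circuit):
        cfg = EnsembleConfig(n_models=5, seed=0)
        with pytest.raises(KeyError):
            perturb_ensemble(circuit, cfg, "NOPE", "OE")
        with pytest.raises(ConfigError):
            perturb_ensemble(circuit, cfg, "SMAD3", "sideways")
        with pytest.raises(ConfigError):
            perturb_ensemble(circuit, cfg, "SMAD3", "OE", fold=1.0)
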