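import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzfd import (
    GridSpec,
    ModelSpec,
    caputo_weights,
    explicit_step,
    explicit_step_regrouped,
    scheme_coefficients,
    solve_crisp,
    solve_fuzzy,
)
from fuzzfd.experiments import ExperimentConfig, build_fuzzy_model
from fuzzfd.oracle import classical_heat_exact


def classical_ftcs(ic_vals, s, n_steps, bc_left=0.0, bc_right=0.0):
    """Independent forward-time centered-space stepper (no reaction, no memory)."""
    u = np.array(ic_vals, dtype=float)
    for _ in range(n_steps):
        new = u.copy()
        new[1:-1] = u[1:-1] + s * (u[2:] - 2 * u[1:-1] + u[:-2])
        new[0], new[-1] = bc_left, bc_right
        u = new
    return u


class TestCaputoWeights:
    def test_memory_vanishes_at_alpha_one(self):
        w = caputo_weights(1.0, 50)
        assert np.all(w.weights == 0.0)

    @pytest.mark.parametrize(
        "alpha, j, expected",
        [(0.9, 1, 0.07177346253629313), (0.5, 3, 0.2679491924311228)],
    )
    def test_direct_values(self, alpha, j, expected):
        w = caputo_weights(alpha, j)
        assert w.b(j) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("alpha", [round(0.1 * k, 1) for k in range(1, 10)])
    def test_weight_properties_hold(self, alpha):
        """Positivity, boundedness, monotone decay, and telescoping identity."""
        n = 10_000
        w = caputo_weights(alpha, n)
        b = w.weights
        assert np.all(b > 0.0) and np.all(b <= 1.0)
        assert np.all(b[:-1] > b[1:])
        # with b_0 = 1: sum_{j=0}^{n-1} (b_j - b_{j+1}) = 1 - b_n
        full = np.concatenate([[1.0], b])
        assert np.sum(full[:-1] - full[1:]) == pytest.approx(1.0 - w.b(n), abs=1e-12)

    def test_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            caputo_weights(0.0, 5)
        with pytest.raises(ValueError):
            caputo_weights(1.2, 5)


class TestSchemeCoefficients:
    @pytest.mark.parametrize(
        "alpha, dt, dx, expected",
        [
            (1.0, 0.01, 0.5, 0.04),
            (0.9, 0.01, 0.5, 0.06031157435218588),
            (0.5, 0.01, 0.1, 8.862269254527579),
        ],
    )
    def test_diffusion_number(self, alpha, dt, dx, expected):
        grid = GridSpec(L=dx * 4, T=dt * 2, dx=dx, dt=dt, alpha=alpha)
        coeff = scheme_coefficients(grid)
        assert coeff.s == pytest.approx(expected, rel=1e-10)
        assert coeff.s == pytest.approx(coeff.rho / dx ** 2, rel=1e-14)

    def test_grid_requires_whole_steps(self):
        with pytest.raises(ValueError):
            GridSpec(L=1.0, T=0.05, dx=0.3, dt=0.01, alpha=0.9)


class TestExplicitStep:
    def test_uniform_field_without_reaction_is_preserved(self):
        grid = GridSpec(L=1.0, T=0.01, dx=0.2, dt=0.01, alpha=0.8)
        coeff = scheme_coefficients(grid)
        w = caputo_weights(0.8, 1)
        u = np.full((2, 6), 3.7)
        new = explicit_step(u, 0, coeff, w, lambda x, t: 0.0 * x, x=grid.x_nodes, dt=grid.dt)
        assert new == pytest.approx(np.full(4, 3.7), rel=1e-14)

    def test_single_step_of_worked_example(self):
        # IC e^{-x}, alpha=0.9, dx=0.5, dt=0.01, k(t)=t^2 -> k=0 at t=0;
        # frozen one-step value at x=4 from the update formula
        grid = GridSpec(L=8.0, T=0.01, dx=0.5, dt=0.01, alpha=0.9)
        coeff = scheme_coefficients(grid)
        w = caputo_weights(0.9, 1)
        x = grid.x_nodes
        u = np.empty((2, len(x)))
        u[0] = np.exp(-x)
        new = explicit_step(u, 0, coeff, w, lambda x, t: t ** 2 + 0.0 * x, x=x, dt=grid.dt)
        i4 = grid.node_index(4.0) - 1  # interior offset
        assert new[i4] == pytest.approx(0.018597601661653824, rel=1e-12)

    def test_step_beyond_available_weights_raises(self):
        grid = GridSpec(L=1.0, T=0.02, dx=0.2, dt=0.01, alpha=0.8)
        coeff = scheme_coefficients(grid)
        w = caputo_weights(0.8, 1)
        u = np.zeros((3, 6))
        with pytest.raises(ValueError, match="exceeds"):
            explicit_step(u, 2, coeff, w, lambda x, t: 0.0 * x, x=grid.x_nodes, dt=grid.dt)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        alpha=st.floats(0.1, 1.0),
        n=st.integers(0, 3),
    )
    def test_regrouped_form_matches_direct_form(self, seed, alpha, n):
        """The telescoped update is algebraically identical to the direct sum."""
        rng = np.random.default_rng(seed)
        grid = GridSpec(L=1.0, T=0.04, dx=0.25, dt=0.01, alpha=alpha)
        coeff = scheme_coefficients(grid)
        w = caputo_weights(alpha, 4)
        hist = rng.uniform(-1, 1, size=(n + 1, 5))
        k_fn = lambda x, t: 0.5 + x * t
        a = explicit_step(hist, n, coeff, w, k_fn, x=grid.x_nodes, dt=grid.dt)
        b = explicit_step_regrouped(hist, n, coeff, w, k_fn, x=grid.x_nodes, dt=grid.dt)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-14)


class TestSolveCrisp:
    def test_zero_ic_stays_zero(self):
        model = ModelSpec(
            ic=lambda x: np.zeros_like(x),
            killing_rate=lambda x, t: 1.0 + 0.0 * x,
            bc_left=lambda t: 0.0,
            bc_right=lambda t: 0.0,
        )
        grid = GridSpec(L=1.0, T=0.05, dx=0.1, dt=0.005, alpha=0.7)
        sol = solve_crisp(model, grid)
        assert np.all(sol.values == 0.0)

    def test_initial_row_is_the_sampled_ic(self):
        model = ModelSpec(
            ic=lambda x: np.cos(x),
            killing_rate=lambda x, t: 0.0 * x,
            bc_left=lambda t: 1.0,
            bc_right=lambda t: np.cos(1.0),
        )
        grid = GridSpec(L=1.0, T=0.01, dx=0.1, dt=0.005, alpha=0.9)
        sol = solve_crisp(model, grid)
        assert sol.values[0] == pytest.approx(np.cos(grid.x_nodes), rel=1e-14)
        assert sol.values[1:, 0] == pytest.approx(np.ones(2))

    @pytest.mark.parametrize("seed", range(20))
    def test_alpha_one_reduces_to_classical_ftcs(self, seed):
        """At alpha=1 with k=0 the solver is node-for-node classical FTCS."""
        rng = np.random.default_rng(seed)
        n_space = int(rng.integers(4, 9))
        n_steps = int(rng.integers(1, 6))
        dx = 1.0 / n_space
        dt = 0.2 * dx ** 2 * float(rng.uniform(0.5, 1.0))
        grid = GridSpec(L=1.0, T=n_steps * dt, dx=dx, dt=dt, alpha=1.0)
        ic_vals = rng.uniform(-1, 1, size=n_space + 1)
        ic_vals[0] = ic_vals[-1] = 0.0
        x_nodes = grid.x_nodes
        model = ModelSpec(
            ic=lambda x: np.interp(x, x_nodes, ic_vals),
            killing_rate=lambda x, t: 0.0 * x,
            bc_left=lambda t: 0.0,
            bc_right=lambda t: 0.0,
        )
        sol = solve_crisp(model, grid)
        expected = classical_ftcs(ic_vals, scheme_coefficients(grid).s, n_steps)
        assert sol.values[-1] == pytest.approx(expected, rel=1e-12, abs=1e-14)

    def test_heat_equation_accuracy(self, heat_config):
        """alpha=1, k=0, sin(pi x) IC: max error vs e^{-pi^2 t} sin(pi x) below 5e-3."""
        from fuzzfd.experiments import build_crisp_model

        grid = heat_config.grid()
        sol = solve_crisp(build_crisp_model(heat_config), grid)
        exact = np.array([classical_heat_exact(x, 0.05) for x in grid.x_nodes])
        assert np.max(np.abs(sol.values[-1] - exact)) < 5e-3

    def test_linearity_in_initial_and_boundary_data(self):
        c = -2.5
        grid = GridSpec(L=1.0, T=0.02, dx=0.1, dt=0.005, alpha=0.6)
        k_fn = lambda x, t: 1.0 + x + t
        base = ModelSpec(
            ic=lambda x: np.sin(np.pi * x) + 0.3,
            killing_rate=k_fn,
            bc_left=lambda t: 0.3,
            bc_right=lambda t: 0.3,
        )
        scaled = ModelSpec(
            ic=lambda x: c * (np.sin(np.pi * x) + 0.3),
            killing_rate=k_fn,
            bc_left=lambda t: c * 0.3,
            bc_right=lambda t: c * 0.3,
        )
        u1 = solve_crisp(base, grid, warn_unstable=False).values
        uc = solve_crisp(scaled, grid, warn_unstable=False).values
        # roundoff accumulates a little on this deliberately coarse grid
        assert uc == pytest.approx(c * u1, rel=1e-10)

    def test_unstable_grid_warns(self):
        grid = GridSpec(L=1.0, T=0.02, dx=0.1, dt=0.01, alpha=1.0)  # s = 1
        model = ModelSpec(
            ic=lambda x: np.sin(np.pi * x),
            killing_rate=lambda x, t: 0.0 * x,
            bc_left=lambda t: 0.0,
            bc_right=lambda t: 0.0,
        )
        with pytest.warns(RuntimeWarning, match="exceeds the stability"):
            solve_crisp(model, grid)


class TestSolveFuzzy:
    def test_core_level_solution_vanishes(self, eq30_config):
        """phi(1, beta) = 0 for the zero-core scale, so the r=1 branch is zero."""
        model = build_fuzzy_model(eq30_config)
        bundle = solve_fuzzy(model, eq30_config.grid(), [1.0], [0.0, 0.5, 1.0])
        for beta in (0.0, 0.5, 1.0):
            assert np.all(bundle.at(1.0, beta).values == 0.0)

    def test_upper_branch_is_negated_lower_branch(self, eq30_config):
        """phi antisymmetry at r=0 plus linearity of the scheme."""
        model = build_fuzzy_model(eq30_config)
        bundle = solve_fuzzy(model, eq30_config.grid(), [0.0], [0.0, 1.0])
        lo = bundle.at(0.0, 0.0).values
        up = bundle.at(0.0, 1.0).values
        assert up == pytest.approx(-lo, rel=1e-12)

    def test_crisp_degenerate_scales_reduce_to_crisp_solve(self):
        import dataclasses

        from fuzzfd import TriangularFuzzyNumber
        from fuzzfd.experiments import build_crisp_model

        cfg = dataclasses.replace(
            ExperimentConfig(), ic_scale=TriangularFuzzyNumber(1.0, 1.0, 1.0)
        )
        bundle = solve_fuzzy(build_fuzzy_model(cfg), cfg.grid(), [0.0, 0.5], [0.0, 1.0])
        crisp = solve_crisp(build_crisp_model(cfg), cfg.grid())
        for key, sol in bundle.solutions.items():
            assert sol.values == pytest.approx(crisp.values, rel=1e-14)

    def test_empty_grids_rejected(self, eq30_config):
        model = build_fuzzy_model(eq30_config)
        with pytest.raises(ValueError, match="non-empty"):
            solve_fuzzy(model, eq30_config.grid(), [], [0.0])

    def test_band_validity_of_worked_example(self, eq30_config):
        model = build_fuzzy_model(eq30_config)
        bundle = solve_fuzzy(
            model, eq30_config.grid(), eq30_config.r_grid, [0.0, 1.0]
        )
        assert bundle.band_valid_at(4.0, 0.05)


class TestSolutionGrid:
    def test_off_node_evaluation_rejected(self, eq30_config):
        from fuzzfd.experiments import build_crisp_model

        sol = solve_crisp(build_crisp_model(eq30_config), eq30_config.grid())
        with pytest.raises(ValueError, match="node"):
            sol.value_at(4.1, 0.05)
        with pytest.raises(ValueError, match="time level"):
            sol.value_at(4.0, 0.013)

    def test_tidy_frame_round_trips(self, heat_config):
        from fuzzfd.experiments import build_crisp_model

        grid = heat_config.grid()
        sol = solve_crisp(build_crisp_model(heat_config), grid)
        frame = sol.to_tidy_frame()
        rebuilt = (
            frame.pivot(index="n", columns="i", values="u").to_numpy()
        )
        assert rebuilt == pytest.approx(sol.values, rel=0, abs=0)
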