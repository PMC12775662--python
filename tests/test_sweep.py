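"""Retention grids, panel tallies, boundary extraction, cross-validation."""

import math

import numpy as np
import pytest

from embersim import (
    GridSpec,
    ModelParams,
    ParameterError,
    RetentionGrid,
    classify_cells,
    count_loss_majority_panels,
    cross_validate,
    default_nu_axis,
    default_theta_axis,
    discontinuity_probability,
    find_boundary,
    grid_to_dataframe,
    sweep_grid,
)


def _make_grid(p_r, theta=None, nu=None, tau=4.0, eta_max=43.0):
    p_r = np.asarray(p_r, dtype=float)
    theta = np.arange(1.0, p_r.shape[1] + 1) if theta is None else theta
    nu = np.arange(0.0, p_r.shape[0]) * 0.1 if nu is None else nu
    spec = GridSpec(theta_values=theta, nu_values=nu, tau=tau, eta_max=eta_max)
    return RetentionGrid(spec, p_r, tau * math.log(eta_max))


class TestSweepGrid:
    def test_zero_variability_row_is_a_step_at_dt_max(self):
        spec = GridSpec(
            theta_values=np.linspace(1, 20, 39),  # includes theta = 15.0
            nu_values=np.array([0.0]),
            tau=4, eta_max=43,
        )
        grid = sweep_grid(spec)
        theta = spec.theta_values
        dt_max = 4 * math.log(43)
        assert np.all(grid.p_r[0, theta <= dt_max] == 1.0)
        assert np.all(grid.p_r[0, theta > dt_max] == 0.0)

    def test_engines_agree_exactly_without_stochasticity(self):
        axes = dict(theta_values=np.array([4.0]), nu_values=np.array([0.0]),
                    tau=4.0, eta_max=43.0)
        ana = sweep_grid(GridSpec(**axes, engine="analytical"))
        num = sweep_grid(GridSpec(**axes, engine="numerical", seed=5))
        assert ana.p_r[0, 0] == num.p_r[0, 0] == 1.0

    def test_single_cell_worked_value(self):
        spec = GridSpec(
            theta_values=np.array([4.0]), nu_values=np.array([0.3]),
            tau=4, eta_max=9,
        )
        assert sweep_grid(spec).p_r[0, 0] == pytest.approx(0.992, abs=5e-4)

    def test_analytical_grid_monotone_in_both_axes(self):
        grid = sweep_grid(
            GridSpec(default_theta_axis(30), default_nu_axis(30), tau=4,
                     eta_max=43)
        )
        assert np.all(np.diff(grid.p_r, axis=1) <= 1e-12)  # along theta
        assert np.all(np.diff(grid.p_r, axis=0) <= 1e-12)  # along nu

    def test_numerical_grid_seeded_reproducibly(self):
        spec = GridSpec(
            theta_values=np.array([6.0, 10.0]), nu_values=np.array([0.5]),
            tau=4, eta_max=12, engine="numerical", seed=11,
        )
        assert np.array_equal(sweep_grid(spec).p_r, sweep_grid(spec).p_r)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(theta_values=np.array([]), nu_values=np.array([0.1])),
            dict(theta_values=np.array([2.0, 1.0]), nu_values=np.array([0.1])),
            dict(theta_values=np.array([1.0]), nu_values=np.array([0.1]),
                 engine="bogus"),
            dict(theta_values=np.array([1.0]), nu_values=np.array([0.1]),
                 engine="numerical"),  # missing seed
        ],
    )
    def test_invalid_spec(self, kwargs):
        kwargs.setdefault("tau", 4.0)
        kwargs.setdefault("eta_max", 9.0)
        with pytest.raises(ParameterError):
            GridSpec(**kwargs)


class TestClassifyCells:
    def test_all_retention(self):
        s = classify_cells(_make_grid(np.ones((3, 4))))
        assert s.n_loss_cells == 0
        assert s.n_retention_cells == 12
        assert not s.loss_majority

    def test_all_loss(self):
        s = classify_cells(_make_grid(np.zeros((3, 4))))
        assert s.n_retention_cells == 0
        assert s.loss_majority

    def test_transition_band_is_informational(self):
        s = classify_cells(_make_grid([[0.0, 0.2, 0.6, 1.0]]))
        assert s.n_loss_cells == 2
        assert s.n_retention_cells == 2
        assert s.n_transition_cells == 2
        assert s.n_loss_cells + s.n_retention_cells == 4

    def test_invalid_cut(self):
        with pytest.raises(ParameterError):
            classify_cells(_make_grid(np.ones((2, 2))), loss_cut=1.5)


class TestPanelTally:
    def test_single_short_memory_panel_is_loss_majority(self):
        # tau=1, pool 3: dt_max ~ 1.1 yr, nearly every (theta, nu) cell dies
        assert count_loss_majority_panels(tau_values=[1], eta_values=[3]) == 1

    def test_resilient_panel_is_not_loss_majority(self):
        # tau=16, pool 60: dt_max ~ 65 yr dwarfs every theta; at modest nu
        # the exceedance tail is negligible so retention dominates
        n = count_loss_majority_panels(
            tau_values=[16], eta_values=[60],
            nu_values=np.linspace(0.1, 0.5, 20),
        )
        assert n == 0

    def test_fig1_loss_fraction_left_of_dt_max(self):
        grid = sweep_grid(
            GridSpec(default_theta_axis(), default_nu_axis(), tau=4, eta_max=43)
        )
        left = grid.grid_spec.theta_values < 15
        frac = (grid.p_r[:, left] < 0.5).mean()
        assert 0.55 <= frac <= 0.75  # "approximately two-thirds"


class TestFindBoundary:
    def test_boundary_positions_match_reported_narrative(self):
        grid = sweep_grid(
            GridSpec(np.linspace(1, 20, 1000),
                     np.array([0.001, 0.32, 0.88, 2.0]), tau=4, eta_max=43)
        )
        b = find_boundary(grid)["boundary_theta"].to_numpy()
        assert round(b[0]) == 15
        assert 7 <= b[1] <= 10  # "about nine years"
        assert 3.5 <= b[2] <= 6  # "approximately five years"
        assert 2 <= b[3] <= 4  # "around three years"

    def test_no_crossing_reported_as_nan(self):
        grid = _make_grid(np.full((2, 5), 0.9))
        assert find_boundary(grid)["boundary_theta"].isna().all()

    def test_interpolation_is_linear_between_cells(self):
        grid = _make_grid([[1.0, 0.75, 0.25, 0.0]])
        b = find_boundary(grid)
        # crossing halfway between theta=2 (0.75) and theta=3 (0.25)
        assert b["boundary_theta"].iloc[0] == pytest.approx(2.5)
        assert not b["non_monotone"].iloc[0]

    def test_non_monotone_row_flagged_first_crossing(self):
        grid = _make_grid([[1.0, 0.2, 0.8, 0.1]])
        b = find_boundary(grid)
        assert b["non_monotone"].iloc[0]
        assert 1.0 < b["boundary_theta"].iloc[0] < 2.0

    def test_transition_zone_in_tau_widens_with_variability(self):
        # at theta=4, pool of 8: the tau-span between near-certain retention
        # and near-certain loss grows with nu
        from scipy.optimize import brentq

        def pr(nu, tau):
            p_d = discontinuity_probability(4.0, nu, tau, 8.0)
            return math.exp(250 * math.log1p(-p_d)) if p_d < 1 else 0.0

        widths = []
        for nu in (0.1, 0.3, 0.6, 1.0, 2.0):
            lo = brentq(lambda t: pr(nu, t) - 0.05, 0.01, 200)
            hi = brentq(lambda t: pr(nu, t) - 0.95, 0.01, 200)
            widths.append(hi - lo)
        assert np.all(np.diff(widths) > 0)

    def test_doubling_variability_roughly_quadruples_expert_need(self):
        # at theta=4, tau=4 the pool needed to hold P_r = 0.5 grows about
        # fourfold per doubling of nu; nu = 0.6 needs ~14 experts
        from scipy.optimize import brentq

        def pr(nu, eta):
            p_d = discontinuity_probability(4.0, nu, 4.0, eta)
            return math.exp(250 * math.log1p(-p_d)) if p_d < 1 else 0.0

        def eta_needed(nu):
            return brentq(lambda e: pr(nu, e) - 0.5, 1.0001, 1e7)

        assert 12 <= eta_needed(0.6) <= 17
        for nu in (0.3, 0.6):
            ratio = eta_needed(2 * nu) / eta_needed(nu)
            assert 2 <= ratio <= 9


class TestCrossValidation:
    def test_degenerate_points_agree_exactly(self):
        points = [
            ModelParams(theta=4, nu=0, eta_max=43, tau=4),
            ModelParams(theta=16, nu=0, eta_max=43, tau=4),
        ]
        report = cross_validate(points, K=111, seed=0)
        assert (report.table["discrepancy"] == 0.0).all()
        assert report.pass_fraction == 1.0

    def test_stochastic_point_within_tolerance(self):
        report = cross_validate(
            [ModelParams(theta=4, nu=0.3, eta_max=9, tau=4)], K=111, seed=2
        )
        assert not report.table["flagged"].iloc[0]

    def test_table_contents(self):
        report = cross_validate(
            [ModelParams(theta=6, nu=0.5, eta_max=12, tau=4)], K=111, seed=4
        )
        row = report.table.iloc[0]
        assert set(report.table.columns) >= {
            "theta", "nu", "p_r_numerical", "p_r_analytical", "std_error",
            "discrepancy", "flagged",
        }
        assert row["discrepancy"] == pytest.approx(
            abs(row["p_r_numerical"] - row["p_r_analytical"])
        )


class TestTidyOutput:
    def test_long_format_round_trip(self):
        grid = sweep_grid(
            GridSpec(np.array([4.0, 8.0]), np.array([0.2, 0.5, 1.0]),
                     tau=4, eta_max=43)
        )
        df = grid_to_dataframe(grid)
        assert len(df) == 6
        assert list(df["theta"].unique()) == [4.0, 8.0]
        wide = df.pivot(index="nu", columns="theta", values="p_r")
        assert np.allclose(wide.to_numpy(), grid.p_r)
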