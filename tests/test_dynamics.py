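"""Community ODE: derivatives, integration, equilibria, stability, basins."""

import numpy as np
import pytest

from cspcoex import (
    CommunityParams,
    CommunityState,
    MatingProbabilities,
    basins,
    community_derivative,
    exclusion_boundary,
    find_equilibria,
    integrate,
    invasion_fitness,
    portrait_export,
    stability_report,
)
from cspcoex.dynamics import _jacobian

from conftest import random_probs


class TestDerivative:
    def test_boundary_equilibrium_is_stationary(self, high_overlap):
        dX, _ = community_derivative(CommunityState(25.0, 0.0), high_overlap)
        assert dX == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self, high_overlap):
        dX, dY = community_derivative(CommunityState(1.0, 1.0), high_overlap)
        assert dX == pytest.approx((13.0 - 1.0 - 0.3) * 1.0, abs=1e-9)
        assert dY == pytest.approx((20.5 - 1.0 - 0.3) * 1.0, abs=1e-9)

    def test_origin_convention(self, high_overlap):
        assert community_derivative(CommunityState(0.0, 0.0), high_overlap) == (
            0.0,
            0.0,
        )

    def test_negative_density_rejected(self, high_overlap):
        with pytest.raises(ValueError):
            community_derivative(CommunityState(-1.0, 1.0), high_overlap)


class TestIntegration:
    @pytest.mark.parametrize("start", [(1.0, 0.0), (0.0, 1.0)])
    def test_single_species_reaches_carrying_density(self, high_overlap, start):
        traj = integrate(CommunityState(*start), high_overlap)
        terminal = traj.terminal
        survivor = terminal.NX if start[0] > 0 else terminal.NY
        assert abs(survivor - 25.0) < 1e-6

    def test_axes_are_invariant(self, low_overlap):
        traj = integrate(CommunityState(7.0, 0.0), low_overlap, horizon=50.0)
        assert np.all(traj.states[:, 1] == 0.0)

    def test_exclusion_regime_ends_on_an_axis(self, high_overlap):
        terminal = integrate(CommunityState(1.0, 1.0), high_overlap).terminal
        assert min(terminal.NX, terminal.NY) == 0.0
        assert max(terminal.NX, terminal.NY) == pytest.approx(25.0, abs=1e-6)

    def test_densities_stay_bounded_and_nonnegative(self, high_overlap):
        traj = integrate(CommunityState(40.0, 35.0), high_overlap, horizon=200.0)
        assert np.all(traj.states >= 0.0)
        bound = max(high_overlap.carrying_density, 40.0) + 1.0
        assert traj.states.max() <= bound

    def test_times_strictly_increasing(self, low_overlap):
        traj = integrate(CommunityState(2.0, 3.0), low_overlap, horizon=100.0)
        assert np.all(np.diff(traj.times) > 0)


class TestStability:
    def test_exclusion_boundary_equilibrium_stable_at_high_overlap(
        self, high_overlap
    ):
        rep = stability_report(CommunityState(25.0, 0.0), high_overlap)
        eig = sorted(e.real for e in rep.eigenvalues)
        assert rep.kind == "boundary_X"
        assert rep.stability == "stable"
        assert eig[0] == pytest.approx(-25.0, abs=1e-6)
        assert eig[1] == pytest.approx(-5.0, abs=1e-6)

    def test_exclusion_boundary_equilibrium_saddle_at_low_overlap(
        self, low_overlap
    ):
        rep = stability_report(CommunityState(25.0, 0.0), low_overlap)
        assert rep.stability == "saddle"
        assert max(e.real for e in rep.eigenvalues) == pytest.approx(7.5, abs=1e-6)

    def test_marginal_exactly_at_threshold(self, caption_probs):
        params = CommunityParams(c=0.7, b=0.3, probs=caption_probs)  # b + c = 1
        rep = stability_report(CommunityState(25.0, 0.0), params)
        assert rep.stability == "marginal"

    def test_non_equilibrium_rejected_with_residual(self, high_overlap):
        with pytest.raises(ValueError, match="residual"):
            stability_report(CommunityState(10.0, 10.0), high_overlap)

    def test_boundary_eigenvalues_match_closed_form(self):
        """Finite-difference Jacobian vs {-r, r(1-c-b)} on random draws."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            params = CommunityParams(
                c=rng.uniform(0.0, 1.0),
                r=rng.uniform(1.0, 50.0),
                b=rng.uniform(0.0, 1.0),
                probs=random_probs(rng),
            )
            nx = params.carrying_density
            J = _jacobian(np.array([nx, 0.0]), params)
            eig = np.sort(np.linalg.eigvals(J).real)
            expected = np.sort(
                [-params.r, params.r * (1 - params.c - params.b)]
            )
            assert np.allclose(eig, expected, atol=1e-6)


class TestInvasionAndBoundary:
    @pytest.mark.parametrize(
        "c, expected", [(0.9, -5.0), (0.4, 7.5), (0.7, 0.0)]
    )
    def test_invader_growth_rate(self, caption_probs, c, expected):
        params = CommunityParams(c=c, probs=caption_probs)
        assert invasion_fitness(params, "Y") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("b, c_star", [(0.3, 0.7), (1.0, 0.0), (0.0, 1.0)])
    def test_critical_overlap_solves_b_plus_c_equals_one(
        self, high_overlap, b, c_star
    ):
        assert exclusion_boundary(high_overlap, b) == pytest.approx(
            c_star, abs=1e-6
        )


class TestEquilibria:
    def test_high_overlap_is_bistable_exclusion(self, high_overlap):
        reports = {r.kind: r for r in find_equilibria(high_overlap)}
        assert reports["origin"].stability == "unstable"
        assert reports["boundary_X"].stability == "stable"
        assert reports["boundary_Y"].stability == "stable"

    def test_low_overlap_has_stable_interior(self, low_overlap):
        reports = find_equilibria(low_overlap)
        interior = [r for r in reports if r.kind == "interior"]
        assert any(r.stability == "stable" for r in interior)

    def test_reports_invariant_under_species_exchange(self, low_overlap):
        direct = find_equilibria(low_overlap)
        swapped = find_equilibria(low_overlap.swapped())
        points = sorted(
            (round(r.state.NX, 5), round(r.state.NY, 5), r.stability)
            for r in direct
        )
        mirrored = sorted(
            (round(r.state.NY, 5), round(r.state.NX, 5), r.stability)
            for r in swapped
        )
        assert points == mirrored

    def test_symmetric_parameters_can_be_bistable(self):
        """Exclusion and coexistence simultaneously stable under symmetry."""
        params = CommunityParams(
            c=0.8,
            b=0.3,
            probs=MatingProbabilities(
                pXX=0.9, pXY=0.05, pYX=0.05, pYY=0.9, qXX=0.9, qYY=0.9
            ),
        )
        reports = find_equilibria(params)
        stable_kinds = {r.kind for r in reports if r.stability == "stable"}
        assert {"boundary_X", "boundary_Y", "interior"} <= stable_kinds


class TestBasins:
    def test_exclusion_regime_partitions_grid_between_axes(self, high_overlap):
        bm = basins(high_overlap, grid=(10, 10), box=(0.0, 30.0, 0.0, 30.0))
        labels = set(bm.labels.ravel())
        assert set(bm.attractors) == {"boundary_X", "boundary_Y"}
        counts = {
            lab: int((bm.labels == lab).sum()) for lab in bm.attractors
        }
        assert counts["boundary_X"] > 0 and counts["boundary_Y"] > 0
        # the origin (a stationary unstable equilibrium) is the only
        # unresolved lattice point
        assert labels <= {"boundary_X", "boundary_Y", "unresolved"}
        assert int((bm.labels == "unresolved").sum()) == 1

    def test_axis_points_assigned_to_their_axis_attractor(self, high_overlap):
        bm = basins(high_overlap, grid=(8, 8), box=(0.0, 30.0, 0.0, 30.0))
        assert set(bm.labels[1:, 0]) == {"boundary_X"}  # NY = 0 row
        assert set(bm.labels[0, 1:]) == {"boundary_Y"}  # NX = 0 column

    def test_coexistence_regime_has_interior_basin(self, low_overlap):
        bm = basins(low_overlap, grid=(6, 6), box=(1.0, 30.0, 1.0, 30.0))
        assert "interior_1" in bm.attractors
        assert int((bm.labels == "interior_1").sum()) > 0

    def test_error_without_stable_equilibrium(self, low_overlap):
        unstable_only = [
            r
            for r in find_equilibria(low_overlap)
            if r.stability != "stable"
        ]
        with pytest.raises(ValueError, match="no stable equilibrium"):
            basins(low_overlap, grid=(3, 3), equilibria=unstable_only)


class TestPortraitExport:
    def test_exclusion_setup_tables(self, high_overlap, tmp_path):
        tables = portrait_export(
            high_overlap, grid=(9, 9), outdir=tmp_path, nullcline_grid=61
        )
        eq = tables["equilibria"]
        assert (eq["stability"] == "stable").sum() == 2
        assert (eq["stability"] != "stable").sum() >= 1
        assert "basins" not in tables
        field = tables["field"]
        at_eq = field[
            (field["NX"].round(6) == 25.0) & (field["NY"] == 0.0)
        ]
        if len(at_eq):
            assert abs(at_eq["dNX_dt"].iloc[0]) < 1e-8
        for name in ("field", "nullclines", "equilibria"):
            assert (tmp_path / f"{name}.csv").exists()

    def test_field_vanishes_at_boundary_equilibrium(self, high_overlap):
        tables = portrait_export(
            high_overlap,
            grid=(2, 2),
            box=(25.0, 26.0, 0.0, 1.0),
            nullcline_grid=11,
        )
        row = tables["field"].iloc[0]  # (25, 0)
        assert row["dNX_dt"] == pytest.approx(0.0, abs=1e-9)
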