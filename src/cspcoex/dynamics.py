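"""ODE community dynamics, equilibria, stability, and basins of attraction.

The two species grow according to

    dN_X/dt = [E_X(N_X, N_Y) - v (N_X + b N_Y)] N_X
    dN_Y/dt = [E_Y(N_X, N_Y) - v (N_Y + b N_X)] N_Y

where ``E_i`` is the expected per-capita fecundity from the mating decision
tree (see :mod:`cspcoex.mating`) and ``v``/``b`` tune intra- and interspecific
resource competition.  Mating happens on a fast timescale relative to the
birth-death dynamics (quasi-stationarity), so ``E_i`` is evaluated at the
instantaneous densities.

Species exclusion corresponds to the boundary equilibria ``B_X = (r/v, 0)``
and ``B_Y = (0, r/v)``.  The Jacobian there has eigenvalues ``{-r,
r (1 - c - b)}``: the exclusion state is locally stable exactly when
``b + c > 1``, i.e. when combined resource competition and reproductive
interference are strong enough to repel a rare invader.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import bisect, root

from .mating import _P_closed, expected_fecundity
from .params import CommunityParams, CommunityState

__all__ = [
    "Trajectory",
    "EquilibriumReport",
    "BasinMap",
    "community_derivative",
    "integrate",
    "find_equilibria",
    "stability_report",
    "invasion_fitness",
    "exclusion_boundary",
    "basins",
    "portrait_export",
]

#: Densities below this are treated as extinct during integration, preventing
#: rescue of atto-scale populations by positive growth terms.
EXTINCTION_FLOOR = 1e-9

#: Eigenvalue real parts within +/- this of zero classify as "marginal".
STABILITY_TOL = 1e-8


# ---------------------------------------------------------------------------
# right-hand side


def _rhs(n: np.ndarray, params: CommunityParams, max_matings: int = 2) -> np.ndarray:
    """Unvalidated growth rates; tolerant of tiny negative finite-difference probes."""
    NX, NY = float(n[0]), float(n[1])
    wX = params.aX * NX
    wY = params.aY * NY
    total = wX + wY
    if total <= 0.0:
        # Origin convention (and guard for probes at/below the origin).
        return np.zeros(2)
    fX = wX / total
    fY = wY / total
    p = params.probs
    PX, _ = _P_closed(fX, fY, p.pXX, p.pXY, p.qXX, max_matings)
    PY, _ = _P_closed(fY, fX, p.pYY, p.pYX, p.qYY, max_matings)
    c, r, v, b = params.c, params.r, params.v, params.b
    EX = ((1.0 - c) + c * PX) * r
    EY = ((1.0 - c) + c * PY) * r
    return np.array(
        [
            (EX - v * (NX + b * NY)) * NX,
            (EY - v * (NY + b * NX)) * NY,
        ]
    )


def community_derivative(
    state: CommunityState, params: CommunityParams, max_matings: int = 2
) -> tuple[float, float]:
    """Growth rates (dN_X/dt, dN_Y/dt) at ``state``.

    The exact origin returns (0, 0) by convention (frequencies are undefined
    there, but the origin is an equilibrium by continuity along the axes).
    """
    if state.total == 0.0:
        return 0.0, 0.0
    EX, EY = expected_fecundity(params, state, max_matings)
    v, b = params.v, params.b
    return (
        (EX - v * (state.NX + b * state.NY)) * state.NX,
        (EY - v * (state.NY + b * state.NX)) * state.NY,
    )


# ---------------------------------------------------------------------------
# integration


@dataclass(frozen=True)
class Trajectory:
    """Time points and the non-negative density path aligned to them."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("trajectory densities must be non-negative")

    @property
    def terminal(self) -> CommunityState:
        return CommunityState(*self.states[-1])


def integrate(
    start: CommunityState,
    params: CommunityParams,
    horizon: float = 1000.0,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    extinction_floor: float = EXTINCTION_FLOOR,
    steady_tol: float = 1e-10,
    max_matings: int = 2,
) -> Trajectory:
    """Integrate the community ODE from ``start`` for ``horizon`` time units.

    Adaptive stiff-capable integration (LSODA).  Two kinds of terminal
    events are monitored: (i) steady state, declared when the derivative
    norm drops below ``steady_tol``; (ii) extinction, when a density falls
    through ``extinction_floor`` from above, in which case that species is
    set to exactly zero and integration resumes on the (invariant) axis.
    """
    if horizon <= 0.0:
        raise ValueError(f"horizon must be > 0, got {horizon!r}")
    y = start.as_array()
    y[y < extinction_floor] = 0.0

    def f(t, y):
        return _rhs(y, params, max_matings)

    def ev_steady(t, y):
        return float(np.linalg.norm(_rhs(y, params, max_matings))) - steady_tol

    ev_steady.terminal = True
    ev_steady.direction = -1

    def make_floor(i):
        def ev(t, y):
            return y[i] - extinction_floor

        ev.terminal = True
        ev.direction = -1
        return ev

    events = [ev_steady, make_floor(0), make_floor(1)]

    t0 = 0.0
    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    for _ in range(8):  # at most a few extinction restarts
        sol = solve_ivp(
            f, (t0, horizon), y, method="LSODA", rtol=rtol, atol=atol, events=events
        )
        if sol.status == -1:
            err = RuntimeError(
                f"integration failed at t={sol.t[-1]:.6g}: {sol.message}"
            )
            err.last_state = CommunityState(*np.maximum(sol.y[:, -1], 0.0))
            raise err
        seg_t, seg_y = sol.t, np.maximum(sol.y.T, 0.0)
        if times and seg_t[0] == times[-1][-1]:
            seg_t, seg_y = seg_t[1:], seg_y[1:]
        times.append(seg_t)
        states.append(seg_y)
        if sol.status == 0:  # reached horizon
            break
        # An event fired: steady state ends the run, extinction restarts it.
        if len(sol.t_events[0]) > 0:
            break
        t0 = sol.t[-1]
        y = np.maximum(sol.y[:, -1], 0.0)
        for i in range(2):
            # Zero the species whose floor event fired (the event leaves it
            # within rounding of the floor, not strictly below it).
            if len(sol.t_events[i + 1]) > 0:
                y[i] = 0.0
        y[y <= extinction_floor] = 0.0
        if t0 >= horizon:
            break
    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    return Trajectory(times=t_all[keep], states=y_all[keep])


# ---------------------------------------------------------------------------
# equilibria and stability


@dataclass(frozen=True)
class EquilibriumReport:
    """An equilibrium point with its Jacobian eigenvalues and stability class."""

    state: CommunityState
    kind: str  # origin | boundary_X | boundary_Y | interior
    eigenvalues: tuple[complex, complex]
    stability: str  # stable | unstable | saddle | marginal
    residual: float


def _jacobian(
    point: np.ndarray, params: CommunityParams, max_matings: int = 2
) -> np.ndarray:
    """Central finite-difference Jacobian, step scaled to density magnitude."""
    scale = params.carrying_density
    J = np.empty((2, 2))
    for j in range(2):
        h = 6e-6 * max(abs(point[j]), 1e-2 * scale)
        ep = np.zeros(2)
        ep[j] = h
        J[:, j] = (
            _rhs(point + ep, params, max_matings) - _rhs(point - ep, params, max_matings)
        ) / (2.0 * h)
    return J


def _classify(eigs: np.ndarray, tol: float = STABILITY_TOL) -> str:
    re = np.real(eigs)
    if np.all(re < -tol):
        return "stable"
    if np.all(re > tol):
        return "unstable"
    if re.max() > tol and re.min() < -tol:
        return "saddle"
    return "marginal"


def stability_report(
    point: CommunityState,
    params: CommunityParams,
    *,
    max_matings: int = 2,
    resid_tol: float | None = None,
    tol: float = STABILITY_TOL,
) -> EquilibriumReport:
    """Classify an equilibrium by the eigenvalues of its Jacobian.

    The Jacobian is computed by central finite differences on the growth
    rates.  The origin (where frequencies are undefined) is probed at an
    epsilon offset of ``1e-8 * r`` along both axes.  A point whose growth
    residual exceeds ``resid_tol`` (default ``1e-6 * r``) is rejected.
    """
    if resid_tol is None:
        resid_tol = 1e-6 * params.r
    n = point.as_array()
    residual = float(np.linalg.norm(_rhs(n, params, max_matings)))
    if residual > resid_tol:
        raise ValueError(
            f"point ({point.NX:.6g}, {point.NY:.6g}) is not an equilibrium: "
            f"residual {residual:.3e} exceeds tolerance {resid_tol:.3e}"
        )
    scale = params.carrying_density
    zero = 1e-6 * scale
    at_origin = point.NX < zero and point.NY < zero
    probe = n
    if at_origin:
        eps = 1e-8 * params.r
        probe = np.array([eps, eps])
        kind = "origin"
    elif point.NY < zero:
        kind = "boundary_X"
    elif point.NX < zero:
        kind = "boundary_Y"
    else:
        kind = "interior"
    eigs = np.linalg.eigvals(_jacobian(probe, params, max_matings))
    eigs = eigs[np.argsort(-np.real(eigs))]
    return EquilibriumReport(
        state=point,
        kind=kind,
        eigenvalues=(complex(eigs[0]), complex(eigs[1])),
        stability=_classify(eigs, tol),
        residual=residual,
    )


def _boundary_density(params: CommunityParams, species: str, max_matings: int) -> float:
    """Single-species equilibrium density E_i(alone) / v."""
    if species == "X":
        state = CommunityState(1.0, 0.0)
        E = expected_fecundity(params, state, max_matings)[0]
    else:
        state = CommunityState(0.0, 1.0)
        E = expected_fecundity(params, state, max_matings)[1]
    return E / params.v


def find_equilibria(
    params: CommunityParams,
    box: tuple[float, float, float, float] | None = None,
    resolution: int = 20,
    *,
    max_matings: int = 2,
    resid_tol: float = 1e-8,
    merge_radius: float | None = None,
) -> list[EquilibriumReport]:
    """All equilibria in ``box`` (default ``[0, 2 r/v]^2``) with stability.

    The origin and the two boundary (exclusion) equilibria are always
    reported.  Interior candidates come from multi-start root-finding on the
    per-capita growth system ``(E_X - v (N_X + b N_Y), E_Y - v (N_Y + b
    N_X))``, de-duplicated within ``merge_radius`` (default ``1e-4 * r/v``)
    and verified against the full growth residual.  An empty interior set is
    a valid outcome.
    """
    scale = params.carrying_density
    if box is None:
        box = (0.0, 2.0 * scale, 0.0, 2.0 * scale)
    if merge_radius is None:
        merge_radius = 1e-4 * scale

    reports = [
        stability_report(CommunityState(0.0, 0.0), params, max_matings=max_matings),
        stability_report(
            CommunityState(_boundary_density(params, "X", max_matings), 0.0),
            params,
            max_matings=max_matings,
        ),
        stability_report(
            CommunityState(0.0, _boundary_density(params, "Y", max_matings)),
            params,
            max_matings=max_matings,
        ),
    ]

    def percap(n: np.ndarray) -> np.ndarray:
        NX, NY = n
        EX, EY = expected_fecundity(
            params, CommunityState(max(NX, 0.0), max(NY, 0.0)), max_matings
        )
        v, b = params.v, params.b
        return np.array([EX - v * (NX + b * NY), EY - v * (NY + b * NX)])

    xs = np.linspace(box[0], box[1], resolution + 2)[1:-1]
    ys = np.linspace(box[2], box[3], resolution + 2)[1:-1]
    margin = 1e-6 * scale
    interior: list[np.ndarray] = []
    for x0 in xs:
        for y0 in ys:
            sol = root(percap, np.array([x0, y0]), method="hybr")
            if not sol.success:
                continue
            cand = sol.x
            if cand[0] <= margin or cand[1] <= margin:
                continue
            if not (
                box[0] - margin <= cand[0] <= box[1] + margin
                and box[2] - margin <= cand[1] <= box[3] + margin
            ):
                continue
            if np.linalg.norm(percap(cand)) > resid_tol * params.r:
                continue
            if any(np.linalg.norm(cand - seen) < merge_radius for seen in interior):
                continue
            interior.append(cand)
    interior.sort(key=lambda p: p[0])
    for cand in interior:
        reports.append(
            stability_report(
                CommunityState(*cand), params, max_matings=max_matings
            )
        )
    return reports


def invasion_fitness(params: CommunityParams, invader: str = "Y") -> float:
    """Per-capita growth rate of a rare invader at the resident's equilibrium.

    A vanishingly rare invader almost never meets conspecifics inside the
    decision tree (P -> 0), so its fecundity is ``(1 - c) r`` while it
    suffers competition ``b v (r/v)`` from the resident at carrying density:
    the growth rate is ``r (1 - c - b)``, negative exactly when ``b + c > 1``.
    The model is ecologically neutral, so the value is the same for either
    ``invader`` label.
    """
    if invader not in ("X", "Y"):
        raise ValueError(f"species label must be 'X' or 'Y', got {invader!r}")
    return (1.0 - params.c) * params.r - params.b * params.v * params.carrying_density


def exclusion_boundary(
    params: CommunityParams,
    b: float | None = None,
    *,
    xtol: float = 1e-9,
    max_matings: int = 2,
) -> float:
    """Critical niche overlap ``c*`` above which species exclusion is stable.

    Located by bisection on the sign of the transverse Jacobian eigenvalue
    at the boundary equilibrium ``B_X`` as a function of ``c``; analytically
    ``c* = 1 - b``.
    """
    if b is None:
        b = params.b
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"b must lie in [0, 1], got {b!r}")

    def transverse(c: float) -> float:
        pars = replace(params, c=c, b=b)
        nx = _boundary_density(pars, "X", max_matings)
        J = _jacobian(np.array([nx, 0.0]), pars, max_matings)
        return float(J[1, 1])

    g0, g1 = transverse(0.0), transverse(1.0)
    if g0 <= 0.0:
        return 0.0
    if g1 >= 0.0:
        return 1.0
    return float(bisect(transverse, 0.0, 1.0, xtol=xtol))


# ---------------------------------------------------------------------------
# basins of attraction


@dataclass(frozen=True)
class BasinMap:
    """Attractor label for every point of a rectangular lattice.

    ``labels[i, j]`` is the attractor reached from initial condition
    ``(nx[i], ny[j])``; points whose terminal state is not within the
    assignment radius of any stable equilibrium are labelled "unresolved".
    """

    nx: np.ndarray
    ny: np.ndarray
    labels: np.ndarray  # shape (len(nx), len(ny)), dtype=object
    attractors: dict[str, EquilibriumReport]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.nx[i], self.ny[j], self.labels[i, j])
            for i in range(len(self.nx))
            for j in range(len(self.ny))
        ]
        return pd.DataFrame(rows, columns=["NX", "NY", "label"])


def _attractor_labels(stable: list[EquilibriumReport]) -> dict[str, EquilibriumReport]:
    labels: dict[str, EquilibriumReport] = {}
    n_interior = 0
    for rep in stable:
        if rep.kind == "interior":
            n_interior += 1
            labels[f"interior_{n_interior}"] = rep
        else:
            labels[rep.kind] = rep
    return labels


def basins(
    params: CommunityParams,
    grid: tuple[int, int] = (50, 50),
    box: tuple[float, float, float, float] | None = None,
    horizon: float = 1000.0,
    *,
    equilibria: list[EquilibriumReport] | None = None,
    assign_radius: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    max_matings: int = 2,
) -> BasinMap:
    """Basins of attraction by forward integration of every lattice point.

    Each point of a ``grid`` lattice over ``box`` (default ``[0, 1.2 r/v]^2``)
    is integrated to ``horizon`` and assigned to the nearest stable
    equilibrium within ``assign_radius`` (default ``1e-2 * r``); otherwise it
    is reported as "unresolved", never silently dropped.
    """
    scale = params.carrying_density
    if box is None:
        box = (0.0, 1.2 * scale, 0.0, 1.2 * scale)
    if assign_radius is None:
        assign_radius = 1e-2 * params.r
    if equilibria is None:
        equilibria = find_equilibria(params, max_matings=max_matings)
    stable = [rep for rep in equilibria if rep.stability == "stable"]
    if not stable:
        raise ValueError("no stable equilibrium found; basins are undefined")
    attractors = _attractor_labels(stable)
    points = np.array([rep.state.as_array() for rep in attractors.values()])
    names = list(attractors.keys())

    nx = np.linspace(box[0], box[1], grid[0])
    ny = np.linspace(box[2], box[3], grid[1])
    labels = np.empty((grid[0], grid[1]), dtype=object)
    for i, x0 in enumerate(nx):
        for j, y0 in enumerate(ny):
            traj = integrate(
                CommunityState(x0, y0),
                params,
                horizon,
                rtol=rtol,
                atol=atol,
                max_matings=max_matings,
            )
            terminal = traj.states[-1]
            dists = np.linalg.norm(points - terminal, axis=1)
            k = int(np.argmin(dists))
            labels[i, j] = names[k] if dists[k] <= assign_radius else "unresolved"
    return BasinMap(nx=nx, ny=ny, labels=labels, attractors=attractors)


# ---------------------------------------------------------------------------
# phase-portrait export


def _nullcline_traces(
    params: CommunityParams,
    box: tuple[float, float, float, float],
    n: int,
    max_matings: int,
) -> pd.DataFrame:
    from contourpy import contour_generator

    xs = np.linspace(box[0], box[1], n)
    ys = np.linspace(box[2], box[3], n)
    ZX = np.empty((n, n))
    ZY = np.empty((n, n))
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            d = _rhs(np.array([x, y]), params, max_matings)
            ZX[j, i] = d[0]
            ZY[j, i] = d[1]
    rows = []
    for comp, Z in (("X", ZX), ("Y", ZY)):
        gen = contour_generator(x=xs, y=ys, z=Z)
        for k, line in enumerate(gen.lines(0.0)):
            for px, py in line:
                rows.append((comp, k, px, py))
    return pd.DataFrame(rows, columns=["component", "trace", "NX", "NY"])


def portrait_export(
    params: CommunityParams,
    box: tuple[float, float, float, float] | None = None,
    grid: tuple[int, int] = (25, 25),
    equilibria: list[EquilibriumReport] | None = None,
    basin_map: BasinMap | None = None,
    outdir: str | Path | None = None,
    *,
    nullcline_grid: int = 201,
    max_matings: int = 2,
) -> dict[str, pd.DataFrame]:
    """Tabular phase-portrait data: derivative field, nullclines, equilibria.

    Returns a dict of data frames (keys ``field``, ``nullclines``,
    ``equilibria`` and, when a basin map is supplied, ``basins``); if
    ``outdir`` is given each table is also written as a headed CSV suitable
    for any plotting tool.
    """
    scale = params.carrying_density
    if box is None:
        box = (0.0, 1.2 * scale, 0.0, 1.2 * scale)
    if equilibria is None:
        equilibria = find_equilibria(params, max_matings=max_matings)

    xs = np.linspace(box[0], box[1], grid[0])
    ys = np.linspace(box[2], box[3], grid[1])
    field_rows = []
    for x in xs:
        for y in ys:
            d = _rhs(np.array([x, y]), params, max_matings)
            field_rows.append((x, y, d[0], d[1]))
    field = pd.DataFrame(field_rows, columns=["NX", "NY", "dNX_dt", "dNY_dt"])

    eq_rows = [
        (
            rep.state.NX,
            rep.state.NY,
            rep.kind,
            rep.stability,
            rep.eigenvalues[0].real,
            rep.eigenvalues[0].imag,
            rep.eigenvalues[1].real,
            rep.eigenvalues[1].imag,
            rep.residual,
        )
        for rep in equilibria
    ]
    eq = pd.DataFrame(
        eq_rows,
        columns=[
            "NX",
            "NY",
            "kind",
            "stability",
            "eig1_re",
            "eig1_im",
            "eig2_re",
            "eig2_im",
            "residual",
        ],
    )

    tables = {
        "field": field,
        "nullclines": _nullcline_traces(params, box, nullcline_grid, max_matings),
        "equilibria": eq,
    }
    if basin_map is not None:
        tables["basins"] = basin_map.to_frame()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
    return tables
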