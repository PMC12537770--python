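"""Three-species Lotka-Volterra dynamics with serial-transfer protocols.

Implements the classic competitive Lotka-Volterra model and a
frequency-dependent variant in which each interspecific competition term
``alpha_ij * N_j`` is down-weighted by the relative abundance
``N_j / N_total`` of the interacting species.  Species roles follow the
E. coli (E) / yeast (Y) / competitor bacterium (B) convention used
throughout the package.

Populations are in cells/mL, time in hours, growth rates in 1/h and
interaction coefficients dimensionless (``alpha_ij`` is the effect of
species j on species i, relative to i's self-limitation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

ROLES = ("E", "Y", "B")

#: Populations below this density (cells/mL) are zeroed at cycle
#: boundaries to prevent numerical resurrection of extinct species.
EXTINCTION_FLOOR = 1e-3

#: Default daily dilution: two sequential 1:2^5 transfers.
DEFAULT_DILUTION = 2.0 ** -10

DEFAULT_CYCLE_HOURS = 24.0
DEFAULT_GRID_DT = 0.1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesParams:
    """Logistic growth parameters for one community member.

    Parameters
    ----------
    role : {"E", "Y", "B"}
        E. coli, yeast, or the competitor bacterium.
    r : float
        Intrinsic growth rate (1/h).
    K : float
        Carrying capacity (cells/mL).
    N0 : float
        Initial population density (cells/mL); may be 0 (species absent).
    """

    role: str
    r: float
    K: float
    N0: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if not (self.r > 0 and math.isfinite(self.r)):
            raise ValueError(f"r must be positive and finite, got {self.r}")
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValueError(f"K must be positive and finite, got {self.K}")
        if not (self.N0 >= 0 and math.isfinite(self.N0)):
            raise ValueError(f"N0 must be non-negative and finite, got {self.N0}")


@dataclass(frozen=True)
class InteractionMatrix:
    """The six interspecific coefficients of the three-species model.

    ``alpha_EY`` is the effect of yeast (Y) on E. coli (E), and so on;
    all coefficients are non-negative (purely competitive model).
    """

    alpha_EY: float = 0.0
    alpha_EB: float = 0.0
    alpha_YE: float = 0.0
    alpha_YB: float = 0.0
    alpha_BE: float = 0.0
    alpha_BY: float = 0.0

    def __post_init__(self) -> None:
        for name, val in self.as_dict().items():
            if not (val >= 0 and math.isfinite(val)):
                raise ValueError(f"{name} must be non-negative and finite, got {val}")

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha_EY": self.alpha_EY,
            "alpha_EB": self.alpha_EB,
            "alpha_YE": self.alpha_YE,
            "alpha_YB": self.alpha_YB,
            "alpha_BE": self.alpha_BE,
            "alpha_BY": self.alpha_BY,
        }

    def as_matrix(self) -> np.ndarray:
        """3x3 matrix A with A[i, j] = alpha_ij in (E, Y, B) order; zero diagonal."""
        return np.array(
            [
                [0.0, self.alpha_EY, self.alpha_EB],
                [self.alpha_YE, 0.0, self.alpha_YB],
                [self.alpha_BE, self.alpha_BY, 0.0],
            ]
        )

    def with_values(self, **alphas: float) -> "InteractionMatrix":
        return replace(self, **alphas)


@dataclass(frozen=True)
class CommunityState:
    """Population densities (cells/mL) of the three species at time t (h)."""

    t: float
    N_E: float
    N_Y: float
    N_B: float

    def __post_init__(self) -> None:
        for name in ("N_E", "N_Y", "N_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.N_E, self.N_Y, self.N_B])


@dataclass
class Trajectory:
    """One batch-growth episode of the community.

    ``times`` are absolute hours since the start of the experiment;
    ``populations`` is shaped (len(times), 3) in (E, Y, B) order.
    """

    model: str
    params: tuple[SpeciesParams, SpeciesParams, SpeciesParams]
    alphas: InteractionMatrix
    times: np.ndarray
    populations: np.ndarray
    cycle: int = 0

    @property
    def states(self) -> list[CommunityState]:
        return [
            CommunityState(t=float(t), N_E=float(n[0]), N_Y=float(n[1]), N_B=float(n[2]))
            for t, n in zip(self.times, self.populations)
        ]

    @property
    def end_state(self) -> CommunityState:
        n = self.populations[-1]
        return CommunityState(
            t=float(self.times[-1]), N_E=float(n[0]), N_Y=float(n[1]), N_B=float(n[2])
        )


@dataclass
class InvasionResult:
    """Serial-transfer trajectories with the invader-introduction cycle marked."""

    cycles: list[Trajectory]
    introduction_cycle: int


# ---------------------------------------------------------------------------
# Derivative fields
# ---------------------------------------------------------------------------

def _unpack(params: tuple[SpeciesParams, ...]) -> tuple[np.ndarray, np.ndarray]:
    order = {p.role: p for p in params}
    if set(order) != set(ROLES):
        raise ValueError(f"params must cover roles {ROLES} exactly")
    r = np.array([order[s].r for s in ROLES])
    K = np.array([order[s].K for s in ROLES])
    return r, K


def _rhs_classic(N: np.ndarray, r: np.ndarray, K: np.ndarray, A: np.ndarray) -> np.ndarray:
    return N * r * (1.0 - (N + A @ N) / K)


def _rhs_freqdep(N: np.ndarray, r: np.ndarray, K: np.ndarray, A: np.ndarray) -> np.ndarray:
    total = N.sum()
    if total <= 0.0:
        return np.zeros_like(N)
    # alpha_ij * (N_j / N_total) * N_j : self term stays unweighted
    weighted = A @ (N * N) / total
    return N * r * (1.0 - (N + weighted) / K)


_RHS = {"classic": _rhs_classic, "freqdep": _rhs_freqdep}


def derivatives_classic(
    state: CommunityState,
    params: tuple[SpeciesParams, SpeciesParams, SpeciesParams],
    alphas: InteractionMatrix,
) -> np.ndarray:
    """Per-species growth rates (cells mL^-1 h^-1) of the classic LV model.

    dN_i/dt = N_i r_i (1 - (N_i + sum_j alpha_ij N_j) / K_i)
    """
    r, K = _unpack(params)
    return _rhs_classic(state.as_array(), r, K, alphas.as_matrix())


def derivatives_freqdep(
    state: CommunityState,
    params: tuple[SpeciesParams, SpeciesParams, SpeciesParams],
    alphas: InteractionMatrix,
) -> np.ndarray:
    """Per-species rates of the frequency-dependent model.

    Each interspecific term ``alpha_ij N_j`` is weighted by the relative
    abundance ``N_j / (N_E + N_Y + N_B)``; the self-limitation term is
    unweighted.  All rates are zero when the total population is zero.
    """
    r, K = _unpack(params)
    return _rhs_freqdep(state.as_array(), r, K, alphas.as_matrix())


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_batch(
    model: str,
    params: tuple[SpeciesParams, SpeciesParams, SpeciesParams],
    alphas: InteractionMatrix,
    t_end: float = DEFAULT_CYCLE_HOURS,
    grid: np.ndarray | None = None,
    N_start: np.ndarray | None = None,
    t_start: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-3,
    cycle: int = 0,
) -> Trajectory:
    """Integrate one batch-growth episode of ``t_end`` hours.

    Parameters
    ----------
    model : {"classic", "freqdep"}
        Which derivative field to integrate.
    grid : array of output times (hours, relative to the cycle start) or
        None for the default 0.1-h grid.
    N_start : starting densities in (E, Y, B) order; defaults to each
        species' ``N0``.
    t_start : absolute time of the cycle start, used to label outputs.

    Output populations are clamped at >= 0.  Raises ``RuntimeError`` if the
    adaptive integrator fails.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if model not in _RHS:
        raise ValueError(f"model must be one of {sorted(_RHS)}, got {model!r}")
    r, K = _unpack(params)
    A = alphas.as_matrix()
    rhs = _RHS[model]
    if N_start is None:
        order = {p.role: p for p in params}
        N_start = np.array([order[s].N0 for s in ROLES])
    N_start = np.asarray(N_start, dtype=float)
    if grid is None:
        grid = np.arange(0.0, t_end + 0.5 * DEFAULT_GRID_DT, DEFAULT_GRID_DT)
        grid[-1] = t_end
    grid = np.asarray(grid, dtype=float)

    sol = solve_ivp(
        lambda t, y: rhs(np.maximum(y, 0.0), r, K, A),
        (0.0, t_end),
        N_start,
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")
    pops = np.maximum(sol.y.T, 0.0)
    # species absent at the start stay exactly absent
    pops[:, N_start == 0.0] = 0.0
    if grid[0] == 0.0:
        pops[0] = N_start  # exact, not the dense-output interpolant
    order = tuple(sorted(params, key=lambda p: ROLES.index(p.role)))
    return Trajectory(
        model=model,
        params=order,
        alphas=alphas,
        times=grid + t_start,
        populations=pops,
        cycle=cycle,
    )


def simulate_serial_transfer(
    model: str,
    params: tuple[SpeciesParams, SpeciesParams, SpeciesParams],
    alphas: InteractionMatrix,
    n_cycles: int = 7,
    dilution_factor: float = DEFAULT_DILUTION,
    cycle_hours: float = DEFAULT_CYCLE_HOURS,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-3,
    N_start: np.ndarray | None = None,
) -> list[Trajectory]:
    """Daily growth-and-dilution cycles.

    Each cycle integrates ``cycle_hours`` of batch growth, then multiplies
    all populations by ``dilution_factor`` (default 2^-10, i.e. two
    sequential 1:2^5 transfers) to seed the next cycle.  Densities below
    ``EXTINCTION_FLOOR`` after dilution are set to 0.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if not (0 < dilution_factor <= 1):
        raise ValueError("dilution_factor must be in (0, 1]")
    trajectories: list[Trajectory] = []
    N = N_start
    for cycle in range(n_cycles):
        traj = integrate_batch(
            model,
            params,
            alphas,
            t_end=cycle_hours,
            grid=None if grid is None else np.asarray(grid),
            N_start=N,
            t_start=cycle * cycle_hours,
            rtol=rtol,
            atol=atol,
            cycle=cycle,
        )
        trajectories.append(traj)
        N = traj.populations[-1] * dilution_factor
        if dilution_factor < 1:
            N = np.where(N < EXTINCTION_FLOOR, 0.0, N)
    return trajectories


def simulate_invasion(
    model: str,
    pair_params: tuple[SpeciesParams, SpeciesParams],
    alphas: InteractionMatrix,
    invader_params: SpeciesParams,
    equilibration_cycles: int = 3,
    total_cycles: int = 10,
    invader_density: float | None = None,
    dilution_factor: float = DEFAULT_DILUTION,
    cycle_hours: float = DEFAULT_CYCLE_HOURS,
    rtol: float = 1e-8,
    atol: float = 1e-3,
) -> InvasionResult:
    """Delayed-invader protocol.

    The E-Y pair grows through ``equilibration_cycles`` daily cycles with
    the competitor absent; the competitor is then introduced at
    ``invader_density`` (default: its configured ``N0``) and the community
    runs to ``total_cycles``.
    """
    if not (0 <= equilibration_cycles < total_cycles):
        raise ValueError("need 0 <= equilibration_cycles < total_cycles")
    roles = {p.role for p in pair_params}
    if roles != {"E", "Y"} or invader_params.role != "B":
        raise ValueError("pair_params must be roles E and Y; invader role B")
    if invader_density is None:
        invader_density = invader_params.N0
    if invader_density < 0:
        raise ValueError("invader_density must be non-negative")

    resident_b = replace(invader_params, N0=0.0)
    params = tuple(
        sorted((*pair_params, resident_b), key=lambda p: ROLES.index(p.role))
    )
    cycles: list[Trajectory] = []
    N = None
    if equilibration_cycles > 0:
        cycles = simulate_serial_transfer(
            model,
            params,
            alphas,
            n_cycles=equilibration_cycles,
            dilution_factor=dilution_factor,
            cycle_hours=cycle_hours,
            rtol=rtol,
            atol=atol,
        )
        N = cycles[-1].populations[-1] * dilution_factor
        N = np.where(N < EXTINCTION_FLOOR, 0.0, N)
    else:
        order = {p.role: p for p in params}
        N = np.array([order[s].N0 for s in ROLES])
    N = np.asarray(N, dtype=float).copy()
    N[ROLES.index("B")] = invader_density

    post = simulate_serial_transfer(
        model,
        params,
        alphas,
        n_cycles=total_cycles - equilibration_cycles,
        dilution_factor=dilution_factor,
        cycle_hours=cycle_hours,
        rtol=rtol,
        atol=atol,
        N_start=N,
    )
    for traj in post:
        traj.cycle += equilibration_cycles
        traj.times = traj.times + equilibration_cycles * cycle_hours
    return InvasionResult(cycles=cycles + post, introduction_cycle=equilibration_cycles)


# ---------------------------------------------------------------------------
# Protocol arithmetic
# ---------------------------------------------------------------------------

def doublings_per_cycle(dilution_factor: float = DEFAULT_DILUTION) -> float:
    """Cell doublings required to regrow after one dilution: log2(1/dilution)."""
    if not (0 < dilution_factor < 1):
        raise ValueError("dilution_factor must be in (0, 1)")
    return math.log2(1.0 / dilution_factor)


def total_generations(
    n_cycles: int = 7, dilution_factor: float = DEFAULT_DILUTION
) -> float:
    """Generations elapsed over a serial-transfer experiment.

    With the default two sequential 1:2^5 dilutions per day (2^-10) and
    7 daily cycles this is 10 doublings/day * 7 days = 70 generations.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return n_cycles * doublings_per_cycle(dilution_factor)


def default_community(
    r: tuple[float, float, float] = (0.7, 0.35, 0.6),
    K: tuple[float, float, float] = (1e9, 1e8, 1e9),
    N0: tuple[float, float, float] = (1e7, 1e7, 1e7),
) -> tuple[SpeciesParams, SpeciesParams, SpeciesParams]:
    """Representative (E, Y, B) parameter set.

    Defaults mirror the experimental mixing densities (1e7 cells/mL per
    species in co-cultures with yeast), the ~10x E. coli : yeast abundance
    ratio at equilibrium (K_E/K_Y = 10) and a bacterium-faster,
    yeast-slower ordering of growth rates.
    """
    return tuple(
        SpeciesParams(role=s, r=r[i], K=K[i], N0=N0[i]) for i, s in enumerate(ROLES)
    )
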