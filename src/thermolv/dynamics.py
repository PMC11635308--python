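"""Temperature-dependent Lotka–Volterra competition, integrated to steady state.

Each of ``n`` competing species grows logistically while being suppressed by
the *summed* density of all competitors relative to its own carrying
capacity:

    dN_i/dt = r_i(T) * N_i * (1 - (sum_j N_j) / K_i),

with the intrinsic growth rate ``r_i(T)`` supplied by the species' thermal
performance curve at the (fixed) environmental temperature ``T``. All
pairwise competition coefficients equal 1 — every bracket contains the same
total density — so, with equal capacities, the system admits an exact
conservation law: dividing any two equations,

    d ln N_i / d ln N_j = r_i / r_j   (constant in time),

hence ``ln(N_i(t)/N_i(0)) / r_i`` is identical across species along the
whole trajectory and final densities satisfy ``N_i* = N_i(0) * g**r_i`` for
a single community-wide scalar ``g``. This composition law is the module's
exact oracle: with equal initial densities, the steady-state ranking equals
the growth-rate ranking at ``T``.

Steady state is detected by a derivative criterion (``max_i |dN_i/dt|``
below a tolerance), not a state-difference one: the equal-capacity system
converges to a neutrally stable manifold ``sum N = K`` on which individual
densities still creep, so only the derivative reliably vanishes. Species
with strictly negative growth at ``T`` decay to zero only asymptotically;
their exact limit (extinction) is reported as density 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .curves import ParameterError, TPCParams, TPCurve, growth_rate, make_tpc

__all__ = [
    "Species",
    "Community",
    "IntegrationControl",
    "SteadyState",
    "IntegrationError",
    "lv_derivatives",
    "integrate_to_steady_state",
    "integrate_trajectory",
    "default_community",
    "DEFAULT_SPECIES_PARAMS",
]


class IntegrationError(RuntimeError):
    """Integration produced a non-finite state or the solver failed.

    Carries the time and state at failure when available.
    """

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass(frozen=True)
class Species:
    """One competitor: a thermal performance curve plus a carrying capacity."""

    id: str
    curve: TPCurve
    k: float = 1.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ParameterError(f"carrying capacity must be positive, got {self.k}")


@dataclass(frozen=True)
class Community:
    """Ordered species with their initial densities.

    Invariants: unique ids, all initial densities non-negative with at least
    one positive, matching lengths.
    """

    species: tuple[Species, ...]
    n0: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.species) == 0:
            raise ParameterError("community must contain at least one species")
        if len(self.species) != len(self.n0):
            raise ParameterError(
                f"species/initial-density length mismatch: "
                f"{len(self.species)} vs {len(self.n0)}"
            )
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ParameterError(f"duplicate species ids: {ids}")
        if any(n < 0 for n in self.n0):
            raise ParameterError("initial densities must be non-negative")
        if not any(n > 0 for n in self.n0):
            raise ParameterError("at least one initial density must be positive")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def capacities(self) -> np.ndarray:
        return np.array([s.k for s in self.species])

    def rates_at(self, T: float) -> np.ndarray:
        """Per-species intrinsic growth rates at environmental temperature T."""
        return np.array([growth_rate(s.curve, T) for s in self.species])


@dataclass(frozen=True)
class IntegrationControl:
    """Solver settings for steady-state integration.

    deriv_tol : steady-state criterion on max |dN_i/dt| (density/time).
    horizon : maximum integration time (time units).
    extinction_threshold : densities below this (relative to mean K) report as 0.
    method : any stiff-capable scipy method name; LSODA switches automatically.
    """

    deriv_tol: float = 1e-9
    horizon: float = 1e4
    extinction_threshold: float = 1e-9
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12


@dataclass(frozen=True)
class SteadyState:
    """Converged densities at one temperature, with diagnostics."""

    densities: np.ndarray
    converged: bool
    t_final: float
    max_abs_derivative: float

    def __post_init__(self) -> None:
        if np.any(self.densities < 0):
            raise ParameterError("steady-state densities must be non-negative")


def lv_derivatives(
    densities: Sequence[float],
    rates: Sequence[float],
    capacities: Sequence[float],
) -> np.ndarray:
    """Right-hand side of the shared-sum competition equations.

    Component ``i`` is exactly ``r_i * N_i * (1 - sum_j N_j / K_i)``; a
    species at zero density has zero derivative.
    """
    N = np.asarray(densities, dtype=float)
    r = np.asarray(rates, dtype=float)
    K = np.asarray(capacities, dtype=float)
    if not (N.shape == r.shape == K.shape):
        raise ParameterError(
            f"length mismatch: densities {N.shape}, rates {r.shape}, "
            f"capacities {K.shape}"
        )
    return r * N * (1.0 - N.sum() / K)


def _lv_jacobian(N: np.ndarray, r: np.ndarray, K: np.ndarray) -> np.ndarray:
    S = N.sum()
    J = np.outer(-r * N / K, np.ones_like(N))
    J[np.diag_indices_from(J)] += r * (1.0 - S / K)
    return J


def integrate_to_steady_state(
    community: Community,
    T: float,
    control: IntegrationControl | None = None,
) -> SteadyState:
    """Integrate the community at fixed temperature ``T`` until steady state.

    Growth rates are evaluated once from each species' thermal performance
    curve (the environment is constant within a run). Integration terminates
    when ``max_i |dN_i/dt|`` drops below ``control.deriv_tol`` or at the
    horizon; the ``converged`` flag records which. Densities below the
    extinction threshold — and species whose growth rate at ``T`` is
    strictly negative and which have declined, whose exact asymptotic limit
    is zero — are reported as exactly 0.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite or the solver reports failure.
    """
    if control is None:
        control = IntegrationControl()
    r = community.rates_at(T)
    K = community.capacities
    n0 = np.asarray(community.n0, dtype=float)
    ext = control.extinction_threshold * float(K.mean())

    def rhs(t, y):
        return r * y * (1.0 - y.sum() / K)

    def jac(t, y):
        return _lv_jacobian(y, r, K)

    d0 = rhs(0.0, n0)
    if np.max(np.abs(d0)) < control.deriv_tol:
        # Already stationary (e.g. all rates zero at this temperature).
        return SteadyState(
            densities=_finalize(n0, r, n0, ext),
            converged=True,
            t_final=0.0,
            max_abs_derivative=float(np.max(np.abs(d0))),
        )

    def settled(t, y):
        return float(np.max(np.abs(rhs(t, y)))) - control.deriv_tol

    settled.terminal = True
    settled.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, control.horizon),
        n0,
        method=control.method,
        jac=jac,
        events=settled,
        rtol=control.rtol,
        atol=control.atol,
    )
    if not sol.success:
        t_bad = float(sol.t[-1]) if sol.t.size else 0.0
        y_bad = sol.y[:, -1] if sol.t.size else n0
        raise IntegrationError(
            f"solver failed at T={T}: {sol.message}", t=t_bad, state=y_bad
        )
    y_end = sol.y[:, -1]
    if not np.all(np.isfinite(y_end)):
        raise IntegrationError(
            f"non-finite state at T={T}", t=float(sol.t[-1]), state=y_end
        )
    max_d = float(np.max(np.abs(rhs(sol.t[-1], y_end))))
    converged = bool(sol.t_events[0].size) or max_d < control.deriv_tol
    return SteadyState(
        densities=_finalize(y_end, r, n0, ext),
        converged=converged,
        t_final=float(sol.t[-1]),
        max_abs_derivative=max_d,
    )


def integrate_trajectory(
    community: Community,
    T: float,
    times: Sequence[float],
    control: IntegrationControl | None = None,
) -> np.ndarray:
    """Densities at the requested times (shape ``len(times) × n``).

    Same dynamics as :func:`integrate_to_steady_state` but without the
    steady-state termination event — useful for checking trajectories
    against closed-form solutions.
    """
    if control is None:
        control = IntegrationControl()
    r = community.rates_at(T)
    K = community.capacities
    n0 = np.asarray(community.n0, dtype=float)
    times = np.asarray(times, dtype=float)

    sol = solve_ivp(
        lambda t, y: r * y * (1.0 - y.sum() / K),
        (0.0, float(times.max())),
        n0,
        method=control.method,
        jac=lambda t, y: _lv_jacobian(y, r, K),
        t_eval=times,
        rtol=control.rtol,
        atol=control.atol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed at T={T}: {sol.message}")
    return sol.y.T


def _finalize(y: np.ndarray, r: np.ndarray, n0: np.ndarray, ext: float) -> np.ndarray:
    """Clip integrator undershoot and take exact extinction limits."""
    out = np.clip(y, 0.0, None)
    # A species with strictly negative growth that is declining has limit 0;
    # the derivative-stopping rule alone would strand it at ~deriv_tol/|r|.
    dying = (r < 0) & (out <= n0)
    out[dying] = 0.0
    out[out < ext] = 0.0
    return out


# ---------------------------------------------------------------------------
# Default three-species scenario
# ---------------------------------------------------------------------------

#: Cardinal temperatures for the default community: S1's optimum sits at the
#: long-term maximum environmental (ocean) temperature of 37°C, S2 above it,
#: S3 below; a shared t_min of 0°C gives every curve the right-skewed shape.
DEFAULT_SPECIES_PARAMS: dict[str, dict] = {
    "S1": dict(t_min=0.0, t_opt=37.0, t_max=41.0),
    "S2": dict(t_min=0.0, t_opt=42.0, t_max=46.0),
    "S3": dict(t_min=0.0, t_opt=32.0, t_max=37.0),
}


def default_community(
    r_peak: float = 1.0,
    death_slope: float = 0.1,
    k: float = 1.0,
    n0_frac: float = 0.01,
    form: str = "beta",
) -> Community:
    """The default three-species community (S1, S2, S3).

    Peaks are normalized to ``r_peak``, capacities equal, initial densities
    equal at ``n0_frac`` of the mean capacity.
    """
    species = tuple(
        Species(
            id=name,
            curve=make_tpc(
                TPCParams(r_peak=r_peak, death_slope=death_slope, **cardinals),
                form=form,
            ),
            k=k,
        )
        for name, cardinals in DEFAULT_SPECIES_PARAMS.items()
    )
    n0 = tuple(n0_frac * k for _ in species)
    return Community(species=species, n0=n0)
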