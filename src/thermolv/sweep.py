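"""Steady-state competition outcomes across an environmental-temperature grid.

Runs the community to steady state independently at every grid temperature
(cold start from the same initial densities — equilibrium outcomes, no
thermal history) and derives the dominance structure: which species holds
the largest equilibrium density where, and the maximal temperature
intervals over which dominance is constant. With right-skewed curves whose
optima are staggered, dominance hands over from the low-optimum species to
progressively higher-optimum species as temperature rises.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import ParameterError
from .dynamics import Community, IntegrationControl, SteadyState, integrate_to_steady_state

__all__ = [
    "SweepResult",
    "temperature_grid",
    "run_temperature_sweep",
    "dominant_species",
    "dominance_intervals",
    "sweep_to_tsv",
]

#: Marker values used in the per-temperature dominance column.
NONE_MARKER = "none"
TIE_MARKER = "tie"

DEFAULT_TIE_TOL = 1e-6


@dataclass(frozen=True)
class SweepResult:
    """Temperature grid × species density matrix with dominance annotations.

    ``relative`` rows sum to 1 wherever any species survives, else 0.
    """

    grid: np.ndarray
    species_ids: tuple[str, ...]
    densities: np.ndarray  # shape (n_temperatures, n_species)
    relative: np.ndarray
    dominant: tuple[str, ...]  # species id, "tie", or "none" per grid point
    converged: np.ndarray  # bool per grid point

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ParameterError("temperature grid must be strictly increasing")


def temperature_grid(t_start: float, t_end: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid from ``t_start`` to ``t_end``.

    Built with ``linspace`` so the endpoint is hit exactly (no float-step
    accumulation); 25→45 at 0.1°C gives 201 points.
    """
    if not t_start < t_end:
        raise ParameterError(f"t_start must be below t_end: {t_start} vs {t_end}")
    if not step > 0:
        raise ParameterError(f"step must be positive, got {step}")
    n = int(round((t_end - t_start) / step)) + 1
    return np.linspace(t_start, t_end, n)


def dominant_species(
    state: SteadyState,
    community: Community,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> str:
    """Id of the strictly largest-density species, ``"tie"`` or ``"none"``.

    A tie is declared when the top two densities agree within ``tie_tol``
    relative to the larger; ``"none"`` means universal extinction.
    """
    d = state.densities
    if np.all(d == 0):
        return NONE_MARKER
    order = np.argsort(d)
    top = d[order[-1]]
    if d.size > 1 and top - d[order[-2]] <= tie_tol * top:
        return TIE_MARKER
    return community.ids[int(order[-1])]


def run_temperature_sweep(
    community: Community,
    t_start: float = 25.0,
    t_end: float = 45.0,
    step: float = 0.1,
    control: IntegrationControl | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> SweepResult:
    """Integrate the community to steady state at every grid temperature.

    Each temperature is an independent cold start from the community's
    initial densities. Integration failures propagate annotated with the
    failing temperature.
    """
    grid = temperature_grid(t_start, t_end, step)
    n_sp = community.n
    densities = np.zeros((grid.size, n_sp))
    converged = np.zeros(grid.size, dtype=bool)
    dominant: list[str] = []
    for i, T in enumerate(grid):
        try:
            state = integrate_to_steady_state(community, float(T), control)
        except Exception as exc:
            raise type(exc)(f"sweep failed at T={T:.4g}°C: {exc}") from exc
        densities[i] = state.densities
        converged[i] = state.converged
        dominant.append(dominant_species(state, community, tie_tol))
    totals = densities.sum(axis=1)
    relative = np.zeros_like(densities)
    alive = totals > 0
    relative[alive] = densities[alive] / totals[alive, None]
    return SweepResult(
        grid=grid,
        species_ids=tuple(community.ids),
        densities=densities,
        relative=relative,
        dominant=tuple(dominant),
        converged=converged,
    )


def dominance_intervals(sweep: SweepResult) -> list[tuple[str, tuple[float, float]]]:
    """Maximal runs of consecutive grid points sharing a dominant species.

    Returned as ``(species_id, (T_low, T_high))`` closed intervals in grid
    order; tie and all-extinct points terminate runs and are not reported.
    """
    intervals: list[tuple[str, tuple[float, float]]] = []
    current: str | None = None
    start = 0.0
    last = 0.0
    for T, dom in zip(sweep.grid, sweep.dominant):
        if dom in (NONE_MARKER, TIE_MARKER):
            dom = None
        if dom != current:
            if current is not None:
                intervals.append((current, (start, last)))
            current = dom
            start = float(T)
        last = float(T)
    if current is not None:
        intervals.append((current, (start, last)))
    return intervals


def sweep_to_tsv(
    sweep: SweepResult, scenario_id: str = "default"
) -> str:
    """Tidy TSV: one row per (scenario, temperature, species)."""
    rows = []
    for i, T in enumerate(sweep.grid):
        for j, sid in enumerate(sweep.species_ids):
            rows.append(
                dict(
                    scenario_id=scenario_id,
                    T_celsius=round(float(T), 10),
                    species_id=sid,
                    density=sweep.densities[i, j],
                    relative_density=sweep.relative[i, j],
                    dominant_flag=int(sweep.dominant[i] == sid),
                    converged=int(sweep.converged[i]),
                )
            )
    frame = pd.DataFrame(rows)
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    return buf.getvalue()
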