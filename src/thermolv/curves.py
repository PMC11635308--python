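"""Skewed thermal performance curves (TPCs) for intrinsic growth rate r(T).

A thermal performance curve maps environmental temperature (°C) to an
organism's intrinsic growth rate. The curves modelled here are unimodal and
typically right-skewed: growth rises gradually from a lower thermal limit
``t_min`` to a maximum ``r_peak`` at the optimum ``t_opt``, then collapses
rapidly to zero at the upper critical temperature ``t_max``. Beyond
``t_max`` organisms face maintenance costs and death, represented by a
linear net-decline term of slope ``death_slope``; below ``t_min`` the rate
is clamped at zero (cold temperatures arrest growth rather than kill).

The default functional form is the Yan–Hunt beta curve,

    r(T) = r_peak * ((t_max - T)/(t_max - t_opt))
                  * ((T - t_min)/(t_opt - t_min)) ** beta,

with shape exponent ``beta = (t_opt - t_min)/(t_max - t_opt)``. It attains
its exact maximum ``r_peak`` at ``t_opt``, is zero at both thermal limits,
and its asymmetry is controlled purely by the spacing of the three cardinal
temperatures. Alternate forms can be registered for sensitivity analyses.

Skewness is summarised by the ratio ``(t_max - t_opt)/(t_opt - t_min)``:
values below 1 mean a steeper decline above the optimum than the rise
below it, the shape characteristic of empirical growth curves.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "TPCParams",
    "TPCurve",
    "ParameterError",
    "UnknownFormError",
    "make_tpc",
    "growth_rate",
    "normalize_curves",
    "skewness_metric",
    "register_form",
    "available_forms",
    "curves_from_config",
    "curves_to_config",
    "export_samples_tsv",
]


class ParameterError(ValueError):
    """Raised when curve parameters violate their ordering or sign constraints."""


class UnknownFormError(KeyError):
    """Raised when a functional form name is not in the registry."""

    def __init__(self, form: str):
        self.form = form
        super().__init__(
            f"unknown functional form {form!r}; registered forms: "
            f"{sorted(_FORM_REGISTRY)}"
        )


@dataclass(frozen=True)
class TPCParams:
    """Cardinal temperatures and rates of one thermal performance curve.

    Parameters
    ----------
    t_min : float
        Lower zero-growth temperature (°C).
    t_opt : float
        Temperature of maximal growth (°C); must satisfy
        ``t_min < t_opt < t_max``.
    t_max : float
        Upper critical temperature for growth (°C).
    r_peak : float
        Growth rate at ``t_opt`` (per unit time); must be positive.
    death_slope : float, default 0.1
        Magnitude of the net decline rate per °C beyond ``t_max``
        (per unit time per °C). Zero disables death above ``t_max``.
    """

    t_min: float
    t_opt: float
    t_max: float
    r_peak: float
    death_slope: float = 0.1

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt):
            raise ParameterError(
                f"t_min < t_opt violated: t_min={self.t_min}, t_opt={self.t_opt}"
            )
        if not (self.t_opt < self.t_max):
            raise ParameterError(
                f"t_opt < t_max violated: t_opt={self.t_opt}, t_max={self.t_max}"
            )
        if not (self.r_peak > 0):
            raise ParameterError(f"r_peak must be positive, got {self.r_peak}")
        if self.death_slope < 0:
            raise ParameterError(
                f"death_slope must be non-negative, got {self.death_slope}"
            )
        for name in ("t_min", "t_opt", "t_max", "r_peak", "death_slope"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")


# A form maps (params, T-array restricted to the open interval
# (t_min, t_max)) to positive rates; anchoring at the limits and the death
# extension are handled uniformly by growth_rate.
FormFunc = Callable[[TPCParams, np.ndarray], np.ndarray]

_FORM_REGISTRY: dict[str, FormFunc] = {}


def register_form(name: str, func: FormFunc) -> None:
    """Register a functional form under ``name`` (overwrites silently)."""
    _FORM_REGISTRY[name] = func


def available_forms() -> list[str]:
    return sorted(_FORM_REGISTRY)


def _beta_form(p: TPCParams, T: np.ndarray) -> np.ndarray:
    beta = (p.t_opt - p.t_min) / (p.t_max - p.t_opt)
    fall = (p.t_max - T) / (p.t_max - p.t_opt)
    rise = (T - p.t_min) / (p.t_opt - p.t_min)
    return p.r_peak * fall * rise**beta


def _gaussian_form(p: TPCParams, T: np.ndarray) -> np.ndarray:
    # Gaussian rise anchored to zero at t_min, quadratic fall to zero at t_max.
    sigma = (p.t_opt - p.t_min) / 2.0
    floor = math.exp(-(((p.t_min - p.t_opt) / sigma) ** 2))
    rise = (np.exp(-(((T - p.t_opt) / sigma) ** 2)) - floor) / (1.0 - floor)
    fall = 1.0 - ((T - p.t_opt) / (p.t_max - p.t_opt)) ** 2
    return p.r_peak * np.where(T <= p.t_opt, rise, fall)


register_form("beta", _beta_form)
register_form("gaussian", _gaussian_form)


@dataclass(frozen=True)
class TPCurve:
    """A thermal performance curve: parameters plus a registered form."""

    params: TPCParams
    form: str = "beta"

    def __call__(self, T):
        return growth_rate(self, T)

    @property
    def peak(self) -> float:
        """Maximum growth rate (attained at ``t_opt`` by construction)."""
        return self.params.r_peak


def make_tpc(params: TPCParams, form: str = "beta") -> TPCurve:
    """Construct a thermal performance curve.

    Raises
    ------
    ParameterError
        If the cardinal temperatures are mis-ordered or rates invalid.
    UnknownFormError
        If ``form`` is not registered.
    """
    if form not in _FORM_REGISTRY:
        raise UnknownFormError(form)
    return TPCurve(params=params, form=form)


def growth_rate(curve: TPCurve, T):
    """Evaluate the intrinsic growth rate at temperature(s) ``T`` (°C).

    Piecewise contract: 0 for ``T <= t_min``; the positive unimodal form on
    ``(t_min, t_max)``; 0 at ``t_max``; ``-death_slope * (T - t_max)`` above
    ``t_max``. Total on finite inputs; accepts scalars or arrays.
    """
    p = curve.params
    form = _FORM_REGISTRY[curve.form]
    T_arr = np.asarray(T, dtype=float)
    scalar = T_arr.ndim == 0
    T_arr = np.atleast_1d(T_arr)
    out = np.zeros_like(T_arr)
    inside = (T_arr > p.t_min) & (T_arr < p.t_max)
    if inside.any():
        out[inside] = form(p, T_arr[inside])
    above = T_arr > p.t_max
    if above.any():
        out[above] = -p.death_slope * (T_arr[above] - p.t_max)
    return float(out[0]) if scalar else out


def skewness_metric(curve: TPCurve) -> float:
    """Asymmetry ratio ``(t_max - t_opt) / (t_opt - t_min)``.

    Values below 1 indicate the right-skewed shape (faster decline above the
    optimum than rise below it); 1 is symmetric spacing.
    """
    p = curve.params
    return (p.t_max - p.t_opt) / (p.t_opt - p.t_min)


def normalize_curves(
    curves: Sequence[TPCurve], r_common: float = 1.0
) -> list[TPCurve]:
    """Rescale every curve to share the maximum growth rate ``r_common``.

    Shape-preserving: cardinal temperatures and skewness are untouched; only
    the peak rate changes. Idempotent for a fixed ``r_common``.
    """
    if len(curves) == 0:
        raise ParameterError("normalize_curves requires a non-empty curve list")
    if not r_common > 0:
        raise ParameterError(f"r_common must be positive, got {r_common}")
    return [
        TPCurve(params=replace(c.params, r_peak=float(r_common)), form=c.form)
        for c in curves
    ]


# ---------------------------------------------------------------------------
# Plain-text round-trip and tabular export
# ---------------------------------------------------------------------------

_FIELDS = ("form", "t_min", "t_opt", "t_max", "r_peak", "death_slope")


def curves_to_config(curves: dict[str, TPCurve]) -> str:
    """Serialise labelled curves to a key–value text block per species."""
    blocks = []
    for label, curve in curves.items():
        p = curve.params
        lines = [f"[{label}]", f"form = {curve.form}"]
        lines += [
            f"{k} = {getattr(p, k)!r}"
            for k in ("t_min", "t_opt", "t_max", "r_peak", "death_slope")
        ]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def curves_from_config(text: str) -> dict[str, TPCurve]:
    """Parse the block format written by :func:`curves_to_config`."""
    curves: dict[str, TPCurve] = {}
    label = None
    fields: dict[str, str] = {}

    def flush():
        if label is None:
            return
        unknown = set(fields) - set(_FIELDS)
        if unknown:
            raise ParameterError(f"unknown keys in block [{label}]: {sorted(unknown)}")
        params = TPCParams(
            t_min=float(fields["t_min"]),
            t_opt=float(fields["t_opt"]),
            t_max=float(fields["t_max"]),
            r_peak=float(fields["r_peak"]),
            death_slope=float(fields.get("death_slope", 0.1)),
        )
        curves[label] = make_tpc(params, form=fields.get("form", "beta"))

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            label = line[1:-1].strip()
            fields = {}
        else:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    flush()
    return curves


def export_samples_tsv(
    curves: dict[str, TPCurve], temperatures: Iterable[float]
) -> str:
    """Tabulate (species, T, r) samples as TSV with a header line."""
    grid = np.asarray(list(temperatures), dtype=float)
    buf = io.StringIO()
    buf.write("species_id\tT_celsius\tgrowth_rate\n")
    for label, curve in curves.items():
        rates = growth_rate(curve, grid)
        for t, r in zip(grid, rates):
            buf.write(f"{label}\t{t:.6g}\t{r:.12g}\n")
    return buf.getvalue()
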