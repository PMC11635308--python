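"""Run configuration: YAML schema, validation, and the run manifest.

A run config describes one experiment end to end — the community (per-
species curve parameters, capacities, initial densities), the temperature
grid, integrator settings, and optionally a robustness-ensemble spec. All
child-type invariants are validated up front, before any computation, and
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curves import ParameterError, TPCParams, make_tpc
from .dynamics import Community, IntegrationControl, Species
from .ensemble import ScenarioSpec

__all__ = ["RunConfig", "SweepSettings", "load_config", "config_to_dict", "manifest"]


@dataclass(frozen=True)
class SweepSettings:
    t_start: float = 25.0
    t_end: float = 45.0
    step: float = 0.1
    tie_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ParameterError(
                f"sweep.t_start must be below t_end: {self.t_start} vs {self.t_end}"
            )
        if not self.step > 0:
            raise ParameterError(f"sweep.step must be positive, got {self.step}")


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run description."""

    community: Community
    sweep: SweepSettings = field(default_factory=SweepSettings)
    integration: IntegrationControl = field(default_factory=IntegrationControl)
    ensemble: ScenarioSpec | None = None
    seed: int = 0
    output_dir: Path = Path("out")
    log_level: str = "INFO"


_TOP_KEYS = {
    "community",
    "sweep",
    "integration",
    "ensemble",
    "seed",
    "output_dir",
    "log_level",
}
_SPECIES_KEYS = {"id", "form", "t_min", "t_opt", "t_max", "r_peak", "death_slope", "k"}
_COMMUNITY_KEYS = {"species", "initial_density", "initial_densities"}
_SWEEP_KEYS = {"t_start", "t_end", "step", "tie_tol"}
_INTEGRATION_KEYS = {
    "deriv_tol",
    "horizon",
    "extinction_threshold",
    "method",
    "rtol",
    "atol",
}
_ENSEMBLE_KEYS = {
    "skew_range",
    "spacing_range",
    "peak_range",
    "normalize",
    "subset_sizes",
    "n_draws",
}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _parse_community(section: dict) -> Community:
    _check_keys(section, _COMMUNITY_KEYS, "community")
    species_list = section.get("species")
    if not species_list:
        raise ParameterError("community.species must be a non-empty list")
    species = []
    for entry in species_list:
        _check_keys(entry, _SPECIES_KEYS, f"community.species[{entry.get('id')}]")
        params = TPCParams(
            t_min=float(entry["t_min"]),
            t_opt=float(entry["t_opt"]),
            t_max=float(entry["t_max"]),
            r_peak=float(entry.get("r_peak", 1.0)),
            death_slope=float(entry.get("death_slope", 0.1)),
        )
        species.append(
            Species(
                id=str(entry["id"]),
                curve=make_tpc(params, form=entry.get("form", "beta")),
                k=float(entry.get("k", 1.0)),
            )
        )
    if "initial_densities" in section:
        n0 = tuple(float(x) for x in section["initial_densities"])
    else:
        frac = float(section.get("initial_density", 0.01))
        k_mean = sum(s.k for s in species) / len(species)
        n0 = tuple(frac * k_mean for _ in species)
    return Community(species=tuple(species), n0=n0)


def _parse_range(value, name: str) -> tuple[float, float]:
    if not (isinstance(value, (list, tuple)) and len(value) == 2):
        raise ParameterError(f"{name} must be a [low, high] pair")
    return (float(value[0]), float(value[1]))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config.

    Raises :class:`ParameterError` naming the first failed validation.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError("config root must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(raw, _TOP_KEYS, "config root")
    if "community" not in raw:
        raise ParameterError("config must define a community")
    community = _parse_community(raw["community"])

    sweep_raw = raw.get("sweep", {})
    _check_keys(sweep_raw, _SWEEP_KEYS, "sweep")
    sweep = SweepSettings(**{k: float(v) for k, v in sweep_raw.items()})

    integ_raw = dict(raw.get("integration", {}))
    _check_keys(integ_raw, _INTEGRATION_KEYS, "integration")
    method = integ_raw.pop("method", None)
    integ_kwargs = {k: float(v) for k, v in integ_raw.items()}
    if method is not None:
        integ_kwargs["method"] = str(method)
    integration = IntegrationControl(**integ_kwargs)

    seed = int(raw.get("seed", 0))

    ensemble = None
    if "ensemble" in raw:
        ens_raw = dict(raw["ensemble"])
        _check_keys(ens_raw, _ENSEMBLE_KEYS, "ensemble")
        ensemble = ScenarioSpec(
            base_community=community,
            skew_range=_parse_range(
                ens_raw.get("skew_range", (0.05, 0.8)), "ensemble.skew_range"
            ),
            spacing_range=_parse_range(
                ens_raw.get("spacing_range", (2.0, 8.0)), "ensemble.spacing_range"
            ),
            peak_range=_parse_range(
                ens_raw.get("peak_range", (0.5, 2.0)), "ensemble.peak_range"
            ),
            normalize=bool(ens_raw.get("normalize", True)),
            subset_sizes=tuple(int(s) for s in ens_raw.get("subset_sizes", (2, 3))),
            n_draws=int(ens_raw.get("n_draws", 10)),
            seed=seed,
        )

    return RunConfig(
        community=community,
        sweep=sweep,
        integration=integration,
        ensemble=ensemble,
        seed=seed,
        output_dir=Path(raw.get("output_dir", "out")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def config_to_dict(config: RunConfig) -> dict:
    """Invert parsing: a mapping that re-parses to an equivalent RunConfig."""
    community = {
        "species": [
            {
                "id": s.id,
                "form": s.curve.form,
                "t_min": s.curve.params.t_min,
                "t_opt": s.curve.params.t_opt,
                "t_max": s.curve.params.t_max,
                "r_peak": s.curve.params.r_peak,
                "death_slope": s.curve.params.death_slope,
                "k": s.k,
            }
            for s in config.community.species
        ],
        "initial_densities": list(config.community.n0),
    }
    out = {
        "community": community,
        "sweep": {
            "t_start": config.sweep.t_start,
            "t_end": config.sweep.t_end,
            "step": config.sweep.step,
            "tie_tol": config.sweep.tie_tol,
        },
        "integration": {
            "deriv_tol": config.integration.deriv_tol,
            "horizon": config.integration.horizon,
            "extinction_threshold": config.integration.extinction_threshold,
            "method": config.integration.method,
            "rtol": config.integration.rtol,
            "atol": config.integration.atol,
        },
        "seed": config.seed,
        "output_dir": str(config.output_dir),
        "log_level": config.log_level,
    }
    if config.ensemble is not None:
        e = config.ensemble
        out["ensemble"] = {
            "skew_range": list(e.skew_range),
            "spacing_range": list(e.spacing_range),
            "peak_range": list(e.peak_range),
            "normalize": e.normalize,
            "subset_sizes": list(e.subset_sizes),
            "n_draws": e.n_draws,
        }
    return out


def manifest(config: RunConfig) -> str:
    """YAML run manifest: config echo plus versions and a timestamp."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    doc = {
        "config": config_to_dict(config),
        "versions": {
            "thermolv": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return yaml.safe_dump(doc, sort_keys=False)
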