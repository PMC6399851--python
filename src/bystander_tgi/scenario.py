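"""Scenario configuration, dispatch and figure-style fixtures.

A :class:`ScenarioConfig` bundles every parameter of a single simulation
run — payload exchange, dose response, tumor growth, optional Erlang age
structure, bystander switch, horizon and output resolution — and
round-trips losslessly through YAML (or a JSON mirror).  Defaults are the
package's reference scenario: k_in = 1/day, k = 2, beta = 0.7,
C0 = 200 nM, E0 = 120 nM, Emax = 0.6931, IC50 = 300 nM, Hill 1,
c = 4.6e-3 /(nM day), lam = 0.5 /day, T0 = 1000 mm^3, Tmax = 2e4 mm^3,
logistic growth, 60-day horizon at 0.1-day output steps.

Figure fixtures (``fig2`` .. ``fig5``) are named parameter sweeps over
that scenario: payload dynamics across k and beta, two-population TGI
across beta, paired bystander on/off comparisons, and the age-structured
delay runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, NamedTuple

import numpy as np
import yaml

from .age_structured import AgeStructureParameters, simulate_age_structured
from .dose_response import DoseResponseParameters
from .errors import ConfigError
from .payload_kinetics import PayloadParameters, simulate_payload
from .tgi_dynamics import TumorParameters, bystander_gap, simulate_tgi
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

FIGURE_NAMES = ("fig2", "fig3", "fig4", "fig5")

#: beta sweep used by the figure fixtures
BETA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
K_GRID = (1.0, 2.0, 3.0)


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-8
    method: str = "RK45"

    def __post_init__(self) -> None:
        if not (0 < self.rtol < 1) or not (0 < self.atol < 1):
            raise ConfigError("solver tolerances must lie in (0, 1)")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full configuration of one simulation run."""

    payload: PayloadParameters = field(default_factory=PayloadParameters)
    dose_response: DoseResponseParameters = field(default_factory=DoseResponseParameters)
    tumor: TumorParameters = field(default_factory=TumorParameters)
    age_structure: AgeStructureParameters | None = None
    bystander: bool = True
    horizon: float = 60.0
    output_step: float = 0.1
    solver: SolverOptions = field(default_factory=SolverOptions)
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.horizon) and self.horizon > 0):
            raise ConfigError(f"horizon must be positive, got {self.horizon}")
        if not (0 < self.output_step <= self.horizon):
            raise ConfigError(
                f"output_step must lie in (0, horizon], got {self.output_step}"
            )

    def time_grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.output_step))
        return np.linspace(0.0, n * self.output_step, n + 1)

    def replace(self, **changes: Any) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "payload": dataclasses.asdict(self.payload),
            "dose_response": dataclasses.asdict(self.dose_response),
            "tumor": dataclasses.asdict(self.tumor),
            "bystander": "on" if self.bystander else "off",
            "horizon": self.horizon,
            "output_step": self.output_step,
            "solver": dataclasses.asdict(self.solver),
            "label": self.label,
        }
        d["tumor"]["growth_form"] = self.tumor.growth_form.value
        if self.age_structure is not None:
            d["age_structure"] = dataclasses.asdict(self.age_structure)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any] | None) -> "ScenarioConfig":
        data = dict(data or {})
        known = {
            "payload",
            "dose_response",
            "tumor",
            "age_structure",
            "bystander",
            "horizon",
            "output_step",
            "solver",
            "label",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown configuration keys {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        kwargs: dict[str, Any] = {}
        for key, typ in (
            ("payload", PayloadParameters),
            ("dose_response", DoseResponseParameters),
            ("tumor", TumorParameters),
            ("solver", SolverOptions),
        ):
            if key in data:
                kwargs[key] = _build_section(key, typ, data[key])
        if data.get("age_structure") is not None:
            kwargs["age_structure"] = _build_section(
                "age_structure", AgeStructureParameters, data["age_structure"]
            )
        if "bystander" in data:
            kwargs["bystander"] = _parse_switch("bystander", data["bystander"])
        for key in ("horizon", "output_step", "label"):
            if key in data:
                kwargs[key] = data[key]
        try:
            return cls(**kwargs)
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc


def _build_section(name: str, typ: type, values: Any) -> Any:
    if not isinstance(values, Mapping):
        raise ConfigError(f"section {name!r} must be a mapping, got {values!r}")
    fields = {f.name for f in dataclasses.fields(typ)}
    unknown = set(values) - fields
    if unknown:
        raise ConfigError(
            f"unknown keys {sorted(unknown)} in section {name!r}; "
            f"expected a subset of {sorted(fields)}"
        )
    try:
        return typ(**values)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def _parse_switch(name: str, value: Any) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.lower() in ("on", "off"):
        return value.lower() == "on"
    raise ConfigError(f"{name} must be 'on', 'off' or a boolean, got {value!r}")


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario from a YAML (or ``.json``) file.

    An empty file yields the full default configuration.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else None
    else:
        data = yaml.safe_load(text)
    if data is not None and not isinstance(data, Mapping):
        raise ConfigError(f"{path} does not contain a mapping")
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    d = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    return path


# -- running scenarios -----------------------------------------------------


class BystanderComparison(NamedTuple):
    with_bystander: Trajectory
    without_bystander: Trajectory
    gap_percent: np.ndarray


def run_scenario(
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    fmt: str = "csv",
    compare_bystander: bool = False,
) -> Trajectory | BystanderComparison:
    """Run one scenario; optionally write output and pair bystander on/off.

    Dispatches to the age-structured simulator when ``age_structure`` is
    configured and to the memoryless two-population TGI model otherwise.
    With ``compare_bystander=True`` the scenario is run twice (k_out as
    configured vs forced to 0) and the bystander-extent series is
    returned alongside both trajectories.
    """
    logger.info("running scenario %r: %s", config.label or "<unnamed>", config.to_dict())
    if compare_bystander:
        on = _dispatch(config.replace(bystander=True))
        off = _dispatch(config.replace(bystander=False))
        gap = bystander_gap(on, off, config.tumor.t0)
        result: Trajectory | BystanderComparison = BystanderComparison(on, off, gap)
        if out_dir is not None:
            _export(on, Path(out_dir), f"{config.label or 'scenario'}_bystander_on", fmt)
            _export(off, Path(out_dir), f"{config.label or 'scenario'}_bystander_off", fmt)
            gap_traj = Trajectory(
                on.time, {"bystander_gap_percent": gap}, {"model": "bystander_gap"}
            )
            _export(gap_traj, Path(out_dir), f"{config.label or 'scenario'}_gap", fmt)
        return result
    traj = _dispatch(config)
    if out_dir is not None:
        _export(traj, Path(out_dir), config.label or "scenario", fmt)
    return traj


def _dispatch(config: ScenarioConfig) -> Trajectory:
    grid = config.time_grid()
    solver = {
        "rtol": config.solver.rtol,
        "atol": config.solver.atol,
        "method": config.solver.method,
    }
    if config.age_structure is not None:
        traj = simulate_age_structured(
            config.payload,
            config.dose_response,
            config.tumor,
            config.age_structure,
            grid,
            bystander=config.bystander,
            **solver,
        )
    else:
        traj = simulate_tgi(
            config.payload,
            config.dose_response,
            config.tumor,
            grid,
            bystander=config.bystander,
            **solver,
        )
    traj.metadata["label"] = config.label
    traj.metadata["config"] = config.to_dict()
    logger.info(
        "scenario %r finished: %d output points, %s rhs evaluations",
        config.label or "<unnamed>",
        traj.time.size,
        traj.metadata.get("nfev", "?"),
    )
    return traj


def _export(traj: Trajectory, out_dir: Path, stem: str, fmt: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        return traj.to_csv(out_dir / f"{stem}.csv")
    if fmt == "json":
        return traj.to_json(out_dir / f"{stem}.json")
    raise ConfigError(f"format must be 'csv' or 'json', got {fmt!r}")


def add_lognormal_noise(
    traj: Trajectory, sigma: float, seed: int, series: tuple[str, ...] = ("T1", "T2", "T_total")
) -> Trajectory:
    """Multiply tumor series by seeded lognormal(0, sigma) measurement noise.

    A convenience for downstream pipelines that want noisy pseudo-data;
    the simulation itself is fully deterministic.
    """
    rng = np.random.default_rng(seed)
    noisy = dict(traj.series)
    for name in series:
        if name in noisy:
            noisy[name] = noisy[name] * rng.lognormal(0.0, sigma, size=traj.time.size)
    meta = dict(traj.metadata)
    meta["noise"] = {"sigma": sigma, "seed": seed}
    return Trajectory(traj.time, noisy, meta)


# -- figure fixtures -------------------------------------------------------


def figure_scenarios(name: str) -> list[ScenarioConfig]:
    """Parameter sweeps mirroring the reference figure panels."""
    base = ScenarioConfig()
    if name == "fig2":
        # payload dynamics: k in {1,2,3} x beta grid, short horizon
        return [
            base.replace(
                payload=PayloadParameters(k_in=1.0, k_out=k, beta=b),
                horizon=10.0,
                output_step=0.01,
                label=f"fig2_k{k:g}_beta{b:g}",
            )
            for k in K_GRID
            for b in BETA_GRID
        ]
    if name == "fig3":
        # two-population TGI across beta at fixed k = 2
        return [
            base.replace(
                payload=PayloadParameters(beta=b),
                label=f"fig3_beta{b:g}",
            )
            for b in BETA_GRID
        ]
    if name == "fig4":
        # bystander on/off pairs for Ag+-dominant mixes
        return [
            base.replace(
                payload=PayloadParameters(beta=b),
                label=f"fig4_beta{b:g}",
            )
            for b in (0.1, 0.2, 0.7, 0.8, 0.9, 1.0)
        ]
    if name == "fig5":
        # age-structured delay runs, bystander on/off
        return [
            base.replace(
                age_structure=AgeStructureParameters(),
                label="fig5",
            )
        ]
    raise ConfigError(f"unknown figure fixture {name!r}; choose from {FIGURE_NAMES}")


def run_figure(
    name: str, out_dir: str | Path | None = None, fmt: str = "csv"
) -> dict[str, Trajectory]:
    """Run every scenario of a figure fixture; returns label -> trajectory.

    For the paired fixtures (fig4, fig5) each scenario contributes three
    entries: ``<label>_on``, ``<label>_off`` and ``<label>_gap``.
    """
    scenarios = figure_scenarios(name)
    results: dict[str, Trajectory] = {}
    paired = name in ("fig4", "fig5")
    for cfg in scenarios:
        if name == "fig2":
            traj = simulate_payload(
                cfg.payload,
                cfg.time_grid(),
                rtol=cfg.solver.rtol,
                atol=min(cfg.solver.atol, 1e-10),
                method=cfg.solver.method,
            )
            traj.metadata["label"] = cfg.label
            results[cfg.label] = traj
            if out_dir is not None:
                _export(traj, Path(out_dir), cfg.label, fmt)
        elif paired:
            cmp = run_scenario(cfg, out_dir=out_dir, fmt=fmt, compare_bystander=True)
            results[f"{cfg.label}_on"] = cmp.with_bystander
            results[f"{cfg.label}_off"] = cmp.without_bystander
            results[f"{cfg.label}_gap"] = Trajectory(
                cmp.with_bystander.time,
                {"bystander_gap_percent": cmp.gap_percent},
                {"model": "bystander_gap", "label": f"{cfg.label}_gap"},
            )
        else:
            results[cfg.label] = run_scenario(cfg, out_dir=out_dir, fmt=fmt)
    return results
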