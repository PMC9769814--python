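"""Run configuration: defaults, YAML loading and override precedence.

Built-in defaults reproduce the published parameter set verbatim
(Table-value fixation rates, Y^C:N = 1, R_N:C = 0.159, 100 mol C start,
30 days of hourly steps, and the stated sweep ranges).  A YAML config
file overrides the defaults and CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model import (
    COLONY,
    DEFAULT_CONFIG,
    DEFAULT_STOICHIOMETRY,
    TRICHOME,
    MetabolicRates,
    SimulationConfig,
    Stoichiometry,
)
from .sampling import SweepGrid
from .scenarios import DEFAULT_GRIDS, DEFAULT_RP_LEVELS, DEFAULT_SEED

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Complete parameter ledger for a pipeline run."""

    colony: MetabolicRates = COLONY
    trichome: MetabolicRates = TRICHOME
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY
    simulation: SimulationConfig = DEFAULT_CONFIG
    seed: int = DEFAULT_SEED
    n_draws: int = 500
    f_res_max: float = 0.02
    rp_levels: tuple[float, ...] = DEFAULT_RP_LEVELS
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def _grid_from_mapping(name: str, m: dict) -> SweepGrid:
    if "values" in m:
        return SweepGrid(name, values=tuple(m["values"]))
    return SweepGrid(name, start=m["start"], stop=m["stop"], step=m["step"])


def load_config(path: str | Path | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file.

    Recognized top-level keys: ``rates`` (colony/trichome blocks with
    c_fix and n_fix), ``stoichiometry`` (y_cn, r_nc), ``simulation``
    (c0, duration_hours, dt_hours), ``seed``, ``n_draws``, ``f_res_max``,
    ``rp_levels`` and ``grids`` (per-parameter start/stop/step or an
    explicit values list).  Absent keys keep their defaults.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}

    kwargs: dict = {}
    rates = raw.get("rates", {})
    if "colony" in rates:
        kwargs["colony"] = MetabolicRates(
            rates["colony"]["c_fix"], rates["colony"]["n_fix"], "colony"
        )
    if "trichome" in rates:
        kwargs["trichome"] = MetabolicRates(
            rates["trichome"]["c_fix"], rates["trichome"]["n_fix"], "trichome"
        )
    if "stoichiometry" in raw:
        kwargs["stoich"] = Stoichiometry(**raw["stoichiometry"])
    if "simulation" in raw:
        kwargs["simulation"] = SimulationConfig(**raw["simulation"])
    for key in ("seed", "n_draws", "f_res_max"):
        if key in raw:
            kwargs[key] = raw[key]
    if "rp_levels" in raw:
        kwargs["rp_levels"] = tuple(raw["rp_levels"])
    if "grids" in raw:
        grids = dict(DEFAULT_GRIDS)
        for name, m in raw["grids"].items():
            grids[name] = _grid_from_mapping(name, m)
        kwargs["grids"] = grids
    return cfg.with_overrides(**kwargs)
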