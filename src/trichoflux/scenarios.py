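"""Scenario sweeps comparing colony and free-trichome carbon storage.

Each runner reproduces one published experiment as a tidy table:

* ``run_fixed_equal`` — fixed respiration, identical for both morphotypes.
* ``run_theta``      — trichome respiration drawn uniformly at random,
  colony respiration a fraction θ of it.
* ``run_rp``         — respiration proportional to each morphotype's
  carbon fixation rate (coefficient r_p).
* ``run_ip``         — external influence multiplying the metabolic net
  flux (interaction strength i_p), at several r_p levels.
* ``run_it``         — external influence proportional to the stored
  carbon itself (i_t, h⁻¹), at several r_p levels.
* ``run_tau``        — C:N fixation ratios τ varied per morphotype with
  a shared respiration-coefficient grid.

All comparisons use end-of-run storage (default hour 720), and "colony
success" is the fraction of paired runs where the colony pool strictly
exceeds the trichome pool.  Every result carries metadata (seed, grids,
rates, version) sufficient to regenerate it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .model import (
    COLONY,
    DEFAULT_CONFIG,
    DEFAULT_STOICHIOMETRY,
    TRICHOME,
    MetabolicRates,
    SimulationConfig,
    Stoichiometry,
    euler_final,
    net_flux,
)
from .sampling import SweepGrid, UniformSampler, make_grid, substream_seed

__all__ = [
    "ScenarioResult",
    "DEFAULT_SEED",
    "DEFAULT_GRIDS",
    "run_fixed_equal",
    "run_theta",
    "run_rp",
    "run_ip",
    "run_it",
    "run_tau",
    "colony_success_proportion",
]

DEFAULT_SEED = 42

# Published sweep designs; unstated steps chosen fine enough to bracket
# every reported threshold while keeping full sweeps fast.
DEFAULT_GRIDS = {
    "f_res": SweepGrid("f_res", 0.0, 0.02, 0.0005),
    "theta": SweepGrid("theta", 0.01, 1.0, 0.01),
    "r_p": SweepGrid("r_p", 0.001, 1.0, 0.001),
    "i_p": SweepGrid("i_p", -2.0, 2.0, 0.01),
    "i_t": SweepGrid("i_t", -0.002, 0.002, 0.0001),
    "tau": SweepGrid("tau", 1.0, 5.0, 0.1),
    "r_p_shared": SweepGrid("r_p_shared", 0.0, 1.0, 0.01),
}
DEFAULT_RP_LEVELS = (0.0, 0.3, 0.6, 0.9)


@dataclass
class ScenarioResult:
    """Tidy sweep output plus the metadata needed to regenerate it."""

    scenario: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def success_proportion(self) -> float | None:
        """Maximum colony-success proportion in the table, if one exists."""
        if "success_proportion" in self.table.columns:
            return float(self.table["success_proportion"].max())
        return None


def colony_success_proportion(colony_final, trichome_final) -> float:
    """Fraction of paired runs where colony storage strictly exceeds trichome's."""
    c = np.asarray(colony_final, dtype=float)
    t = np.asarray(trichome_final, dtype=float)
    if c.size == 0 or c.shape != t.shape:
        raise ValueError("need non-empty, equally shaped paired storages")
    return float(np.mean(c > t))


def _metadata(scenario: str, grids: dict, colony, trichome, stoich, config, seed=None, **extra) -> dict:
    md = {
        "scenario": scenario,
        "version": __version__,
        "seed": seed,
        "grids": {k: g.to_dict() for k, g in grids.items()},
        "rates": {
            "colony": {"c_fix": colony.c_fix, "n_fix": colony.n_fix},
            "trichome": {"c_fix": trichome.c_fix, "n_fix": trichome.n_fix},
        },
        "stoichiometry": {"y_cn": stoich.y_cn, "r_nc": stoich.r_nc},
        "simulation": {
            "c0": config.c0,
            "duration_hours": config.duration_hours,
            "dt_hours": config.dt_hours,
        },
    }
    md.update(extra)
    return md


def run_fixed_equal(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    config: SimulationConfig = DEFAULT_CONFIG,
    f_res_grid: SweepGrid | None = None,
) -> ScenarioResult:
    """Sweep a fixed respiration rate applied equally to both morphotypes."""
    grid = f_res_grid or DEFAULT_GRIDS["f_res"]
    f_res = make_grid(grid)
    rows = []
    for rates in (colony, trichome):
        finals = euler_final(net_flux(rates, stoich) - f_res, 0.0, config)
        rows.append(
            pd.DataFrame(
                {
                    "f_res": f_res,
                    "morphotype": rates.label,
                    "final_c_sto": finals,
                    "delta_c_sto": finals - config.c0,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return ScenarioResult(
        "fixed_equal",
        table,
        _metadata("fixed_equal", {"f_res": grid}, colony, trichome, stoich, config),
    )


def run_theta(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    config: SimulationConfig = DEFAULT_CONFIG,
    n_draws: int = 500,
    f_res_max: float = 0.02,
    theta_grid: SweepGrid | None = None,
    seed: int = DEFAULT_SEED,
) -> ScenarioResult:
    """Unequal respiration: colonies respire a fraction θ of each trichome draw.

    Trichome respiration rates are drawn once, uniformly on
    [0, f_res_max), and reused across every θ (variance reduction).  The
    table reports the empirical colony-success proportion per θ next to
    the analytic uniform-tail probability
    P(draw > gap/(1−θ)) — the two must agree to binomial error.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    grid = theta_grid or DEFAULT_GRIDS["theta"]
    theta = make_grid(grid)
    sub = substream_seed(seed, "theta")
    draws = UniformSampler(0.0, f_res_max, n_draws, sub).draw()

    net_t = net_flux(trichome, stoich) - draws  # (n_draws,)
    net_c = net_flux(colony, stoich) - theta[:, None] * draws  # (n_theta, n_draws)
    final_t = euler_final(net_t, 0.0, config)
    final_c = euler_final(net_c, 0.0, config)
    success = np.mean(final_c > final_t[None, :], axis=1)

    gap = net_flux(trichome, stoich) - net_flux(colony, stoich)
    with np.errstate(divide="ignore"):
        needed = np.where(theta < 1.0, gap / (1.0 - theta), np.inf)
    tail = np.clip((f_res_max - needed) / f_res_max, 0.0, 1.0)
    if gap <= 0:  # colonies ahead even without a respiration handicap
        tail = np.where(theta >= 1.0, float(gap < 0), tail)

    table = pd.DataFrame(
        {
            "theta": theta,
            "success_proportion": success,
            "analytic_tail_probability": tail,
        }
    )
    return ScenarioResult(
        "theta",
        table,
        _metadata(
            "theta",
            {"theta": grid},
            colony,
            trichome,
            stoich,
            config,
            seed=seed,
            substream_seed=sub,
            n_draws=n_draws,
            f_res_max=f_res_max,
        ),
    )


def run_rp(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    config: SimulationConfig = DEFAULT_CONFIG,
    rp_grid: SweepGrid | None = None,
) -> ScenarioResult:
    """Respiration proportional to carbon fixation: F_res = r_p · F_cfix."""
    grid = rp_grid or DEFAULT_GRIDS["r_p"]
    r_p = make_grid(grid)
    rows = []
    for rates in (colony, trichome):
        f_res = r_p * rates.c_fix
        finals = euler_final(net_flux(rates, stoich) - f_res, 0.0, config)
        rows.append(
            pd.DataFrame(
                {
                    "r_p": r_p,
                    "morphotype": rates.label,
                    "f_res": f_res,
                    "final_c_sto": finals,
                    "delta_c_sto": finals - config.c0,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return ScenarioResult(
        "rp",
        table,
        _metadata("rp", {"r_p": grid}, colony, trichome, stoich, config),
    )


def run_ip(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    config: SimulationConfig = DEFAULT_CONFIG,
    ip_grid: SweepGrid | None = None,
    rp_values: Sequence[float] = DEFAULT_RP_LEVELS,
) -> ScenarioResult:
    """External influence on metabolic rates: (1+i_p) scales the net
    metabolic term; respiration (r_p · F_cfix) is unaffected by i_p."""
    grid = ip_grid or DEFAULT_GRIDS["i_p"]
    i_p = make_grid(grid)
    rows = []
    for r_p in rp_values:
        for rates in (colony, trichome):
            net0 = net_flux(rates, stoich)
            nets = (1.0 + i_p) * net0 - r_p * rates.c_fix
            finals = euler_final(nets, 0.0, config)
            rows.append(
                pd.DataFrame(
                    {
                        "r_p": r_p,
                        "i_p": i_p,
                        "morphotype": rates.label,
                        "final_c_sto": finals,
                        "delta_c_sto": finals - config.c0,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    return ScenarioResult(
        "ip",
        table,
        _metadata(
            "ip", {"i_p": grid}, colony, trichome, stoich, config,
            rp_values=list(rp_values),
        ),
    )


def _signed_log10(diff: np.ndarray) -> np.ndarray:
    # sign(d) * log10|d|; exact zero has no defined magnitude -> NaN sentinel
    out = np.full_like(diff, np.nan)
    nz = diff != 0
    out[nz] = np.sign(diff[nz]) * np.log10(np.abs(diff[nz]))
    return out


def run_it(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    config: SimulationConfig = DEFAULT_CONFIG,
    it_grid: SweepGrid | None = None,
    rp_values: Sequence[float] = DEFAULT_RP_LEVELS,
) -> ScenarioResult:
    """External influence on total biomass: dC/dt gains an i_t·C term.

    Both morphotypes share c0 and i_t, so the winner is decided by the
    sign of the net-flux difference alone — the table makes that
    invariance visible across the i_t range.
    """
    grid = it_grid or DEFAULT_GRIDS["i_t"]
    i_t = make_grid(grid)
    rows = []
    for r_p in rp_values:
        final_c = euler_final(net_flux(colony, stoich) - r_p * colony.c_fix, i_t, config)
        final_t = euler_final(net_flux(trichome, stoich) - r_p * trichome.c_fix, i_t, config)
        diff = final_c - final_t
        rows.append(
            pd.DataFrame(
                {
                    "r_p": r_p,
                    "i_t": i_t,
                    "c_sto_colony": final_c,
                    "c_sto_trichome": final_t,
                    "difference": diff,
                    "signed_log10_difference": _signed_log10(diff),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return ScenarioResult(
        "it",
        table,
        _metadata(
            "it", {"i_t": grid}, colony, trichome, stoich, config,
            rp_values=list(rp_values),
        ),
    )


def run_tau(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    config: SimulationConfig = DEFAULT_CONFIG,
    tau_grid_colony: SweepGrid | None = None,
    tau_grid_trichome: SweepGrid | None = None,
    rp_grid: SweepGrid | None = None,
    allow_tau_below_one: bool = False,
) -> ScenarioResult:
    """Vary the C:N fixation ratio τ of each morphotype independently.

    Carbon fixation rates are held at their defaults and
    ``n_fix = c_fix/τ``.  For every (τ_colony, τ_trichome) pair the
    success proportion is the fraction of shared respiration
    coefficients r_p on the grid at which the colony ends with strictly
    more stored carbon.
    """
    gc = tau_grid_colony or DEFAULT_GRIDS["tau"]
    gt = tau_grid_trichome or DEFAULT_GRIDS["tau"]
    gr = rp_grid or DEFAULT_GRIDS["r_p_shared"]
    tau_c = make_grid(gc)
    tau_t = make_grid(gt)
    r_p = make_grid(gr)
    if not allow_tau_below_one and (tau_c.min() < 1.0 or tau_t.min() < 1.0):
        raise ValueError("tau values below 1 are outside the studied range")

    # Final storage factorizes over (tau, r_p) per morphotype; pair-level
    # success is then a strict comparison across the shared r_p grid.
    cost_c = stoich.r_nc * stoich.y_cn * colony.c_fix / tau_c  # (n_tc,)
    cost_t = stoich.r_nc * stoich.y_cn * trichome.c_fix / tau_t  # (n_tt,)
    net_c = colony.c_fix - cost_c[:, None] - r_p[None, :] * colony.c_fix
    net_t = trichome.c_fix - cost_t[:, None] - r_p[None, :] * trichome.c_fix
    final_c = euler_final(net_c, 0.0, config)  # (n_tc, n_rp)
    final_t = euler_final(net_t, 0.0, config)  # (n_tt, n_rp)
    wins = final_c[:, None, :] > final_t[None, :, :]
    success = wins.mean(axis=2)  # (n_tc, n_tt)

    tc_mesh, tt_mesh = np.meshgrid(tau_c, tau_t, indexing="ij")
    table = pd.DataFrame(
        {
            "tau_colony": tc_mesh.ravel(),
            "tau_trichome": tt_mesh.ravel(),
            "ratio": (tt_mesh / tc_mesh).ravel(),
            "success_proportion": success.ravel(),
        }
    )
    return ScenarioResult(
        "tau",
        table,
        _metadata(
            "tau",
            {"tau_colony": gc, "tau_trichome": gt, "r_p": gr},
            colony,
            trichome,
            stoich,
            config,
        ),
    )
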