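"""Closed-form break-even and crossover thresholds.

Because all fluxes except the biomass-coupled interaction term are
constant, every competitive outcome of the model reduces to a sign
condition on the constant net flux.  Each threshold below is therefore
available in closed form; the scenario sweeps in
:mod:`trichoflux.scenarios` must bracket these values, which makes this
module the independent oracle for the whole pipeline.

Notation: ``net0`` is the zero-respiration net flux
``F_cfix − F_nfix·Y·R``; subscripts ``c``/``t`` denote colony and free
trichome.  "Winning" is strict: exact ties count as non-success.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    COLONY,
    DEFAULT_STOICHIOMETRY,
    TRICHOME,
    MetabolicRates,
    Stoichiometry,
    net_flux,
    nfix_carbon_cost,
)

__all__ = [
    "ThresholdReport",
    "breakeven_respiration",
    "theta_feasibility_limit",
    "rp_crossover",
    "rp_sustain_limit",
    "tau_ratio_bound",
    "tau_win_threshold",
    "ip_crossover",
    "snap_to_grid",
    "all_thresholds",
]


@dataclass(frozen=True)
class ThresholdReport:
    """A named threshold with its units and human-readable derivation."""

    name: str
    value: float
    units: str
    derivation: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("threshold value must be finite")


def breakeven_respiration(
    rates: MetabolicRates, stoich: Stoichiometry = DEFAULT_STOICHIOMETRY
) -> float:
    """Respiration rate at which the net carbon flux is exactly zero.

    Any fixed respiration above ``c_fix − n_fix·Y·R`` produces a net
    loss of stored carbon over the run; units mol C h⁻¹ mol C⁻¹.
    """
    return rates.c_fix - nfix_carbon_cost(rates, stoich)


def theta_feasibility_limit(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    f_res_max: float = 0.02,
) -> float:
    """Largest colony:trichome respiration ratio θ at which colonies can win.

    With trichome respiration ``F ≤ f_res_max`` and colony respiration
    ``θ·F``, the colony storage exceeds the trichome storage iff
    ``F(1−θ)`` exceeds the zero-respiration net-flux gap.  The supremum
    of feasible θ is ``1 − gap/f_res_max``; below it at least one
    trichome respiration rate in (0, f_res_max] lets colonies win.

    Raises ``ValueError`` when the gap exceeds ``f_res_max`` (colonies
    can never win) or ``f_res_max ≤ 0``.
    """
    if f_res_max <= 0:
        raise ValueError("f_res_max must be positive")
    gap = net_flux(trichome, stoich) - net_flux(colony, stoich)
    if gap > f_res_max:
        raise ValueError(
            "net-flux gap exceeds the respiration ceiling: colonies can never win"
        )
    return 1.0 - gap / f_res_max


def rp_crossover(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
) -> float:
    """Shared respiration coefficient r_p above which colonies win.

    With ``F_res = r_p·F_cfix`` for each morphotype, the net fluxes
    cross at ``r_p* = 1 − (cost_t − cost_c)/(c_fix_t − c_fix_c)`` where
    ``cost`` is the nitrogen-fixation carbon drain.  Requires
    ``c_fix_t > c_fix_c`` (otherwise there is no crossover).
    """
    dc = trichome.c_fix - colony.c_fix
    if dc == 0:
        raise ValueError("equal carbon fixation rates: no crossover exists")
    dcost = nfix_carbon_cost(trichome, stoich) - nfix_carbon_cost(colony, stoich)
    return 1.0 - dcost / dc


def rp_sustain_limit(
    rates: MetabolicRates, stoich: Stoichiometry = DEFAULT_STOICHIOMETRY
) -> float:
    """Largest r_p with non-negative net flux: 1 − cost/c_fix."""
    if rates.c_fix <= 0:
        raise ValueError("c_fix must be positive")
    return 1.0 - nfix_carbon_cost(rates, stoich) / rates.c_fix


def tau_ratio_bound(
    colony: MetabolicRates = COLONY, trichome: MetabolicRates = TRICHOME
) -> float:
    """Supremum of τ_t/τ_c for which colonies can ever win.

    Holding carbon fixation fixed and setting ``n_fix = c_fix/τ``, the
    shared-r_p win threshold stays ≤ 1 exactly while
    ``τ_t/τ_c < c_fix_t/c_fix_c``; the bound is the C-fixation ratio
    itself.
    """
    if colony.c_fix <= 0 or trichome.c_fix <= 0:
        raise ValueError("carbon fixation rates must be positive")
    return trichome.c_fix / colony.c_fix


def tau_win_threshold(
    tau_colony: float,
    tau_trichome: float,
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
):
    """Shared r_p above which colonies win, with N fixation set by τ.

    Each morphotype keeps its carbon fixation rate and has
    ``n_fix = c_fix/τ``.  Values > 1 mean colonies never win for any
    admissible respiration coefficient.  Accepts scalars or arrays
    (broadcast) for the two τ values.
    """
    tc = np.asarray(tau_colony, dtype=float)
    tt = np.asarray(tau_trichome, dtype=float)
    dc = trichome.c_fix - colony.c_fix
    if dc <= 0:
        raise ValueError("requires trichome c_fix > colony c_fix")
    dcost = stoich.r_nc * stoich.y_cn * (trichome.c_fix / tt - colony.c_fix / tc)
    out = 1.0 - dcost / dc
    if out.shape == ():
        return float(out)
    return out


def ip_crossover(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    r_p: float = 0.9,
) -> float:
    """Interaction strength i_p at which the two morphotypes tie.

    Under shared respiration coefficient r_p and metabolic scaling
    ``(1+i_p)``, end-of-run storages are equal at
    ``i_p* = r_p (c_fix_t − c_fix_c)/(net0_t − net0_c) − 1``;
    colonies win strictly below it (negative influence favors the
    morphotype with the smaller metabolic term).
    """
    gap = net_flux(trichome, stoich) - net_flux(colony, stoich)
    if gap == 0:
        raise ValueError("zero net-flux gap: morphotypes tie for every i_p")
    return r_p * (trichome.c_fix - colony.c_fix) / gap - 1.0


def snap_to_grid(value: float, grid: np.ndarray, side: str = "below") -> float:
    """Last grid point at or below (or first at/above) an analytic threshold.

    Reported thresholds in sweep studies are grid-resolution values;
    this maps a closed-form threshold onto the sweep grid it would be
    observed at.
    """
    grid = np.asarray(grid, dtype=float)
    if side == "below":
        eligible = grid[grid <= value + 1e-12]
        if eligible.size == 0:
            raise ValueError("no grid point at or below the value")
        return float(eligible[-1])
    if side == "above":
        eligible = grid[grid >= value - 1e-12]
        if eligible.size == 0:
            raise ValueError("no grid point at or above the value")
        return float(eligible[0])
    raise ValueError("side must be 'below' or 'above'")


def all_thresholds(
    colony: MetabolicRates = COLONY,
    trichome: MetabolicRates = TRICHOME,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    f_res_max: float = 0.02,
) -> list[ThresholdReport]:
    """Ledger of every closed-form threshold at the given parameters."""
    return [
        ThresholdReport(
            "breakeven_respiration_colony",
            breakeven_respiration(colony, stoich),
            "mol C h-1 mol C-1",
            "c_fix - n_fix*y_cn*r_nc (colony)",
        ),
        ThresholdReport(
            "breakeven_respiration_trichome",
            breakeven_respiration(trichome, stoich),
            "mol C h-1 mol C-1",
            "c_fix - n_fix*y_cn*r_nc (trichome)",
        ),
        ThresholdReport(
            "theta_feasibility_limit",
            theta_feasibility_limit(colony, trichome, stoich, f_res_max),
            "dimensionless",
            f"1 - (net0_t - net0_c)/f_res_max, f_res_max={f_res_max}",
        ),
        ThresholdReport(
            "rp_crossover",
            rp_crossover(colony, trichome, stoich),
            "dimensionless",
            "1 - (cost_t - cost_c)/(c_fix_t - c_fix_c)",
        ),
        ThresholdReport(
            "rp_sustain_limit_colony",
            rp_sustain_limit(colony, stoich),
            "dimensionless",
            "1 - cost/c_fix (colony)",
        ),
        ThresholdReport(
            "rp_sustain_limit_trichome",
            rp_sustain_limit(trichome, stoich),
            "dimensionless",
            "1 - cost/c_fix (trichome)",
        ),
        ThresholdReport(
            "tau_ratio_bound",
            tau_ratio_bound(colony, trichome),
            "dimensionless",
            "c_fix_t / c_fix_c",
        ),
    ]
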