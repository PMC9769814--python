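"""Coarse-grained carbon-flux model for *Trichodesmium* morphotypes.

The model tracks a single biomass-normalized carbon storage pool
``C_sto`` (mol C) for each morphotype (colony or free trichome).  Its
rate of change is the balance of three constant fluxes, all in
mol C h⁻¹ mol C⁻¹:

    dC_sto/dt = F_cfix − F_nfix · Y^C:N · R_N:C − F_res

where ``F_cfix`` and ``F_nfix`` are the carbon- and nitrogen-fixation
rates, ``Y^C:N`` is the carbon cost per mole of nitrogen fixed, and
``R_N:C`` the cellular N:C quota.  Two optional "interaction" terms
represent net external influence: ``i_p`` multiplies the metabolic net
flux (influence on rates) and ``i_t`` acts proportionally on the stored
carbon itself (influence on biomass), giving the general step

    C(t+Δt) = C(t) + Δt · [ (1 + i_p)(F_cfix − F_nfix Y R) − F_res + i_t · C(t) ]

integrated by forward Euler with hourly steps over 30 days by default.
Fluxes are deliberately *not* scaled by the current storage (growth is
linear except under ``i_t``); storage may go negative — no floor is
applied, since net carbon loss is a meaningful model outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetabolicRates",
    "Stoichiometry",
    "SimulationConfig",
    "Trajectory",
    "COLONY",
    "TRICHOME",
    "DEFAULT_STOICHIOMETRY",
    "DEFAULT_CONFIG",
    "nfix_carbon_cost",
    "net_flux",
    "integrate",
    "euler_final",
    "closed_form_final",
]


@dataclass(frozen=True)
class MetabolicRates:
    """Per-morphotype fixation rates.

    Parameters
    ----------
    c_fix : float
        Carbon fixation rate, mol C h⁻¹ mol C⁻¹ (biomass-normalized).
    n_fix : float
        Nitrogen fixation rate, mol N h⁻¹ mol N⁻¹.
    label : str
        Morphotype identifier, e.g. ``"colony"`` or ``"trichome"``.
    """

    c_fix: float
    n_fix: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c_fix) and math.isfinite(self.n_fix)):
            raise ValueError("fixation rates must be finite")
        if self.c_fix < 0 or self.n_fix < 0:
            raise ValueError("fixation rates must be non-negative")

    @property
    def tau(self) -> float:
        """C:N fixation-rate ratio τ = F_cfix / F_nfix (requires n_fix > 0)."""
        if self.n_fix <= 0:
            raise ZeroDivisionError("tau undefined for n_fix = 0")
        return self.c_fix / self.n_fix

    def with_tau(self, tau: float) -> "MetabolicRates":
        """Return rates with the same c_fix and n_fix replaced by c_fix / τ."""
        if tau <= 0:
            raise ValueError("tau must be positive")
        return MetabolicRates(self.c_fix, self.c_fix / tau, self.label)


@dataclass(frozen=True)
class Stoichiometry:
    """Conversion constants linking nitrogen fixation to carbon cost.

    ``y_cn`` is the carbon cost of fixing one mole of nitrogen
    (mol C mol N⁻¹); the default of 1 follows the electron balance of a
    typical carbohydrate.  ``r_nc`` is the cellular N:C quota
    (mol N mol C⁻¹), default 0.159.
    """

    y_cn: float = 1.0
    r_nc: float = 0.159

    def __post_init__(self) -> None:
        if self.y_cn <= 0 or self.r_nc <= 0:
            raise ValueError("stoichiometric constants must be strictly positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings: initial storage, horizon and step size."""

    c0: float = 100.0
    duration_hours: float = 720.0  # 30 days
    dt_hours: float = 1.0

    def __post_init__(self) -> None:
        if self.dt_hours <= 0:
            raise ValueError("dt_hours must be positive")
        if self.duration_hours < 0:
            raise ValueError("duration_hours must be non-negative")
        if abs(self.duration_hours / self.dt_hours - round(self.duration_hours / self.dt_hours)) > 1e-9:
            raise ValueError("duration_hours must be an integer multiple of dt_hours")

    @property
    def n_steps(self) -> int:
        return round(self.duration_hours / self.dt_hours)


@dataclass(frozen=True)
class Trajectory:
    """Time series of stored carbon from a single integration."""

    times: np.ndarray = field(repr=False)
    c_sto: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.c_sto):
            raise ValueError("times and c_sto must have equal length")

    @property
    def delta_c_sto(self) -> float:
        """Net change in storage over the run (final − initial), mol C."""
        return float(self.c_sto[-1] - self.c_sto[0])

    @property
    def final(self) -> float:
        return float(self.c_sto[-1])


# Reported metabolic rates: colonies fix C and N more slowly per biomass
# than free trichomes.
TRICHOME = MetabolicRates(c_fix=0.015, n_fix=0.0075, label="trichome")
COLONY = MetabolicRates(c_fix=0.010, n_fix=0.004, label="colony")
DEFAULT_STOICHIOMETRY = Stoichiometry()
DEFAULT_CONFIG = SimulationConfig()


def nfix_carbon_cost(rates: MetabolicRates, stoich: Stoichiometry = DEFAULT_STOICHIOMETRY) -> float:
    """Carbon drain of nitrogen fixation: F_nfix · Y^C:N · R_N:C.

    Returned in mol C h⁻¹ mol C⁻¹, i.e. on the same footing as the
    carbon fixation and respiration fluxes.
    """
    return rates.n_fix * stoich.y_cn * stoich.r_nc


def net_flux(
    rates: MetabolicRates,
    stoich: Stoichiometry = DEFAULT_STOICHIOMETRY,
    f_res: float = 0.0,
    i_p: float = 0.0,
) -> float:
    """Constant net carbon flux (1 + i_p)(F_cfix − F_nfix Y R) − F_res.

    With ``i_p = 0`` this is the plain flux balance; ``i_p`` scales the
    metabolic term only — respiration is not subject to the external
    influence.  ``f_res`` must be non-negative.
    """
    if f_res < 0:
        raise ValueError("respiration rate must be non-negative")
    return (1.0 + i_p) * (rates.c_fix - nfix_carbon_cost(rates, stoich)) - f_res


def integrate(net: float, i_t: float = 0.0, config: SimulationConfig = DEFAULT_CONFIG) -> Trajectory:
    """Forward-Euler integration of dC/dt = net + i_t · C.

    Records the full trajectory: ``n_steps + 1`` points including the
    initial condition.  ``net`` is the constant metabolic net flux
    (mol C h⁻¹ mol C⁻¹); ``i_t`` (h⁻¹) couples the flux to the current
    storage.  Non-finite inputs are rejected.
    """
    if not (math.isfinite(net) and math.isfinite(i_t)):
        raise ValueError("net and i_t must be finite")
    n = config.n_steps
    dt = config.dt_hours
    c = np.empty(n + 1)
    c[0] = config.c0
    for k in range(n):
        c[k + 1] = c[k] + dt * (net + i_t * c[k])
    times = np.arange(n + 1) * dt
    return Trajectory(times=times, c_sto=c)


def euler_final(net, i_t=0.0, config: SimulationConfig = DEFAULT_CONFIG):
    """Final storage of the forward-Euler recurrence, vectorized.

    ``net`` and ``i_t`` may be scalars or broadcastable arrays; the
    recurrence ``C ← C + Δt(net + i_t·C)`` is applied ``n_steps`` times
    elementwise.  This is the workhorse used by the scenario sweeps.
    """
    net = np.asarray(net, dtype=float)
    i_t = np.asarray(i_t, dtype=float)
    if not (np.all(np.isfinite(net)) and np.all(np.isfinite(i_t))):
        raise ValueError("net and i_t must be finite")
    shape = np.broadcast_shapes(net.shape, i_t.shape)
    c = np.full(shape, float(config.c0))
    dt = config.dt_hours
    for _ in range(config.n_steps):
        c = c + dt * (net + i_t * c)
    if c.shape == ():
        return float(c)
    return c


def closed_form_final(net: float, i_t: float = 0.0, config: SimulationConfig = DEFAULT_CONFIG) -> float:
    """Exact solution of the discrete Euler recurrence.

    For i_t = 0:  C_N = c0 + net · N · Δt.  Otherwise, with growth
    factor g = 1 + i_t·Δt, the geometric sum gives
    C_N = g^N · c0 + net·Δt·(g^N − 1)/(g − 1); the (g^N − 1) factor is
    evaluated as expm1(N·log1p(i_t·Δt)) so the expression stays accurate
    down to vanishingly small i_t, where it degrades gracefully to the
    linear case.

    Serves as the independent analytic oracle for :func:`integrate` and
    :func:`euler_final`.
    """
    n = config.n_steps
    dt = config.dt_hours
    gm1 = i_t * dt  # g − 1
    if gm1 == 0.0 or 1.0 + gm1 == 1.0:
        return config.c0 + net * n * dt
    growth = math.expm1(n * math.log1p(gm1))  # g^N − 1
    return config.c0 * (1.0 + growth) + net * dt * growth / gm1
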