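# Methods

## Model

The state variable is a biomass-normalized stored-carbon pool C_sto
(mol C) per morphotype, with dynamics

    dC_sto/dt = F_cfix − F_nfix·Y^C:N·R_N:C − F_res + F_int

All fluxes are constants in mol C h⁻¹ mol C⁻¹ except the optional
interaction term F_int, which takes one of two forms:

* rate influence: F_int = i_p · (F_cfix − F_nfix·Y·R), i_p ∈ [−2, 2] —
  a multiplier on the net metabolic term. Respiration is *not* scaled by
  i_p, so at i_p = −1 only respiration remains.
* biomass influence: F_int = i_t · C_sto, i_t ∈ [−0.002, 0.002] h⁻¹ —
  e.g. mortality (negative) or subsidy (positive) proportional to
  standing stock.

Two modeling assumptions are deliberate and load-bearing:

1. **Fluxes are not scaled by the current storage** (except via i_t).
   Growth is therefore linear in time outside the i_t scenario. All
   competitive outcomes reduce to sign conditions on the constant net
   flux, which is what makes the closed-form thresholds exact.
2. **Storage may go negative; no extinction floor.** Net carbon loss is
   a reported model outcome, not a failure state.

A unit note: the storage pool is carbon (mol C) and all fluxes are
biomass-C-normalized carbon rates; the N-fixation term enters as a
carbon drain via the Y^C:N·R_N:C conversion.

## Parameters

| parameter | value | units | meaning |
|---|---|---|---|
| F_cfix (trichome / colony) | 0.015 / 0.010 | mol C h⁻¹ mol C⁻¹ | carbon fixation |
| F_nfix (trichome / colony) | 0.0075 / 0.004 | mol N h⁻¹ mol N⁻¹ | nitrogen fixation |
| Y^C:N | 1 | mol C mol N⁻¹ | C cost of N fixation (electron balance of a typical carbohydrate) |
| R_N:C | 0.159 | mol N mol C⁻¹ | cellular N:C quota |
| C_sto(0) | 100 | mol C | initial storage, both morphotypes |
| horizon / step | 720 h / 1 h | — | 30 days, forward Euler |

The fixation rates are the published morphotype measurements; they imply
C:N fixation ratios τ = F_cfix/F_nfix of 2.0 (trichomes) and 2.5
(colonies), ratio τ_t/τ_c = 0.8.

## Integration and its oracle

`integrate`/`euler_final` apply the explicit recurrence
C ← C + Δt(net + i_t·C). `closed_form_final` is the exact solution of
that *discrete* recurrence (not of the continuous ODE): linear in the
i_t = 0 case, geometric otherwise, with the (gᴺ − 1) factor computed as
expm1(N·log1p(i_t·Δt)) so the expression stays accurate for arbitrarily
small i_t instead of cancelling catastrophically. Property tests hold
the two routes together to ≤ 1e−9 relative over randomized
(net, i_t, horizon).

Because both morphotypes share C_sto(0) and i_t, and the Euler
amplification factor (1 + i_t·Δt)ᴺ is positive throughout the studied
range, the end-of-run winner is decided by the sign of the net-flux
difference alone — which is why the i_t sweep shows an
i_t-invariant winner.

## Scenario designs

* **fixed-equal** — F_res on 0→0.02 step 0.0005 (41 points), shared.
* **θ (unequal)** — 500 trichome respiration rates ~ U[0, 0.02); colony
  rate θ×draw; θ on 0.01→1 step 0.01. The same 500 draws are reused
  across all θ (variance reduction; the per-θ analytic tail probability
  P(draw > gap/(1−θ)) is emitted alongside for cross-checking). The
  ceiling `f_res_max` is configurable; raising it raises the feasible-θ
  limit 1 − gap/f_res_max accordingly.
* **r_p** — F_res = r_p·F_cfix per morphotype, r_p on 0.001→1 step 0.001.
* **i_p** — i_p on −2→2 step 0.01, at r_p ∈ {0, 0.3, 0.6, 0.9} (shared
  respiration-coefficient convention).
* **i_t** — i_t on −0.002→0.002 step 0.0001, same r_p levels. The
  "signed log difference" column is sign(d)·log₁₀|d| with exact zero
  mapped to NaN; the raw difference is kept next to it since the log
  transform of a signed quantity is otherwise lossy.
* **τ** — both τ grids 1→5 step 0.1, n_fix = c_fix/τ, with a shared r_p
  grid 0→1 step 0.01 per pair; success = fraction of r_p values where
  colonies end strictly ahead.

Grid steps not fixed by the published designs (i_p, i_t, τ, shared r_p)
were chosen once as the finest steps that bracket every analytic
threshold while keeping each full sweep under a few seconds; all are
config-overridable. Grids are built index-wise (start + k·step), never
by repeated addition, so points are platform-exact to 1e−12.

Winning is strict (ties are failures). Thresholds are reported at full
float precision; grid-snapped counterparts (last winning grid point) are
what a sweep at the stated increments observes — e.g. break-evens
0.009364/0.0138075 are observed as 0.009/0.0135 on the 0.0005 grid, and
the feasible-θ limit 0.777825 as 0.77 on the 0.01 grid.

## Randomness and reproducibility

One master seed (default 42) derives a labelled substream per scenario
via `numpy.random.SeedSequence` with a CRC32 label hash; only the θ
scenario consumes randomness. Identical seed + grids + rates reproduce
every table bit-identically, and each CSV's JSON sidecar records
everything needed to do so.

## What the sweeps do and do not show

The inputs here are parameters, not measurements: the "synthetic data"
is the seeded uniform respiration sample of the θ scenario, which
emulates an unobserved spread of trichome respiration rates, plus the
deterministic grids. Passing sweeps therefore demonstrate internal
consistency of the flux model and its analytic thresholds at the
published rates — not that real colonies behave this way. Real
*Trichodesmium* has diel rate cycling, storage-dependent metabolism,
oxygen management and nutrient co-limitation, none of which are modeled;
nor are grazing, epibiont interactions or CO₂ diffusion limits beyond
what the aggregate i_p/i_t terms can caricature.

## Design choices on open points

* **Shared r_p in the τ scenario.** Whether the respiration coefficient
  is shared or varied independently per morphotype is underdetermined;
  shared is used because it reproduces both the ≈42 % success ceiling
  and the ratio bound τ_t/τ_c = c_fix_t/c_fix_c = 1.5. (Independent
  variation yields a lower ceiling, ≈37 % at the reported rates.)
* **Shared r_p in the i_p scenario** for the same reason: the sweep's
  cost levels are stated as fractions of each morphotype's own carbon
  fixation.
* **Success at ratio 0.8.** At the reported-rate τ values
  (τ_c = 2.5, τ_t = 2.0) the shared-r_p win threshold is 0.8887, giving
  a success fraction of 1 − 0.8887 ≈ 11.1 % over a uniform r_p ∈ [0, 1]
  (11.9 % on the default 0.01 grid); averaging over all grid pairs with
  ratio 0.8 gives ≈10 %. A figure of ~14 % sometimes quoted for this
  configuration is not recovered by any reading of the model we could
  construct; this package reports its computed values.

## Known limitations

* Forward Euler at Δt = 1 h is exact for the linear (i_t = 0) cases and
  a first-order approximation of exponential growth otherwise; the
  discrete recurrence, not the ODE, is the object all oracles target.
* The θ-scenario success proportions carry binomial noise of order
  √(p(1−p)/500) ≈ 2 %; the grid ceiling θ = 0.77 itself is robust to the
  seed (the infeasibility of θ ≥ 0.78 is analytic, and feasibility at
  0.77 fails only with probability ≈3·10⁻⁸ per 500-draw sample).
* No uncertainty is attached to the input rates themselves; all
  thresholds are conditional on the tabulated point values.
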