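"""Scenario sweeps: published experiment designs and their invariants."""

import numpy as np
import pandas as pd
import pytest

from trichoflux import (
    COLONY,
    DEFAULT_CONFIG,
    DEFAULT_STOICHIOMETRY,
    TRICHOME,
    SweepGrid,
    breakeven_respiration,
    colony_success_proportion,
    ip_crossover,
    rp_crossover,
    rp_sustain_limit,
    run_fixed_equal,
    run_ip,
    run_it,
    run_rp,
    run_tau,
    run_theta,
    tau_win_threshold,
)

STOICH = DEFAULT_STOICHIOMETRY


def _pivot(table, value="delta_c_sto", index="f_res"):
    return table.pivot(index=index, columns="morphotype", values=value)

@pytest.fixture(scope="module")
def fixed_equal_result():
    return run_fixed_equal()


@pytest.fixture(scope="module")
def theta_result():
    return run_theta(seed=42)


@pytest.fixture(scope="module")
def rp_result():
    return run_rp()


@pytest.fixture(scope="module")
def ip_result():
    return run_ip()


@pytest.fixture(scope="module")
def it_result():
    return run_it()


@pytest.fixture(scope="module")
def tau_result(coarse_tau_grids):
    return run_tau(
        tau_grid_colony=coarse_tau_grids["tau"],
        tau_grid_trichome=coarse_tau_grids["tau"],
        rp_grid=coarse_tau_grids["r_p"],
    )



class TestFixedEqual:
    def test_zero_respiration_storage_gains(self, fixed_equal_result):
        piv = _pivot(fixed_equal_result.table)
        assert piv.loc[0.0, "colony"] == pytest.approx(6.74208, rel=1e-9)
        assert piv.loc[0.0, "trichome"] == pytest.approx(9.9414, rel=1e-9)

    def test_breakeven_grid_points(self, fixed_equal_result):
        """Colonies first lose at 0.0095 and trichomes at 0.014 on the 0.0005 grid."""
        piv = _pivot(fixed_equal_result.table)
        col = piv["colony"]
        tri = piv["trichome"]
        assert col[col >= 0].index.max() == pytest.approx(0.009)
        assert col[col < 0].index.min() == pytest.approx(0.0095)
        assert tri[tri >= 0].index.max() == pytest.approx(0.0135)
        assert tri[tri < 0].index.min() == pytest.approx(0.014)

    def test_analytic_breakeven_in_first_losing_cell(self, fixed_equal_result):
        piv = _pivot(fixed_equal_result.table)
        for morph, rates in [("colony", COLONY), ("trichome", TRICHOME)]:
            be = breakeven_respiration(rates, STOICH)
            series = piv[morph]
            last_win = series[series >= 0].index.max()
            first_lose = series[series < 0].index.min()
            assert last_win <= be < first_lose

    def test_trichomes_always_ahead_with_equal_respiration(self, fixed_equal_result):
        piv = _pivot(fixed_equal_result.table)
        assert (piv["trichome"] > piv["colony"]).all()


class TestTheta:
    def test_equal_respiration_never_succeeds(self, theta_result):
        tab = theta_result.table
        assert tab.loc[tab.theta == 1.0, "success_proportion"].item() == 0.0

    def test_success_ceiling_on_grid(self, theta_result):
        tab = theta_result.table
        nonzero = tab[tab.success_proportion > 0]
        assert nonzero.theta.max() == pytest.approx(0.77)

    def test_success_tracks_analytic_tail(self, theta_result):
        """Empirical proportions match the uniform-tail probability to binomial error."""
        tab = theta_result.table
        n = theta_result.metadata["n_draws"]
        se = np.sqrt(tab.analytic_tail_probability * (1 - tab.analytic_tail_probability) / n)
        assert (np.abs(tab.success_proportion - tab.analytic_tail_probability) <= 4 * se + 1e-12).all()

    def test_success_nonincreasing_in_theta(self, theta_result):
        s = theta_result.table.success_proportion.to_numpy()
        assert (np.diff(s) <= 1e-12).all()

    def test_bit_identical_rerun(self, theta_result):
        again = run_theta(seed=42)
        pd.testing.assert_frame_equal(theta_result.table, again.table)
        assert run_theta(seed=43).table.equals(theta_result.table) is False

    def test_higher_respiration_ceiling_raises_theta_ceiling(self):
        tab = run_theta(f_res_max=0.04, seed=42).table
        ceiling = tab[tab.success_proportion > 0].theta.max()
        assert 0.88 <= ceiling <= 0.89


class TestRp:
    def test_crossover_bracket_contains_analytic_value(self, rp_result):
        piv = _pivot(rp_result.table, index="r_p")
        wins = piv[piv["colony"] > piv["trichome"]]
        first_win = wins.index.min()
        assert first_win == pytest.approx(0.889)
        assert first_win - 0.001 <= rp_crossover() < first_win

    def test_sustain_limits_bracket_analytic_values(self, rp_result):
        piv = _pivot(rp_result.table, index="r_p")
        for morph, rates in [("colony", COLONY), ("trichome", TRICHOME)]:
            series = piv[morph]
            last_keep = series[series >= 0].index.max()
            limit = rp_sustain_limit(rates, STOICH)
            assert last_keep <= limit < last_keep + 0.001

    def test_grid_refinement_moves_crossover_at_most_one_cell(self):
        fine = run_rp(rp_grid=SweepGrid("r_p", 0.001, 1.0, 0.0005))
        piv = _pivot(fine.table, index="r_p")
        first_win_fine = piv[piv["colony"] > piv["trichome"]].index.min()
        assert abs(first_win_fine - 0.889) <= 0.001


class TestIp:
    def test_no_metabolic_cost_colonies_never_match(self, ip_result):
        tab = ip_result.table[ip_result.table.r_p == 0.0]
        piv = tab.pivot(index="i_p", columns="morphotype", values="delta_c_sto")
        active = piv[piv.index > -1.0 + 1e-9]
        assert (active["colony"] < active["trichome"]).all()

    def test_flip_bracket_contains_analytic_crossover(self, ip_result):
        tab = ip_result.table[ip_result.table.r_p == 0.9]
        piv = tab.pivot(index="i_p", columns="morphotype", values="delta_c_sto")
        colony_wins = piv["colony"] > piv["trichome"]
        # negative influence favors colonies, positive favors trichomes
        last_win = piv.index[colony_wins][-1]
        star = ip_crossover(r_p=0.9)
        assert last_win < star <= last_win + 0.01
        assert (piv.index[colony_wins] < star).all()

    def test_full_annihilation_leaves_only_respiration(self, ip_result):
        tab = ip_result.table[np.isclose(ip_result.table.i_p, -1.0)]
        for _, row in tab.iterrows():
            c_fix = COLONY.c_fix if row.morphotype == "colony" else TRICHOME.c_fix
            assert row.delta_c_sto == pytest.approx(-720 * row.r_p * c_fix, rel=1e-9, abs=1e-9)


class TestIt:
    def test_winner_invariant_to_biomass_interaction(self, it_result):
        """Trichomes win at r_p ≤ 0.6 and colonies at 0.9, for every i_t."""
        tab = it_result.table
        for r_p in (0.0, 0.3, 0.6):
            assert (tab.loc[tab.r_p == r_p, "difference"] < 0).all()
        assert (tab.loc[tab.r_p == 0.9, "difference"] > 0).all()

    def test_no_interaction_matches_rp_scenario(self, it_result):
        rp_tab = run_rp(rp_grid=SweepGrid("r_p", values=(0.3,))).table
        expected = rp_tab.set_index("morphotype")["final_c_sto"]
        row = it_result.table[(it_result.table.r_p == 0.3) & (it_result.table.i_t == 0.0)]
        assert row["c_sto_colony"].item() == pytest.approx(expected["colony"], rel=1e-12)
        assert row["c_sto_trichome"].item() == pytest.approx(expected["trichome"], rel=1e-12)

    def test_signed_log_magnitude(self, it_result):
        tab = it_result.table
        nz = tab[tab.difference != 0]
        expected = np.sign(nz.difference) * np.log10(np.abs(nz.difference))
        assert np.allclose(nz.signed_log10_difference, expected)


class TestTau:
    def test_no_success_at_or_beyond_ratio_bound(self, tau_result):
        beyond = tau_result.table[tau_result.table.ratio >= 1.5 - 1e-12]
        assert (beyond.success_proportion == 0.0).all()

    def test_success_matches_win_threshold(self, tau_result):
        """Each pair's success equals the grid measure above the analytic threshold."""
        gr = np.asarray(tau_result.metadata["grids"]["r_p"]["step"])
        rp = np.arange(0.0, 1.0 + 1e-9, gr)
        for _, row in tau_result.table.iterrows():
            thr = tau_win_threshold(row.tau_colony, row.tau_trichome)
            expected = np.mean(rp > thr)
            assert row.success_proportion == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_tau(self, tau_result):
        tab = tau_result.table
        # more N fixation pressure on trichomes (higher τ_t) never helps colonies
        for tc, group in tab.groupby("tau_colony"):
            s = group.sort_values("tau_trichome").success_proportion.to_numpy()
            assert (np.diff(s) <= 1e-12).all()
        for tt, group in tab.groupby("tau_trichome"):
            s = group.sort_values("tau_colony").success_proportion.to_numpy()
            assert (np.diff(s) >= -1e-12).all()

    def test_tau_below_one_rejected_unless_overridden(self):
        bad = SweepGrid("tau", 0.5, 1.0, 0.5)
        with pytest.raises(ValueError):
            run_tau(tau_grid_colony=bad)
        ok = run_tau(
            tau_grid_colony=bad,
            tau_grid_trichome=SweepGrid("tau", values=(2.0,)),
            rp_grid=SweepGrid("r_p", 0.0, 1.0, 0.5),
            allow_tau_below_one=True,
        )
        assert len(ok.table) == 2


class TestSuccessProportion:
    def test_counting_and_strictness(self):
        assert colony_success_proportion([1, 2, 3], [1, 2, 3]) == 0.0  # ties lose
        assert colony_success_proportion([4, 1, 5, 0, 2, 9, 0, 0, 0, 0],
                                         [3, 2, 4, 1, 3, 2, 1, 1, 1, 1]) == 0.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            colony_success_proportion([], [])
        with pytest.raises(ValueError):
            colony_success_proportion([1, 2], [1])
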