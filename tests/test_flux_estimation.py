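"""Branch-point flux ratios, the analytical flux solution, replicate
statistics and the least-squares cross-check."""

import logging

import numpy as np
import pandas as pd
import pytest

import emuflux as ef
from emuflux.fluxes import (
    FluxModel,
    FluxRatio,
    compare_conditions,
    compute_branch_ratios,
    estimate_fluxes,
    fit_fluxes_least_squares,
    ratios_from_flux_vector,
    solve_fluxes_analytical,
)
from emuflux.mid import MID, MIDSet, apply_natural_abundance, ElementalFormula

SERINE_BRANCH_NET = """
SOURCE 3PG 3
SOURCE SER_E 3
BIOMASS SER 0.4
BIOMASS GLY 0.6
SSP: 1 3PG (abc) -> 1 SER (abc)
SER_UPT: 1 SER_E (abc) -> 1 SER (abc)
SHMT: 1 SER (abc) -> 1 GLY (ab) + 1 MEETHF (c)
FOR_EX: 1 MEETHF (a) -> 1 FOR (a)
SINK FOR
BRANCH SER SSP = SER:3 / 3PG:3 REST SER_UPT
"""


def _mids(**kwargs):
    return {k: MID(k, tuple(v)) for k, v in kwargs.items()}


class TestBranchRatios:
    def test_reporter_ratio_example(self):
        """3PG m+3 = 0.8, serine m+3 = 0.08 -> de novo share 0.10."""
        net = ef.parse_network_text(SERINE_BRANCH_NET)
        mids = _mids(**{"3PG": [0.2, 0, 0, 0.8], "SER": [0.92, 0, 0, 0.08]})
        (ratio,) = compute_branch_ratios(mids, net, None)
        assert ratio.shares["SSP"] == pytest.approx(0.10, abs=1e-12)
        assert ratio.shares["SER_UPT"] == pytest.approx(0.90, abs=1e-12)

    def test_single_source_limit(self, network, tracer, control):
        """Salvage share 0 <=> nucleotide reporter equals its de novo value."""
        shares = {br.pool: {e.reaction: s for e, s in
                            zip(br.entries, [1.0])} for br in network.branches
                  if br.pool == "IMP"}
        fluxes = dict(control.fluxes.values)
        fluxes["IMP_SALV"] = 0.0
        fluxes["IMP_DN"] = network.biomass["IMP"]
        mids_set = ef.simulate_mid_dataset(
            ef.Scenario("x", ef.FluxVector(fluxes, "x")), network, tracer,
            n_replicates=1)
        ratios = compute_branch_ratios(mids_set, network, tracer, "x", "1")
        imp = next(r for r in ratios if r.pool == "IMP")
        assert imp.shares["IMP_DN"] == pytest.approx(1.0, abs=1e-9)

    def test_unlabeled_everything_is_unidentifiable(self):
        net = ef.parse_network_text(SERINE_BRANCH_NET)
        mids = _mids(**{"3PG": [1, 0, 0, 0], "SER": [1, 0, 0, 0]})
        (ratio,) = compute_branch_ratios(mids, net, None)
        assert not ratio.identifiable

    def test_noisy_share_clipped_with_warning(self, caplog):
        net = ef.parse_network_text(SERINE_BRANCH_NET)
        mids = _mids(**{"3PG": [0.9, 0, 0, 0.1], "SER": [0.88, 0, 0, 0.12]})
        with caplog.at_level(logging.WARNING, logger="emuflux"):
            (ratio,) = compute_branch_ratios(mids, net, None)
        assert ratio.shares["SSP"] == 1.0
        assert ratio.clipped
        assert "clipped" in caplog.text

    def test_inversion_recovers_anaplerotic_share(self, network, tracer, control):
        ds = ef.simulate_mid_dataset(control, network, tracer, n_replicates=1)
        ratios = compute_branch_ratios(ds, network, tracer, "control", "1")
        oaa = next(r for r in ratios if r.pool == "OAA")
        assert oaa.shares["PC"] == pytest.approx(0.25, abs=1e-9)

    def test_missing_mid_raises(self, network, tracer):
        with pytest.raises(KeyError, match="SER"):
            compute_branch_ratios({}, network, tracer)


class TestAnalyticalSolve:
    def test_single_chain_flux_equals_demand(self):
        net = ef.parse_network_text(
            "SOURCE S 2\nBIOMASS A 1.0\nR1: 1 S (ab) -> 1 A (ab)"
        )
        fv = solve_fluxes_analytical([], net)
        assert fv["R1"] == pytest.approx(1.0)

    def test_hand_solved_serine_balance(self):
        """De novo share 0.1; serine demand = biomass 0.4 + glycine-route 0.6
        -> 3PG->Ser flux = 0.1 x 1.0."""
        net = ef.parse_network_text(SERINE_BRANCH_NET)
        ratios = [FluxRatio("SER", {"SSP": 0.1, "SER_UPT": 0.9})]
        fv = solve_fluxes_analytical(ratios, net)
        assert fv["SHMT"] == pytest.approx(0.6)
        assert fv["SSP"] == pytest.approx(0.1 * (0.6 + 0.4))
        assert fv["SER_UPT"] == pytest.approx(0.9)

    def test_underdetermined_names_missing_branches(self, network):
        with pytest.raises(ValueError, match="underdetermined"):
            solve_fluxes_analytical([], network)

    def test_infeasible_ratios_raise(self, network):
        shares = {"SER": 0.15, "GLY": 0.05, "ASP": 0.7, "IMP": 0.85,
                  "OAA": 0.25, "UMP": 0.8}
        ratios = []
        for br in network.branches:
            r = shares[br.pool]
            ratios.append(FluxRatio(br.pool, {br.entries[0].reaction: r,
                                              br.rest: 1 - r}))
        with pytest.raises(ValueError, match="infeasible"):
            # glycine-from-serine share 0.05 starves the one-carbon balance
            solve_fluxes_analytical(ratios, network)

    def test_mass_balance_and_ratio_consistency(self, network, tracer, control,
                                                control_mids):
        ratios = compute_branch_ratios(control_mids, network, tracer,
                                       "control", "1")
        fv = solve_fluxes_analytical(ratios, network)
        assert fv.steady_state_residual(network) < 1e-8
        assert min(fv.values.values()) >= 0
        rederived = {r.pool: r for r in ratios_from_flux_vector(fv, network)}
        for ratio in ratios:
            for rxn, share in ratio.shares.items():
                assert rederived[ratio.pool].shares[rxn] == pytest.approx(
                    share, abs=1e-8)


class TestEstimate:
    def test_noise_free_recovery(self, network, tracer, control, inhibited):
        for sc in (control, inhibited):
            ds = ef.simulate_mid_dataset(sc, network, tracer, n_replicates=1)
            est = estimate_fluxes(ds, network, tracer, sc.name)
            truth = sc.fluxes.as_series()
            rel = ((est.mean - truth).abs() / truth).max()
            assert rel < 1e-6

    def test_identical_replicates_zero_sd(self, network, tracer, control):
        ds = ef.simulate_mid_dataset(control, network, tracer, n_replicates=3)
        est = estimate_fluxes(ds, network, tracer, "control")
        assert est.n_replicates == 3
        assert (est.sd == 0).all()

    def test_bad_replicate_excluded_with_reason(self, network, tracer, control):
        ds = ef.simulate_mid_dataset(control, network, tracer, n_replicates=2)
        for met in network.balanced_pools():
            n = network.n_carbons(met)
            ds.add(met, "control", "2",
                   MID(met, (1.0,) + (0.0,) * n, "simulated"))  # unlabeled: unidentifiable
        est = estimate_fluxes(ds, network, tracer, "control")
        assert est.n_replicates == 1
        assert "2" in est.excluded

    def test_no_usable_replicates_raises(self, network, tracer):
        ds = MIDSet()
        for met in network.balanced_pools():
            n = network.n_carbons(met)
            ds.add(met, "c", "1", MID(met, (1.0,) + (0.0,) * n, "simulated"))
        with pytest.raises(ValueError, match="no usable replicate"):
            estimate_fluxes(ds, network, tracer, "c")


class TestCompare:
    def test_identical_estimates(self, network, tracer, control):
        ds = ef.simulate_mid_dataset(control, network, tracer, n_replicates=3)
        est = estimate_fluxes(ds, network, tracer, "control")
        cmp_df = compare_conditions(est, est)
        assert np.allclose(cmp_df["ratio"], 1.0)
        assert (cmp_df["p"] == 1.0).all()

    def test_zero_variance_different_means(self, network, tracer, control,
                                           inhibited):
        est_c = estimate_fluxes(
            ef.simulate_mid_dataset(control, network, tracer, n_replicates=3),
            network, tracer, "control")
        est_i = estimate_fluxes(
            ef.simulate_mid_dataset(inhibited, network, tracer, n_replicates=3),
            network, tracer, "phgdh_inhibited")
        cmp_df = compare_conditions(est_c, est_i)
        assert cmp_df.loc["PPP", "ratio"] == pytest.approx(0.4, abs=1e-6)
        assert cmp_df.loc["PPP", "p"] == 0.0  # deterministic difference

    def test_mismatched_names_rejected(self, network, tracer, control):
        ds = ef.simulate_mid_dataset(control, network, tracer, n_replicates=2)
        est = estimate_fluxes(ds, network, tracer, "control")
        other = ef.FluxEstimate("x", est.per_replicate,
                                est.mean.iloc[::-1], est.sd.iloc[::-1])
        with pytest.raises(ValueError, match="names"):
            compare_conditions(est, other)


class TestLeastSquares:
    def test_agrees_with_analytical_on_noise_free_data(self, network, tracer,
                                                       control, control_mids):
        fv = fit_fluxes_least_squares(control_mids, network, tracer, "control",
                                      n_starts=2, seed=0)
        truth = control.fluxes.as_series()
        rel = ((fv.as_series() - truth).abs() / truth).max()
        assert rel < 1e-4

    def test_multi_start_stability(self, network, tracer, control_mids):
        a = fit_fluxes_least_squares(control_mids, network, tracer, "control",
                                     n_starts=1, seed=1)
        b = fit_fluxes_least_squares(control_mids, network, tracer, "control",
                                     n_starts=3, seed=99)
        rel = ((a.as_series() - b.as_series()).abs() /
               a.as_series().clip(lower=1e-9)).max()
        assert rel < 1e-6

    def test_identical_data_identical_fits(self, network, tracer, control_mids):
        a = fit_fluxes_least_squares(control_mids, network, tracer, "control",
                                     n_starts=1, seed=5)
        b = fit_fluxes_least_squares(control_mids, network, tracer, "control",
                                     n_starts=1, seed=5)
        assert a.values == b.values


class TestFluxModel:
    def test_summary_and_tables(self, network, tracer, control):
        ds = ef.simulate_mid_dataset(control, network, tracer, n_replicates=3)
        res = FluxModel(ds, network, tracer).fit()
        text = res.summary()
        assert "G6P->R5P" in text and "control" in text
        table = res.flux_table()
        assert set(table["replicate"]) == {"1", "2", "3", "mean", "sd"}

    def test_auto_natural_abundance_correction(self, network, tracer, control):
        """Measured-style MIDs (with natural isotopes folded in) estimate the
        same fluxes after the automatic correction."""
        ds = ef.simulate_mid_dataset(control, network, tracer, n_replicates=1)
        measured = ds.map(lambda mid: apply_natural_abundance(
            mid, ElementalFormula(C=mid.n_carbons)))
        res = FluxModel(measured, network, tracer, natural_abundance="auto").fit()
        truth = control.fluxes.as_series()
        rel = ((res["control"].mean - truth).abs() / truth).max()
        assert rel < 1e-6
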