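"""Operational fits and transduction-coefficient bias statistics."""

import numpy as np
import pandas as pd
import pytest

from gpcrbias.assaysim import (
    LigandPathwayParams,
    NoiseModel,
    example_bias_study,
    simulate_concentration_response_study,
)
from gpcrbias.bias import (
    bias_interval,
    delta_delta_log_r,
    delta_log_r,
    fit_operational,
    transduction_bias,
)
from gpcrbias.doseresponse import ConcentrationResponse
from gpcrbias.operational import observed_ec50, observed_emax, operational_response

CONC = np.logspace(-12, -6, 9)


def cr_from_params(p, conc=CONC, block="B1"):
    df = simulate_concentration_response_study([p], conc, n_blocks=1)
    df["block"] = block
    return ConcentrationResponse(
        p.ligand_id, p.pathway_id,
        df[["concentration_M", "response", "block"]])


class TestFitOperational:
    def test_closed_form_n1_reduction(self):
        # tau=1, K_A=10 nM, Em=100: observed Emax 50, EC50 5 nM, log_R 8.0
        p = LigandPathwayParams("L", "cAMP", Em=100.0, log_tau=0.0, log_KA=-8.0)
        assert observed_emax(100.0, 0.0) == pytest.approx(50.0)
        assert observed_ec50(0.0, -8.0) == pytest.approx(5e-9)
        ref = LigandPathwayParams("REF", "cAMP", Em=100.0, log_tau=1.0, log_KA=-8.0)
        fit = fit_operational([cr_from_params(ref), cr_from_params(p)])
        assert fit.log_R("L") == pytest.approx(8.0, abs=1e-6)

    def test_fitted_curve_matches_logistic_mapping(self):
        # the n=1 operational model IS a logistic with Emax = Em*tau/(1+tau),
        # EC50 = K_A/(1+tau); check the fitted parameters honor the mapping
        ref = LigandPathwayParams("REF", "cAMP", Em=100.0, log_tau=1.0, log_KA=-8.0)
        par = LigandPathwayParams("PAR", "cAMP", Em=100.0, log_tau=-0.3, log_KA=-7.2)
        fit = fit_operational([cr_from_params(ref), cr_from_params(par)])
        for p in (ref, par):
            row = fit.ligands[fit.ligands["ligand"] == p.ligand_id].iloc[0]
            emax_fit = observed_emax(fit.Em, row["log_tau"], fit.basal)
            ec50_fit = observed_ec50(row["log_tau"], row["log_KA"])
            assert emax_fit == pytest.approx(observed_emax(100.0, p.log_tau), rel=1e-6)
            assert ec50_fit == pytest.approx(observed_ec50(p.log_tau, p.log_KA), rel=1e-6)

    def test_full_agonist_limit(self):
        # tau -> large at fixed K_A: observed Emax -> Em, EC50 -> K_A/(1+tau)
        assert observed_emax(100.0, 3.0) == pytest.approx(100.0, rel=1e-2)
        assert observed_ec50(3.0, -8.0) == pytest.approx(1e-8 / 1001.0)

    def test_identical_ligands_identical_log_r(self):
        a = LigandPathwayParams("A", "cAMP", Em=100.0, log_tau=0.5, log_KA=-8.0)
        b = LigandPathwayParams("B", "cAMP", Em=100.0, log_tau=0.5, log_KA=-8.0)
        fit = fit_operational([cr_from_params(a), cr_from_params(b)])
        assert fit.log_R("A") == pytest.approx(fit.log_R("B"), abs=1e-6)

    def test_matches_grid_search_oracle_on_toy_data(self):
        # dense (log_tau, log_KA) grid with fixed shared parameters as oracle
        conc = np.logspace(-10, -6, 5)
        p = LigandPathwayParams("L", "p", Em=80.0, log_tau=0.2, log_KA=-8.0)
        rng = np.random.default_rng(9)
        y = p.response(conc) + rng.normal(0, 1.0, conc.shape)
        cr = ConcentrationResponse("L", "p", pd.DataFrame(
            {"concentration_M": conc, "response": y, "block": "B1"}))
        ref = LigandPathwayParams("REF", "p", Em=80.0, log_tau=1.5, log_KA=-8.0)
        yref = ref.response(conc)
        cr_ref = ConcentrationResponse("REF", "p", pd.DataFrame(
            {"concentration_M": conc, "response": yref, "block": "B1"}))
        fit = fit_operational([cr_ref, cr], n_hill=1.0)

        lt_grid = np.arange(-1.0, 1.0, 0.01)
        lk_grid = np.arange(-9.0, -7.0, 0.01)
        Em_fit, basal_fit = fit.Em, fit.basal
        best = (np.inf, None, None)
        for lt in lt_grid:
            pred = operational_response(conc[None, :], Em_fit, lt,
                                        lk_grid[:, None], 1.0, basal_fit)
            sse = ((pred - y) ** 2).sum(1)
            i = int(np.argmin(sse))
            if sse[i] < best[0]:
                best = (sse[i], lt, lk_grid[i])
        _, g_lt, g_lk = best
        row = fit.ligands[fit.ligands["ligand"] == "L"].iloc[0]
        assert abs(row["log_tau"] - g_lt) <= 0.011
        assert abs(row["log_KA"] - g_lk) <= 0.011

    def test_weak_partial_agonist_flagged_with_wide_error(self):
        ref = LigandPathwayParams("REF", "p", Em=100.0, log_tau=1.0, log_KA=-8.0)
        weak = LigandPathwayParams("W", "p", Em=100.0, log_tau=-1.8, log_KA=-8.0)
        noise = NoiseModel(cv_multiplicative=0.05, sd_additive=0.5, seed=2)
        df = simulate_concentration_response_study([ref, weak], CONC, 1, noise)
        crs = [ConcentrationResponse.from_study(df, l, "p") for l in ("REF", "W")]
        fit = fit_operational(crs)
        row = fit.ligands[fit.ligands["ligand"] == "W"].iloc[0]
        ref_row = fit.ligands[fit.ligands["ligand"] == "REF"].iloc[0]
        assert row["weak_partial"]
        assert row["se_log_R"] > ref_row["se_log_R"]

    def test_reference_ligand_required_when_named(self):
        a = LigandPathwayParams("A", "p", Em=100.0, log_tau=0.5, log_KA=-8.0)
        with pytest.raises(ValueError, match="reference"):
            fit_operational([cr_from_params(a)], reference_ligand="GLP-1")


class TestDeltaStatistics:
    def make_fit(self, log_rs, block="B1"):
        ligands = pd.DataFrame({
            "ligand": list(log_rs),
            "log_tau": 0.0, "log_KA": 0.0,
            "log_R": list(log_rs.values()),
            "se_log_R": 0.0, "weak_partial": False,
        })
        from gpcrbias.bias import OperationalFit
        return OperationalFit("p", block, 100.0, 1.0, 0.0, ligands, True, 0.0)

    def test_delta_arithmetic_and_reference_zero(self):
        fit = self.make_fit({"REF": 8.5, "A": 8.0, "B": 6.5})
        d = delta_log_r(fit, "REF").set_index("ligand")["delta_log_R"]
        assert d["A"] == pytest.approx(-0.5)
        assert d["B"] == pytest.approx(-2.0)  # 100-fold weaker transduction
        assert d["REF"] == 0.0  # exactly

    def test_delta_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            delta_log_r(self.make_fit({"A": 8.0}), "REF")

    def test_delta_delta_arithmetic_and_antisymmetry(self):
        d_camp = pd.DataFrame({"ligand": ["A"], "block": ["B1"], "delta_log_R": [-0.5]})
        d_barr = pd.DataFrame({"ligand": ["A"], "block": ["B1"], "delta_log_R": [-1.0]})
        dd = delta_delta_log_r(d_camp, d_barr)
        assert dd["delta_delta"].iloc[0] == pytest.approx(0.5)
        assert 10 ** dd["delta_delta"].iloc[0] == pytest.approx(3.16, abs=0.01)
        flipped = delta_delta_log_r(d_barr, d_camp)
        assert flipped["delta_delta"].iloc[0] == pytest.approx(-0.5)

    def test_delta_delta_uses_block_intersection(self):
        d_camp = pd.DataFrame({"ligand": ["A", "A"], "block": ["B1", "B2"],
                               "delta_log_R": [-0.5, -0.6]})
        d_barr = pd.DataFrame({"ligand": ["A"], "block": ["B1"],
                               "delta_log_R": [-1.0]})
        dd = delta_delta_log_r(d_camp, d_barr)
        assert list(dd["block"]) == ["B1"]


class TestBiasInterval:
    def test_t_interval_arithmetic(self):
        res = bias_interval([0.4, 0.5, 0.6, 0.5, 0.5])
        assert res.mean == pytest.approx(0.5)
        assert res.sem == pytest.approx(0.0316, abs=2e-4)
        assert res.ci95[0] == pytest.approx(0.412, abs=2e-3)
        assert res.ci95[1] == pytest.approx(0.588, abs=2e-3)
        assert res.significant

    def test_symmetric_values_not_significant(self):
        res = bias_interval([-0.3, 0.0, 0.3])
        assert not res.significant

    def test_degenerate_spread_zero_width_interval(self):
        res = bias_interval([0.3, 0.3, 0.3])
        assert res.ci95 == (pytest.approx(0.3), pytest.approx(0.3))
        assert res.significant

    def test_single_block_interval_undefined(self):
        res = bias_interval([0.3])
        assert res.ci95 is None and res.significant is None


class TestTransductionBias:
    def test_noise_free_recovery_and_reference_zeroing(self):
        study = simulate_concentration_response_study(
            example_bias_study(0.5), n_blocks=3, noise=NoiseModel())
        results, table = transduction_bias(study, "GIP")
        ref = table[table["is_reference"]].iloc[0]
        assert ref["delta_delta_log_R"] == 0.0  # exact in every block
        ref_res = [r for r in results if r.is_reference][0]
        assert (ref_res.per_block["delta_delta"] == 0.0).all()
        ana = table[~table["is_reference"]].iloc[0]
        assert ana["delta_delta_log_R"] == pytest.approx(0.5, abs=1e-6)
        assert ana["bias_factor"] == pytest.approx(10 ** 0.5, rel=1e-4)

    def test_scale_invariance_of_delta_delta(self):
        # multiplying all responses of one pathway by a positive constant is a
        # system-scale change and must not move the bias estimate
        study = simulate_concentration_response_study(
            example_bias_study(0.5), n_blocks=2,
            noise=NoiseModel(0.03, 0.0, 0.05, seed=8))
        scaled = study.copy()
        scaled.loc[scaled["pathway"] == "barr2", "response"] *= 7.3
        _, t1 = transduction_bias(study, "GIP")
        _, t2 = transduction_bias(scaled, "GIP")
        a = t1[~t1["is_reference"]]["delta_delta_log_R"].iloc[0]
        b = t2[~t2["is_reference"]]["delta_delta_log_R"].iloc[0]
        assert a == pytest.approx(b, abs=1e-4)

    def test_missing_reference_ligand_rejected(self):
        study = simulate_concentration_response_study(
            example_bias_study(), n_blocks=2, noise=NoiseModel())
        with pytest.raises(ValueError, match="reference ligand"):
            transduction_bias(study, "nonexistent")
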