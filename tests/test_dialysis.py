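"""Dialysis pipeline: chamber arithmetic, least-squares fits, cross-experiment SEM."""

import numpy as np
import pytest

from vlbind.binding_models import (
    CooperativeParams,
    EquivalentNSParams,
    InsufficientDataError,
    bound_cooperative,
    bound_equivalent_ns,
)
from vlbind.dialysis import (
    DialysisExperiment,
    FitResult,
    bound_free_from_chambers,
    fit_binding_model,
    protein_molar_uM,
    read_dialysis_csv,
    receptor_conc_uM,
    summarize_experiments,
    write_dialysis_csv,
)
from vlbind.synthetic import GeneratorConfig, gen_binding_curve, gen_dialysis


def make_experiment(series, **kw):
    defaults = dict(experiment_id="e0", protein_mg_ml=1.0, ligand_name="dye")
    defaults.update(kw)
    return DialysisExperiment(series=np.asarray(series, float), **defaults)


class TestChamberArithmetic:
    def test_definition(self):
        exp = make_experiment([[40.0, 30.0, 10.0]])
        curve = bound_free_from_chambers(exp)
        assert curve.free[0] == 10.0
        assert curve.bound[0] == 20.0

    def test_no_binding(self):
        curve = bound_free_from_chambers(make_experiment([[20.0, 10.0, 10.0]]))
        assert curve.bound[0] == 0.0

    def test_negative_difference_floored(self):
        curve = bound_free_from_chambers(make_experiment([[20.0, 9.9, 10.0]]))
        assert curve.bound[0] == 0.0

    def test_empty_series_raises(self):
        exp = make_experiment([[1.0, 1.0, 1.0]])
        exp.series = exp.series[:0]
        with pytest.raises(InsufficientDataError):
            bound_free_from_chambers(exp)

    def test_generator_inversion_noiseless(self, mb_params, mb_totals):
        """Chamber arithmetic exactly inverts the generator's mass balance."""
        exps = gen_dialysis(
            "cooperative", mb_params, 1.0, mb_totals, GeneratorConfig(seed=0)
        )
        curve = bound_free_from_chambers(exps[0])
        truth = gen_binding_curve(
            "cooperative",
            CooperativeParams(mb_params.k1, mb_params.k2, receptor_conc_uM(1.0, "cooperative")),
            mb_totals,
        )
        np.testing.assert_allclose(curve.free, truth.free, rtol=1e-12)
        np.testing.assert_allclose(curve.bound, truth.bound, rtol=1e-12, atol=1e-12)


def test_protein_molar_conversion():
    assert protein_molar_uM(1.0, 11_800.0) == pytest.approx(84.7458, rel=1e-4)
    assert receptor_conc_uM(1.0, "cooperative") == pytest.approx(42.3729, rel=1e-4)
    assert receptor_conc_uM(1.0, "equivalent_ns") == pytest.approx(84.7458, rel=1e-4)


class TestFit:
    def test_cooperative_round_trip(self, mb_params, mb_totals):
        exps = gen_dialysis("cooperative", mb_params, 1.0, mb_totals, GeneratorConfig(seed=0))
        curve = bound_free_from_chambers(exps[0])
        fit = fit_binding_model(curve, "cooperative", receptor_conc_uM(1.0, "cooperative"))
        assert fit.converged
        assert fit.params["k1"] == pytest.approx(207.0, rel=1e-6)
        assert fit.params["k2"] == pytest.approx(21.0, rel=1e-6)

    def test_equivalent_ns_round_trip(self, ssz_params, ssz_totals):
        exps = gen_dialysis("equivalent_ns", ssz_params, 5.0, ssz_totals, GeneratorConfig(seed=0))
        curve = bound_free_from_chambers(exps[0])
        fit = fit_binding_model(curve, "equivalent_ns", receptor_conc_uM(5.0, "equivalent_ns"))
        assert fit.converged
        assert fit.params["k1"] == pytest.approx(698.0, rel=1e-6)
        assert fit.params["ns"] == pytest.approx(21.0, rel=1e-6)

    def test_rss_matches_independent_recomputation(self, mb_params, mb_totals):
        cfg = GeneratorConfig(seed=3, noise_model="gaussian_relative", noise_scale=0.05)
        exps = gen_dialysis("cooperative", mb_params, 1.0, mb_totals, cfg)
        curve = bound_free_from_chambers(exps[0])
        r0 = receptor_conc_uM(1.0, "cooperative")
        fit = fit_binding_model(curve, "cooperative", r0)
        pred = bound_cooperative(curve.free, CooperativeParams(fit.params["k1"], fit.params["k2"], r0))
        rss = float(np.sum((pred - curve.bound) ** 2))
        assert fit.rss == pytest.approx(rss, rel=1e-12, abs=1e-12)

    def test_optimum_agrees_with_grid_search(self, mb_totals):
        """Coarse brute-force (k1, k2) scan brackets the least-squares optimum."""
        truth = CooperativeParams(100.0, 10.0, 40.0)
        curve = gen_binding_curve("cooperative", truth, mb_totals)
        fit = fit_binding_model(curve, "cooperative", truth.r0)

        k1_grid = np.geomspace(10.0, 1000.0, 41)
        k2_grid = np.geomspace(1.0, 100.0, 41)
        rss = np.array(
            [
                [
                    np.sum(
                        (bound_cooperative(curve.free, CooperativeParams(a, b, truth.r0)) - curve.bound)
                        ** 2
                    )
                    for b in k2_grid
                ]
                for a in k1_grid
            ]
        )
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        step = np.log(k1_grid[1] / k1_grid[0])
        assert abs(np.log(fit.params["k1"] / k1_grid[i])) <= step
        assert abs(np.log(fit.params["k2"] / k2_grid[j])) <= step

    def test_overparameterised_fit_surfaces_degeneracy(self, ssz_totals):
        """Cooperative fit to one-site data must expose the unidentifiable k2."""
        one_site = EquivalentNSParams(k1=300.0, ns=0.0, r0=100.0)
        curve = gen_binding_curve("equivalent_ns", one_site, ssz_totals)
        fit = fit_binding_model(curve, "cooperative", 50.0)
        k2, se_k2 = fit.params["k2"], fit.std_errors["k2"]
        # either k2 escapes to a huge value or its SE dwarfs the estimate
        assert (k2 > 100 * one_site.k1) or (se_k2 > k2)

    def test_degenerate_free_concentrations_rejected(self):
        from vlbind.binding_models import BindingCurve

        curve = BindingCurve(free=[5.0, 5.0, 5.0, 5.0], bound=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fit_binding_model(curve, "cooperative", 10.0)

    def test_too_few_points_rejected(self):
        from vlbind.binding_models import BindingCurve

        curve = BindingCurve(free=[1.0, 2.0], bound=[0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            fit_binding_model(curve, "cooperative", 10.0)

    def test_fit_r0_recovers_receptor_concentration(self, mb_totals):
        truth = CooperativeParams(207.0, 21.0, 42.0)
        curve = gen_binding_curve("cooperative", truth, mb_totals)
        fit = fit_binding_model(curve, "cooperative", r0=1.0, fit_r0=True)
        assert fit.params["r0"] == pytest.approx(42.0, rel=1e-4)
        assert fit.params["k1"] == pytest.approx(207.0, rel=1e-3)


class TestSummary:
    @staticmethod
    def _fit(k1, k2):
        return FitResult(
            model="cooperative",
            params={"k1": k1, "k2": k2},
            std_errors={"k1": 1.0, "k2": 1.0},
            rss=0.0,
            converged=True,
            n_points=12,
        )

    def test_two_point_mean_sem(self):
        s = summarize_experiments([self._fit(200.0, 20.0), self._fit(214.0, 22.0)])
        assert s.means["k1"] == pytest.approx(207.0)
        assert s.sems["k1"] == pytest.approx(7.0)
        assert s.n_experiments == 2

    def test_identical_fits_zero_sem(self):
        s = summarize_experiments([self._fit(207.0, 21.0)] * 3)
        assert s.sems["k1"] == 0.0

    def test_nonconverged_excluded_and_counted(self):
        bad = self._fit(999.0, 99.0)
        bad.converged = False
        s = summarize_experiments([self._fit(200.0, 20.0), self._fit(214.0, 22.0), bad])
        assert s.n_experiments == 2
        assert s.n_excluded == 1

    def test_fewer_than_two_converged_raises(self):
        with pytest.raises(InsufficientDataError):
            summarize_experiments([self._fit(207.0, 21.0)])

    def test_mixed_models_rejected(self):
        other = FitResult("equivalent_ns", {"k1": 1.0, "ns": 0.0}, {"k1": 1, "ns": 1}, 0.0, True, 12)
        with pytest.raises(ValueError):
            summarize_experiments([self._fit(1.0, 1.0), other])


def test_stochastic_recovery_and_sem_shrinkage(mb_params, mb_totals):
    """With 5% noise: mean k1 near truth; SEM of the mean shrinks roughly as 1/sqrt(n)."""
    r0 = receptor_conc_uM(1.0, "cooperative")
    truth = (mb_params.k1, mb_params.k2)

    def sem_for(n, seed):
        cfg = GeneratorConfig(
            seed=seed, noise_model="gaussian_relative", noise_scale=0.05, n_experiments=n
        )
        exps = gen_dialysis("cooperative", mb_params, 1.0, mb_totals, cfg)
        fits = [
            fit_binding_model(bound_free_from_chambers(e), "cooperative", r0, init=truth)
            for e in exps
        ]
        return summarize_experiments(fits)

    s8 = sem_for(8, 11)
    assert abs(s8.means["k1"] - 207.0) <= 2.0 * s8.sems["k1"] + 1e-9

    # RMS over repeats: mean(SEM^2) is unbiased for SD^2/n, unlike mean(SEM)
    ns = np.array([2, 4, 8, 16])
    sems = np.array(
        [np.sqrt(np.mean([sem_for(int(n), 100 + r).sems["k1"] ** 2 for r in range(24)])) for n in ns]
    )
    slope = np.polyfit(np.log(ns), np.log(sems), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.2)


def test_dialysis_csv_round_trip(tmp_path, mb_params, mb_totals):
    exps = gen_dialysis(
        "cooperative", mb_params, 0.5, mb_totals,
        GeneratorConfig(seed=4, noise_model="gaussian_relative", noise_scale=0.02, n_experiments=2),
    )
    path = tmp_path / "dialysis.csv"
    write_dialysis_csv(exps, path)
    back = read_dialysis_csv(path)
    assert [e.experiment_id for e in back] == [e.experiment_id for e in exps]
    np.testing.assert_allclose(back[0].series, exps[0].series)
    assert back[1].protein_mg_ml == 0.5
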