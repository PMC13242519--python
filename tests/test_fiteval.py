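import numpy as np
import pandas as pd
import pytest

from grnloop import network as net
from grnloop.fiteval import (L1Config, chi2_objective, fit, gof_stats,
                             l1_reduce_refit, per_gene_chi2, plot_fits)
from grnloop.odemodel import build_model
from grnloop.preprocess import TimeSeriesDataset
from grnloop.synthdata import make_ground_truth, simulate_dataset


def make_dataset(rows, n_eff=15):
    return TimeSeriesDataset(
        table=pd.DataFrame(rows, columns=["gene", "time_days", "mean",
                                          "se_eff", "n_cells"]),
        n_eff=n_eff)


class TestGofStats:
    def test_p_monotone_decreasing_in_chi2(self):
        ps = [gof_stats(c, 50, 20).p_value for c in (10.0, 20.0, 40.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_criteria_monotone_increasing_in_k(self):
        stats = [gof_stats(30.0, 84, k) for k in (10, 20, 40)]
        assert stats[0].aic < stats[1].aic < stats[2].aic
        assert stats[0].bic < stats[1].bic < stats[2].bic

    def test_chi2_zero_gives_p_one(self):
        assert gof_stats(0.0, 10, 2).p_value == pytest.approx(1.0)

    def test_n_not_greater_than_k_is_undefined_with_warning(self):
        with pytest.warns(UserWarning):
            stats = gof_stats(5.0, 10, 10)
        assert np.isnan(stats.p_value)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            gof_stats(-1.0, 10, 2)

    def test_aicc_exceeds_aic_when_defined(self):
        stats = gof_stats(12.0, 30, 10)
        assert stats.aicc > stats.aic


class TestChi2Objective:
    def test_single_record_hand_value(self):
        adj = net.build_adjacency([], genes=["A"])
        model = build_model(adj)
        # delta tiny and b = 0: the state stays at x0 = 0.6
        ds = make_dataset([("A", 0.0, 0.6, 0.1, 15),
                           ("A", 1.0, 0.4, 0.1, 15)])
        r, chi2 = chi2_objective(model, {"b_1": 0.0, "delta_1": 1e-3}, ds,
                                 x0=np.array([0.6]))
        assert chi2 == pytest.approx(4.0, rel=1e-2)  # ((0.6-0.4)/0.1)^2

    def test_perfect_simulation_gives_zero(self, cascade_truth,
                                           cascade_noisefree):
        r, chi2 = chi2_objective(cascade_truth.model, cascade_truth.params,
                                 cascade_noisefree.dataset,
                                 x0=cascade_truth.x0)
        assert chi2 == pytest.approx(0.0, abs=1e-8)

    def test_total_equals_summation_oracle(self, cascade_truth, cascade_noisy):
        r, chi2 = chi2_objective(cascade_truth.model, cascade_truth.params,
                                 cascade_noisy.dataset, x0=cascade_truth.x0)
        assert chi2 == pytest.approx(float(np.sum(np.square(r))), rel=1e-12)

    def test_nonpositive_se_rejected(self, cascade_truth):
        ds = make_dataset([("G01", 0.0, 0.5, 0.0, 15)])
        with pytest.raises(ValueError):
            chi2_objective(cascade_truth.model, cascade_truth.params, ds)


class TestFit:
    def test_start_at_truth_converges_immediately(self, cascade_truth,
                                                  cascade_noisefree):
        model = cascade_truth.model
        start = np.array([cascade_truth.params[n] for n in model.param_names])
        fr = fit(model, cascade_noisefree.dataset, n_starts=1, seed=0,
                 starts=start[None, :], x0=cascade_truth.x0,
                 rtol=1e-8, atol=1e-10)
        assert fr.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_reproduces_result(self, cascade_truth, cascade_noisy):
        kwargs = dict(n_starts=3, seed=42, max_nfev=40,
                      x0=cascade_truth.x0)
        a = fit(cascade_truth.model, cascade_noisy.dataset, **kwargs)
        b = fit(cascade_truth.model, cascade_noisy.dataset, **kwargs)
        assert a.chi2 == b.chi2
        assert a.params == b.params

    def test_more_starts_never_worse(self, cascade_truth, cascade_noisy):
        """A superset of starts can only improve or tie the best chi2."""
        model = cascade_truth.model
        from grnloop.fiteval import _Objective, sample_starts

        obj = _Objective(model, cascade_noisy.dataset, x0=cascade_truth.x0)
        all_starts = sample_starts(model, obj.free_names, 4, seed=3)
        small = fit(model, cascade_noisy.dataset, starts=all_starts[:2],
                    x0=cascade_truth.x0, max_nfev=40)
        large = fit(model, cascade_noisy.dataset, starts=all_starts,
                    x0=cascade_truth.x0, max_nfev=40)
        assert large.chi2 <= small.chi2 + 1e-9

    def test_total_chi2_equals_per_point_sum(self, cascade_truth,
                                             cascade_noisy):
        fr = fit(cascade_truth.model, cascade_noisy.dataset, n_starts=2,
                 seed=1, max_nfev=40, x0=cascade_truth.x0)
        assert fr.chi2 == pytest.approx(fr.per_point["chi2"].sum(), abs=1e-8)
        assert fr.n == len(fr.per_point)

    def test_fixed_parameters_are_excluded(self, cascade_truth,
                                           cascade_noisy):
        model = cascade_truth.model
        fixed = {"b_1": 0.05}
        fr = fit(model, cascade_noisy.dataset, n_starts=1, seed=2,
                 fixed=fixed, max_nfev=20, x0=cascade_truth.x0)
        assert fr.k == model.n_parameters - 1
        assert fr.params["b_1"] == 0.05


class TestL1ReduceRefit:
    def test_zero_penalty_zero_threshold_is_plain_fit(self, cascade_truth,
                                                      cascade_noisy):
        cfg = L1Config(penalty=0.0, fix_threshold=0.0)
        l1_fit, fixed, reduced, kept = l1_reduce_refit(
            cascade_truth.model, cascade_noisy.dataset, cfg, seed=4,
            n_starts=2, max_nfev=40, x0=cascade_truth.x0)
        assert fixed == {}
        assert reduced.k == cascade_truth.model.n_parameters
        assert len(kept) == cascade_truth.model.n_edges

    def test_spurious_edge_is_fixed_true_edges_survive(self):
        """Planted-sparsity recovery: a zero-strength edge gets fixed."""
        truth = make_ground_truth(3, edge_density=0.0, seed=20)
        genes = truth.genes
        # true edge G01 -> G02 plus a spurious zero-strength G03 -> G02
        adj = net.build_adjacency([("G01", "G02", 1), ("G03", "G02", 1)],
                                  genes=genes)
        gen_model = build_model(adj)
        params = dict(truth.params)
        params["a_2_1"] = 0.9
        params["h_2_1"] = 3.0
        params["a_2_3"] = 0.0
        params["h_2_3"] = 2.0
        gen_truth = type(truth)(model=gen_model, params=params,
                                x0=truth.x0, seed=20)
        syn = simulate_dataset(gen_truth, noise_sd=0.05, seed=21)
        cfg = L1Config(penalty=2.0, prefixes=("a_",), fix_threshold=0.15)
        l1_fit, fixed, reduced, kept = l1_reduce_refit(
            gen_model, syn.dataset, cfg, seed=5, n_starts=8,
            max_nfev=200, x0=gen_truth.x0)
        assert "a_2_3" in fixed
        assert abs(fixed["a_2_3"]) < 0.15
        assert ("G01", "G02", 1) in kept
        assert ("G03", "G02", 1) not in kept

    def test_refit_stays_close_to_l1_fit(self, cascade_truth, cascade_noisy):
        """Reduction stability: chi2 essentially unchanged after refit."""
        cfg = L1Config(penalty=1.0, fix_threshold=0.05)
        l1_fit, fixed, reduced, kept = l1_reduce_refit(
            cascade_truth.model, cascade_noisy.dataset, cfg, seed=6,
            n_starts=4, max_nfev=150, x0=cascade_truth.x0)
        assert reduced.k == cascade_truth.model.n_parameters - len(fixed)
        # the unpenalized refit can only improve on the L1 solution's misfit
        assert reduced.chi2 <= l1_fit.chi2 + 1e-6


class TestPerGeneChi2:
    def _fake_fit(self, rows):
        from grnloop.fiteval import FitResult

        per_point = pd.DataFrame(rows, columns=["gene", "time_days",
                                                "exp_mean", "se",
                                                "simulated", "chi2"])
        return FitResult(params={}, chi2=float(per_point["chi2"].sum()),
                         per_point=per_point, n=len(per_point), k=0)

    def test_totals_and_argmax(self):
        fr = self._fake_fit([("G1", 0, 0, 1, 0, 1.0), ("G1", 1, 0, 1, 0, 2.0),
                             ("G2", 0, 0, 1, 0, 0.5)])
        totals, worst = per_gene_chi2(fr)
        assert dict(zip(totals["gene"], totals["chi2"])) == \
            {"G1": 3.0, "G2": 0.5}
        assert worst == "G1"

    def test_obs_suffix_stripped(self):
        fr = self._fake_fit([("TP53_obs", 0, 0, 1, 0, 1.0)])
        totals, worst = per_gene_chi2(fr)
        assert worst == "TP53"
        assert list(totals["gene"]) == ["TP53"]

    def test_tie_broken_alphabetically_with_warning(self):
        fr = self._fake_fit([("B", 0, 0, 1, 0, 1.0), ("A", 0, 0, 1, 0, 1.0)])
        with pytest.warns(UserWarning):
            _, worst = per_gene_chi2(fr)
        assert worst == "A"

    def test_totals_conserve_total_chi2(self, cascade_truth, cascade_noisy):
        fr = fit(cascade_truth.model, cascade_noisy.dataset, n_starts=1,
                 seed=7, max_nfev=20, x0=cascade_truth.x0)
        totals, _ = per_gene_chi2(fr)
        assert totals["chi2"].sum() == pytest.approx(fr.chi2, abs=1e-8)


class TestPlotFits:
    def test_writes_panel_figure(self, tmp_path, cascade_truth,
                                 cascade_noisy):
        fr = fit(cascade_truth.model, cascade_noisy.dataset, n_starts=1,
                 seed=8, max_nfev=20, x0=cascade_truth.x0)
        paths = plot_fits(fr, cascade_noisy.dataset, model=cascade_truth.model,
                          out_path=tmp_path / "fits", formats=("png",))
        assert len(paths) == 1
        import os

        assert os.path.getsize(paths[0]) > 0

    def test_empty_dataset_rejected(self, cascade_truth):
        from grnloop.fiteval import FitResult

        empty = TimeSeriesDataset(table=pd.DataFrame(
            columns=["gene", "time_days", "mean", "se_eff", "n_cells"]),
            n_eff=15)
        fr = FitResult(params={}, chi2=0.0,
                       per_point=pd.DataFrame(columns=["gene", "time_days",
                                                       "exp_mean", "se",
                                                       "simulated", "chi2"]),
                       n=0, k=0)
        with pytest.raises((ValueError, IndexError)):
            plot_fits(fr, empty)
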