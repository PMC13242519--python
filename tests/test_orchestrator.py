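import numpy as np
import pytest

import grnloop as gl
from grnloop.orchestrator import (LoopConfig, assign_regulation,
                                  lever_analysis, lever_candidates,
                                  load_config, run_loop, run_pipeline)


class TestAssignRegulation:
    def test_overestimation_is_inhibition(self):
        call = assign_regulation([0.8, 0.8], [0.4, 0.4], "G")
        assert call.direction == "inhibition"
        assert call.ratio == pytest.approx(2.0)

    def test_ratio_one_is_activation(self):
        call = assign_regulation([0.4, 0.6], [0.4, 0.6], "G")
        assert call.direction == "activation"

    def test_underestimation_is_activation(self):
        call = assign_regulation([0.2], [0.4], "G")
        assert call.direction == "activation"

    def test_scale_equivariance(self):
        a = assign_regulation([0.2, 0.9], [0.5, 0.1], "G")
        b = assign_regulation([2.0, 9.0], [5.0, 1.0], "G")
        assert a.direction == b.direction

    def test_zero_experimental_mean_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            call = assign_regulation([0.3], [0.0], "G")
        assert call.direction == "inhibition"

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            assign_regulation([0.1], [0.1, 0.2], "G")


@pytest.fixture(scope="module")
def planted():
    truth, syn, kb, start = gl.make_planted_regulator_scenario(seed=0)
    return truth, syn, kb, start


class TestBackloopStep:
    def test_adds_planted_regulator_and_chi2_drops(self, planted):
        truth, syn, kb, start = planted
        provider = gl.MockProvider(kb)
        cfg = LoopConfig(n_starts=8, max_nfev=150, refine_top=4, seed=0)
        state = gl.initial_state(list(start), provider, syn.dataset, cfg)
        new = gl.backloop_step(state, provider, syn.dataset, cfg)
        assert new.history[-1]["added_gene"] == "G01"
        assert new.fit_result.chi2 < state.fit_result.chi2
        # each added gene contributes one residual per time point
        assert new.fit_result.n == state.fit_result.n + 7

    def test_empty_answer_preserves_state(self, planted):
        truth, syn, kb, start = planted
        # knowledge base with no edges: every upstream query is EMPTY
        empty_kb = gl.MockKnowledgeBase(edges={}, genes=truth.genes)
        provider = gl.MockProvider(empty_kb)
        cfg = LoopConfig(n_starts=2, max_nfev=30, seed=0)
        state = gl.initial_state(list(start), provider, syn.dataset, cfg)
        chi2_before = state.fit_result.chi2
        out = gl.backloop_step(state, provider, syn.dataset, cfg)
        assert out.stop_reason == "empty"
        assert out.genes == state.genes
        assert out.fit_result.chi2 == chi2_before

    def test_regulator_not_in_dataset_rejected(self, planted):
        truth, syn, kb, start = planted
        # same planted edges, but the regulator is renamed to a symbol
        # absent from the measured genes
        edges = {("XREG" if a == "G01" else a,
                  "XREG" if b == "G01" else b): s
                 for (a, b), s in kb.edges.items()}
        kb2 = gl.MockKnowledgeBase(edges=edges, genes=truth.genes)
        provider = gl.MockProvider(kb2)
        cfg = LoopConfig(n_starts=2, max_nfev=30, seed=0)
        state = gl.initial_state(list(start), provider, syn.dataset, cfg)
        with pytest.warns(UserWarning):
            out = gl.backloop_step(state, provider, syn.dataset, cfg)
        assert out.stop_reason == "empty"


class TestRunLoop:
    def test_recovers_regulator_and_terminates(self, planted):
        truth, syn, kb, start = planted
        provider = gl.MockProvider(kb)
        cfg = LoopConfig(n_starts=8, max_nfev=150, refine_top=4, max_iter=3,
                         seed=0)
        state = run_loop(list(start), provider, syn.dataset, cfg)
        assert "G01" in state.genes
        assert state.stop_reason in ("converged", "max_iter",
                                     "no_improvement")
        assert len(state.history) == state.iteration

    def test_max_iter_zero_returns_initial_fit(self, planted):
        truth, syn, kb, start = planted
        provider = gl.MockProvider(kb)
        cfg = LoopConfig(n_starts=2, max_nfev=30, max_iter=0, seed=0,
                         alpha=1e-12)
        state = run_loop(list(start), provider, syn.dataset, cfg)
        assert state.iteration == 0
        assert state.stop_reason == "max_iter"

    def test_alpha_one_stops_after_first_fit(self, planted):
        truth, syn, kb, start = planted
        provider = gl.MockProvider(kb)
        cfg = LoopConfig(n_starts=2, max_nfev=30, alpha=1.0, seed=0)
        state = run_loop(list(start), provider, syn.dataset, cfg)
        assert state.iteration == 0
        assert state.stop_reason == "converged"

    def test_initial_genes_must_be_in_dataset(self, planted):
        truth, syn, kb, start = planted
        provider = gl.MockProvider(kb)
        with pytest.raises(ValueError):
            run_loop(["NOSUCH"], provider, syn.dataset, LoopConfig())


@pytest.fixture(scope="module")
def fitted():
    truth = gl.make_ground_truth(3, edge_density=0.4, seed=11)
    syn = gl.simulate_dataset(truth, noise_sd=0.05, seed=12)
    fr = gl.fit(truth.model, syn.dataset, n_starts=1, seed=0,
                starts=truth.model.params_to_vector(truth.params)[None, :],
                max_nfev=30, x0=truth.x0)
    return truth, syn, fr


class TestLeverAnalysis:

    def test_factor_one_rows_are_exactly_zero(self, fitted):
        truth, syn, fr = fitted
        calls = [gl.RegulationCall("G02", "activation", 0, 0, 1.0)]
        report = lever_analysis(truth.model, fr, calls, syn.dataset,
                                factors=(1.0,))
        assert (report["delta_peak"] == 0).all()
        assert (report["delta_auc"] == 0).all()
        assert (report["delta_chi2"] == 0).all()

    def test_scaling_activator_strength_raises_target_auc(self):
        adj = gl.build_adjacency([("A", "B", 1)])
        model = gl.build_model(adj)
        params = {"b_1": 0.8, "delta_1": 1.0, "b_2": 0.02, "delta_2": 1.0,
                  "a_2_1": 0.8, "h_2_1": 2.0}
        import pandas as pd

        from grnloop.fiteval import FitResult
        from grnloop.preprocess import TimeSeriesDataset

        times = [0.0, 1.0, 2.0, 4.0]
        ds = TimeSeriesDataset(table=pd.DataFrame(
            [("A", t, 0.5, 0.05, 15) for t in times]
            + [("B", t, 0.5, 0.05, 15) for t in times],
            columns=["gene", "time_days", "mean", "se_eff", "n_cells"]),
            n_eff=15)
        traj = gl.simulate(model, params, np.array(times),
                           np.array([0.1, 0.1]))
        per_point = pd.DataFrame({
            "gene": ["A"] * 4 + ["B"] * 4,
            "time_days": times * 2,
            "exp_mean": 0.5, "se": 0.05,
            "simulated": np.concatenate([traj.values[:, 0],
                                         traj.values[:, 1]]),
        })
        per_point["chi2"] = ((per_point.simulated - 0.5) / 0.05) ** 2
        fr = FitResult(params=params, chi2=float(per_point.chi2.sum()),
                       per_point=per_point, n=8, k=6)
        calls = [gl.RegulationCall("B", "activation", 0, 0, 0.9)]
        report = lever_analysis(model, fr, calls, ds, factors=(2.0,))
        row = report[report.parameter == "a_2_1"].iloc[0]
        assert row["delta_auc"] > 0

    def test_candidates_limited_to_incoming_parameters(self, fitted):
        truth, _, _ = fitted
        for target in truth.genes:
            names = lever_candidates(truth.model, target)
            gi = truth.genes.index(target) + 1
            for n in names:
                parts = n.split("_")
                assert int(parts[1]) == gi  # every candidate feeds the target

    def test_report_ordering_is_permutation_of_candidates(self, fitted):
        truth, syn, fr = fitted
        calls = [gl.RegulationCall(truth.genes[1], "activation", 0, 0, 0.5)]
        report = lever_analysis(truth.model, fr, calls, syn.dataset,
                                factors=(0.5, 2.0))
        expected = {(n, f) for n in lever_candidates(truth.model,
                                                     truth.genes[1])
                    for f in (0.5, 2.0)}
        assert {(r.parameter, r.factor) for r in report.itertuples()} == \
            expected

    def test_nonpositive_factors_rejected(self, fitted):
        truth, syn, fr = fitted
        with pytest.raises(ValueError):
            lever_analysis(truth.model, fr, [], syn.dataset, factors=(0.0,))


class TestPipelineConfig:
    def test_unknown_key_is_named_in_error(self, tmp_path):
        import yaml

        path = tmp_path / "bad.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump({"dataset": {}, "provider": {},
                            "initial_genes": [], "bogus_key": 1}, fh)
        with pytest.raises(ValueError, match="bogus_key"):
            load_config(path)

    def test_demo_bundle_runs_end_to_end(self, tmp_path):
        paths = gl.make_demo_bundle(tmp_path / "demo", seed=42)
        report = run_pipeline(paths["config"],
                              out_dir=tmp_path / "demo" / "run")
        assert report["summary"]["stop_reason"] in (
            "converged", "empty", "max_iter", "no_improvement")
        assert (tmp_path / "demo" / "run" / "report.json").exists()
        assert (tmp_path / "demo" / "run" / "manifest.json").exists()

    def test_demo_bundle_deterministic(self, tmp_path):
        import filecmp

        a = gl.make_demo_bundle(tmp_path / "a", seed=7)
        b = gl.make_demo_bundle(tmp_path / "b", seed=7)
        assert filecmp.cmp(a["dataset"], b["dataset"], shallow=False)
        assert filecmp.cmp(a["knowledge"], b["knowledge"], shallow=False)
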