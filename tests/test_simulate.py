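import numpy as np
import pandas as pd
import pytest

from sipflow.integrate import GeneClassification, classify_genes
from sipflow.pipeline import PipelineConfig, run_dataset, run_integration
from sipflow.simulate import (SimConfig, TruthTable, evaluate_classification,
                              run_ofdr_experiment, simulate_experiment)


class TestSimConfig:
    def test_class_counts_validated(self):
        with pytest.raises(ValueError, match="exceed"):
            SimConfig(n_genes=100, n_srb=90, n_srp=20)

    def test_lfc_constraints_validated(self):
        with pytest.raises(ValueError, match="margin"):
            SimConfig(lfc_range_log2=(1.0, 2.0))
        with pytest.raises(ValueError, match="margin"):
            SimConfig(null_lfc_max_log2=2.0)

    def test_scaled_preserves_proportions(self):
        cfg = SimConfig().scaled(5000)
        assert cfg.n_genes == 5000
        assert cfg.n_srb == 100
        assert cfg.n_srp == cfg.n_srm == 50


class TestSimulateExperiment:
    def test_same_seed_identical_outputs(self):
        from dataclasses import replace
        cfg = replace(SimConfig().scaled(200), seed=11)
        a_plus, a_minus, a_truth = simulate_experiment(cfg)
        b_plus, b_minus, b_truth = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a_plus.counts.counts,
                                      b_plus.counts.counts)
        pd.testing.assert_frame_equal(a_minus.counts.counts,
                                      b_minus.counts.counts)
        pd.testing.assert_frame_equal(a_truth.table, b_truth.table)

    def test_study_layout_dimensions(self, small_sim):
        b_plus, b_minus, _ = small_sim
        # MT+: 3 dark controls + 5 timepoints x 2 conditions x 3 reps
        assert b_plus.n_samples == 33
        # MT-: (3 + 1) timepoints x 2 conditions x 3 reps over two batches
        assert b_minus.n_samples == 24
        assert set(b_minus.samples["experiment_batch"]) == {"minusA", "minusB"}

    def test_null_counts_match_nb_moments(self):
        """With every gene null and the temporal trend off, control-sample
        variances agree with the NB mean-variance law on average."""
        cfg = SimConfig(n_genes=5000, n_srb=0, n_srp=0, n_srm=0,
                        n_filtered_minus=0, n_filtered_plus=0,
                        trend_on=False, lib_size_range=(1e6, 1e6), seed=1)
        b_plus, _, truth = simulate_experiment(cfg)
        ctrl = b_plus.samples.loc[b_plus.samples["condition"] == "control",
                                  "sample_id"]
        y = b_plus.counts.counts[list(ctrl)].to_numpy(dtype=float)
        mu = truth.table["baseline_plus"].to_numpy()
        phi = truth.table["dispersion_plus"].to_numpy()
        mean_ratio = (y.mean(axis=1) / mu).mean()
        var_ratio = (y.var(axis=1, ddof=1) / (mu + phi * mu ** 2)).mean()
        assert mean_ratio == pytest.approx(1.0, abs=0.02)
        assert var_ratio == pytest.approx(1.0, abs=0.05)

    def test_srp_truth_respects_margins(self, small_sim):
        _, _, truth = small_sim
        t = truth.table
        srp = t[t["true_class"] == "SRP"]
        for tp in (15, 60, 180):
            assert (srp[f"lfc_plus_t{tp}"].abs() > np.log2(3)).all()
            assert (srp[f"lfc_minus_t{tp}"].abs() < 0.2).all()

    def test_minus_effects_scaled_up(self, small_sim):
        _, _, truth = small_sim
        t = truth.table
        srb = t[t["true_class"] == "SRB"]
        ratio = (srb["lfc_minus_t15"] / srb["lfc_plus_t15"]).to_numpy()
        assert np.allclose(ratio, 1.25)


class TestEvaluateClassification:
    def _toy(self, claimed):
        genes = [f"g{i}" for i in range(10)]
        truth = TruthTable(pd.DataFrame({
            "gene_id": genes,
            "true_class": ["SRB", "SRB", "SRP", "SRM", "filtered_minus",
                           "filtered_plus", "null", "null", "null", "null"],
        }).set_index("gene_id"))
        table = pd.DataFrame({
            "gene_id": genes, "gene_class": claimed,
            "discovery_timepoint": np.nan, "lfc_log2_plus": np.nan,
            "lfc_log2_minus": np.nan, "other_side_status": "inconclusive"})
        cls = GeneClassification(table=table, evidence=pd.DataFrame(),
                                 shared=[15, 60, 180])
        return cls, truth

    def test_perfect_classification(self):
        cls, truth = self._toy(["SRB", "SRB", "SRP", "SRM", "SRP", "SRM",
                                "nonresponsive", "nonresponsive",
                                "nonresponsive", "nonresponsive"])
        m = evaluate_classification(cls, truth)
        for c in ("SRB", "SRP", "SRM"):
            assert m[f"recall_{c}"] == 1.0
            assert m[f"precision_{c}"] == 1.0
        assert m["fdp_key_genes"] == 0.0

    def test_hand_computed_confusion(self):
        # one SRB missed, one null falsely claimed SRP
        cls, truth = self._toy(["SRB", "unclassified", "SRP", "SRM", "SRP",
                                "SRM", "SRP", "nonresponsive",
                                "nonresponsive", "nonresponsive"])
        m = evaluate_classification(cls, truth)
        assert m["recall_SRB"] == pytest.approx(0.5)
        assert m["precision_SRB"] == 1.0
        assert m["recall_SRP"] == pytest.approx(1.0)       # 2 of 2 expected
        assert m["precision_SRP"] == pytest.approx(2 / 3)  # 1 false of 3
        assert m["fdp_key_genes"] == pytest.approx(1 / 6)
        assert m["confusion"].loc["null", "SRP"] == 1

    def test_empty_discovery_fdp_zero(self):
        cls, truth = self._toy(["unclassified"] * 10)
        m = evaluate_classification(cls, truth)
        assert m["fdp_key_genes"] == 0.0
        assert m["n_discovered"] == 0


class TestPipelineRecovery:
    def test_stronger_effects_never_hurt_recall(self):
        """Raising every planted fold change (same seeds) cannot lower
        per-class recall."""
        base = SimConfig(seed=5).scaled(2000)
        strong = SimConfig(
            seed=5, lfc_range_log2=(np.log2(3) + 1.5, 5.0)).scaled(2000)
        recalls = {}
        for name, cfg in (("base", base), ("strong", strong)):
            b_plus, b_minus, truth = simulate_experiment(cfg)
            res_plus = run_dataset(b_plus)
            res_minus = run_dataset(b_minus)
            cls = run_integration(res_plus, res_minus, build_evidence=False)
            recalls[name] = evaluate_classification(cls, truth)
        for c in ("SRB", "SRP", "SRM"):
            assert recalls["strong"][f"recall_{c}"] >= \
                recalls["base"][f"recall_{c}"]

    def test_equivalence_step_prevents_srb_leaking_into_srp(self, default_run):
        """Dropping the equivalence requirement (specificity by mere lack of
        significance) strictly increases planted-SRB genes miscalled as
        mating-type specific — the point of equivalence testing."""
        truth = default_run["truth"]
        rp, rm = default_run["plus"], default_run["minus"]
        shared = default_run["classification"].shared
        strict = default_run["classification"]
        loose = classify_genes(rp.decisions, rm.decisions, rp.filter,
                               rm.filter, shared,
                               require_equivalence=False,
                               build_evidence=False)
        srb = set(truth.table.index[truth.table["true_class"] == "SRB"])

        def miscalls(cls):
            t = cls.table.set_index("gene_id")
            sub = t.loc[t.index.isin(srb), "gene_class"]
            return int(sub.isin(["SRP", "SRM"]).sum())

        assert miscalls(loose) > miscalls(strict)

    def test_ofdr_experiment_shape_contract(self):
        cfg = SimConfig(seed=3).scaled(400)
        res = run_ofdr_experiment(cfg, n_reps=2)
        s = res["summary"]
        assert s["n_reps"] == 2
        for key in ("mean_ofdr", "se_ofdr", "mean_fdp_key_genes"):
            assert np.isfinite(s[key])
        assert len(res["replicates"]) == 2
        assert set(res["replicates"]["seed"]) == {3, 4}
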