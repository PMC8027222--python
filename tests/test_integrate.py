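import numpy as np
import pandas as pd
import pytest

from sipflow.integrate import (classification_report, classify_genes,
                               shared_timepoints)
from sipflow.normfilter import FilterResult
from sipflow.stagewise import stagewise_decisions

from conftest import one_timepoint_samples

SHARED = [15, 60, 180]


def make_decisions(genes, confirmed, equivalent, timepoints=SHARED):
    """DecisionTable with prescribed boolean calls (p-values chosen to land
    exactly on the requested decisions)."""
    confirmed = np.atleast_2d(np.asarray(confirmed, dtype=bool))
    equivalent = np.atleast_2d(np.asarray(equivalent, dtype=bool))
    p_screen = np.where(confirmed.any(axis=1), 1e-12, 1.0)
    p_conf = np.where(confirmed, 1e-15, 1.0)
    p_eq = np.where(equivalent, 1e-15, 1.0)
    return stagewise_decisions(p_screen, p_conf, alpha=0.05, p_equiv=p_eq,
                               genes=list(genes), timepoints=list(timepoints))


def make_filter(kept, filtered):
    return FilterResult(kept=list(kept), filtered=list(filtered),
                        cpm_threshold=1.0, min_samples=3)


class TestSharedTimepoints:
    def _samples(self, spec):
        rows = []
        for t, conds in spec.items():
            for c in conds:
                rows.append({"sample_id": f"s{t}{c}", "dataset": "d",
                             "mating_type": "MTplus", "timepoint": t,
                             "condition": c, "replicate": 1})
        from sipflow.ingest import make_sample_table
        return make_sample_table(pd.DataFrame(rows))

    def test_study_layouts_give_15_60_180(self):
        plus = self._samples({0: ["control"],
                              **{t: ["control", "treated"]
                                 for t in [15, 60, 180, 360, 540]}})
        minus = self._samples({t: ["control", "treated"]
                               for t in [15, 60, 180, 600]})
        assert shared_timepoints(plus, minus) == [15, 60, 180]

    def test_identical_grids_full_overlap(self):
        s = self._samples({t: ["control", "treated"] for t in [15, 60]})
        assert shared_timepoints(s, s) == [15, 60]

    def test_disjoint_grids_raise(self):
        a = self._samples({15: ["control", "treated"]})
        b = self._samples({600: ["control", "treated"]})
        with pytest.raises(ValueError):
            shared_timepoints(a, b)


class TestClassify:
    def _case(self, conf_p, eq_p, conf_m, eq_m, filt_p=False, filt_m=False):
        """One-gene scenario; returns the classification row."""
        gene = ["g1"]
        dec_p = make_decisions(gene, [conf_p], [eq_p])
        dec_m = make_decisions(gene, [conf_m], [eq_m])
        fp = make_filter([] if filt_p else gene, gene if filt_p else [])
        fm = make_filter([] if filt_m else gene, gene if filt_m else [])
        cls = classify_genes(dec_p, dec_m, fp, fm, SHARED)
        return cls.table.iloc[0]

    def test_de_plus_equivalent_minus_is_srp(self):
        row = self._case(conf_p=[False, True, False],
                         eq_p=[False] * 3,
                         conf_m=[False] * 3,
                         eq_m=[True, True, True])
        assert row["gene_class"] == "SRP"
        assert row["other_side_status"] == "equivalent"
        assert row["discovery_timepoint"] == 60

    def test_de_both_at_3h_is_srb(self):
        row = self._case(conf_p=[False, False, True], eq_p=[False] * 3,
                         conf_m=[False, False, True], eq_m=[False] * 3)
        assert row["gene_class"] == "SRB"
        assert row["other_side_status"] == "responsive"

    def test_de_minus_filtered_plus_is_srm_diamond(self):
        gene = ["g1"]
        dec_p = make_decisions([], np.zeros((0, 3)), np.zeros((0, 3)))
        dec_m = make_decisions(gene, [[True, False, False]], [[False] * 3])
        fp = make_filter([], gene)
        fm = make_filter(gene, [])
        cls = classify_genes(dec_p, dec_m, fp, fm, SHARED)
        row = cls.table.iloc[0]
        assert row["gene_class"] == "SRM"
        assert row["other_side_status"] == "filtered"

    def test_de_one_side_inconclusive_other_is_unclassified(self):
        row = self._case(conf_p=[True, False, False], eq_p=[False] * 3,
                         conf_m=[False] * 3, eq_m=[True, True, False])
        assert row["gene_class"] == "unclassified"

    def test_equivalent_both_sides_nonresponsive(self):
        row = self._case(conf_p=[False] * 3, eq_p=[True] * 3,
                         conf_m=[False] * 3, eq_m=[True] * 3)
        assert row["gene_class"] == "nonresponsive"

    def test_partial_equivalence_not_enough_for_srp(self):
        # equivalence at only 2 of 3 shared timepoints in MT-
        row = self._case(conf_p=[True, False, False], eq_p=[False] * 3,
                         conf_m=[False] * 3, eq_m=[True, True, False])
        assert row["gene_class"] == "unclassified"

    def test_de_timepoints_only_mode_accepts_partial_equivalence(self):
        gene = ["g1"]
        dec_p = make_decisions(gene, [[True, False, False]], [[False] * 3])
        dec_m = make_decisions(gene, [[False] * 3], [[True, False, False]])
        fp = fm = make_filter(gene, [])
        strict = classify_genes(dec_p, dec_m, fp, fm, SHARED)
        loose = classify_genes(dec_p, dec_m, fp, fm, SHARED,
                               equivalence_mode="de_timepoints_only")
        assert strict.table.iloc[0]["gene_class"] == "unclassified"
        assert loose.table.iloc[0]["gene_class"] == "SRP"

    def test_swapping_datasets_maps_srp_to_srm(self):
        """Full symmetry over 20 random decision tables."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            G = 40
            genes = [f"g{i}" for i in range(G)]
            conf_p = rng.uniform(size=(G, 3)) < 0.25
            conf_m = rng.uniform(size=(G, 3)) < 0.25
            eq_p = rng.uniform(size=(G, 3)) < 0.4
            eq_m = rng.uniform(size=(G, 3)) < 0.4
            filt = rng.uniform(size=G) < 0.15
            kept = [g for g, f in zip(genes, filt) if not f]
            dec_p = make_decisions(kept, conf_p[~filt], eq_p[~filt])
            dec_m = make_decisions(genes, conf_m, eq_m)
            fp = make_filter(kept, [g for g in genes if g not in kept])
            fm = make_filter(genes, [])
            fwd = classify_genes(dec_p, dec_m, fp, fm, SHARED,
                                 build_evidence=False)
            rev = classify_genes(dec_m, dec_p, fm, fp, SHARED,
                                 build_evidence=False)
            swap = {"SRP": "SRM", "SRM": "SRP"}
            expected = [swap.get(c, c) for c in fwd.table["gene_class"]]
            assert list(rev.table["gene_class"]) == expected


class TestReport:
    def test_counts_partition_universe(self, small_run):
        cls = small_run["classification"]
        rep = classification_report(cls)
        assert rep["counts"].sum() == rep["n_universe"] == len(cls.table)

    def test_empty_classification_all_zero(self):
        genes = ["g1"]
        dec = make_decisions(genes, [[False] * 3], [[False] * 3])
        filt = make_filter(genes, [])
        cls = classify_genes(dec, dec, filt, filt, SHARED)
        rep = classification_report(cls)
        assert rep["counts"][["SRB", "SRP", "SRM"]].sum() == 0
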