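"""De novo phenotyping workflow: enumeration, controls, acceptance."""

import numpy as np
import pandas as pd
import pytest

import metaphen as mp
from metaphen.workflow import (
    BLOCK_SUBSETS,
    CandidateDataset,
    _misclassification,
    accept,
    run_denovo,
)


class TestEnumeration:
    def test_yields_exactly_24_datasets(self, integrated, default_cohort):
        datasets = mp.enumerate_datasets(integrated, default_cohort.subjects)
        assert len(datasets) == 24
        assert len({d.dataset_id for d in datasets}) == 24

    def test_copd_scope_halves_the_crossproduct(self, integrated, default_cohort):
        datasets = mp.enumerate_datasets(integrated, default_cohort.subjects)
        copd_only = [d for d in datasets if d.scope == "copd_only"]
        assert len(copd_only) == 12
        for d in copd_only:
            assert d.matrix.shape[0] == 25

    def test_no_block_leakage(self, integrated, default_cohort):
        """Every original-feature dataset contains exactly the features of
        its declared block subset."""
        datasets = mp.enumerate_datasets(integrated, default_cohort.subjects)
        for d in datasets:
            if d.representation != "original":
                continue
            blocks_seen = {integrated.blocks[f] for f in d.matrix.columns}
            assert blocks_seen <= set(BLOCK_SUBSETS[d.subset])
            expected = set(integrated.features_of(*BLOCK_SUBSETS[d.subset]))
            assert set(d.matrix.columns) == expected

    def test_pc_representation_respects_variance_threshold(self, integrated, default_cohort):
        datasets = mp.enumerate_datasets(integrated, default_cohort.subjects,
                                         variance_threshold=0.05)
        for d in datasets:
            if d.representation != "pcs":
                continue
            sub = integrated.subset(BLOCK_SUBSETS[d.subset],
                                    subjects=list(d.matrix.index))
            model = mp.pca(sub.values)
            n_keep = max(int((model.explained_fraction >= 0.05).sum()), 1)
            assert d.matrix.shape[1] == n_keep

    def test_missing_block_is_an_error(self, integrated, default_cohort):
        crippled = integrated.subset(("clinical", "targeted"))
        with pytest.raises(ValueError, match="missing blocks"):
            mp.enumerate_datasets(crippled, default_cohort.subjects)


class TestPositiveControl:
    def _dataset(self, X):
        return CandidateDataset("t/orig/all", "copd_only", "original", "all",
                                X, ("clinical",))

    def test_gold_aligned_structure_beats_random_partitions(self, rng):
        """With label-aligned planted structure the control's CH exceeds the
        CH of random partitions of the same sizes (permutation baseline)."""
        labels = np.repeat(["A", "B", "C", "D"], 6)
        X = pd.DataFrame(rng.standard_normal((24, 12)),
                         index=[f"s{i}" for i in range(24)])
        for j, g in enumerate("ABCD"):
            X.iloc[labels == g, j] += 4.0
        rep = mp.positive_control(self._dataset(X), labels)
        part = np.array([{"A": 1, "B": 2, "C": 3, "D": 4}[g] for g in labels])
        baseline = []
        for _ in range(200):
            perm = rng.permutation(part)
            baseline.append(mp.validity_report(X, perm)["calinski_harabasz"])
        assert rep["calinski_harabasz"] > np.quantile(baseline, 0.99)

    def test_permuted_labels_destroy_structure(self, rng):
        labels = np.repeat(["A", "B", "C", "D"], 6)
        X = pd.DataFrame(rng.standard_normal((24, 12)),
                         index=[f"s{i}" for i in range(24)])
        sils = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(labels)
            rep = mp.positive_control(self._dataset(X), perm, space="raw")
            sils.append(rep["silhouette"])
        assert abs(np.mean(sils)) < 0.1

    def test_copd_only_control_has_four_groups(self, integrated, default_cohort):
        datasets = mp.enumerate_datasets(integrated, default_cohort.subjects)
        ds = next(d for d in datasets if d.dataset_id == "copd_only/original/targeted")
        gold = default_cohort.subjects.set_index("subject_id").loc[
            ds.matrix.index, "gold"].to_numpy()
        rep = mp.positive_control(ds, gold)
        assert rep.k == 4

    def test_control_is_perfectly_stable_by_construction(self, rng):
        labels = np.repeat(["A", "B"], 6)
        X = pd.DataFrame(rng.standard_normal((12, 6)),
                         index=[f"s{i}" for i in range(12)])
        rep = mp.positive_control(self._dataset(X), labels)
        assert rep["apn"] == 0.0


class TestAcceptance:
    def test_perfect_split_better_than_control_is_accepted(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 6)) * 0.1,
                         index=[f"s{i}" for i in range(20)])
        X.iloc[:10] += 5.0
        ds = CandidateDataset("t", "all_subjects", "original", "all", X, ())
        denovo = run_denovo(ds, k_range=(2, 3), apn_columns=None)
        groups = np.array(["COPD"] * 10 + ["control"] * 10)
        control = mp.positive_control(ds, groups, space="raw")
        ok, reasons = accept(ds, denovo, control, group_labels=groups)
        assert ok, reasons

    def test_excess_misclassification_is_rejected_with_reason(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 6)) * 0.1,
                         index=[f"s{i}" for i in range(20)])
        X.iloc[:10] += 5.0
        ds = CandidateDataset("t", "all_subjects", "original", "all", X, ())
        denovo = run_denovo(ds, k_range=(2,), apn_columns=None)
        # labels disagree with the geometric split for 3 subjects
        groups = np.array(["COPD"] * 7 + ["control"] * 3 + ["control"] * 10)
        control = mp.positive_control(ds, groups, space="raw")
        ok, reasons = accept(ds, denovo, control, group_labels=groups)
        assert not ok
        assert any("misclassification" in r for r in reasons)

    def test_much_worse_indices_rejected_on_quality(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 6)),
                         index=[f"s{i}" for i in range(20)])
        ds = CandidateDataset("t", "copd_only", "original", "all", X, ())
        denovo = run_denovo(ds, k_range=(2, 3), apn_columns=None)
        # a fake control far better than anything the noise supports
        fake = mp.validity_report(
            np.array([[0.0, 0.0]] * 10 + [[9.0, 9.0]] * 10),
            np.array([1] * 10 + [2] * 10))
        fake.indices["apn"] = 0.0
        ok, reasons = accept(ds, denovo, fake)
        assert not ok and reasons

    def test_misclassification_counter_uses_best_assignment(self):
        labels2 = np.array([1, 1, 1, 2, 2, 2])
        groups = np.array(["COPD"] * 3 + ["control"] * 3)
        assert _misclassification(labels2, groups) == 0
        assert _misclassification(labels2[::-1], groups) == 0  # swapped mapping
        # one control in cluster 1 and one COPD in cluster 2 -> 2 mismatches
        groups2 = np.array(["COPD", "COPD", "control", "COPD", "control", "control"])
        assert _misclassification(labels2, groups2) == 2

    def test_acceptance_monotone_in_index_improvement(self, rng):
        """Improving every oriented index never flips accepted to rejected."""
        X = pd.DataFrame(rng.standard_normal((20, 6)) * 0.1,
                         index=[f"s{i}" for i in range(20)])
        X.iloc[:10] += 5.0
        ds = CandidateDataset("t", "copd_only", "original", "all", X, ())
        denovo = run_denovo(ds, k_range=(2,), apn_columns=None)
        control = mp.positive_control(
            ds, np.array(["A"] * 10 + ["B"] * 10), space="raw")
        ok_before, _ = accept(ds, denovo, control)
        rep = denovo.reports[2]
        for name, orient in mp.validity.INDEX_ORIENTATION.items():
            if np.isfinite(rep.indices.get(name, np.nan)):
                rep.indices[name] += orient * abs(rep.indices[name]) * 0.5
        ok_after, _ = accept(ds, denovo, control)
        assert ok_after or not ok_before


class TestRunDenovo:
    def test_planted_two_subtypes_give_ch_optimum_at_two(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((25, 10)),
                             index=[f"s{i}" for i in range(25)])
            X.iloc[:12] += 3.0
            ds = CandidateDataset("t", "copd_only", "original", "all", X, ())
            res = run_denovo(ds, k_range=range(2, 9), apn_columns=None)
            hits += res.ch_best_k == 2
        assert hits >= 8

    def test_structureless_data_spreads_index_optima(self):
        """On noise the indices disagree about the best k."""
        distinct = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((25, 10)),
                             index=[f"s{i}" for i in range(25)])
            ds = CandidateDataset("t", "copd_only", "original", "all", X, ())
            res = run_denovo(ds, k_range=range(2, 9), apn_columns=None, seed=seed)
            distinct.append(len(set(res.best_k.values())))
        assert np.median(distinct) >= 3

    def test_reports_cover_k_range(self, integrated, default_cohort):
        datasets = mp.enumerate_datasets(integrated, default_cohort.subjects)
        ds = next(d for d in datasets if d.dataset_id == "copd_only/pcs/all")
        res = run_denovo(ds, k_range=(2, 3, 4), apn_columns=10, seed=0)
        assert sorted(res.partitions) == [2, 3, 4]
        assert list(res.table.index) == [2, 3, 4]
        for k, part in res.partitions.items():
            assert set(part) == set(range(1, k + 1))


class TestRunWorkflow:
    def test_summary_covers_all_datasets(self, subtype_workflow):
        assert len(subtype_workflow.summary) == 24
        assert subtype_workflow.summary["dataset_id"].is_unique

    def test_planted_subtype_cohort_accepts_a_dataset(self, subtype_workflow):
        assert len(subtype_workflow.accepted) >= 1

    def test_planted_subtype_recovered(self, subtype_workflow, subtype_cohort):
        det = subtype_workflow.details["copd_only/original/all"]
        truth = subtype_cohort.truth["subtypes"]
        part = det["denovo"].best_partition
        ids = list(det["dataset"].matrix.index)
        import sklearn.metrics as skm
        assert skm.adjusted_rand_score([truth[i] for i in ids], part) > 0.5

    def test_deterministic_given_config(self, subtype_cohort):
        c = subtype_cohort
        m = mp.integrate(c.subjects, c.targeted, c.peaks)
        a = mp.run_workflow(m, c.subjects)
        b = mp.run_workflow(m, c.subjects)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_report_is_readable(self, subtype_workflow):
        text = subtype_workflow.report()
        assert "Candidate datasets: 24" in text
        assert "ACCEPTED" in text or "rejected" in text
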