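import itertools

import numpy as np
import pytest

from kirbind import evaluation
from kirbind.evaluation import (
    auc,
    compare_configurations,
    make_folds,
    one_way_anova_tasks,
    run_cv_experiment,
    summarize_auc,
)


class TestMakeFolds:
    def test_hundred_alleles_five_folds_of_twenty(self):
        scheme = make_folds([f"a{i}" for i in range(100)], k=5, seed=1)
        sizes = [len(scheme.fold_members(f)) for f in range(5)]
        assert sizes == [20] * 5

    def test_determinism(self):
        alleles = [f"a{i}" for i in range(23)]
        assert make_folds(alleles, seed=7).fold_of_allele == make_folds(alleles, seed=7).fold_of_allele

    def test_fold_sizes_differ_by_at_most_one(self):
        for n in range(5, 26):
            scheme = make_folds([f"a{i}" for i in range(n)], k=5, seed=n)
            sizes = [len(scheme.fold_members(f)) for f in range(5)]
            assert max(sizes) - min(sizes) <= 1

    def test_stratified_folds_spread_classes(self):
        alleles = [f"a{i}" for i in range(40)]
        labels = {a: ("pos" if i < 10 else "neg") for i, a in enumerate(alleles)}
        scheme = make_folds(alleles, k=5, seed=0, stratify=labels)
        for f in range(5):
            members = scheme.fold_members(f)
            assert any(labels[m] == "pos" for m in members)
        sizes = [len(scheme.fold_members(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_k_too_small_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_folds(["a", "b", "c"], k=1)


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([1.0, 2.0, 3.0, 4.0], [-1, -1, 1, 1]) == 1.0

    def test_null_simulation_centers_at_half(self):
        rng = np.random.default_rng(12)
        values = []
        for _ in range(500):
            scores = rng.normal(size=200)
            labels = np.where(rng.random(200) < 0.5, 1, -1)
            if len(set(labels)) == 2:
                values.append(auc(scores, labels))
        assert np.mean(values) == pytest.approx(0.5, abs=0.02)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        scores = np.round(rng.normal(size=50), 1)  # rounding forces ties
        labels = np.where(rng.random(50) < 0.4, 1, -1)
        pos = scores[labels == 1]
        neg = scores[labels == -1]
        wins = sum(
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p, n in itertools.product(pos, neg)
        )
        assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.5, 1, -1)
        assert auc(scores, labels) == pytest.approx(auc(np.exp(scores), labels))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1.0, 2.0], [1, 1])


class TestRunCV:
    def test_noiseless_signal_gives_auc_one(self):
        # only the signal positions are polymorphic, so the rank-<=7 panel
        # is projected losslessly and the noiseless labels are separable
        from kirbind import binding, simulate
        from kirbind.clustering import BindingClassLabels

        import numpy as np

        panel = simulate.generate_panel(
            97, polymorphic_positions=simulate.DEFAULT_SIGNAL_POSITIONS, seed=11
        )
        betas = {}
        for pos in simulate.DEFAULT_SIGNAL_POSITIONS:
            observed = sorted({s.residues[pos - 1] for s in panel})
            betas[(pos, observed[0])] = np.full(9, 3.0)
            betas[(pos, observed[1])] = np.zeros(9)
        quiet = simulate.PlantedModel(
            kir_ids=simulate.DEFAULT_KIR_IDS, betas=betas, noise_sigma=0.0,
            thresholds=(4.5, 10.5), seed=11,
        )
        runs, truth = simulate.generate_binding(panel, quiet)
        log_m = binding.log_transform(binding.aggregate_replicates(runs))
        labels = BindingClassLabels(class_of=truth)
        table = run_cv_experiment(
            panel, log_m, labels, mask="helices", task="overall_binder",
            method="mlvo", seed=2,
        )
        assert (table["test_auc"] == 1.0).all()

    def test_shuffled_labels_auc_near_half(self, planted):
        from kirbind.clustering import BindingClassLabels

        rng = np.random.default_rng(8)
        means = []
        names = list(planted["truth"])
        classes = list(planted["truth"].values())
        for rep in range(5):
            rng.shuffle(classes)
            labels = BindingClassLabels(class_of=dict(zip(names, classes)))
            table = run_cv_experiment(
                planted["panel"], planted["log"], labels,
                mask="helices", task="overall_binder", method="svm", seed=rep,
            )
            means.append(table["test_auc"].mean())
        assert np.mean(means) == pytest.approx(0.5, abs=0.12)

    def test_leakage_guard_fold_partition(self, planted):
        table = run_cv_experiment(
            planted["panel"], planted["log"], planted["labels"],
            mask="bw4", task="overall_binder", method="svm", seed=0,
        )
        assert table["n_train"].add(table["n_test"]).nunique() == 1

    def test_per_allotype_task(self, planted):
        table = run_cv_experiment(
            planted["panel"], planted["log"], planted["labels"],
            mask="helices", task="001", method="mlvo", seed=0,
        )
        assert set(table["task"]) == {"001"}
        assert table["test_auc"].mean() > 0.8

    def test_scheme_shared_across_tasks(self, planted):
        scheme = make_folds(
            [s.name for s in planted["panel"]], k=5, seed=4,
            stratify=planted["labels"].binder_labels,
        )
        tables = [
            run_cv_experiment(
                planted["panel"], planted["log"], planted["labels"],
                mask="bw4", task=task, method="svm", scheme=scheme,
            )
            for task in ("001", "002")
        ]
        assert tables[0]["n_test"].tolist() == tables[1]["n_test"].tolist()

    def test_unknown_task_raises(self, planted):
        with pytest.raises(ValueError, match="unknown task"):
            run_cv_experiment(
                planted["panel"], planted["log"], planted["labels"], task="077"
            )


class TestCompareConfigurations:
    @staticmethod
    def _table(shift=0.0, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        rows = []
        for mask in ("bw4", "helices"):
            for loci in ("A/B", "A/B/C"):
                for fold in range(5):
                    value = 0.7 + rng.normal(0, 0.02)
                    if mask == "helices":
                        value += shift
                    rows.append(
                        {"mask": mask, "loci": loci, "task": "overall_binder",
                         "method": "mlvo", "fold": fold, "test_auc": value}
                    )
        return pd.DataFrame(rows)

    def test_no_signal_no_significance(self):
        report = compare_configurations(self._table(shift=0.0, seed=1))
        anova = report["anova"]
        assert anova.loc["C(mask)", "PR(>F)"] > 0.05

    def test_shifted_mask_detected(self):
        report = compare_configurations(self._table(shift=0.2, seed=1))
        assert report["anova"].loc["C(mask)", "PR(>F)"] < 0.05
        assert (report["tukey"]["mask"]["p_adj"] < 0.05).all()

    def test_f_statistic_matches_hand_decomposition(self):
        # balanced 2x2x5 table: two-way ANOVA sums of squares by hand
        table = self._table(shift=0.1, seed=3)
        report = compare_configurations(table)
        y = table["test_auc"].to_numpy()
        grand = y.mean()
        ss_a = sum(
            len(sub) * (sub["test_auc"].mean() - grand) ** 2
            for _, sub in table.groupby("mask")
        )
        cell_means = table.groupby(["mask", "loci"])["test_auc"].transform("mean")
        ss_resid = ((table["test_auc"] - cell_means) ** 2).sum()
        df_resid = len(table) - 4
        f_hand = (ss_a / 1) / (ss_resid / df_resid)
        assert report["anova"].loc["C(mask)", "F"] == pytest.approx(f_hand, rel=1e-8)

    def test_single_level_factor_raises(self):
        table = self._table()
        with pytest.raises(ValueError, match="two levels"):
            compare_configurations(table[table["mask"] == "bw4"])

    def test_one_way_anova_tasks(self):
        table = self._table()
        table.loc[table.index[:10], "task"] = "001"
        out = one_way_anova_tasks(table)
        assert set(out) == {"F", "p", "tasks"}

    def test_summarize_auc_shape(self):
        out = summarize_auc(self._table())
        assert len(out) == 2 * 2
        assert {"mean", "std", "count"}.issubset(out.columns)
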