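import numpy as np
import pytest

from blasso.evaluation import (
    CVError,
    EvaluationReport,
    auc,
    compare_models,
    evaluate_model,
    make_cv_plan,
    nested_cv_fit,
    robustness_index,
    robustness_index_rep,
)
from blasso.priors import CitationTable, PenaltyVector, build_penalty_vector
from blasso.synthetic import make_synthetic_dataset


def brute_force_auc(scores, labels):
    """Pair-counting oracle: P(case outranks control), ties = 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestCVPlan:
    def test_equal_split_singleton_folds(self):
        plan = make_cv_plan(10, 10, 1, seed=0)
        sizes = np.bincount(plan.assignments[0], minlength=10)
        assert (sizes == 1).all()

    def test_partition_at_study_scale(self):
        n = 1212
        labels = np.zeros(n, dtype=int)
        labels[:199] = 1  # the imbalance of the breast-cancer cohort
        plan = make_cv_plan(n, 10, 3, seed=4, stratify_labels=labels)
        for r in range(3):
            sizes = np.bincount(plan.assignments[r], minlength=10)
            assert set(sizes) <= {121, 122}
            assert sizes.sum() == n
            # stratification: every fold has 19-20 cases
            for k in range(10):
                assert 19 <= labels[plan.assignments[r] == k].sum() <= 20

    def test_reproducible_and_distinct_across_repetitions(self):
        a = make_cv_plan(50, 5, 3, seed=9)
        b = make_cv_plan(50, 5, 3, seed=9)
        assert np.array_equal(a.assignments, b.assignments)
        assert not np.array_equal(a.assignments[0], a.assignments[1])

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(CVError):
            make_cv_plan(5, 10, 1, seed=0)

    def test_impossible_stratification_rejected(self):
        labels = np.zeros(20, dtype=int)
        labels[0] = 1  # one case cannot stratify into 5 folds
        with pytest.raises(CVError):
            make_cv_plan(20, 5, 1, seed=0, stratify_labels=labels)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.6, 0.4], [1, 1, 0]) == 1.0

    def test_interleaved_scores(self):
        # cases at 0.2 and 0.6 around a control at 0.4: one win, one loss
        assert auc([0.2, 0.6, 0.4], [1, 1, 0]) == 0.5

    def test_all_ties_give_half(self):
        assert auc([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(CVError):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_rank_formulation_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestRobustnessIndex:
    def test_identical_sets(self):
        assert robustness_index_rep([{"A", "B"}] * 10) == 1.0

    def test_disjoint_sets(self):
        assert robustness_index_rep([{"A"}, {"B"}, {"C"}]) == 0.0

    def test_hand_worked_example(self):
        sigs = [{"A", "B", "C"}, {"A", "B", "D"}, {"A", "E"}]
        assert robustness_index_rep(sigs) == pytest.approx(0.375)

    def test_all_empty_sets_define_zero(self):
        assert robustness_index_rep([set(), set()]) == 0.0

    def test_aggregation(self):
        assert robustness_index([0.5]) == (0.5, 0.0)
        assert robustness_index([0.0, 1.0])[0] == pytest.approx(0.5)
        mean, sd = robustness_index([0.37] * 100)
        assert mean == pytest.approx(0.37)
        assert sd == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(CVError):
            robustness_index([])

    def test_bounded_by_one(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(30)]
        for _ in range(50):
            sigs = [
                set(rng.choice(genes, size=rng.integers(0, 20), replace=False))
                for _ in range(5)
            ]
            if all(len(s) == 0 for s in sigs):
                continue
            assert 0.0 <= robustness_index_rep(sigs) <= 1.0


@pytest.fixture(scope="module")
def small_synthetic():
    ds, truth = make_synthetic_dataset(
        n=150, p=40, k=4, block_size=10, within_block_corr=0.4,
        flip_fraction=0.05, seed=21,
    )
    return ds, truth


class TestNestedCV:
    def test_single_epsilon_reduces_to_lambda_selection(self, small_synthetic):
        ds, _ = small_synthetic
        sel = nested_cv_fit(
            ds, lambda e: PenaltyVector.ones(ds.n_genes),
            epsilon_grid=[0.4], inner_K=3, seed=5, n_lambdas=20,
        )
        assert sel.epsilon == 0.4
        assert sel.lam in sel.lambda_grids[0.4]

    def test_uninformative_counts_tie_break_to_largest_epsilon(self, small_synthetic):
        ds, _ = small_synthetic
        table = CitationTable(counts={})  # every gene: 0 citations, gamma = 1
        sel = nested_cv_fit(
            ds, lambda e: build_penalty_vector(ds, table, e),
            epsilon_grid=[0.1, 0.5, 1.0], inner_K=3, seed=5, n_lambdas=15,
        )
        assert sel.epsilon == 1.0
        np.testing.assert_array_equal(sel.score_curves[0.1], sel.score_curves[1.0])

    def test_citations_on_causal_genes_help_inner_auc(self, small_synthetic):
        # when the truly causal genes are heavily cited, a strong prior
        # (larger epsilon) should score at least as well as the flat limit
        ds, truth = small_synthetic
        table = CitationTable(counts={g: 1000 for g in truth.causal_genes})
        sel = nested_cv_fit(
            ds, lambda e: build_penalty_vector(ds, table, e),
            epsilon_grid=[0.01, 1.0], inner_K=3, seed=6, n_lambdas=20,
        )
        assert sel.score_curves[1.0].max() >= sel.score_curves[0.01].max()

    def test_epsilon_outside_unit_interval_rejected(self, small_synthetic):
        ds, _ = small_synthetic
        with pytest.raises(CVError):
            nested_cv_fit(ds, lambda e: PenaltyVector.ones(ds.n_genes),
                          epsilon_grid=[0.5, 1.5])


@pytest.fixture(scope="module")
def tiny_run():
    ds, _ = make_synthetic_dataset(
        n=80, p=20, k=3, block_size=5, within_block_corr=0.3,
        flip_fraction=0.0, seed=31,
    )
    plan = make_cv_plan(80, 2, 1, seed=13, stratify_labels=ds.labels)
    builder = lambda e: PenaltyVector.ones(ds.n_genes)
    report = evaluate_model(ds, builder, plan, epsilon_grid=[1.0],
                            inner_K=3, n_lambdas=15)
    return ds, plan, builder, report


class TestEvaluateModel:
    def test_bookkeeping_shapes(self, tiny_run):
        _, plan, _, report = tiny_run
        assert report.auc_values.shape == (1, 2)
        assert len(report.signatures[0]) == 2
        assert ((report.auc_values >= 0) & (report.auc_values <= 1)).all()

    def test_same_seed_reproduces_report_exactly(self, tiny_run):
        ds, plan, builder, report = tiny_run
        again = evaluate_model(ds, builder, plan, epsilon_grid=[1.0],
                               inner_K=3, n_lambdas=15)
        np.testing.assert_array_equal(report.auc_values, again.auc_values)
        assert report.signatures == again.signatures
        assert report.chosen_hparams == again.chosen_hparams

    def test_report_summary_and_save(self, tiny_run, tmp_path):
        _, _, _, report = tiny_run
        assert "AUC" in report.summary() and "RI" in report.summary()
        report.save(str(tmp_path / "run"))
        assert (tmp_path / "run.json").exists()
        assert (tmp_path / "run_auc.tsv").exists()
        assert (tmp_path / "run_signatures.tsv").exists()

    def test_plan_must_cover_dataset(self, tiny_run):
        ds, _, builder, _ = tiny_run
        bad_plan = make_cv_plan(30, 2, 1, seed=0)
        with pytest.raises(CVError):
            evaluate_model(ds, builder, bad_plan, epsilon_grid=[1.0])


def _report_from_auc(plan, values, name):
    R, K = values.shape
    sigs = [[frozenset({"G"})] * K for _ in range(R)]
    pars = [[(1.0, 0.1)] * K for _ in range(R)]
    return EvaluationReport(plan=plan, auc_values=values, signatures=sigs,
                            chosen_hparams=pars, model_name=name)


class TestCompareModels:
    def setup_method(self):
        self.plan = make_cv_plan(100, 5, 4, seed=3)  # 20 fold pairs
        rng = np.random.default_rng(7)
        self.base = rng.uniform(0.6, 0.9, size=(4, 5))

    def test_identical_reports_are_degenerate(self):
        a = _report_from_auc(self.plan, self.base, "a")
        b = _report_from_auc(self.plan, self.base.copy(), "b")
        res = compare_models(a, b)
        assert res.degenerate and res.pvalue == 1.0

    def test_uniform_improvement_exact_pvalue(self):
        # a beats b on all 20 pairs (distinct margins, so the exact
        # signed-rank distribution applies): two-sided p = 2 / 2^20
        margins = np.linspace(0.005, 0.02, 20).reshape(4, 5)
        a = _report_from_auc(self.plan, self.base + margins, "a")
        b = _report_from_auc(self.plan, self.base, "b")
        res = compare_models(a, b)
        assert res.pvalue == pytest.approx(2.0 / 2**20)
        assert res.n_nonzero == 20

    def test_swapping_flips_sign_same_pvalue(self):
        rng = np.random.default_rng(11)
        other = self.base + rng.normal(0, 0.02, size=self.base.shape)
        a = _report_from_auc(self.plan, self.base, "a")
        b = _report_from_auc(self.plan, other, "b")
        ab = compare_models(a, b)
        ba = compare_models(b, a)
        assert ab.pvalue == pytest.approx(ba.pvalue)
        assert ab.mean_difference == pytest.approx(-ba.mean_difference)

    def test_mismatched_plans_rejected(self):
        other_plan = make_cv_plan(100, 5, 4, seed=99)
        a = _report_from_auc(self.plan, self.base, "a")
        b = _report_from_auc(other_plan, self.base, "b")
        with pytest.raises(CVError):
            compare_models(a, b)

    def test_repetition_means_pairing_unit(self):
        margins = np.linspace(0.005, 0.02, 20).reshape(4, 5)
        a = _report_from_auc(self.plan, self.base + margins, "a")
        b = _report_from_auc(self.plan, self.base, "b")
        res = compare_models(a, b, unit="repetitions")
        assert res.n_pairs == 4
        assert res.pvalue == pytest.approx(2.0 / 2**4)


def test_report_invariant_to_sample_ordering():
    ds, _ = make_synthetic_dataset(n=60, p=15, k=3, block_size=5,
                                   within_block_corr=0.3, flip_fraction=0.0,
                                   seed=41)
    plan = make_cv_plan(60, 3, 1, seed=2, stratify_labels=ds.labels)
    builder = lambda e: PenaltyVector.ones(ds.n_genes)
    rep = evaluate_model(ds, builder, plan, epsilon_grid=[1.0], inner_K=2,
                         n_lambdas=10)
    perm = np.random.default_rng(0).permutation(60)
    ds_p = ds.subset_samples(perm)
    plan_p = make_cv_plan(60, 3, 1, seed=2, stratify_labels=ds.labels)
    plan_p.assignments = plan.assignments[:, perm]
    rep_p = evaluate_model(ds_p, builder, plan_p, epsilon_grid=[1.0],
                           inner_K=2, n_lambdas=10)
    assert rep.mean_auc == pytest.approx(rep_p.mean_auc, abs=1e-9)
    assert rep.n_genes == pytest.approx(rep_p.n_genes, abs=1e-9)
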