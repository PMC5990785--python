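"""LDA fit/classification, balanced selection and the crossed pDFA."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from hoovar.call_table import TransformSpec, apply_transforms
from hoovar.pdfa import (
    DegeneracyError,
    DesignError,
    PDFAConfig,
    classify,
    cross_classification_rate,
    fit_lda,
    loo_crossvalidated_rates,
    permute_within_subjects,
    run_pdfa,
    select_balanced_training,
)
from hoovar.simulate import generate_feature_table, paper_like_truth


def _two_group_1d(rng, n=50):
    X = np.concatenate([rng.normal(0, 1, n), rng.normal(10, 1, n)])[:, None]
    y = np.array(["a"] * n + ["b"] * n, object)
    return X, y


class TestFitLda:
    def test_separable_two_group_boundary(self, rng):
        X, y = _two_group_1d(rng)
        model = fit_lda(X, y, label_order=("a", "b"))
        pred, _, _ = classify(model, X)
        assert (pred == y).mean() == 1.0
        # decision boundary near the midpoint of the group means
        lo, hi = np.linspace(2, 8, 601), None
        preds, _, _ = classify(model, lo[:, None])
        boundary = lo[np.argmax(preds == "b")]
        assert boundary == pytest.approx(5.0, abs=0.5)

    def test_loadings_match_reference_eigen_solver(self, rng):
        # 3 groups, 2 variables; oracle solves the same generalized
        # eigenproblem with an independent whitening construction
        X = rng.normal(0, 1, (90, 2))
        X[:30] += [3, 0]
        X[30:60] += [0, 2.5]
        y = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30, object)
        model = fit_lda(X, y, label_order=("a", "b", "c"))

        n, g = len(y), 3
        means = np.stack([X[y == lab].mean(0) for lab in "abc"])
        Sw = sum(
            (X[y == lab] - means[i]).T @ (X[y == lab] - means[i])
            for i, lab in enumerate("abc")
        ) / (n - g)
        grand = X.mean(0)
        Sb = sum(30 * np.outer(means[i] - grand, means[i] - grand) for i in range(3))
        # whiten within, eigendecompose between, map back
        evals_w, evecs_w = np.linalg.eigh(Sw)
        W = evecs_w @ np.diag(evals_w**-0.5) @ evecs_w.T
        bw, bv = np.linalg.eigh(W @ Sb @ W)
        order = np.argsort(bw)[::-1][:2]
        L_ref = W @ bv[:, order]
        for j in range(2):
            a, b = model.loadings[:, j], L_ref[:, j]
            if np.sign(a[np.argmax(np.abs(a))]) != np.sign(b[np.argmax(np.abs(b))]):
                b = -b
            np.testing.assert_allclose(a, b, atol=1e-8)
            # unit pooled within-group variance of each discriminant score
            assert a @ Sw @ a == pytest.approx(1.0, abs=1e-10)

    def test_duration_and_f0max_are_the_influential_variables(
        self, transformed_table, screened
    ):
        # on study-like data the discrimination is carried by call duration
        # (rest vs travel) and maximum F0 (alert vs the rest), while the F0
        # drop contributes almost nothing — the |loading| > 1 influence rule
        # singles out the variables the mixed-model stage then tests
        tfm, _ = transformed_table
        v1 = [v for v in screened.retained if v != "inter_call_interval_s"]
        view = tfm.analysis_view(variables=v1)
        model = fit_lda(
            view.X, view.labels, label_order=("rest", "travel", "alert"), variables=v1
        )
        influence = dict(zip(v1, np.abs(model.loadings).max(axis=1)))
        assert influence["duration_s"] > 1.0
        assert influence["f0_max_hz"] > 1.0
        assert influence["f0_drop_hz"] < min(influence["duration_s"], influence["f0_max_hz"])

    def test_singular_covariance_raises_degeneracy(self, rng):
        x = rng.normal(0, 1, 40)
        X = np.column_stack([x, x])  # exactly collinear
        y = np.array(["a"] * 20 + ["b"] * 20, object)
        with pytest.raises(DegeneracyError):
            fit_lda(X, y, label_order=("a", "b"))

    def test_too_small_groups_rejected(self, rng):
        X = rng.normal(size=(3, 1))
        y = np.array(["a", "a", "b"], object)
        with pytest.raises(DesignError):
            fit_lda(X, y, label_order=("a", "b"))


class TestClassify:
    def test_centroid_classified_to_own_group(self, rng):
        X, y = _two_group_1d(rng)
        model = fit_lda(X, y, label_order=("a", "b"))
        pred, post, _ = classify(model, model.group_means)
        assert list(pred) == ["a", "b"]
        assert post[0, 0] > post[0, 1]
        np.testing.assert_allclose(post.sum(axis=1), 1.0)

    def test_equidistant_tie_goes_to_first_label_and_is_flagged(self, rng):
        X, y = _two_group_1d(rng)
        model = fit_lda(X, y, priors_policy="equal", label_order=("a", "b"))
        mid = model.group_means.mean(axis=0, keepdims=True)
        pred, _, ties = classify(model, mid)
        assert pred[0] == "a"
        assert ties[0]

    def test_variable_mismatch_rejected(self, rng):
        X, y = _two_group_1d(rng)
        model = fit_lda(X, y, label_order=("a", "b"))
        with pytest.raises(ValueError, match="variable mismatch"):
            classify(model, np.zeros((2, 3)))

    def test_agrees_with_gaussian_posterior_oracle(self, rng):
        # random small instances against the brute-force likelihood evaluation
        for _ in range(200):
            g = int(rng.integers(2, 5))
            p = int(rng.integers(1, 5))
            n = int(rng.integers(p + 3 * g, 40))
            labels = tuple(f"g{i}" for i in range(g))
            y = np.array([labels[i % g] for i in range(n)], object)
            X = rng.normal(0, 2, (g, p))[[i % g for i in range(n)]] + rng.normal(0, 1, (n, p))
            model = fit_lda(X, y, label_order=labels)
            pred, post, _ = classify(model, X)
            dens = np.column_stack(
                [
                    model.priors[i]
                    * multivariate_normal.pdf(X, model.group_means[i], model.pooled_cov)
                    for i in range(g)
                ]
            )
            oracle_post = dens / dens.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(post, oracle_post, atol=1e-10)
            assert (pred == np.asarray(labels, object)[np.argmax(dens, axis=1)]).all()


class TestBalancedSelection:
    def test_paper_preset_accounting(self, transformed_table, screened, rng):
        tfm, _ = transformed_table
        v1 = [v for v in screened.retained if v != "inter_call_interval_s"]
        view = tfm.analysis_view(variables=v1)
        sel = select_balanced_training(view.labels, view.subjects, ("rest", "travel", "alert"), rng)
        assert len(sel.eligible_subjects) == 11
        assert len(sel.train_idx) == 33
        assert len(sel.heldout_idx) == 129
        assert len(sel.novel_idx) == 109
        # exact partition
        union = np.concatenate([sel.train_idx, sel.heldout_idx, sel.novel_idx])
        assert len(union) == len(view.labels)
        assert len(np.unique(union)) == len(union)

    def test_partial_contributor_never_eligible(self, transformed_table, screened, rng):
        tfm, truth = transformed_table
        v1 = [v for v in screened.retained if v != "inter_call_interval_s"]
        view = tfm.analysis_view(variables=v1)
        partial = truth.roster.loc[
            ~(truth.roster[["n_alert", "n_rest", "n_travel"]] > 0).all(axis=1),
            "subject_id",
        ]
        for _ in range(5):
            sel = select_balanced_training(
                view.labels, view.subjects, ("rest", "travel", "alert"), rng
            )
            assert not set(partial) & set(sel.eligible_subjects)
            novel_subjects = set(view.subjects[sel.novel_idx])
            assert set(partial) <= novel_subjects

    def test_one_call_per_subject_per_context(self, transformed_table, screened, rng):
        tfm, _ = transformed_table
        view = tfm.analysis_view(
            variables=[v for v in screened.retained if v != "inter_call_interval_s"]
        )
        sel = select_balanced_training(view.labels, view.subjects, ("rest", "travel", "alert"), rng)
        import collections

        c = collections.Counter(
            (view.subjects[i], view.labels[i]) for i in sel.train_idx
        )
        assert set(c.values()) == {1}


class TestPermutation:
    def test_conserves_per_subject_label_multisets(self, rng):
        y = np.array(list("rrtataartt"), object)
        subjects = np.array(list("AAABBBCCDD"), object)
        for _ in range(200):
            perm = permute_within_subjects(y, subjects, rng)
            for s in "ABCD":
                assert sorted(perm[subjects == s]) == sorted(y[subjects == s])

    def test_single_context_subject_unchanged(self, rng):
        y = np.array(["rest"] * 5, object)
        subjects = np.array(["A"] * 5, object)
        assert (permute_within_subjects(y, subjects, rng) == y).all()

    def test_orderings_uniform_for_three_distinct_labels(self, rng):
        y = np.array(["rest", "travel", "alert"], object)
        subjects = np.array(["A"] * 3, object)
        from collections import Counter

        n = 6000
        counts = Counter(
            tuple(permute_within_subjects(y, subjects, rng)) for _ in range(n)
        )
        assert len(counts) == 6
        # each of the 6 orderings within 3 multinomial SEs of n/6
        se = np.sqrt(n * (1 / 6) * (5 / 6))
        for v in counts.values():
            assert abs(v - n / 6) < 3 * se


class TestCrossClassification:
    def test_chance_level_for_unrelated_labels(self, rng):
        n_subj, per = 12, 9
        subjects = np.repeat([f"s{i}" for i in range(n_subj)], per).astype(object)
        y = np.array((["a", "b", "c"] * (n_subj * per // 3)), object)
        X = rng.normal(size=(n_subj * per, 3))
        rate, per_ctx, acc = cross_classification_rate(
            X, y, subjects, ("a", "b", "c"), n_selections=60, rng=rng
        )
        assert rate == pytest.approx(1 / 3, abs=0.06)
        assert acc["n_training"] == 3 * n_subj

    def test_separable_generator_classifies_perfectly(self):
        truth = paper_like_truth(seed=21).replace(
            context_means={
                "log_duration": {"rest": 3.0, "travel": -3.0, "alert": 0.0},
                "log_f0max": {"rest": 9.0, "travel": 5.0, "alert": 1.0},
                "sqrt_ici": {"rest": 1.0, "travel": 1.0, "alert": 1.0},
            },
            subject_sd={"log_duration": 0.0, "log_f0max": 0.0, "sqrt_ici": 0.0},
            residual_sd={"log_duration": 1e-3, "log_f0max": 1e-3, "sqrt_ici": 1e-3},
            observer_effect={"log_duration": 0.0, "log_f0max": 0.0, "sqrt_ici": 0.0},
            device_effect={"log_duration": {}, "log_f0max": {}, "sqrt_ici": {}},
            sex_effect={"log_duration": 0.0, "log_f0max": 0.0, "sqrt_ici": 0.0},
        )
        fm, _ = generate_feature_table(truth)
        tfm = apply_transforms(fm, TransformSpec.table_defaults())
        view = tfm.analysis_view(variables=["duration_s", "f0_max_hz"])
        cfg = PDFAConfig(n_selections=5, n_permutations=99, seed=1)
        res = run_pdfa(view, ("rest", "travel", "alert"), cfg)
        assert res.observed_rate == 1.0
        assert res.observed_rate > res.expected_rate
        assert res.p_value == pytest.approx(1 / (cfg.n_permutations + 1))

    def test_run_pdfa_deterministic_under_seed(self, transformed_table, screened):
        tfm, _ = transformed_table
        view = tfm.analysis_view(
            variables=[v for v in screened.retained if v != "inter_call_interval_s"]
        )
        cfg = PDFAConfig(n_selections=4, n_permutations=50, seed=9)
        a = run_pdfa(view, ("rest", "travel", "alert"), cfg)
        b = run_pdfa(view, ("rest", "travel", "alert"), cfg)
        assert a.observed_rate == b.observed_rate
        assert a.expected_rate == b.expected_rate
        assert a.p_value == b.p_value

    def test_p_value_monotone_in_observed_rate(self):
        # fixed null sample; larger observed rate can only shrink p
        null = np.array([0.2, 0.3, 0.3, 0.5, 0.8])
        def p_of(obs):
            return (1 + np.sum(null >= obs - 1e-12)) / (1 + len(null))
        ps = [p_of(o) for o in (0.1, 0.3, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestLeaveOneOut:
    def test_perfect_separation_gives_unit_rates(self, rng):
        X, y = _two_group_1d(rng)
        per_ctx, overall = loo_crossvalidated_rates(X, y, label_order=("a", "b"))
        assert per_ctx == {"a": 1.0, "b": 1.0}
        assert overall == 1.0

    def test_planted_mislabel_costs_exactly_one_call(self, rng):
        n = 30
        X = np.concatenate([rng.normal(0, 0.5, n), rng.normal(10, 0.5, n)])[:, None]
        y = np.array(["a"] * n + ["b"] * n, object)
        y[0] = "b"  # an 'a'-looking call labelled b, deep inside group a
        per_ctx, _ = loo_crossvalidated_rates(X, y, label_order=("a", "b"))
        # group b now has n+1 members, one of which (the planted point) fails
        assert per_ctx["b"] == pytest.approx(n / (n + 1), abs=1e-9)
        assert per_ctx["a"] == pytest.approx(1.0)

    def test_shuffled_labels_fall_to_chance(self, rng):
        n = 150
        X = rng.normal(size=(n, 3))
        y = np.array(["a", "b", "c"] * (n // 3), object)
        per_ctx, overall = loo_crossvalidated_rates(X, y, label_order=("a", "b", "c"))
        assert overall == pytest.approx(1 / 3, abs=0.12)
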