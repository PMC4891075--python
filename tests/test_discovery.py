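import numpy as np
import pandas as pd
import pytest

import mmresponse as mm
from mmresponse.discovery import (
    PairScore,
    Signature,
    confusion_metrics,
    decision_values,
    fit_qda,
    predict_qda,
)


def _loo_refit_oracle(X, y):
    """Literal LOO: refit per fold with fit_qda, predict the held-out sample."""
    n = len(y)
    conf = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_qda(X[mask], y[mask])
        pred = int(predict_qda(model, X[i : i + 1])[0])
        mask[i] = True
        key = ("fn", "tp")[pred] if y[i] == 1 else ("tn", "fp")[pred]
        conf[key] += 1
    return conf


class TestQDA:
    def test_1d_equal_variance_boundary_at_midpoint(self):
        """With equal class variances and priors the quadratic discriminant
        reduces to the LDA threshold halfway between the class means."""
        X = np.array([[0.0], [2.0], [4.0], [10.0], [12.0], [14.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_qda(X, y)
        midpoint = (2.0 + 12.0) / 2
        assert predict_qda(model, np.array([[midpoint - 0.01]]))[0] == 0
        assert predict_qda(model, np.array([[midpoint + 0.01]]))[0] == 1
        # exactly at the midpoint the discriminants tie -> positive class
        assert predict_qda(model, np.array([[midpoint]]))[0] == 1

    def test_2d_toy_matches_direct_formula(self):
        """Predictions equal brute-force evaluation of g_pos - g_neg with the
        textbook Gaussian discriminant formula."""
        X = np.array(
            [[0.0, 0.0], [1.0, 0.5], [0.5, 1.2], [0.2, 0.3],
             [3.0, 3.0], [4.0, 3.5], [3.5, 4.2], [3.2, 3.1]]
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = fit_qda(X, y)
        test_points = np.array([[0.5, 0.5], [3.5, 3.5], [2.0, 2.0], [1.8, 2.1]])

        def g(x, mu, cov, prior):
            inv = np.linalg.inv(cov)
            _, logdet = np.linalg.slogdet(cov)
            d = x - mu
            return np.log(prior) - 0.5 * logdet - 0.5 * d @ inv @ d

        for x in test_points:
            expected = g(x, model.mu_pos, model.cov_pos, 0.5) - g(
                x, model.mu_neg, model.cov_neg, 0.5
            )
            got = decision_values(model, x[None, :])[0]
            assert got == pytest.approx(expected, rel=1e-10)
            assert predict_qda(model, x[None, :])[0] == int(expected >= 0)

    def test_collinear_features_regularized(self):
        """Duplicated feature gives a singular covariance; escalated
        regularization keeps the fit usable and predictions stable."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        X = np.column_stack([base, base])  # rank 1
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        X[y == 1] += 3.0
        model = fit_qda(X, y)
        assert model.lam <= 1e-2
        assert (predict_qda(model, X) == y).all()

    def test_class_smaller_than_features_rejected(self):
        X = np.random.default_rng(1).normal(size=(5, 3))
        y = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="d\\+1"):
            fit_qda(X, y)

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(2).normal(size=(10, 2))
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        model = fit_qda(X, y)
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict_qda(model, np.zeros((1, 3)))

    def test_agrees_with_sklearn_qda(self):
        """Cross-check the discriminant against an independent implementation
        at negligible regularization."""
        sklearn_qda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).QuadraticDiscriminantAnalysis
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(1.5, 2, (20, 3))])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        ours = predict_qda(fit_qda(X, y), X)
        ref = sklearn_qda(priors=[0.5, 0.5], reg_param=0.0).fit(X, y).predict(X)
        assert (ours == ref).mean() == 1.0


class TestLOOScore:
    def test_perfectly_separated_pair(self, separable_matrix):
        matrix, contrast = separable_matrix
        ps = mm.loo_score(matrix, contrast, ["PA", "PB"])
        assert ps.score == 1.0
        assert (ps.tp, ps.fn, ps.fp) == (contrast.n_positive, 0, 0)

    def test_confusion_sums_to_n(self, small_cohort, cr_vs_rest):
        ps = mm.loo_score(small_cohort.expression, cr_vs_rest, ["P00001", "P00002"])
        assert ps.n == len(cr_vs_rest.samples)

    @pytest.mark.parametrize("n_probes", [1, 2, 3, 5])
    def test_equals_per_fold_refit(self, small_cohort, cr_vs_rest, n_probes):
        """The closed-form downdate path reproduces the literal
        fit-per-fold LOO exactly."""
        probes = list(small_cohort.expression.index[10 : 10 + n_probes])
        ps = mm.loo_score(small_cohort.expression, cr_vs_rest, probes)
        X = small_cohort.expression.loc[probes, list(cr_vs_rest.samples)].to_numpy().T
        oracle = _loo_refit_oracle(X, cr_vs_rest.labels())
        assert (ps.tp, ps.fp, ps.tn, ps.fn) == (
            oracle["tp"], oracle["fp"], oracle["tn"], oracle["fn"]
        )

    def test_small_n_exhaustive_enumeration(self):
        """For n <= 8 the LOO confusion equals explicit enumeration of every
        single-sample held-out fold."""
        rng = np.random.default_rng(5)
        for n_pos, n_neg in [(4, 4), (3, 5), (4, 3)]:
            samples = [f"S{i}" for i in range(n_pos + n_neg)]
            contrast = mm.BinaryContrast(tuple(samples[:n_pos]), tuple(samples[n_pos:]))
            X = rng.normal(size=(n_pos + n_neg, 1))
            X[: n_pos] += 1.0
            matrix = pd.DataFrame(X.T, index=["PX"], columns=samples)
            ps = mm.loo_score(matrix, contrast, ["PX"])
            oracle = _loo_refit_oracle(X, contrast.labels())
            assert (ps.tp, ps.fp, ps.tn, ps.fn) == (
                oracle["tp"], oracle["fp"], oracle["tn"], oracle["fn"]
            )

    def test_permutation_null_centred_at_half(self):
        """Random label permutations give LOO balanced accuracy whose mean is
        within 3 standard errors of 0.5."""
        rng = np.random.default_rng(6)
        n = 30
        samples = [f"S{i}" for i in range(n)]
        matrix = pd.DataFrame(
            rng.normal(size=(2, n)), index=["PA", "PB"], columns=samples
        )
        scores = []
        for _ in range(100):
            perm = rng.permutation(n)
            pos = tuple(samples[i] for i in perm[:10])
            neg = tuple(samples[i] for i in perm[10:])
            scores.append(mm.loo_score(matrix, mm.BinaryContrast(pos, neg), ["PA", "PB"]).score)
        scores = np.array(scores)
        sem = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean() - 0.5) < 3 * sem

    def test_relabeling_swaps_sensitivity_specificity(self, small_cohort, cr_vs_rest):
        probes = ["P00003", "P00007"]
        fwd = mm.loo_score(small_cohort.expression, cr_vs_rest, probes)
        swapped = mm.BinaryContrast(cr_vs_rest.negative, cr_vs_rest.positive)
        rev = mm.loo_score(small_cohort.expression, swapped, probes)
        assert (rev.tp, rev.fn, rev.tn, rev.fp) == (fwd.tn, fwd.fp, fwd.tp, fwd.fn)
        m_fwd = confusion_metrics(fwd.tp, fwd.fp, fwd.tn, fwd.fn)
        m_rev = confusion_metrics(rev.tp, rev.fp, rev.tn, rev.fn)
        assert m_rev["sensitivity"] == m_fwd["specificity"]
        assert m_rev["ppv"] == m_fwd["npv"]


class TestEnumeratePairs:
    def test_three_probes_three_pairs(self, small_cohort, cr_vs_rest):
        sub = small_cohort.expression.iloc[:3]
        pairs = mm.enumerate_pairs(sub, cr_vs_rest, prefilter_m=None)
        assert len(pairs) == 3
        assert {frozenset(p.probes) for p in pairs} == {
            frozenset(c) for c in [("P00001", "P00002"), ("P00001", "P00003"), ("P00002", "P00003")]
        }

    def test_matches_loo_score_per_pair(self, small_cohort, cr_vs_rest):
        sub = small_cohort.expression.iloc[:12]
        pairs = mm.enumerate_pairs(sub, cr_vs_rest, prefilter_m=None)
        assert len(pairs) == 66
        for ps in pairs[:8] + pairs[-3:]:
            ref = mm.loo_score(small_cohort.expression, cr_vs_rest, list(ps.probes))
            assert (ps.tp, ps.fp, ps.tn, ps.fn) == (ref.tp, ref.fp, ref.tn, ref.fn)

    def test_prefilter_equal_to_total_is_identity(self, small_cohort, cr_vs_rest):
        sub = small_cohort.expression.iloc[:30]
        a = mm.enumerate_pairs(sub, cr_vs_rest, prefilter_m=None)
        b = mm.enumerate_pairs(sub, cr_vs_rest, prefilter_m=30)
        assert [(p.probes, p.score) for p in a] == [(p.probes, p.score) for p in b]

    def test_ordering_deterministic(self, small_cohort, cr_vs_rest):
        sub = small_cohort.expression.iloc[:20]
        pairs = mm.enumerate_pairs(sub, cr_vs_rest, prefilter_m=None)
        keys = [(-p.score, p.probes) for p in pairs]
        assert keys == sorted(keys)


class TestNetworkSignatures:
    def _pair(self, a, b, score):
        return PairScore((a, b), 10, 0, 10, 0, score)

    def test_two_disjoint_couples(self, separable_matrix):
        matrix, contrast = separable_matrix
        extra = matrix.copy()
        # two disjoint, individually separating couples
        extra.loc["PC"] = matrix.loc["PA"].to_numpy() + 0.01
        extra.loc["PD"] = matrix.loc["PB"].to_numpy() - 0.01
        pairs = [self._pair("PA", "PB", 1.0), self._pair("PC", "PD", 1.0)]
        sigs = mm.build_network_signatures(extra, contrast, pairs, top_k=2)
        # both couples survive as their own component candidates
        assert {s.probes for s in sigs} >= {("PA", "PB"), ("PC", "PD")}
        by_probes = {s.probes: s for s in sigs}
        assert by_probes[("PA", "PB")].provenance.startswith("component")
        assert by_probes[("PC", "PD")].provenance.startswith("component")

    def test_chain_component(self, small_cohort, cr_vs_rest):
        """Couples a-b and b-c merge into the component candidate {a,b,c}."""
        pairs = [self._pair("P00001", "P00002", 0.9), self._pair("P00002", "P00003", 0.8)]
        sigs = mm.build_network_signatures(
            small_cohort.expression, cr_vs_rest, pairs, top_k=2
        )
        assert ("P00001", "P00002", "P00003") in {s.probes for s in sigs}

    def test_top_k_one_single_candidate(self, separable_matrix):
        matrix, contrast = separable_matrix
        pairs = mm.enumerate_pairs(matrix, contrast, prefilter_m=None)
        sigs = mm.build_network_signatures(matrix, contrast, pairs, top_k=1)
        assert len(sigs) == 1 and sigs[0].probes == tuple(sorted(pairs[0].probes))

    def test_component_reduced_to_max_size(self, small_cohort, cr_vs_rest):
        probes = [f"P{i + 1:05d}" for i in range(6)]
        chain = [self._pair(probes[i], probes[i + 1], 0.9 - 0.01 * i) for i in range(5)]
        sigs = mm.build_network_signatures(
            small_cohort.expression, cr_vs_rest, chain, top_k=5, max_size=4
        )
        assert all(s.size <= 4 for s in sigs)


class TestSelectBestSignature:
    def test_single_candidate_returned(self, separable_matrix):
        matrix, contrast = separable_matrix
        sig = Signature(("PA", "PB"))
        assert mm.select_best_signature(matrix, contrast, [sig]) is sig

    def test_tie_goes_to_smaller_signature(self, separable_matrix):
        """A perfectly separating couple and a perfectly separating 4-probe
        superset tie at LOO score 1.0; the smaller signature wins."""
        matrix, contrast = separable_matrix
        extra = matrix.copy()
        extra.loc["PC"] = matrix.loc["PA"].to_numpy() * 0.9
        extra.loc["PD"] = matrix.loc["PB"].to_numpy() * 1.1
        small = Signature(("PA", "PB"))
        large = Signature(("PA", "PB", "PC", "PD"))
        assert mm.select_best_signature(extra, contrast, [large, small]) is small

    def test_empty_candidates_rejected(self, separable_matrix):
        matrix, contrast = separable_matrix
        with pytest.raises(ValueError, match="no candidate"):
            mm.select_best_signature(matrix, contrast, [])


class TestEvaluateSignature:
    def test_perfectly_separated_all_medians_one(self, separable_matrix):
        matrix, contrast = separable_matrix
        cv = mm.evaluate_signature(matrix, contrast, ("PA", "PB"), k=2, n_repeats=20, seed=0)
        summary = cv.summary()
        for metric in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert summary[metric]["median"] == 1.0

    def test_confusions_sum_to_n(self, small_cohort, cr_vs_rest):
        cv = mm.evaluate_signature(
            small_cohort.expression, cr_vs_rest, ("P00001", "P00002"), n_repeats=5, seed=0
        )
        # accuracy numerator+denominator consistency implies the pooled
        # confusion covers all n samples each repeat
        n = len(cr_vs_rest.samples)
        acc = cv.accuracy
        assert np.all((acc * n) - np.round(acc * n) < 1e-9)

    def test_same_seed_bit_identical(self, small_cohort, cr_vs_rest):
        a = mm.evaluate_signature(
            small_cohort.expression, cr_vs_rest, ("P00001", "P00002"), n_repeats=10, seed=42
        )
        b = mm.evaluate_signature(
            small_cohort.expression, cr_vs_rest, ("P00001", "P00002"), n_repeats=10, seed=42
        )
        for m in a.METRICS:
            np.testing.assert_array_equal(getattr(a, m), getattr(b, m))

    def test_class_smaller_than_k_rejected(self, separable_matrix):
        matrix, contrast = separable_matrix
        with pytest.raises(ValueError, match="stratified 9-fold"):
            mm.evaluate_signature(matrix, contrast, ("PA", "PB"), k=9, n_repeats=2)

    def test_undefined_metrics_excluded_from_summary(self):
        report = mm.CVReport(signature=("P1",), k=3, n_repeats=3, seed=0)
        report.accuracy = np.array([0.8, 0.9, 1.0])
        report.sensitivity = np.array([1.0, np.nan, 0.5])
        report.specificity = np.array([1.0, 1.0, 1.0])
        report.ppv = np.array([np.nan, np.nan, np.nan])
        report.npv = np.array([0.9, 0.95, 1.0])
        s = report.summary()
        assert s["sensitivity"]["median"] == 0.75 and s["sensitivity"]["n_defined"] == 2
        assert np.isnan(s["ppv"]["median"]) and s["ppv"]["n_defined"] == 0


class TestMetricArithmetic:
    def test_npv_from_fixed_confusion(self):
        """TP=13, FN=2, TN=75, FP=28 gives NPV = 75/77 ~ 0.974, matching the
        ~97% NPV implied by the reported sensitivity/specificity."""
        m = confusion_metrics(tp=13, fp=28, tn=75, fn=2)
        assert m["npv"] == pytest.approx(75 / 77)
        assert m["npv"] == pytest.approx(0.974, abs=5e-4)
        assert m["sensitivity"] == pytest.approx(13 / 15)
        assert m["accuracy"] == pytest.approx(88 / 118)

    def test_implied_npv_at_cohort_split(self):
        npv = mm.implied_npv(sensitivity=0.87, specificity=0.73, n_pos=15, n_neg=103)
        assert round(npv, 2) == 0.97

    def test_zero_denominators_are_nan(self):
        m = confusion_metrics(tp=0, fp=0, tn=5, fn=5)
        assert np.isnan(m["ppv"]) and m["npv"] == 0.5


class TestApplySignature:
    def test_identity_map_reproduces_in_sample_predictions(self, separable_matrix):
        matrix, contrast = separable_matrix
        model = mm.fit_signature_model(matrix, contrast, ("PA", "PB"))
        preds, used = mm.apply_signature(model, matrix, {"PA": ["PA"], "PB": ["PB"]})
        Z = mm.discovery.standardize_probes(matrix.loc[["PA", "PB"]])
        in_sample = predict_qda(model, Z[list(matrix.columns)].to_numpy().T)
        np.testing.assert_array_equal(preds.to_numpy(), in_sample)
        assert used == {"PA": ["PA"], "PB": ["PB"]}

    def test_two_probe_gene_feature_is_mean_of_standardized(self, separable_matrix):
        matrix, contrast = separable_matrix
        model = mm.fit_signature_model(
            matrix, contrast, ("PA", "PB"), gene_names={"PA": "GA", "PB": "GB"}
        )
        external = matrix.copy()
        external.loc["PA2"] = matrix.loc["PA"].to_numpy() * 2 + 5  # same gene, rescaled
        preds, used = mm.apply_signature(
            model, external, {"GA": ["PA", "PA2"], "GB": ["PB"]}
        )
        Z = mm.discovery.standardize_probes(external)
        feature_ga = Z.loc[["PA", "PA2"]].to_numpy().mean(axis=0)
        manual = np.column_stack([feature_ga, Z.loc["PB"].to_numpy()])
        np.testing.assert_array_equal(preds.to_numpy(), predict_qda(model, manual))
        assert used["GA"] == ["PA", "PA2"]

    def test_missing_gene_errors_with_names(self, separable_matrix):
        matrix, contrast = separable_matrix
        model = mm.fit_signature_model(
            matrix, contrast, ("PA", "PB"), gene_names={"PA": "GA", "PB": "GB"}
        )
        with pytest.raises(KeyError, match="GB"):
            mm.apply_signature(model, matrix, {"GA": ["PA"]})
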