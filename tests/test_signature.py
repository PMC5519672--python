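"""Ridge regression, couple splitting and signature extraction."""

import numpy as np
import pandas as pd
import pytest

import twinclock as tc
from twinclock.signature import RidgeModel, Signature

from conftest import make_cohort, make_matrix


def _standardize(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


def _augmented_ridge(X, y, k):
    """Independent dense solve: ridge as augmented least squares on standardized X."""
    Xs = _standardize(X)
    yc = y - y.mean()
    m = Xs.shape[1]
    A = np.vstack([Xs, np.sqrt(k) * np.eye(m)])
    b = np.concatenate([yc, np.zeros(m)])
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    return beta


class TestRidgeFit:
    def test_k_zero_equals_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        model = tc.ridge_fit(X, y, k=0.0)
        design = np.column_stack([np.ones(30), X])
        ols, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert model.intercept == pytest.approx(ols[0], abs=1e-9)
        assert np.allclose(model.coefficients, ols[1:], atol=1e-9)

    def test_single_predictor_closed_form(self, rng):
        X = rng.normal(size=(25, 1))
        y = rng.normal(size=25)
        k = 1e-4
        model = tc.ridge_fit(X, y, k=k)
        Xs = _standardize(X)[:, 0]
        yc = y - y.mean()
        beta_std = (Xs @ yc) / (Xs @ Xs + k)
        assert model.standardized_coefficients[0] == pytest.approx(beta_std, rel=1e-10)

    def test_constant_target(self, rng):
        X = rng.normal(size=(10, 3))
        model = tc.ridge_fit(X, np.full(10, 55.0), k=1e-4)
        assert np.allclose(model.coefficients, 0.0, atol=1e-12)
        assert model.intercept == pytest.approx(55.0)

    def test_zero_variance_predictor_dropped(self, rng):
        X = rng.normal(size=(12, 3))
        X[:, 1] = 4.2
        y = rng.normal(size=12)
        model = tc.ridge_fit(X, y, k=1e-4)
        assert model.coefficients[1] == 0.0

    @pytest.mark.parametrize("k", [0.0, 1e-4, 1.0, 100.0])
    def test_agrees_with_dense_augmented_solve(self, k, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        model = tc.ridge_fit(X, y, k=k)
        beta = _augmented_ridge(X, y, k)
        assert np.allclose(model.standardized_coefficients, beta, atol=1e-9)

    def test_agrees_with_sklearn(self, rng):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        k = 0.5
        model = tc.ridge_fit(X, y, k=k)
        ref = sklearn_lm.Ridge(alpha=k).fit(_standardize(X), y)
        assert np.allclose(model.standardized_coefficients, ref.coef_, atol=1e-9)

    def test_coefficient_norm_shrinks_with_k(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        norms = [
            np.linalg.norm(tc.ridge_fit(X, y, k=k).standardized_coefficients)
            for k in [0.0, 1e-4, 1e-2, 1.0, 10.0, 100.0]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestRidgePredict:
    def test_ols_residuals_orthogonal_to_predictors(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        model = tc.ridge_fit(X, y, k=0.0)
        resid = y - tc.ridge_predict(model, X)
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_zero_coefficients_predict_intercept(self):
        model = RidgeModel(["P1"], [0.0], 42.0, 1e-4, [0.0], [1.0])
        preds = tc.ridge_predict(model, np.array([[1.0], [5.0]]))
        assert np.allclose(preds, 42.0)

    def test_standardization_folding_equivalence(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = tc.ridge_fit(X, y, k=1e-4)
        direct = tc.ridge_predict(model, X)
        # apply standardization at predict time with standardized-scale coefficients
        Xs = (X - model.center) / model.scale
        via_std = y.mean() + Xs @ model.standardized_coefficients
        assert np.allclose(direct, via_std, atol=1e-10)

    def test_missing_probe_column_reported(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["P1", "P2"])
        model = tc.ridge_fit(X, rng.normal(size=10), k=1e-4)
        with pytest.raises(KeyError, match="P2"):
            tc.ridge_predict(model, X[["P1"]])


class TestSplitCouples:
    def test_halves_partition_the_cohort(self):
        cohort = make_cohort(np.linspace(22, 98, 27))
        a, b = tc.split_couples(cohort, seed=0)
        assert len(a) == len(b) == 27
        assert not set(a) & set(b)
        for cid, s1, s2 in cohort.iter_couples():
            assert (s1 in a) != (s2 in a)
            assert (s1 in b) != (s2 in b)

    def test_seed_deterministic_and_seed_sensitive(self):
        cohort = make_cohort(np.linspace(22, 98, 27))
        assert tc.split_couples(cohort, seed=5) == tc.split_couples(cohort, seed=5)
        pairs = [(i, i + 100) for i in range(5)]
        assert any(
            tc.split_couples(cohort, seed=s1) != tc.split_couples(cohort, seed=s2)
            for s1, s2 in pairs
        )

    def test_unpaired_cohort_rejected(self):
        df = pd.DataFrame({"age": [30.0, 60.0]}, index=["V1", "V2"])
        with pytest.raises(ValueError, match="paired"):
            tc.split_couples(tc.TwinCohort(df), seed=0)


def _crafted_cohort(n_good=10, n_bad=90, n_couples=12, unknown_idx=0, seed=0):
    """Good probes are identical within couples (delta 0); bad probes are noisy."""
    rng = np.random.default_rng(seed)
    cohort = make_cohort(np.linspace(25, 95, n_couples))
    shared = rng.normal(0, 2, size=(n_good, n_couples))
    ages = np.array([cohort.couple_age(c) for c in cohort.couple_ids])
    shared += 0.05 * ages[None, :]  # age trend so ridge has signal
    good = np.repeat(shared, 2, axis=1)
    bad = rng.normal(size=(n_bad, 2 * n_couples))
    values = np.vstack([good, bad])
    probes = [f"G{i:02d}" for i in range(n_good)] + [f"B{i:02d}" for i in range(n_bad)]
    symbols = [f"SYM{i}" for i in range(n_good + n_bad)]
    symbols[unknown_idx] = tc.UNKNOWN_SYMBOL
    mat = make_matrix(values, probes=probes, samples=cohort.sample_ids, symbols=symbols)
    return mat, cohort


class TestExtractSignature:
    def test_stable_selection_minus_unknown(self):
        mat, cohort = _crafted_cohort()
        config = tc.PipelineConfig(seed=0, z_threshold_signature=2.0)
        sig = tc.extract_signature(mat, cohort, config)
        # the ten zero-divergence probes pass in every fold; G00 is unannotated
        assert sig.probes == [f"G{i:02d}" for i in range(1, 10)]

    def test_signature_equals_provenance_intersection(self, default_run):
        sig = default_run["signature"]
        matrix = default_run["matrix"]
        fold_sets = [set(f["selected"]) for f in sig.provenance["folds"]]
        intersection = set.intersection(*fold_sets)
        known = {p for p in intersection if matrix.annotation[p] != tc.UNKNOWN_SYMBOL}
        assert set(sig.probes) == known
        for fold in fold_sets:
            assert set(sig.probes) <= fold

    def test_subset_of_global_selection(self, default_run):
        res = tc.zscore_delta(tc.delta_scores(default_run["matrix"], default_run["cohort"]))
        global_sel = tc.select_low_divergence(res, 2.5)
        assert set(default_run["signature"].probes) <= global_sel

    def test_deterministic_given_seed(self):
        mat, cohort = _crafted_cohort()
        config = tc.PipelineConfig(seed=3, z_threshold_signature=2.0)
        sig1 = tc.extract_signature(mat, cohort, config)
        sig2 = tc.extract_signature(mat, cohort, config)
        assert sig1.probes == sig2.probes
        assert np.array_equal(sig1.model.coefficients, sig2.model.coefficients)

    def test_recovers_planted_age_regulated_genes(self, default_run):
        labels = default_run["truth"].labels[default_run["signature"].probes]
        assert (labels == "age_regulated").mean() >= 0.8

    def test_empty_intersection_suggests_laxer_threshold(self):
        mat, cohort = _crafted_cohort()
        config = tc.PipelineConfig(z_threshold_signature=50.0, seed=0)
        with pytest.raises(ValueError, match="laxer"):
            tc.extract_signature(mat, cohort, config)


class TestEvaluateSignature:
    def test_noiseless_cohort_validates_perfectly(self):
        cfg = tc.SyntheticConfig(
            n_couples=12, n_probes=300, individual_sd=0.0, divergence_growth=0.0, seed=4
        )
        mat, cohort, truth = tc.generate_twin_cohort(cfg)
        probes = [
            p for p in truth.probes_of("age_regulated")
            if mat.annotation[p] != tc.UNKNOWN_SYMBOL
        ][:20]  # more probes than training samples: tiny-k ridge interpolates
        train, val = tc.split_couples(cohort, seed=4)
        model = tc.ridge_fit(mat.design(probes, train), cohort.ages[train], k=1e-4,
                             probes=probes)
        sig = Signature(probes, [mat.annotation[p] for p in probes], model,
                        provenance={"split": (train, val)})
        r, preds = tc.evaluate_signature(sig, mat, cohort)
        # validation twins are copies of training twins: prediction is exact
        assert r == pytest.approx(1.0, abs=1e-6)
        assert set(preds.columns) == {"age", "predicted_age"}

    def test_anti_ordered_predictions_give_minus_one(self):
        cohort = make_cohort([30.0, 60.0, 90.0])
        values = np.array([[1.0, 1.0, 2.0, 2.0, 3.0, 3.0]])  # rises with age
        mat = make_matrix(values, probes=["P1"], samples=cohort.sample_ids, symbols=["A"])
        model = RidgeModel(["P1"], [-1.0], 0.0, 0.0, [0.0], [1.0])
        sig = Signature(["P1"], ["A"], model)
        train = cohort.sample_ids[::2]
        val = cohort.sample_ids[1::2]
        r, _ = tc.evaluate_signature(sig, mat, cohort, split=(train, val))
        assert r == pytest.approx(-1.0)

    def test_overlapping_split_rejected(self, default_run):
        sig = default_run["signature"]
        train, val = sig.provenance["split"]
        with pytest.raises(ValueError, match="overlap"):
            tc.evaluate_signature(
                sig, default_run["matrix"], default_run["cohort"], split=(train, train)
            )


class TestRankSignatureGenes:
    def _signature(self, coefs, probes=None):
        probes = probes or [f"P{i}" for i in range(len(coefs))]
        model = RidgeModel(probes, coefs, 0.0, 1e-4,
                           np.zeros(len(coefs)), np.ones(len(coefs)))
        return Signature(probes, [f"SYM{p}" for p in probes], model)

    def test_order_by_absolute_coefficient(self):
        ranked = tc.rank_signature_genes(self._signature([0.5, -2.0, 1.0]))
        assert list(ranked["probe_id"]) == ["P1", "P2", "P0"]
        assert list(ranked["direction"]) == ["down", "up", "up"]

    def test_ties_break_lexicographically(self):
        ranked = tc.rank_signature_genes(self._signature([1.0, -1.0], probes=["PB", "PA"]))
        assert list(ranked["probe_id"]) == ["PA", "PB"]

    def test_top_gene_has_planted_slope(self, default_run):
        ranked = tc.rank_signature_genes(default_run["signature"])
        top_probe = ranked["probe_id"].iloc[0]
        assert default_run["truth"].table.loc[top_probe, "slope"] != 0.0
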