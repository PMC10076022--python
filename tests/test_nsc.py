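import numpy as np
import pytest

from metacrit.enrich import EnrichmentMatrix
from metacrit.nsc import (
    NSCModel,
    ProjectionConfig,
    fit_nsc,
    predict_nsc,
    project_cohort,
    train_projection,
)
from metacrit.synth import make_disjoint_pathways, simulate_cluster_cohort

from oracles import NSCOracle


def score_matrix(rng, n_features=12, per_class=(10, 10), informative=4, gap=3.0):
    cols, labels = [], []
    for k, n in enumerate(per_class):
        block = rng.standard_normal((n_features, n))
        block[k * informative: (k + 1) * informative] += gap
        cols.append(block)
        labels += [f"C{k + 1}"] * n
    X = np.hstack(cols)
    samples = [f"s{j}" for j in range(X.shape[1])]
    E = EnrichmentMatrix([f"p{i}" for i in range(n_features)], samples, X,
                         scaled=True)
    return E, dict(zip(samples, labels))


class TestFit:
    def test_zero_threshold_equals_nearest_centroid_oracle(self, rng):
        for trial in range(10):
            E, labels = score_matrix(rng, per_class=(8, 7))
            model = fit_nsc(E, labels, thresholds=[0.0], cv_folds=2, seed=trial)
            y = np.array([labels[s] for s in E.sample_ids])
            oracle = NSCOracle(E.scores, y)
            pred = predict_nsc(model, E)["predicted"].tolist()
            assert pred == oracle.predict(E.scores, 0.0)

    def test_total_shrinkage_predicts_majority_prior(self, rng):
        E, labels = score_matrix(rng, per_class=(14, 6))
        big = float(np.abs(
            fit_nsc(E, labels, thresholds=[0.0], cv_folds=2).d
        ).max()) + 1.0
        model = fit_nsc(E, labels, thresholds=[big], cv_folds=2, seed=0)
        assert np.all(model.d_shrunk == 0.0)
        pred = predict_nsc(model, E)["predicted"]
        assert (pred == "C1").all()          # the 0.7-prior class

    def test_selected_threshold_keeps_only_informative_features(self, rng):
        """With 10 features separated by 5 pooled SDs, CV is error-free and
        the parsimonious threshold silences every noise feature."""
        E, labels = score_matrix(rng, n_features=50, per_class=(20, 20),
                                 informative=10, gap=5.0)
        model = fit_nsc(E, labels, cv_folds=5, seed=0)
        assert model.cv_errors[model.threshold] == 0.0
        informative = {f"p{i}" for i in range(20)}
        active = set(model.active_features)
        assert active and active <= informative

    def test_monotone_shrinkage_in_threshold(self, rng):
        E, labels = score_matrix(rng)
        grid = np.linspace(0, 3, 7)
        model = fit_nsc(E, labels, thresholds=list(grid), cv_folds=2, seed=0)
        prev = None
        for t in grid:
            model.threshold = float(t)
            live = set(model.active_features)
            if prev is not None:
                assert live <= prev
            prev = live

    def test_class_with_too_few_samples_rejected(self, rng):
        E, labels = score_matrix(rng, per_class=(10, 3))
        with pytest.raises(ValueError, match="cv_folds"):
            fit_nsc(E, labels, cv_folds=5)


class TestPredict:
    def test_sample_at_shrunken_centroid_is_classified_there(self, rng):
        E, labels = score_matrix(rng)
        model = fit_nsc(E, labels, cv_folds=2, seed=0)
        cents = model.shrunken_centroids
        probe = EnrichmentMatrix(model.feature_ids, ["q1", "q2"],
                                 np.column_stack([cents[:, 0], cents[:, 1]]),
                                 scaled=True)
        out = predict_nsc(model, probe)
        assert out.loc["q1", "predicted"] == model.classes[0]
        assert out.loc["q2", "predicted"] == model.classes[1]
        assert out.loc["q1", f"posterior_{model.classes[0]}"] == out.loc["q1"][
            [f"posterior_{c}" for c in model.classes]
        ].max()

    def test_equal_distances_resolved_by_prior(self, rng):
        E, labels = score_matrix(rng, per_class=(14, 6))
        model = fit_nsc(E, labels, thresholds=[0.0], cv_folds=2, seed=0)
        midpoint = model.shrunken_centroids.mean(axis=1)
        probe = EnrichmentMatrix(model.feature_ids, ["mid"],
                                 midpoint[:, None], scaled=True)
        assert predict_nsc(model, probe).loc["mid", "predicted"] == "C1"

    def test_discriminants_match_literal_equations(self, rng):
        for trial in range(10):
            E, labels = score_matrix(rng, n_features=int(rng.integers(5, 20)))
            y = np.array([labels[s] for s in E.sample_ids])
            oracle = NSCOracle(E.scores, y)
            for delta in (0.0, 0.5, 1.7):
                model = fit_nsc(E, labels, thresholds=[delta], cv_folds=2,
                                seed=trial)
                out = predict_nsc(model, E)
                for j, s in enumerate(E.sample_ids):
                    for c in model.classes:
                        assert out.loc[s, f"delta_{c}"] == pytest.approx(
                            oracle.discriminant(E.scores[:, j], c, delta),
                            abs=1e-10,
                        )

    def test_feature_affine_invariance(self, rng):
        E, labels = score_matrix(rng)
        model = fit_nsc(E, labels, thresholds=[0.4], cv_folds=2, seed=0)
        base = predict_nsc(model, E)["predicted"].tolist()
        a = rng.uniform(0.5, 2.0, size=E.n_pathways)[:, None]
        b = rng.normal(size=E.n_pathways)[:, None]
        E2 = EnrichmentMatrix(E.pathway_ids, E.sample_ids,
                              a * E.scores + b, scaled=True)
        model2 = fit_nsc(E2, labels, thresholds=[0.4], cv_folds=2, seed=0)
        assert predict_nsc(model2, E2)["predicted"].tolist() == base

    def test_missing_features_imputed_or_rejected(self, rng):
        E, labels = score_matrix(rng, n_features=10)
        model = fit_nsc(E, labels, cv_folds=2, seed=0)
        partial = EnrichmentMatrix(E.pathway_ids[:9], E.sample_ids,
                                   E.scores[:9], scaled=True)
        with pytest.warns(UserWarning, match="imputed"):
            predict_nsc(model, partial)
        tiny = EnrichmentMatrix(E.pathway_ids[:5], E.sample_ids,
                                E.scores[:5], scaled=True)
        with pytest.raises(ValueError, match="overlap"):
            predict_nsc(model, tiny)

    def test_model_json_roundtrip(self, rng, tmp_path):
        from metacrit.io import read_report, write_report

        E, labels = score_matrix(rng)
        model = fit_nsc(E, labels, cv_folds=2, seed=0)
        path = tmp_path / "model.json"
        write_report(model, path)
        back = read_report(path, NSCModel)
        assert back.feature_ids == model.feature_ids
        assert np.allclose(back.d, model.d)
        assert predict_nsc(back, E)["predicted"].tolist() == predict_nsc(
            model, E
        )["predicted"].tolist()


class TestProjection:
    def cohorts(self, seed, batch=5.0):
        sets = make_disjoint_pathways(n_sets=8, set_size=25)
        a = simulate_cluster_cohort(120, 4, sets, effect_size=3.0, seed=seed,
                                    cohort="A")
        b = simulate_cluster_cohort(80, 4, sets, effect_size=3.0,
                                    batch_shift=batch, seed=seed + 1000,
                                    cohort="B", gene_param_seed=seed)
        return sets, a, b

    def accuracy(self, predictions, truth):
        return float(np.mean(
            [predictions.loc[s, "predicted"] == truth[s]
             for s in predictions.index]
        ))

    def test_self_projection_meets_cv_accuracy(self):
        sets, a, _ = self.cohorts(seed=21)
        model, cfg, _ = train_projection(a.expression, sets,
                                         a.truth.cluster_labels, seed=0)
        pred, report = project_cohort(a.expression, sets, model, cfg)
        self_acc = self.accuracy(pred, a.truth.cluster_labels)
        cv_acc = 1.0 - model.cv_errors[model.threshold]
        assert self_acc >= cv_acc
        assert report["alignment"] == "reference_standardize"

    def test_batch_shifted_cohort_recovered_with_alignment(self):
        sets, a, b = self.cohorts(seed=31)
        model, cfg, _ = train_projection(a.expression, sets,
                                         a.truth.cluster_labels, seed=0)
        pred, _ = project_cohort(b.expression, sets, model, cfg)
        assert self.accuracy(pred, b.truth.cluster_labels) >= 0.9

    def test_absent_class_not_forced(self):
        sets, a, b = self.cohorts(seed=41, batch=0.0)
        keep = [s for s, c in b.truth.cluster_labels.items() if c != "C4"]
        expr_b = b.expression.subset(samples=keep)
        model, cfg, _ = train_projection(a.expression, sets,
                                         a.truth.cluster_labels, seed=0)
        pred, _ = project_cohort(expr_b, sets, model, cfg)
        assert (pred["predicted"] == "C4").mean() <= 0.05

    def test_projection_config_roundtrip(self):
        sets, a, _ = self.cohorts(seed=51)
        _, cfg, _ = train_projection(a.expression, sets,
                                     a.truth.cluster_labels, seed=0)
        back = ProjectionConfig.from_dict(cfg.to_dict())
        assert back.alignment == cfg.alignment
        assert np.allclose(back.pathway_mean, cfg.pathway_mean)
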