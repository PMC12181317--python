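import numpy as np
import pytest
from scipy.stats import multivariate_normal

from irclass.classification import (
    QdaModel,
    classify_samples,
    kfold_cross_validate,
    normalization_fingerprint,
    qda_fit,
    qda_posterior,
    render_probability_grid,
)
from irclass.core import SpectrumSet, WavenumberGrid
from irclass.region_selection import RegionSet

from conftest import make_spectrum


def model_1d(mu_a, mu_b, var=1.0, priors=(0.5, 0.5)):
    return QdaModel(
        classes=["A", "B"],
        means=np.array([[mu_a], [mu_b]]),
        covariances=np.array([[[var]], [[var]]]),
        priors=np.array(priors),
        shrinkage=0.0,
    )


class TestQdaFit:
    def test_means_of_tiny_classes(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = ["A", "A", "B", "B"]
        m = qda_fit(X, y)
        np.testing.assert_allclose(m.means, [[-1.0], [1.0]])

    def test_equal_classes_posterior_equals_priors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        Xall = np.vstack([X, X])
        y = ["A"] * 20 + ["B"] * 20
        m = qda_fit(Xall, y, shrinkage=1e-3)
        post = qda_posterior(m, np.array([0.3, -0.7]))
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)

    def test_covariance_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 3))
        m = qda_fit(X, ["A"] * 15, shrinkage=0.0, priors=np.array([1.0]))
        n = X.shape[0]
        mu = X.mean(axis=0)
        oracle = sum(np.outer(x - mu, x - mu) for x in X) / (n - 1)
        np.testing.assert_allclose(m.covariances[0], oracle, atol=1e-10)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            qda_fit(np.array([[0.0], [1.0], [2.0]]), ["A", "B", "B"])

    def test_empirical_priors(self):
        X = np.arange(10, dtype=float)[:, None]
        y = ["A"] * 4 + ["B"] * 6
        m = qda_fit(X, y)
        np.testing.assert_allclose(m.priors, [0.4, 0.6])


class TestQdaPosterior:
    def test_symmetric_point(self):
        post = qda_posterior(model_1d(-1.0, 1.0), np.array([0.0]))
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-14)

    def test_closed_form_log_likelihood_ratio(self):
        # µ_A=0, µ_B=2, σ²=1, x=0.5: log LR = 1 → P(A) = 1/(1+e⁻¹)
        post = qda_posterior(model_1d(0.0, 2.0), np.array([0.5]))
        assert post[0] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    def test_matches_direct_density_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = rng.integers(1, 4)
            k = rng.integers(2, 4)
            means = rng.normal(size=(k, d))
            covs = np.empty((k, d, d))
            for i in range(k):
                A = rng.normal(size=(d, d))
                covs[i] = A @ A.T + d * np.eye(d)
            priors = rng.dirichlet(np.ones(k))
            m = QdaModel(classes=[f"C{i}" for i in range(k)], means=means,
                         covariances=covs, priors=priors, shrinkage=0.0)
            x = rng.normal(size=d)
            dens = np.array([
                priors[i] * multivariate_normal.pdf(x, means[i], covs[i])
                for i in range(k)
            ])
            np.testing.assert_allclose(qda_posterior(m, x), dens / dens.sum(),
                                       atol=1e-8)

    def test_agrees_with_sklearn_qda(self):
        """Independent cross-check against sklearn's QDA (no shrinkage)."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1.5, 0.8, (30, 3))])
        y = np.array(["A"] * 30 + ["B"] * 30)
        ours = qda_fit(X, y, shrinkage=0.0)
        theirs = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y)
        np.testing.assert_allclose(
            qda_posterior(ours, X), theirs.predict_proba(X), atol=1e-8
        )

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            qda_posterior(model_1d(0, 1), np.array([np.nan]))

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(4)
        m = qda_fit(rng.normal(size=(40, 2)),
                    ["A"] * 20 + ["B"] * 20, shrinkage=1e-3)
        post = qda_posterior(m, rng.normal(size=(25, 2)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


def spectral_set(grid, rows, labels, patients=None, samples=None,
                 state=("raw", "minmax_normalized")):
    patients = patients or [f"P{i}" for i in range(len(rows))]
    samples = samples or ["S0"] * len(rows)
    return SpectrumSet([
        make_spectrum(grid, row, patient=p, sample=s, slice_id=f"C{i}",
                      label=l, state=state)
        for i, (row, l, p, s) in enumerate(zip(rows, labels, patients, samples))
    ])


class TestKfold:
    def test_perfectly_separable_any_k(self):
        g = WavenumberGrid.regular(950, 1480, 2.0)
        rng = np.random.default_rng(5)
        rows = [np.full(len(g), 0.1) + rng.normal(0, 0.01, len(g)) for _ in range(12)]
        rows += [np.full(len(g), 0.9) + rng.normal(0, 0.01, len(g)) for _ in range(12)]
        sset = spectral_set(g, rows, ["normal"] * 12 + ["tumor"] * 12)
        for k in (2, 4):
            cv = kfold_cross_validate(sset, RegionSet([(1000, 1020)]), k=k, seed=0)
            assert cv["pooled_accuracy"] == 1.0

    def test_shuffled_labels_near_chance(self):
        g = WavenumberGrid.regular(950, 1480, 2.0)
        rng = np.random.default_rng(6)
        rows = [rng.normal(0.5, 0.1, len(g)) for _ in range(60)]
        labels = ["normal"] * 30 + ["tumor"] * 30
        sset = spectral_set(g, rows, labels)
        cv = kfold_cross_validate(sset, RegionSet([(1000, 1040)]), k=5, seed=1)
        assert abs(cv["pooled_accuracy"] - 0.5) < 3 * np.sqrt(0.25 / 60)

    def test_leave_one_out_matches_explicit_loop(self):
        from irclass.classification import qda_fit as fit, qda_posterior as post_f
        from irclass.region_selection import extract_features

        g = WavenumberGrid.regular(950, 1480, 50.0)
        rng = np.random.default_rng(7)
        rows = [rng.normal(0.2 * (i % 2), 0.1, len(g)) for i in range(12)]
        labels = ["normal", "tumor"] * 6
        sset = spectral_set(g, rows, labels)
        regions = RegionSet([(950, 1480)])
        cv = kfold_cross_validate(sset, regions, k=12, seed=2)
        feats = extract_features(sset, regions).to_numpy()
        y = np.asarray(sset.labels)
        correct = 0
        for i in range(12):
            mask = np.ones(12, dtype=bool)
            mask[i] = False
            m = fit(feats[mask], y[mask])
            pred = np.asarray(m.classes)[np.argmax(post_f(m, feats[i]))]
            correct += pred == y[i]
        assert cv["pooled_accuracy"] == pytest.approx(correct / 12)

    def test_k_too_large_rejected(self, tiny_set):
        with pytest.raises(ValueError):
            kfold_cross_validate(tiny_set, None, k=50)


class TestClassifySamples:
    def grid(self):
        return WavenumberGrid.regular(950, 1480, 2.0)

    def trained(self, g):
        rng = np.random.default_rng(8)
        rows = [np.full(len(g), 0.2) + rng.normal(0, 0.02, len(g)) for _ in range(10)]
        rows += [np.full(len(g), 0.8) + rng.normal(0, 0.02, len(g)) for _ in range(10)]
        train = spectral_set(g, rows, ["normal"] * 10 + ["tumor"] * 10)
        regions = RegionSet([(1000, 1010)])
        from irclass.region_selection import extract_features

        return qda_fit(extract_features(train, regions).to_numpy(), train.labels,
                       regions=regions,
                       normalization_hash=normalization_fingerprint(train, regions))

    def test_mean_posterior_and_assignment(self):
        g = self.grid()
        model = self.trained(g)
        rng = np.random.default_rng(9)
        rows = [np.full(len(g), v) + rng.normal(0, 0.01, len(g))
                for v in (0.18, 0.22, 0.2)]
        sset = spectral_set(g, rows, ["normal"] * 3,
                            patients=["P1"] * 3, samples=["S1"] * 3)
        results = classify_samples(model, sset)
        assert len(results) == 1
        r = results[0]
        assert r.n_spectra == 3
        np.testing.assert_allclose(
            [r.mean_probability[c] for c in model.classes],
            r.posteriors.mean(axis=0),
        )
        assert r.assigned_class == "normal"
        assert r.mean_probability["normal"] > 0.5

    def test_three_spectra_mean_arithmetic(self):
        post = np.array([[0.9, 0.1], [0.7, 0.3], [0.8, 0.2]])
        from irclass.classification import _assign

        cls, amb = _assign(["normal", "tumor"], post.mean(axis=0), post)
        assert post.mean(axis=0)[0] == pytest.approx(0.8)
        assert cls == "normal" and not amb

    def test_three_class_argmax_rule(self):
        from irclass.classification import _assign

        post = np.array([[0.2, 0.5, 0.3]])
        cls, amb = _assign(["CCC", "HCC", "metastasis"], post[0], post)
        assert cls == "HCC" and not amb

    def test_binary_tie_goes_to_tumor_flagged(self):
        from irclass.classification import _assign

        post = np.array([[0.5, 0.5]])
        cls, amb = _assign(["normal", "tumor"], post[0], post)
        assert cls == "tumor" and amb

    def test_normalization_hash_mismatch_rejected(self):
        g = self.grid()
        model = self.trained(g)
        rows = [np.full(len(g), 0.2)]
        raw = spectral_set(g, rows, ["normal"], state=("raw",))
        with pytest.raises(ValueError, match="fingerprint"):
            classify_samples(model, raw)


class TestRenderGrid:
    def test_table_row_count_and_csv(self, tmp_path):
        g = WavenumberGrid.regular(950, 1480, 2.0)
        rng = np.random.default_rng(10)
        rows = [np.full(len(g), 0.2) + rng.normal(0, 0.02, len(g)) for _ in range(6)]
        rows += [np.full(len(g), 0.8) + rng.normal(0, 0.02, len(g)) for _ in range(6)]
        train = spectral_set(g, rows, ["normal"] * 6 + ["tumor"] * 6)
        regions = RegionSet([(1000, 1010)])
        from irclass.region_selection import extract_features

        model = qda_fit(extract_features(train, regions).to_numpy(), train.labels,
                        regions=regions)
        results = classify_samples(model, train)
        csv = tmp_path / "grid.csv"
        png = tmp_path / "grid.png"
        table = render_probability_grid(results, csv_path=csv, png_path=png)
        assert len(table) == len(results)
        assert csv.exists() and png.exists()
        assert {"P_normal", "P_tumor", "assigned_class"} <= set(table.columns)
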