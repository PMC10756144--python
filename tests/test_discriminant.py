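import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from morphodelim import (
    MorphometryError,
    backward_stepwise,
    fit_lda,
    loo_crossvalidate,
    published_keys,
    score,
    wildcard_classify,
)

from conftest import make_record


def two_class_data(rng, n0=20, n1=20, p=3, sep=3.0):
    X0 = rng.normal(0, 1, (n0, p))
    X1 = rng.normal(0, 1, (n1, p)) + sep / np.sqrt(p)
    X = pd.DataFrame(np.vstack([X0, X1]), columns=[f"c{i}" for i in range(p)],
                     index=[f"s{i}" for i in range(n0 + n1)])
    y = {f"s{i}": ("A" if i < n0 else "B") for i in range(n0 + n1)}
    return X, y


class TestFitConvention:
    def test_unit_pooled_sd_and_symmetric_means(self, rng):
        X, y = two_class_data(rng)
        f = fit_lda(X, y)
        scores = X.to_numpy() @ f.coefficients + f.offset
        labels = np.array([y[i] for i in X.index])
        mean_a = scores[labels == "A"].mean()
        mean_b = scores[labels == "B"].mean()
        assert mean_a == pytest.approx(-mean_b, abs=1e-9)
        # pooled within-class score variance = 1
        pooled = (
            ((scores[labels == "A"] - mean_a) ** 2).sum()
            + ((scores[labels == "B"] - mean_b) ** 2).sum()
        ) / (len(scores) - 2)
        assert pooled == pytest.approx(1.0, rel=1e-9)

    def test_one_dimensional_limit(self, rng):
        n = 4000
        X = pd.DataFrame({"x": np.concatenate([rng.normal(-1, 1, n),
                                               rng.normal(1, 1, n)])})
        y = {i: ("neg" if int(i) < n else "pos") for i in X.index.astype(str)}
        X.index = X.index.astype(str)
        f = fit_lda(X, y, positive_class="pos")
        assert f.coefficients[0] == pytest.approx(1.0, abs=0.05)
        assert f.class_stats["pos"]["mean"] == pytest.approx(1.0, abs=0.07)

    def test_closed_form_direction_oracle(self, rng):
        X, y = two_class_data(rng, n0=8, n1=8, p=2)
        f = fit_lda(X, y, positive_class="A")
        Xa = X.to_numpy()
        labels = np.array([y[i] for i in X.index])
        mu_a, mu_b = Xa[labels == "A"].mean(0), Xa[labels == "B"].mean(0)
        S = (
            np.cov(Xa[labels == "A"], rowvar=False) * 7
            + np.cov(Xa[labels == "B"], rowvar=False) * 7
        ) / 14
        w = np.linalg.inv(S) @ (mu_a - mu_b)
        w = w / np.sqrt(w @ S @ w)
        np.testing.assert_allclose(f.coefficients, w, rtol=1e-9)

    def test_identical_means_flagged(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
                          "z": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]},
                         index=list("abcdef"))
        y = {"a": "A", "b": "A", "c": "A", "d": "B", "e": "B", "f": "B"}
        X.loc[list("def")] = X.loc[list("abc")].to_numpy()
        f = fit_lda(X, y)
        assert f.metadata["degenerate"]

    def test_class_size_precondition(self, rng):
        X, y = two_class_data(rng, n0=3, n1=20, p=4)
        with pytest.raises(MorphometryError, match="reduce"):
            fit_lda(X, y)

    def test_duplicated_records_preserve_direction(self, rng):
        X, y = two_class_data(rng)
        f1 = fit_lda(X, y)
        X2 = pd.concat([X, X.set_axis([f"{i}_dup" for i in X.index])])
        y2 = {**y, **{f"{i}_dup": v for i, v in y.items()}}
        f2 = fit_lda(X2, y2)
        cos = (f1.coefficients @ f2.coefficients) / (
            np.linalg.norm(f1.coefficients) * np.linalg.norm(f2.coefficients)
        )
        assert cos == pytest.approx(1.0, abs=1e-9)


class TestScore:
    def test_published_gyne_key_worked_example(self):
        gyne = {k.name: k for k in published_keys()}["gyne_key"]
        s = score(gyne, {"CW": 0.827, "CLSPD": 0.140}, units="mm")
        assert round(s, 2) == -1.69

    def test_midpoint_scores_zero(self, rng):
        X, y = two_class_data(rng)
        f = fit_lda(X, y)
        labels = np.array([y[i] for i in X.index])
        mid = (X.to_numpy()[labels == "A"].mean(0)
               + X.to_numpy()[labels == "B"].mean(0)) / 2
        assert score(f, dict(zip(X.columns, mid))) == pytest.approx(0.0, abs=1e-9)

    def test_table_mean_gyne_scores_in_printed_range(self):
        # mean large-species gyne reconstructed from CS, CL/CW and CLSPD/CS
        cs = 0.897  # mm
        cl_cw = 0.939
        cw = 2 * cs / (1 + cl_cw)
        clspd = 0.141 * cs
        gyne = {k.name: k for k in published_keys()}["gyne_key"]
        s = score(gyne, {"CW": cw, "CLSPD": clspd}, units="mm")
        lo, hi = gyne.class_stats["fugax"]["range"]
        assert lo <= s <= hi

    def test_unit_conversion_from_stored_um(self):
        gyne = {k.name: k for k in published_keys()}["gyne_key"]
        rec = make_record("g", "N1", caste="gyne", CW=827, CLSPD=140)
        assert score(gyne, rec) == pytest.approx(
            score(gyne, {"CW": 0.827, "CLSPD": 0.140}, units="mm")
        )

    def test_missing_character(self):
        gyne = {k.name: k for k in published_keys()}["gyne_key"]
        with pytest.raises(MorphometryError, match="CLSPD"):
            score(gyne, {"CW": 0.8}, units="mm")


class TestLOOCrossValidation:
    def test_separable_classes_perfect(self, rng):
        X, y = two_class_data(rng, sep=20.0)
        cm = loo_crossvalidate(X, y)
        assert (cm.percent_correct == 100.0).all()
        assert cm.overall_accuracy == 1.0

    def test_brute_force_sklearn_oracle(self, rng):
        X, y = two_class_data(rng, n0=10, n1=10, p=2, sep=1.5)
        cm = loo_crossvalidate(X, y)
        preds = cm.metadata["predictions"]
        for item in X.index:
            rest = X.drop(index=item)
            yrest = [y[i] for i in rest.index]
            clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            clf.fit(rest.to_numpy(), yrest)
            assert preds[item] == clf.predict(X.loc[[item]].to_numpy())[0]

    def test_counts_structure(self, rng):
        X, y = two_class_data(rng)
        cm = loo_crossvalidate(X, y)
        assert cm.n_per_class["A"] == 20
        assert cm.counts.to_numpy().sum() == 40


class TestWildcard:
    def test_far_query_near_certain(self, rng):
        X, y = two_class_data(rng, sep=10.0)
        labels = np.array([y[i] for i in X.index])
        q = pd.DataFrame([X.to_numpy()[labels == "B"].mean(0)],
                         columns=X.columns, index=["query"])
        post = wildcard_classify(X, y, q)
        assert post.loc["query", "B"] > 0.999
        assert post.loc["query"].sum() == pytest.approx(1.0)

    def test_hand_bayes_oracle(self):
        # two points per class in 1-D: pooled var known in closed form
        X = pd.DataFrame({"x": [0.0, 2.0, 6.0, 8.0]}, index=list("abcd"))
        y = {"a": "L", "b": "L", "c": "R", "d": "R"}
        q = pd.DataFrame({"x": [3.0]}, index=["q"])
        post = wildcard_classify(X, y, q)
        mu_l, mu_r, s2 = 1.0, 7.0, (2 + 2) / 2  # pooled within-class variance
        ll = np.exp(-0.5 * (3 - mu_l) ** 2 / s2)
        lr = np.exp(-0.5 * (3 - mu_r) ** 2 / s2)
        assert post.loc["q", "L"] == pytest.approx(ll / (ll + lr), rel=1e-9)

    def test_sklearn_posterior_oracle(self, rng):
        X, y = two_class_data(rng, n0=12, n1=9, p=3, sep=2.0)
        q = pd.DataFrame(rng.normal(1.0, 1.0, (4, 3)), columns=X.columns,
                         index=[f"q{i}" for i in range(4)])
        post = wildcard_classify(X, y, q)
        clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        clf.fit(X.to_numpy(), [y[i] for i in X.index])
        expected = clf.predict_proba(q.to_numpy())
        np.testing.assert_allclose(post.to_numpy(), expected, atol=1e-6)

    def test_affine_rescaling_invariance(self, rng):
        X, y = two_class_data(rng)
        q = pd.DataFrame(rng.normal(size=(2, 3)), columns=X.columns,
                         index=["q0", "q1"])
        post1 = wildcard_classify(X, y, q)
        X2, q2 = X.copy(), q.copy()
        X2["c0"] = X2["c0"] * 1000 + 7
        q2["c0"] = q2["c0"] * 1000 + 7
        post2 = wildcard_classify(X2, y, q2)
        np.testing.assert_allclose(post1.to_numpy(), post2.to_numpy(), atol=1e-8)

    def test_query_in_training_rejected(self, rng):
        X, y = two_class_data(rng)
        with pytest.raises(MorphometryError, match="training"):
            wildcard_classify(X, y, X.iloc[[0]])


class TestBackwardStepwise:
    def test_pure_noise_character_removed_first(self, rng):
        X, y = two_class_data(rng, n0=25, n1=25, p=2, sep=4.0)
        X["noise"] = rng.normal(size=len(X))
        f = backward_stepwise(X, y, target_k=2)
        assert f.metadata["selection_trace"][0]["removed"] == "noise"
        assert set(f.characters) == {"c0", "c1"}

    def test_matches_exhaustive_subset_search(self, rng):
        X, y = two_class_data(rng, n0=12, n1=12, p=4, sep=2.0)
        f = backward_stepwise(X, y, target_k=3)
        greedy_acc = loo_crossvalidate(X[f.characters], y).overall_accuracy
        best_acc = max(
            loo_crossvalidate(X[list(sub)], y).overall_accuracy
            for sub in itertools.combinations(X.columns, 3)
        )
        # greedy must reach the exhaustive optimum up to one misclassification
        assert greedy_acc >= best_acc - 1.0 / len(X)

    def test_invalid_target(self, rng):
        X, y = two_class_data(rng)
        with pytest.raises(MorphometryError):
            backward_stepwise(X, y, target_k=0)


class TestPublishedKeys:
    def test_d3_constants(self):
        d3 = {k.name: k for k in published_keys()}["D3"]
        np.testing.assert_allclose(d3.coefficients, [0.060, -0.047, -0.125])
        assert d3.offset == -4.582
        assert d3.characters == ["ML", "CWB", "CLYW"]
        assert d3.class_stats["fugax"]["mean"] == 1.713
        assert d3.class_stats["juliae"]["n"] == 62

    def test_gyne_key_constants(self):
        gyne = {k.name: k for k in published_keys()}["gyne_key"]
        np.testing.assert_allclose(gyne.coefficients, [35.24, -58.91])
        assert gyne.offset == -22.59

    def test_d3_zero_vector_gives_offset(self):
        d3 = {k.name: k for k in published_keys()}["D3"]
        s = score(d3, {"ML": 0.0, "CWB": 0.0, "CLYW": 0.0})
        assert s == pytest.approx(-4.582)

    def test_json_round_trip(self, tmp_path):
        from morphodelim import DiscriminantFunction

        d3 = published_keys()[0]
        p = tmp_path / "d3.json"
        d3.to_json(p)
        back = DiscriminantFunction.from_json(p)
        np.testing.assert_allclose(back.coefficients, d3.coefficients)
        assert back.class_stats == d3.class_stats
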