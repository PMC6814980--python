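"""Logistic loop model: fitting, prediction, averaging, cutoff, serialization."""

import numpy as np
import pandas as pd
import pytest

from chiploop import model as M


def make_rows(n, rng, with_r=True):
    rows = pd.DataFrame(
        {
            "d": rng.integers(1_000, 100_000, size=n).astype(float),
            "o": rng.choice(["convergent", "forward", "reverse", "divergent"], size=n),
            "s": 5.6 + rng.exponential(1.5, size=n),
        }
    )
    if with_r:
        rows["r_t"] = rng.uniform(-0.2, 1.0, size=n)
    return rows


TRUE_BETA = {
    "intercept": -2.0,
    "d": -3.0e-5,
    "o_forward": -1.0,
    "o_reverse": -1.2,
    "o_divergent": -1.6,
    "s": 0.12,
    "r_t": 3.0,
}


def simulate_labels(rows, rng):
    X, names, _ = M.design_matrix(rows)
    beta = np.array([TRUE_BETA[n] for n in names])
    p = 1 / (1 + np.exp(-(X @ beta)))
    rows = rows.copy()
    rows["label"] = rng.random(len(rows)) < p
    return rows, X, names, beta


class TestFit:
    def test_single_class_raises(self, rng):
        rows = make_rows(20, rng)
        rows["label"] = True
        X, names, _ = M.design_matrix(rows)
        with pytest.raises(M.SeparationError):
            M.fit(X, rows["label"].to_numpy(float), names)

    def test_tiny_dataset_matches_statsmodels_glm(self):
        # 8-row dataset with an independent Newton/IRLS implementation
        import statsmodels.api as sm

        X = np.column_stack(
            [
                np.ones(8),
                [0.1, 0.5, 0.9, 1.3, 0.2, 0.8, 1.1, 0.4],
                [1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 1.0, 0.0],
            ]
        )
        y = np.array([0, 1, 1, 0, 0, 1, 1, 0], dtype=float)  # overlapping classes
        ours = M.fit(X, y, ("intercept", "x1", "x2"))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(
            ours.diagnostics.std_errors, ref.bse, rtol=1e-5
        )

    def test_simulation_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        rows = make_rows(20_000, rng)
        rows, X, names, beta = simulate_labels(rows, rng)
        m = M.fit(X, rows["label"].to_numpy(float), names)
        z = np.abs(m.beta - beta) / m.diagnostics.std_errors
        assert np.all(z < 3.0), dict(zip(names, z))

    def test_complete_separation_raises_with_last_iterate(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = (np.arange(10) >= 5).astype(float)
        with pytest.raises(M.SeparationError) as err:
            M.fit(X, y, ("intercept", "x"))
        assert err.value.last_beta is not None

    def test_deterministic(self, rng):
        rows = make_rows(500, rng)
        rows, X, names, _ = simulate_labels(rows, rng)
        y = rows["label"].to_numpy(float)
        m1 = M.fit(X, y, names)
        m2 = M.fit(X, y, names)
        np.testing.assert_array_equal(m1.beta, m2.beta)


class TestPredict:
    def test_zero_coefficients_give_half(self, rng):
        rows = make_rows(5, rng)
        X, names, _ = M.design_matrix(rows)
        m = M.LoopModel(names, np.zeros(len(names)))
        np.testing.assert_array_equal(M.predict(m, X, names), 0.5)

    def test_extreme_linear_predictor_saturates(self):
        m = M.LoopModel(("intercept",), np.array([800.0]))
        assert M.predict(m, np.ones((1, 1))) == pytest.approx(1.0)

    def test_matches_hand_computed_logistic(self):
        m = M.LoopModel(("intercept", "x"), np.array([-1.0, 2.0]))
        x = np.array([[1.0, 0.7]])
        expected = 1 / (1 + np.exp(-(-1.0 + 2.0 * 0.7)))
        assert M.predict(m, x) == pytest.approx(expected, abs=1e-12)

    def test_manifest_mismatch_is_hard_error(self, rng):
        rows = make_rows(5, rng)
        X, names, _ = M.design_matrix(rows)
        m = M.LoopModel(("intercept", "x"), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="manifest"):
            M.predict(m, X, names)

    def test_monotone_in_correlation_when_coefficient_positive(self, rng):
        rows = make_rows(2_000, rng)
        rows, X, names, _ = simulate_labels(rows, rng)
        m = M.fit(X, rows["label"].to_numpy(float), names)
        assert m.beta[names.index("r_t")] > 0
        row = rows.iloc[[0]].copy()
        ps = []
        for r in np.linspace(-1, 1, 9):
            row["r_t"] = r
            Xr, _, _ = M.design_matrix(row)
            ps.append(M.predict(m, Xr).item())
        assert np.all(np.diff(ps) > 0)

    def test_fit_predict_reproduces_fitted_probabilities(self, rng):
        rows = make_rows(300, rng)
        rows, X, names, _ = simulate_labels(rows, rng)
        y = rows["label"].to_numpy(float)
        m = M.fit(X, y, names)
        p1 = M.predict(m, X, names)
        p2 = M.predict(M.fit(X, y, names), X, names)
        np.testing.assert_array_equal(p1, p2)  # no stochastic step anywhere


class TestAverageModels:
    def test_average_of_one_is_identity(self):
        m = M.LoopModel(("intercept", "x"), np.array([0.3, -2.0]), cutoff=0.2)
        avg = M.average_models([m])
        np.testing.assert_array_equal(avg.beta, m.beta)
        assert avg.cutoff == m.cutoff
        assert avg.provenance == "averaged"

    def test_opposite_models_cancel(self):
        a = M.LoopModel(("intercept", "x"), np.array([1.0, -2.0]))
        b = M.LoopModel(("intercept", "x"), np.array([-1.0, 2.0]))
        np.testing.assert_array_equal(M.average_models([a, b]).beta, 0.0)

    def test_three_fixed_vectors_mean(self):
        vecs = [np.array([0.0, 3.0]), np.array([1.0, 0.0]), np.array([2.0, 0.0])]
        ms = [M.LoopModel(("intercept", "x"), v, cutoff=c)
              for v, c in zip(vecs, (0.1, 0.2, 0.3))]
        avg = M.average_models(ms)
        np.testing.assert_allclose(avg.beta, [1.0, 1.0])
        assert avg.cutoff == pytest.approx(0.2)

    def test_permutation_invariance(self):
        ms = [
            M.LoopModel(("intercept", "x"), np.array([i, -i], dtype=float), cutoff=0.1 * (i + 1))
            for i in range(1, 4)
        ]
        a = M.average_models(ms)
        b = M.average_models(ms[::-1])
        np.testing.assert_allclose(a.beta, b.beta, rtol=1e-15)
        assert a.cutoff == pytest.approx(b.cutoff, rel=1e-15)

    def test_manifest_mismatch_raises(self):
        a = M.LoopModel(("intercept", "x"), np.zeros(2) + 0.1)
        b = M.LoopModel(("intercept", "y"), np.zeros(2) + 0.1)
        with pytest.raises(ValueError, match="manifest"):
            M.average_models([a, b])


class TestSelectCutoff:
    def test_perfect_separation_returns_highest_perfect_threshold(self):
        scores = np.array([0.9] * 5 + [0.1] * 5)
        labels = np.array([True] * 5 + [False] * 5)
        assert M.select_cutoff(scores, labels) == pytest.approx(0.9)

    def test_matches_bruteforce_grid(self, rng):
        scores = rng.random(200).round(2)  # force ties
        labels = rng.random(200) < 0.3

        def brute():
            best, best_f1 = None, -1.0
            for t in np.unique(scores):
                call = scores >= t
                tp = (call & labels).sum()
                prec = tp / call.sum() if call.sum() else np.nan
                rec = tp / labels.sum()
                f1 = 0.0 if prec + rec == 0 or np.isnan(prec) else 2 * prec * rec / (prec + rec)
                if f1 > best_f1:  # strict: keeps smallest threshold on ties
                    best, best_f1 = t, f1
            return best

        assert M.select_cutoff(scores, labels) == pytest.approx(brute())

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            M.select_cutoff(np.array([0.1, 0.9]), np.array([True, True]))


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        m = M.LoopModel(
            ("intercept", "d", "o_forward", "o_reverse", "o_divergent", "s", "r_t"),
            rng.normal(size=7) * np.array([1, 1e-5, 1, 1, 1, 0.1, 3]),
            cutoff=float(rng.uniform(0.01, 0.99)),
            provenance="trained",
        )
        path = tmp_path / "m.txt"
        M.save_model(m, path)
        back = M.load_model(path)
        assert back.features == m.features
        np.testing.assert_array_equal(back.beta, m.beta)
        assert back.cutoff == m.cutoff
        assert back.provenance == m.provenance

    def test_rejects_non_model_file(self, tmp_path):
        path = tmp_path / "x.txt"
        path.write_text("hello\n")
        with pytest.raises(ValueError):
            M.load_model(path)


def test_design_matrix_imputes_missing_correlations(rng):
    rows = make_rows(10, rng)
    rows.loc[3, "r_t"] = np.nan
    X, names, imputed = M.design_matrix(rows)
    assert names[-1] == "r_t"
    assert X[3, -1] == 0.0
    assert imputed["r_t"].tolist() == [False] * 3 + [True] + [False] * 6
    # dummy coding: indicators sum <= 1, convergent is all-zeros reference
    dummies = X[:, [names.index(f"o_{l}") for l in ("forward", "reverse", "divergent")]]
    assert np.all(dummies.sum(axis=1) <= 1)
    conv = rows["o"].to_numpy() == "convergent"
    assert np.all(dummies[conv].sum(axis=1) == 0)
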