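"""Tests for the seven model families, the BIOCLIM envelope, AUC, and
map prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harpyrange.background import build_design
from harpyrange.sdm_models import (
    MODEL_FAMILIES,
    FeatureError,
    ModelSpec,
    compute_auc,
    fit_model,
    predict_map,
    score_bioclim,
)


def pairwise_auc(labels, scores):
    """Brute-force AUC oracle: enumerate all presence/absence pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_hand_enumerated_example(self):
        # pairs: (0.8 vs 0.7) win, (0.8 vs 0.1) win, (0.3 vs 0.7) loss,
        # (0.3 vs 0.1) win -> 3/4
        assert compute_auc([1, 0, 1, 0], [0.8, 0.7, 0.3, 0.1]) == 0.75

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        assert compute_auc(labels, scores) == pytest.approx(
            pairwise_auc(labels, scores), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=40)
        a = compute_auc(labels, scores)
        b = compute_auc(labels, np.exp(3 * scores) - 1)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([1, 1], [0.5, 0.6])


def naive_bioclim(train: pd.DataFrame, query: pd.DataFrame) -> np.ndarray:
    """Independent loop-based envelope-score oracle."""
    out = []
    for _, q in query.iterrows():
        per_var = []
        for col in train.columns:
            t = train[col].to_numpy()
            x = q[col]
            if x < t.min() or x > t.max():
                per_var.append(0.0)
                continue
            F = (np.sum(t < x) + 0.5 * np.sum(t == x)) / len(t)
            per_var.append(1.0 - 2.0 * abs(F - 0.5))
        out.append(min(per_var))
    return np.array(out)


class TestBioclim:
    @pytest.fixture
    def train(self):
        rng = np.random.default_rng(2)
        return pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))

    def test_median_site_scores_one(self, train):
        # odd trick: use a training set with odd row count per variable so
        # the median is an observed value with F = 0.5
        t = train.iloc[:19]
        q = pd.DataFrame([t.median()], columns=t.columns)
        assert score_bioclim(t, q)[0] == pytest.approx(1.0)

    def test_outside_range_scores_zero(self, train):
        q = pd.DataFrame([{"a": 99.0, "b": 0.0, "c": 0.0}])
        assert score_bioclim(train, q)[0] == 0.0

    def test_matches_naive_oracle(self, train):
        rng = np.random.default_rng(3)
        q = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        np.testing.assert_allclose(
            score_bioclim(train, q), naive_bioclim(train, q), atol=1e-12
        )

    def test_invariant_to_row_duplication(self, train):
        rng = np.random.default_rng(4)
        q = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        doubled = pd.concat([train] * 2, ignore_index=True)
        np.testing.assert_allclose(
            score_bioclim(train, q), score_bioclim(doubled, q), atol=1e-12
        )

    def test_zero_variance_variable(self, train):
        t = train.copy()
        t["a"] = 1.0
        q = pd.DataFrame([{"a": 1.0, "b": t["b"].median(), "c": t["c"].median()},
                          {"a": 2.0, "b": t["b"].median(), "c": t["c"].median()}])
        with pytest.warns(UserWarning):
            s = score_bioclim(t, q)
        assert s[0] > 0 and s[1] == 0.0


def separable_design(n=200, seed=0, gap=6.0):
    rng = np.random.default_rng(seed)
    pres = pd.DataFrame(rng.normal(loc=gap / 2, size=(n // 2, 2)), columns=["a", "b"])
    abse = pd.DataFrame(rng.normal(loc=-gap / 2, size=(n // 2, 2)), columns=["a", "b"])
    return build_design(pres, abse, seed=seed)


class TestModelFamilies:
    @pytest.mark.parametrize("family", MODEL_FAMILIES)
    def test_separable_clouds_near_perfect_auc(self, family):
        design = separable_design(n=200, seed=5)
        m = fit_model(ModelSpec(family=family, seed=1), design)
        assert m.test_auc >= 0.95

    @pytest.mark.parametrize("family", MODEL_FAMILIES)
    def test_permuted_labels_null_auc(self, family):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(400, 3)), columns=list("abc"))
        design = build_design(X.iloc[:200], X.iloc[200:], seed=6)
        m = fit_model(ModelSpec(family=family, seed=2), design)
        assert 0.35 <= m.test_auc <= 0.65

    def test_glm_recovers_known_slope(self):
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-2.0 * x))
        y = rng.uniform(size=n) < p
        k = min(y.sum(), (~y).sum())
        pres = pd.DataFrame({"x": x[y][:k]})
        abse = pd.DataFrame({"x": x[~y][:k]})
        design = build_design(pres, abse, seed=7)
        m = fit_model(ModelSpec(family="glm"), design)
        slope = float(m.fit_artifacts["sk_model"].coef_[0][0])
        assert slope == pytest.approx(2.0, abs=0.15)

    def test_seeded_refit_is_reproducible(self):
        design = separable_design(n=100, seed=8, gap=2.0)
        for family in ("rf", "svm", "maxent_like", "mars"):
            a = fit_model(ModelSpec(family=family, seed=9), design)
            b = fit_model(ModelSpec(family=family, seed=9), design)
            np.testing.assert_array_equal(
                a.predict(design.X_test), b.predict(design.X_test)
            )

    def test_scores_bounded(self):
        design = separable_design(n=100, seed=9, gap=1.0)
        probe = pd.DataFrame(
            np.random.default_rng(0).normal(scale=5, size=(50, 2)), columns=["a", "b"]
        )
        for family in MODEL_FAMILIES:
            m = fit_model(ModelSpec(family=family, seed=3), design)
            s = m.predict(probe)
            assert (s >= 0).all() and (s <= 1).all()


@pytest.fixture(scope="module")
def fitted(dataset64):
    from harpyrange.environment import extract_values

    X, _ = extract_values(dataset64.stack, dataset64.occurrences)
    names = dataset64.stack.names
    tbl = dataset64.stack.table()
    abs_rows = tbl.sample(n=len(X), random_state=1)[names]
    design = build_design(X[names], abs_rows, seed=10)
    model = fit_model(ModelSpec(family="glm"), design)
    return design, model


class TestPredictMap:
    def test_map_matches_point_predictions(self, dataset64, fitted):
        design, model = fitted
        smap = predict_map(model, dataset64.stack)
        tbl = dataset64.stack.table()
        expected = model.predict(tbl[dataset64.stack.names])
        np.testing.assert_allclose(
            smap.grid.values[tbl["row"], tbl["col"]], expected, atol=1e-12
        )

    def test_nodata_propagates(self, dataset64, fitted):
        _, model = fitted
        from harpyrange.environment import EnvStack

        stack = EnvStack()
        for name in dataset64.stack.names:
            g = dataset64.stack[name]
            vals = g.values.copy()
            vals[2, 3] = g.nodata
            stack.add(name, g.copy_with(vals))
        smap = predict_map(model, stack)
        assert not smap.grid.valid_mask()[2, 3]

    def test_missing_layer_rejected(self, dataset64, fitted):
        _, model = fitted
        from harpyrange.environment import EnvStack

        partial = EnvStack()
        partial.add("SYN01", dataset64.stack["SYN01"])
        with pytest.raises(FeatureError):
            predict_map(model, partial)

    def test_all_families_share_grid_and_mask(self, dataset64, fitted):
        design, _ = fitted
        masks = []
        for family in ("bioclim", "glm", "rf"):
            m = fit_model(ModelSpec(family=family, seed=4), design)
            smap = predict_map(m, dataset64.stack)
            assert smap.grid.same_grid(dataset64.stack.ref)
            masks.append(smap.grid.valid_mask())
        assert all(np.array_equal(masks[0], m_) for m_ in masks[1:])
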