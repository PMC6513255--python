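"""The seven suitability-model families behind one fit/predict contract.

Families: a BIOCLIM climatic envelope, a maxent-like presence-background
regularized logistic (linear + quadratic features), multivariate adaptive
regression splines (MARS, main effects), plain logistic regression, an
additive logistic model with per-variable smooths (GAM), a random forest,
and a probability-calibrated support-vector machine.  Linear/additive
models enter variables as main effects only — no interactions.  Every
family trains on the 80% partition of a balanced presence/pseudo-absence
design, scores in [0, 1], and records its train and held-out AUC.

The maxent-like family is this package's own presence-background model: a
ridge-penalized logistic on linear + quadratic feature expansions with the
penalty chosen by held-out likelihood.  Its provenance string is
"maxent_like".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .background import DesignError, DesignSet
from .environment import EnvStack, RasterGrid

MODEL_FAMILIES = ("bioclim", "glm", "gam", "mars", "rf", "maxent_like", "svm")


class FitError(RuntimeError):
    """A model family failed to fit; the message names the family."""


class FeatureError(KeyError):
    pass


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}")


@dataclass
class FittedModel:
    spec: ModelSpec
    feature_names: list[str]
    fit_artifacts: dict
    predict_fn: Callable[[np.ndarray], np.ndarray]
    train_auc: float = float("nan")
    test_auc: float = float("nan")

    def predict(self, X) -> np.ndarray:
        """Suitability scores in [0, 1] for rows of X (model feature order)."""
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.feature_names if n not in X.columns]
            if missing:
                raise FeatureError(f"missing features {missing}")
            X = X[self.feature_names].to_numpy(dtype=np.float64)
        else:
            X = np.asarray(X, dtype=np.float64)
        scores = np.asarray(self.predict_fn(X), dtype=np.float64)
        return np.clip(scores, 0.0, 1.0)


@dataclass
class SuitabilityMap:
    """A continuous habitat-quality raster in [0, 1] with provenance."""

    grid: RasterGrid
    provenance: str
    auc_weight: Optional[float] = None


# -- AUC ------------------------------------------------------------------


def compute_auc(labels, scores) -> float:
    """Area under the ROC curve, Mann-Whitney form with half-credit ties.

    AUC = (#{presence > absence pairs} + 0.5 * #ties) / (n1 * n0),
    computed via midranks.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties with half credit
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


# -- BIOCLIM envelope -----------------------------------------------------


def score_bioclim(presence_train, query) -> np.ndarray:
    """Classic climatic-envelope percentile score.

    Per variable v with empirical CDF F_v over the presence training
    values (midpoint ranks, ties averaged), a query x scores
    s_v = 1 - 2*|F_v(x) - 0.5| inside the training min-max and 0 outside;
    the site score is the minimum over variables.  A site matching every
    per-variable median scores 1.
    """
    P = pd.DataFrame(presence_train)
    Q = pd.DataFrame(query)
    if P.shape[0] < 5:
        raise ValueError("need at least 5 presence training rows")
    if list(P.columns) != list(Q.columns):
        Q = Q[P.columns]
    scores = np.ones(len(Q), dtype=np.float64)
    for col in P.columns:
        train = np.sort(P[col].to_numpy(dtype=np.float64))
        x = Q[col].to_numpy(dtype=np.float64)
        lo, hi = train[0], train[-1]
        if lo == hi:
            warnings.warn(f"zero-variance variable {col!r} in BIOCLIM envelope")
            s = np.where(x == lo, 1.0, 0.0)
        else:
            # midpoint-rank ECDF: F(x) = (#<x + 0.5 * #==x) / n
            below = np.searchsorted(train, x, side="left")
            upto = np.searchsorted(train, x, side="right")
            F = (below + 0.5 * (upto - below)) / train.size
            s = 1.0 - 2.0 * np.abs(F - 0.5)
            s = np.where((x < lo) | (x > hi), 0.0, s)
        scores = np.minimum(scores, s)
    return scores


# -- MARS (main effects, forward hinge pairs + GCV pruning) ---------------


def _hinge_basis(X: np.ndarray, terms: list[tuple[int, float, int]]) -> np.ndarray:
    """Design matrix: intercept + hinge terms (var, knot, sign)."""
    cols = [np.ones(X.shape[0])]
    for var, knot, sign in terms:
        cols.append(np.maximum(0.0, sign * (X[:, var] - knot)))
    return np.column_stack(cols)


def _lstsq_sse(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _gcv(sse: float, n: int, n_terms: int, penalty: float) -> float:
    # effective parameters: terms plus a knot-selection charge
    c = n_terms + penalty * (n_terms - 1) / 2.0
    denom = (1.0 - c / n) ** 2
    if denom <= 0:
        return np.inf
    return sse / n / denom


def _fit_mars(
    X: np.ndarray,
    y: np.ndarray,
    max_terms: int = 21,
    gcv_penalty: float = 3.0,
    n_knots: int = 20,
) -> dict:
    """Forward hinge-pair growth to ``max_terms`` basis functions, then
    backward deletion by generalized cross-validation."""
    n, p = X.shape
    candidates: list[tuple[int, float]] = []
    for var in range(p):
        qs = np.unique(np.quantile(X[:, var], np.linspace(0.05, 0.95, n_knots)))
        candidates.extend((var, float(k)) for k in qs)

    terms: list[tuple[int, float, int]] = []
    used: set[tuple[int, float]] = set()
    B = _hinge_basis(X, terms)
    coef, sse = _lstsq_sse(B, y)
    while len(terms) + 2 <= max_terms - 1:  # -1: intercept counts as a term
        best = None
        for var, knot in candidates:
            if (var, knot) in used:
                continue
            trial = terms + [(var, knot, 1), (var, knot, -1)]
            _, trial_sse = _lstsq_sse(_hinge_basis(X, trial), y)
            if best is None or trial_sse < best[0] - 1e-12:
                best = (trial_sse, var, knot)
        if best is None or best[0] >= sse * (1 - 1e-9):
            break
        sse, var, knot = best
        terms += [(var, knot, 1), (var, knot, -1)]
        used.add((var, knot))

    # backward pass: drop whichever term most improves GCV
    def gcv_of(tt):
        _, s = _lstsq_sse(_hinge_basis(X, tt), y)
        return _gcv(s, n, len(tt) + 1, gcv_penalty)

    best_terms = list(terms)
    best_gcv = gcv_of(best_terms)
    current = list(terms)
    while current:
        trials = [(gcv_of(current[:i] + current[i + 1:]), i) for i in range(len(current))]
        g, i = min(trials)
        current = current[:i] + current[i + 1:]
        if g < best_gcv:
            best_gcv, best_terms = g, list(current)

    coef, _ = _lstsq_sse(_hinge_basis(X, best_terms), y)
    return {"terms": best_terms, "coef": coef, "gcv": best_gcv,
            "max_terms": max_terms, "gcv_penalty": gcv_penalty}


# -- family fitters -------------------------------------------------------


def _standardizer(X: np.ndarray):
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _fit_glm(Xtr, ytr, spec):
    # C = inf: plain maximum-likelihood logistic regression, no penalty
    model = LogisticRegression(C=np.inf, max_iter=2000)
    model.fit(Xtr, ytr)
    return {"sk_model": model}, lambda X: model.predict_proba(X)[:, 1]


def _fit_gam(Xtr, ytr, spec):
    """Additive logistic model: one cubic B-spline smooth per variable,
    no interactions, with a mild ridge for numerical stability (separable
    designs otherwise send the MLE to infinity)."""
    from statsmodels.gam.api import BSplines

    df = int(spec.hyperparameters.get("spline_df", 5))
    lo, hi = Xtr.min(axis=0), Xtr.max(axis=0)
    bs = BSplines(Xtr, df=[df] * Xtr.shape[1], degree=[3] * Xtr.shape[1])
    model = LogisticRegression(
        C=float(spec.hyperparameters.get("C", 10.0)), max_iter=5000
    )
    model.fit(bs.basis, ytr)

    def predict(X):
        # clip to the training support: B-spline bases are undefined beyond
        # their boundary knots
        Xc = np.clip(X, lo, hi)
        return model.predict_proba(bs.transform(Xc))[:, 1]

    return {"sk_model": model, "smoother": bs, "clip": (lo, hi)}, predict


def _fit_mars_family(Xtr, ytr, spec):
    art = _fit_mars(
        Xtr, ytr.astype(np.float64),
        max_terms=int(spec.hyperparameters.get("max_terms", 21)),
        gcv_penalty=float(spec.hyperparameters.get("gcv_penalty", 3.0)),
    )
    terms, coef = art["terms"], art["coef"]

    def predict(X):
        return _hinge_basis(X, terms) @ coef

    return art, predict


def _fit_rf(Xtr, ytr, spec):
    model = RandomForestClassifier(
        n_estimators=int(spec.hyperparameters.get("n_estimators", 300)),
        random_state=spec.seed,
        n_jobs=1,
    )
    model.fit(Xtr, ytr)
    return {"sk_model": model}, lambda X: model.predict_proba(X)[:, 1]


def _fit_maxent_like(Xtr, ytr, spec):
    """Presence-background ridge logistic on linear + quadratic features.

    The ridge penalty C is chosen by held-out log-likelihood on an internal
    seeded 75/25 split of the training rows, then the model is refit on the
    full training partition.
    """
    mu, sd = _standardizer(Xtr)

    def expand(X):
        Z = (X - mu) / sd
        return np.column_stack([Z, Z**2])

    E = expand(Xtr)
    rng = np.random.default_rng(spec.seed)
    n = len(ytr)
    val = np.zeros(n, dtype=bool)
    val[rng.choice(n, size=max(1, n // 4), replace=False)] = True
    if len(np.unique(ytr[~val])) < 2 or len(np.unique(ytr[val])) < 2:
        val = np.zeros(n, dtype=bool)  # tiny data: skip internal tuning
    grid = spec.hyperparameters.get("C_grid", (0.01, 0.1, 1.0, 10.0))
    best_C, best_ll = None, -np.inf
    for C in grid:
        if not val.any():
            best_C = grid[len(grid) // 2]
            break
        m = LogisticRegression(C=C, max_iter=2000)
        m.fit(E[~val], ytr[~val])
        p = np.clip(m.predict_proba(E[val])[:, 1], 1e-12, 1 - 1e-12)
        ll = float(np.sum(ytr[val] * np.log(p) + (1 - ytr[val]) * np.log(1 - p)))
        if ll > best_ll:
            best_ll, best_C = ll, C
    model = LogisticRegression(C=best_C, max_iter=2000)
    model.fit(E, ytr)
    return (
        {"sk_model": model, "C": best_C, "standardize": (mu, sd)},
        lambda X: model.predict_proba(expand(X))[:, 1],
    )


def _fit_svm(Xtr, ytr, spec):
    from sklearn.calibration import CalibratedClassifierCV

    mu, sd = _standardizer(Xtr)
    base = SVC(kernel="rbf", C=float(spec.hyperparameters.get("C", 1.0)),
               random_state=spec.seed)
    # sigmoid calibration on deterministic stratified folds of the training
    # split turns the margin into a probability
    model = CalibratedClassifierCV(base, method="sigmoid", cv=3)
    model.fit((Xtr - mu) / sd, ytr)
    return (
        {"sk_model": model, "standardize": (mu, sd)},
        lambda X: model.predict_proba((X - mu) / sd)[:, 1],
    )


_FITTERS = {
    "glm": _fit_glm,
    "gam": _fit_gam,
    "mars": _fit_mars_family,
    "rf": _fit_rf,
    "maxent_like": _fit_maxent_like,
    "svm": _fit_svm,
}


def fit_model(spec: ModelSpec, design: DesignSet) -> FittedModel:
    """Fit one family on the training partition and score both partitions.

    BIOCLIM uses only the presence rows of the training partition (it is a
    presence-only envelope); every other family uses presences and
    pseudo-absences.  Train and held-out AUC are stored on the result.
    """
    ytr, yte = design.y_train, design.y_test
    if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
        raise DesignError("both classes required in each partition")
    names = design.feature_names
    Xtr = design.X_train.to_numpy(dtype=np.float64)
    Xte = design.X_test.to_numpy(dtype=np.float64)

    if spec.family == "bioclim":
        P = design.presence_train().to_numpy(dtype=np.float64)

        def predict(X):
            return score_bioclim(
                pd.DataFrame(P, columns=names), pd.DataFrame(X, columns=names)
            )

        artifacts = {"presence_train": P}
    else:
        try:
            artifacts, predict = _FITTERS[spec.family](Xtr, ytr, spec)
        except FitError:
            raise
        except Exception as exc:
            raise FitError(f"{spec.family} failed to fit: {exc}") from exc

    model = FittedModel(spec=spec, feature_names=names,
                        fit_artifacts=artifacts, predict_fn=predict)
    model.train_auc = compute_auc(ytr, model.predict(design.X_train))
    model.test_auc = compute_auc(yte, model.predict(design.X_test))
    return model


def predict_map(model: FittedModel, stack: EnvStack) -> SuitabilityMap:
    """Score every jointly-valid cell of the stack; nodata propagates."""
    missing = [n for n in model.feature_names if n not in stack.names]
    if missing:
        raise FeatureError(f"stack lacks model features {missing}")
    ref = stack.ref
    mask = stack.valid_mask()
    rr, cc = np.nonzero(mask)
    X = pd.DataFrame(
        {n: stack[n].values[rr, cc] for n in model.feature_names}
    )
    scores = model.predict(X)
    out = np.full(ref.shape, ref.nodata, dtype=np.float64)
    out[rr, cc] = scores
    return SuitabilityMap(
        grid=ref.copy_with(out),
        provenance=model.spec.family,
        auc_weight=model.test_auc,
    )


def auc_table(models: dict[str, FittedModel], data_label: str) -> pd.DataFrame:
    """Per-family AUC table (columns model, data, auc) for reporting."""
    return pd.DataFrame(
        [
            {"model": fam, "data": data_label, "auc": m.test_auc,
             "train_auc": m.train_auc}
            for fam, m in models.items()
        ]
    )
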