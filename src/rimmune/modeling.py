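"""Prediction of high/low immune status from radiomic features.

The classifier roster: penalized logistic regression, penalized
discriminant analysis, sparse discriminant analysis, linear
discriminant analysis (LDA), naive Bayes, CART, bagged CART and random
forest.  LDA and Gaussian naive Bayes are implemented from their
closed-form definitions (shared-covariance Gaussian discriminant,
per-class independent Gaussians); the remaining models follow their
canonical algorithms via scikit-learn, all behind one interface that
returns a continuous score for ROC analysis.  "high" is the positive
class throughout.

Preprocessing (fitted on training folds only, in this order): remove
zero-variance features, KNN imputation of missing values, per-feature
Yeo-Johnson power transform with maximum-likelihood lambda, centering
and scaling to unit SD.

Evaluation uses the 0.632 bootstrap: per resample the preprocessing and
model are refit on the bootstrap sample, metrics are measured on the
apparent (full training) data and on the out-of-bag samples, and the
per-resample estimate is 0.368 * apparent + 0.632 * out-of-bag; the
report gives the mean and SD of these per-resample estimates.
Sensitivity/specificity use the score cutoff maximizing Youden's J on
the apparent data of each resample.  Hyperparameters, where a model
has any, are chosen inside each resample by out-of-bag AUC over a
small fixed grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "yeo_johnson",
    "PreprocessorState",
    "preprocess_fit",
    "preprocess_transform",
    "ModelSpec",
    "MODEL_ROSTER",
    "fit_predict",
    "roc_auc",
    "youden_threshold",
    "ResampleEstimate",
    "bootstrap632_evaluate",
    "bootstrap632_evaluate_roster",
    "select_final_model",
    "evaluate_on_test",
    "lda_group_means",
    "LdaGroupMeanReport",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def yeo_johnson(x, lam: float):
    """Yeo-Johnson power transform, defined on all reals.

    x >= 0: ((x+1)^lam - 1)/lam, or log(x+1) at lam = 0;
    x <  0: -(((-x+1)^(2-lam)) - 1)/(2-lam), or -log(-x+1) at lam = 2.
    """
    arr = np.asarray(x, dtype=np.float64)
    out = np.empty_like(arr)
    pos = arr >= 0
    if lam != 0:
        out[pos] = ((arr[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(arr[pos])
    if lam != 2:
        out[~pos] = -(((-arr[~pos] + 1.0) ** (2.0 - lam)) - 1.0) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-arr[~pos])
    return out if np.ndim(x) else float(out)


@dataclass
class PreprocessorState:
    retained: list[str]
    imputer: KNNImputer
    lambdas: np.ndarray
    center: np.ndarray
    scale: np.ndarray


def preprocess_fit(table: pd.DataFrame, k_neighbors: int = 5) -> PreprocessorState:
    """Fit the preprocessing chain on a (training) feature table."""
    variances = table.var(axis=0, ddof=0, skipna=True)
    retained = [c for c in table.columns if np.isfinite(variances[c]) and variances[c] > 0]
    if not retained:
        raise ValueError("all features have zero variance")
    x = table[retained].to_numpy(dtype=np.float64)
    imputer = KNNImputer(n_neighbors=k_neighbors)
    x = imputer.fit_transform(x)
    lambdas = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        try:
            x[:, j], lambdas[j] = stats.yeojohnson(x[:, j])
        except Exception:  # pathological columns keep the identity transform
            logger.info("Yeo-Johnson MLE failed for %s; lambda=1", retained[j])
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return PreprocessorState(
        retained=retained, imputer=imputer, lambdas=lambdas, center=center, scale=scale
    )


def preprocess_transform(state: PreprocessorState, table: pd.DataFrame) -> np.ndarray:
    x = state.imputer.transform(table[state.retained].to_numpy(dtype=np.float64))
    for j, lam in enumerate(state.lambdas):
        x[:, j] = yeo_johnson(x[:, j], float(lam))
    return (x - state.center) / state.scale


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A roster entry: name, hyperparameter grid, complexity rank.

    Lower complexity rank means a simpler model; linear/probabilistic
    models rank below the tree ensembles.
    """

    name: str
    grid: tuple = ()  # candidate hyperparameter dicts
    complexity_rank: int = 0


MODEL_ROSTER: list[ModelSpec] = [
    ModelSpec("penalized_logistic", ({"C": 0.1}, {"C": 1.0}), 3),
    ModelSpec("penalized_DA", ({"shrinkage": 0.1}, {"shrinkage": 0.5}), 4),
    ModelSpec("sparse_DA", ({"alpha": 0.01}, {"alpha": 0.1}), 5),
    ModelSpec("LDA", (), 1),
    ModelSpec("naive_bayes", (), 2),
    ModelSpec("CART", ({"max_depth": 3}, {"max_depth": 5}), 6),
    ModelSpec("bagged_CART", (), 7),
    ModelSpec("random_forest", (), 8),
]


class _HandLDA:
    """Shared-covariance Gaussian discriminant from the closed form.

    A singular pooled covariance is ridge-regularized (logged epsilon).
    """

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_HandLDA":
        x0, x1 = x[y == 0], x[y == 1]
        self.mu0, self.mu1 = x0.mean(axis=0), x1.mean(axis=0)
        n = len(y)
        cov = ((x0 - self.mu0).T @ (x0 - self.mu0) + (x1 - self.mu1).T @ (x1 - self.mu1)) / max(
            n - 2, 1
        )
        self.log_prior = np.log(len(x1) / n) - np.log(len(x0) / n)
        p = cov.shape[0]
        eps = 0.0
        diff = self.mu1 - self.mu0
        while True:
            try:
                reg = cov + eps * np.eye(p)
                if eps == 0 and (n - 2) < p:
                    raise np.linalg.LinAlgError("p > n: pooled covariance singular")
                self.w = np.linalg.solve(reg, diff)
                break
            except np.linalg.LinAlgError:
                eps = max(eps * 10, 1e-4 * max(np.trace(cov) / p, 1e-12))
                logger.info("singular pooled covariance; ridge epsilon %.3g", eps)
        self.b = -0.5 * (self.mu0 + self.mu1) @ self.w + self.log_prior
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return x @ self.w + self.b


class _HandNB:
    """Gaussian naive Bayes: per-class independent Gaussians, closed form."""

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_HandNB":
        self.params = {}
        self.priors = {}
        global_var = x.var(axis=0).max()
        self.eps = 1e-9 * max(global_var, 1e-12)
        for c in (0, 1):
            xc = x[y == c]
            self.params[c] = (xc.mean(axis=0), xc.var(axis=0) + self.eps)
            self.priors[c] = len(xc) / len(y)
        return self

    def _log_lik(self, x: np.ndarray, c: int) -> np.ndarray:
        mu, var = self.params[c]
        return (-0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)).sum(axis=1) + np.log(
            self.priors[c]
        )

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self._log_lik(x, 1) - self._log_lik(x, 0)


class _LassoScorer:
    """Sparse discriminant via l1-penalized optimal scoring (lasso on +-1)."""

    def __init__(self, alpha: float):
        self.alpha = alpha

    def fit(self, x, y):
        self.model = Lasso(alpha=self.alpha, max_iter=2000)
        self.model.fit(x, 2.0 * y - 1.0)
        return self

    def decision_function(self, x):
        return self.model.predict(x)


class _ProbaWrapper:
    def __init__(self, est):
        self.est = est

    def fit(self, x, y):
        self.est.fit(x, y)
        return self

    def decision_function(self, x):
        return self.est.predict_proba(x)[:, 1]


def _build_model(name: str, params: dict, seed: int = 0):
    if name == "LDA":
        return _HandLDA()
    if name == "naive_bayes":
        return _HandNB()
    if name == "penalized_logistic":
        return _ProbaWrapper(
            LogisticRegression(C=params.get("C", 1.0), max_iter=500)  # ridge penalty (default)
        )
    if name == "penalized_DA":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=params.get("shrinkage", 0.5))
    if name == "sparse_DA":
        return _LassoScorer(alpha=params.get("alpha", 0.01))
    if name == "CART":
        return _ProbaWrapper(
            DecisionTreeClassifier(max_depth=params.get("max_depth", 5), random_state=seed)
        )
    if name == "bagged_CART":
        return _ProbaWrapper(
            BaggingClassifier(
                DecisionTreeClassifier(random_state=seed), n_estimators=25, random_state=seed
            )
        )
    if name == "random_forest":
        return _ProbaWrapper(RandomForestClassifier(n_estimators=100, random_state=seed))
    raise ValueError(f"unknown model {name!r}")


def fit_predict(
    model: ModelSpec,
    train: tuple[np.ndarray, np.ndarray],
    test: np.ndarray,
    params: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one roster model and score a test matrix.

    Returns (continuous scores, hard labels at the model's natural
    threshold).  Inputs are preprocessed arrays; labels are 0/1 with 1
    = "high" as the positive class.
    """
    x, y = train
    if params is None:
        params = model.grid[0] if model.grid else {}
    est = _build_model(model.name, params, seed=seed).fit(x, y)
    scores = est.decision_function(test)
    thr = 0.5 if model.name in {"penalized_logistic", "CART", "bagged_CART", "random_forest"} else 0.0
    return scores, (scores > thr).astype(int)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC by the pairwise Mann-Whitney formulation plus its p-value.

    Ties count one half.  The p-value is the two-sided Mann-Whitney
    test of score separation (null: AUC = 0.5).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for ROC analysis")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return auc, float(res.pvalue)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cutoff maximizing sensitivity + specificity - 1."""
    order = np.argsort(scores)
    s, y = scores[order], np.asarray(labels)[order]
    n_pos, n_neg = y.sum(), (1 - y).sum()
    cuts = np.unique(s)
    best_j, best_c = -np.inf, cuts[0]
    for c in cuts:
        pred = s > c
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        if sens + spec - 1 > best_j:
            best_j, best_c = sens + spec - 1, c
    return float(best_c)


def _sens_spec(scores, labels, thr):
    pred = scores > thr
    y = np.asarray(labels)
    sens = float((pred & (y == 1)).sum() / max((y == 1).sum(), 1))
    spec = float((~pred & (y == 0)).sum() / max((y == 0).sum(), 1))
    return sens, spec


# ---------------------------------------------------------------------------
# 0.632 bootstrap
# ---------------------------------------------------------------------------

@dataclass
class ResampleEstimate:
    """0.632-bootstrap performance of one model with across-resample SDs."""

    model: str
    auc: float
    sens: float
    spec: float
    auc_sd: float
    sens_sd: float
    spec_sd: float
    B: int
    seed: int
    n_used: int = 0

    def __post_init__(self) -> None:
        for v, nm in [(self.auc, "AUC"), (self.sens, "Sens"), (self.spec, "Spec")]:
            if not (0.0 <= v <= 1.0 or np.isnan(v)):
                raise ValueError(f"{nm} out of [0, 1]: {v}")


def bootstrap632_evaluate_roster(
    specs: list[ModelSpec],
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    B: int = 25,
    seed: int = 0,
    k_neighbors: int = 5,
) -> dict[str, ResampleEstimate]:
    """0.632-bootstrap evaluation of several models on shared resamples.

    Preprocessing is refit inside every resample (no leakage) and shared
    across models; hyperparameters are selected per resample by
    out-of-bag AUC.  Out-of-bag sets containing a single class skip
    that resample's contribution (logged).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    y = np.asarray(pd.Series(labels).loc[table.index] if isinstance(labels, pd.Series) else labels)
    n = len(table)
    rng = np.random.default_rng(seed)
    per_model: dict[str, list[tuple[float, float, float]]] = {s.name: [] for s in specs}

    for b in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        y_boot, y_oob = y[idx], y[oob]
        if len(np.unique(y_boot)) < 2:
            logger.info("resample %d: single-class bootstrap sample, skipped", b)
            continue
        state = preprocess_fit(table.iloc[idx], k_neighbors=k_neighbors)
        x_boot = preprocess_transform(state, table.iloc[idx])
        x_full = preprocess_transform(state, table)
        x_oob = x_full[oob] if len(oob) else np.empty((0, x_full.shape[1]))
        oob_ok = len(oob) >= 2 and len(np.unique(y_oob)) == 2
        if not oob_ok:
            logger.info("resample %d: out-of-bag set single-class/empty, skipped", b)
            continue
        mseed = int(rng.integers(0, 2**31))

        for spec in specs:
            grid = spec.grid if spec.grid else ({},)
            best_params, best_oob_auc = None, -np.inf
            for params in grid:
                sc_oob, _ = fit_predict(spec, (x_boot, y_boot), x_oob, params=params, seed=mseed)
                a, _ = roc_auc(sc_oob, y_oob)
                if a > best_oob_auc:
                    best_oob_auc, best_params = a, params
            est = _build_model(spec.name, best_params or {}, seed=mseed).fit(x_boot, y_boot)
            sc_full = est.decision_function(x_full)
            sc_oob = sc_full[oob]
            auc_app, _ = roc_auc(sc_full, y)
            auc_oob, _ = roc_auc(sc_oob, y_oob)
            thr = youden_threshold(sc_full, y)
            sens_app, spec_app = _sens_spec(sc_full, y, thr)
            sens_oob, spec_oob = _sens_spec(sc_oob, y_oob, thr)
            per_model[spec.name].append(
                (
                    0.368 * auc_app + 0.632 * auc_oob,
                    0.368 * sens_app + 0.632 * sens_oob,
                    0.368 * spec_app + 0.632 * spec_oob,
                )
            )

    out: dict[str, ResampleEstimate] = {}
    for spec in specs:
        vals = np.array(per_model[spec.name])
        if len(vals) == 0:
            raise RuntimeError(f"no usable resamples for model {spec.name}")
        mean = np.clip(vals.mean(axis=0), 0.0, 1.0)
        sd = vals.std(axis=0, ddof=1) if len(vals) > 1 else np.zeros(3)
        out[spec.name] = ResampleEstimate(
            model=spec.name,
            auc=float(mean[0]),
            sens=float(mean[1]),
            spec=float(mean[2]),
            auc_sd=float(sd[0]),
            sens_sd=float(sd[1]),
            spec_sd=float(sd[2]),
            B=B,
            seed=seed,
            n_used=len(vals),
        )
    return out


def bootstrap632_evaluate(
    model: ModelSpec,
    table: pd.DataFrame,
    labels,
    B: int = 25,
    seed: int = 0,
    k_neighbors: int = 5,
) -> ResampleEstimate:
    """0.632-bootstrap evaluation of a single model."""
    return bootstrap632_evaluate_roster([model], table, labels, B=B, seed=seed, k_neighbors=k_neighbors)[
        model.name
    ]


def select_final_model(
    estimates: list[ResampleEstimate], specs: list[ModelSpec] | None = None
) -> ModelSpec:
    """Simplicity-aware selection among statistically comparable models.

    Candidates are the models whose AUC is within one across-resample SD
    of the best model's AUC; among them the one with the smallest
    complexity rank wins, ties broken by roster order.
    """
    if not estimates:
        raise ValueError("no estimates to select from")
    specs = MODEL_ROSTER if specs is None else specs
    by_name = {s.name: s for s in specs}
    best = max(estimates, key=lambda e: e.auc)
    window = best.auc - best.auc_sd
    candidates = [e for e in estimates if e.auc >= window]
    roster_pos = {s.name: i for i, s in enumerate(specs)}
    chosen = min(
        candidates, key=lambda e: (by_name[e.model].complexity_rank, roster_pos[e.model])
    )
    return by_name[chosen.model]


def evaluate_on_test(
    model: ModelSpec,
    train_table: pd.DataFrame,
    train_labels,
    test_table: pd.DataFrame,
    test_labels,
    seed: int = 0,
    k_neighbors: int = 5,
) -> dict[str, float]:
    """Refit preprocessing+model on the full training set; test AUC and p."""
    y_tr = np.asarray(train_labels)
    y_te = np.asarray(test_labels)
    state = preprocess_fit(train_table, k_neighbors=k_neighbors)
    x_tr = preprocess_transform(state, train_table)
    x_te = preprocess_transform(state, test_table)
    params = model.grid[0] if model.grid else {}
    est = _build_model(model.name, params, seed=seed).fit(x_tr, y_tr)
    scores = est.decision_function(x_te)
    auc, p = roc_auc(scores, y_te)
    thr = youden_threshold(est.decision_function(x_tr), y_tr)
    sens, spec = _sens_spec(scores, y_te, thr)
    return {"auc": auc, "p_value": p, "sens": sens, "spec": spec}


# ---------------------------------------------------------------------------
# LDA group means (standardized predictor report)
# ---------------------------------------------------------------------------

@dataclass
class LdaGroupMeanReport:
    """Standardized group means of named predictors, rows = low/high."""

    table: pd.DataFrame  # index ["low", "high"], columns = predictors


def lda_group_means(
    table: pd.DataFrame,
    labels,
    predictors: list[str],
    k_neighbors: int = 5,
) -> LdaGroupMeanReport:
    """Per-class means of standardized predictors (Table-style report).

    With centered, standardized predictors the weighted class means sum
    to zero: n_low * mean_low + n_high * mean_high = 0 per predictor.
    """
    y = np.asarray(labels)
    state = preprocess_fit(table, k_neighbors=k_neighbors)
    x = preprocess_transform(state, table)
    cols = {c: j for j, c in enumerate(state.retained)}
    missing = [p for p in predictors if p not in cols]
    if missing:
        raise KeyError(f"predictors not in retained feature set: {missing}")
    sel = [cols[p] for p in predictors]
    rows = {
        "low": x[y == 0][:, sel].mean(axis=0),
        "high": x[y == 1][:, sel].mean(axis=0),
    }
    return LdaGroupMeanReport(
        table=pd.DataFrame.from_dict(rows, orient="index", columns=predictors)
    )
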