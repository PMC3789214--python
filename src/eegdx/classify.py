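"""Logistic diagnostic index and biomarker selection.

The diagnostic index is a logistic model f(z) = 1/(1+e^-z) with
z = beta0 + sum_i beta_i x_i over k selected biomarkers; f is read as the
probability of conversion to Alzheimer's disease and thresholded at 0.5
(boundary inclusive -> converter). Selection is by a genetic search
(mutation rules on the biomarker set, positive-likelihood-ratio survival)
or by elastic-net penalized logistic regression. Evaluation uses five
outcome measures (SE, SP, PPV, PLR, MCC) with Monte-Carlo null critical
values and stratified half-split cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .signal_core import InvalidArgumentError

#: PLR when specificity is 1 and sensitivity > 0: an infinity sentinel that
#: orders above every finite PLR (matters for genetic-search survival).
PLR_INF = np.inf


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LogisticIndexModel:
    """Fitted diagnostic index: intercept, per-biomarker coefficients and
    the probability threshold."""

    beta0: float
    betas: np.ndarray
    biomarker_names: list[str]
    threshold: float = 0.5
    separated: bool = False

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.size != len(self.biomarker_names):
            raise InvalidArgumentError("coefficient count must equal name count")
        if not (0 < self.threshold < 1):
            raise InvalidArgumentError("threshold must be in (0, 1)")


@dataclass
class OutcomeMetrics:
    """Confusion counts and the five outcome measures."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    positive_predictive_value: float
    positive_likelihood_ratio: float
    matthews_correlation: float

    def as_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
                "SE": self.sensitivity, "SP": self.specificity,
                "PPV": self.positive_predictive_value,
                "PLR": self.positive_likelihood_ratio,
                "MCC": self.matthews_correlation}


@dataclass(frozen=True)
class GeneticSearchConfig:
    n_generations: int = 100
    rule_applications_per_rule: int = 5
    seed_set_size: int = 5
    survival_criterion: str = "PLR"
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_generations, self.rule_applications_per_rule,
               self.seed_set_size) < 0 or self.seed_set_size < 1:
            raise InvalidArgumentError("config counts must be >= 1")


@dataclass(frozen=True)
class ElasticNetConfig:
    """Mixing parameter ``alpha`` follows the lambda2/(lambda1+lambda2)
    convention, i.e. the *ridge* fraction (0.8 -> L1 fraction 0.2)."""

    alpha: float = 0.8
    n_cv_splits: int = 5
    n_lambdas: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1):
            raise InvalidArgumentError("alpha must be in [0, 1]")


# ---------------------------------------------------------------------------
# Logistic index
# ---------------------------------------------------------------------------

def fit_logistic(features: pd.DataFrame | np.ndarray, labels,
                 biomarker_names: list[str] | None = None) -> LogisticIndexModel:
    """Maximum-likelihood logistic fit.

    A vanishing ridge (1e-6) guards against divergence under perfect
    separation; such fits are flagged ``separated`` (detected by perfect
    training classification with large coefficient norm).
    """
    if isinstance(features, pd.DataFrame):
        biomarker_names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if biomarker_names is None:
            biomarker_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise InvalidArgumentError("need both classes in the labels")
    if np.bincount(y).min() < 2:
        raise InvalidArgumentError("need >= 2 subjects per class")
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("missing features are not allowed in the fit")
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    preds = clf.predict(X)
    z = clf.decision_function(X)
    separated = bool(np.all(preds == y) and np.min(np.abs(z)) > 4)
    return LogisticIndexModel(beta0=float(clf.intercept_[0]),
                              betas=clf.coef_[0],
                              biomarker_names=biomarker_names,
                              separated=separated)


def predict(model: LogisticIndexModel,
            features: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probability of conversion and hard class (prob >= threshold -> 1)."""
    if isinstance(features, pd.DataFrame):
        missing = [n for n in model.biomarker_names if n not in features.columns]
        if missing:
            raise InvalidArgumentError(f"missing features: {missing}")
        X = features[model.biomarker_names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :] if X.size == len(model.biomarker_names) else X[:, None]
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("missing feature values")
    z = model.beta0 + X @ model.betas
    prob = 1.0 / (1.0 + np.exp(-z))
    return prob, (prob >= model.threshold).astype(int)


# ---------------------------------------------------------------------------
# Outcome metrics
# ---------------------------------------------------------------------------

def outcome_metrics(predicted, truth) -> OutcomeMetrics:
    """SE, SP, PPV, PLR and MCC from predicted and true binary labels.

    Degenerate denominators: PLR is +inf when SP = 1 and SE > 0 (and 0
    when additionally SE = 0); MCC is 0 when its denominator vanishes.
    """
    yhat = np.asarray(predicted, dtype=int)
    y = np.asarray(truth, dtype=int)
    if yhat.shape != y.shape:
        raise InvalidArgumentError("length mismatch")
    if np.unique(y).size < 2:
        raise InvalidArgumentError("both classes must be present in the truth")
    tp = int(np.sum((yhat == 1) & (y == 1)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    return metrics_from_counts(tp, fp, tn, fn)


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> OutcomeMetrics:
    se = tp / (tp + fn) if tp + fn else np.nan
    sp = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else 0.0
    if sp == 1.0:
        plr = PLR_INF if se > 0 else 0.0
    else:
        plr = se / (1.0 - sp)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return OutcomeMetrics(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=se,
                          specificity=sp, positive_predictive_value=ppv,
                          positive_likelihood_ratio=plr,
                          matthews_correlation=float(mcc))


def _criterion(m: OutcomeMetrics, name: str) -> float:
    return {"PLR": m.positive_likelihood_ratio,
            "MCC": m.matthews_correlation,
            "SE": m.sensitivity, "SP": m.specificity,
            "PPV": m.positive_predictive_value}[name]


# ---------------------------------------------------------------------------
# Genetic search
# ---------------------------------------------------------------------------

def single_biomarker_mcc(features: pd.DataFrame, labels) -> pd.Series:
    """Training MCC of each biomarker's own logistic fit (seeding rank)."""
    y = np.asarray(labels, dtype=int)
    out = {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)) or np.ptp(x) == 0:
            out[name] = -np.inf
            continue
        model = fit_logistic(x[:, None], y, [name])
        _, cls = predict(model, x[:, None])
        out[name] = outcome_metrics(cls, y).matthews_correlation
    return pd.Series(out).sort_values(ascending=False)


def _evaluate_set(features: pd.DataFrame, y: np.ndarray,
                  subset: tuple[str, ...], criterion: str):
    model = fit_logistic(features[list(subset)], y)
    _, cls = predict(model, features[list(subset)])
    m = outcome_metrics(cls, y)
    return (_criterion(m, criterion), m.matthews_correlation, -len(subset)), model, m


def genetic_search(features: pd.DataFrame, labels,
                   config: GeneticSearchConfig | None = None,
                   ) -> tuple[list[str], LogisticIndexModel, list[float]]:
    """Genetic biomarker-set search with elitist survival.

    Seeded with the ``seed_set_size`` biomarkers of highest single-
    biomarker MCC. Each generation applies four mutation rules (add a
    random biomarker, remove one, draw a fresh random set of four,
    substitute one) ``rule_applications_per_rule`` times each; every
    offspring is scored by fitting a logistic model and computing the
    survival criterion (PLR) on the training data, and the best of
    {current, offspring} survives, so the criterion trace is
    non-decreasing. Ties break by higher MCC, then smaller set size. There
    is no constraint on the set size.

    Returns (selected names, fitted model, per-generation criterion trace).
    """
    config = config or GeneticSearchConfig()
    y = np.asarray(labels, dtype=int)
    candidates = list(features.columns)
    if len(candidates) < config.seed_set_size:
        raise InvalidArgumentError("fewer candidate biomarkers than seed size")
    rng = np.random.default_rng(config.seed)
    ranking = single_biomarker_mcc(features, y)
    current = tuple(ranking.index[:config.seed_set_size])
    current_score, current_model, _ = _evaluate_set(features, y, current,
                                                    config.survival_criterion)
    trace = [current_score[0]]

    def mutate(rule: int, subset: tuple[str, ...]) -> tuple[str, ...]:
        s = list(subset)
        if rule == 0:  # add a random biomarker
            pool = [c for c in candidates if c not in s]
            if pool:
                s.append(rng.choice(pool))
        elif rule == 1:  # remove a biomarker
            if len(s) > 1:
                s.pop(rng.integers(len(s)))
        elif rule == 2:  # fresh random set of four
            s = list(rng.choice(candidates, size=min(4, len(candidates)),
                                replace=False))
        else:  # substitute one biomarker
            pool = [c for c in candidates if c not in s]
            if pool and s:
                s[rng.integers(len(s))] = rng.choice(pool)
        return tuple(dict.fromkeys(s))

    for _ in range(config.n_generations):
        for rule in range(4):
            for _ in range(config.rule_applications_per_rule):
                child = mutate(rule, current)
                if not child:
                    continue
                try:
                    score, model, _ = _evaluate_set(features, y, child,
                                                    config.survival_criterion)
                except InvalidArgumentError:
                    continue
                if score > current_score:
                    current, current_score, current_model = child, score, model
        trace.append(current_score[0])
    return list(current), current_model, trace


# ---------------------------------------------------------------------------
# Elastic net
# ---------------------------------------------------------------------------

def fit_elastic_net(features: pd.DataFrame, labels,
                    config: ElasticNetConfig | None = None,
                    ) -> tuple[list[str], LogisticIndexModel]:
    """Elastic-net penalized logistic regression over a lambda path.

    Features are z-scored with training statistics; zero-variance features
    are dropped with a warning. The penalty strength is chosen by
    stratified ``n_cv_splits``-fold cross-validated deviance (the
    "lambda.min" convention); the selected biomarkers are those with
    nonzero coefficients there. The returned model carries the penalized
    coefficients mapped back to the original feature scale.
    """
    import warnings

    config = config or ElasticNetConfig()
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        dead = [n for n, s in zip(names, sd) if s == 0]
        warnings.warn(f"dropping zero-variance features: {dead}")
        keep = sd > 0
        X, names, sd = X[:, keep], [n for n, k in zip(names, keep) if k], sd[keep]
    mu = X.mean(axis=0)
    Z = (X - mu) / sd
    l1_ratio = 1.0 - config.alpha  # ridge-fraction convention -> L1 fraction

    n = y.size
    lam_max = 1.05 * np.max(np.abs(Z.T @ (y - y.mean()))) / (n * max(l1_ratio, 1e-3))
    lambdas = np.geomspace(lam_max, lam_max * 1e-3, config.n_lambdas)

    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(y, config.n_cv_splits, rng)
    dev = np.zeros(lambdas.size)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(y[train]).size < 2 or np.unique(y[test_idx]).size < 1:
            continue
        for i, lam in enumerate(lambdas):
            clf = _enet_clf(lam, l1_ratio, n)
            clf.fit(Z[train], y[train])
            p = np.clip(clf.predict_proba(Z[test_idx])[:, 1], 1e-12, 1 - 1e-12)
            dev[i] -= np.sum(y[test_idx] * np.log(p)
                             + (1 - y[test_idx]) * np.log(1 - p))
    best = lambdas[int(np.argmin(dev))]
    clf = _enet_clf(best, l1_ratio, n)
    clf.fit(Z, y)
    coef_z = clf.coef_[0]
    selected = [n_ for n_, c in zip(names, coef_z) if abs(c) > 1e-8]
    betas = coef_z / sd
    beta0 = float(clf.intercept_[0] - np.sum(coef_z * mu / sd))
    model = LogisticIndexModel(beta0=beta0, betas=betas, biomarker_names=names)
    return selected, model


def _enet_clf(lam: float, l1_ratio: float, n: int) -> LogisticRegression:
    if l1_ratio == 0.0:
        return LogisticRegression(C=1.0 / (n * lam), solver="lbfgs",
                                  max_iter=5000)
    return LogisticRegression(l1_ratio=l1_ratio, C=1.0 / (n * lam),
                              solver="saga", max_iter=5000, tol=1e-4)


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.asarray(sorted(f)) for f in folds]


# ---------------------------------------------------------------------------
# Monte-Carlo null calibration and half-split cross-validation
# ---------------------------------------------------------------------------

def monte_carlo_thresholds(n_subjects: int, n_positive: int,
                           n_iterations: int = 5000, level: float = 0.95,
                           seed=None) -> dict:
    """Null critical values of the five outcome measures.

    Null model: a random classifier labelling each subject positive with
    probability 0.5, independent of the fixed true labels. Returns the
    ``level`` quantile of each metric's null distribution. These critical
    values depend on the sample size.
    """
    if not n_positive < n_subjects:
        raise InvalidArgumentError("n_positive must be < n_subjects")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_subjects, dtype=int)
    y[:n_positive] = 1
    vals = {k: np.empty(n_iterations) for k in ("MCC", "SE", "SP", "PPV", "PLR")}
    for i in range(n_iterations):
        yhat = rng.integers(0, 2, n_subjects)
        m = outcome_metrics(yhat, y)
        vals["MCC"][i] = m.matthews_correlation
        vals["SE"][i] = m.sensitivity
        vals["SP"][i] = m.specificity
        vals["PPV"][i] = m.positive_predictive_value
        vals["PLR"][i] = m.positive_likelihood_ratio
    out = {}
    for k, v in vals.items():
        q = np.quantile(v, level)
        if not np.isfinite(q):  # interpolation between infinite PLR values
            q = np.quantile(v, level, method="nearest")
        out[k] = float(q)
    return out


def half_split_cv(features: pd.DataFrame, labels, train_fn=None,
                  n_iterations: int = 1000, seed=None) -> dict:
    """Median outcome measures over stratified random half-splits.

    Per iteration the subjects are split in half (stratified by class), the
    full training procedure ``train_fn(features, labels) -> model`` runs on
    the first half and the metrics are computed on the second; the
    per-metric medians are returned. The default ``train_fn`` fits the
    plain logistic index on all columns.
    """
    y = np.asarray(labels, dtype=int)
    if np.bincount(y).min() < 4:
        raise InvalidArgumentError("need >= 4 subjects per class")
    if train_fn is None:
        train_fn = lambda f, l: fit_logistic(f, l)
    rng = np.random.default_rng(seed)
    acc = {k: [] for k in ("MCC", "SE", "SP", "PPV", "PLR")}
    done = 0
    while done < n_iterations:
        train_idx, test_idx = _stratified_half(y, rng)
        if (np.unique(y[train_idx]).size < 2 or np.unique(y[test_idx]).size < 2
                or np.bincount(y[train_idx]).min() < 2):
            continue
        model = train_fn(features.iloc[train_idx], y[train_idx])
        _, cls = predict(model, features.iloc[test_idx])
        m = outcome_metrics(cls, y[test_idx])
        for k, v in (("MCC", m.matthews_correlation), ("SE", m.sensitivity),
                     ("SP", m.specificity), ("PPV", m.positive_predictive_value),
                     ("PLR", m.positive_likelihood_ratio)):
            acc[k].append(v)
        done += 1
    return {k: float(np.median(v)) for k, v in acc.items()}


def _stratified_half(y: np.ndarray, rng: np.random.Generator):
    train, test = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        half = idx.size // 2
        train.extend(idx[:half])
        test.extend(idx[half:])
    return np.asarray(sorted(train)), np.asarray(sorted(test))
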