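"""Best-subset logistic modelling and leave-one-subject-out classification.

The analysis asks whether attentional-bias features predict smoking status.
Feature selection enumerates every subset of the candidate predictors in a
logistic model and ranks them by BIC (AIC reported alongside); the chosen
subset is then assessed with leave-one-subject-out (LOO) cross-validation:
each participant is classified (probability threshold 0.5, smoker = positive
class) by a model trained on all the others, and pooled held-out predictions
yield accuracy, sensitivity, specificity and AUC.  Accuracy is tested
against chance with an exact one-sided binomial test and an exact
Clopper-Pearson 95% interval.

Selection runs on the full sample before cross-validation, as is common in
small-sample biomarker studies; this is optimistic, and a nested variant
(selection repeated inside each training fold) is available via
``loo_cv(..., nested_selection=True)``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import binomtest

from .errors import ConfigError, DegenerateDataError

logger = logging.getLogger(__name__)

MAX_SUBSET_FEATURES = 20
RIDGE_LAMBDA = 1e-4
COEF_DIVERGENCE_LIMIT = 30.0


@dataclass
class LogisticFit:
    feature_names: tuple[str, ...]
    params: np.ndarray              # intercept first
    deviance: float
    converged: bool
    separation: bool                # ridge fallback applied

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        design = np.column_stack([np.ones(x.shape[0]), x])
        return expit(design @ self.params)


@dataclass
class SubsetModelScore:
    features: tuple[str, ...]
    deviance: float
    aic: float
    bic: float
    params: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.features)


@dataclass
class CVResult:
    participant_ids: list[str]
    probabilities: np.ndarray       # held-out P(smoker)
    predictions: np.ndarray         # 0/1 at threshold 0.5
    labels: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    binomial_p: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "participant_ids": list(self.participant_ids),
            "probabilities": self.probabilities.tolist(),
            "predictions": self.predictions.astype(int).tolist(),
            "labels": self.labels.astype(int).tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "binomial_p": self.binomial_p,
            "ci95": list(self.ci95),
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _ridge_irls(design: np.ndarray, y: np.ndarray,
                lam: float = RIDGE_LAMBDA, tol: float = 1e-10,
                maxiter: int = 200) -> np.ndarray:
    """Newton/IRLS for logistic regression with an L2 penalty on slopes."""
    p = design.shape[1]
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0  # intercept unpenalised
    beta = np.zeros(p)
    for _ in range(maxiter):
        mu = expit(design @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = design.T @ (mu - y) + pen @ beta
        hess = (design * w[:, None]).T @ design + pen
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _deviance(design: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = design @ beta
    # -2 log-likelihood via the numerically stable log(1 + exp) form
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(-2.0 * ll.sum())


def fit_logistic(features: np.ndarray | pd.DataFrame, labels: np.ndarray,
                 feature_names: tuple[str, ...] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS via statsmodels).

    Perfect separation or non-convergence triggers a ridge-penalised IRLS
    refit (lambda = 1e-4 on slopes) and sets ``separation=True``.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = tuple(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(x.shape[1]))
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigError("labels must be binary 0/1")
    n, k = x.shape
    if n < k + 2:
        raise DegenerateDataError(f"need at least {k + 2} observations for "
                                  f"{k} feature(s)")
    design = np.column_stack([np.ones(n), x])

    params, converged, separation = None, False, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        if converged and np.all(np.isfinite(res.params)) \
                and np.max(np.abs(res.params)) < COEF_DIVERGENCE_LIMIT:
            params = np.asarray(res.params)
    except Exception:  # statsmodels raises several types (PerfectSeparation,
        params = None  # LinAlgError, ...); all route to the ridge fallback

    if params is None:
        separation = True
        logger.info("logistic fit unstable (separation or non-convergence); "
                    "applying ridge fallback")
        params = _ridge_irls(design, y)
        converged = True
        if not np.all(np.isfinite(params)):
            raise DegenerateDataError("ridge fallback failed to converge")
    return LogisticFit(feature_names, params, _deviance(design, y, params),
                       converged, separation)


# ---------------------------------------------------------------------------
# best-subset selection
# ---------------------------------------------------------------------------

def best_subset(features: pd.DataFrame, labels: np.ndarray,
                ) -> list[SubsetModelScore]:
    """Score all 2^k feature subsets (null model included), ranked by BIC.

    AIC = deviance + 2(k+1); BIC = deviance + ln(n)(k+1), counting the
    intercept.  Ties in BIC go to the smaller model.
    """
    names = list(features.columns)
    if len(names) > MAX_SUBSET_FEATURES:
        raise ConfigError(f"best_subset refuses more than "
                          f"{MAX_SUBSET_FEATURES} features "
                          f"(got {len(names)})")
    y = np.asarray(labels, dtype=float)
    n = len(y)
    scores = []
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            if combo:
                fit = fit_logistic(features[list(combo)], y)
            else:
                fit = fit_logistic(np.empty((n, 0)), y, feature_names=())
            npar = len(combo) + 1
            scores.append(SubsetModelScore(
                combo, fit.deviance,
                aic=fit.deviance + 2.0 * npar,
                bic=fit.deviance + np.log(n) * npar,
                params=fit.params))
    scores.sort(key=lambda s: (s.bic, s.k))
    return scores


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def concordance_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the concordance probability over all positive/negative pairs,
    with half credit for tied scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError("AUC needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (pos.size * neg.size))


def loo_cv(features: pd.DataFrame, labels: np.ndarray,
           subset: tuple[str, ...] | list[str] | None = None,
           p0: float = 0.5, nested_selection: bool = False) -> CVResult:
    """Leave-one-subject-out cross-validated classification.

    One fit per participant, excluding them; the held-out probability of the
    smoker class is thresholded at 0.5.  Metrics are computed on the pooled
    held-out predictions; the accuracy is tested against chance level ``p0``
    with an exact one-sided binomial test and an exact 95% Clopper-Pearson
    interval.  With ``nested_selection=True`` the BIC-best subset is
    re-selected inside every training fold.
    """
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if subset is None and not nested_selection:
        subset = tuple(best_subset(features, y)[0].features)
    ids = [str(v) for v in features.index]
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise DegenerateDataError("a training fold lost one class")
        cols = (tuple(best_subset(features.loc[mask], y_train)[0].features)
                if nested_selection else tuple(subset))
        if cols:
            fit = fit_logistic(features.loc[mask, list(cols)], y_train)
            probs[i] = fit.predict_proba(
                features.loc[~mask, list(cols)].to_numpy(dtype=float))[0]
        else:
            fit = fit_logistic(np.empty((mask.sum(), 0)), y_train,
                               feature_names=())
            probs[i] = expit(fit.params[0])
    preds = (probs >= 0.5).astype(float)
    tp = float(np.sum((preds == 1) & (y == 1)))
    tn = float(np.sum((preds == 0) & (y == 0)))
    fp = float(np.sum((preds == 1) & (y == 0)))
    fn = float(np.sum((preds == 0) & (y == 1)))
    accuracy = (tp + tn) / n
    p, ci = binomial_inference(int(tp + tn), n, p0=p0)
    return CVResult(
        participant_ids=ids,
        probabilities=probs,
        predictions=preds,
        labels=y,
        accuracy=accuracy,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        auc=concordance_auc(probs, y),
        binomial_p=p,
        ci95=ci,
    )


def binomial_inference(successes: int, n: int, p0: float = 0.5,
                       ) -> tuple[float, tuple[float, float]]:
    """Exact one-sided binomial p (upper tail, P(X >= successes | p0)) and
    the exact two-sided 95% Clopper-Pearson interval for successes / n."""
    if not 0.0 < p0 < 1.0:
        raise ConfigError("p0 must lie strictly inside (0, 1)")
    if not 0 <= successes <= n:
        raise ConfigError("successes must lie in [0, n]")
    test = binomtest(successes, n, p0, alternative="greater")
    ci = binomtest(successes, n).proportion_ci(confidence_level=0.95,
                                               method="exact")
    return float(test.pvalue), (float(ci.low), float(ci.high))
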