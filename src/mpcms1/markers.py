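"""Module-guided marker selection with an L1-regularized logistic model.

The feature module whose eigenfeature is most correlated (in absolute
value) with the outcome condition supplies the candidate features.  An L1
(Lasso) logistic path is fitted over a log-spaced penalty grid; the penalty
is chosen by leave-one-out cross-validated binomial deviance using the
one-standard-error rule (largest lambda within 1 SE of the minimum — the
most regularized near-optimal model).  A model is kept only when the Lasso
selects more than one feature, and discrimination is reported as the
leave-one-out AUC computed exclusively from held-out probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .eigenfeatures import GroupCorrelationProfile

logger = logging.getLogger(__name__)


@dataclass
class MarkerModel:
    outcome: str
    module_id: int
    feature_ids: list[str]
    lambda_path: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_1se: float
    lambda_min: float
    coefficients: np.ndarray  # on the original log2 scale
    intercept: float
    nonzero_features: list[str] = field(default_factory=list)
    loocv_auc: float | None = None
    kept: bool = False
    # standardization constants for prediction
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None


def select_marker_module(R, outcome_condition: str) -> int:
    """Module with maximum |correlation| for the outcome; ties -> smallest id."""
    if not isinstance(R, GroupCorrelationProfile):
        raise TypeError("expected a GroupCorrelationProfile")
    if R.R.size == 0:
        raise ValueError("empty correlation profile")
    if outcome_condition not in R.conditions:
        raise KeyError(f"outcome condition {outcome_condition!r} not in profile")
    col = np.abs(R.R[:, R.conditions.index(outcome_condition)])
    best = int(np.flatnonzero(col == col.max())[0])
    if (col == col.max()).sum() > 1:
        logger.info("marker-module tie broken toward smallest module id %d", best)
    return int(R.module_ids[best])


def l1_logistic_path(
    Xs: np.ndarray,
    y: np.ndarray,
    lams: np.ndarray,
    tol: float = 1e-7,
    max_outer: int = 30,
    max_cd: int = 1000,
    warm: tuple[np.ndarray, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-descent L1-logistic path, warm-started down the penalties.

    Minimizes (1/n) sum log(1 + exp(-y_i eta_i)) + lam * |beta|_1 with an
    unpenalized intercept, via iteratively reweighted least squares with
    cyclic coordinate soft-thresholding (the standard path algorithm for
    penalized GLMs).  Weights are floored at 1e-5 so separation causes a
    bounded-iteration stop rather than divergence.  Starting from
    beta = 0, any lam >= max |X'(y - ybar)| / n keeps beta exactly zero
    by the soft-threshold rule.

    Returns (coefs with shape (len(lams), p), intercepts).
    """
    n, p = Xs.shape
    beta = np.zeros(p) if warm is None else warm[0].copy()
    b0 = (
        float(np.log(y.mean() / (1 - y.mean()))) if warm is None else warm[1]
    )
    coefs = np.zeros((len(lams), p))
    intercepts = np.zeros(len(lams))
    cols = [Xs[:, j] for j in range(p)]
    for li, lam in enumerate(lams):
        for _ in range(max_outer):
            eta = b0 + Xs @ beta
            prob = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(prob * (1.0 - prob), 1e-5, None)
            z = eta + (y - prob) / w
            # weighted lasso on the working response
            r = z - eta  # residual of current fit
            beta_old_outer = beta.copy()
            b0_old_outer = b0
            wx = [w * c for c in cols]
            wxx = np.array([(wc * c).sum() for wc, c in zip(wx, cols)])
            wsum = w.sum()
            for _ in range(max_cd):
                delta = 0.0
                for j in range(p):
                    xj = cols[j]
                    num = (wx[j] @ r + wxx[j] * beta[j]) / n
                    denom = wxx[j] / n
                    if denom <= 0:
                        continue
                    # relative guard so the exact KKT tie at lambda_max
                    # cannot admit a rounding-level coefficient
                    if abs(num) <= lam * (1.0 + 1e-12):
                        new = 0.0
                    else:
                        new = np.sign(num) * (abs(num) - lam) / denom
                    if new != beta[j]:
                        r = r - xj * (new - beta[j])
                        delta = max(delta, abs(new - beta[j]))
                        beta[j] = new
                new_b0 = b0 + (w @ r) / wsum
                if new_b0 != b0:
                    r = r - (new_b0 - b0)
                    delta = max(delta, abs(new_b0 - b0))
                    b0 = new_b0
                if delta < tol:
                    break
            if (
                abs(b0 - b0_old_outer) < 1e-6
                and np.max(np.abs(beta - beta_old_outer), initial=0.0) < 1e-6
            ):
                break
        coefs[li] = beta
        intercepts[li] = b0
    return coefs, intercepts


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """One L1-logistic fit at penalty ``lam`` (glmnet parameterization)."""
    coefs, intercepts = l1_logistic_path(Xs, y, np.array([lam]))
    return coefs[0], float(intercepts[0])


def _deviance(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))


def _predict(Xs: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(Xs @ coef + intercept)))


def lambda_max(Xs: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which all coefficients are zero (KKT bound)."""
    n = len(y)
    return float(np.abs(Xs.T @ (y - y.mean())).max() / n)


def fit_lasso_loocv(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str] | None = None,
    outcome: str = "case",
    module_id: int = 0,
    n_lambda: int = 100,
    seed: int = 0,
) -> MarkerModel:
    """Lasso logistic path with LOOCV-chosen lambda.1se penalty.

    ``X`` is samples x features on the log2 scale, ``y`` binary.  Features
    are standardized internally; reported coefficients are rescaled to the
    original scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(p)]
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("outcome must have exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 samples for LOOCV")
    if p < 2:
        raise ValueError("need at least 2 candidate features")
    y = (y == classes.max()).astype(float)

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale

    lmax = lambda_max(Xs, y)
    lams = np.geomspace(lmax, lmax * 1e-2, n_lambda)

    dev = np.zeros((n, n_lambda))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = Xs[mask], y[mask]
        if len(np.unique(yi)) < 2:
            dev[i] = _deviance(np.full(n_lambda, yi.mean()), y[i])
            continue
        coefs, intercepts = l1_logistic_path(Xi, yi, lams)
        probs_i = 1.0 / (1.0 + np.exp(-(coefs @ Xs[i] + intercepts)))
        dev[i] = _deviance(probs_i, np.full(n_lambda, y[i]))
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n)
    i_min = int(np.argmin(cv_mean))
    bound = cv_mean[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_mean <= bound)[0])  # largest lambda within 1 SE
    lam_1se = float(lams[i_1se])

    coef_path, b0_path = l1_logistic_path(Xs, y, lams[: i_1se + 1])
    coef_s, b0 = coef_path[-1], float(b0_path[-1])
    nonzero = np.flatnonzero(coef_s != 0)
    coef_orig = coef_s / x_scale
    kept = len(nonzero) > 1
    if not kept:
        logger.info(
            "model for %r discarded: %d nonzero coefficient(s)", outcome, len(nonzero)
        )
    return MarkerModel(
        outcome=outcome,
        module_id=module_id,
        feature_ids=list(feature_ids),
        lambda_path=lams,
        cv_deviance=cv_mean,
        cv_deviance_se=cv_se,
        lambda_1se=lam_1se,
        lambda_min=float(lams[i_min]),
        coefficients=coef_orig,
        intercept=b0,
        nonzero_features=[feature_ids[i] for i in nonzero],
        kept=kept,
        x_mean=x_mean,
        x_scale=x_scale,
    )


def loocv_auc(
    model: MarkerModel, X: np.ndarray, y: np.ndarray, force: bool = False
) -> float:
    """Leave-one-out AUC at lambda.1se from held-out probabilities only.

    By contract only kept models (>1 selected feature) are evaluated;
    ``force`` overrides that for calibration studies on null data.
    """
    if not model.kept and not force:
        raise ValueError("AUC is only computed for kept models (>1 selected feature)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    y = (y == classes.max()).astype(float)
    if not np.any(model.coefficients != 0):
        # an intercept-only final model is a constant classifier: its ROC is
        # the diagonal, so discrimination is chance by definition
        logger.warning("final model selected no features; AUC is 0.5")
        model.loocv_auc = 0.5
        return 0.5
    n = len(y)
    scores = np.zeros(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi = X[mask]
        x_mean = Xi.mean(axis=0)
        x_scale = Xi.std(axis=0)
        x_scale[x_scale == 0] = 1.0
        Xis = (Xi - x_mean) / x_scale
        yi = y[mask]
        if len(np.unique(yi)) < 2:
            scores[i] = 0.0
            continue
        coef, b0 = _fit_l1(Xis, yi, model.lambda_1se)
        # rank by the covariate contribution only: each fold's intercept
        # tracks the fold's base rate, which shifts against the left-out
        # label and would rank samples by fold composition, not signal
        scores[i] = float(((X[i] - x_mean) / x_scale) @ coef)
    if np.allclose(scores, scores[0]):
        logger.warning("degenerate held-out predictions (all equal); AUC set to 0.5")
        model.loocv_auc = 0.5
        return 0.5
    auc = float(roc_auc_score(y, scores))
    model.loocv_auc = auc
    return auc
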