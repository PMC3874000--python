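"""Marker operating characteristics: probit transform, ROC curves,
likelihood ratios and two-marker logistic combination.

A candidate immunohistochemical biomarker is evaluated by how well its
per-core score (area fraction, usually probit-transformed) separates malignant
from non-malignant cores.  The empirical ROC enumerates every achievable
operating point under the ``score > criterion`` rule; its AUC is the
concordance probability (Mann-Whitney identity).  The binormal ROC summarizes
the same data by per-class Gaussian moments: a = (m1 - m0)/s1, b = s0/s1,
AUC = Phi(a / sqrt(1 + b^2)).  Pairs of markers are combined with a logistic
regression fitted by iteratively reweighted least squares; its in-sample
percent-correct at probability cutoff 0.5 measures the panel's added value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocResult",
    "LogisticPairModel",
    "probit_transform",
    "empirical_roc",
    "binormal_roc",
    "operating_point",
    "fit_logistic_pair",
]

_EPS = 1e-6  # probit clamp for proportions at 0 or 100 percent


@dataclass
class RocResult:
    """Ordered ROC operating points plus empirical (and optional binormal) AUC.

    ``operating_points`` rows are (criterion, sensitivity, one_minus_specificity,
    lr_plus, lr_minus), ordered from the strictest criterion (0, 0) to the most
    permissive (1, 1); lr_plus is ``inf`` where specificity is 1.
    """

    operating_points: list[tuple[float, float, float, float, float]]
    auc_empirical: float
    auc_binormal: float | None = None
    binormal_a: float | None = None
    binormal_b: float | None = None


@dataclass
class LogisticPairModel:
    beta0: float
    beta1: float
    beta2: float
    pct_correct: float  # percent of cases on the correct side of p = 0.5
    converged: bool
    separation_flag: bool
    n_used: int


def probit_transform(af_percent, mode: str = "proportion") -> np.ndarray:
    """Probit (inverse standard-normal CDF) transform of area-fraction percents.

    ``proportion`` mode treats af/100 as a proportion, clamped to
    [1e-6, 1 - 1e-6] before Phi^-1 so the boundary values stay finite.
    ``rank_INT`` applies the rank-based inverse-normal transform
    Phi^-1((rank - 0.5)/n).  Both are strictly monotone, so ROC analyses are
    unchanged by the transform.
    """
    x = np.asarray(af_percent, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("area-fraction values must lie in [0, 100]")
    if mode == "proportion":
        p = np.clip(x / 100.0, _EPS, 1.0 - _EPS)
        return sps.norm.ppf(p)
    if mode == "rank_INT":
        ranks = sps.rankdata(x)
        return sps.norm.ppf((ranks - 0.5) / x.size)
    raise ValueError(f"unknown probit mode: {mode!r}")


def empirical_roc(scores, labels) -> RocResult:
    """Empirical ROC under the ``score > criterion`` decision rule.

    One operating point per distinct score value (criteria taken at the
    distinct scores, so the endpoints (0,0) and (1,1) are always present);
    sensitivity = P(score > c | positive), 1 - specificity = P(score > c |
    negative).  AUC is the concordance (concordant pairs + half ties) /
    (n0 * n1) — the Mann-Whitney identity U/(n0*n1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    # AUC via midranks: U of the positive sample over n0*n1
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = float(u / (pos.size * neg.size))

    points = []
    crits = np.unique(scores)  # ascending
    # strictest first: criterion at the max score gives (0 or tie-share, ...)
    for c in crits[::-1]:
        sens = float(np.mean(pos > c))
        fpr = float(np.mean(neg > c))
        spec = 1.0 - fpr
        lr_plus = sens / fpr if fpr > 0 else float("inf")
        lr_minus = (1.0 - sens) / spec if spec > 0 else float("inf")
        points.append((float(c), sens, fpr, lr_plus, lr_minus))
    # guarantee closed endpoints
    if points[0][1] != 0.0 or points[0][2] != 0.0:
        points.insert(0, (float(crits[-1]), 0.0, 0.0, float("inf"), 1.0))
    last = points[-1]
    if last[1] != 1.0 or last[2] != 1.0:
        points.append((float(crits[0] - 1.0), 1.0, 1.0, 1.0, float("inf")))
    if auc < 0.5:
        warnings.warn(
            f"AUC {auc:.3f} < 0.5: scores may be oriented low = positive",
            stacklevel=2,
        )
    return RocResult(operating_points=points, auc_empirical=auc)


def binormal_roc(scores, labels) -> tuple[float, float, float]:
    """Binormal ROC parameters from per-class moments.

    Returns (a, b, auc) with a = (m1 - m0)/s1, b = s0/s1 and
    AUC = Phi(a / sqrt(1 + b^2)).  Scores are used as given; pass
    probit-transformed area fractions for the conventional analysis.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two scores per class")
    s1 = pos.std(ddof=1)
    s0 = neg.std(ddof=1)
    if s1 == 0 or s0 == 0:
        raise ValueError("zero within-class variance")
    a = (pos.mean() - neg.mean()) / s1
    b = s0 / s1
    auc = float(sps.norm.cdf(a / np.sqrt(1.0 + b * b)))
    return float(a), float(b), auc


def operating_point(
    scores, labels, criterion: float
) -> tuple[float, float, float, float]:
    """Sensitivity, specificity and likelihood ratios at one criterion.

    sensitivity = P(score > criterion | positive), specificity = P(score <=
    criterion | negative); LR+ = sens/(1 - spec) (``inf`` when specificity is
    1), LR- = (1 - sens)/spec.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    sens = float(np.mean(pos > criterion))
    spec = float(np.mean(neg <= criterion))
    lr_plus = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    lr_minus = (1.0 - sens) / spec if spec > 0 else float("inf")
    return sens, spec, lr_plus, lr_minus


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int, tol: float):
    beta = np.zeros(X.shape[1])
    penalty = np.zeros(X.shape[1])
    penalty[1:] = ridge  # intercept unpenalized
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / w
        xtw = X.T * w
        lhs = xtw @ X + np.diag(penalty)
        # lstsq handles the singular systems that arise under separation or
        # degenerate predictors (minimum-norm solution)
        beta_new = np.linalg.lstsq(lhs, xtw @ z, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return beta, converged


def fit_logistic_pair(x1, x2, labels) -> LogisticPairModel:
    """Two-marker logistic regression logit(p) = b0 + b1*x1 + b2*x2.

    Fitted by iteratively reweighted least squares (max 100 iterations).
    Complete or quasi-complete separation (all fitted probabilities within
    1e-6 of the labels, or diverging coefficients) triggers a refit with a
    small ridge penalty (lambda = 1e-4 on the slopes) and sets
    ``separation_flag``; percent-correct is the share of cases whose fitted
    probability falls on the correct side of 0.5.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("predictors must be finite")
    X = np.column_stack([np.ones_like(x1), x1, x2])

    beta, converged = _irls(X, y, ridge=0.0, max_iter=100, tol=1e-10)
    eta = np.clip(X @ beta, -700, 700)
    p = 1.0 / (1.0 + np.exp(-eta))
    separated = bool(np.all(np.abs(p - y) < 1e-6)) or not np.all(
        np.abs(beta) < 1e6
    )
    if separated:
        beta, converged = _irls(X, y, ridge=1e-4, max_iter=100, tol=1e-10)
        eta = np.clip(X @ beta, -700, 700)
        p = 1.0 / (1.0 + np.exp(-eta))
    if not converged:
        warnings.warn("logistic fit did not converge in 100 iterations", stacklevel=2)

    pct = 100.0 * float(np.mean((p > 0.5) == (y == 1.0)))
    return LogisticPairModel(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        pct_correct=pct,
        converged=bool(converged),
        separation_flag=separated,
        n_used=int(y.size),
    )
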