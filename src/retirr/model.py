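"""Feature selection and the exhaustive quadratic-discriminant search.

Candidate features come from L1-regularized regression of the numeric class
label (PVD -> 1, RD -> 2) on the standardized 126-feature matrix: LASSO, or
elastic net with mixing 0.5, with the penalty chosen at minimum 10-fold
cross-validated MSE.  Every nonempty subset of the candidates (up to a size
cap) is then fitted with quadratic discriminant analysis on the training
set and ranked by training sensitivity among models whose training
specificity exceeds a threshold (0.90 by default) — the asymmetry reflects
that labelling a PVD eye as detachment is the costlier error.

The QDA here fits one Gaussian per class with its own covariance (plus a
small ridge for conditioning) and empirical priors; with class-specific
variances the acceptance region for the tighter class can be a central
band, i.e. a two-sided (U-shaped) decision rule in one dimension.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

RIDGE_FRACTION = 1e-6
LABELS = (1, 2)  # 1 = PVD, 2 = retinal detachment


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    method: str
    candidate_indices: np.ndarray  # 0-based, ordered by |coefficient| descending
    coefficients: np.ndarray      # matching candidate_indices
    cv_mse: float
    penalty: float


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "enet",
    alpha: float = 0.5,
    n_cv_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """LASSO / elastic-net candidate screening on standardized inputs.

    ``alpha`` is the L1/L2 mixing (1 = LASSO); the regression target is the
    numeric label.  Returns the nonzero-coefficient indices ordered by
    coefficient magnitude, with the cross-validated MSE at the chosen
    penalty.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes for selection")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    l1_ratio = 1.0 if method == "lasso" else alpha
    cv = KFold(n_splits=n_cv_folds, shuffle=True, random_state=seed)
    est = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, alphas=100, max_iter=5000)
    est.fit(Xs, y.astype(float))
    coef = est.coef_
    nz = np.flatnonzero(coef)
    order = nz[np.argsort(-np.abs(coef[nz]))]
    if order.size == 0:
        logger.warning("select_features: all coefficients zero at chosen penalty")
    cv_mse = float(est.mse_path_.mean(axis=-1).min())
    return SelectionResult(
        method=method,
        candidate_indices=order,
        coefficients=coef[order],
        cv_mse=cv_mse,
        penalty=float(est.alpha_),
    )


# ---------------------------------------------------------------------------
# QDA
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """Fitted QDA over a feature subset, with its training standardization."""

    feature_indices: np.ndarray            # 0-based columns of the 126-vector
    means: dict[int, np.ndarray]           # per class label, standardized space
    covariances: dict[int, np.ndarray]
    priors: dict[int, float]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    metadata: dict = field(default_factory=dict)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Xsub = np.asarray(X, dtype=float)[:, self.feature_indices]
        return (Xsub - self.scaler_mean) / self.scaler_sd

    def _log_joint(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(X)
        out = np.empty((Z.shape[0], len(LABELS)))
        for j, lab in enumerate(LABELS):
            mu, cov = self.means[lab], self.covariances[lab]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError("class covariance not positive definite")
            diff = Z - mu
            maha = np.einsum("ij,ij->i", diff, np.linalg.solve(cov, diff.T).T)
            out[:, j] = np.log(self.priors[lab]) - 0.5 * (logdet + maha)
        return out

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """P(label 2 | x): the classifier output used for ROC analysis."""
        lj = self._log_joint(X)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p[:, 1] / p.sum(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        lj = self._log_joint(X)
        return np.array(LABELS)[np.argmax(lj, axis=1)]

    def to_json(self) -> str:
        payload = {
            "feature_indices": self.feature_indices.tolist(),
            "means": {str(k): v.tolist() for k, v in self.means.items()},
            "covariances": {str(k): v.tolist() for k, v in self.covariances.items()},
            "priors": {str(k): v for k, v in self.priors.items()},
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            feature_indices=np.array(d["feature_indices"], dtype=int),
            means={int(k): np.array(v) for k, v in d["means"].items()},
            covariances={int(k): np.array(v) for k, v in d["covariances"].items()},
            priors={int(k): float(v) for k, v in d["priors"].items()},
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_sd=np.array(d["scaler_sd"]),
            metadata=d.get("metadata", {}),
        )


def train_qda(X: np.ndarray, y: np.ndarray, feature_indices) -> ClassifierModel:
    """Fit class-specific Gaussians on the selected (standardized) columns.

    A ridge of RIDGE_FRACTION * trace/d is added to each class covariance;
    classes must have more samples than selected features.
    """
    idx = np.asarray(feature_indices, dtype=int)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = idx.size
    Xsub = X[:, idx]
    mu = Xsub.mean(axis=0)
    sd = Xsub.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (Xsub - mu) / sd
    means, covs, priors = {}, {}, {}
    for lab in LABELS:
        rows = Z[y == lab]
        if rows.shape[0] <= d:
            raise ValueError(
                f"class {lab} has {rows.shape[0]} samples for {d} features; "
                "select fewer features"
            )
        means[lab] = rows.mean(axis=0)
        cov = np.cov(rows, rowvar=False, ddof=1).reshape(d, d)
        cov = cov + (RIDGE_FRACTION * np.trace(cov) / d) * np.eye(d)
        sign, _ = np.linalg.slogdet(cov)
        if sign <= 0:
            raise ValueError("singular class covariance after ridge; select fewer features")
        covs[lab] = cov
        priors[lab] = rows.shape[0] / Z.shape[0]
    return ClassifierModel(
        feature_indices=idx, means=means, covariances=covs, priors=priors,
        scaler_mean=mu, scaler_sd=sd,
    )


def _train_sens_spec(model: ClassifierModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pred = model.predict(X)
    sens = float(np.mean(pred[y == 2] == 2))
    spec = float(np.mean(pred[y == 1] == 1))
    return sens, spec


@dataclass
class RankedModel:
    model: ClassifierModel
    sensitivity: float
    specificity: float
    meets_threshold: bool

    @property
    def feature_indices(self) -> np.ndarray:
        return self.model.feature_indices


def search_qda_combinations(
    X: np.ndarray,
    y: np.ndarray,
    candidates,
    max_size: int = 6,
    spec_threshold: float = 0.90,
    size_preference: int | None = 3,
) -> list[RankedModel]:
    """Fit and rank every nonempty candidate subset up to ``max_size``.

    Ranking: training sensitivity descending among models with training
    specificity > threshold; ties broken by fewer features, then higher
    specificity, then lexicographic indices.  ``size_preference`` expresses
    the preference for parsimonious classifiers ("three or fewer features"
    by default): models at or under that size outrank larger ones.  Set it
    to None to rank purely on performance.  If no model meets the
    specificity threshold, all models are returned ranked by specificity
    (flagged via ``meets_threshold=False``).
    """
    cand = sorted(int(c) for c in np.asarray(candidates, dtype=int))
    if not cand:
        raise ValueError("candidate set is empty")
    results: list[RankedModel] = []
    for size in range(1, min(max_size, len(cand)) + 1):
        for subset in itertools.combinations(cand, size):
            model = train_qda(X, y, np.array(subset))
            sens, spec = _train_sens_spec(model, X, y)
            model.metadata = {
                "train_sensitivity": sens, "train_specificity": spec,
                "n_features": size,
            }
            results.append(RankedModel(model, sens, spec, spec > spec_threshold))

    def small(r: RankedModel) -> int:
        if size_preference is None:
            return 0
        return int(len(r.feature_indices) > size_preference)

    passing = [r for r in results if r.meets_threshold]
    if passing:
        key = lambda r: (
            small(r), -r.sensitivity, len(r.feature_indices), -r.specificity,
            tuple(r.feature_indices),
        )
        return sorted(passing, key=key) + sorted(
            (r for r in results if not r.meets_threshold),
            key=lambda r: (small(r), -r.specificity, -r.sensitivity, tuple(r.feature_indices)),
        )
    logger.warning(
        "search_qda_combinations: no model reached training specificity > %.2f; "
        "returning best-specificity ranking", spec_threshold,
    )
    return sorted(
        results,
        key=lambda r: (small(r), -r.specificity, -r.sensitivity, tuple(r.feature_indices)),
    )


def n_subsets(n_candidates: int, max_size: int) -> int:
    """Exact count of subsets the exhaustive search evaluates."""
    from math import comb
    return sum(comb(n_candidates, k) for k in range(1, min(max_size, n_candidates) + 1))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    feature_indices,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeated stratified k-fold success rate of the QDA on given features.

    Per repeat, folds are re-randomized; the success rate is the overall
    proportion of correctly labelled eyes.  Returns (mean, SD) over repeats.
    """
    y = np.asarray(y)
    min_class = min(np.sum(y == lab) for lab in LABELS)
    if k > min_class:
        raise ValueError(f"k={k} exceeds the smallest class count {min_class}")
    rates = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        correct = 0
        for tr, te in skf.split(X, y):
            model = train_qda(X[tr], y[tr], feature_indices)
            correct += int(np.sum(model.predict(X[te]) == y[te]))
        rates.append(correct / len(y))
    rates = np.array(rates)
    return float(rates.mean()), float(rates.std(ddof=1)) if repeats > 1 else 0.0
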