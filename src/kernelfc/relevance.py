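"""Sparse elastic-net relevance estimation over connectivity features.

The concatenated (band, window, pair) connectivity features are matched
to the binary trial labels (regressed as 0/1 targets) under the elastic
net: squared error + alpha1 ||v||_1 + alpha2 ||v||_2^2.  The penalty pair
is selected on a grid of l2/l1 mixing ratios {0.1, 0.5, 0.9} times ten
log-spaced overall strengths by seeded inner cross-validation.  The
absolute coefficients, min-max normalized, are the relevance weights
used for feature selection, per-pair aggregation and topographies.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

__all__ = [
    "ElasticNetRelevance",
    "fit_relevance",
    "select_features",
    "pair_relevance",
]

# l2/l1 penalty ratios r = alpha2/alpha1 map to sklearn's l1_ratio = 1/(1+2r)
DEFAULT_L2_L1_RATIOS = (0.1, 0.5, 0.9)


def _l1_ratios(l2_l1_ratios) -> list[float]:
    return [1.0 / (1.0 + 2.0 * r) for r in l2_l1_ratios]


def _minmax_unit(values: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; a constant nonzero vector is reported as uniform 1s."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi > lo:
        return (values - lo) / (hi - lo)
    if hi > 0:
        warnings.warn("constant relevance vector: reported as uniform", stacklevel=3)
        return np.ones_like(values)
    return np.zeros_like(values)


class ElasticNetRelevance(TransformerMixin, BaseEstimator):
    """Elastic-net relevance model: fit coefficients, transform selects support.

    Parameters
    ----------
    l2_l1_ratios : grid of alpha2/alpha1 penalty mixing ratios.
    n_alphas : number of log-spaced overall penalty strengths.
    alphas : explicit overall strengths (overrides ``n_alphas`` when given).
    inner_folds : folds of the seeded inner CV selecting the penalty pair.
    random_state : seed for the inner-CV shuffling (full determinism).
    fallback_k : columns kept (by |coefficient|) when the support is empty.

    Fitted attributes
    -----------------
    coef_ : full-length coefficient vector (zeros at dropped columns).
    intercept_ : scalar intercept on the 0/1 target scale.
    alpha1_, alpha2_ : selected l1 and squared-l2 penalty weights.
    mean_, scale_ : training-data standardization statistics.
    support_ : boolean mask of nonzero coefficients.
    normalized_relevance_ : |coef_| min-max scaled to [0, 1].
    """

    def __init__(
        self,
        l2_l1_ratios: tuple[float, ...] = DEFAULT_L2_L1_RATIOS,
        n_alphas: int = 10,
        alphas: tuple[float, ...] | None = None,
        inner_folds: int = 5,
        random_state: int = 0,
        fallback_k: int = 10,
        max_iter: int = 2000,
        tol: float = 1e-4,
    ):
        self.l2_l1_ratios = l2_l1_ratios
        self.n_alphas = n_alphas
        self.alphas = alphas
        self.inner_folds = inner_folds
        self.random_state = random_state
        self.fallback_k = fallback_k
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"expected a 2D feature matrix; got shape {X.shape}")
        n, d = X.shape
        if n < 2 * self.inner_folds:
            raise ValueError(
                f"need at least {2 * self.inner_folds} trials for "
                f"{self.inner_folds}-fold inner CV; got {n}"
            )
        self.n_features_in_ = d
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        keep = scale > 0
        if not keep.any():
            raise ValueError("all feature columns are constant")
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant feature column(s)",
                stacklevel=2,
            )
        self.scale_ = np.where(keep, scale, 1.0)
        self.kept_columns_ = keep
        xs = (X[:, keep] - self.mean_[keep]) / self.scale_[keep]

        coef = np.zeros(d)
        if np.ptp(y) == 0:
            # constant target: the penalized optimum is the bare intercept
            self.intercept_ = float(y[0])
            self.alpha1_ = 0.0
            self.alpha2_ = 0.0
        else:
            cv = KFold(
                n_splits=self.inner_folds, shuffle=True, random_state=self.random_state
            )
            model = ElasticNetCV(
                l1_ratio=_l1_ratios(self.l2_l1_ratios),
                alphas=self.n_alphas if self.alphas is None else list(self.alphas),
                cv=cv,
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=self.random_state,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # benign convergence chatter
                model.fit(xs, y)
            coef[keep] = model.coef_
            self.intercept_ = float(model.intercept_)
            # sklearn objective: 1/(2n)||y-Xw||^2 + a*l1r*||w||_1 + a*(1-l1r)/2*||w||^2
            # rescale to the unit-residual objective used here
            a, l1r = float(model.alpha_), float(model.l1_ratio_)
            self.alpha1_ = 2.0 * a * l1r
            self.alpha2_ = a * (1.0 - l1r)
        self.coef_ = coef
        self.support_ = coef != 0
        self.normalized_relevance_ = _minmax_unit(np.abs(coef))
        return self

    def _ranked_columns(self) -> np.ndarray:
        """Columns ordered by |coef| descending, ties broken by lower index."""
        absv = np.abs(self.coef_)
        return np.lexsort((np.arange(absv.size), -absv))

    def selected_columns(self) -> np.ndarray:
        """Nonzero-support columns; top-``fallback_k`` |coef| columns if empty."""
        if self.support_.any():
            return np.flatnonzero(self.support_)
        warnings.warn(
            f"empty support: falling back to top-{self.fallback_k} columns",
            stacklevel=2,
        )
        k = min(self.fallback_k, self.coef_.size)
        return np.sort(self._ranked_columns()[:k])

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        cols = self.selected_columns()
        return (X[:, cols] - self.mean_[cols]) / self.scale_[cols]

    def predict(self, X) -> np.ndarray:
        """Linear predictor on the 0/1 target scale (thresholdable at 0.5)."""
        X = np.asarray(X, dtype=np.float64)
        xs = (X - self.mean_) / self.scale_
        return xs @ self.coef_ + self.intercept_


def fit_relevance(
    X: np.ndarray,
    y: np.ndarray,
    l2_l1_ratios: tuple[float, ...] = DEFAULT_L2_L1_RATIOS,
    n_alphas: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
) -> ElasticNetRelevance:
    """Functional wrapper over :class:`ElasticNetRelevance`."""
    return ElasticNetRelevance(
        l2_l1_ratios=l2_l1_ratios,
        n_alphas=n_alphas,
        inner_folds=inner_folds,
        random_state=seed,
    ).fit(X, y)


def select_features(
    model: ElasticNetRelevance,
    X: np.ndarray,
    index_map: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduced feature matrix plus per-column metadata.

    Returns ``(X_selected, metadata)`` where metadata holds the retained
    column indices, or their (band, window, pair) rows when ``index_map``
    is given.
    """
    cols = model.selected_columns()
    meta = cols if index_map is None else np.asarray(index_map)[cols]
    return np.asarray(X)[:, cols], meta


def pair_relevance(
    model: ElasticNetRelevance, index_map: np.ndarray, n_pairs: int
) -> np.ndarray:
    """Aggregate |coef| over each pair's (band, window) block, min-max to [0,1]."""
    index_map = np.asarray(index_map)
    raw = np.zeros(n_pairs)
    np.add.at(raw, index_map[:, 2], np.abs(model.coef_))
    return _minmax_unit(raw)
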