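"""Classifier training on selected features and stratified 10-fold CV.

The full decoder is an sklearn-style classifier chaining the stages:
filter-bank + sliding windows -> per-trial connectivity features
(Gaussian-kernel bandwidth fitted on training trials only) -> optional
CSP-on-FC projection per (band, window) split -> elastic-net relevance
selection -> a linear discriminant (the contribution is the features,
not the classifier; a thresholded elastic-net prediction is available
as an alternative).  Accuracy is (TP+TN)/(TP+TN+FP+FN) under seeded
stratified k-fold cross-validation; every fitted statistic (bandwidth,
standardization, penalties, discriminant) is computed inside the
training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .csp import CSPProjector
from .data_model import EpochsSet
from .fc import ConnectivityTransformer, connectivity_matrices, feature_index_map
from .filterbank import FilterBankSpec, FilterBankWindower
from .relevance import DEFAULT_L2_L1_RATIOS, ElasticNetRelevance

__all__ = [
    "SubjectResult",
    "accuracy_from_counts",
    "cross_validate",
    "SingleTrialFCDecoder",
    "decode_cv",
]


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN), exact as a rational before float."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be non-negative; got {counts}")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts are all zero")
    return float(Fraction(tp + tn, total))


@dataclass
class SubjectResult:
    """Per-fold accuracies of one (subject, configuration) evaluation."""

    fold_accuracies: list[float]
    config: dict = field(default_factory=dict)
    fold_sizes: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def as_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "fold_sizes": [int(s) for s in self.fold_sizes],
            "config": self.config,
        }


def _check_cv_inputs(y: np.ndarray, k: int) -> np.ndarray:
    y = np.asarray(y)
    for cls in np.unique(y):
        n_cls = int((y == cls).sum())
        if n_cls < k:
            raise ValueError(
                f"class {cls} has only {n_cls} trials; use k <= {n_cls}"
            )
    return y


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    make_pipeline,
    k: int = 10,
    seed: int = 0,
    config: dict | None = None,
) -> SubjectResult:
    """Stratified seeded k-fold CV of a pipeline factory on trial features.

    ``make_pipeline()`` must return an unfitted estimator with
    fit/predict; all fitting happens inside each training fold.
    """
    X = np.asarray(X)
    y = _check_cv_inputs(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs: list[float] = []
    sizes: list[int] = []
    for train, test in skf.split(np.zeros(len(y)), y):
        est = make_pipeline()
        est.fit(X[train], y[train])
        pred = np.asarray(est.predict(X[test]))
        accs.append(float(np.mean(pred == y[test])))
        sizes.append(len(test))
    return SubjectResult(
        fold_accuracies=accs, config=dict(config or {}), fold_sizes=sizes
    )


class SingleTrialFCDecoder(ClassifierMixin, BaseEstimator):
    """End-to-end decoder: raw epochs (R, C, T) -> class predictions.

    Parameters
    ----------
    fs : sampling rate of the epochs, Hz.
    bank : :class:`FilterBankSpec` or preset name ``"MI"`` / ``"ME"``.
    tau, overlap : sliding-window length (s) and fractional overlap.
    measure : ``"gfc"`` | ``"ccf"`` | ``"plv"``.
    use_csp : project per-(band, window) FC matrices through CSP before
        concatenation instead of vectorizing the upper triangle.
    classifier : ``"lda"`` (shrinkage linear discriminant) or ``"enet"``
        (elastic-net prediction thresholded at 0.5).
    random_state : seeds the inner model-selection CV.
    """

    def __init__(
        self,
        fs: float = 128.0,
        bank: FilterBankSpec | str = "MI",
        tau: float = 1.0,
        overlap: float = 0.75,
        measure: str = "gfc",
        use_csp: bool = False,
        csp_components: int = 3,
        l2_l1_ratios: tuple[float, ...] = DEFAULT_L2_L1_RATIOS,
        n_alphas: int = 10,
        inner_folds: int = 5,
        classifier: str = "lda",
        random_state: int = 0,
    ):
        self.fs = fs
        self.bank = bank
        self.tau = tau
        self.overlap = overlap
        self.measure = measure
        self.use_csp = use_csp
        self.csp_components = csp_components
        self.l2_l1_ratios = l2_l1_ratios
        self.n_alphas = n_alphas
        self.inner_folds = inner_folds
        self.classifier = classifier
        self.random_state = random_state

    # -- feature extraction -------------------------------------------------
    def _segments(self, X: np.ndarray) -> np.ndarray:
        return self.windower_.transform(np.asarray(X, dtype=np.float64))

    def _features(self, seg_values: np.ndarray, fit: bool, y=None) -> np.ndarray:
        if not self.use_csp:
            if fit:
                self.connectivity_.fit(seg_values)
                self.sigma_ = self.connectivity_.sigma_
                self.feature_index_ = self.connectivity_.feature_index_
            return self.connectivity_.transform(seg_values)
        # CSP path: one projector per (band, window) split, features concatenated
        if fit:
            self.connectivity_.fit(seg_values)
            self.sigma_ = self.connectivity_.sigma_
        seg = self.connectivity_._as_segments(seg_values)
        mats = connectivity_matrices(seg, self.measure, self.connectivity_.sigma_)
        n_bands, n_windows = mats.shape[1], mats.shape[2]
        if fit:
            self.csp_models_ = [
                [
                    CSPProjector(n_components=self.csp_components).fit(
                        mats[:, b, w], y
                    )
                    for w in range(n_windows)
                ]
                for b in range(n_bands)
            ]
            kk = self.csp_components * (self.csp_components + 1) // 2
            self.feature_index_ = feature_index_map(n_bands, n_windows, kk)
        blocks = [
            self.csp_models_[b][w].transform(mats[:, b, w])
            for b in range(n_bands)
            for w in range(n_windows)
        ]
        return np.concatenate(blocks, axis=1)

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary decoding requires exactly two classes")
        self.windower_ = FilterBankWindower(
            fs=self.fs, bank=self.bank, tau=self.tau, overlap=self.overlap
        ).fit(np.asarray(X))
        self.connectivity_ = ConnectivityTransformer(
            measure=self.measure, fs=self.fs, tau=self.tau
        )
        seg = self._segments(X)
        feats = self._features(seg, fit=True, y=y)
        self.selector_ = ElasticNetRelevance(
            l2_l1_ratios=self.l2_l1_ratios,
            n_alphas=self.n_alphas,
            inner_folds=self.inner_folds,
            random_state=self.random_state,
        ).fit(feats, (y == self.classes_[1]).astype(float))
        if self.classifier == "lda":
            reduced = self.selector_.transform(feats)
            self.clf_ = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage="auto"
            ).fit(reduced, y)
        elif self.classifier == "enet":
            self.clf_ = None
        else:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        return self

    def decision_function(self, X) -> np.ndarray:
        seg = self._segments(X)
        feats = self._features(seg, fit=False)
        if self.classifier == "enet":
            return self.selector_.predict(feats) - 0.5
        return self.clf_.decision_function(self.selector_.transform(feats))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes_[1], self.classes_[0])


def decode_cv(
    epochs: EpochsSet,
    k: int = 10,
    seed: int = 0,
    **decoder_params,
) -> SubjectResult:
    """Stratified k-fold CV of :class:`SingleTrialFCDecoder` on one subject.

    The kernel bandwidth, standardization, penalty selection and the
    discriminant are all re-fitted inside every training fold.
    """
    y = _check_cv_inputs(epochs.labels, k)
    decoder_params.setdefault("fs", epochs.fs)
    proto = SingleTrialFCDecoder(random_state=seed, **decoder_params)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs: list[float] = []
    sizes: list[int] = []
    for train, test in skf.split(np.zeros(len(y)), y):
        est = clone(proto)
        est.fit(epochs.data[train], y[train])
        pred = est.predict(epochs.data[test])
        accs.append(float(np.mean(pred == y[test])))
        sizes.append(len(test))
    config = {"k": k, "seed": seed, "subject": epochs.subject_id}
    config.update(
        {
            key: (val if isinstance(val, (int, float, str, bool)) else str(val))
            for key, val in proto.get_params().items()
        }
    )
    return SubjectResult(fold_accuracies=accs, config=config, fold_sizes=sizes)
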