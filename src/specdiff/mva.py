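"""PCA and PLS-DA on preprocessed peak-intensity matrices.

Both methods yield per-peak loading vectors interpreted as directions of
chemical change. For a two-class design the *discriminating* component is
the one whose scores maximize the between-class over within-class sum of
squares; for PLS-DA this is in practice the first component, while for
PCA it need not be. All reported loadings are back-transformed to the
original intensity scale and unit-normalized, so PCA and PLS-DA loadings
are directly comparable directions.

Estimators follow the scikit-learn protocol (``fit``, fitted attributes
with trailing underscores, ``get_params``/``set_params``); the
module-level :func:`fit_pca` / :func:`fit_plsda` functions are thin
wrappers returning a plain :class:`MVAModel` record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .loading import LoadingVector, as_coeffs
from .preprocess import ScalingState, back_transform_loading

__all__ = [
    "MVAModel",
    "LoadingVector",
    "ProcessPCA",
    "ProcessPLSDA",
    "fit_pca",
    "fit_plsda",
    "between_within_ratio",
    "select_discriminating_component",
    "align_sign",
    "plsda_permutation_pvalue",
]

#: sentinel between/within ratio for perfect separation (zero within-SS)
PERFECT_SEPARATION = np.inf


def _as_label_array(labels) -> np.ndarray:
    if isinstance(labels, str):
        labels = list(labels)
    return np.asarray(labels)


def between_within_ratio(scores_1d, labels) -> float:
    """Between-class over within-class sum of squares of 1-D scores.

    Between-SS weighs each class mean's squared deviation from the grand
    mean by class size; within-SS sums squared deviations from the class
    means. Perfect separation (zero within-SS, distinct class means)
    returns ``inf`` as a sentinel maximal ratio; identical scores with
    equal class means return 0.
    """
    scores = np.asarray(scores_1d, dtype=float).ravel()
    labels = _as_label_array(labels)
    if scores.size != labels.size:
        raise ValueError("scores and labels lengths differ")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly 2 classes required, got {classes.size}")
    grand = scores.mean()
    between = 0.0
    within = 0.0
    for c in classes:
        cls = scores[labels == c]
        between += cls.size * (cls.mean() - grand) ** 2
        within += float(np.sum((cls - cls.mean()) ** 2))
    if within == 0.0:
        return 0.0 if between == 0.0 else PERFECT_SEPARATION
    return between / within


def _encode_two_class(labels) -> np.ndarray:
    """+1/-1 dummy coding of a two-class label vector (first class = -1)."""
    labels = _as_label_array(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(
            f"two-class response required, got {classes.size} class(es)"
        )
    return np.where(labels == classes[0], -1.0, 1.0)


def _select(scores: np.ndarray, labels) -> int:
    ratios = [between_within_ratio(scores[:, k], labels)
              for k in range(scores.shape[1])]
    return int(np.argmax(ratios))  # argmax takes the lowest index on ties


@dataclass
class MVAModel:
    """A fitted PCA or PLS-DA model on a preprocessed intensity matrix."""

    method: str
    scores: np.ndarray
    raw_loadings: np.ndarray
    loadings: list[LoadingVector]
    selected: int | None = None
    labels: tuple | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def selected_loading(self) -> LoadingVector:
        if self.selected is None:
            raise ValueError("no discriminating component selected")
        return self.loadings[self.selected]


class _BaseMVA(BaseEstimator):
    """Shared back-transformation and component selection."""

    def _finalize(self, scores, raw_loadings, labels, prov):
        scaling = self.scaling
        if scaling is None:
            # no scaling recorded: back-transform degenerates to
            # unit-normalization of the raw loadings
            scaling = ScalingState(np.ones(raw_loadings.shape[1]))
        self.scores_ = scores
        self.raw_loadings_ = raw_loadings
        self.loadings_ = [
            back_transform_loading(
                raw_loadings[k], scaling,
                provenance={**prov, "component": k},
            )
            for k in range(raw_loadings.shape[0])
        ]
        self.selected_ = _select(scores, labels) if labels is not None else None
        self.labels_ = tuple(labels) if labels is not None else None
        self.provenance_ = prov
        return self

    def to_model(self) -> MVAModel:
        check_is_fitted(self, "scores_")
        return MVAModel(
            method=self.method,
            scores=self.scores_,
            raw_loadings=self.raw_loadings_,
            loadings=self.loadings_,
            selected=self.selected_,
            labels=self.labels_,
            provenance=self.provenance_,
        )

    @property
    def selected_loading_(self) -> LoadingVector:
        check_is_fitted(self, "scores_")
        if self.selected_ is None:
            raise ValueError("fit with labels to select a component")
        return self.loadings_[self.selected_]


class ProcessPCA(_BaseMVA):
    """PCA via exact full SVD, with back-transformed unit loadings.

    Parameters
    ----------
    n_components : int or None
        Number of components; defaults to ``min(n_spectra - 1, n_peaks)``.
    scaling : ScalingState or None
        The scaling applied upstream; used to back-transform loadings.
    """

    method = "PCA"

    def __init__(self, n_components: int | None = None,
                 scaling: ScalingState | None = None):
        self.n_components = n_components
        self.scaling = scaling

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA requires at least 2 spectra")
        k = self.n_components or min(X.shape[0] - 1, X.shape[1])
        if k > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                f"n_components={k} exceeds min(n_spectra - 1, n_peaks)"
            )
        pca = PCA(n_components=k, svd_solver="full", whiten=False)
        scores = pca.fit_transform(X)
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self._finalize(
            scores, pca.components_, y,
            {"method": self.method, "solver": "full-svd"},
        )


class ProcessPLSDA(_BaseMVA):
    """Two-class PLS-DA (PLS regression on a +1/-1 dummy response).

    The loading reported per component is the x-rotation (the weight
    direction mapped to x-space), matching how PLS-DA loadings are
    plotted alongside PCA loadings as comparable directions.

    Parameters
    ----------
    n_components : int or None
        Defaults to ``min(n_spectra - 1, n_peaks)``.
    scaling : ScalingState or None
        Upstream scaling for loading back-transformation.
    tol, max_iter : float, int
        NIPALS convergence tolerance (default 1e-6) and iteration cap
        (default 500). Non-convergence is recorded in provenance as a
        warning, not raised.
    """

    method = "PLSDA"

    def __init__(self, n_components: int | None = None,
                 scaling: ScalingState | None = None,
                 tol: float = 1e-6, max_iter: int = 500):
        self.n_components = n_components
        self.scaling = scaling
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("PLS-DA requires class labels")
        response = _encode_two_class(y)
        k = self.n_components or min(X.shape[0] - 1, X.shape[1])
        # identical class means give zero x-y covariance: NIPALS has no
        # defined direction, so report a degenerate model (ratio 0) instead
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ (response - response.mean())
        if np.linalg.norm(cov) <= 1e-12 * max(1.0, np.linalg.norm(Xc)):
            prov = {"method": self.method, "response_coding": "+1/-1",
                    "loading_kind": "x-rotation", "degenerate": True,
                    "converged": True, "warnings":
                    ["zero covariance between intensities and response"]}
            basis = np.zeros((k, X.shape[1]))
            basis[np.arange(k), np.arange(k)] = 1.0
            return self._finalize(np.zeros((X.shape[0], k)), basis, y, prov)
        pls = PLSRegression(n_components=k, scale=False,
                            tol=self.tol, max_iter=self.max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            pls.fit(X, response)
        n_iter = list(np.atleast_1d(getattr(pls, "n_iter_", [])))
        converged = all(n < self.max_iter for n in n_iter) if n_iter else True
        prov = {
            "method": self.method,
            "response_coding": "+1/-1",
            "loading_kind": "x-rotation",
            "tol": self.tol,
            "max_iter": self.max_iter,
            "converged": converged,
            "warnings": [str(w.message) for w in caught],
        }
        return self._finalize(pls.x_scores_, pls.x_rotations_.T, y, prov)


def fit_pca(m, st: ScalingState | None = None, n_components: int | None = None,
            labels=None) -> MVAModel:
    """Fit PCA on a centered matrix; loadings back-transformed via ``st``."""
    est = ProcessPCA(n_components=n_components, scaling=st).fit(m, labels)
    return est.to_model()


def fit_plsda(m, labels, st: ScalingState | None = None,
              n_components: int | None = None, tol: float = 1e-6,
              max_iter: int = 500) -> MVAModel:
    """Fit two-class PLS-DA on a centered matrix with categorical labels."""
    est = ProcessPLSDA(n_components=n_components, scaling=st,
                       tol=tol, max_iter=max_iter).fit(m, labels)
    return est.to_model()


def select_discriminating_component(model: MVAModel, labels) -> int:
    """Pick (and record) the component maximizing the between-within ratio."""
    idx = _select(model.scores, labels)
    model.selected = idx
    return idx


def align_sign(v: LoadingVector, ref) -> LoadingVector:
    """Return ``v`` or ``-v``, whichever has nonnegative cosine with ``ref``.

    Loading signs are arbitrary (an SVD convention), so vectors are
    flipped to the half-space of the reference before similarities are
    averaged. A vector exactly orthogonal to the reference is returned
    unchanged.
    """
    c = as_coeffs(v)
    r = as_coeffs(ref)
    if float(c @ r) < 0:
        return -v if isinstance(v, LoadingVector) else -np.asarray(v)
    return v


def plsda_permutation_pvalue(m, labels, st: ScalingState | None = None,
                             n_permutations: int = 100, rng=None,
                             n_components: int | None = None) -> float:
    """Permutation p-value for PLS-DA class separation.

    Refits PLS-DA under ``n_permutations`` random label shuffles and
    compares the observed between-within ratio of the selected component
    against the null distribution, using the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)

    def _ratio(lab):
        model = fit_plsda(m, lab, st, n_components=n_components)
        return between_within_ratio(model.scores[:, model.selected], lab)

    observed = _ratio(labels)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _ratio(perm) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)
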