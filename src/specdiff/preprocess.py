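"""Preprocessing for count-valued peak tables: saturated-peak removal,
Poisson scaling, mean centering, and loading back-transformation.

Poisson scaling divides every peak column by the square root of its
across-spectra mean intensity. For counting noise (variance equal to the
mean) this approximately equalizes the noise variance of all peaks, so
that high-intensity peaks do not dominate a variance-based decomposition
merely through their shot noise. Loadings fitted in the scaled space are
*back-transformed* (divided by the same per-peak factors, then
renormalized) so they can be interpreted against the original spectra.

The pipeline order is fixed: remove saturated peaks, then scale, then
mean-center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .loading import LoadingVector
from .peaktable import PeakList, SpectrumSet

__all__ = [
    "ScalingState",
    "PoissonScaler",
    "remove_peaks",
    "poisson_scale",
    "mean_center",
    "back_transform_loading",
    "preprocess",
]

#: identifier of the implemented scaling variant, recorded for auditability
SCALING_VARIANT = "column-sqrt-mean"


@dataclass
class ScalingState:
    """Per-peak factors recorded during scaling/centering.

    Attributes
    ----------
    peak_scale : ndarray
        Strictly positive divide-by factor per retained peak
        (sqrt of the column mean intensity).
    peak_mean : ndarray or None
        Mean of each *scaled* column, filled in by :func:`mean_center`.
    removed_peaks : tuple of int
        peak_ids dropped before scaling.
    peaks : PeakList or None
        The retained peak list the factors are aligned to.
    """

    peak_scale: np.ndarray
    peak_mean: np.ndarray | None = None
    removed_peaks: tuple = ()
    peaks: PeakList | None = None
    meta: dict[str, Any] = field(default_factory=lambda: {"variant": SCALING_VARIANT})

    def __post_init__(self) -> None:
        s = np.asarray(self.peak_scale, dtype=float).ravel()
        if s.size == 0 or s.min() <= 0:
            raise ValueError("peak_scale must be strictly positive and nonempty")
        self.peak_scale = s
        if self.peak_mean is not None:
            m = np.asarray(self.peak_mean, dtype=float).ravel()
            if m.size != s.size:
                raise ValueError("peak_mean and peak_scale lengths differ")
            self.peak_mean = m


class PoissonScaler(BaseEstimator, TransformerMixin):
    """Poisson scaling plus mean centering as a scikit-learn transformer.

    ``transform`` maps a counts matrix X to ``X / scale_ - mean_`` where
    ``scale_[j] = sqrt(mean(X_fit[:, j]))`` and ``mean_`` is the column
    mean of the scaled fit data.

    Parameters
    ----------
    row_scale : bool, default False
        Additionally divide each spectrum (row) by the square root of its
        total counts before column scaling. Off by default: total-count
        normalization has little effect on this kind of data and is left
        as an explicit opt-in.
    """

    def __init__(self, row_scale: bool = False):
        self.row_scale = row_scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (spectra x peaks)")
        if X.size and X.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if self.row_scale:
            totals = X.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise ValueError("row_scale requires every spectrum to have counts")
            X = X / np.sqrt(totals)
        col_means = X.mean(axis=0)
        if np.any(col_means <= 0):
            j = int(np.argmax(col_means <= 0))
            raise ValueError(
                f"peak column {j} has zero mean intensity; remove the peak "
                "or add a pseudocount before scaling (no silent fix is applied)"
            )
        self.scale_ = np.sqrt(col_means)
        self.mean_ = (X / self.scale_).mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = np.asarray(X, dtype=float)
        if self.row_scale:
            X = X / np.sqrt(X.sum(axis=1, keepdims=True))
        return X / self.scale_ - self.mean_

    def inverse_transform(self, X):
        check_is_fitted(self, "scale_")
        return (np.asarray(X, dtype=float) + self.mean_) * self.scale_

    def state(self, peaks: PeakList | None = None,
              removed_peaks: tuple = ()) -> ScalingState:
        """Export the fitted factors as a :class:`ScalingState`."""
        check_is_fitted(self, "scale_")
        return ScalingState(
            peak_scale=self.scale_.copy(),
            peak_mean=self.mean_.copy(),
            removed_peaks=tuple(removed_peaks),
            peaks=peaks,
            meta={"variant": SCALING_VARIANT, "row_scale": self.row_scale},
        )


def remove_peaks(s: SpectrumSet, ids: Iterable[int]) -> SpectrumSet:
    """Drop the named peak columns (e.g. saturated peaks) from a SpectrumSet.

    The removed peak_ids are recorded in the returned set's ``meta`` so a
    later :class:`ScalingState` can carry them.
    """
    ids = tuple(int(i) for i in ids)
    if not ids:
        return s
    drop_idx = s.peaks.index_of(ids)  # raises on unknown id
    keep = np.setdiff1d(np.arange(s.n_peaks), drop_idx)
    if keep.size == 0:
        raise ValueError("cannot remove every peak: no features would remain")
    meta = dict(s.meta)
    meta["removed_peaks"] = tuple(meta.get("removed_peaks", ())) + ids
    return SpectrumSet(
        peaks=s.peaks.take(keep),
        intensities=s.intensities[:, keep],
        labels=s.labels,
        spectrum_names=s.spectrum_names,
        meta=meta,
    )


def poisson_scale(s: SpectrumSet, row_scale: bool = False):
    """Poisson-scale a SpectrumSet; returns ``(scaled_matrix, ScalingState)``.

    Each column is divided by the square root of its across-spectra mean
    intensity. A zero-mean column is a hard error (no silent drop), since
    dropping features here would desynchronize loadings from the peak list.
    The returned state's ``peak_mean`` is filled by :func:`mean_center`.
    """
    scaler = PoissonScaler(row_scale=row_scale).fit(s.intensities)
    X = np.asarray(s.intensities, dtype=float)
    if row_scale:
        X = X / np.sqrt(X.sum(axis=1, keepdims=True))
    scaled = X / scaler.scale_
    state = ScalingState(
        peak_scale=scaler.scale_,
        peak_mean=None,
        removed_peaks=tuple(s.meta.get("removed_peaks", ())),
        peaks=s.peaks,
        meta={"variant": SCALING_VARIANT, "row_scale": row_scale},
    )
    return scaled, state


def mean_center(m: np.ndarray, state: ScalingState) -> np.ndarray:
    """Subtract each column's mean; the means are stored in the state."""
    m = np.asarray(m, dtype=float)
    if m.shape[1] != state.peak_scale.size:
        raise ValueError("matrix column count does not match ScalingState")
    means = m.mean(axis=0)
    state.peak_mean = means
    return m - means


def back_transform_loading(raw, state: ScalingState,
                           provenance: dict | None = None) -> LoadingVector:
    """Map a scaled-space loading back to the original intensity scale.

    The data columns were divided by ``peak_scale``; inverting that
    variable scaling means multiplying coefficient *i* by
    ``peak_scale[i]``, after which the vector is renormalized to unit
    length. The result is a direction in raw count space, directly
    comparable with per-peak intensity changes and raw spectra.
    """
    raw = np.asarray(raw, dtype=float).ravel()
    if raw.size != state.peak_scale.size:
        raise ValueError(
            f"loading length {raw.size} does not match retained peak "
            f"count {state.peak_scale.size}"
        )
    prov = dict(provenance or {})
    prov.setdefault("scaling_variant", state.meta.get("variant", SCALING_VARIANT))
    return LoadingVector(raw * state.peak_scale, peaks=state.peaks, provenance=prov)


def preprocess(s: SpectrumSet, remove_ids: Iterable[int] = (),
               row_scale: bool = False):
    """Full chain remove -> Poisson scale -> mean center.

    Returns ``(centered_matrix, ScalingState)``.
    """
    s = remove_peaks(s, remove_ids)
    scaled, state = poisson_scale(s, row_scale=row_scale)
    centered = mean_center(scaled, state)
    return centered, state
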