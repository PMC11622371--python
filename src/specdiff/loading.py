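"""Unit-norm loading vectors aligned to a peak list.

A loading vector holds per-peak coefficients describing a direction of
spectral change in the original intensity space (after back-transformation
of any variable scaling). It is the exchange object between the fitting,
decomposition and ranking stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .peaktable import PeakList

_UNIT_NORM_TOL = 1e-12


@dataclass
class LoadingVector:
    """Per-peak coefficients with unit Euclidean norm.

    Parameters
    ----------
    coeffs : ndarray of shape (n_peaks,)
        Coefficients; normalized to unit length on construction.
    peaks : PeakList, optional
        The peak list the coefficients are aligned to.
    provenance : dict
        Free-form record of how the vector was obtained (method, dataset
        id, process time, sign convention, ...).
    """

    coeffs: np.ndarray
    peaks: "PeakList | None" = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float).ravel()
        norm = float(np.linalg.norm(c))
        if norm == 0.0:
            raise ValueError("loading vector must be nonzero")
        if abs(norm - 1.0) > _UNIT_NORM_TOL:
            c = c / norm
        self.coeffs = c
        if self.peaks is not None and len(self.peaks) != c.size:
            raise ValueError(
                f"coefficient count {c.size} does not match "
                f"peak list length {len(self.peaks)}"
            )

    def __len__(self) -> int:
        return self.coeffs.size

    def __neg__(self) -> "LoadingVector":
        return LoadingVector(-self.coeffs, self.peaks, dict(self.provenance))

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        arr = self.coeffs
        if dtype is not None:
            arr = arr.astype(dtype)
        return np.array(arr) if copy else arr


def as_coeffs(v: "LoadingVector | np.ndarray") -> np.ndarray:
    """Return the coefficient array of a LoadingVector or array-like."""
    if isinstance(v, LoadingVector):
        return v.coeffs
    return np.asarray(v, dtype=float).ravel()
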