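"""Comparing and decomposing loading vectors.

Two similar processes each yield a loading vector (a direction of
chemical change in peak space). Projecting the long-process loading onto
the short-process loading by Gram-Schmidt splits it into a *parallel*
component (change the processes share) and an *orthogonal* component
(change that maximally differentiates them). Cosine similarity and its
angle quantify how close two directions are; ranking the orthogonal
component's coefficients points at the peaks behind the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .loading import LoadingVector, as_coeffs
from .peaktable import PeakList

__all__ = [
    "Decomposition",
    "RankedPeaks",
    "cosine_similarity",
    "angle_deg",
    "gram_schmidt",
    "planarity_residual",
    "rank_peaks",
    "plane_coordinates",
]

#: similarity above 1 - this is treated as parallel input degeneracy
_DEGENERACY_TOL = 1e-12
#: allowed arccos-argument overshoot from floating-point rounding
_CLIP_TOL = 1e-12


def cosine_similarity(v1, v2) -> float:
    """Cosine similarity ``v1 . v2 / (||v1|| ||v2||)`` in [-1, 1]."""
    a = as_coeffs(v1)
    b = as_coeffs(v2)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    aa = float(a @ a)
    bb = float(b @ b)
    if aa == 0.0 or bb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    # single-sqrt denominator: exact +/-1 for (anti)parallel inputs
    return float(a @ b) / float(np.sqrt(aa * bb))


def angle_deg(similarity: float) -> float:
    """Transform a (mean) cosine similarity into an angle in degrees."""
    s = float(similarity)
    if abs(s) > 1.0 + _CLIP_TOL:
        raise ValueError(f"|similarity| = {abs(s)} exceeds 1")
    return float(np.degrees(np.arccos(np.clip(s, -1.0, 1.0))))


@dataclass
class Decomposition:
    """Gram-Schmidt split of ``v1`` relative to ``v2``.

    ``parallel + orthogonal`` reconstructs ``v1`` exactly;
    ``orthogonal`` is perpendicular to ``v2``. ``degenerate`` flags
    (anti)parallel inputs, for which the orthogonal part is the exact
    zero vector.
    """

    parallel: np.ndarray
    orthogonal: np.ndarray
    similarity: float
    angle_deg: float
    degenerate: bool = False
    peaks: PeakList | None = None
    inputs: dict[str, Any] = field(default_factory=dict)


def gram_schmidt(v1, v2) -> Decomposition:
    """Decompose ``v1`` into components parallel and orthogonal to ``v2``.

    parallel = (v1.v2 / v2.v2) v2 ; orthogonal = v1 - parallel.

    For loading vectors the convention is to project the long-time
    loading (``v1``) onto the short-time loading (``v2``): the parallel
    part is what the long process shares with the short one, the
    orthogonal part is what distinguishes it.
    """
    a = as_coeffs(v1)
    b = as_coeffs(v2)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if np.linalg.norm(b) == 0.0:
        raise ValueError("cannot project onto a zero vector")
    sim = cosine_similarity(a, b)
    peaks = None
    for v in (v1, v2):
        if isinstance(v, LoadingVector) and v.peaks is not None:
            peaks = v.peaks
            break
    inputs = {
        "v1": getattr(v1, "provenance", None),
        "v2": getattr(v2, "provenance", None),
    }
    if abs(sim) > 1.0 - _DEGENERACY_TOL:
        return Decomposition(
            parallel=a.copy(), orthogonal=np.zeros_like(a),
            similarity=sim, angle_deg=angle_deg(sim),
            degenerate=True, peaks=peaks, inputs=inputs,
        )
    parallel = (a @ b) / (b @ b) * b
    return Decomposition(
        parallel=parallel, orthogonal=a - parallel,
        similarity=sim, angle_deg=angle_deg(sim),
        degenerate=False, peaks=peaks, inputs=inputs,
    )


def planarity_residual(ref, v_short, v_long) -> float:
    """Coplanarity diagnostic for three loading vectors, in degrees.

    Returns ``|theta(ref -> v_long) - theta(ref -> v_short)
    - theta(v_short -> v_long)|``. Near zero when the three vectors lie
    in one plane with ``v_short`` between ``ref`` and ``v_long`` —
    the geometry expected when the short-time loading interpolates
    between the reference mechanism direction and the long-time loading.
    Signs are assumed pre-aligned to ``ref``.
    """
    t_long = angle_deg(cosine_similarity(ref, v_long))
    t_short = angle_deg(cosine_similarity(ref, v_short))
    t_between = angle_deg(cosine_similarity(v_short, v_long))
    return abs(t_long - t_short - t_between)


@dataclass
class RankedPeaks:
    """The ``k`` most positive and most negative coefficients with peaks.

    ``top_positive`` is strictly descending by coefficient,
    ``top_negative`` strictly ascending (most negative first); the lists
    are disjoint. Ties are broken by ascending m/z, and tied peaks are
    assigned to the positive list first.
    """

    top_positive: list
    top_negative: list
    k: int
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [(*t, "+") for t in self.top_positive]
        rows += [(*t, "-") for t in self.top_negative]
        return pd.DataFrame(rows, columns=["peak_id", "mz", "coefficient", "sign"])


def rank_peaks(v, peaks: PeakList, k: int = 5, source: str = "") -> RankedPeaks:
    """Peaks with the ``k`` largest positive and negative coefficients."""
    c = as_coeffs(v)
    if c.size != len(peaks):
        raise ValueError("coefficient count does not match peak list")
    if k > c.size:
        raise ValueError(f"k={k} exceeds peak count {c.size}")
    mz = peaks.center_mz
    # lexsort: primary key last; ties on coefficient fall back to ascending m/z
    pos_order = np.lexsort((mz, -c))
    pos_idx = pos_order[:k]
    taken = set(pos_idx.tolist())
    neg_order = [i for i in np.lexsort((mz, c)) if i not in taken]
    neg_idx = np.array(neg_order[:k], dtype=int)

    def _entries(idx):
        return [(int(peaks.peak_id[i]), float(mz[i]), float(c[i])) for i in idx]

    return RankedPeaks(_entries(pos_idx), _entries(neg_idx), k=k, source=source)


def plane_coordinates(ref, others: Sequence) -> np.ndarray:
    """2-D coordinates of loading vectors relative to a reference.

    The reference maps to (1, 0); every other vector maps to
    (cos theta, sin theta) with theta its angle to the reference. Only
    angles *to the reference* are faithful in this representation: two
    non-reference vectors need not lie in the same plane, so the angle
    between their 2-D images understates nothing about the reference but
    says little about each other.
    """
    coords = np.empty((len(others), 2))
    for i, v in enumerate(others):
        theta = np.radians(angle_deg(cosine_similarity(ref, v)))
        coords[i] = (np.cos(theta), np.sin(theta))
    return coords
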