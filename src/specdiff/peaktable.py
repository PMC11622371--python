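"""Peak-table containers, delimited I/O, and ppm-tolerance peak-list merging.

A *peak table* is the standard exchange format for integrated mass spectra:
one row per peak (center m/z plus one summed-count intensity per spectrum),
optionally carrying a class label per spectrum. Peak lists from separate
measurements are unified by merging peaks that fall within a relative
"catch mass radius" (in ppm) of each other, so that every measurement
shares the same feature set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "SpectrumSet",
    "PeakTableFormatError",
    "read_peak_table",
    "write_peak_table",
    "merge_peak_lists",
]

#: m/z separation below which two peaks in one table are considered duplicates
_DUPLICATE_MZ_TOL = 1e-9

_MZ_COLUMN_NAMES = {"mz", "m/z", "center_mz", "mass"}


class PeakTableFormatError(ValueError):
    """Raised when a delimited peak table cannot be parsed."""


@dataclass(frozen=True)
class PeakList:
    """An ordered list of mass-spectral peaks.

    Attributes
    ----------
    center_mz : ndarray of float
        Peak center masses in Da; strictly positive, sorted ascending.
    peak_id : ndarray of int
        Stable unique integer identifiers, aligned with ``center_mz``.
    label : tuple of str or None
        Optional text annotation per peak (e.g. a fragment assignment).
    """

    center_mz: np.ndarray
    peak_id: np.ndarray | None = None
    label: tuple | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.center_mz, dtype=float).ravel()
        if mz.size and mz.min() <= 0:
            raise ValueError("center_mz must be strictly positive")
        if np.any(np.diff(mz) < 0):
            raise ValueError("center_mz must be sorted ascending")
        object.__setattr__(self, "center_mz", mz)
        if self.peak_id is None:
            object.__setattr__(self, "peak_id", np.arange(mz.size))
        else:
            ids = np.asarray(self.peak_id, dtype=int).ravel()
            if ids.size != mz.size:
                raise ValueError("peak_id and center_mz lengths differ")
            if np.unique(ids).size != ids.size:
                raise ValueError("peak_ids must be unique")
            object.__setattr__(self, "peak_id", ids)
        if self.label is not None:
            lab = tuple(self.label)
            if len(lab) != mz.size:
                raise ValueError("label and center_mz lengths differ")
            object.__setattr__(self, "label", lab)

    def __len__(self) -> int:
        return self.center_mz.size

    def take(self, indices: np.ndarray) -> "PeakList":
        """Subset/reorder; indices must yield an ascending m/z sequence."""
        indices = np.asarray(indices)
        label = None
        if self.label is not None:
            label = tuple(self.label[i] for i in indices)
        return PeakList(self.center_mz[indices], self.peak_id[indices], label)

    def index_of(self, ids: Iterable[int]) -> np.ndarray:
        """Positional indices of the given peak_ids (error on unknown id)."""
        lookup = {pid: i for i, pid in enumerate(self.peak_id)}
        try:
            return np.array([lookup[int(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown peak_id {exc.args[0]}") from None


@dataclass
class SpectrumSet:
    """A peak list plus a spectra-by-peaks matrix of summed counts.

    ``intensities`` has one row per spectrum and one column per peak;
    entries are nonnegative counts. ``labels`` assigns one class per
    spectrum (row) when present. ``meta`` carries free-form provenance.
    """

    peaks: PeakList
    intensities: np.ndarray
    labels: tuple | None = None
    spectrum_names: tuple | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.intensities, dtype=float)
        if m.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if m.shape[1] != len(self.peaks):
            raise ValueError(
                f"intensity column count {m.shape[1]} does not match "
                f"peak count {len(self.peaks)}"
            )
        if m.size and m.min() < 0:
            r, c = np.argwhere(m < 0)[0]
            raise ValueError(f"negative intensity at spectrum {r}, peak column {c}")
        self.intensities = m
        if self.labels is not None:
            lab = tuple(str(x) for x in self.labels)
            if len(lab) != m.shape[0]:
                raise ValueError("labels must cover every spectrum row")
            self.labels = lab
        if self.spectrum_names is not None:
            names = tuple(str(x) for x in self.spectrum_names)
            if len(names) != m.shape[0]:
                raise ValueError("spectrum_names must cover every spectrum row")
            self.spectrum_names = names

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[1]


def _check_duplicates(mz: np.ndarray) -> None:
    if mz.size > 1 and np.any(np.diff(mz) < _DUPLICATE_MZ_TOL):
        i = int(np.argmax(np.diff(mz) < _DUPLICATE_MZ_TOL))
        raise ValueError(
            f"duplicate center m/z near {mz[i]:.9f} (rows {i} and {i + 1})"
        )


def read_peak_table(path, dialect: str = "\t") -> SpectrumSet:
    """Read a delimited peak table into a :class:`SpectrumSet`.

    The format is one header row naming the m/z column (``mz`` or ``m/z``)
    and one column per spectrum; an optional ``#labels:`` comment line
    before the header assigns a class to each spectrum column. Comment
    lines start with ``#``. Rows are re-sorted by ascending m/z; integer
    counts round-trip exactly.
    """
    path = Path(path)
    labels = None
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#labels:"):
            labels = tuple(line[len("#labels:"):].strip().split(dialect))
        elif not line.startswith("#"):
            data_lines.append(line)
    if not data_lines:
        raise PeakTableFormatError(f"{path}: no header row found")
    df = pd.read_csv(io.StringIO("".join(data_lines)), sep=dialect)
    mz_col = next((c for c in df.columns if c.strip().lower() in _MZ_COLUMN_NAMES), None)
    if mz_col is None:
        raise PeakTableFormatError(
            f"{path}: no m/z column (expected one of {sorted(_MZ_COLUMN_NAMES)})"
        )
    mz = df[mz_col].to_numpy(dtype=float)
    spectra_cols = [c for c in df.columns if c != mz_col]
    intensities = df[spectra_cols].to_numpy(dtype=float).T  # spectra x peaks
    if intensities.size and intensities.min() < 0:
        r, c = np.argwhere(intensities < 0)[0]
        raise ValueError(
            f"{path}: negative intensity in column '{spectra_cols[r]}', "
            f"data row {c + 1}"
        )
    order = np.argsort(mz, kind="stable")
    mz = mz[order]
    _check_duplicates(mz)
    intensities = intensities[:, order]
    if labels is not None and len(labels) != len(spectra_cols):
        raise PeakTableFormatError(
            f"{path}: #labels: line has {len(labels)} entries for "
            f"{len(spectra_cols)} spectrum columns"
        )
    return SpectrumSet(
        peaks=PeakList(mz),
        intensities=intensities,
        labels=labels,
        spectrum_names=tuple(spectra_cols),
        meta={"source": str(path)},
    )


def _format_value(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_peak_table(s: SpectrumSet, path, dialect: str = "\t"):
    """Write a :class:`SpectrumSet` as a delimited text peak table.

    Integer intensities are written without a decimal point so that
    ``read_peak_table(write_peak_table(s))`` is bit-exact for counts.
    """
    path = Path(path)
    names = s.spectrum_names or tuple(f"spectrum_{i}" for i in range(s.n_spectra))
    with open(path, "w", encoding="utf-8") as fh:
        if s.labels is not None:
            fh.write("#labels:" + dialect.join(s.labels) + "\n")
        fh.write(dialect.join(["mz", *names]) + "\n")
        for j in range(s.n_peaks):
            row = [repr(float(s.peaks.center_mz[j]))]
            row += [_format_value(s.intensities[i, j]) for i in range(s.n_spectra)]
            fh.write(dialect.join(row) + "\n")
    return path


def merge_peak_lists(lists: Sequence[PeakList], ppm_radius: float = 200.0) -> PeakList:
    """Merge peak lists into one unified list by a ppm catch mass radius.

    All peaks are pooled and sorted; a single left-to-right greedy pass
    clusters each peak with the running cluster whenever it lies within
    ``ppm_radius`` (relative to the running cluster mean), otherwise a new
    cluster starts. Each cluster is represented by the unweighted mean of
    its member masses. Chained clusters may span more than the radius
    end-to-end; cluster *means* always remain separated by at least the
    radius, which makes the operation idempotent.
    """
    if not lists:
        raise ValueError("merge_peak_lists requires at least one PeakList")
    if ppm_radius <= 0:
        raise ValueError("ppm_radius must be positive")
    mz_all = np.sort(np.concatenate([pl.center_mz for pl in lists]))
    if mz_all.size == 0:
        return PeakList(mz_all)
    centers = []
    members: list[float] = [mz_all[0]]
    for mz in mz_all[1:]:
        mean = float(np.mean(members))
        if (mz - mean) / mean * 1e6 < ppm_radius:
            members.append(mz)
        else:
            centers.append(mean)
            members = [mz]
    centers.append(float(np.mean(members)))
    return PeakList(np.asarray(centers))
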