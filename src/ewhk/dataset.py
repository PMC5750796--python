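"""In-memory container for absorbance spectra with class labels.

A :class:`SpectraDataset` holds an ``m x n`` matrix of absorbance values
(``m`` samples, ``n`` wavenumber channels), the shared wavenumber axis in
cm^-1, one class label per sample, and unique sample identifiers.  The
wavenumber axis is canonicalized to strictly increasing order on
construction: FTIR instruments frequently export descending axes, and a
silent axis flip is a classic source of transposed-feature bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["SpectraDataset", "select_regions"]


@dataclass
class SpectraDataset:
    """Sample x wavenumber absorbance matrix with labels and metadata.

    Parameters
    ----------
    wavenumbers : array-like of float, shape (n,)
        Spectral axis in cm^-1.  Must be strictly monotonic; a strictly
        decreasing axis is reversed (with columns permuted to match).
    absorbance : array-like of float, shape (m, n)
        Absorbance values (dimensionless).  NaN/Inf are rejected.
    labels : array-like of str, shape (m,)
        Class label per sample.
    sample_ids : array-like of str, shape (m,)
        Unique identifier per sample.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray = field(repr=False)
    sample_ids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray([str(s) for s in np.asarray(self.sample_ids)], dtype=object)

        if self.wavenumbers.ndim != 1:
            raise ValidationError("wavenumbers must be one-dimensional")
        n = self.wavenumbers.size
        m = self.absorbance.shape[0]
        if self.absorbance.shape != (m, n):
            raise ValidationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{m} samples x {n} wavenumbers"
            )
        if self.labels.shape != (m,) or self.sample_ids.shape != (m,):
            raise ValidationError("labels and sample_ids must each have one entry per sample")
        if m == 0:
            raise ValidationError("dataset must contain at least one sample")

        diffs = np.diff(self.wavenumbers)
        if n > 1 and np.all(diffs < 0):
            # canonicalize descending instrument export to ascending
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()
            diffs = np.diff(self.wavenumbers)
        if n > 1 and not np.all(diffs > 0):
            raise ValidationError("wavenumbers must be strictly monotonic")

        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance contains missing or non-finite values")
        if len(set(self.sample_ids)) != m:
            raise ValidationError("sample_ids must be unique")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_features(self) -> int:
        return self.absorbance.shape[1]

    @property
    def classes(self) -> list[str]:
        """Represented class labels, sorted lexicographically."""
        return sorted({str(label) for label in self.labels})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraDataset):
            return NotImplemented
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.sample_ids, other.sample_ids)
        )

    # -- derived datasets ----------------------------------------------------

    def subset(self, rows: np.ndarray) -> "SpectraDataset":
        """Return a new dataset restricted to the given sample rows."""
        rows = np.asarray(rows)
        return SpectraDataset(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[rows].copy(),
            labels=self.labels[rows].copy(),
            sample_ids=self.sample_ids[rows].copy(),
        )

    def select_regions(self, regions) -> "SpectraDataset":
        return select_regions(self, regions)


def _validate_regions(regions) -> list[tuple[float, float]]:
    out = []
    for reg in regions:
        low, high = float(reg[0]), float(reg[1])
        if not low <= high:
            raise ValidationError(f"region [{low}, {high}] has low > high")
        out.append((low, high))
    out.sort()
    for (lo1, hi1), (lo2, _) in zip(out, out[1:]):
        if lo2 <= hi1:
            raise ValidationError("regions must be non-overlapping")
    return out


def region_masks(wavenumbers: np.ndarray, regions) -> list[np.ndarray]:
    """Boolean column mask per closed interval [low, high] in cm^-1."""
    regs = _validate_regions(regions)
    wn = np.asarray(wavenumbers, dtype=float)
    return [(wn >= lo) & (wn <= hi) for lo, hi in regs]


def select_regions(ds: SpectraDataset, regions) -> SpectraDataset:
    """Restrict a dataset to wavenumbers inside closed intervals.

    Intervals are closed, ``[low, high]`` in cm^-1, and must not overlap.
    Columns outside every interval are dropped.  Raises
    :class:`ValidationError` if no column survives.
    """
    masks = region_masks(ds.wavenumbers, regions)
    keep = np.logical_or.reduce(masks)
    if not keep.any():
        raise ValidationError("region selection removed every wavenumber column")
    return SpectraDataset(
        wavenumbers=ds.wavenumbers[keep].copy(),
        absorbance=ds.absorbance[:, keep].copy(),
        labels=ds.labels.copy(),
        sample_ids=ds.sample_ids.copy(),
    )
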