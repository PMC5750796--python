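"""Read and write spectra tables in a flat CSV dialect.

Dialect: UTF-8, comma separated.  First column ``id`` (unique sample
identifier), second the label column (``label`` by default), remaining
column headers are wavenumbers in cm^-1 written as decimal numbers.
Descending wavenumber headers are accepted and canonicalized to ascending
on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpectraDataset
from .exceptions import FormatError, ValidationError

__all__ = ["read_spectra", "write_spectra"]


def read_spectra(path, label_column: str = "label") -> SpectraDataset:
    """Load a spectra CSV into a validated :class:`SpectraDataset`.

    Raises
    ------
    FormatError
        Non-numeric wavenumber headers, ragged rows or missing cells.
    ValidationError
        Duplicate sample ids or other integrity violations.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    if frame.shape[1] < 3:
        raise FormatError(f"{path}: need an id column, a label column and at least one wavenumber column")
    id_col = frame.columns[0]
    if label_column not in frame.columns:
        raise FormatError(f"{path}: label column {label_column!r} not found")

    wn_headers = [c for c in frame.columns if c not in (id_col, label_column)]
    try:
        wavenumbers = np.array([float(h) for h in wn_headers])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber header ({exc})") from exc

    values = frame[wn_headers]
    if values.isna().any().any():
        raise FormatError(f"{path}: missing absorbance cells")
    try:
        absorbance = values.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric absorbance value ({exc})") from exc

    ids = frame[id_col].astype(str).to_numpy()
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    return SpectraDataset(
        wavenumbers=wavenumbers,
        absorbance=absorbance,
        labels=frame[label_column].astype(str).to_numpy(dtype=object),
        sample_ids=ids,
    )


def write_spectra(ds: SpectraDataset, path, label_column: str = "label") -> None:
    """Write a dataset in the CSV dialect; round-trips through read_spectra.

    Values are rendered with ``repr``-style shortest round-trip decimals,
    so ``read_spectra(write_spectra(ds))`` reproduces ``ds`` exactly.
    """
    if not isinstance(ds, SpectraDataset):
        raise ValidationError("write_spectra expects a SpectraDataset")
    frame = pd.DataFrame(ds.absorbance, columns=[repr(float(w)) for w in ds.wavenumbers])
    frame.insert(0, label_column, ds.labels)
    frame.insert(0, "id", ds.sample_ids)
    frame.to_csv(path, index=False, float_format="%.17g")
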