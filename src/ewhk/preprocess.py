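"""Spectral preprocessing: Savitzky-Golay smoothing and region-wise SNV.

The pipeline order is smooth first, then standard normal variate (SNV)
normalization, applied separately to each spectral region.  For FTIR
tissue spectra the informative bands lie in 1000-1800 cm^-1 and
2800-3800 cm^-1; the silent 1800-2800 cm^-1 window carries no
bio-molecular absorbance and is dropped by the default region choice.

SNV standardizes each spectrum (row) within a region:

    x_snv = (x - mean(x)) / sd(x),    sd with n-1 degrees of freedom,

which removes per-sample additive offsets and multiplicative scatter:
``snv(a*x + b) == snv(x)`` for any ``a > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraDataset, region_masks, select_regions
from .exceptions import DegenerateSampleError, ValidationError

__all__ = ["PreprocessConfig", "savgol_smooth", "snv_normalize", "preprocess"]

DEFAULT_SNV_REGIONS: tuple[tuple[float, float], ...] = ((1000.0, 1800.0), (2800.0, 3800.0))


@dataclass(frozen=True)
class PreprocessConfig:
    """Savitzky-Golay window/order and SNV region layout.

    sg_window must be odd and >= 3; sg_polyorder < sg_window.  The default
    5-point window with a quadratic fit is the standard light-smoothing
    choice for spectra on a fine grid.  snv_regions are closed cm^-1
    intervals, non-overlapping.
    """

    sg_window: int = 5
    sg_polyorder: int = 2
    snv_regions: tuple[tuple[float, float], ...] = DEFAULT_SNV_REGIONS

    def __post_init__(self) -> None:
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValidationError("sg_window must be an odd integer >= 3")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ValidationError("sg_polyorder must satisfy 0 <= order < window")
        # normalize to hashable nested tuples and validate non-overlap
        regs = tuple((float(lo), float(hi)) for lo, hi in self.snv_regions)
        object.__setattr__(self, "snv_regions", regs)
        region_masks(np.array([r[0] for r in regs]), regs)  # overlap check


def savgol_smooth(ds: SpectraDataset, cfg: PreprocessConfig = PreprocessConfig()) -> SpectraDataset:
    """Smooth each spectrum with a Savitzky-Golay filter.

    Boundary points are handled by evaluating the polynomial fitted to the
    first/last full window (no mirroring), so a spectrum that is globally a
    polynomial of degree <= sg_polyorder passes through unchanged.
    """
    if ds.n_features < cfg.sg_window:
        raise ValidationError(
            f"need at least sg_window={cfg.sg_window} wavenumber points, have {ds.n_features}"
        )
    smoothed = savgol_filter(ds.absorbance, cfg.sg_window, cfg.sg_polyorder, axis=1, mode="interp")
    return SpectraDataset(ds.wavenumbers.copy(), smoothed, ds.labels.copy(), ds.sample_ids.copy())


def snv_normalize(ds: SpectraDataset, cfg: PreprocessConfig = PreprocessConfig()) -> SpectraDataset:
    """Apply SNV independently per spectrum and per region.

    Every column of ``ds`` must fall inside one of ``cfg.snv_regions``
    (run :func:`ewhk.dataset.select_regions` first, or use
    :func:`preprocess` which composes the two).  Each region segment
    needs >= 2 points and nonzero sample standard deviation; a flat
    segment raises :class:`DegenerateSampleError` naming the sample.
    """
    masks = region_masks(ds.wavenumbers, cfg.snv_regions)
    covered = np.logical_or.reduce(masks) if masks else np.zeros(ds.n_features, bool)
    if not covered.all():
        stray = ds.wavenumbers[~covered]
        raise ValidationError(
            f"{(~covered).sum()} columns (e.g. {stray[0]:g} cm^-1) lie outside the SNV regions; "
            "apply select_regions first or widen snv_regions"
        )

    out = ds.absorbance.copy()
    for mask in masks:
        if not mask.any():
            continue
        if mask.sum() < 2:
            raise ValidationError("each SNV region needs at least 2 wavenumber points")
        seg = out[:, mask]
        means = seg.mean(axis=1, keepdims=True)
        sds = seg.std(axis=1, ddof=1, keepdims=True)
        flat = np.flatnonzero(sds.ravel() == 0)
        if flat.size:
            raise DegenerateSampleError(
                f"sample {ds.sample_ids[flat[0]]!r} is flat within an SNV region; SNV undefined"
            )
        out[:, mask] = (seg - means) / sds
    return SpectraDataset(ds.wavenumbers.copy(), out, ds.labels.copy(), ds.sample_ids.copy())


def preprocess(ds: SpectraDataset, cfg: PreprocessConfig = PreprocessConfig()) -> SpectraDataset:
    """Full pipeline: smooth, restrict to the SNV regions, then SNV."""
    smoothed = savgol_smooth(ds, cfg)
    restricted = select_regions(smoothed, cfg.snv_regions)
    return snv_normalize(restricted, cfg)
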