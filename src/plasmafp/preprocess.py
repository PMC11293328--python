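"""Spectral preprocessing: water correction, truncation/masking, L2 norm.

The raw absorbance spectrum of a plasma sample referenced against pure water
goes negative wherever the sample contains less water than the reference.
The correction adds back a scaled water spectrum, with the scale chosen so
that the first derivative of the corrected spectrum is minimal (in the L2
sense) over the biologically silent 2000-2300 cm^-1 window.  Spectra are
then truncated to 1000-3000 cm^-1 with the silent 1800-2800 cm^-1 region
removed, and finally L2-normalized to unit Euclidean length.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .containers import PhenotypeMatrix, Spectrum, SpectraMatrix, PHENOTYPES

__all__ = [
    "CorrectionResult",
    "DifferentialSignature",
    "correct_water",
    "truncate_and_mask",
    "l2_normalize",
    "preprocess_matrix",
    "differential_signature",
    "WATER_WINDOW",
    "KEEP_REGIONS",
]

#: window over which the water-scaling coefficient is optimized (cm^-1)
WATER_WINDOW: tuple[float, float] = (2000.0, 2300.0)

#: retained closed intervals after truncation and masking (cm^-1)
KEEP_REGIONS: tuple[tuple[float, float], ...] = (
    (1000.0, 1800.0),
    (2800.0, 3000.0),
)


class DegenerateReferenceError(ValueError):
    """The water reference has no derivative energy in the fit window."""


class NormalizationError(ValueError):
    pass


class RangeError(ValueError):
    pass


class CohortError(ValueError):
    pass


@dataclass
class CorrectionResult:
    corrected: Spectrum
    coefficient: float
    objective_before: float
    objective_after: float


@dataclass
class DifferentialSignature:
    """Mean fingerprint of phenotype-positive samples minus the mean of
    phenotype-negative samples, with the negative group's per-wavenumber SD."""

    grid: np.ndarray
    delta: np.ndarray
    negative_sd: np.ndarray
    phenotype: str


def _window_derivative(values: np.ndarray, grid: np.ndarray,
                       window: tuple[float, float]) -> np.ndarray:
    """First-order finite differences restricted to grid points inside
    the (closed) window.  Values may be a vector or a matrix of rows."""
    lo, hi = window
    idx = np.flatnonzero((grid >= lo) & (grid <= hi))
    if idx.size < 2:
        raise RangeError("fit window contains fewer than two grid points")
    return np.diff(np.atleast_2d(values)[:, idx], axis=-1)


def correct_water(
    raw: Spectrum,
    water_ref: Spectrum,
    window: tuple[float, float] = WATER_WINDOW,
) -> CorrectionResult:
    """Add a scaled water spectrum to flatten the silent window.

    The coefficient c minimizes || d/dnu (raw + c * W) ||_2 over the window;
    with finite differences this is a scalar least-squares problem with the
    closed form c = -<A', W'> / <W', W'>.  Positive c means the sample held
    less water than the reference.
    """
    if raw.grid.shape != water_ref.grid.shape or not np.allclose(
        raw.grid, water_ref.grid
    ):
        raise ValueError("raw and water reference must share one grid")
    da = _window_derivative(raw.absorbance, raw.grid, window)[0]
    dw = _window_derivative(water_ref.absorbance, raw.grid, window)[0]
    denom = float(dw @ dw)
    if denom <= 0.0 or not np.isfinite(denom):
        raise DegenerateReferenceError(
            "water reference has zero derivative energy in the window"
        )
    c = float(-(da @ dw) / denom)
    corrected = Spectrum(raw.grid, raw.absorbance + c * water_ref.absorbance)
    return CorrectionResult(
        corrected=corrected,
        coefficient=c,
        objective_before=float(np.linalg.norm(da)),
        objective_after=float(np.linalg.norm(da + c * dw)),
    )


def retained_indices(grid: np.ndarray) -> np.ndarray:
    keep = np.zeros(grid.size, dtype=bool)
    for lo, hi in KEEP_REGIONS:
        keep |= (grid >= lo) & (grid <= hi)
    return np.flatnonzero(keep)


def truncate_and_mask(s: Spectrum) -> Spectrum:
    """Keep the closed intervals 1000-1800 and 2800-3000 cm^-1 only."""
    if s.grid[0] > KEEP_REGIONS[0][0] or s.grid[-1] < KEEP_REGIONS[-1][-1]:
        raise RangeError(
            f"grid [{s.grid[0]}, {s.grid[-1]}] does not cover 1000-3000 cm^-1"
        )
    idx = retained_indices(s.grid)
    return Spectrum(s.grid[idx], s.absorbance[idx])


def l2_normalize(s: Spectrum) -> Spectrum:
    """Scale the spectrum vector to unit Euclidean norm."""
    norm = float(np.linalg.norm(s.absorbance))
    if norm == 0.0 or not np.isfinite(norm):
        raise NormalizationError("cannot normalize a zero or non-finite vector")
    return Spectrum(s.grid, s.absorbance / norm)


def preprocess_matrix(
    raw: SpectraMatrix,
    water_ref: Spectrum,
    normalize: bool = True,
    window: tuple[float, float] = WATER_WINDOW,
) -> tuple[SpectraMatrix, np.ndarray]:
    """Water-correct, truncate/mask and optionally L2-normalize each row.

    Returns the processed matrix (sample order and ids preserved) and the
    per-sample water coefficients.
    """
    if raw.grid.shape != water_ref.grid.shape or not np.allclose(
        raw.grid, water_ref.grid
    ):
        raise ValueError("spectra and water reference must share one grid")
    da = _window_derivative(raw.absorbance, raw.grid, window)
    dw = _window_derivative(water_ref.absorbance, raw.grid, window)[0]
    denom = float(dw @ dw)
    if denom <= 0.0:
        raise DegenerateReferenceError(
            "water reference has zero derivative energy in the window"
        )
    coeffs = -(da @ dw) / denom
    corrected = raw.absorbance + coeffs[:, None] * water_ref.absorbance[None, :]
    idx = retained_indices(raw.grid)
    if raw.grid[0] > KEEP_REGIONS[0][0] or raw.grid[-1] < KEEP_REGIONS[-1][-1]:
        raise RangeError("grid does not cover 1000-3000 cm^-1")
    out = corrected[:, idx]
    if normalize:
        norms = np.linalg.norm(out, axis=1)
        if np.any(norms == 0.0):
            raise NormalizationError("zero row after masking")
        out = out / norms[:, None]
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values after preprocessing")
    return SpectraMatrix(raw.sample_ids, raw.grid[idx], out), coeffs


def differential_signature(
    X: SpectraMatrix,
    labels: PhenotypeMatrix,
    phenotype: str,
) -> DifferentialSignature:
    """Columnwise mean(positive) - mean(negative) for one phenotype, with
    the per-wavenumber SD (n-1 denominator) of the negative group."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    lab = labels.subset(X.sample_ids.tolist())
    col = PHENOTYPES.index(phenotype)
    keep = ~lab.unknown
    pos = lab.values[:, col] & keep
    neg = ~lab.values[:, col] & keep
    if pos.sum() == 0 or neg.sum() == 0:
        raise CohortError(
            f"both groups must be nonempty for {phenotype!r} "
            f"(positive={int(pos.sum())}, negative={int(neg.sum())})"
        )
    if neg.sum() < 2:
        warnings.warn("negative group has fewer than 2 samples; SD undefined")
    delta = X.absorbance[pos].mean(axis=0) - X.absorbance[neg].mean(axis=0)
    sd = X.absorbance[neg].std(axis=0, ddof=1)
    return DifferentialSignature(
        grid=X.grid, delta=delta, negative_sd=sd, phenotype=phenotype
    )
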