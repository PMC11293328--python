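"""Shared in-memory containers for spectra and phenotype labels.

The pipeline passes absorbance data around as a :class:`SpectraMatrix`
(samples x wavenumbers) and phenotype labels as a :class:`PhenotypeMatrix`
of five binary columns subject to clinical feasibility constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical phenotype order used throughout (also the default chain order).
PHENOTYPES: tuple[str, ...] = (
    "dyslipidemia",
    "hypertension",
    "prediabetes",
    "t2d",
    "healthy",
)

#: The 12-analyte clinical panel, with units fixed per field.
ANALYTES: tuple[str, ...] = (
    "fasting_glucose",   # mg/dL
    "hba1c",             # %
    "total_cholesterol", # mmol/L
    "ldl",               # mmol/L
    "hdl",               # mmol/L
    "triglycerides",     # mg/dL
    "creatinine",        # mg/dL
    "albumin",           # g/L
    "leukocytes",        # 10^9/L
    "erythrocytes",      # 10^12/L
    "hematocrit",        # fraction
    "platelets",         # 10^9/L
)


class FeasibilityError(ValueError):
    """A phenotype label row violates the clinical feasibility constraints."""


@dataclass
class Spectrum:
    """A single absorbance spectrum on an ascending wavenumber grid (cm^-1)."""

    grid: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.grid.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("grid and absorbance must be 1-D")
        if self.grid.shape != self.absorbance.shape:
            raise ValueError("grid and absorbance lengths differ")
        if self.grid.size >= 2 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")


@dataclass
class SpectraMatrix:
    """Absorbance matrix with sample identity.

    Rows are samples, columns are wavenumbers.  ``sample_ids`` keys rows into
    the clinical and label tables.
    """

    sample_ids: np.ndarray
    grid: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.sample_ids.size, self.grid.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} inconsistent with "
                f"{self.sample_ids.size} ids x {self.grid.size} grid points"
            )
        if self.grid.size >= 2 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if len(set(self.sample_ids.tolist())) != self.sample_ids.size:
            raise ValueError("duplicate sample_id in SpectraMatrix")

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def row(self, sample_id) -> Spectrum:
        idx = np.flatnonzero(self.sample_ids == sample_id)
        if idx.size != 1:
            raise KeyError(sample_id)
        return Spectrum(self.grid, self.absorbance[idx[0]])

    def subset(self, sample_ids: Sequence) -> "SpectraMatrix":
        """Row subset in the order of ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return SpectraMatrix(
            np.asarray(list(sample_ids), dtype=object),
            self.grid,
            self.absorbance[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.absorbance, columns=self.grid)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def validate_label_row(row: Iterable[bool]) -> None:
    """Raise :class:`FeasibilityError` unless a 5-vector is clinically feasible.

    Constraints: a diabetic individual cannot be prediabetic, and ``healthy``
    holds exactly when all four conditions are absent.
    """
    d, h, pre, t2d, healthy = (bool(v) for v in row)
    if pre and t2d:
        raise FeasibilityError("prediabetes and t2d are mutually exclusive")
    if healthy != (not (d or h or pre or t2d)):
        raise FeasibilityError(
            "healthy must hold iff all four conditions are absent"
        )


def enumerate_feasible_vectors() -> list[tuple[bool, ...]]:
    """All feasible 5-label vectors, by exhaustive enumeration of 2^5 = 32.

    Exactly 12 clinically feasible co-occurrence patterns exist.
    """
    out = []
    for bits in product((False, True), repeat=len(PHENOTYPES)):
        try:
            validate_label_row(bits)
        except FeasibilityError:
            continue
        out.append(bits)
    return out


@dataclass
class PhenotypeMatrix:
    """Binary label matrix over :data:`PHENOTYPES` with feasibility checking.

    ``unknown`` marks samples whose determining clinical fields were missing;
    such rows are excluded from analyses rather than guessed.
    """

    sample_ids: np.ndarray
    values: np.ndarray  # (n, 5) bool
    unknown: np.ndarray = field(default=None)  # type: ignore[assignment]
    validate: bool = True

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=bool)
        if self.unknown is None:
            self.unknown = np.zeros(self.sample_ids.size, dtype=bool)
        self.unknown = np.asarray(self.unknown, dtype=bool)
        if self.values.shape != (self.sample_ids.size, len(PHENOTYPES)):
            raise ValueError("label matrix must be n_samples x 5")
        if self.unknown.shape != (self.sample_ids.size,):
            raise ValueError("unknown mask length mismatch")
        if self.validate:
            for i, row in enumerate(self.values):
                if self.unknown[i]:
                    continue
                try:
                    validate_label_row(row)
                except FeasibilityError as exc:
                    raise FeasibilityError(
                        f"sample {self.sample_ids[i]!r}: {exc}"
                    ) from exc

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def subset(self, sample_ids: Sequence) -> "PhenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return PhenotypeMatrix(
            np.asarray(list(sample_ids), dtype=object),
            self.values[idx],
            self.unknown[idx],
            validate=False,
        )

    def known(self) -> "PhenotypeMatrix":
        """Drop rows flagged unknown."""
        keep = ~self.unknown
        return PhenotypeMatrix(
            self.sample_ids[keep], self.values[keep], validate=False
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values.astype(int), columns=list(PHENOTYPES)
        )
        df.insert(0, "sample_id", self.sample_ids)
        df["unknown"] = self.unknown.astype(int)
        return df
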