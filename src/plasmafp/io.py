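"""File I/O for spectra, clinical tables, and phenotype labels.

Spectra travel as CSV with a ``sample_id`` first column and numeric
wavenumber headers; the water reference is a single-row file of the same
dialect.  Clinical and label tables are sample_id-keyed CSV.  A minimal
reader for the JCAMP-DX IR interchange format is included for single
spectra from other instruments.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ANALYTES,
    PHENOTYPES,
    PhenotypeMatrix,
    Spectrum,
    SpectraMatrix,
)

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_water_csv",
    "write_water_csv",
    "read_clinical_csv",
    "read_labels_csv",
    "read_jcamp",
]

_CLINICAL_BOOL = ("med_antihypertensive", "med_antidiabetic", "med_fibrates")
_CLINICAL_NUMERIC = (
    "age", "bmi", "waist", "sbp", "dbp", "glucose_2h",
) + ANALYTES


def read_spectra_csv(path: str | Path) -> SpectraMatrix:
    """Load a sample x wavenumber absorbance matrix.

    Wavenumber columns are re-sorted ascending (with a warning) if the file
    stores them descending; duplicate sample ids are an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise ValueError("first column must be 'sample_id'")
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber header: {exc}") from exc
    ids = df["sample_id"].to_numpy(dtype=object)
    if pd.Series(ids).duplicated().any():
        raise ValueError(f"duplicate sample_id in {path}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    order = np.argsort(grid)
    if not np.array_equal(order, np.arange(grid.size)):
        warnings.warn(f"re-sorting wavenumber columns of {path} ascending")
        grid, values = grid[order], values[:, order]
    return SpectraMatrix(ids, grid, values)


def write_spectra_csv(matrix: SpectraMatrix, path: str | Path) -> None:
    # repr() of Python floats keeps full precision for round-trips
    header = "sample_id," + ",".join(repr(float(w)) for w in matrix.grid)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.absorbance):
            fh.write(
                str(sid) + "," + ",".join(repr(float(v)) for v in row) + "\n"
            )


def read_water_csv(path: str | Path) -> Spectrum:
    matrix = read_spectra_csv(path)
    if matrix.n_samples != 1:
        raise ValueError("water reference must contain exactly one row")
    return Spectrum(matrix.grid, matrix.absorbance[0])


def write_water_csv(water: Spectrum, path: str | Path) -> None:
    write_spectra_csv(
        SpectraMatrix(
            np.array(["water"], dtype=object),
            water.grid,
            water.absorbance[None, :],
        ),
        path,
    )


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Typed parse of the clinical table; empty cells become NaN (missing)."""
    df = pd.read_csv(path)
    required = {"sample_id", "individual_id", "visit", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    if df.duplicated(["individual_id", "visit"]).any():
        raise ValueError("duplicate (individual_id, visit) pair")
    for col in _CLINICAL_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _CLINICAL_BOOL:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(
            f"invalid sex values: {df.loc[bad_sex, 'sex'].unique()}"
        )
    return df


def read_labels_csv(path: str | Path) -> PhenotypeMatrix:
    """Load a phenotype label table, validating clinical feasibility.

    Raises a feasibility error naming the offending row when a label vector
    is infeasible (e.g. prediabetes and t2d both set).
    """
    df = pd.read_csv(path)
    needed = {"sample_id", *PHENOTYPES}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"label table lacks columns: {sorted(missing)}")
    unknown = (
        df["unknown"].astype(bool).to_numpy()
        if "unknown" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    values = df[list(PHENOTYPES)].to_numpy().astype(bool)
    return PhenotypeMatrix(
        df["sample_id"].to_numpy(dtype=object), values, unknown
    )


def read_jcamp(path: str | Path) -> Spectrum:
    """Minimal JCAMP-DX reader: (X++(Y..Y)) and XYPOINTS AFFN tables only."""
    lines = Path(path).read_text().splitlines()
    fields: dict[str, str] = {}
    data: list[tuple[float, float]] = []
    mode = None
    for line in lines:
        line = line.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            fields[key] = value.strip()
            if key == "XYDATA" and "X++" in value:
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                mode = None
            else:
                mode = None
            continue
        if mode == "xydata":
            parts = line.replace(",", " ").split()
            x0 = float(parts[0])
            ys = [float(p) for p in parts[1:]]
            dx = float(fields.get("DELTAX", "0") or 0) or (
                (float(fields["LASTX"]) - float(fields["FIRSTX"]))
                / (float(fields["NPOINTS"]) - 1)
            )
            for i, y in enumerate(ys):
                data.append((x0 + i * dx, y))
        elif mode == "xypoints":
            for pair in line.replace(";", " ").split():
                x, _, y = pair.partition(",")
                data.append((float(x), float(y)))
    if not data:
        raise ValueError(f"no spectral data found in {path}")
    xf = float(fields.get("XFACTOR", 1.0))
    yf = float(fields.get("YFACTOR", 1.0))
    arr = np.array(data)
    x, y = arr[:, 0] * xf, arr[:, 1] * yf
    order = np.argsort(x)
    return Spectrum(x[order], y[order])


# --------------------------------------------------------------------------
# run configuration

_RUN_CONFIG_KEYS = {
    "paths", "seed", "preprocessing", "model", "validation", "metrics",
    "output_dir",
}


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration with strict key checking.

    Top-level keys outside the declared set (paths, seed, preprocessing,
    model, validation, metrics, output_dir) are rejected so that typos
    cannot silently change a run.
    """
    import yaml

    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError("run configuration must be a mapping")
    unknown = set(payload) - _RUN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    payload.setdefault("seed", 0)
    payload.setdefault("output_dir", "runs")
    return payload
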