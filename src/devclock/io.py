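"""Readers and writers for the delimited-text formats the toolkit touches.

All tabular inputs are plain TSV/CSV: matrices carry probe ids in the
first column and sample ids in the header; clock coefficient files are
two-column ``term, coefficient`` tables with ``#key=value`` metadata
lines and a reserved ``(Intercept)`` term, so a published supplementary
coefficient table can be dropped in after trivial reshaping.

Missing values are "NA" or the empty string on read and "NA" on write.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    ClockModel,
    FormatError,
    OutputUnit,
    ProbeAnnotation,
    SampleSheet,
    Transform,
    ValidationError,
)

_NA_VALUES = ["", "NA"]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    raise FormatError(f"{path}: empty file")


def read_matrix(
    path: str | Path,
    kind: Literal["beta", "intensity", "detection_p"] = "beta",
) -> BetaMatrix:
    """Read a probes × samples matrix from delimited text.

    First column holds probe ids, header row sample ids; the delimiter is
    auto-detected among tab/comma. Empty cells and "NA" become missing.
    ``kind`` selects validation: "beta" and "detection_p" require values in
    [0, 1]; "intensity" requires non-negative values. All kinds return a
    :class:`BetaMatrix`-shaped container (ids + float matrix) — for
    non-beta kinds the [0, 1] invariant is checked per kind here instead.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False,
        comment="#", float_precision="round_trip",
    )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    if pd.Index(df.columns).has_duplicates:
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    probe_ids = [str(p) for p in df.index]
    sample_ids = [str(s) for s in df.columns]
    if kind in ("beta", "detection_p"):
        bad = np.where(~np.isnan(values) & ((values < -1e-9) | (values > 1 + 1e-9)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"{path}: {kind} value {values[i, j]:g} outside [0, 1] at probe "
                f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
            )
    else:
        if np.nanmin(values, initial=0.0) < 0:
            raise ValidationError(f"{path}: negative intensity value")
    if kind == "beta":
        return BetaMatrix(probe_ids, sample_ids, values)
    from .datamodel import matrix_container

    return matrix_container(probe_ids, sample_ids, values)


def write_matrix(matrix: BetaMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text; missing values become "NA"."""
    frame = pd.DataFrame(
        matrix.values, index=matrix.probe_ids, columns=matrix.sample_ids
    )
    frame.index.name = "probe_id"
    frame.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


def read_clock(path: str | Path) -> ClockModel:
    """Read a clock coefficient file.

    Layout: optional ``#name=``, ``#output_unit=``, ``#transform=``,
    ``#adult_age=``, ``#alpha=``, ``#lambda=``, ``#n_train=``,
    ``#train_age_min_dpc=``, ``#train_age_max_dpc=`` metadata lines, then a
    two-column delimited table (term, coefficient) with a reserved
    ``(Intercept)`` row. Zero-coefficient rows are dropped with a warning.
    Defaults: output_unit=dpc, transform=identity, name from file stem.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        header_skipped = False
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            term, _, coef = line.partition(sep)
            term = term.strip().strip('"')
            coef = coef.strip()
            if not header_skipped:
                header_skipped = True
                try:
                    float(coef)
                except ValueError:
                    continue  # header row like "term<sep>coefficient"
            try:
                value = float(coef)
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric coefficient for {term!r}") from exc
            rows.append((term, value))
    intercept = None
    coefficients: dict[str, float] = {}
    n_zero = 0
    for term, value in rows:
        if term == "(Intercept)":
            intercept = value
        elif value == 0.0:
            n_zero += 1
        else:
            if term in coefficients:
                raise FormatError(f"{path}: duplicate coefficient term {term!r}")
            coefficients[term] = value
    if intercept is None:
        raise FormatError(f"{path}: no '(Intercept)' row")
    if n_zero:
        warnings.warn(f"{path}: dropped {n_zero} zero-coefficient row(s)")
    transform_params: dict[str, float] = {}
    if "adult_age" in meta:
        transform_params["adult_age"] = float(meta["adult_age"])
    training_meta: dict[str, object] = {}
    for key in ("alpha", "lambda", "train_age_min_dpc", "train_age_max_dpc"):
        if key in meta:
            training_meta[key] = float(meta[key])
    if "n_train" in meta:
        training_meta["n_train"] = int(meta["n_train"])
    return ClockModel(
        name=meta.get("name", path.stem),
        intercept=intercept,
        coefficients=coefficients,
        output_unit=OutputUnit(meta.get("output_unit", "dpc")),
        transform=Transform(meta.get("transform", "identity")),
        transform_params=transform_params,
        training_meta=training_meta,
    )


def write_clock(model: ClockModel, path: str | Path, sep: str = "\t") -> None:
    """Write a clock so that ``read_clock(write_clock(m))`` reproduces it
    bit-for-bit (coefficients serialized at full precision via repr)."""
    if not model.coefficients:
        raise ValidationError("refusing to write a clock with no coefficients")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#name={model.name}\n")
        fh.write(f"#output_unit={model.output_unit.value}\n")
        fh.write(f"#transform={model.transform.value}\n")
        if "adult_age" in model.transform_params:
            fh.write(f"#adult_age={model.transform_params['adult_age']!r}\n")
        for key in ("alpha", "lambda", "n_train", "train_age_min_dpc", "train_age_max_dpc"):
            if key in model.training_meta:
                fh.write(f"#{key}={model.training_meta[key]!r}\n")
        fh.write(f"term{sep}coefficient\n")
        fh.write(f"(Intercept){sep}{model.intercept!r}\n")
        for probe, coef in model.coefficients.items():
            fh.write(f"{probe}{sep}{coef!r}\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV/TSV with the required metadata columns."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = ",") -> None:
    sheet.table.to_csv(path, sep=sep, index=False, na_rep="NA")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read probe annotation (probe_id, design_type, snp_affected,
    cross_hybridizing, optional platform flag columns)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False)
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: annotation needs a 'probe_id' column")
    df = df.set_index("probe_id")
    for col in ("snp_affected", "cross_hybridizing"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False}
            )
    return ProbeAnnotation(df)


def write_annotation(annot: ProbeAnnotation, path: str | Path, sep: str = "\t") -> None:
    out = annot.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep, na_rep="NA")
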