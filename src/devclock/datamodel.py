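"""Core data objects for methylation-array clock analyses.

The central measurement object is the :class:`BetaMatrix` — a probes ×
samples matrix of methylation proportions (beta values) in [0, 1].
Raw-signal inputs are carried by :class:`IntensitySet` (methylated /
unmethylated fluorescence plus detection p-values), sample metadata by
:class:`SampleSheet`, probe metadata by :class:`ProbeAnnotation`, and a
fitted or published age clock by :class:`ClockModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file or table violates the expected layout (duplicates, missing rows)."""


class ValidationError(ValueError):
    """Values violate a domain invariant (e.g. beta outside [0, 1])."""


class AgeUnit(str, Enum):
    """Age encodings encountered across prenatal and postnatal datasets."""

    DPC = "dpc"
    WEEKS_PC = "weeks_pc"
    YEARS = "years"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class DesignType(str, Enum):
    """Illumina probe chemistry: Type I and Type II have distinct intensity
    distributions and are normalized separately."""

    I = "I"
    II = "II"


class OutputUnit(str, Enum):
    """Native unit of a clock's predictions."""

    DPC = "dpc"
    YEARS = "years"
    WEEKS_GA = "weeks_ga"


class Transform(str, Enum):
    """Output transform applied to a clock's linear predictor.

    ``horvath_log_linear`` is the log-linear age transform used by the
    multi-tissue clock: linear above ``adult_age``, logarithmic below.
    """

    IDENTITY = "identity"
    HORVATH_LOG_LINEAR = "horvath_log_linear"


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise FormatError(f"duplicate {what} id: {x!r}")
            seen.add(x)


@dataclass
class BetaMatrix:
    """Probes × samples methylation proportions with NaN as missing.

    Invariants: probe and sample ids unique; all non-missing values in
    [0, 1] (to 1e-9); ``values.shape == (len(probe_ids), len(sample_ids))``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        bad = np.where(
            ~np.isnan(self.values)
            & ((self.values < -1e-9) | (self.values > 1 + 1e-9))
        )
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {self.values[i, j]:g} outside [0, 1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        idx = pd.Index(self.probe_ids)
        locs = idx.get_indexer(list(probes))
        if (locs < 0).any():
            missing = [p for p, l in zip(probes, locs) if l < 0]
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(list(probes), self.sample_ids, self.values[locs, :])

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        idx = pd.Index(self.sample_ids)
        locs = idx.get_indexer(list(samples))
        if (locs < 0).any():
            missing = [s for s, l in zip(samples, locs) if l < 0]
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self.probe_ids, list(samples), self.values[:, locs])


def matrix_container(
    probe_ids: Sequence[str], sample_ids: Sequence[str], values: np.ndarray
) -> "BetaMatrix":
    """A BetaMatrix-shaped container without the [0, 1] value check —
    for detection-p / intensity components that share the layout."""
    m = BetaMatrix.__new__(BetaMatrix)
    m.probe_ids = list(probe_ids)
    m.sample_ids = list(sample_ids)
    m.values = np.asarray(values, dtype=float)
    _check_unique(m.probe_ids, "probe")
    _check_unique(m.sample_ids, "sample")
    if m.values.shape != (len(m.probe_ids), len(m.sample_ids)):
        raise ValidationError("matrix shape inconsistent with id lists")
    return m


@dataclass
class IntensitySet:
    """Methylated/unmethylated intensities + detection p-values.

    All three matrices share probe/sample ordering; intensities are
    non-negative, detection p-values live in [0, 1].
    """

    probe_ids: list[str]
    sample_ids: list[str]
    methylated: np.ndarray
    unmethylated: np.ndarray
    detection_p: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        shape = (len(self.probe_ids), len(self.sample_ids))
        for name in ("methylated", "unmethylated", "detection_p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != shape:
                raise ValidationError(f"{name} shape {arr.shape} != {shape}")
        if np.nanmin(self.methylated, initial=0) < 0 or np.nanmin(
            self.unmethylated, initial=0
        ) < 0:
            raise ValidationError("negative intensity")
        finite_p = self.detection_p[~np.isnan(self.detection_p)]
        if finite_p.size and (finite_p.min() < 0 or finite_p.max() > 1):
            raise ValidationError("detection p-value outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.probe_ids), len(self.sample_ids)


@dataclass
class ProbeAnnotation:
    """Per-probe metadata: design type, blacklist flags, platform presence.

    Backed by a DataFrame indexed by probe_id with columns ``design_type``
    ("I"/"II"), ``snp_affected``, ``cross_hybridizing`` (bool) and optional
    boolean platform columns (``platform_450k``, ``platform_epic``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate probe in annotation: {dup!r}")
        for col, default in (
            ("design_type", "II"),
            ("snp_affected", False),
            ("cross_hybridizing", False),
        ):
            if col not in self.table.columns:
                self.table[col] = default
        bad = set(self.table["design_type"].unique()) - {"I", "II"}
        if bad:
            raise ValidationError(f"unknown probe design type(s): {sorted(bad)}")

    def design_types(self, probe_ids: Sequence[str]) -> np.ndarray:
        """Design type per probe; raises on probes lacking a known type."""
        ser = self.table["design_type"].reindex(list(probe_ids))
        if ser.isna().any():
            missing = ser.index[ser.isna()].tolist()
            raise ValidationError(
                f"{len(missing)} probe(s) with unknown design type, e.g. {missing[:3]}"
            )
        return ser.to_numpy()

    def blacklist_flags(self, probe_ids: Sequence[str]) -> pd.DataFrame:
        """snp_affected / cross_hybridizing flags, NaN where unannotated."""
        return self.table[["snp_affected", "cross_hybridizing"]].reindex(list(probe_ids))


@dataclass
class SampleSheet:
    """Per-sample metadata driving harmonization, splits and statistics.

    Required columns: sample_id, age_value, age_unit, sex, dataset_id,
    group. ``chronological_age_dpc`` is filled by
    :func:`devclock.ages.harmonize_sheet`.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "age_value", "age_unit", "sex", "dataset_id", "group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing column(s): {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id: {dup!r}")
        units = set(self.table["age_unit"].dropna().unique())
        bad = units - {u.value for u in AgeUnit}
        if bad:
            raise ValidationError(f"unknown age_unit(s): {sorted(bad)}")
        sexes = set(self.table["sex"].dropna().unique())
        bad = sexes - {s.value for s in Sex}
        if bad:
            raise ValidationError(f"unknown sex value(s): {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ClockModel:
    """An age clock: intercept + sparse probe coefficients + output spec.

    ``coefficients`` holds only nonzero probe weights on the beta scale.
    ``output_unit`` and ``transform`` describe how the linear predictor
    maps to an age; ``horvath_log_linear`` is only meaningful for clocks
    calibrated in years.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    output_unit: OutputUnit = OutputUnit.DPC
    transform: Transform = Transform.IDENTITY
    transform_params: dict[str, float] = field(default_factory=dict)
    training_meta: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_unit = OutputUnit(self.output_unit)
        self.transform = Transform(self.transform)
        # An empty coefficient map is tolerated as the degenerate
        # intercept-only model (the over-shrunk limit of a penalized fit);
        # serialization and prediction refuse it.
        if self.transform is Transform.HORVATH_LOG_LINEAR:
            if self.output_unit is not OutputUnit.YEARS:
                raise ValidationError(
                    "horvath_log_linear transform requires output_unit=years"
                )
            self.transform_params.setdefault("adult_age", 20.0)

    @property
    def n_probes(self) -> int:
        return len(self.coefficients)

    @property
    def is_intercept_only(self) -> bool:
        return not self.coefficients

    def coefficient_series(self) -> pd.Series:
        return pd.Series(self.coefficients, dtype=float)


@dataclass
class PredictionResult:
    """One clock applied to one sample."""

    sample_id: str
    clock_name: str
    raw_score: float
    predicted_age_native: float
    predicted_age_dpc: float
    probe_coverage: float
    low_coverage: bool = False
    out_of_training_range: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.probe_coverage <= 1 + 1e-12):
            raise ValidationError(
                f"probe_coverage {self.probe_coverage} outside (0, 1]"
            )
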