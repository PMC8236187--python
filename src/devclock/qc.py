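"""Quality control and normalization for methylation-array data.

The pipeline mirrors standard array practice: detection-p filtering of
samples then probes, removal of blacklisted probes (SNP-affected or
cross-hybridizing), probe-type-aware quantile normalization of raw
intensities (with Type I/II background equalization), cross-dataset
probe intersection, and a dataset-stratified train/test split.

Detection-p filtering uses strict inequalities: a sample is dropped iff
strictly more than ``sample_frac_thresh`` of its probes fail
(p > ``p_thresh``), then a probe is dropped iff strictly more than
``probe_frac_thresh`` of the *retained* samples fail. Sample removal
precedes probe statistics so one bad sample cannot take probes with it;
the order is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import (
    BetaMatrix,
    IntensitySet,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)


@dataclass
class QCReport:
    """What was excluded, why, and under which thresholds."""

    samples_excluded: list[tuple[str, str]] = field(default_factory=list)
    probes_excluded: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_probes_before: int = 0
    n_probes_after: int = 0
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_samples_after != self.n_samples_before - len(self.samples_excluded):
            raise ValidationError("sample counts inconsistent with exclusions")
        if self.n_probes_after != self.n_probes_before - len(self.probes_excluded):
            raise ValidationError("probe counts inconsistent with exclusions")

    def to_dict(self) -> dict:
        return {
            "samples_excluded": [list(x) for x in self.samples_excluded],
            "probes_excluded": [list(x) for x in self.probes_excluded],
            "thresholds": self.thresholds,
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
            "n_probes_before": self.n_probes_before,
            "n_probes_after": self.n_probes_after,
            "warnings": self.warnings,
        }


@dataclass
class SplitAssignment:
    """Train/test assignment, stratified by dataset."""

    assignment: dict[str, str]
    fraction_train: float
    seed: int
    strata: dict[str, str]

    @property
    def train_ids(self) -> list[str]:
        return [s for s, a in self.assignment.items() if a == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [s for s, a in self.assignment.items() if a == "test"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.assignment),
                "split": list(self.assignment.values()),
                "dataset_id": [self.strata[s] for s in self.assignment],
            }
        )


def pfilter(
    det_p: BetaMatrix,
    sample_frac_thresh: float = 0.01,
    probe_frac_thresh: float = 0.01,
    p_thresh: float = 0.05,
    order: str = "samples_first",
) -> tuple[list[str], list[str], QCReport]:
    """Detection-p filtering of samples then probes (strict > thresholds)."""
    P = det_p.values
    if P.size == 0:
        raise ValidationError("empty detection-p matrix")
    if order not in ("samples_first", "probes_first"):
        raise ValueError(f"unknown order {order!r}")
    report = QCReport(
        thresholds={
            "sample_frac_thresh": sample_frac_thresh,
            "probe_frac_thresh": probe_frac_thresh,
            "p_thresh": p_thresh,
        },
        n_samples_before=len(det_p.sample_ids),
        n_probes_before=len(det_p.probe_ids),
    )
    fail = P > p_thresh

    def _filter_samples(probe_mask: np.ndarray) -> np.ndarray:
        frac = fail[probe_mask, :].mean(axis=0)
        keep = frac <= sample_frac_thresh
        for j in np.where(~keep)[0]:
            report.samples_excluded.append(
                (det_p.sample_ids[j], f"detection_p: {frac[j]:.4g} of probes failing")
            )
        return keep

    def _filter_probes(sample_mask: np.ndarray) -> np.ndarray:
        frac = fail[:, sample_mask].mean(axis=1)
        keep = frac <= probe_frac_thresh
        for i in np.where(~keep)[0]:
            report.probes_excluded.append(
                (det_p.probe_ids[i], f"detection_p: {frac[i]:.4g} of samples failing")
            )
        return keep

    all_probes = np.ones(P.shape[0], dtype=bool)
    all_samples = np.ones(P.shape[1], dtype=bool)
    if order == "samples_first":
        keep_samples = _filter_samples(all_probes)
        if not keep_samples.any():
            report.n_samples_after = 0
            report.n_probes_after = report.n_probes_before
            raise ValidationError(f"pfilter removed all samples; report: {report.to_dict()}")
        keep_probes = _filter_probes(keep_samples)
    else:
        keep_probes = _filter_probes(all_samples)
        keep_samples = _filter_samples(keep_probes)
        if not keep_samples.any():
            report.n_samples_after = 0
            report.n_probes_after = int(keep_probes.sum())
            raise ValidationError(f"pfilter removed all samples; report: {report.to_dict()}")
    retained_samples = [s for s, k in zip(det_p.sample_ids, keep_samples) if k]
    retained_probes = [p for p, k in zip(det_p.probe_ids, keep_probes) if k]
    report.n_samples_after = len(retained_samples)
    report.n_probes_after = len(retained_probes)
    report.validate()
    return retained_samples, retained_probes, report


def exclude_blacklisted(
    probes: list[str], annot: ProbeAnnotation
) -> tuple[list[str], QCReport]:
    """Drop probes flagged SNP-affected or cross-hybridizing.

    Probes absent from the annotation are retained with a warning.
    """
    flags = annot.blacklist_flags(probes)
    report = QCReport(n_probes_before=len(probes), n_samples_before=0)
    retained: list[str] = []
    n_unannotated = 0
    for probe, snp, xhyb in zip(
        probes, flags["snp_affected"], flags["cross_hybridizing"]
    ):
        if snp is None or (isinstance(snp, float) and math.isnan(snp)):
            n_unannotated += 1
            retained.append(probe)
            continue
        if bool(snp):
            report.probes_excluded.append((probe, "snp_affected"))
        elif bool(xhyb):
            report.probes_excluded.append((probe, "cross_hybridizing"))
        else:
            retained.append(probe)
    if n_unannotated:
        msg = f"{n_unannotated} probe(s) absent from annotation; retained"
        report.warnings.append(msg)
        warnings.warn(msg)
    report.n_probes_after = len(retained)
    report.validate()
    return retained, report


def quantile_normalize_columns(X: np.ndarray) -> np.ndarray:
    """Between-sample quantile normalization of the columns of ``X``.

    Every column's sorted values are replaced by the across-column mean of
    order statistics; ties within a column receive the average of the
    reference values at their tied ranks (average-rank convention,
    interpolated for fractional ranks).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 0:
        return X.copy()
    ref = np.sort(X, axis=0).mean(axis=1)
    ranks = rankdata(X, axis=0, method="average")
    return np.interp(ranks, np.arange(1, n + 1), ref)


def _smooth_offsets(offsets: np.ndarray) -> np.ndarray:
    """Linear fit of per-sample offsets against sample index (fitted values)."""
    n = offsets.size
    if n < 3:
        return np.full(n, offsets.mean())
    x = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(x, offsets, 1)
    return intercept + slope * x


def dasen_normalize(
    intens: IntensitySet,
    annot: ProbeAnnotation,
    beta_offset: float = 100.0,
    background_quantile: float = 0.05,
    smooth: bool = True,
) -> BetaMatrix:
    """Probe-type-aware quantile normalization of raw intensities.

    Three steps: (1) background equalization — per sample, Type II
    methylated and unmethylated intensities are shifted by the offset that
    equates their ``background_quantile`` (default 5th percentile) with
    that of Type I, the offsets smoothed by a linear fit across sample
    index; (2) four independent between-sample quantile normalizations
    (methylated and unmethylated, separately within Type I and within
    Type II); (3) beta = M / (M + U + ``beta_offset``).

    Negative intensities produced by the background shift are clamped to
    zero (count reported via a warning).
    """
    if len(intens.sample_ids) < 2:
        raise ValidationError("dasen_normalize needs >= 2 samples")
    design = annot.design_types(intens.probe_ids)
    type1 = design == "I"
    type2 = design == "II"
    M = intens.methylated.copy()
    U = intens.unmethylated.copy()

    n_clamped = 0
    if type1.any() and type2.any():
        for X in (M, U):
            q1 = np.quantile(X[type1, :], background_quantile, axis=0)
            q2 = np.quantile(X[type2, :], background_quantile, axis=0)
            offsets = q1 - q2
            if smooth:
                offsets = _smooth_offsets(offsets)
            X[type2, :] += offsets[np.newaxis, :]
            neg = X < 0
            n_clamped += int(neg.sum())
            X[neg] = 0.0
    if n_clamped:
        warnings.warn(f"dasen: clamped {n_clamped} negative intensities to 0")

    for mask in (type1, type2):
        if mask.sum() >= 1:
            M[mask, :] = quantile_normalize_columns(M[mask, :])
            U[mask, :] = quantile_normalize_columns(U[mask, :])

    beta = M / (M + U + beta_offset)
    return BetaMatrix(intens.probe_ids, intens.sample_ids, beta)


def beta_quantile_normalize(
    betas: BetaMatrix, annot: ProbeAnnotation
) -> BetaMatrix:
    """Between-sample quantile normalization of beta values within each
    probe design type — the fallback when only processed betas exist."""
    if len(betas.sample_ids) < 2:
        warnings.warn("single sample: beta quantile normalization is the identity")
        return BetaMatrix(betas.probe_ids, betas.sample_ids, betas.values.copy())
    design = annot.design_types(betas.probe_ids)
    out = betas.values.copy()
    for dt in ("I", "II"):
        mask = design == dt
        if mask.sum() >= 1:
            out[mask, :] = quantile_normalize_columns(out[mask, :])
    return BetaMatrix(betas.probe_ids, betas.sample_ids, out)


def intersect_probes(
    matrices: list[BetaMatrix],
) -> tuple[list[str], list[BetaMatrix]]:
    """Probes present — and fully observed — in every matrix.

    Returned in the order of the first matrix; all matrices are subsetted
    and row-aligned to the common list.
    """
    if not matrices:
        raise ValidationError("no matrices given")
    common: set[str] | None = None
    for m in matrices:
        observed = {
            p
            for p, fully in zip(m.probe_ids, ~np.isnan(m.values).any(axis=1))
            if fully
        }
        common = observed if common is None else common & observed
    ordered = [p for p in matrices[0].probe_ids if p in common]
    if not ordered:
        raise ValidationError("empty probe intersection")
    return ordered, [m.subset_probes(ordered) for m in matrices]


def stratified_split(
    sheet: SampleSheet, fraction_train: float = 0.75, seed: int = 0
) -> SplitAssignment:
    """Random train/test split within each dataset stratum.

    Train count per stratum is floor(fraction × n), plus one when the
    fractional part is ≥ 0.5 (round-half-up). Deterministic given seed;
    a stratum of size 1 goes entirely to train with a warning.
    """
    table = sheet.table
    if table["dataset_id"].isna().any():
        raise ValidationError("dataset_id required for all samples")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    strata: dict[str, str] = {}
    for dataset in sorted(table["dataset_id"].astype(str).unique()):
        ids = table.loc[table["dataset_id"].astype(str) == dataset, "sample_id"].tolist()
        n = len(ids)
        t = fraction_train * n
        n_train = math.floor(t)
        if t - n_train >= 0.5 - 1e-12:
            n_train += 1
        if n == 1:
            warnings.warn(f"stratum {dataset!r} has a single sample; assigned to train")
            n_train = 1
        perm = rng.permutation(n)
        for k, idx in enumerate(perm):
            assignment[ids[idx]] = "train" if k < n_train else "test"
            strata[ids[idx]] = dataset
    # restore sheet order for readability
    assignment = {s: assignment[s] for s in table["sample_id"]}
    strata = {s: strata[s] for s in table["sample_id"]}
    return SplitAssignment(assignment, fraction_train, seed, strata)
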