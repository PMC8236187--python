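"""Apply age clocks to beta matrices.

Any :class:`~devclock.datamodel.ClockModel` — freshly trained or a
published coefficient set — is applied the same way: the linear
predictor intercept + Σ coefⱼ·betaⱼ over the clock's probes, then the
clock's output transform and a conversion of the native prediction to
days post-conception.

Cross-platform probe loss is a real hazard (a 450K-trained clock applied
to EPIC data, or vice versa, can miss probes), so the missing-probe
policy is explicit and defaults to ``fail``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import ages
from .datamodel import (
    BetaMatrix,
    ClockModel,
    PredictionResult,
    SampleSheet,
    Transform,
    ValidationError,
)


_UNIT_MAP = {"dpc": "dpc", "years": "years", "weeks_ga": "weeks_pc"}


def _native_to_dpc(value: float, clock: ClockModel) -> float:
    return float(ages.to_dpc(value, _UNIT_MAP[clock.output_unit.value]))


def predict_age(
    betas: BetaMatrix,
    clock: ClockModel,
    missing_policy: str = "fail",
    reference_means: Mapping[str, float] | None = None,
    coverage_floor: float = 0.8,
) -> list[PredictionResult]:
    """Predict each sample's age with one clock.

    missing_policy:
        "fail"        — any absent clock probe aborts;
        "mean_impute" — absent probes contribute ``reference_means[probe]``
                        (0.5 when no reference is supplied);
        "drop"        — absent probes are omitted from the sum.

    Missing *values* (NaN) at present probes are handled by the same
    policy. Coverage below ``coverage_floor`` flags the result (never
    silently); predictions outside the clock's training age range are
    flagged when the clock carries that metadata.
    """
    if missing_policy not in ("fail", "mean_impute", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if clock.is_intercept_only:
        raise ValidationError(f"clock {clock.name!r} has no probe coefficients")
    probe_index = pd.Index(betas.probe_ids)
    clock_probes = list(clock.coefficients)
    locs = probe_index.get_indexer(clock_probes)
    present = locs >= 0
    if not present.any():
        raise ValidationError(
            f"none of clock {clock.name!r}'s {len(clock_probes)} probes are present"
        )
    if missing_policy == "fail" and not present.all():
        absent = [p for p, ok in zip(clock_probes, present) if not ok]
        raise ValidationError(
            f"clock {clock.name!r}: {len(absent)} probe(s) absent, e.g. {absent[:5]} "
            "(missing_policy='fail')"
        )
    coefs = np.array([clock.coefficients[p] for p in clock_probes])
    n_samples = len(betas.sample_ids)
    B = np.empty((len(clock_probes), n_samples))
    for k, (loc, probe) in enumerate(zip(locs, clock_probes)):
        if loc >= 0:
            B[k] = betas.values[loc]
        else:
            B[k] = np.nan
    observed = ~np.isnan(B)  # per probe × sample

    results: list[PredictionResult] = []
    tmin = clock.training_meta.get("train_age_min_dpc")
    tmax = clock.training_meta.get("train_age_max_dpc")
    for j, sample in enumerate(betas.sample_ids):
        obs = observed[:, j]
        coverage = float(obs.mean())
        if coverage == 0:
            raise ValidationError(
                f"sample {sample!r}: no observed clock probes for {clock.name!r}"
            )
        if missing_policy == "fail" and not obs.all():
            raise ValidationError(
                f"sample {sample!r}: missing beta at clock probe(s) "
                f"(missing_policy='fail')"
            )
        b = B[:, j].copy()
        if missing_policy == "mean_impute":
            for k, probe in enumerate(clock_probes):
                if not obs[k]:
                    b[k] = (
                        reference_means.get(probe, 0.5)
                        if reference_means is not None
                        else 0.5
                    )
            score = clock.intercept + float(coefs @ b)
        else:  # drop (or fail with full coverage)
            score = clock.intercept + float(coefs[obs] @ b[obs])
        if clock.transform is Transform.HORVATH_LOG_LINEAR:
            native = ages.horvath_anti_transform(
                score, clock.transform_params.get("adult_age", 20.0)
            )
        else:
            native = score
        dpc = _native_to_dpc(native, clock)
        out_of_range = bool(
            tmin is not None and tmax is not None and not (tmin <= dpc <= tmax)
        )
        results.append(
            PredictionResult(
                sample_id=sample,
                clock_name=clock.name,
                raw_score=score,
                predicted_age_native=float(native),
                predicted_age_dpc=dpc,
                probe_coverage=coverage,
                low_coverage=coverage < coverage_floor,
                out_of_training_range=out_of_range,
            )
        )
    return results


def predictions_to_frame(results: Iterable[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "clock_name": r.clock_name,
                "raw_score": r.raw_score,
                "predicted_age_native": r.predicted_age_native,
                "predicted_age_dpc": r.predicted_age_dpc,
                "probe_coverage": r.probe_coverage,
                "low_coverage": r.low_coverage,
                "out_of_training_range": r.out_of_training_range,
            }
            for r in results
        ]
    )


def batch_predict(
    datasets: list[tuple[BetaMatrix, SampleSheet]],
    clocks: list[ClockModel],
    missing_policy: str = "fail",
    reference_means: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Apply every clock to every dataset; one long-format table.

    A clock failing on one dataset (e.g. platform probe loss under
    missing_policy='fail') is recorded in the table's ``error`` column
    without aborting the other clock × dataset blocks.
    """
    blocks: list[pd.DataFrame] = []
    for betas, sheet in datasets:
        meta = sheet.table.set_index("sample_id")
        for clock in clocks:
            try:
                frame = predictions_to_frame(
                    predict_age(
                        betas,
                        clock,
                        missing_policy=missing_policy,
                        reference_means=reference_means,
                    )
                )
            except (ValidationError, ValueError) as exc:
                blocks.append(
                    pd.DataFrame(
                        {
                            "sample_id": betas.sample_ids,
                            "clock_name": clock.name,
                            "error": str(exc),
                        }
                    )
                )
                continue
            frame["dataset_id"] = meta["dataset_id"].reindex(frame["sample_id"]).to_numpy()
            frame["group"] = meta["group"].reindex(frame["sample_id"]).to_numpy()
            if "chronological_age_dpc" in meta.columns:
                frame["chronological_age_dpc"] = (
                    meta["chronological_age_dpc"].reindex(frame["sample_id"]).to_numpy()
                )
            frame["error"] = ""
            blocks.append(frame)
    return pd.concat(blocks, ignore_index=True)
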