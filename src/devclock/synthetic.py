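"""Synthetic methylation datasets with the structure clock fitting assumes.

Two generators:

* :func:`simulate_age_dataset` emulates an age-structured fetal-brain
  beta matrix: a minority of probes carry a linear age signal on the
  logit scale (so betas stay inside (0, 1) without clipping), the rest
  are age-flat; Gaussian logit-scale noise on top; matched methylated /
  unmethylated intensities whose recomputed beta reproduces the stored
  one exactly; detection p-values with a configurable failure rate; and
  optional per-dataset platform masks emulating 450K/EPIC probe subsets.

* :func:`simulate_cellstage_datasets` emulates a multi-dataset stem-cell
  panel: per-stage true mean predicted ages plus a per-dataset random
  intercept plus residual noise — exactly the generative model the
  random-intercept meta-analysis assumes. Default stage means are the
  observed cellular means (iPSC 75.6, NPC 79.1, neuron 83.2 dpc) and the
  default per-dataset availability reproduces the pooled design of
  30 iPSC / 4 NPC / 48 neuron samples over five datasets.

Sample-level and probe-level draws use separate seeds so probe truth can
be held fixed across replicates. Everything is deterministic given the
spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import BetaMatrix, IntensitySet, SampleSheet, ValidationError

DEFAULT_AGE_RANGE_DPC = (37.0, 185.0)  # the fetal training window
DEFAULT_STAGE_MEANS_DPC = {"iPSC": 75.6, "NPC": 79.1, "neuron": 83.2}
# five-dataset availability summing to the pooled 30 iPSC / 4 NPC / 48 neurons
DEFAULT_STAGE_AVAILABILITY = {
    "ds1": {"iPSC": 4, "NPC": 2, "neuron": 12},
    "ds2": {"iPSC": 8, "NPC": 2},
    "ds3": {"iPSC": 6, "neuron": 12},
    "ds4": {"iPSC": 8, "neuron": 14},
    "ds5": {"iPSC": 4, "neuron": 10},
}


@dataclass
class SimSpec:
    """Generative settings for an age-structured methylation dataset.

    effect_scale is the typical |logit slope| per dpc of an age probe
    (individual slopes draw magnitude U(0.5, 1.5)·effect_scale and a
    random sign); noise_sd is the logit-scale measurement noise. The
    default age range mirrors a fetal training window so extrapolation
    tests can deliberately exceed it.
    """

    n_samples: int = 200
    n_probes: int = 2000
    n_age_probes: int = 50
    age_range_dpc: tuple[float, float] = DEFAULT_AGE_RANGE_DPC
    effect_scale: float = 0.002
    noise_sd: float = 0.02
    fraction_type1: float = 0.3
    sex_slope_factor: float = 0.0
    detection_fail_rate: float = 0.001
    platform_masks: dict[str, np.ndarray] | None = None
    beta_offset: float = 100.0
    depth_log_mean: float = np.log(8000.0)
    depth_log_sd: float = 0.2
    seed: int = 0
    probe_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_probes <= 0 or self.n_age_probes < 0:
            raise ValidationError("counts must be positive")
        if self.n_age_probes > self.n_probes:
            raise ValidationError("n_age_probes > n_probes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass
class CellStageSimSpec:
    """Generative settings for a multi-dataset cell-stage panel."""

    n_datasets: int = 5
    stage_means_dpc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MEANS_DPC)
    )
    dataset_intercept_sd: float = 5.0
    residual_sd: float = 7.0
    stage_availability: dict[str, dict[str, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.stage_means_dpc.values()):
            raise ValidationError("stage means must be positive")
        if self.dataset_intercept_sd < 0 or self.residual_sd < 0:
            raise ValidationError("sds must be >= 0")


def simulate_age_dataset(
    spec: SimSpec,
) -> tuple[BetaMatrix, IntensitySet, SampleSheet, pd.DataFrame]:
    """Draw one dataset: betas, intensities, sample sheet, probe truth.

    Probe model: logit(mean betaᵢⱼ) = aⱼ + sⱼ·(ageᵢ − mean age) with
    aⱼ ~ U(logit 0.2, logit 0.8); sⱼ = 0 for null probes. Observed
    logit adds N(0, noise_sd). Intensities satisfy
    M/(M + U + beta_offset) = beta exactly, with U = (1 − beta)·T for a
    lognormal per-sample depth T and M solving the beta identity; both
    are non-negative for any beta in (0, 1).
    """
    probe_rng = np.random.default_rng(
        spec.seed if spec.probe_seed is None else spec.probe_seed
    )
    rng = np.random.default_rng(spec.seed)
    p, n = spec.n_probes, spec.n_samples

    probe_ids = [f"cg{j:08d}" for j in range(p)]
    sample_ids = [f"sim{i:04d}" for i in range(n)]

    # probe-level truth
    intercepts = probe_rng.uniform(logit(0.2), logit(0.8), size=p)
    slopes = np.zeros(p)
    age_idx = probe_rng.choice(p, size=spec.n_age_probes, replace=False)
    magnitudes = probe_rng.uniform(0.5, 1.5, size=spec.n_age_probes) * spec.effect_scale
    signs = probe_rng.choice([-1.0, 1.0], size=spec.n_age_probes)
    slopes[age_idx] = magnitudes * signs
    design_type = np.where(
        probe_rng.uniform(size=p) < spec.fraction_type1, "I", "II"
    )

    # sample-level draws
    lo, hi = spec.age_range_dpc
    ages = rng.uniform(lo, hi, size=n)
    sex = rng.choice(["female", "male"], size=n)
    age_c = ages - ages.mean()
    slope_matrix = np.broadcast_to(slopes[:, None], (p, n)).copy()
    if spec.sex_slope_factor:
        male = sex == "male"
        slope_matrix[:, male] *= 1.0 + spec.sex_slope_factor
    mean_logit = intercepts[:, None] + slope_matrix * age_c[None, :]
    obs_logit = mean_logit + rng.normal(0.0, spec.noise_sd, size=(p, n))
    beta = expit(obs_logit)

    depth = np.exp(rng.normal(spec.depth_log_mean, spec.depth_log_sd, size=n))
    # non-negative for any beta in (0,1) and exactly invertible:
    # M/(M + U + offset) = beta with U = (1-beta)·T, M = beta·(U + offset)/(1-beta)
    U = (1.0 - beta) * depth[None, :]
    M = beta * (U + spec.beta_offset) / (1.0 - beta)

    det_p = rng.uniform(0.0, 0.01, size=(p, n))
    fails = rng.uniform(size=(p, n)) < spec.detection_fail_rate
    det_p[fails] = rng.uniform(0.05, 1.0, size=int(fails.sum()))

    dataset_ids = np.full(n, "sim", dtype=object)
    beta_out = beta.copy()
    if spec.platform_masks:
        names = list(spec.platform_masks)
        for key, mask in spec.platform_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (p,):
                raise ValidationError(
                    f"platform mask {key!r} has shape {mask.shape}, expected ({p},)"
                )
        dataset_ids = np.array([names[i % len(names)] for i in range(n)], dtype=object)
        for key, mask in spec.platform_masks.items():
            cols = dataset_ids == key
            beta_out[np.ix_(~np.asarray(mask, dtype=bool), cols)] = np.nan

    betas = BetaMatrix(probe_ids, sample_ids, beta_out)
    intens = IntensitySet(probe_ids, sample_ids, M, U, det_p)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age_value": ages,
                "age_unit": "dpc",
                "sex": sex,
                "dataset_id": dataset_ids,
                "group": "fetal_brain",
                "chronological_age_dpc": ages,
            }
        )
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_age_probe": np.isin(np.arange(p), age_idx),
            "intercept_logit": intercepts,
            "slope_per_dpc": slopes,
            "design_type": design_type,
        }
    )
    return betas, intens, sheet, truth


def truth_annotation(truth: pd.DataFrame):
    """ProbeAnnotation matching a simulated truth table (no blacklist)."""
    from .datamodel import ProbeAnnotation

    table = truth.set_index("probe_id")[["design_type"]].copy()
    table["snp_affected"] = False
    table["cross_hybridizing"] = False
    return ProbeAnnotation(table)


def simulate_cellstage_datasets(
    spec: CellStageSimSpec,
) -> tuple[pd.DataFrame, dict]:
    """Draw a multi-dataset panel of predicted ages by cell stage.

    predicted_age_dpc = stage mean + dataset intercept (N(0, sd²)) +
    residual (N(0, sd²)). Returns the long table consumed by the
    group-statistics module and a truth record of the generating
    parameters.
    """
    rng = np.random.default_rng(spec.seed)
    availability = spec.stage_availability
    if availability is None:
        availability = {
            k: dict(v)
            for k, v in list(DEFAULT_STAGE_AVAILABILITY.items())[: spec.n_datasets]
        }
        if spec.n_datasets > len(DEFAULT_STAGE_AVAILABILITY):
            for extra in range(len(DEFAULT_STAGE_AVAILABILITY), spec.n_datasets):
                availability[f"ds{extra + 1}"] = {"iPSC": 4, "neuron": 6}
    rows = []
    intercepts = {}
    for dataset, stages in availability.items():
        u = float(rng.normal(0.0, spec.dataset_intercept_sd))
        intercepts[dataset] = u
        for stage, count in stages.items():
            if stage not in spec.stage_means_dpc:
                raise ValidationError(f"no mean specified for stage {stage!r}")
            mu = spec.stage_means_dpc[stage]
            values = mu + u + rng.normal(0.0, spec.residual_sd, size=count)
            for k, v in enumerate(values):
                rows.append(
                    {
                        "sample_id": f"{dataset}_{stage}_{k}",
                        "dataset_id": dataset,
                        "group": stage,
                        "predicted_age_dpc": float(v),
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "stage_means_dpc": dict(spec.stage_means_dpc),
        "dataset_intercepts": intercepts,
        "dataset_intercept_sd": spec.dataset_intercept_sd,
        "residual_sd": spec.residual_sd,
        "seed": spec.seed,
    }
    return table, truth
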