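"""End-to-end workflow runner: simulate → qc → split → train → predict →
evaluate → compare-stages, driven by a structured config.

All randomness flows from one top-level seed, expanded into per-step
seeds that are recorded in the run log, so re-running with an identical
config and inputs reproduces every output byte-for-byte. Each step
writes its outputs before the next starts; a mid-pipeline failure
leaves earlier outputs intact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ages, apply as apply_mod, evaluate as eval_mod
from . import groupstats, io as io_mod, qc as qc_mod, synthetic, train as train_mod
from .datamodel import IntensitySet, ValidationError, matrix_container

KNOWN_STEPS = (
    "simulate",
    "simulate_stages",
    "qc",
    "split",
    "train",
    "predict",
    "evaluate",
    "compare_stages",
)


def derive_step_seeds(seed: int, steps: list[str]) -> dict[str, int]:
    """Expand one top-level seed into a recorded per-step seed map."""
    rng = np.random.default_rng(seed)
    return {step: int(rng.integers(0, 2**31 - 1)) for step in steps}


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the steps named in ``config["steps"]`` in order.

    Unknown step names and missing input files fail before any step
    runs. Returns the output directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    steps: list[str] = list(config.get("steps", []))
    unknown = [s for s in steps if s not in KNOWN_STEPS]
    if unknown:
        raise ValidationError(f"unknown step(s): {unknown}; known: {list(KNOWN_STEPS)}")
    out = Path(outdir or config.get("outdir", "devclock_out"))
    missing = [
        str(p)
        for key in ("betas", "meth", "unmeth", "detp", "sheet", "annot", "clock")
        for p in [config.get("inputs", {}).get(key)]
        if p is not None and not Path(p).exists()
    ]
    if missing:
        raise ValidationError(f"input file(s) not found: {missing}")
    out.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    step_seeds = derive_step_seeds(seed, steps)
    _write_json(
        {
            "devclock_version": __version__,
            "seed": seed,
            "step_seeds": step_seeds,
            "config": config,
        },
        out / "run_log.json",
    )

    state: dict = {}
    inputs = config.get("inputs", {})
    if "betas" in inputs:
        state["betas"] = io_mod.read_matrix(inputs["betas"], kind="beta")
    if "sheet" in inputs:
        state["sheet"] = ages.harmonize_sheet(io_mod.read_sample_sheet(inputs["sheet"]))
    if "annot" in inputs:
        state["annot"] = io_mod.read_annotation(inputs["annot"])
    if "detp" in inputs:
        state["detp"] = io_mod.read_matrix(inputs["detp"], kind="detection_p")
    if "meth" in inputs and "unmeth" in inputs:
        m = io_mod.read_matrix(inputs["meth"], kind="intensity")
        u = io_mod.read_matrix(inputs["unmeth"], kind="intensity")
        dp = state.get("detp")
        state["intens"] = IntensitySet(
            m.probe_ids,
            m.sample_ids,
            m.values,
            u.values,
            dp.values if dp is not None else np.zeros_like(m.values),
        )
    if "clock" in inputs:
        state["clocks"] = [io_mod.read_clock(inputs["clock"])]

    for step in steps:
        _run_step(step, config.get(step, {}) or {}, state, out, step_seeds[step])
    return out


def _run_step(step: str, params: dict, state: dict, out: Path, seed: int) -> None:
    if step == "simulate":
        spec = synthetic.SimSpec(seed=seed, **params)
        betas, intens, sheet, truth = synthetic.simulate_age_dataset(spec)
        state.update(
            betas=betas,
            intens=intens,
            sheet=sheet,
            truth=truth,
            annot=synthetic.truth_annotation(truth),
            detp=matrix_container(
                intens.probe_ids, intens.sample_ids, intens.detection_p
            ),
        )
        io_mod.write_matrix(betas, out / "simulated_betas.tsv")
        io_mod.write_sample_sheet(sheet, out / "sample_sheet.csv")
        truth.to_csv(out / "probe_truth.tsv", sep="\t", index=False, float_format="%.17g")
        io_mod.write_annotation(state["annot"], out / "probe_annotation.tsv")
    elif step == "simulate_stages":
        spec = synthetic.CellStageSimSpec(seed=seed, **params)
        table, truth = synthetic.simulate_cellstage_datasets(spec)
        state["stage_table"] = table
        table.to_csv(out / "stage_predictions.tsv", sep="\t", index=False, float_format="%.17g")
        _write_json(truth, out / "stage_truth.json")
    elif step == "qc":
        betas, annot = state["betas"], state["annot"]
        report = qc_mod.QCReport()
        if state.get("detp") is not None:
            keep_s, keep_p, report = qc_mod.pfilter(
                state["detp"],
                sample_frac_thresh=params.get("sample_frac_thresh", 0.01),
                probe_frac_thresh=params.get("probe_frac_thresh", 0.01),
                p_thresh=params.get("p_thresh", 0.05),
            )
            betas = betas.subset_probes(keep_p).subset_samples(keep_s)
        retained, bl_report = qc_mod.exclude_blacklisted(betas.probe_ids, annot)
        report.probes_excluded += bl_report.probes_excluded
        report.n_probes_after = len(retained)
        betas = betas.subset_probes(retained)
        if state.get("intens") is not None and params.get("normalize", "dasen") == "dasen":
            intens = state["intens"]
            idx = pd.Index(intens.probe_ids).get_indexer(betas.probe_ids)
            jdx = pd.Index(intens.sample_ids).get_indexer(betas.sample_ids)
            intens = IntensitySet(
                betas.probe_ids,
                betas.sample_ids,
                intens.methylated[np.ix_(idx, jdx)],
                intens.unmethylated[np.ix_(idx, jdx)],
                intens.detection_p[np.ix_(idx, jdx)],
            )
            betas = qc_mod.dasen_normalize(
                intens, annot, beta_offset=params.get("beta_offset", 100.0)
            )
        else:
            betas = qc_mod.beta_quantile_normalize(betas, annot)
        state["betas"] = betas
        io_mod.write_matrix(betas, out / "normalized_betas.tsv")
        _write_json(report.to_dict(), out / "qc_report.json")
    elif step == "split":
        split = qc_mod.stratified_split(
            state["sheet"], fraction_train=params.get("fraction_train", 0.75), seed=seed
        )
        state["split"] = split
        split.to_frame().to_csv(out / "split.csv", index=False)
    elif step == "train":
        betas, sheet = state["betas"], state["sheet"]
        if "split" in state:
            train_ids = [s for s in state["split"].train_ids if s in betas.sample_ids]
        else:
            train_ids = betas.sample_ids
        params = dict(params)
        sub = betas.subset_samples(train_ids)
        sub = train_mod.impute_missing(sub, params.pop("impute", "probe_mean"))
        meta = sheet.table.set_index("sample_id")
        y = meta["chronological_age_dpc"].reindex(train_ids).to_numpy(dtype=float)
        cfg = train_mod.TrainConfig(seed=seed, **params)
        model, diag = train_mod.fit_elastic_net_clock(sub, y, cfg, name="trained_clock")
        state["clocks"] = [model]
        state["diagnostics"] = diag
        io_mod.write_clock(model, out / "clock.tsv")
        _write_json(
            {
                "selected_lambda": diag.selected_lambda,
                "n_nonzero": diag.n_nonzero,
                "lambda_grid": diag.lambda_grid.tolist(),
                "cv_mse_mean": diag.cv_mse_mean.tolist(),
                "cv_mse_se": diag.cv_mse_se.tolist(),
                "seed": diag.seed,
            },
            out / "train_diagnostics.json",
        )
    elif step == "predict":
        betas, sheet = state["betas"], state["sheet"]
        if params.get("subset") == "test" and "split" in state:
            ids = [s for s in state["split"].test_ids if s in betas.sample_ids]
            betas = betas.subset_samples(ids)
        betas = train_mod.impute_missing(betas, params.get("impute", "probe_mean"))
        table = apply_mod.batch_predict(
            [(betas, sheet)],
            state["clocks"],
            missing_policy=params.get("missing_policy", "fail"),
        )
        state["predictions"] = table
        table.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.17g")
    elif step == "evaluate":
        table = state["predictions"]
        report = eval_mod.evaluation_table(
            table.loc[table["error"] == ""], max_dpc=params.get("max_dpc")
        )
        state["evaluation"] = report
        report.to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format="%.17g")
        _write_json(report.to_dict(orient="records"), out / "evaluation.json")
    elif step == "compare_stages":
        table = state.get("stage_table", state.get("predictions"))
        if table is None:
            raise ValidationError("compare_stages needs predictions or a stage table")
        contrasts = groupstats.per_dataset_contrasts(
            table, reference=params.get("reference", "iPSC")
        )
        contrasts.to_csv(out / "stage_contrasts.tsv", sep="\t", index=False, float_format="%.17g")
        fit = groupstats.stage_meta_analysis(
            table, reference=params.get("reference", "iPSC")
        )
        state["meta_fit"] = fit
        _write_json(
            {
                "fixed_effects": fit.fixed_effects,
                "std_errors": fit.std_errors,
                "pvalues": fit.pvalues,
                "random_intercept_var": fit.random_intercept_var,
                "residual_var": fit.residual_var,
                "n": fit.n,
                "n_datasets": fit.n_datasets,
                "converged": fit.converged,
                "method": fit.method,
            },
            out / "stage_meta_analysis.json",
        )
    else:  # pragma: no cover - guarded upstream
        raise ValidationError(f"unknown step {step!r}")
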