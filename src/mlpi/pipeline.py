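"""End-to-end driver: phantoms (or loaded cases) through tuning, maps, Relief.

``run_pipeline`` executes every stage on a synthetic cohort — PI
simulation, feature extraction, synthetic-biopsy augmentation, grid
tuning, model comparison, per-patient density maps, and Relief
attribution — writing each artifact plus a JSON manifest (config hash,
seed, package version) that suffices to replay the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .evaluation import (
    TuningGrid,
    compare_models,
    evaluate_grid,
    select_partial_uniform,
    select_patient_specific,
    select_uniform,
)
from .io import write_case_dir, write_density
from .relief import relief_for_cohort
from .ssl_core import fit_mlpi, predict_density_map
from .synthetic import CHANNEL_NAMES, cohort_from_cases, generate_cohort

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_patients: int = 6
    n_biopsies_min: int = 4
    n_biopsies_max: int = 8
    blend_weight: float = 0.5
    grid_size: int = 64
    margin: float = 0.05
    box_edge: int = 8
    coarse_grid: bool = True
    max_unlabeled_per_patient: int = 25
    relief_r: int = 10
    relief_tau: float = 0.05
    strategies: list[str] = ["patient_specific", "uniform"]
    write_maps: bool = True
    write_cases: bool = False
    out_dir: str = "mlpi_run"

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _select(ev, strategy, margin):
    if strategy == "patient_specific":
        return select_patient_specific(ev, margin)
    if strategy == "uniform":
        return select_uniform(ev, margin)
    if strategy.startswith("partial:"):
        return select_partial_uniform(ev, strategy.split(":", 1)[1], margin)
    raise ValueError(f"unknown strategy {strategy!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; artifacts land under ``config.out_dir``.

    Any stage failure aborts with the stage name; artifacts written so far
    are preserved for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.model_dump(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    results: dict = {"manifest": manifest}
    stage = "synthesize"
    try:
        cases = generate_cohort(
            config.n_patients, config.seed,
            per_patient_biopsy_range=(config.n_biopsies_min, config.n_biopsies_max),
            blend_weight=config.blend_weight, grid_size=config.grid_size,
        )
        if config.write_cases:
            for case in cases:
                write_case_dir(case, out / "cases" / case.patient_id)
        manifest["stages"].append(stage)

        stage = "features"
        cohort = cohort_from_cases(cases)
        rows = [
            {"patient_id": s.patient_id, "location": s.location, "y": s.y,
             "pi": s.pi, "is_synthetic": s.is_synthetic, "is_bat": s.is_bat}
            for pid in cohort.patient_ids for s in cohort.samples_by_patient[pid]
        ]
        pd.DataFrame(rows).to_csv(out / "samples.csv", index=False)
        manifest["stages"].append(stage)

        stage = "tuning"
        grid = TuningGrid.coarse() if config.coarse_grid else TuningGrid()
        ev = evaluate_grid(cohort, grid, max_unlabeled_per_patient=config.max_unlabeled_per_patient)
        tuning = {s: _select(ev, s, config.margin) for s in config.strategies}
        tuning_rows = []
        for s, res in tuning.items():
            for pid, (ga, gi, eta) in res.selected.items():
                tuning_rows.append({
                    "strategy": s, "patient_id": pid, "gamma_a": ga, "gamma_i": gi,
                    "eta": eta, "mape": res.per_patient_mape[pid],
                    "pearson": res.per_patient_pearson[pid],
                })
        pd.DataFrame(tuning_rows).to_csv(out / "tuning.csv", index=False)
        (out / "tuning.json").write_text(json.dumps(
            {s: {"pooled_mape": r.pooled_mape, "pooled_pearson": r.pooled_pearson,
                 "selected": {p: list(v) for p, v in r.selected.items()}}
             for s, r in tuning.items()}, indent=2))
        manifest["stages"].append(stage)

        stage = "comparison"
        table = compare_models(
            cohort, grid, margin=config.margin,
            max_unlabeled_per_patient=config.max_unlabeled_per_patient,
        )
        table.to_csv(out / "comparison.csv")
        results["comparison"] = table
        manifest["stages"].append(stage)

        stage = "maps"
        primary = tuning.get("patient_specific") or next(iter(tuning.values()))
        if config.write_maps:
            for case in cases:
                pid = case.patient_id
                ga, gi, eta = primary.selected[pid]
                labeled = [
                    s for other in cohort.patient_ids if other != pid
                    for s in cohort.training_labeled(other)
                ]
                unlabeled = [s for other in cohort.patient_ids for s in cohort.unlabeled(other)]
                model = fit_mlpi(labeled, unlabeled[: 25 * len(cohort.patient_ids)], ga, gi, eta)
                from .features import standardize_channels
                chans = standardize_channels(case.channels, case.tissue.brain_mask)
                field = predict_density_map(model, chans, case.pi_field, case.roi_mask)
                write_density(out / f"map_{pid}.nii.gz", field)
                save_density_png(out / f"map_{pid}.png", field)
        manifest["stages"].append(stage)

        stage = "relief"
        agg, per_patient = relief_for_cohort(
            cohort, primary, r=config.relief_r, tau=config.relief_tau,
            feature_names=CHANNEL_NAMES + ["PI"],
            max_unlabeled_per_patient=config.max_unlabeled_per_patient,
        )
        relief_df = pd.DataFrame({
            "feature": agg.feature_names,
            "aggregated_score": agg.raw,
            **{pid: sc.normalized for pid, sc in per_patient.items() if sc.normalized is not None},
        })
        relief_df.to_csv(out / "relief.csv", index=False)
        save_relief_png(out / "relief.png", agg)
        results["relief"] = agg
        manifest["stages"].append(stage)

        results["tuning"] = tuning
    except Exception:
        logger.exception("pipeline failed at stage %r; partial artifacts kept in %s", stage, out)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def save_density_png(path, field) -> None:
    """Density map with red = 100% density through blue = 0%."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = field.values if field.values.ndim == 2 else field.values[:, :, field.values.shape[2] // 2]
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(values.T, origin="lower", cmap="RdYlBu_r", vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, label="tumor cell density fraction")
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def save_relief_png(path, scores) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    order = np.argsort(scores.raw)[::-1]
    ax.bar([scores.feature_names[i] for i in order], scores.raw[order])
    ax.set_ylabel("aggregated contribution")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
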