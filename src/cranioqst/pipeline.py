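"""End-to-end pipeline: phantoms -> segmentation -> features -> two classifiers.

Mirrors the clinical workflow: acquire data (here: generate phantoms or
ingest NIfTI volumes), segment the seven tissue classes, extract the 34
clinical features, then classify each case twice — with the rule-based
clinical scale and with the fusion network — and report segmentation Dice
and both classification performances side by side.  Every run persists its
resolved configuration next to its outputs so results are reproducible
from config + seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .classifier import assemble_inputs, train_classifier
from .features import FEATURE_NAMES, ClinicalFeatureExtractor
from .label_schema import LabelMap, MRIVolume, read_volume, write_volume
from .metrics import classification_report, multiclass_dice
from .scale import QSTScaleClassifier, ScaleThresholds
from .segmentation import SwapUNetSegmenter, slices_from_cohort

log = logging.getLogger("cranioqst")

__all__ = ["PipelineConfig", "run_full", "write_cohort", "load_cohort"]


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    out_dir: str = "cranioqst_run"
    seed: int = 0
    n_phantoms: int = 30
    mixture: tuple = ph.DEFAULT_MIXTURE
    grid_shape: tuple = ph.DESK_GRID_SHAPE
    spacing: tuple = ph.DESK_SPACING
    input_dir: str | None = None        # ingest NIfTI pairs instead of phantoms
    use_reference_labels: bool = False  # skip segmentation training, use given maps
    seg_epochs: int = 30
    seg_train_fraction: float = 0.7
    cls_epochs: int = 20
    n_folds: int = 5
    thresholds: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        return asdict(self)


def write_cohort(cohort_with_specs, out_dir) -> pd.DataFrame:
    """Write a phantom cohort as paired NIfTI files plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (mri, lm, qst, spec) in enumerate(cohort_with_specs):
        mri_path = out / f"case{i:04d}_mri.nii.gz"
        lab_path = out / f"case{i:04d}_labels.nii.gz"
        write_volume(mri, mri_path)
        write_volume(lm, lab_path)
        row = {"case_id": f"case{i:04d}", "qst_type": str(qst),
               "mri": mri_path.name, "labels": lab_path.name}
        row.update({f"spec_{k}": v for k, v in asdict(spec).items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_cohort(in_dir):
    """Load (MRIVolume, LabelMap, type) triples from a manifest directory."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    cohort = []
    for _, row in manifest.iterrows():
        mri = read_volume(in_dir / row["mri"])
        lm = read_volume(in_dir / row["labels"], expect_labels=True)
        cohort.append((mri, lm, row["qst_type"]))
    return cohort


def run_full(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a run report dictionary.

    Stages: data -> (optional) segmentation training & evaluation ->
    feature extraction -> scale scoring and fusion classification (both
    always run and are reported side by side) -> metrics.  Each stage logs
    its seed and writes partial outputs before the next begins, so a
    failure leaves everything completed so far in ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh)
    report: dict = {"config": config.resolved()}

    # --- stage 1: data ----------------------------------------------------
    stage = "data"
    try:
        if config.input_dir:
            cohort = load_cohort(config.input_dir)
            log.info("loaded %d cases from %s", len(cohort), config.input_dir)
        else:
            cohort = ph.generate_cohort(
                config.n_phantoms, config.mixture, seed=config.seed,
                grid_shape=tuple(config.grid_shape), spacing=tuple(config.spacing),
            )
            log.info("generated %d phantoms (seed %d)", len(cohort), config.seed)

        # --- stage 2: segmentation ----------------------------------------
        stage = "segmentation"
        label_maps = [lm for _, lm, _ in cohort]
        if not config.use_reference_labels:
            n_train = max(1, int(round(config.seg_train_fraction * len(cohort))))
            seg = SwapUNetSegmenter(epochs=config.seg_epochs, random_state=config.seed)
            seg.fit(*slices_from_cohort(cohort[:n_train]))
            dice_rows = []
            pred_maps = []
            for mri, lm, _ in cohort:
                pred = seg.predict_volume(mri)
                pred_maps.append(pred)
                rep = multiclass_dice(pred, lm)
                dice_rows.append({**{f"dice_{c}": v for c, v in rep.per_class.items()},
                                  "dice_mean": rep.mean})
            dice_df = pd.DataFrame(dice_rows)
            dice_df.to_csv(out / "dice_report.csv", index=False)
            heldout = dice_df.iloc[n_train:]
            report["segmentation"] = {
                "n_train_cases": n_train,
                "heldout_tumor_dice": float(heldout["dice_1"].mean()),
                "heldout_mean_dice": float(heldout["dice_mean"].mean()),
                "loss_final": float(seg.loss_history_[-1]),
            }
            log.info("segmentation held-out tumor Dice %.3f",
                     report["segmentation"]["heldout_tumor_dice"])
        else:
            log.info("using provided label maps; segmentation training skipped")
            report["segmentation"] = {"skipped": True}

        # classification always proceeds from the reference label maps,
        # mirroring auto-segmentations augmented with expert modifications
        stage = "features"
        feats = ClinicalFeatureExtractor().fit().transform(label_maps)
        fdf = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
        fdf.insert(0, "case_id", [f"case{i:04d}" for i in range(len(label_maps))])
        fdf.to_csv(out / "features.csv", index=False)

        stage = "classification"
        y = np.asarray([str(t) for _, _, t in cohort])
        scale_pred = QSTScaleClassifier(
            thresholds=ScaleThresholds(**config.thresholds) if config.thresholds else None
        ).fit().predict(label_maps)
        scale_report = classification_report(y, scale_pred)

        images, clinical, _ = assemble_inputs(cohort)
        _, net_pred, net_report = train_classifier(
            images, clinical, y, n_folds=config.n_folds, seed=config.seed,
            epochs=config.cls_epochs,
        )
        pred_df = pd.DataFrame({
            "case_id": fdf["case_id"], "true": y,
            "scale_pred": scale_pred, "network_pred": net_pred,
        })
        pred_df[["p_Q", "p_S", "p_T"]] = net_report.probabilities
        pred_df.to_csv(out / "predictions.csv", index=False)
        comparison = pd.concat(
            [net_report.to_frame().assign(model="network"),
             scale_report.to_frame().assign(model="scale")]
        )
        comparison.to_csv(out / "classification_report.csv", index=False)
        report["classification"] = {
            "scale_accuracy": scale_report.overall_accuracy,
            "network_accuracy": net_report.overall_accuracy,
        }
        log.info("accuracy: scale %.3f, network %.3f",
                 scale_report.overall_accuracy, net_report.overall_accuracy)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
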