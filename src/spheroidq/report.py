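"""Cohort-level aggregation: per-condition averages and fold changes.

Each experimental condition is imaged for a handful of isolated spheroids
(biological replicates); per-spheroid measurements are averaged per
condition and expressed as fold changes against a reference condition
(ratio of condition means).  Repeated-measures designs additionally get a
per-batch paired table; inferential statistics are left to downstream
tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import quantify as _quantify
from . import regions as _regions
from . import stacks as _stacks

#: metrics whose summaries exclude images flagged "empty core"
RATIO_METRICS_PREFIXES = ("outgrowth_core_ratio", "pct_integrated_density")


@dataclass
class ConditionManifest:
    """Maps image files to experimental conditions and donor/batch ids."""

    table: pd.DataFrame  # columns: path, condition, batch, model_override

    def __post_init__(self):
        required = {"path", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest lacks required columns {sorted(missing)}")
        t = self.table.copy()
        if "batch" not in t.columns:
            t["batch"] = ""
        if "model_override" not in t.columns:
            t["model_override"] = ""
        t["batch"] = t["batch"].fillna("")
        t["model_override"] = t["model_override"].fillna("")
        if (t["condition"].astype(str).str.len() == 0).any():
            raise ValueError("empty condition labels in manifest")
        counts = t["condition"].value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ValueError(
                f"conditions with fewer than 2 images (replicates): "
                f"{sorted(thin.index.tolist())}"
            )
        self.table = t.reset_index(drop=True)

    @classmethod
    def read_csv(cls, path) -> "ConditionManifest":
        return cls(pd.read_csv(path))

    @property
    def conditions(self) -> list:
        return sorted(self.table["condition"].unique().tolist())


@dataclass
class ConditionSummary:
    """Per-condition n/mean/SD/SEM and fold changes vs. a reference.

    ``per_image`` retains the tidy per-spheroid table (with condition and
    batch columns) that the summary was computed from; ``exclusions`` lists
    (image id, reason) for images dropped from ratio/percentage averages.
    """

    summary: pd.DataFrame  # index (condition, metric); columns n/mean/sd/sem/fold_change
    per_image: pd.DataFrame
    reference: str
    exclusions: list = field(default_factory=list)


def _metric_columns(df: pd.DataFrame) -> list:
    skip = {"image_id", "path", "condition", "batch", "qc_flags"}
    return [c for c in df.columns if c not in skip and pd.api.types.is_numeric_dtype(df[c])]


def summarize_conditions(
    per_image: pd.DataFrame, reference: str, exclusions: list | None = None
) -> ConditionSummary:
    """Aggregate a per-image metric table into per-condition statistics."""
    if reference not in set(per_image["condition"]):
        raise ValueError(f"reference condition {reference!r} not present")
    rows = []
    for metric in _metric_columns(per_image):
        grouped = per_image.groupby("condition")[metric]
        stats = grouped.agg(n="count", mean="mean", sd="std", sem="sem")
        ref_mean = stats.loc[reference, "mean"]
        for cond, srow in stats.iterrows():
            fold = srow["mean"] / ref_mean if ref_mean and not np.isnan(ref_mean) else np.nan
            if cond == reference and ref_mean and not np.isnan(ref_mean):
                fold = 1.0  # exact by definition
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "n": int(srow["n"]),
                    "mean": srow["mean"],
                    "sd": srow["sd"],
                    "sem": srow["sem"],
                    "fold_change": fold,
                }
            )
    summary = pd.DataFrame(rows).set_index(["condition", "metric"]).sort_index()
    return ConditionSummary(
        summary=summary,
        per_image=per_image.reset_index(drop=True),
        reference=reference,
        exclusions=list(exclusions or []),
    )


def paired_summary(summary: ConditionSummary, metric: str, condition: str) -> pd.DataFrame:
    """Per-batch paired table of one metric: reference vs. one condition.

    Returns columns (batch, reference, condition, ratio); every batch id must
    be present in both conditions.  No p-value is computed.
    """
    df = summary.per_image
    ref = df[df["condition"] == summary.reference].set_index("batch")[metric]
    cond = df[df["condition"] == condition].set_index("batch")[metric]
    ref = ref.groupby(level=0).mean()
    cond = cond.groupby(level=0).mean()
    unmatched = sorted(set(ref.index).symmetric_difference(cond.index))
    if unmatched:
        raise ValueError(f"batch id(s) {unmatched} not present in both conditions")
    out = pd.DataFrame(
        {
            "batch": ref.index,
            "reference": ref.values,
            "condition": cond.reindex(ref.index).values,
        }
    )
    out["ratio"] = out["condition"] / out["reference"]
    return out.reset_index(drop=True)


def quantify_image(
    img: _stacks.ProjectedImage,
    model: "_classify.PixelClassifierModel | None",
    refine_config: "_regions.RefineConfig | None" = None,
    detection_params: "_quantify.DetectionParams | None" = None,
    detection_channel: str = "MACROPHAGE",
    threshold="otsu",
) -> tuple:
    """Segment, refine and measure one projected image.

    With a model, pixel classification is refined into regions; without one,
    the deterministic threshold fallback is used.  Returns
    ``(RegionLabelMap, RegionMetrics, CellDetections | None)``; detection is
    skipped when the image lacks the detection channel.
    """
    if model is not None:
        raw, _ = _classify.apply_classifier(model, img)
        labels = _regions.refine_regions(raw, refine_config)
        labels.provenance = "classifier+refine"
    else:
        labels = _classify.segment_by_threshold(img, threshold, refine_config)
    metrics = _quantify.measure_regions(img, labels)
    detections = None
    if detection_channel in img.channel_names:
        detections = _quantify.detect_cells_outside_core(
            img, labels, detection_channel, detection_params
        )
    return labels, metrics, detections


def run_pipeline(
    manifest: ConditionManifest,
    model: "_classify.PixelClassifierModel | None",
    out_dir,
    reference: str | None = None,
    refine_config: "_regions.RefineConfig | None" = None,
    detection_params: "_quantify.DetectionParams | None" = None,
    detection_channel: str = "MACROPHAGE",
    projection_method: str = "max",
    threshold="otsu",
    channel_names: list | None = None,
) -> tuple:
    """Project, segment and measure every manifest image; aggregate by condition.

    Per-image failures are recorded and skipped, never abort the batch.
    Images flagged "empty core" are excluded from ratio and percentage
    summaries only (exclusions are logged).  Writes ``per_image.csv``,
    ``summary.csv``, ``exclusions.csv`` and ``run_config.yaml`` into
    ``out_dir``; deterministic given model and inputs.

    Returns ``(per_image DataFrame, ConditionSummary)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = reference or manifest.conditions[0]

    rows, exclusions = [], []
    for idx, mrow in manifest.table.iterrows():
        image_id = Path(str(mrow["path"])).stem
        try:
            img_model = model
            if mrow["model_override"]:
                img_model = _classify.load_model(mrow["model_override"])
            stack = _stacks.read_stack(mrow["path"])
            if channel_names is not None:
                stack.channel_names = list(channel_names)
            img = _stacks.project(stack, projection_method)
            labels, metrics, detections = quantify_image(
                img,
                img_model,
                refine_config,
                detection_params,
                detection_channel,
                threshold,
            )
        except Exception as exc:  # noqa: BLE001 - batch must survive bad images
            exclusions.append(
                {"image_id": image_id, "condition": mrow["condition"], "reason": str(exc)}
            )
            continue
        row = {
            "image_id": image_id,
            "path": mrow["path"],
            "condition": mrow["condition"],
            "batch": mrow["batch"],
            **metrics.to_row(),
        }
        if detections is not None:
            row[f"cell_count[{detection_channel}]"] = detections.count
        rows.append(row)
        if _regions.FLAG_EMPTY_CORE in metrics.qc_flags:
            exclusions.append(
                {
                    "image_id": image_id,
                    "condition": mrow["condition"],
                    "reason": "empty core: excluded from ratio/percentage summaries",
                }
            )

    per_image = pd.DataFrame(rows)
    if per_image.empty:
        raise RuntimeError("no image in the batch could be processed")
    counts = per_image.groupby("condition").size()
    empty = [c for c in manifest.conditions if c not in counts.index]
    if empty:
        raise RuntimeError(f"condition(s) {empty} empty after per-image failures")

    # ratio/percentage metrics are blanked (not zeroed) for empty-core images
    masked = per_image.copy()
    bad = masked["qc_flags"].str.contains(_regions.FLAG_EMPTY_CORE, regex=False)
    for col in masked.columns:
        if col.startswith(RATIO_METRICS_PREFIXES):
            masked.loc[bad, col] = np.nan

    summary = summarize_conditions(masked, reference, exclusions)
    per_image.to_csv(out_dir / "per_image.csv", index=False, float_format="%.10g")
    summary.summary.to_csv(out_dir / "summary.csv", float_format="%.10g")
    pd.DataFrame(exclusions, columns=["image_id", "condition", "reason"]).to_csv(
        out_dir / "exclusions.csv", index=False
    )
    cfg = {
        "reference": reference,
        "projection_method": projection_method,
        "detection_channel": detection_channel,
        "threshold": str(threshold),
        "model": "external" if model is not None else "threshold_fallback",
        "n_images": int(len(manifest.table)),
    }
    (out_dir / "run_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return per_image, summary
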