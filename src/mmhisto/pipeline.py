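"""End-to-end orchestration: register -> segment -> extract -> select -> evaluate.

Each stage writes per-sample artifacts next to a content hash of the
configuration that produced them, so a rerun resumes from whatever is still
valid and a change to, say, a segmentation constant transparently
invalidates the segmentation and every stage downstream of it.

Samples whose registered epithelium is too small to support the analysis
(fewer than ``min_epithelium`` epithelial pixels on the H&E grid, default
100) are excluded from the cohort with reason code
``insufficient_epithelium``; exclusions are accounted for at this level so
the cohort bookkeeping stays auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import tomllib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from . import classify, features, segmentation, selection
from .imaging import read_manifest, read_sample_pair, binarize_he, binarize_ir
from .registration import RegistrationResult, AffineParams, register

log = logging.getLogger("mmhisto")


@dataclass
class PipelineConfig:
    segmentation: segmentation.SegmentationConfig = field(default_factory=segmentation.SegmentationConfig)
    features: features.FeatureConfig = field(default_factory=features.FeatureConfig)
    selection: selection.SelectionConfig = field(default_factory=selection.SelectionConfig)
    classifier: classify.ClassifierConfig = field(default_factory=classify.ClassifierConfig)
    registry_path: str | None = None
    min_epithelium: int = 100
    seed: int = 0
    log_level: str = "INFO"

    def registry(self) -> features.FeatureRegistry:
        if self.registry_path:
            return features.FeatureRegistry.from_json(self.registry_path)
        return features.default_registry()


_SECTION_TYPES = {
    "segmentation": segmentation.SegmentationConfig,
    "features": features.FeatureConfig,
    "selection": selection.SelectionConfig,
    "classifier": classify.ClassifierConfig,
}


def load_config(path: str | None) -> PipelineConfig:
    """Load a TOML config; unknown sections or keys are rejected."""
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    top_scalars = {"registry_path", "min_epithelium", "seed", "log_level"}
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - valid
            if unknown:
                raise ValueError(f"unknown key(s) {sorted(unknown)} in [{key}]")
            if key == "classifier" and "gamma_grid" in value:
                value["gamma_grid"] = tuple(value["gamma_grid"])
            kwargs[key] = cls(**value)
        elif key in top_scalars:
            kwargs[key] = raw[key]
        else:
            raise ValueError(f"unknown config key '{key}'")
    return PipelineConfig(**kwargs)


def setup_logging(cfg: PipelineConfig, log_file: str | None = None) -> None:
    log.setLevel(cfg.log_level)
    log.handlers.clear()
    for handler in [logging.StreamHandler(sys.stderr)] + (
        [logging.FileHandler(log_file)] if log_file else []
    ):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)


def _hash(payload) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def stage_hashes(cfg: PipelineConfig) -> dict:
    """Chained content hashes: downstream hashes depend on upstream config."""
    h_reg = _hash({"stage": "register"})
    h_seg = _hash({"prev": h_reg, "segmentation": cfg.segmentation.to_dict()})
    h_feat = _hash({
        "prev": h_seg,
        "features": dataclasses.asdict(cfg.features),
        "registry": cfg.registry().feature_ids,
    })
    return {"register": h_reg, "segment": h_seg, "extract": h_feat}


def _load_json_if_fresh(path: str, expect_hash: str):
    if not os.path.exists(path):
        return None
    with open(path) as fh:
        payload = json.load(fh)
    return payload if payload.get("config_hash") == expect_hash else None


def process_sample(
    row, cfg: PipelineConfig, out_dir: str, hashes: dict
) -> tuple[features.FeatureVector | None, str | None]:
    """Run register/segment/extract for one manifest row.

    Returns (feature vector, exclusion reason); exactly one is not None.
    Stage artifacts are reused when their config hash still matches.
    """
    sid = row["sample_id"]
    sdir = os.path.join(out_dir, "samples", sid)
    os.makedirs(sdir, exist_ok=True)
    pair = read_sample_pair(row["he_path"], row["ir_path"], sample_id=sid,
                            class_label=int(row["label"]))

    params_path = os.path.join(sdir, "params.json")
    cached = _load_json_if_fresh(params_path, hashes["register"])
    if cached is not None:
        reg = RegistrationResult(
            params=AffineParams(**{k: cached[k] for k in ("tx", "ty", "theta", "s")}),
            objective=cached["objective"], n_evaluations=cached["n_evaluations"],
        )
    else:
        ref = binarize_he(pair.he, cfg.segmentation.white_threshold)
        tgt = binarize_ir(pair.ir)
        if tgt.sum() == 0:
            return None, "insufficient_epithelium"
        reg = register(ref, tgt)
        with open(params_path, "w") as fh:
            json.dump({**reg.params.to_dict(), "objective": reg.objective,
                       "n_evaluations": reg.n_evaluations,
                       "config_hash": hashes["register"]}, fh, indent=1)

    epi = segmentation.epithelium_mask_from_ir(pair, reg)
    if epi.sum() <= cfg.min_epithelium:
        log.info("excluding %s: %d epithelial pixels <= %d", sid, epi.sum(), cfg.min_epithelium)
        return None, "insufficient_epithelium"

    seg_meta_path = os.path.join(sdir, "segmentation.json")
    seg = None
    if _load_json_if_fresh(seg_meta_path, hashes["segment"]) is None:
        seg = segmentation.segment_sample(pair, reg, cfg.segmentation)
        tifffile.imwrite(os.path.join(sdir, "lumens.tif"),
                         segmentation.objects_to_label_image(seg.lumens, pair.he.shape))
        tifffile.imwrite(os.path.join(sdir, "nuclei.tif"),
                         segmentation.objects_to_label_image(seg.nuclei, pair.he.shape))
        with open(seg_meta_path, "w") as fh:
            json.dump({"lumens": segmentation.objects_to_table(seg.lumens),
                       "nuclei": segmentation.objects_to_table(seg.nuclei),
                       "tissue_circle": seg.tissue_circle,
                       "config_hash": hashes["segment"]}, fh, indent=1)

    feat_path = os.path.join(sdir, "features.json")
    cached = _load_json_if_fresh(feat_path, hashes["extract"])
    registry = cfg.registry()
    if cached is not None:
        return features.FeatureVector(sample_id=sid, names=cached["names"],
                                      values=np.array(cached["values"]),
                                      missing_policy_applied=cached["missing_policy_applied"]), None
    if seg is None:  # segmentation artifact was fresh but features were not
        seg = segmentation.segment_sample(pair, reg, cfg.segmentation)
    vec = features.extract_features(seg, pair.he, registry, cfg.features, sample_id=sid)
    with open(feat_path, "w") as fh:
        json.dump({"names": vec.names, "values": vec.values.tolist(),
                   "missing_policy_applied": vec.missing_policy_applied,
                   "config_hash": hashes["extract"]}, fh, indent=1)
    return vec, None


def extract_cohort(manifest_path: str, cfg: PipelineConfig, out_dir: str) -> pd.DataFrame:
    """Register/segment/extract every manifest row; returns the feature table.

    Excluded samples are recorded in ``exclusions.csv``.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = read_manifest(manifest_path)
    hashes = stage_hashes(cfg)
    log.info("pipeline config hashes %s seed %d", hashes, cfg.seed)
    vectors, labels, excluded = [], [], []
    for _, row in manifest.iterrows():
        vec, reason = process_sample(row, cfg, out_dir, hashes)
        if vec is None:
            excluded.append({"sample_id": row["sample_id"], "reason": reason})
        else:
            vectors.append(vec)
            labels.append(int(row["label"]))
    pd.DataFrame(excluded, columns=["sample_id", "reason"]).to_csv(
        os.path.join(out_dir, "exclusions.csv"), index=False)
    table = features.feature_table(vectors, labels)
    table.to_csv(os.path.join(out_dir, "features.csv"))
    return table


def evaluate_table(table: pd.DataFrame, cfg: PipelineConfig) -> classify.EvalReport:
    """Cross-validated evaluation of a cohort feature table."""
    y = table["label"].to_numpy()
    X = table.drop(columns="label").to_numpy(dtype=float)
    clf_cfg = dataclasses.replace(cfg.classifier, seed=cfg.seed)
    return classify.cross_validate(X, y, clf_cfg, cfg.selection)


def report_to_dict(report: classify.EvalReport, feature_names=None) -> dict:
    names = list(feature_names) if feature_names is not None else None
    return {
        "auc_mean": report.auc_mean,
        "auc_std": report.auc_std,
        "spec_at_sens": {str(k): list(v) for k, v in report.spec_at_sens.items()},
        "selected_features_per_fold": [
            sorted(names[j] for j in s) if names else sorted(s)
            for s in report.selected_features_per_fold
        ],
    }


def run_pipeline(manifest_path: str, cfg: PipelineConfig, out_dir: str) -> classify.EvalReport:
    """Full pipeline: per-sample artifacts, cohort selection + CV evaluation."""
    setup_logging(cfg, log_file=os.path.join(out_dir, "run.log") if out_dir else None)
    table = extract_cohort(manifest_path, cfg, out_dir)
    if table["label"].nunique() < 2:
        raise ValueError("evaluation requires both classes after exclusions")
    report = evaluate_table(table, cfg)
    feature_names = [c for c in table.columns if c != "label"]
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report_to_dict(report, feature_names), fh, indent=1)
    report.per_fold_scores.to_csv(os.path.join(out_dir, "held_out_scores.csv"), index=False)
    log.info("cross-validated AUC %.3f +/- %.3f", report.auc_mean, report.auc_std)
    return report
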