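"""File-level pipeline stages behind the command-line interface.

A *cohort directory* is the on-disk exchange format: per-study NIfTI pairs
``<study_id>_ct.nii.gz`` / ``<study_id>_mask.nii.gz`` plus ``manifest.csv``
with columns ``study_id, label[, tumor_diameter_mm, stratum]``.  Stages:

* :func:`extract_cohort` — per-study 3D feature CSV and per-patch 2D
  feature/audit CSVs, with empty-segmentation studies excluded and logged;
* :func:`train_bundle` — trains the 3D and 2D models, searches the area
  threshold, fits (or fixes) the fusion model and selects Youden cutoffs,
  persisting everything as one JSON bundle;
* :func:`predict_cohort` — applies a bundle to a cohort, producing the
  per-study calls table consumed by the report builder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputFormatError
from .features import (FeatureManifest, default_manifest_2d, default_manifest_3d,
                       extract_feature_vector, extract_patch_features)
from .fusion import (CutoffSet, FusionModel, REFERENCE_FUSION,
                     combined_probability, decide, fit_fusion, select_cutoffs)
from .heatmap import build_heatmap, largest_high_risk_area, search_area_threshold
from .patches import CANCEROUS, generate_patches, label_patches, set_probabilities
from .training import (TrainedClassifier, TrainingConfig, predict_probability,
                       train_classifier)
from .volume import (ExclusionRecord, ResampleSpec, log_exclusions, read_mask,
                     read_volume, resample_pair, roi_union)


def _load_manifest(cohort_dir: Path) -> pd.DataFrame:
    path = cohort_dir / "manifest.csv"
    if not path.exists():
        raise InputFormatError(f"missing cohort manifest: {path}")
    return pd.read_csv(path)


def _load_study(cohort_dir: Path, study_id: str,
                resample: ResampleSpec = ResampleSpec()):
    vol = read_volume(cohort_dir / f"{study_id}_ct.nii.gz")
    mask = read_mask(cohort_dir / f"{study_id}_mask.nii.gz")
    if tuple(vol.spacing) != tuple(resample.target_spacing):
        vol, mask = resample_pair(vol, mask, resample)
    return vol, mask, roi_union(mask)


def iter_cohort(cohort_dir: str | Path, resample: ResampleSpec = ResampleSpec()):
    """Yield (row, volume, mask, roi) per study; missing/empty studies are
    yielded as (row, None, None, None) for the caller to log and skip."""
    cohort_dir = Path(cohort_dir)
    manifest = _load_manifest(cohort_dir)
    for _, row in manifest.iterrows():
        try:
            vol, mask, roi = _load_study(cohort_dir, row["study_id"], resample)
        except InputFormatError:
            yield row, None, None, None
            continue
        if roi.is_empty:
            yield row, None, None, None
            continue
        yield row, vol, mask, roi


def extract_cohort(cohort_dir: str | Path, out_dir: str | Path,
                   manifest3d: FeatureManifest | None = None,
                   manifest2d: FeatureManifest | None = None) -> dict:
    """Write features_3d.csv, patch_features.csv and patches_audit.csv."""
    manifest3d = manifest3d or default_manifest_3d()
    manifest2d = manifest2d or default_manifest_2d()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows3d, patch_frames, audit_frames, excluded = [], [], [], []
    for row, vol, mask, roi in iter_cohort(cohort_dir):
        sid = row["study_id"]
        if vol is None:
            excluded.append(ExclusionRecord(study_id=str(sid),
                                            reason="missing-or-empty-segmentation"))
            continue
        vec = extract_feature_vector(vol, roi, manifest3d)
        rows3d.append({"study_id": sid, "label": row["label"], **vec.values})
        pset = label_patches(generate_patches(roi, study_id=str(sid)), mask)
        feats = extract_patch_features(vol, pset, manifest2d)
        audit = pset.to_frame()
        feats.insert(0, "study_id", sid)
        patch_frames.append(feats)
        audit_frames.append(audit)
    pd.DataFrame(rows3d).to_csv(out / "features_3d.csv", index=False)
    if patch_frames:
        pd.concat(patch_frames, ignore_index=True).to_csv(
            out / "patch_features.csv", index=False)
        pd.concat(audit_frames, ignore_index=True).to_csv(
            out / "patches_audit.csv", index=False)
    log_exclusions(excluded, out / "exclusions.jsonl")
    return {"n_studies": len(rows3d), "n_excluded": len(excluded)}


@dataclass
class ModelBundle:
    """All five trained artifacts of the CAD tool."""

    model_3d: TrainedClassifier
    model_2d: TrainedClassifier
    area_threshold: float
    fusion: FusionModel
    cutoffs: CutoffSet
    manifest3d_json: str
    manifest2d_json: str
    connectivity: str = "8"

    def save(self, path: str | Path) -> None:
        def booster_payload(model: TrainedClassifier) -> dict:
            return {
                "feature_names": model.feature_names,
                "selected_iteration": model.selected_iteration,
                "validation_auc_trace": model.validation_auc_trace.tolist(),
                "config": asdict(model.config),
                "manifest_hash": model.manifest_hash,
                "booster": model.booster.save_raw("json").decode(),
            }

        payload = {
            "model_3d": booster_payload(self.model_3d),
            "model_2d": booster_payload(self.model_2d),
            "area_threshold": self.area_threshold,
            "fusion": asdict(self.fusion),
            "cutoffs": json.loads(self.cutoffs.to_json()),
            "manifest3d": json.loads(self.manifest3d_json),
            "manifest2d": json.loads(self.manifest2d_json),
            "connectivity": self.connectivity,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        import xgboost as xgb

        payload = json.loads(Path(path).read_text())

        def restore(obj: dict) -> TrainedClassifier:
            booster = xgb.Booster()
            booster.load_model(bytearray(obj["booster"].encode()))
            return TrainedClassifier(
                booster=booster, feature_names=obj["feature_names"],
                selected_iteration=int(obj["selected_iteration"]),
                validation_auc_trace=np.asarray(obj["validation_auc_trace"]),
                config=TrainingConfig(**obj["config"]),
                manifest_hash=obj.get("manifest_hash", ""))

        return cls(model_3d=restore(payload["model_3d"]),
                   model_2d=restore(payload["model_2d"]),
                   area_threshold=float(payload["area_threshold"]),
                   fusion=FusionModel(**payload["fusion"]),
                   cutoffs=CutoffSet(**payload["cutoffs"]),
                   manifest3d_json=json.dumps(payload["manifest3d"]),
                   manifest2d_json=json.dumps(payload["manifest2d"]),
                   connectivity=payload.get("connectivity", "8"))


def train_bundle(cohort_dir: str | Path, validation_fraction: float = 0.3,
                 seed: int = 0, fusion_source: str = "fit",
                 manifest3d: FeatureManifest | None = None,
                 manifest2d: FeatureManifest | None = None,
                 connectivity: str = "8") -> ModelBundle:
    """Train the full model bundle from a cohort directory.

    Studies are split into fit/validation sets stratified by label with the
    given seed; the validation split drives early stopping, the area
    threshold search, the fusion fit and the Youden cutoffs.
    """
    manifest3d = manifest3d or default_manifest_3d()
    manifest2d = manifest2d or default_manifest_2d()
    studies = []
    for row, vol, mask, roi in iter_cohort(cohort_dir):
        if vol is None:
            continue
        studies.append((row, vol, mask, roi))
    labels = np.asarray([int(r["label"]) for r, *_ in studies])
    if np.unique(labels).size < 2:
        raise ConfigurationError("training cohort needs both classes")
    rng = np.random.default_rng(seed)
    val_idx = set()
    for cls_label in (0, 1):
        idx = np.flatnonzero(labels == cls_label)
        k = max(1, int(round(validation_fraction * len(idx))))
        val_idx.update(rng.choice(idx, size=k, replace=False).tolist())
    if len(val_idx) >= len(studies) - 1:
        raise ConfigurationError("degenerate train/validation split")

    def features_of(subset):
        vecs, ys, psets, pframes = [], [], [], []
        for i in subset:
            row, vol, mask, roi = studies[i]
            vecs.append(extract_feature_vector(vol, roi, manifest3d).as_array())
            ys.append(int(row["label"]))
            pset = label_patches(generate_patches(roi, study_id=str(row["study_id"])),
                                 mask)
            psets.append(pset)
            pframes.append(extract_patch_features(vol, pset, manifest2d))
        return np.stack(vecs), np.asarray(ys), psets, pframes

    def patch_labels(psets):
        return np.concatenate(
            [[p.label == CANCEROUS for p in ps.patches] for ps in psets]).astype(int)

    train_ids = [i for i in range(len(studies)) if i not in val_idx]
    Xtr, ytr, psets_tr, ptr = features_of(train_ids)
    Xva, yva, psets_va, pva = features_of(sorted(val_idx))

    config = TrainingConfig(seed=seed)
    model_3d = train_classifier(pd.DataFrame(Xtr, columns=manifest3d.names), ytr,
                                pd.DataFrame(Xva, columns=manifest3d.names), yva,
                                config)
    model_2d = train_classifier(pd.concat(ptr, ignore_index=True),
                                patch_labels(psets_tr),
                                pd.concat(pva, ignore_index=True),
                                patch_labels(psets_va), config)

    heatmaps = []
    for ps, frame in zip(psets_va, pva):
        probs = predict_probability(model_2d, frame)
        heatmaps.append(build_heatmap(set_probabilities(ps, probs)))
    search = search_area_threshold(heatmaps, yva, connectivity=connectivity)
    areas = np.asarray([largest_high_risk_area(h, search.selected, connectivity).area_mm2
                        for h in heatmaps])
    p3d_val = predict_probability(
        model_3d, pd.DataFrame(Xva, columns=manifest3d.names))
    if fusion_source == "reference":
        fusion = REFERENCE_FUSION
    elif fusion_source == "fit":
        fusion = fit_fusion(p3d_val, areas, yva)
    else:
        raise ConfigurationError(f"unknown fusion source {fusion_source!r}")
    pc_val = combined_probability(fusion, p3d_val, areas)
    cutoffs = select_cutoffs(p3d_val, areas, pc_val, yva)
    return ModelBundle(model_3d=model_3d, model_2d=model_2d,
                       area_threshold=search.selected, fusion=fusion,
                       cutoffs=cutoffs, manifest3d_json=manifest3d.to_json(),
                       manifest2d_json=manifest2d.to_json(),
                       connectivity=connectivity)


def predict_cohort(cohort_dir: str | Path, bundle: ModelBundle) -> pd.DataFrame:
    """Per-study calls table for a cohort under a trained bundle."""
    manifest3d = FeatureManifest.from_json(bundle.manifest3d_json)
    manifest2d = FeatureManifest.from_json(bundle.manifest2d_json)
    rows = []
    for row, vol, mask, roi in iter_cohort(cohort_dir):
        sid = str(row["study_id"])
        if vol is None:
            rows.append({"study_id": sid, "truth": row.get("label"),
                         "excluded": True})
            continue
        vec = extract_feature_vector(vol, roi, manifest3d)
        p3d = float(predict_probability(
            bundle.model_3d,
            pd.DataFrame([vec.as_array()], columns=manifest3d.names))[0])
        pset = generate_patches(roi, study_id=sid)
        feats = extract_patch_features(vol, pset, manifest2d)
        probs = predict_probability(bundle.model_2d, feats)
        hm = build_heatmap(set_probabilities(pset, probs))
        area = largest_high_risk_area(hm, bundle.area_threshold,
                                      bundle.connectivity).area_mm2
        pc = float(combined_probability(bundle.fusion, p3d, area))
        pred = decide(sid, p3d, area, pc, bundle.cutoffs)
        entry = pred.as_dict()
        entry.update({"truth": row.get("label"), "score3d": p3d,
                      "score_combined": pc, "excluded": False})
        if "stratum" in row:
            entry["stratum"] = row["stratum"]
        rows.append(entry)
    return pd.DataFrame(rows)
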