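"""End-to-end orchestration: record -> cycles -> features -> decision.

Classification granularity: metrics are computed per heart cycle; a
record-level (or buffer-level) label is a majority vote over its cycles,
with ties going to abnormal. Model files are self-describing archives
(JSON metadata + arrays), with no executable code inside.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify
from .classify import (CLASSES, CostMatrix, CVResult, TrainedModel, cross_validate,
                       decide_with_cost, holdout_split, predict_proba)
from .features import FEATURE_NAMES, FeatureConfig, extract_features
from .io import DatasetManifest, PCGRecord
from .metrics import compute_metrics, confusion_from_labels
from .preprocess import FilterSpec, preprocess_record
from .segment import detect_s1_peaks, segment_cycles
from .select import REDUCED_FEATURE_NAMES, reduce_features


def record_to_cycles(record: PCGRecord, filter_spec: FilterSpec | None = None,
                     spike_mads: float = 8.0, baseline_cutoff_hz: float = 2.0,
                     hr_bounds_bpm=(40.0, 180.0), pre_offset_s: float = 0.05,
                     min_dur_s: float = 0.3, max_dur_s: float = 2.0) -> list:
    """Pre-process a record and segment it into heart cycles."""
    rec = preprocess_record(record, filter_spec, spike_mads, baseline_cutoff_hz)
    peaks = detect_s1_peaks(rec, hr_bounds_bpm)
    if peaks.size < 2:
        return []
    return segment_cycles(rec, peaks, pre_offset_s, min_dur_s, max_dur_s)


def features_from_record(record: PCGRecord,
                         feature_config: FeatureConfig | None = None,
                         **segment_kwargs) -> pd.DataFrame:
    """One row of 27 features per detected cycle of one record."""
    cycles = record_to_cycles(record, **segment_kwargs)
    rows = []
    for i, cyc in enumerate(cycles):
        fv = extract_features(cyc, feature_config)
        row = {"record_id": record.record_id, "label": record.label,
               "cycle_index": i}
        row.update(fv.as_dict())
        rows.append(row)
    cols = ["record_id", "label", "cycle_index"] + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=cols)


def features_from_manifest(manifest: DatasetManifest,
                           feature_config: FeatureConfig | None = None,
                           **segment_kwargs) -> pd.DataFrame:
    """Cycle-feature table for a whole dataset."""
    frames = [features_from_record(rec, feature_config, **segment_kwargs)
              for rec in manifest.iter_records()]
    frames = [f for f in frames if len(f)]
    if not frames:
        raise ValueError("no cycles detected in any record of the manifest")
    return pd.concat(frames, ignore_index=True)


def _matrix(table: pd.DataFrame, reduced: bool):
    names = list(REDUCED_FEATURE_NAMES) if reduced else list(FEATURE_NAMES)
    return table[names].to_numpy(float), table["label"].to_numpy(), tuple(names)


def train_workflow(manifest: DatasetManifest, seed: int = 0,
                   model_spec: dict | None = None,
                   cost: CostMatrix | None = None, reduced: bool = False,
                   test_fraction: float = 0.2, n_folds: int = 5,
                   feature_config: FeatureConfig | None = None) -> dict:
    """The full training workflow.

    80/20 stratified record-level holdout; 5-fold cross-validation on the
    training side (per cycle); a final model fitted on all training cycles
    and evaluated on the held-out records. Returns a dict with the fitted
    model, the CV result, and the test-set metrics report.
    """
    cost = cost or CostMatrix()
    model_spec = model_spec or {"kind": "weighted_knn"}
    train_man, test_man = holdout_split(manifest, test_fraction, seed)
    train_tab = features_from_manifest(train_man, feature_config)
    test_tab = features_from_manifest(test_man, feature_config)
    Xtr, ytr, names = _matrix(train_tab, reduced)
    Xte, yte, _ = _matrix(test_tab, reduced)
    cv = cross_validate(Xtr, ytr, model_spec, n_folds=n_folds, seed=seed,
                        cost=cost, feature_names=names)
    model = classify._make_model(Xtr, ytr, model_spec, seed, cost, names)
    test_labels = classify.predict(model, Xte)
    test_report = compute_metrics(confusion_from_labels(yte.tolist(), test_labels))
    return {"model": model, "cv": cv, "test_report": test_report,
            "n_train_cycles": len(ytr), "n_test_cycles": len(yte),
            "feature_names": names, "seed": seed}


def classify_record(model: TrainedModel, record: PCGRecord,
                    feature_config: FeatureConfig | None = None,
                    **segment_kwargs) -> dict:
    """Majority-vote decision for one record; ``indeterminate`` if no cycles."""
    cycles = record_to_cycles(record, **segment_kwargs)
    if not cycles:
        return {"label": "indeterminate", "votes": {}, "n_cycles": 0}
    X = np.vstack([extract_features(c, feature_config).values for c in cycles])
    if len(model.feature_names) != X.shape[1]:
        fvs = [extract_features(c, feature_config) for c in cycles]
        X = np.vstack([reduce_features(fv, model.feature_names).values
                       for fv in fvs])
    labels = decide_with_cost(predict_proba(model, X), model.cost)
    votes = {cls: labels.count(cls) for cls in CLASSES}
    label = "abnormal" if votes["abnormal"] >= votes["normal"] else "normal"
    return {"label": label, "votes": votes, "n_cycles": len(cycles)}


def stream_classify(record: PCGRecord, model: TrainedModel,
                    buffer_s: float = 10.0,
                    feature_config: FeatureConfig | None = None) -> list:
    """Buffered streaming classification: one decision per ``buffer_s`` of
    signal, each buffer processed independently (no hidden state)."""
    if record.sample_rate_hz != 2000:
        raise ValueError("streaming expects the canonical 2000 Hz rate")
    n_buf = int(round(buffer_s * record.sample_rate_hz))
    decisions = []
    for start in range(0, record.samples.size, n_buf):
        chunk = record.samples[start:start + n_buf]
        if chunk.size < record.sample_rate_hz:  # ignore a trailing sliver < 1 s
            break
        sub = PCGRecord(f"{record.record_id}@{start}", chunk,
                        record.sample_rate_hz, record.label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = classify_record(model, sub, feature_config)
        out["t_start_s"] = start / record.sample_rate_hz
        decisions.append(out)
    return decisions


# ---------------------------------------------------------------------------
# model serialization: npz archive of arrays + a JSON metadata entry

def save_model(model: TrainedModel, path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    meta = {"kind": model.kind, "hyperparameters": model.hyperparameters,
            "cost": {"cost_fn": model.cost.cost_fn, "cost_fp": model.cost.cost_fp},
            "feature_names": list(model.feature_names)}
    arrays = {"scaler_mean": model.scaler_mean, "scaler_std": model.scaler_std}
    if model.kind in ("fine_knn", "weighted_knn"):
        arrays["train_X"] = model.state["train_X"]
        arrays["train_y"] = np.asarray(model.state["train_y"], dtype="U16")
    else:
        arrays["train_X"] = model.state["train_X"]
        arrays["train_y"] = np.asarray(model.state["train_y"], dtype="U16")
        for i, member in enumerate(model.state["members"]):
            arrays[f"member_{i}_cols"] = member["cols"]
            if "lda" in member:
                lda = member["lda"]
                arrays[f"member_{i}_coef"] = lda.coef_
                arrays[f"member_{i}_intercept"] = lda.intercept_
                arrays[f"member_{i}_classes"] = np.asarray(lda.classes_, dtype="U16")
        meta["n_members"] = len(model.state["members"])
    arrays["metadata_json"] = np.array(json.dumps(meta))
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)
    return path


class _LinearMember:
    """Reconstructed linear-discriminant member: sigmoid of the decision
    function, matching scikit-learn's binary LDA posterior."""

    def __init__(self, coef, intercept, classes):
        self.coef_ = coef
        self.intercept_ = intercept
        self.classes_ = classes

    def predict_proba(self, X):
        score = X @ self.coef_.T + self.intercept_
        p1 = 1.0 / (1.0 + np.exp(-score[:, 0]))
        return np.column_stack([1.0 - p1, p1])


def load_model(path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        alt = path.parent / (path.name + ".npz")
        if alt.exists():
            path = alt
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["metadata_json"]))
        model = TrainedModel(meta["kind"], meta["hyperparameters"],
                             CostMatrix(**meta["cost"]),
                             tuple(meta["feature_names"]),
                             data["scaler_mean"], data["scaler_std"])
        state = {"train_X": data["train_X"], "train_y": data["train_y"]}
        if meta["kind"] == "subspace_ensemble":
            members = []
            for i in range(meta["n_members"]):
                member = {"cols": data[f"member_{i}_cols"]}
                if f"member_{i}_coef" in data:
                    member["lda"] = _LinearMember(data[f"member_{i}_coef"],
                                                  data[f"member_{i}_intercept"],
                                                  data[f"member_{i}_classes"])
                members.append(member)
            state["members"] = members
        model.state = state
    return model
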