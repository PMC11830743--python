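"""Three-time-point latent features and gradient-boosted classification.

Each eye with at least three usable visits contributes one feature row:
the display latents (optionally plus booster latents) at the first visit,
the last visit, and the visit most equidistant between them.  An XGBoost
model (max depth 15, learning rate 0.3, softprob objective) then estimates
either the probability that the eye's thinning progressed beyond the
normal range (binary) or the probability of each cause (within normal
range / glaucoma / ON / NAION).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("gclspace")

BINARY_LABELS = ("within_normal_range", "beyond_normal_range")
MULTI_LABELS = ("within_normal_range", "glaucoma", "ON", "NAION")

XGB_PARAMS = {"max_depth": 15, "learning_rate": 0.3, "n_estimators": 200}


@dataclass
class FeatureRow:
    eye_id: str
    features: np.ndarray  # 6 (dLVs) or 30 (dLVs + bLVs) values
    label: str
    subject_id: str = ""
    visit_indices: tuple = ()

    def as_dict(self):
        d = {"eye_id": self.eye_id, "label": self.label}
        d.update({f"f{i}": v for i, v in enumerate(self.features)})
        return d


def select_three_visits(visit_days) -> tuple[int, int, int]:
    """First, most-equidistant middle, and last visit indices.

    The middle visit minimizes |(t - t1) - (t3 - t)|; ties break toward the
    earlier visit.
    """
    days = np.asarray(visit_days, float)
    if len(days) < 3:
        raise ValueError("need at least 3 visits")
    i1, i3 = 0, len(days) - 1
    scores = np.abs((days - days[i1]) - (days[i3] - days))
    scores[i1] = scores[i3] = np.inf
    i2 = int(np.argmin(scores))  # argmin takes the earliest on ties
    return i1, i2, i3


def assemble_features(series, codes, use_blvs: bool = False, label: str | None = None):
    """Build one FeatureRow from an eye series and its per-visit latent codes.

    Returns None (with a logged reason) for eyes with fewer than 3 visits.
    """
    if len(codes) != series.n_visits:
        raise ValueError("one latent code per visit required")
    if series.n_visits < 3:
        log.info("excluding %s: only %d visits", series.subject_id, series.n_visits)
        return None
    i1, i2, i3 = select_three_visits(series.visit_days)
    feats = []
    for i in (i1, i2, i3):
        feats.append(codes[i].full if use_blvs else codes[i].d)
    return FeatureRow(
        eye_id=f"{series.subject_id}:{series.eye}",
        features=np.concatenate(feats),
        label=label if label is not None else series.progression_label,
        subject_id=series.subject_id,
        visit_indices=(i1, i2, i3),
    )


def rows_to_xy(rows, classes):
    x = np.stack([r.features for r in rows])
    lookup = {c: i for i, c in enumerate(classes)}
    y = np.array([lookup[r.label] for r in rows])
    return x, y


@dataclass
class FittedClassifier:
    booster: object
    classes: tuple
    mode: str
    params: dict

    def predict_proba(self, rows_or_x) -> np.ndarray:
        x = rows_or_x if isinstance(rows_or_x, np.ndarray) else np.stack(
            [r.features for r in rows_or_x]
        )
        return self.booster.predict_proba(x)

    def feature_importances(self) -> np.ndarray:
        return self.booster.feature_importances_

    def save(self, model_path, sidecar_path=None):
        self.booster.get_booster().save_model(str(model_path))
        if sidecar_path is not None:
            from pathlib import Path

            Path(sidecar_path).write_text(
                json.dumps({"classes": list(self.classes), "mode": self.mode,
                            "params": self.params}, indent=2)
            )


def fit_classifier(
    rows,
    mode: str = "binary",
    params: dict | None = None,
    val_rows=None,
    seed: int = 0,
) -> FittedClassifier:
    """Fit the gradient-boosted tree ensemble on assembled feature rows.

    Uses the softprob objective in both modes (the binary task is treated
    as 2-class softprob); 200 boosting rounds with early stopping on the
    validation rows when provided.
    """
    import xgboost as xgb

    classes = BINARY_LABELS if mode == "binary" else MULTI_LABELS
    present = {r.label for r in rows}
    if len(present) < 2:
        raise ValueError(f"need >= 2 classes, got {sorted(present)}")
    classes = tuple(c for c in classes if c in present)
    x, y = rows_to_xy(rows, classes)
    p = dict(XGB_PARAMS)
    p.update(params or {})
    kwargs = dict(
        objective="multi:softprob",
        num_class=len(classes),
        n_jobs=1,
        random_state=seed,
        tree_method="exact",
        **p,
    )
    fit_kwargs = {}
    if val_rows:
        xv, yv = rows_to_xy(val_rows, classes)
        kwargs["early_stopping_rounds"] = 10
        kwargs["eval_metric"] = "mlogloss"
        fit_kwargs["eval_set"] = [(xv, yv)]
        fit_kwargs["verbose"] = False
    clf = xgb.XGBClassifier(**kwargs)
    clf.fit(x, y, **fit_kwargs)
    return FittedClassifier(booster=clf, classes=classes, mode=mode, params=p)


def multiclass_roc(probabilities: np.ndarray, labels, classes) -> dict:
    """One-vs-rest ROC curve and AUC per class.

    Returns {class: {"fpr", "tpr", "auc"}}; a class absent from the labels
    gets auc = nan (undefined, never a silent number).
    """
    from sklearn.metrics import roc_curve, auc as _auc

    probabilities = np.asarray(probabilities, float)
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    labels = np.asarray(labels)
    out = {}
    for k, cls in enumerate(classes):
        y = (labels == cls).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            out[cls] = {"fpr": None, "tpr": None, "auc": float("nan")}
            continue
        fpr, tpr, _ = roc_curve(y, probabilities[:, k])
        out[cls] = {"fpr": fpr, "tpr": tpr, "auc": float(_auc(fpr, tpr))}
    return out


def auc_not_lower_pvalue(y_true, scores_a, scores_b, n_boot=2000, seed=0) -> float:
    """Paired-bootstrap p-value for the one-sided test "AUC(b) < AUC(a)".

    Returns the fraction of bootstrap replicates where AUC(b) >= AUC(a);
    a small value (< alpha) means b is significantly worse, while a large
    value supports "adding features did not significantly reduce the AUC".
    """
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    y = np.asarray(y_true)
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    n = len(y)
    not_worse = 0
    used = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        used += 1
        not_worse += roc_auc_score(y[idx], b[idx]) >= roc_auc_score(y[idx], a[idx])
    return not_worse / max(used, 1)


def rows_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])


def roc_to_frame(roc: dict) -> pd.DataFrame:
    frames = []
    for cls, d in roc.items():
        if d["fpr"] is None:
            continue
        frames.append(pd.DataFrame({"class": cls, "fpr": d["fpr"], "tpr": d["tpr"]}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["class", "fpr", "tpr"]
    )
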