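"""Random-forest cell classification and mixture-proportion estimation.

Cells are described either by 30 Mueller-matrix features (the 15 non-M11
normalized elements at each of the two collection angles; M11 is used only
for normalization, never as a predictor) or by the 6 polarization feature
parameters.  A bagged decision-tree ensemble with Gini splits and majority
vote assigns per-cell labels; mixture proportions are the predicted label
frequencies, scored against the true composition by the absolute error
AE = sum_i |T_i - P_i|.

The ensemble itself is scikit-learn's ``RandomForestClassifier`` (bootstrap
resampling, sqrt-feature subsets per node, unlimited depth, min samples per
leaf 1); out-of-bag accuracy selects the tree count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "CellRecord",
    "MixtureEstimate",
    "records_to_xy",
    "train_forest",
    "oob_curve",
    "predict_proportions",
    "absolute_error",
    "CLASS_ORDER",
]

#: Canonical class ordering for proportion vectors (matches the mixture
#: ratio convention spherocytes : echinocytes : normal).
CLASS_ORDER = ("spherocyte", "echinocyte", "normal")


@dataclass(frozen=True)
class CellRecord:
    """One detected cell: a feature vector (30 MM elements or 6 PFPs) plus an
    optional training label."""

    features: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 1 or f.size not in (6, 30):
            raise ValueError(f"feature vector must have length 6 or 30, got shape {f.shape}")
        object.__setattr__(self, "features", f)


@dataclass(frozen=True)
class MixtureEstimate:
    """Estimated per-class proportions of a mixed suspension."""

    proportions: np.ndarray
    classes: tuple[str, ...]
    n_cells: int
    feature_mode: str = "mm"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")
        object.__setattr__(self, "proportions", p)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.classes, map(float, self.proportions)))


def records_to_xy(records) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack records (CellRecord list or labeled DataFrame) into X, y arrays."""
    if isinstance(records, pd.DataFrame):
        cols = [c for c in records.columns if c != "label"]
        x = records[cols].to_numpy(dtype=float)
        y = records["label"].to_numpy() if "label" in records.columns else None
        return x, y
    x = np.stack([r.features for r in records])
    labels = [r.label for r in records]
    y = None if any(l is None for l in labels) else np.asarray(labels)
    return x, y


def train_forest(
    records,
    n_trees: int = 100,
    seed: int | None = 0,
    oob_score: bool = False,
) -> RandomForestClassifier:
    """Fit the bagged ensemble on labeled records; seeded and deterministic."""
    x, y = records_to_xy(records)
    if y is None:
        raise ValueError("training records must all carry labels")
    if np.unique(y).size < 2:
        raise ValueError("training set is degenerate: fewer than 2 classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        oob_score=oob_score,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(x, y)
    return clf


def oob_curve(
    records,
    tree_counts,
    seed: int | None = 0,
    plateau_tol: float = 0.002,
) -> tuple[list[tuple[int, float]], int]:
    """Out-of-bag accuracy per ensemble size and the selected tree count.

    The selected count is the smallest one whose OOB accuracy is within
    ``plateau_tol`` of the maximum over the scanned counts (the performance
    plateau); if nothing but the maximum qualifies the maximizing count is
    returned.
    """
    tree_counts = sorted(int(t) for t in tree_counts)
    if not tree_counts:
        raise ValueError("tree_counts must be non-empty")
    curve = []
    for n_trees in tree_counts:
        clf = train_forest(records, n_trees=n_trees, seed=seed, oob_score=True)
        curve.append((n_trees, float(clf.oob_score_)))
    best = max(acc for _, acc in curve)
    selected = next(n for n, acc in curve if acc >= best - plateau_tol)
    return curve, selected


def predict_proportions(
    clf: RandomForestClassifier,
    records,
    mode: str = "votes",
    feature_mode: str = "mm",
) -> MixtureEstimate:
    """Mixture composition from per-cell predictions.

    ``mode='votes'`` counts majority-vote labels (the default);
    ``mode='proba'`` averages class probabilities over cells instead.
    """
    x, _ = records_to_xy(records)
    if x.shape[0] == 0:
        raise ValueError("cannot estimate proportions from an empty test set")
    if x.shape[1] != clf.n_features_in_:
        raise ValueError(
            f"feature mode mismatch: records have {x.shape[1]} features, "
            f"classifier expects {clf.n_features_in_}"
        )
    classes = tuple(clf.classes_)
    if mode == "votes":
        labels = clf.predict(x)
        props = np.array([np.mean(labels == c) for c in classes])
    elif mode == "proba":
        props = clf.predict_proba(x).mean(axis=0)
        props = props / props.sum()
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    return MixtureEstimate(
        proportions=props, classes=classes, n_cells=x.shape[0], feature_mode=feature_mode
    )


def absolute_error(true_props, est) -> float:
    """AE = sum_i |T_i - P_i| between true and estimated class proportions.

    ``true_props`` may be a vector aligned with the estimate's class order or
    a class->proportion mapping; ``est`` a MixtureEstimate or plain vector.
    Ranges over [0, 2]; 0 iff the compositions match exactly.
    """
    if isinstance(est, MixtureEstimate):
        p = est.proportions
        if isinstance(true_props, dict):
            t = np.array([true_props[c] for c in est.classes], dtype=float)
        else:
            t = np.asarray(true_props, dtype=float)
    else:
        p = np.asarray(est, dtype=float)
        t = np.asarray(true_props, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"proportion vectors disagree in length: {t.shape} vs {p.shape}")
    for name, v in (("true", t), ("estimated", p)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} proportions must sum to 1 (got {v.sum()})")
    return float(np.abs(t - p).sum())
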