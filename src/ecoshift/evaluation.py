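"""Model validation, permutation importance and partial dependence.

AUC uses the Mann–Whitney formulation (probability a random presence
outscores a random absence, ties counted one half). The Sørensen index
defaults to the standard ``2TP / (FN + 2TP + FP)`` form with range
[0, 1]; a halved ``TP / (FN + 2TP + FP)`` variant (range [0, 0.5]) is
kept behind a flag for comparability with reports that print that form.
Variable importance is permutation-based: the mean/SD increase in RMSE
after permuting one predictor column, over a fixed number of seeded
permutations (default 35).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "PDCurve",
    "auc_roc",
    "confusion_counts",
    "sorensen_index",
    "evaluate_model",
    "permutation_importance",
    "partial_dependence",
    "rmse",
    "AUC_PASS_THRESHOLD",
    "SOR_PASS_THRESHOLD",
]

AUC_PASS_THRESHOLD = 0.75
SOR_PASS_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    """Binarized confusion counts at a stated threshold."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PDCurve:
    """Partial-dependence curve: mean prediction over background rows."""

    predictor: str
    grid: np.ndarray
    mean_prediction: np.ndarray
    n_background: int


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def auc_roc(labels, scores) -> float:
    """Area under the ROC curve via the rank-sum (Mann–Whitney) identity.

    Equals the probability that a uniformly chosen presence outranks a
    uniformly chosen absence, with tied scores counted 1/2.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both presence and absence labels")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_counts(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        threshold=threshold,
    )


def sorensen_index(counts: ConfusionCounts, variant: str = "standard") -> float:
    """Sørensen similarity on binarized predictions.

    standard:   2*TP / (FN + 2*TP + FP), in [0, 1]
    as_printed: TP / (FN + 2*TP + FP), in [0, 0.5]
    """
    denom = counts.fn + 2 * counts.tp + counts.fp
    if denom == 0:
        raise ValueError("Sørensen undefined when TP = FP = FN = 0")
    if variant == "standard":
        return 2.0 * counts.tp / denom
    if variant == "as_printed":
        return counts.tp / denom
    raise ValueError(f"unknown variant {variant!r}")


def evaluate_model(model, table, threshold: float = 0.5,
                   partition: str = "test") -> dict:
    """RMSE, AUC and Sørensen on a held-out partition, with pass flags.

    Pass flags use the conventional performance screens AUC >= 0.75 and
    SOR >= 0.5 (standard variant). The binarization threshold is reported
    alongside the metrics because SOR depends on it.
    """
    rows = table.df[table.df["partition"] == partition]
    if len(rows) == 0:
        raise ValueError(f"empty partition {partition!r}")
    labels = rows["label"].to_numpy()
    scores = model.predict(rows)
    counts = confusion_counts(labels, scores, threshold)
    auc = auc_roc(labels, scores)
    sor = sorensen_index(counts)
    return {
        "n": int(len(rows)),
        "threshold": threshold,
        "rmse": rmse(labels, scores),
        "auc": auc,
        "sorensen": sor,
        "auc_pass": bool(auc >= AUC_PASS_THRESHOLD),
        "sorensen_pass": bool(sor >= SOR_PASS_THRESHOLD),
        "confusion": {"tp": counts.tp, "fp": counts.fp,
                      "fn": counts.fn, "tn": counts.tn},
    }


def permutation_importance(model, table, n_perm: int = 35, seed: int = 0,
                           partition: str = "test",
                           max_rows: int | None = 1000) -> pd.DataFrame:
    """Permutation-RMSE variable importance.

    For each model predictor, its column is permuted ``n_perm`` times
    (seeded); importance is the mean increase of RMSE over the unpermuted
    baseline, reported with its SD. At most ``max_rows`` rows (seeded
    subsample, the conventional default of permutation explainers) are
    evaluated; pass None to use every row. Returns a tidy DataFrame
    sorted by mean increase (descending) with the baseline RMSE in
    ``df.attrs['baseline_rmse']``.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations for an SD")
    if partition == "all":
        rows = table.df
    else:
        rows = table.df[table.df["partition"] == partition]
    if len(rows) == 0:
        rows = table.df
    rng_rows = np.random.default_rng(seed)
    if max_rows is not None and len(rows) > max_rows:
        rows = rows.iloc[np.sort(rng_rows.choice(len(rows), size=max_rows,
                                                 replace=False))]
    y = rows["label"].to_numpy(dtype=float)
    X = rows[model.predictors].to_numpy(dtype=float)
    baseline = rmse(y, model.predict_matrix(X))
    rng = np.random.default_rng(seed)
    n = len(y)
    records = []
    for j, name in enumerate(model.predictors):
        # all permutations of one predictor batched into a single predict
        Xrep = np.tile(X, (n_perm, 1))
        for p in range(n_perm):
            Xrep[p * n : (p + 1) * n, j] = X[rng.permutation(n), j]
        pred = model.predict_matrix(Xrep)
        increases = [
            rmse(y, pred[p * n : (p + 1) * n]) - baseline for p in range(n_perm)
        ]
        records.append({
            "predictor": name,
            "mean_rmse_increase": float(np.mean(increases)),
            "sd_rmse_increase": float(np.std(increases, ddof=1)),
            "n_permutations": n_perm,
        })
    df = pd.DataFrame(records).sort_values(
        "mean_rmse_increase", ascending=False
    ).reset_index(drop=True)
    df.attrs["baseline_rmse"] = baseline
    return df


def partial_dependence(model, data, predictor: str, grid_size: int = 20,
                       n_background: int = 100, seed: int = 0) -> PDCurve:
    """Average-prediction profile along one predictor.

    ``data`` is a DataFrame or a PredictorStack; ``n_background`` rows are
    sampled (seeded), the predictor is swept over ``grid_size`` evenly
    spaced values spanning its observed range, and predictions are
    averaged at each sweep value.
    """
    from .geoprep import PredictorStack

    if predictor not in model.predictors:
        raise ValueError(f"{predictor!r} is not a model predictor")
    if isinstance(data, PredictorStack):
        frame, _, _ = data.to_frame(model.predictors)
    else:
        frame = data[model.predictors]
    lo = float(frame[predictor].min())
    hi = float(frame[predictor].max())
    if lo == hi:
        raise ValueError(f"predictor {predictor!r} has a degenerate range")
    rng = np.random.default_rng(seed)
    n_background = min(n_background, len(frame))
    idx = rng.choice(len(frame), size=n_background, replace=False)
    X = frame.to_numpy(dtype=float)[idx]
    j = model.predictors.index(predictor)
    grid = np.linspace(lo, hi, grid_size)
    Xrep = np.tile(X, (grid_size, 1))
    for g, val in enumerate(grid):
        Xrep[g * n_background : (g + 1) * n_background, j] = val
    pred = model.predict_matrix(Xrep)
    means = pred.reshape(grid_size, n_background).mean(axis=1)
    return PDCurve(predictor, grid, means, n_background)
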