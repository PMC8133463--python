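"""Model evaluation: radial spatial folds, AUC, variable importance, max kappa.

Cross-validation is leave-one-geographic-segment-out: the study area is cut
into k equal-angle sectors about the presence centroid, each model is fitted
k times with one sector held out, and the held-out predictions are pooled
into a single AUC. Variable importance is the drop in that pooled AUC when a
covariate is omitted from the refits (delta AUC), standardised to shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, DegenerateFoldError, UndefinedMetricError
from .models import AlgorithmSpec, fit, predict
from .occurrence import GeoPoint, covariate_columns


@dataclass
class SegmentAssignment:
    """Radial sector index per record, by bearing from a common centre."""

    center: GeoPoint
    k: int
    offset_deg: float
    indices: np.ndarray  # per-record sector in {0..k-1}
    boundaries: np.ndarray  # sector start angles, degrees CCW from east


def radial_segments(
    records: pd.DataFrame,
    k: int,
    center: GeoPoint | None = None,
    offset_deg: float = 0.0,
) -> SegmentAssignment:
    """Assign every record (presences and all zero-response points) to one of
    k equal 360/k-degree sectors by its bearing from `center`.

    `records` needs lon/lat columns; the default centre is the mean lon/lat
    of rows labelled "presence" (all rows if there is no label column).
    Angles are measured counter-clockwise from due east, sector 0 starting at
    `offset_deg`. A record exactly at the centre goes to sector 0.
    """
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    if len(records) == 0:
        raise ConfigurationError("no records to segment")
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    if center is None:
        if "label" in records.columns and (records["label"] == "presence").any():
            sel = (records["label"] == "presence").to_numpy()
        else:
            sel = np.ones(len(records), dtype=bool)
        center = GeoPoint(float(lon[sel].mean()), float(lat[sel].mean()))

    x = (lon - center.lon) * np.cos(np.radians(center.lat))
    y = lat - center.lat
    ang = np.degrees(np.arctan2(y, x)) % 360.0
    width = 360.0 / k
    idx = np.floor(((ang - offset_deg) % 360.0) / width).astype(int)
    idx = np.clip(idx, 0, k - 1)  # guard the 360-degree wraparound edge
    idx[(x == 0) & (y == 0)] = 0
    boundaries = (offset_deg + width * np.arange(k)) % 360.0
    return SegmentAssignment(center, k, offset_deg, idx, boundaries)


@dataclass
class CvEvaluation:
    """Pooled out-of-segment predictions and their AUC."""

    predicted: np.ndarray
    observed: np.ndarray
    fold_index: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": self.fold_index,
                "observed": self.observed,
                "predicted": self.predicted,
            }
        )


def auc_roc(observed: np.ndarray, predicted: np.ndarray) -> float:
    """AUC-ROC as Mann-Whitney concordance: P(score_1 > score_0) + 0.5 P(tie).

    Computed from midranks, equivalent to enumerating all presence-absence
    pairs.
    """
    observed = np.asarray(observed)
    predicted = np.asarray(predicted, dtype=float)
    n1 = int((observed == 1).sum())
    n0 = int((observed == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC requires both classes")
    ranks = rankdata(predicted)
    r1 = ranks[observed == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def loocv_predict(
    spec: AlgorithmSpec, table: pd.DataFrame, segments: SegmentAssignment
) -> CvEvaluation:
    """Leave-one-segment-out CV: fit on k-1 sectors, predict the held-out one.

    Every record is predicted exactly once, by a model that never saw its
    sector; predictions are pooled across sectors into one AUC.
    """
    idx = segments.indices
    if len(idx) != len(table):
        raise ConfigurationError("segment assignment does not match the table")
    predicted = np.full(len(table), np.nan)
    fold_index = np.asarray(idx, dtype=int)
    y = table["response"].to_numpy()
    for f in range(segments.k):
        test = idx == f
        if not test.any():
            continue
        train = ~test
        y_train = y[train]
        if y_train.sum() == 0 or y_train.sum() == len(y_train):
            raise DegenerateFoldError(
                f"fold {f}: training data has a single response class"
            )
        model = fit(spec, table[train])
        predicted[test] = predict(model, table[test])
    auc = auc_roc(y, predicted)
    return CvEvaluation(predicted, y, fold_index, auc)


@dataclass
class VariableImportance:
    """Delta-AUC importance: AUC_full - AUC_without, per covariate."""

    full_auc: float
    delta_auc: dict[str, float]
    shares: dict[str, float] | None  # undefined unless the deltas sum > 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, d in self.delta_auc.items():
            rows.append(
                {
                    "variable": v,
                    "delta_auc": d,
                    "share": self.shares[v] if self.shares else np.nan,
                }
            )
        return pd.DataFrame(rows)


def delta_auc_importance(
    spec: AlgorithmSpec, table: pd.DataFrame, segments: SegmentAssignment
) -> VariableImportance:
    """Leave-one-covariate-out importance under the same spatial folds.

    Refits the cross-validation once per omitted covariate; delta is the drop
    in pooled AUC. Shares (deltas normalised to sum to 1) are reported only
    when the deltas sum to a positive number; raw deltas are always kept.
    """
    covs = covariate_columns(table)
    full = loocv_predict(spec, table, segments)
    deltas: dict[str, float] = {}
    for v in covs:
        reduced = loocv_predict(spec, table.drop(columns=[v]), segments)
        deltas[v] = full.auc - reduced.auc
    total = sum(deltas.values())
    shares = {v: d / total for v, d in deltas.items()} if total > 0 else None
    return VariableImportance(full.auc, deltas, shares)


@dataclass
class ThresholdResult:
    """The probability cut maximising Cohen's kappa, with its confusion counts."""

    threshold: float
    kappa: float
    tp: int
    fp: int
    fn: int
    tn: int


def max_kappa_threshold(
    observed: np.ndarray, predicted: np.ndarray
) -> ThresholdResult:
    """Search all candidate thresholds (every distinct prediction plus 0 and 1)
    for the one maximising Cohen's kappa of the binarised predictions
    (predicted presence iff probability >= threshold). Ties go to the
    smallest threshold.
    """
    observed = np.asarray(observed)
    predicted = np.asarray(predicted, dtype=float)
    n1 = int((observed == 1).sum())
    n0 = int((observed == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("kappa requires both classes")
    pos = np.sort(predicted[observed == 1])
    neg = np.sort(predicted[observed == 0])
    cands = np.unique(np.concatenate([predicted, [0.0, 1.0]]))
    # counts with prediction >= t, via sorted-array positions
    tp = n1 - np.searchsorted(pos, cands, side="left")
    fp = n0 - np.searchsorted(neg, cands, side="left")
    fn = n1 - tp
    tn = n0 - fp
    n = n1 + n0
    po = (tp + tn) / n
    pe = ((tp + fp) * n1 + (fn + tn) * n0) / (n * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)
    best = int(np.flatnonzero(kappa == kappa.max())[0])
    return ThresholdResult(
        threshold=float(cands[best]),
        kappa=float(kappa[best]),
        tp=int(tp[best]),
        fp=int(fp[best]),
        fn=int(fn[best]),
        tn=int(tn[best]),
    )


def select_algorithms(cv_aucs: dict[str, float], cutoff: float = 0.6) -> list[str]:
    """Algorithms whose pooled LOOCV AUC exceeds the cutoff advance to projection."""
    return [a for a, auc in cv_aucs.items() if auc > cutoff]
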