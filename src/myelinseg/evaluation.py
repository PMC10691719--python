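"""Instance-segmentation evaluation and measurement-agreement statistics.

Detection quality is object-based: target and prediction objects are matched
one-to-one at an IoU threshold (greedily, by descending IoU), giving TP/FP/FN
counts from which precision, recall and F1 follow.  Scores are averaged over
IoU thresholds 0.5-0.9 in steps of 0.05; thresholds below 0.5 are excluded
because a target could then overlap two predictions at once.

Measurement agreement between two hierarchies uses Lin's concordance
correlation coefficient (penalising both decorrelation and offset from the
identity line) and Bland-Altman bias with 1.96-SD limits of agreement,
computed on fibres paired at IoU >= 0.5 after discarding border-touching
fibres on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import FibreHierarchy, measure_fibres
from .io import InstanceMap

DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.901, 0.05), 2))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean pixel regions."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("regions must share the raster frame")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both regions empty")
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class MatchResult:
    """One-to-one instance matching at a single IoU threshold."""

    threshold: float
    pairs: list  # (target_label, prediction_label, iou)
    n_targets: int
    n_predictions: int

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return self.n_predictions - self.tp

    @property
    def fn(self) -> int:
        return self.n_targets - self.tp

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fn + self.fp
        return 2 * self.tp / denom if denom else 0.0


def _pairwise_iou(target: InstanceMap, prediction: InstanceMap):
    """IoU for every overlapping (target, prediction) label pair."""
    t, p = target.labels, prediction.labels
    if t.shape != p.shape:
        raise ValueError("instance maps must share dimensions")
    t_areas = np.bincount(t.ravel())
    p_areas = np.bincount(p.ravel())
    both = (t > 0) & (p > 0)
    if not both.any():
        return {}
    # encode overlapping label pairs and count pixels per pair
    pair_codes = t[both].astype(np.int64) * (p.max() + 1) + p[both]
    codes, counts = np.unique(pair_codes, return_counts=True)
    out = {}
    for code, inter in zip(codes, counts):
        tl, pl = divmod(int(code), int(p.max() + 1))
        union = t_areas[tl] + p_areas[pl] - inter
        out[(tl, pl)] = inter / union
    return out


def match_instances(
    target: InstanceMap, prediction: InstanceMap, threshold: float
) -> MatchResult:
    """Greedy one-to-one matching of instances at an IoU threshold.

    Pairs with IoU >= threshold are accepted in descending IoU order (ties:
    lower target label, then lower prediction label).  Thresholds below 0.5
    are refused: in that regime a target can overlap two predictions above
    threshold, making the pairing ambiguous.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0.5, 1.0]")
    ious = _pairwise_iou(target, prediction)
    candidates = sorted(
        ((v, tl, pl) for (tl, pl), v in ious.items() if v >= threshold),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    used_t, used_p, pairs = set(), set(), []
    for v, tl, pl in candidates:
        if tl in used_t or pl in used_p:
            continue
        used_t.add(tl)
        used_p.add(pl)
        pairs.append((tl, pl, float(v)))
    return MatchResult(
        threshold=float(threshold),
        pairs=pairs,
        n_targets=len(target.object_labels),
        n_predictions=len(prediction.object_labels),
    )


@dataclass
class DetectionScores:
    per_threshold: pd.DataFrame  # threshold, tp, fp, fn, precision, recall, f1
    mean_precision: float
    mean_recall: float
    mean_f1: float
    mean_jaccard: float


def detection_scores(
    target: InstanceMap,
    prediction: InstanceMap,
    thresholds=DEFAULT_IOU_THRESHOLDS,
) -> DetectionScores:
    """Precision/recall/F1 across IoU thresholds plus the mean Jaccard index.

    The mean Jaccard is the mean over *target* objects of their best IoU
    against any prediction (zero when a target overlaps nothing).
    """
    if len(target.object_labels) == 0:
        raise ValueError("at least one target object is required")
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    rows = []
    for t in thresholds:
        m = match_instances(target, prediction, t)
        rows.append(
            {
                "threshold": t, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
            }
        )
    per = pd.DataFrame(rows)
    ious = _pairwise_iou(target, prediction)
    best = {}
    for (tl, _), v in ious.items():
        best[tl] = max(best.get(tl, 0.0), v)
    mean_jaccard = float(
        np.mean([best.get(int(tl), 0.0) for tl in target.object_labels])
    )
    return DetectionScores(
        per_threshold=per,
        mean_precision=float(per["precision"].mean()),
        mean_recall=float(per["recall"].mean()),
        mean_f1=float(per["f1"].mean()),
        mean_jaccard=mean_jaccard,
    )


# ---------------------------------------------------------------------------
# measurement agreement
# ---------------------------------------------------------------------------


def lin_ccc(x, y) -> tuple:
    """Lin's concordance correlation coefficient with a 95% CI.

    ``ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` using
    1/n moment estimators; the CI comes from the Fisher z-transform with
    Lin's asymptotic standard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx2, sy2 = x.var(), y.var()
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    d = x.mean() - y.mean()
    ccc = 2 * sxy / (sx2 + sy2 + d**2)
    r = sxy / np.sqrt(sx2 * sy2)
    u = d / (sx2 * sy2) ** 0.25
    c2 = ccc**2
    if abs(ccc) >= 1.0 or r == 0:
        return float(ccc), (float(ccc), float(ccc))
    se_z2 = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - c2**2 * u**4 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    z = np.arctanh(ccc)
    half = 1.959963984540054 * np.sqrt(max(se_z2, 0.0))
    return float(ccc), (float(np.tanh(z - half)), float(np.tanh(z + half)))


def bland_altman(x, y) -> tuple:
    """Bias and 95% limits of agreement of ``y - x`` (prediction - target)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class AgreementStats:
    ccc: float
    ccc_ci95: tuple
    bias: float
    loa: tuple
    n_pairs: int
    fn_rate: float
    fp_rate: float


def pair_fibres_for_agreement(
    target_h: FibreHierarchy,
    pred_h: FibreHierarchy,
    min_iou: float = 0.5,
    exclude_border: bool = True,
):
    """Pair fibres between two hierarchies for agreement analysis.

    Border-touching fibres are removed on both sides first (incomplete fibres
    yield unreliable metrics), then fibres are matched at ``min_iou``.
    Returns a table of paired measurements (area, g-ratios for target and
    prediction) plus pooled false-negative and false-positive rates whose
    denominators also exclude border fibres.
    """
    if not target_h.entries:
        raise ValueError("empty target hierarchy")

    def usable(h):
        return [e for e in h.entries if not (exclude_border and e.border_flag)]

    t_entries, p_entries = usable(target_h), usable(pred_h)
    t_rows = measure_fibres(target_h).set_index("fibre_id")
    p_rows = measure_fibres(pred_h).set_index("fibre_id")

    pairs = []
    used_p = set()
    cands = []
    for te in t_entries:
        for pe in p_entries:
            inter = np.logical_and(te.fibre_mask, pe.fibre_mask).sum()
            if inter == 0:
                continue
            union = te.fibre_mask.sum() + pe.fibre_mask.sum() - inter
            v = inter / union
            if v >= min_iou:
                cands.append((v, te.fibre_id, pe.fibre_id))
    used_t = set()
    for v, tf, pf in sorted(cands, key=lambda x: (-x[0], x[1], x[2])):
        if tf in used_t or pf in used_p:
            continue
        used_t.add(tf)
        used_p.add(pf)
        pairs.append((tf, pf, v))

    rows = []
    for tf, pf, v in pairs:
        rows.append(
            {
                "target_fibre_id": tf,
                "pred_fibre_id": pf,
                "iou": v,
                "area_fibre_target": t_rows.loc[tf, "area_fibre_um2"],
                "area_fibre_pred": p_rows.loc[pf, "area_fibre_um2"],
                "g_myelin_target": t_rows.loc[tf, "g_myelin"],
                "g_myelin_pred": p_rows.loc[pf, "g_myelin"],
                "g_axon_target": t_rows.loc[tf, "g_axon"],
                "g_axon_pred": p_rows.loc[pf, "g_axon"],
            }
        )
    table = pd.DataFrame(rows)
    n_t, n_p = len(t_entries), len(p_entries)
    fn_rate = (n_t - len(pairs)) / n_t if n_t else 0.0
    fp_rate = (n_p - len(pairs)) / n_p if n_p else 0.0
    return table, float(fn_rate), float(fp_rate)


def agreement_stats(
    target_h: FibreHierarchy,
    pred_h: FibreHierarchy,
    measure: str = "area_fibre",
    min_iou: float = 0.5,
    exclude_border: bool = True,
) -> AgreementStats:
    """CCC + Bland-Altman summary for one paired measurement column."""
    table, fn_rate, fp_rate = pair_fibres_for_agreement(
        target_h, pred_h, min_iou, exclude_border
    )
    x = table[f"{measure}_target"].to_numpy()
    y = table[f"{measure}_pred"].to_numpy()
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    ccc, ci = lin_ccc(x, y)
    bias, lo, hi = bland_altman(x, y)
    return AgreementStats(ccc, ci, bias, (lo, hi), int(x.size), fn_rate, fp_rate)
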