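"""Panel-vs-exome TMB classification concordance.

Samples are dichotomised as TMB-high versus non-high at a shared cut-off
(>= counts as high) on both the panel and the exome axis; the exome call is
the reference. Confusion grids over the cut-off sweep {5, 10, 20, 40}/Mb give
the misclassification rate (FP% + FN%). ROC analysis against the exome label
(default dichotomisation 10/Mb) yields a per-panel AUC and the
accuracy-optimal calibrated cut-point, pan-cancer or per tumour type.

Cut-point convention: candidate thresholds are the midpoints between adjacent
distinct panel-TMB values (plus sentinels below the minimum and above the
maximum); accuracy ties are broken toward the lowest threshold. Reporting
midpoints makes calibrated cut-points reproducible regardless of sample
granularity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .tmb import SampleProfile

PAN_CANCER = "pan-cancer"
DEFAULT_CUTOFFS = (5.0, 10.0, 20.0, 40.0)


class ConcordanceError(ValueError):
    pass


class SingleClassError(ConcordanceError):
    """Raised when a stratum has only one exome class: ROC undefined."""


@dataclass(frozen=True)
class ConfusionResult:
    panel: str
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tp_pct(self) -> float:
        return 100.0 * self.tp / self.n

    @property
    def fp_pct(self) -> float:
        return 100.0 * self.fp / self.n

    @property
    def tn_pct(self) -> float:
        return 100.0 * self.tn / self.n

    @property
    def fn_pct(self) -> float:
        return 100.0 * self.fn / self.n

    @property
    def misclassified_pct(self) -> float:
        return self.fp_pct + self.fn_pct


def _panel_scores(profiles: Sequence[SampleProfile], panel: str) -> np.ndarray:
    try:
        return np.array([p.panel_tmb[panel] for p in profiles], dtype=float)
    except KeyError:
        raise ConcordanceError(f"unknown panel name: {panel}") from None


def confusion_at_cutoff(
    profiles: Sequence[SampleProfile], panel: str, cutoff: float
) -> ConfusionResult:
    """Tabulate panel-high vs exome-high calls at one shared cut-off."""
    if not profiles:
        raise ConcordanceError("empty cohort")
    panel_high = _panel_scores(profiles, panel) >= cutoff
    exome_high = np.array([p.exome_tmb for p in profiles]) >= cutoff
    return ConfusionResult(
        panel=panel,
        cutoff=cutoff,
        tp=int(np.sum(panel_high & exome_high)),
        fp=int(np.sum(panel_high & ~exome_high)),
        tn=int(np.sum(~panel_high & ~exome_high)),
        fn=int(np.sum(~panel_high & exome_high)),
    )


def cutoff_sweep(
    profiles: Sequence[SampleProfile],
    panel: str,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> list[ConfusionResult]:
    if not profiles:
        raise ConcordanceError("empty cohort")
    return [confusion_at_cutoff(profiles, panel, c) for c in cutoffs]


def optimal_cutpoint(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float]:
    """Accuracy-maximising threshold for ``score >= t`` against binary labels.

    Returns ``(cutpoint, accuracy)``. Candidates are midpoints between
    adjacent distinct scores plus one sentinel below the minimum (all
    positive) and one above the maximum (all negative); accuracy ties break
    toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0 or scores.size != labels.size:
        raise ConcordanceError("scores and labels must be equal-length and non-empty")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = int(labels.sum())
    # For threshold t: correct = (#pos with score >= t) + (#neg with score < t).
    order = np.argsort(scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    pos_below = np.cumsum(sorted_labels)  # positives with score <= sorted_scores[i]
    idx = np.searchsorted(sorted_scores, candidates, side="left")
    pos_lt = np.where(idx > 0, pos_below[np.maximum(idx - 1, 0)], 0)
    neg_lt = idx - pos_lt
    correct = (n_pos - pos_lt) + neg_lt
    best = int(np.argmax(correct))  # argmax takes the first (lowest) maximiser
    return float(candidates[best]), float(correct[best] / scores.size)


@dataclass(frozen=True)
class RocResult:
    panel: str
    stratum: str
    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float
    optimal_cutpoint: float
    optimal_accuracy: float
    n: int
    n_positive: int


def _stratum_profiles(
    profiles: Sequence[SampleProfile], stratum: str
) -> list[SampleProfile]:
    if stratum == PAN_CANCER:
        return list(profiles)
    subset = [p for p in profiles if p.tumour_type == stratum]
    if not subset:
        raise ConcordanceError(f"no samples with tumour type {stratum!r}")
    return subset


def roc_curve(
    profiles: Sequence[SampleProfile],
    panel: str,
    exome_cutoff: float = 10.0,
    stratum: str = PAN_CANCER,
) -> RocResult:
    """ROC of panel TMB against the exome-high label within one stratum.

    AUC equals the probability-of-correct-ranking (Mann-Whitney) statistic;
    tied scores contribute 1/2 per pair.
    """
    subset = _stratum_profiles(profiles, stratum)
    scores = _panel_scores(subset, panel)
    labels = np.array([p.exome_tmb for p in subset]) >= exome_cutoff
    if labels.all() or not labels.any():
        raise SingleClassError(
            f"ROC undefined for panel {panel}, stratum {stratum!r}: "
            "only one exome class present"
        )
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    cutpoint, accuracy = optimal_cutpoint(scores, labels)
    return RocResult(
        panel=panel,
        stratum=stratum,
        thresholds=tuple(float(t) for t in thresholds),
        fpr=tuple(float(x) for x in fpr),
        tpr=tuple(float(x) for x in tpr),
        auc=auc,
        optimal_cutpoint=cutpoint,
        optimal_accuracy=accuracy,
        n=int(labels.size),
        n_positive=int(labels.sum()),
    )


def table1_frame(
    profiles: Sequence[SampleProfile],
    panel_names: Sequence[str],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Confusion grid (panel x cut-off), full precision."""
    rows = []
    for name in panel_names:
        for res in cutoff_sweep(profiles, name, cutoffs):
            rows.append(
                {
                    "panel": name,
                    "cutoff": res.cutoff,
                    "tp": res.tp,
                    "fp": res.fp,
                    "tn": res.tn,
                    "fn": res.fn,
                    "tp_pct": res.tp_pct,
                    "fp_pct": res.fp_pct,
                    "tn_pct": res.tn_pct,
                    "fn_pct": res.fn_pct,
                    "misclassified_pct": res.misclassified_pct,
                }
            )
    return pd.DataFrame(rows)


def roc_summary_frames(
    profiles: Sequence[SampleProfile],
    panel_names: Sequence[str],
    exome_cutoff: float = 10.0,
    strata: Sequence[str] = (PAN_CANCER,),
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """AUC/cut-point summary and ROC point table over panels x strata.

    Single-class strata are skipped; their names are returned for logging.
    """
    summary_rows, point_rows, skipped = [], [], []
    for stratum in strata:
        for name in panel_names:
            try:
                roc = roc_curve(profiles, name, exome_cutoff, stratum)
            except SingleClassError:
                if stratum not in skipped:
                    skipped.append(stratum)
                break
            summary_rows.append(
                {
                    "panel": name,
                    "stratum": stratum,
                    "n": roc.n,
                    "n_positive": roc.n_positive,
                    "auc": roc.auc,
                    "optimal_cutpoint": roc.optimal_cutpoint,
                    "optimal_accuracy": roc.optimal_accuracy,
                }
            )
            for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr):
                point_rows.append(
                    {"panel": name, "stratum": stratum, "threshold": t, "fpr": f, "tpr": s}
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(point_rows), skipped
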