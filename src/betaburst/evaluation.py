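"""Performance metrics for burst prediction.

Window-level confusion counts feed the ratio metrics (ACC, PRC, SEN,
SPC), the false-positive rate per minute of analyzed data, and the
threshold-sweep trade-off curve.  Event-level bookkeeping supplies the
mean prediction time prior to burst onset (PT-PBO): per burst, the
earliest positive decision among its predictive windows defines the
prediction time, and bursts with no positive window contribute to FN
rather than to PT-PBO.  The module also reconstructs the mean beta
amplitude envelope around TP, FP and FN predictions, which is where the
pre-burst amplitude dip becomes visible.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .preprocess import BurstAnnotation, EnvelopeSeries
from .windowing import CLASS0, CLASS1, CLASS_BURST, LabeledSegmentSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class OutcomeTimeline:
    """Per-window scores, decisions and labels, ordered by window end."""

    scores: np.ndarray
    decisions: np.ndarray
    labels: np.ndarray
    end_times: np.ndarray   # window end, s
    source_burst: np.ndarray
    threshold: float

    def __len__(self) -> int:
        return len(self.scores)


def make_timeline(
    segset: LabeledSegmentSet, scores: np.ndarray, threshold: float
) -> OutcomeTimeline:
    if np.any(segset.labels == CLASS_BURST):
        raise ValueError("timeline must not contain Class Burst windows")
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(segset):
        raise ValueError("one score per segment required")
    return OutcomeTimeline(
        scores=scores,
        decisions=scores >= threshold,
        labels=segset.labels.astype(int),
        end_times=segset.end_samples / segset.sampling_rate,
        source_burst=segset.source_burst.copy(),
        threshold=threshold,
    )


@dataclasses.dataclass
class MetricsReport:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    PRC: float
    SEN: float
    SPC: float
    AUC_ROC: float
    AUC_PR: float
    FP_per_min: float
    PT_PBO: float = math.nan
    flags: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("flags")
        return d


def _safe_ratio(num: float, den: float, name: str, flags: dict) -> float:
    if den == 0:
        flags[name] = "undefined (zero denominator)"
        return math.nan
    return num / den


def compute_metrics(timeline: OutcomeTimeline, test_duration: float) -> MetricsReport:
    """Confusion counts and ratio metrics; undefined ratios are NaN with
    an entry in ``flags`` rather than silently zero."""
    if len(timeline) == 0:
        raise ValueError("empty timeline")
    if test_duration <= 0:
        raise ValueError("test_duration must be positive")
    y, d = timeline.labels, timeline.decisions
    tp = int(np.sum((y == 1) & d))
    fn = int(np.sum((y == 1) & ~d))
    fp = int(np.sum((y == 0) & d))
    tn = int(np.sum((y == 0) & ~d))
    flags: dict = {}
    both = len(np.unique(y)) == 2
    if both:
        auc_roc = float(roc_auc_score(y, timeline.scores))
        auc_pr = float(average_precision_score(y, timeline.scores))
    else:
        flags["AUC"] = "undefined (single class)"
        auc_roc = auc_pr = math.nan
    return MetricsReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        ACC=_safe_ratio(tp + tn, tp + tn + fp + fn, "ACC", flags),
        PRC=_safe_ratio(tp, tp + fp, "PRC", flags),
        SEN=_safe_ratio(tp, tp + fn, "SEN", flags),
        SPC=_safe_ratio(tn, tn + fp, "SPC", flags),
        AUC_ROC=auc_roc,
        AUC_PR=auc_pr,
        FP_per_min=fp / (test_duration / 60.0),
        flags=flags,
    )


def compute_auc(scores: np.ndarray, labels: np.ndarray, kind: str = "roc") -> float:
    """Area under the ROC curve (threshold sweep over all distinct
    scores, equivalent to pairwise concordance with half credit for
    ties) or under the precision-recall curve (interpolation-free step
    summation)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if kind == "roc":
        return float(roc_auc_score(labels, scores))
    if kind == "pr":
        return float(average_precision_score(labels, scores))
    raise ValueError(f"unknown kind {kind!r}")


def prediction_time_pbo(
    timeline: OutcomeTimeline, bursts: BurstAnnotation
) -> float:
    """Mean interval (ms) between the earliest positive predictive
    window and burst onset, over bursts with at least one positive
    window; NaN (flagged in the log) when no burst was predicted."""
    onset_times = bursts.onset_times
    intervals = []
    for b in np.unique(timeline.source_burst[timeline.labels == CLASS1]):
        mask = (timeline.source_burst == b) & (timeline.labels == CLASS1) \
            & timeline.decisions
        if not np.any(mask):
            continue
        earliest_end = timeline.end_times[mask].min()
        intervals.append((onset_times[b] - earliest_end) * 1000.0)
    if not intervals:
        logger.warning("no predicted bursts; PT-PBO undefined")
        return math.nan
    return float(np.mean(intervals))


def threshold_sweep(
    scores: np.ndarray, labels: np.ndarray, duration_min: float
) -> pd.DataFrame:
    """(threshold, SEN, FP_per_min) at every distinct score, ascending.
    Both SEN and FP/min are non-increasing in the threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    last = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tp = np.cumsum(y_sorted)[last]
    fp = np.cumsum(1 - y_sorted)[last]
    df = pd.DataFrame(
        {
            "threshold": s_sorted[last],
            "SEN": tp / labels.sum(),
            "FP_per_min": fp / duration_min,
        }
    )
    return df.iloc[::-1].reset_index(drop=True)


@dataclasses.dataclass
class EnvelopeAverage:
    """Mean +/- SEM envelope for one prediction outcome."""

    time_ms: np.ndarray  # for burst-locked groups: time re burst onset
    mean: np.ndarray
    sem: np.ndarray
    n: int
    t_min_ms: float      # time of the envelope-minimum of the mean trace

    def dip_contrast(
        self,
        tmax_ms: float | None = None,
        baseline_tmax_ms: float | None = None,
    ) -> tuple[float, float]:
        """Depth of the trace minimum below the pre-onset baseline level,
        plus the SEM at the minimum.

        The minimum is searched over times <= ``tmax_ms`` (excluding the
        terminal amplitude rise into the burst), and the baseline is the
        trace mean over times <= ``baseline_tmax_ms`` (a region early
        enough to precede the dip).  A minimum deeper than 2 SEM below
        the baseline indicates a genuine pre-burst dip rather than noise.
        """
        search = np.ones_like(self.mean, dtype=bool) if tmax_ms is None \
            else self.time_ms <= tmax_ms
        base = search if baseline_tmax_ms is None \
            else self.time_ms <= baseline_tmax_ms
        vals = self.mean[search]
        i = int(np.argmin(vals))
        return float(np.mean(self.mean[base]) - vals[i]), \
            float(self.sem[search][i])


def _average(stack: np.ndarray, time_ms: np.ndarray) -> EnvelopeAverage:
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(stack)) if len(stack) > 1 \
        else np.zeros_like(mean)
    return EnvelopeAverage(
        time_ms=time_ms,
        mean=mean,
        sem=sem,
        n=len(stack),
        t_min_ms=float(time_ms[np.argmin(mean)]),
    )


def mean_envelope_by_outcome(
    segset: LabeledSegmentSet,
    timeline: OutcomeTimeline,
    envelope: EnvelopeSeries,
    bursts: BurstAnnotation,
) -> dict[str, EnvelopeAverage]:
    """Mean beta-envelope per outcome group {TP, FP, FN}.

    For TP and FN the latest predictive window preceding each burst is
    selected and time-locked to burst onset (that window's own decision
    determines the group).  FP windows are averaged on their
    window-relative time axis.  Only bursts whose latest predictive
    window shares the modal end offset enter the burst-locked averages,
    so all traces align on one time grid.  Empty groups are omitted.
    """
    fs = segset.sampling_rate
    L = segset.window_samples
    env = envelope.envelope

    tp_windows: list[tuple[int, int]] = []  # (end_sample, onset_sample)
    fn_windows: list[tuple[int, int]] = []
    is_c1 = timeline.labels == CLASS1
    for b in np.unique(timeline.source_burst[is_c1]):
        mask = (timeline.source_burst == b) & is_c1
        i_latest = np.flatnonzero(mask)[np.argmax(timeline.end_times[mask])]
        end = segset.end_samples[i_latest]
        entry = (end, bursts.onsets[b])
        (tp_windows if timeline.decisions[i_latest] else fn_windows).append(entry)

    out: dict[str, EnvelopeAverage] = {}
    for name, items in (("TP", tp_windows), ("FN", fn_windows)):
        if not items:
            logger.info("no %s predictions; group omitted", name)
            continue
        offsets = np.array([end - onset for end, onset in items])
        modal = np.bincount(offsets - offsets.min()).argmax() + offsets.min()
        keep = [it for it, off in zip(items, offsets) if off == modal]
        if len(keep) < len(items):
            logger.info(
                "%s: %d of %d bursts with non-modal window offsets dropped "
                "from the envelope average", name, len(items) - len(keep),
                len(items),
            )
        stack = np.stack([env[end - L : end] for end, _ in keep])
        time_ms = (np.arange(modal - L, modal)) / fs * 1000.0
        out[name] = _average(stack, time_ms)

    fp_mask = (timeline.labels == CLASS0) & timeline.decisions
    if np.any(fp_mask):
        ends = segset.end_samples[fp_mask]
        stack = np.stack([env[e - L : e] for e in ends])
        time_ms = np.arange(-L, 0) / fs * 1000.0
        out["FP"] = _average(stack, time_ms)
    else:
        logger.info("no FP predictions; group omitted")
    return out


def write_metrics_tsv(reports: dict[str, MetricsReport], path) -> None:
    rows = [{"run": name, **rep.to_dict()} for name, rep in reports.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_envelope_averages_tsv(groups: dict[str, EnvelopeAverage], path) -> None:
    frames = []
    for outcome, avg in groups.items():
        frames.append(
            pd.DataFrame(
                {"time_ms": avg.time_ms, "mean": avg.mean, "sem": avg.sem,
                 "outcome": outcome}
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)
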