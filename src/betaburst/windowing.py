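"""Labeled segment construction for burst prediction.

Two labeling schemes operate on the beta-filtered series plus a burst
annotation:

* fixed-window: one predictive (Class 1) segment per burst, ending a
  fixed lead time before onset, with an equal number of randomly
  subsampled non-predictive (Class 0) segments that end at least a guard
  gap before any onset and keep clear of burst intervals;
* sliding-window: windows tiled at a fixed stride along the whole
  series, mimicking real-time operation.  Windows ending inside a burst
  are labeled Class Burst and excluded from model data.  Each burst
  contributes a densely sampled (5 ms stride) set of Class 1 windows
  ending 30-85 ms before onset; grid windows ending within the 0-90 ms
  pre-onset band are dropped (the predictive band is covered by the
  dense set, and ends nearer than 30 ms have no defined label); all
  remaining windows are Class 0, with no class balancing.

All windows are half-open sample ranges [end - L, end); end offsets are
reported in ms relative to the next burst onset (negative = before it).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .preprocess import BurstAnnotation

logger = logging.getLogger(__name__)

CLASS0 = 0
CLASS1 = 1
CLASS_BURST = 2


@dataclasses.dataclass
class WindowConfig:
    """Segmentation geometry, all lengths in ms.

    Defaults follow the 600 Hz regime: 200 ms windows, 30 ms sliding
    stride, 50 ms Class 0 stride in the fixed scheme, 250 ms guard gap,
    and 12 predictive windows per burst ending 30-85 ms before onset on
    a 5 ms grid.
    """

    window_length: float = 200.0
    stride: float = 30.0
    lead_time: float = 60.0
    guard_gap: float = 250.0
    class0_stride: float = 50.0
    augment_stride: float = 5.0
    augment_count: int = 12
    augment_min_lead: float = 30.0
    predictive_band_max: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.stride <= 0:
            raise ValueError("window_length and stride must be positive")
        max_lead = self.augment_min_lead + self.augment_stride * (self.augment_count - 1)
        if self.guard_gap <= max_lead:
            raise ValueError(
                f"guard_gap ({self.guard_gap} ms) must exceed the largest "
                f"augmented lead ({max_lead} ms)"
            )

    def augment_offsets_ms(self) -> np.ndarray:
        """End offsets of the dense Class 1 set, ms before onset."""
        return self.augment_min_lead + self.augment_stride * np.arange(self.augment_count)


@dataclasses.dataclass
class LabeledSegmentSet:
    """Fixed-length windows of the beta-filtered signal with labels."""

    segments: np.ndarray          # (n, window_samples)
    labels: np.ndarray            # (n,) in {CLASS0, CLASS1, CLASS_BURST}
    end_offsets_ms: np.ndarray    # (n,) end time re next onset; NaN if none
    end_samples: np.ndarray       # (n,) window end (exclusive) in samples
    source_burst: np.ndarray      # (n,) burst index for Class 1, else -1
    sampling_rate: float
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("segments", "end_offsets_ms", "end_samples", "source_burst"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def window_samples(self) -> int:
        return self.segments.shape[1]

    @property
    def start_samples(self) -> np.ndarray:
        return self.end_samples - self.window_samples

    def subset(self, mask: np.ndarray, **meta) -> "LabeledSegmentSet":
        return LabeledSegmentSet(
            segments=self.segments[mask],
            labels=self.labels[mask],
            end_offsets_ms=self.end_offsets_ms[mask],
            end_samples=self.end_samples[mask],
            source_burst=self.source_burst[mask],
            sampling_rate=self.sampling_rate,
            metadata={**self.metadata, **meta},
        )

    def model_data(self) -> "LabeledSegmentSet":
        """Drop Class Burst windows: bursts themselves are detectable by
        thresholding and never enter training or testing."""
        return self.subset(self.labels != CLASS_BURST)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @staticmethod
    def concatenate(sets: list["LabeledSegmentSet"], **meta) -> "LabeledSegmentSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        fs = sets[0].sampling_rate
        if any(s.sampling_rate != fs for s in sets):
            raise ValueError("sampling rates differ")
        return LabeledSegmentSet(
            segments=np.concatenate([s.segments for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            end_offsets_ms=np.concatenate([s.end_offsets_ms for s in sets]),
            end_samples=np.concatenate([s.end_samples for s in sets]),
            source_burst=np.concatenate([s.source_burst for s in sets]),
            sampling_rate=fs,
            metadata=meta,
        )


def _ms_to_samples(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def _offset_to_next_onset_ms(end: int, onsets: np.ndarray, fs: float) -> float:
    i = np.searchsorted(onsets, end)
    if i >= len(onsets):
        return np.nan
    return (end - onsets[i]) / fs * 1000.0


def _gather(filtered, ends, L):
    ends = np.asarray(ends, dtype=int)
    idx = ends[:, None] + np.arange(-L, 0)[None, :]
    return filtered[idx]


def fixed_class0_candidate_ends(
    n_samples: int, bursts: BurstAnnotation, cfg: WindowConfig
) -> list[int]:
    """All eligible Class 0 window ends for the fixed scheme: tiled at
    ``cfg.class0_stride``, ending at least ``cfg.guard_gap`` before the
    next onset, and not touching any burst interval (closed-interval
    overlap in continuous time)."""
    fs = bursts.sampling_rate
    L = _ms_to_samples(cfg.window_length, fs)
    guard = _ms_to_samples(cfg.guard_gap, fs)
    ends = []
    for e in range(L, n_samples + 1, _ms_to_samples(cfg.class0_stride, fs)):
        i = np.searchsorted(bursts.onsets, e)
        if i < len(bursts.onsets) and e > bursts.onsets[i] - guard:
            continue
        if np.any((e >= bursts.onsets) & (e - L <= bursts.offsets)):
            continue
        ends.append(e)
    return ends


def make_fixed_window_dataset(
    filtered: np.ndarray,
    bursts: BurstAnnotation,
    cfg: WindowConfig,
    seed: int | None = None,
) -> LabeledSegmentSet:
    """Fixed-window labeling at one lead time, with balanced classes.

    Class 1: one window per usable burst ending exactly ``cfg.lead_time``
    ms before onset.  Class 0: windows tiled at ``cfg.class0_stride``
    that end at least ``cfg.guard_gap`` ms before the next onset and do
    not touch any burst interval (closed-interval overlap), randomly
    subsampled (seeded) to the Class 1 count.
    """
    fs = bursts.sampling_rate
    filtered = np.asarray(filtered, dtype=float)
    n = len(filtered)
    L = _ms_to_samples(cfg.window_length, fs)
    lead = _ms_to_samples(cfg.lead_time, fs)

    class1_ends, class1_src = [], []
    for b, onset in enumerate(bursts.onsets):
        e = onset - lead
        if e - L < 0:
            logger.info("burst %d too close to recording start; skipped", b)
            continue
        class1_ends.append(e)
        class1_src.append(b)
    if not class1_ends:
        raise ValueError("no usable bursts for Class 1 segments")

    candidate_ends = fixed_class0_candidate_ends(n, bursts, cfg)
    if not candidate_ends:
        raise ValueError("no eligible Class 0 segments")

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n1 = len(class1_ends)
    if len(candidate_ends) < n1:
        logger.warning(
            "only %d Class 0 candidates for %d Class 1 segments",
            len(candidate_ends), n1,
        )
        chosen = np.array(candidate_ends)
    else:
        chosen = rng.choice(candidate_ends, size=n1, replace=False)
    chosen = np.sort(chosen)

    ends = np.concatenate([class1_ends, chosen]).astype(int)
    labels = np.r_[np.full(n1, CLASS1), np.full(len(chosen), CLASS0)].astype(np.int8)
    src = np.r_[class1_src, np.full(len(chosen), -1)].astype(int)
    offs = np.array([_offset_to_next_onset_ms(e, bursts.onsets, fs) for e in ends])
    order = np.argsort(ends, kind="stable")
    return LabeledSegmentSet(
        segments=_gather(filtered, ends[order], L),
        labels=labels[order],
        end_offsets_ms=offs[order],
        end_samples=ends[order],
        source_burst=src[order],
        sampling_rate=fs,
        metadata={"scheme": "fixed", "lead_time_ms": cfg.lead_time,
                  "balance_seed": int(cfg.seed if seed is None else seed)},
    )


def make_sliding_window_dataset(
    filtered: np.ndarray,
    bursts: BurstAnnotation,
    cfg: WindowConfig,
) -> LabeledSegmentSet:
    """Sliding-window labeling mimicking real-time prediction."""
    fs = bursts.sampling_rate
    filtered = np.asarray(filtered, dtype=float)
    n = len(filtered)
    L = _ms_to_samples(cfg.window_length, fs)
    stride = _ms_to_samples(cfg.stride, fs)

    ends, labels, src = [], [], []
    for e in range(L, n + 1, stride):
        i = np.searchsorted(bursts.onsets, e)  # onsets[i-1] < e <= onsets[i]
        inside = i > 0 and e <= bursts.offsets[i - 1]
        if inside:
            ends.append(e)
            labels.append(CLASS_BURST)
            src.append(i - 1)
            continue
        if i < len(bursts.onsets):
            d_ms = (bursts.onsets[i] - e) / fs * 1000.0
            if d_ms <= cfg.predictive_band_max:
                # covered by the dense Class 1 set (30-90 ms) or without
                # a defined label (< 30 ms); excluded either way
                continue
        ends.append(e)
        labels.append(CLASS0)
        src.append(-1)

    offsets_ms = cfg.augment_offsets_ms()
    for b, onset in enumerate(bursts.onsets):
        kept = 0
        for d in offsets_ms:
            e = onset - _ms_to_samples(d, fs)
            if e - L < 0:
                continue
            if b > 0 and e <= bursts.offsets[b - 1]:
                continue
            ends.append(e)
            labels.append(CLASS1)
            src.append(b)
            kept += 1
        if 0 < kept < cfg.augment_count:
            logger.info("burst %d: Class 1 set truncated to %d segments", b, kept)

    ends = np.asarray(ends, dtype=int)
    labels = np.asarray(labels, dtype=np.int8)
    src = np.asarray(src, dtype=int)
    offs = np.array([_offset_to_next_onset_ms(e, bursts.onsets, fs) for e in ends])
    order = np.argsort(ends, kind="stable")
    return LabeledSegmentSet(
        segments=_gather(filtered, ends[order], L),
        labels=labels[order],
        end_offsets_ms=offs[order],
        end_samples=ends[order],
        source_burst=src[order],
        sampling_rate=fs,
        metadata={"scheme": "sliding", "stride_ms": cfg.stride},
    )


@dataclasses.dataclass
class SplitSpec:
    """Train/validation/test assignment.

    Either time-contiguous fractions of a single recording, or an
    explicit per-session assignment (values 'train', 'val', 'test' or
    'val+test' for a session split equally between the two).
    """

    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    session_assignment: list[str] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def split_dataset(
    segments: LabeledSegmentSet, spec: SplitSpec
) -> tuple[LabeledSegmentSet, LabeledSegmentSet, LabeledSegmentSet]:
    """Contiguous-in-time partitioning; windows straddling a partition
    boundary are dropped so that no window spans two partitions."""
    n = len(segments)
    order = np.argsort(segments.end_samples, kind="stable")
    f0, f1, _ = spec.fractions
    i1 = int(round(f0 * n))
    i2 = int(round((f0 + f1) * n))
    idx_train, idx_val, idx_test = order[:i1], order[i1:i2], order[i2:]

    def _trim(idx: np.ndarray, prev_idx: np.ndarray) -> np.ndarray:
        if len(idx) == 0 or len(prev_idx) == 0:
            return idx
        boundary = segments.end_samples[prev_idx].max()
        keep = segments.start_samples[idx] >= boundary
        return idx[keep]

    idx_val = _trim(idx_val, idx_train)
    idx_test = _trim(idx_test, idx_val if len(idx_val) else idx_train)

    parts = []
    for name, idx in (("train", idx_train), ("val", idx_val), ("test", idx_test)):
        if len(idx) == 0:
            raise ValueError(
                f"{name} partition is empty; need enough windows that every "
                "fraction contains at least one"
            )
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        parts.append(segments.subset(mask, partition=name, fractions=spec.fractions))
    return tuple(parts)


def split_by_sessions(
    sets: list[LabeledSegmentSet], assignment: list[str]
) -> tuple[LabeledSegmentSet, LabeledSegmentSet, LabeledSegmentSet]:
    """Whole sessions (or days) assigned to partitions; a 'val+test'
    session is split equally between validation and test."""
    if len(sets) != len(assignment):
        raise ValueError("one assignment per session required")
    pools: dict[str, list[LabeledSegmentSet]] = {"train": [], "val": [], "test": []}
    for segset, dest in zip(sets, assignment):
        if dest == "val+test":
            # fractions (0, .5, .5) would make an empty train partition;
            # split manually at the midpoint
            order = np.argsort(segset.end_samples, kind="stable")
            half = len(order) // 2
            m_val = np.zeros(len(segset), dtype=bool)
            m_val[order[:half]] = True
            boundary = segset.end_samples[order[:half]].max()
            m_test = ~m_val & (segset.start_samples >= boundary)
            pools["val"].append(segset.subset(m_val, partition="val"))
            pools["test"].append(segset.subset(m_test, partition="test"))
        elif dest in pools:
            pools[dest].append(segset.subset(np.ones(len(segset), bool), partition=dest))
        else:
            raise ValueError(f"unknown assignment {dest!r}")
    out = []
    for name in ("train", "val", "test"):
        if not pools[name]:
            raise ValueError(f"{name} partition is empty")
        out.append(LabeledSegmentSet.concatenate(pools[name], partition=name))
    return tuple(out)
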