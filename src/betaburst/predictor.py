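"""Patient-specific CNN that maps a beta-filtered window to the
probability of an imminent burst onset.

The network is a compact 1-D temporal CNN: a stack of convolution ->
batch normalization -> ReLU -> max-pool -> dropout blocks, global
average pooling, and a dense sigmoid head.  It is trained with weighted
binary cross-entropy (inverse-frequency class weights, which preserves
the temporal statistics of the majority class better than oversampling)
and early stopping on validation AUC-PR, the imbalance-robust metric.
Input windows are standardized by training-set mean/SD; the sigmoid
decision threshold is calibrated on validation data only.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import pickle
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score

from . import nn
from .windowing import CLASS_BURST, LabeledSegmentSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ModelConfig:
    """Architecture and optimization hyperparameters.

    input_length is in samples and must match the window length times
    the sampling rate (120 for 200 ms at 600 Hz, 100 for 400 ms at
    250 Hz).
    """

    input_length: int = 120
    conv_blocks: int = 3
    kernel_length: int = 13
    filters_per_block: tuple[int, ...] = (8, 16, 32)
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 10
    seed: int = 0
    class_weighting: bool = True
    lr_schedule: str = "constant"  # or "cosine"
    head: str = "flatten"  # position-aware head; "gap" for global average pooling

    def __post_init__(self) -> None:
        if len(self.filters_per_block) != self.conv_blocks:
            raise ValueError("one filter count per conv block required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class BurstPredictorNet:
    """Untrained network plus its seeded random stream."""

    def __init__(self, cfg: ModelConfig):
        length = cfg.input_length
        for depth in range(cfg.conv_blocks):
            if length < 2:
                max_depth = max(int(math.floor(math.log2(cfg.input_length))), 0)
                raise ValueError(
                    f"input_length {cfg.input_length} supports at most "
                    f"{max_depth} pooling stages, got {cfg.conv_blocks}"
                )
            length //= 2
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        layers: list[nn.Layer] = []
        c_in = 1
        for c_out in cfg.filters_per_block:
            layers.append(nn.Conv1d(c_in, c_out, cfg.kernel_length, self.rng))
            layers.append(nn.BatchNorm1d(c_out))
            layers.append(nn.ReLU())
            layers.append(nn.MaxPool1d())
            layers.append(nn.Dropout(cfg.dropout, self.rng))
            c_in = c_out
        if cfg.head == "gap":
            layers.append(nn.GlobalAvgPool())
            layers.append(nn.Dense(c_in))
        elif cfg.head == "flatten":
            # position-aware head: the location of the pre-burst dip
            # relative to the window end is itself discriminative
            layers.append(nn.Flatten())
            layers.append(nn.Dense(c_in * length))
        else:
            raise ValueError(f"unknown head {cfg.head!r}")
        self.net = nn.Sequential(layers)

    def parameter_count(self) -> int:
        return sum(p.size for p in self.net.params())

    def forward_logits(self, segments: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(segments, dtype=nn.DTYPE)[:, None, :]
        return self.net.forward(x, train=train)

    def forward_scores(self, segments: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward_logits(segments, train=False))


def build_model(cfg: ModelConfig) -> BurstPredictorNet:
    """Construct the untrained CNN; identical seeds give identical
    initial parameters."""
    model = BurstPredictorNet(cfg)
    logger.info("built CNN with %d parameters", model.parameter_count())
    return model


@dataclasses.dataclass
class TrainedPredictor:
    """Fitted network with its provenance-tagged statistics.

    Normalization constants come from training data only; the sigmoid
    threshold is calibrated on validation data only.
    """

    model: BurstPredictorNet
    norm_mean: float
    norm_std: float
    threshold: float
    training_history: list[dict]
    config: ModelConfig
    provenance: dict = dataclasses.field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        state = {
            "config": self.config,
            "state": self.model.net.get_state(),
            "norm_mean": self.norm_mean,
            "norm_std": self.norm_std,
            "threshold": self.threshold,
            "history": self.training_history,
            "provenance": self.provenance,
        }
        with open(path, "wb") as f:
            pickle.dump(state, f)

    @staticmethod
    def load(path: str | Path) -> "TrainedPredictor":
        with open(path, "rb") as f:
            state = pickle.load(f)
        model = build_model(state["config"])
        model.net.set_state(state["state"])
        return TrainedPredictor(
            model=model,
            norm_mean=state["norm_mean"],
            norm_std=state["norm_std"],
            threshold=state["threshold"],
            training_history=state["history"],
            config=state["config"],
            provenance=state["provenance"],
        )


def _check_model_classes(segset: LabeledSegmentSet, name: str) -> None:
    if len(segset) == 0:
        raise ValueError(f"{name} set is empty")
    if np.any(segset.labels == CLASS_BURST):
        raise ValueError(
            f"{name} set contains Class Burst segments; call model_data() first"
        )


def train_model(
    model: BurstPredictorNet,
    train: LabeledSegmentSet,
    val: LabeledSegmentSet,
    cfg: ModelConfig,
) -> TrainedPredictor:
    """Minimize weighted BCE with Adam; early-stop on validation AUC-PR
    and restore the best-epoch weights."""
    _check_model_classes(train, "training")
    _check_model_classes(val, "validation")
    y = train.labels.astype(nn.DTYPE)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if train.window_samples != cfg.input_length:
        raise ValueError(
            f"segments of {train.window_samples} samples for input_length "
            f"{cfg.input_length}"
        )

    mu = float(train.segments.mean())
    sd = float(train.segments.std())
    if sd == 0.0:
        raise ValueError("training segments have zero variance")
    x = ((train.segments - mu) / sd).astype(nn.DTYPE)
    xv = ((val.segments - mu) / sd).astype(nn.DTYPE)
    yv = val.labels.astype(int)

    if cfg.class_weighting:
        n, n1 = len(y), float(y.sum())
        w_pos, w_neg = n / (2.0 * n1), n / (2.0 * (n - n1))
    else:
        w_pos = w_neg = 1.0
    weights = np.where(y == 1, w_pos, w_neg)

    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    rng = model.rng
    history: list[dict] = []
    best_metric, best_state, best_epoch = -np.inf, model.net.get_state(), -1
    for epoch in range(cfg.max_epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (
                1.0 + math.cos(math.pi * epoch / cfg.max_epochs)
            )
        perm = rng.permutation(len(y))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(y), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            logits = model.forward_logits(x[idx], train=True)
            loss, dz = nn.weighted_bce_with_logits(logits, y[idx], weights[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{n_batches}: {loss}; check learning rate and data scale"
                )
            model.net.backward(dz)
            opt.step(model.net.grads())
            epoch_loss += loss
            n_batches += 1
        val_scores = _predict_in_batches(model, xv)
        val_aucpr = float(average_precision_score(yv, val_scores))
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_batches,
             "val_auc_pr": val_aucpr}
        )
        if val_aucpr > best_metric:
            best_metric, best_state, best_epoch = val_aucpr, model.net.get_state(), epoch
        if epoch - best_epoch >= cfg.patience:
            logger.info("early stopping at epoch %d (best %d)", epoch, best_epoch)
            break
    model.net.set_state(best_state)
    return TrainedPredictor(
        model=model,
        norm_mean=mu,
        norm_std=sd,
        threshold=0.5,
        training_history=history,
        config=cfg,
        provenance={
            "normalization_from": train.metadata.get("partition", "train"),
            "best_epoch": best_epoch,
            "best_val_auc_pr": best_metric,
            "threshold_from": None,
        },
    )


def _predict_in_batches(model: BurstPredictorNet, x: np.ndarray,
                        batch: int = 512) -> np.ndarray:
    out = np.empty(len(x))
    for start in range(0, len(x), batch):
        out[start : start + batch] = nn.sigmoid(
            model.net.forward(x[start : start + batch, None, :], train=False)
        )
    return out


def predict_scores(
    predictor: TrainedPredictor, segments: np.ndarray | LabeledSegmentSet
) -> np.ndarray:
    """Sigmoid scores in (0, 1); deterministic and batch-order invariant."""
    if isinstance(segments, LabeledSegmentSet):
        segments = segments.segments
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    if segments.shape[1] != predictor.config.input_length:
        raise ValueError(
            f"segments of length {segments.shape[1]} do not match the model "
            f"input length {predictor.config.input_length}"
        )
    x = ((segments - predictor.norm_mean) / predictor.norm_std).astype(nn.DTYPE)
    return _predict_in_batches(predictor.model, x)


def calibrate_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    criterion: str = "f1",
    fp_per_min_ceiling: float | None = None,
    duration_min: float | None = None,
) -> float:
    """Choose the sigmoid cutoff on validation data.

    criterion 'f1' maximizes F1 over a sweep of all distinct score
    values; 'sen_at_fpmin' maximizes sensitivity subject to FP/min <=
    ``fp_per_min_ceiling`` over ``duration_min`` minutes of data.  The
    returned cutoff is the midpoint of the score gap that realizes the
    chosen decisions, so perfectly separated classes get the midpoint of
    the separating interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for calibration")
    distinct = np.unique(scores)
    if len(distinct) == 1:
        logger.warning("degenerate scores (all equal); threshold set to 0.5")
        return 0.5

    # decision = score >= t evaluated at every distinct score value
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    last = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    desc = s_sorted[last]
    n1 = labels.sum()
    tp = np.cumsum(y_sorted)[last].astype(float)
    fp = np.cumsum(1 - y_sorted)[last].astype(float)
    sen = tp / n1
    if criterion == "f1":
        prc = np.divide(tp, tp + fp, out=np.zeros_like(tp), where=(tp + fp) > 0)
        f1 = np.divide(
            2 * prc * sen, prc + sen, out=np.zeros_like(tp), where=(prc + sen) > 0
        )
        best = int(np.argmax(f1))  # ties -> highest threshold
    elif criterion == "sen_at_fpmin":
        if fp_per_min_ceiling is None or duration_min is None:
            raise ValueError(
                "criterion 'sen_at_fpmin' needs fp_per_min_ceiling and duration_min"
            )
        feasible = fp / duration_min <= fp_per_min_ceiling
        if not np.any(feasible):
            logger.warning("no threshold satisfies the FP/min ceiling; "
                           "using the strictest one")
            best = 0
        else:
            cand = np.flatnonzero(feasible)
            best = int(cand[np.argmax(sen[cand])])  # ties -> highest threshold
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    t_best = desc[best]
    below = distinct[distinct < t_best]
    if len(below):
        return float((t_best + below.max()) / 2.0)
    return float(t_best)
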