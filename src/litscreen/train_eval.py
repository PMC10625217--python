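"""Training, evaluation, model comparison and ranked screening.

The full pipeline per batch: encode titles/abstracts with the text
backend, mix each stream across the batch with inter-sample attention,
encode the journal metrics with a ReLU feed-forward layer, concatenate,
apply the two-class softmax head, and minimise the focal loss with Adam.
The text backend is frozen; the attention projections, journal encoder
and head are trained.

Because inter-sample attention mixes batch-mates, predictions depend on
batch composition.  Evaluation batches are therefore formed
deterministically over the id-sorted inputs (logged at DEBUG level), which
makes predictions invariant to input order.

Ablation variants select which feature blocks feed the head: "T" (title),
"A" (abstract), "J" (journal), their pairs, and "FULL".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .classifier import FocalLossParams, focal_loss_from_logits
from .corpus import Article, RawRecord
from .encoders import (
    AttentionParams,
    TextEncoder,
    attention_backward,
    get_encoder,
    init_attention_params,
    intersample_attention,
)
from .journals import FeatureScaler, JournalRecord, VECTOR_LENGTH, fit_scaler, journal_vector

__all__ = [
    "VARIANTS",
    "SplitSpec",
    "TrainConfig",
    "MetricsReport",
    "ScreeningResult",
    "ScreeningModel",
    "split_dataset",
    "train",
    "evaluate",
    "compare_models",
    "rank_screen",
]

logger = logging.getLogger(__name__)

VARIANTS = ("T", "A", "J", "TJ", "TA", "AJ", "FULL")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (fractions sum to 1)."""

    train_frac: float = 0.8
    seed: int = 0
    stratified: bool = True

    @property
    def test_frac(self) -> float:
        return 1.0 - self.train_frac


@dataclass
class TrainConfig:
    """Hyperparameters of one training run; every source of randomness is
    derived from ``seed``."""

    batch_size: int = 32
    epochs: int = 20
    learning_rate: float = 0.01
    optimizer: str = "adam"
    seed: int = 0
    focal: FocalLossParams = field(default_factory=FocalLossParams)
    encoder: dict = field(default_factory=lambda: {"kind": "toy", "dim": 64, "max_len": 512, "seed": 0})
    variant: str = "FULL"
    scaled_attention: bool = False
    journal_hidden: Optional[int] = None  # default: journal feature width

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if isinstance(self.focal, dict):
            self.focal = FocalLossParams(**self.focal)

    def uses(self) -> tuple[bool, bool, bool]:
        """(title, abstract, journal) feature-block usage for this variant."""
        if self.variant == "FULL":
            return True, True, True
        return "T" in self.variant, "A" in self.variant, "J" in self.variant

    def to_dict(self) -> dict:
        d = asdict(self)
        d["focal"] = {"gamma": self.focal.gamma, "alpha": self.focal.alpha}
        return d


@dataclass
class MetricsReport:
    """Confusion counts at a threshold plus the derived rates (percent).

    precision = TP/(TP+FP), recall = TP/(TP+FN), specificity = TN/(FP+TN),
    accuracy = (TP+TN)/total, f1 = harmonic mean of precision and recall.
    ``auc`` is the ROC area (trapezoid over all thresholds) and
    ``average_precision`` the precision-recall summary; both are None when
    the labels contain a single class.  Empty denominators yield 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    specificity: float
    accuracy: float
    f1: float
    auc: Optional[float]
    average_precision: Optional[float]
    threshold: float = 0.5

    def to_dict(self, ndigits: int = 2) -> dict:
        rnd = lambda v: None if v is None else round(v, ndigits)
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "precision": rnd(self.precision),
            "recall": rnd(self.recall),
            "specificity": rnd(self.specificity),
            "accuracy": rnd(self.accuracy),
            "f1": rnd(self.f1),
            "auc": rnd(self.auc),
            "average_precision": rnd(self.average_precision),
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class ScreeningResult:
    """One screened article: predicted probability, descending rank (1 =
    most probable), and whether it clears the retention threshold."""

    id: str
    probability: float
    rank: int
    retained: bool


def split_dataset(
    articles: Sequence[Article], spec: SplitSpec = SplitSpec()
) -> tuple[list[Article], list[Article]]:
    """Random (optionally label-stratified) train/test split."""
    if not 0.0 < spec.train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1 (both splits non-empty)")
    labels = [a.label for a in articles]
    stratify = labels if spec.stratified else None
    if spec.stratified:
        counts = np.bincount(labels, minlength=2)
        if counts.min() < 2:
            raise ValueError(
                f"class counts {counts.tolist()} too small to stratify; "
                "use SplitSpec(stratified=False)"
            )
    idx_train, idx_test = train_test_split(
        np.arange(len(articles)),
        test_size=spec.test_frac,
        random_state=spec.seed,
        shuffle=True,
        stratify=stratify,
    )
    return [articles[i] for i in idx_train], [articles[i] for i in idx_test]


# ---------------------------------------------------------------------------
# model


def _init_params(config: TrainConfig, d: int, j_width: int, rng: np.random.Generator) -> dict:
    use_t, use_a, use_j = config.uses()
    jh = config.journal_hidden or j_width
    params: dict[str, np.ndarray] = {}
    if use_t:
        att = init_attention_params(d, rng)
        params["wq_t"], params["wk_t"], params["wv_t"] = att.wq, att.wk, att.wv
    if use_a:
        att = init_attention_params(d, rng)
        params["wq_a"], params["wk_a"], params["wv_a"] = att.wq, att.wk, att.wv
    if use_j:
        params["wj"] = 0.2 * rng.standard_normal((j_width, jh))
        params["bj"] = np.zeros(jh)
    width = d * (use_t + use_a) + (jh if use_j else 0)
    params["w"] = 0.2 * rng.standard_normal((width, 2))
    params["b"] = np.zeros(2)
    return params


def _forward_backward(
    params: dict,
    rt: Optional[np.ndarray],
    ra: Optional[np.ndarray],
    jraw: Optional[np.ndarray],
    y: np.ndarray,
    config: TrainConfig,
    compute_grads: bool = True,
) -> tuple[float, np.ndarray, dict]:
    """One batch through attention streams, journal encoder and head.

    Returns (loss, positive-class probabilities, gradients)."""
    use_t, use_a, use_j = config.uses()
    blocks: list[np.ndarray] = []
    caches: dict = {}
    if use_t:
        att_t = intersample_attention(
            rt, AttentionParams(params["wq_t"], params["wk_t"], params["wv_t"]),
            scaled=config.scaled_attention, keep_cache=compute_grads,
        )
        blocks.append(att_t.output)
        caches["t"] = att_t
    if use_a:
        att_a = intersample_attention(
            ra, AttentionParams(params["wq_a"], params["wk_a"], params["wv_a"]),
            scaled=config.scaled_attention, keep_cache=compute_grads,
        )
        blocks.append(att_a.output)
        caches["a"] = att_a
    if use_j:
        jpre = jraw @ params["wj"] + params["bj"]
        jact = np.maximum(jpre, 0.0)
        blocks.append(jact)
        caches["jpre"] = jpre
    x = np.concatenate(blocks, axis=1)
    logits = x @ params["w"] + params["b"]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits during training")
    loss, d_logits = focal_loss_from_logits(logits, y, config.focal)
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = (e / e.sum(axis=1, keepdims=True))[:, 1]
    if not compute_grads:
        return loss, probs, {}

    grads: dict[str, np.ndarray] = {
        "w": x.T @ d_logits,
        "b": d_logits.sum(axis=0),
    }
    d_x = d_logits @ params["w"].T
    offset = 0
    d = rt.shape[1] if use_t else (ra.shape[1] if use_a else 0)
    if use_t:
        d_block = d_x[:, offset : offset + d]
        grads["wq_t"], grads["wk_t"], grads["wv_t"] = attention_backward(caches["t"], d_block)
        offset += d
    if use_a:
        d_block = d_x[:, offset : offset + d]
        grads["wq_a"], grads["wk_a"], grads["wv_a"] = attention_backward(caches["a"], d_block)
        offset += d
    if use_j:
        d_jact = d_x[:, offset:]
        d_jpre = d_jact * (caches["jpre"] > 0)
        grads["wj"] = jraw.T @ d_jpre
        grads["bj"] = d_jpre.sum(axis=0)
    return loss, probs, grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class _SGD:
    def __init__(self, params: dict, lr: float) -> None:
        self.lr = lr

    def step(self, params: dict, grads: dict) -> None:
        for k, g in grads.items():
            params[k] -= self.lr * g


_OPTIMIZERS = {"adam": _Adam, "sgd": _SGD}

Record = Union[Article, RawRecord]


@dataclass
class ScreeningModel:
    """A trained screening model: frozen text encoder, fitted journal
    scaler, trained parameters, and the config that produced them."""

    encoder: TextEncoder
    scaler: FeatureScaler
    params: dict
    config: TrainConfig

    def _features(
        self, records: Sequence[Record], journal_table: Mapping[str, JournalRecord]
    ) -> tuple[Optional[np.ndarray], Optional[np.ndarray], Optional[np.ndarray]]:
        use_t, use_a, use_j = self.config.uses()
        rt = self.encoder.encode_batch([r.title for r in records]) if use_t else None
        ra = self.encoder.encode_batch([r.abstract for r in records]) if use_a else None
        jraw = (
            np.stack([journal_vector(r.journal_id, journal_table, self.scaler) for r in records])
            if use_j
            else None
        )
        return rt, ra, jraw

    def predict_proba(
        self,
        records: Sequence[Record],
        journal_table: Mapping[str, JournalRecord],
        batch_size: Optional[int] = None,
    ) -> np.ndarray:
        """Positive-class probabilities, aligned with the input order.

        Inter-sample attention makes predictions depend on batch-mates, so
        batches are formed over the id-sorted records (deterministic and
        input-order invariant); each batch's composition is logged.
        """
        if not records:
            return np.zeros(0)
        s = batch_size or self.config.batch_size
        order = sorted(range(len(records)), key=lambda i: records[i].id)
        probs = np.zeros(len(records))
        for lo in range(0, len(order), s):
            chunk = order[lo : lo + s]
            batch = [records[i] for i in chunk]
            logger.debug("evaluation batch: %s", [r.id for r in batch])
            rt, ra, jraw = self._features(batch, journal_table)
            _, p, _ = _forward_backward(
                self.params, rt, ra, jraw,
                np.zeros(len(batch), dtype=int), self.config, compute_grads=False,
            )
            probs[chunk] = p
        return probs

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize to a single JSON checkpoint; reload restores bit-identical
        evaluation outputs (floats round-trip exactly through repr)."""
        config = self.config.to_dict()
        blob = {
            "config": config,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()
            ).hexdigest(),
            "encoder": self.encoder.config(),
            "scaler": self.scaler.to_dict(),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "ScreeningModel":
        with open(path, encoding="utf-8") as fh:
            blob = json.load(fh)
        config = TrainConfig(**blob["config"])
        return cls(
            encoder=get_encoder(blob["encoder"]),
            scaler=FeatureScaler.from_dict(blob["scaler"]),
            params={k: np.array(v) for k, v in blob["params"].items()},
            config=config,
        )


def train(
    articles: Sequence[Article],
    journal_table: Mapping[str, JournalRecord],
    config: TrainConfig = TrainConfig(),
) -> tuple[ScreeningModel, list[float]]:
    """Train a screening model; returns (model, per-epoch mean loss).

    The journal scaler is fitted on the training articles' journals only.
    With ``epochs=0`` the returned parameters are exactly the seeded
    initialization.  A non-finite loss aborts with diagnostics.
    """
    if not articles:
        raise ValueError("cannot train on an empty corpus")
    encoder = get_encoder(config.encoder)
    train_journals = [journal_table[a.journal_id] for a in {a.journal_id: a for a in articles}.values()]
    scaler = fit_scaler(train_journals)
    model = ScreeningModel(encoder=encoder, scaler=scaler, params={}, config=config)

    use_t, use_a, use_j = config.uses()
    rt_all, ra_all, j_all = model._features(articles, journal_table)
    y_all = np.array([a.label for a in articles], dtype=int)

    rng = np.random.default_rng(config.seed)
    d = encoder.dim
    model.params = _init_params(config, d, VECTOR_LENGTH, rng)
    try:
        opt = _OPTIMIZERS[config.optimizer](model.params, config.learning_rate)
    except KeyError:
        raise ValueError(f"unknown optimizer {config.optimizer!r}; use one of {sorted(_OPTIMIZERS)}")

    history: list[float] = []
    n = len(articles)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            loss, _, grads = _forward_backward(
                model.params,
                rt_all[idx] if use_t else None,
                ra_all[idx] if use_a else None,
                j_all[idx] if use_j else None,
                y_all[idx],
                config,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {lo}: "
                    f"loss={loss}, lr={config.learning_rate}"
                )
            opt.step(model.params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        logger.debug("epoch %d: mean focal loss %.6f", epoch, history[-1])
    return model, history


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    probabilities: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> MetricsReport:
    """Confusion counts at ``threshold`` plus the derived rates (percent)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def rate(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    precision = rate(tp, tp + fp)
    recall = rate(tp, tp + fn)
    specificity = rate(tn, fp + tn)
    accuracy = rate(tp + tn, tp + fp + fn + tn)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if len(np.unique(y)) < 2:
        auc = ap = None
    else:
        auc = 100.0 * float(roc_auc_score(y, p))
        ap = 100.0 * float(average_precision_score(y, p))
    return MetricsReport(tp, tn, fp, fn, precision, recall, specificity, accuracy, f1, auc, ap, threshold)


_DELTA_METRICS = ("precision", "recall", "specificity", "accuracy", "f1", "auc")


def compare_models(
    report_a: Union[MetricsReport, Mapping[str, float]],
    report_b: Union[MetricsReport, Mapping[str, float]],
) -> dict[str, float]:
    """Per-metric differences a - b, in percentage points."""

    def get(rep, name):
        return getattr(rep, name) if isinstance(rep, MetricsReport) else rep.get(name)

    deltas = {}
    for name in _DELTA_METRICS:
        va, vb = get(report_a, name), get(report_b, name)
        if va is not None and vb is not None:
            deltas[name] = va - vb
    return deltas


def rank_screen(
    model: ScreeningModel,
    records: Sequence[Record],
    journal_table: Mapping[str, JournalRecord],
    threshold: float = 0.5,
    batch_size: Optional[int] = None,
) -> list[ScreeningResult]:
    """Score new articles and rank them by descending probability.

    ``retained`` marks probabilities >= threshold; ties in probability are
    broken by article id.  The result is invariant to input order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not records:
        return []
    probs = model.predict_proba(records, journal_table, batch_size=batch_size)
    order = sorted(range(len(records)), key=lambda i: (-probs[i], records[i].id))
    return [
        ScreeningResult(
            id=records[i].id,
            probability=float(probs[i]),
            rank=rank,
            retained=bool(probs[i] >= threshold),
        )
        for rank, i in enumerate(order, start=1)
    ]
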