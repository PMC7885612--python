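"""Multimodal fusion network, loss, training loop and checkpointing.

The temporal LSTM embedding h and the convolutional text feature c are
concatenated (z = h ⊕ c), batch-normalized and dropped out during training,
and passed through a fully connected sigmoid head to give the mortality
probability.  Training minimizes binary cross-entropy plus the
joint-embedding regularizer: the mean over the two label classes of the
cross-entropy between each class indicator and the sigmoid of that class's
max-pooled word-label similarity score.  Optimization is Adam with early
stopping on validation AUCPR.

Model variants mirror the ablation structure of the underlying study:

- ``lstm_only``            temporal branch alone
- ``cn_only``              plain CNN over notes alone
- ``multi_cn``             fusion with a label-agnostic CNN
- ``multi_atten``          fusion with label-aware attention, window notes only
- ``multi_atten_chronic``  as above, plus pre-window history notes for
                           chronic patients
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from .autodiff import Adam, Tensor, concat
from .config import ModelConfig
from .ingest import PatientEpisode, filter_cohort, select_notes
from .metrics import aucpr, aucroc
from .resources import feature_names
from .temporal import (TrainStats, bin_hourly, compute_train_stats,
                       impute_and_scale, init_lstm_params, lstm_forward)
from .text_encoder import encode_text, init_text_params
from .text_prep import TokenSequence, Vocabulary, assemble_bundle_text, flatten_bundle

logger = logging.getLogger(__name__)

_CLAMP = 1e-7
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


# ---------------------------------------------------------------------------
# dataset preparation
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Episodes turned into dense model inputs (order preserved)."""

    stay_ids: list[str]
    temporal: np.ndarray          # (N, T, F) z-scored
    token_ids: np.ndarray         # (N, L) int64
    content_mask: np.ndarray      # (N, L) bool
    sequences: list[TokenSequence]
    labels: np.ndarray | None     # (N,) int, or None at predict time

    def __len__(self) -> int:
        return len(self.stay_ids)

    def batch(self, idx: np.ndarray) -> dict:
        return {
            "temporal": self.temporal[idx],
            "ids": self.token_ids[idx],
            "content_mask": self.content_mask[idx],
            "labels": None if self.labels is None else self.labels[idx],
        }


def prepare_dataset(
    episodes: list[PatientEpisode],
    config: ModelConfig,
    vocab: Vocabulary,
    stats: TrainStats,
    with_labels: bool = True,
) -> Dataset:
    """Bin, impute and scale the temporal grids and tokenize the note bundles.

    Note selection is chronic-aware only for the chronic-aware variant; all
    other variants see observation-window notes regardless of chronic status.
    """
    T, F = config.n_hours, len(feature_names())
    N = len(episodes)
    temporal = np.zeros((N, T, F))
    token_ids = np.zeros((N, config.max_len), dtype=np.int64)
    content = np.zeros((N, config.max_len), dtype=bool)
    seqs: list[TokenSequence] = []
    for i, ep in enumerate(episodes):
        grid = bin_hourly([e for e in ep.events if e.time >= 0], T)
        temporal[i] = impute_and_scale(grid, stats).values
        bundle = select_notes(ep, config.window_h,
                              chronic=ep.chronic and config.chronic_aware)
        seq = assemble_bundle_text(bundle, vocab, config.max_len, config.truncate_side)
        token_ids[i] = seq.ids
        content[i, : seq.content_length] = True
        seqs.append(seq)
    labels = None
    if with_labels:
        missing = [ep.stay_id for ep in episodes if ep.label is None]
        if missing:
            raise ValueError(f"episodes without labels on a labeled path: {missing[:5]}")
        labels = np.array([ep.label for ep in episodes], dtype=np.int64)
    return Dataset([ep.stay_id for ep in episodes], temporal, token_ids, content, seqs, labels)


def build_vocab(episodes: list[PatientEpisode], config: ModelConfig) -> Vocabulary:
    docs = []
    for ep in episodes:
        bundle = select_notes(ep, config.window_h,
                              chronic=ep.chronic and config.chronic_aware)
        tokens, _, _ = flatten_bundle(bundle)
        docs.append(tokens)
    return Vocabulary.build(docs, config.min_token_count)


def training_stats(episodes: list[PatientEpisode], config: ModelConfig) -> TrainStats:
    grids = [bin_hourly([e for e in ep.events if e.time >= 0], config.n_hours)
             for ep in episodes]
    return compute_train_stats(grids)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    y_hat: np.ndarray                 # (B,) probabilities in (0, 1)
    fused: np.ndarray                 # (B, dim(z))
    alpha: np.ndarray | None = None   # (B, L) attention weights
    aux_logits: np.ndarray | None = None  # (B, O) label-wise pooled scores


@dataclass
class LossValue:
    total: float
    ce_term: float
    joint_term: float


class MortalityNet:
    """Parameter container + forward pass for one model variant."""

    def __init__(self, config: ModelConfig, vocab_size: int,
                 pretrained_embeddings: np.ndarray | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        params: dict[str, Tensor] = {}
        F = len(feature_names())
        if config.uses_temporal:
            params.update(init_lstm_params(F, config.hidden_dim, rng))
        if config.uses_text:
            params.update(init_text_params(
                vocab_size, config.embed_dim, config.joint_dim, config.n_filters,
                config.filter_size, config.sim_window, rng,
                attention=config.uses_attention,
                pretrained_embeddings=pretrained_embeddings,
            ))
        D = config.fused_dim
        lim = np.sqrt(6.0 / (D + 1))
        params["head_W"] = Tensor(rng.uniform(-lim, lim, size=(D, 1)), requires_grad=True)
        params["head_b"] = Tensor(np.zeros(1), requires_grad=True)
        if config.batch_norm:
            params["bn_gamma"] = Tensor(np.ones(D), requires_grad=True)
            params["bn_beta"] = Tensor(np.zeros(D), requires_grad=True)
        self.params = params
        self.bn_running_mean = np.zeros(D)
        self.bn_running_var = np.ones(D)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.params.items()}
        out["_bn_running_mean"] = self.bn_running_mean.copy()
        out["_bn_running_var"] = self.bn_running_var.copy()
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=np.float64)
        self.bn_running_mean = np.array(state["_bn_running_mean"])
        self.bn_running_var = np.array(state["_bn_running_var"])

    # -- forward ------------------------------------------------------------
    def _fuse(self, h: Tensor | None, c: Tensor | None) -> Tensor:
        parts = [p for p in (h, c) if p is not None]
        z = parts[0] if len(parts) == 1 else concat(parts, axis=-1)
        if z.shape[-1] != self.config.fused_dim:
            raise ValueError(
                f"fused dim {z.shape[-1]} != expected {self.config.fused_dim} "
                f"(H={self.config.hidden_dim}, n_filters={self.config.n_filters})")
        return z

    def _head(self, z: Tensor, training: bool) -> tuple[Tensor, Tensor]:
        cfg = self.config
        if cfg.batch_norm:
            if training:
                mu = z.mean(axis=0, keepdims=True)
                var = ((z - mu) * (z - mu)).mean(axis=0, keepdims=True)
                self.bn_running_mean = (_BN_MOMENTUM * self.bn_running_mean
                                        + (1 - _BN_MOMENTUM) * mu.data[0])
                self.bn_running_var = (_BN_MOMENTUM * self.bn_running_var
                                       + (1 - _BN_MOMENTUM) * var.data[0])
                z = (z - mu) / (var + _BN_EPS).sqrt()
            else:
                z = (z - Tensor(self.bn_running_mean)) / Tensor(
                    np.sqrt(self.bn_running_var + _BN_EPS))
            z = z * self.params["bn_gamma"] + self.params["bn_beta"]
        if training and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            drop = (self._dropout_rng.random(z.shape) < keep) / keep
            z = z * Tensor(drop)
        logit = (z @ self.params["head_W"]).reshape(z.shape[0]) + self.params["head_b"]
        return logit.sigmoid(), z

    def forward(self, batch: dict, training: bool = False
                ) -> tuple[Tensor, Tensor, Tensor | None, Tensor | None]:
        """Returns (y_hat, z, alpha, aux_logits) as graph tensors."""
        cfg = self.config
        h = lstm_forward(batch["temporal"], self.params) if cfg.uses_temporal else None
        c = alpha = m_label = None
        if cfg.uses_text:
            c, alpha, m_label = encode_text(batch["ids"], batch["content_mask"],
                                            self.params, attention=cfg.uses_attention)
        z = self._fuse(h, c)
        y_hat, z_out = self._head(z, training)
        return y_hat, z_out, alpha, m_label

    def predict_batch(self, batch: dict) -> Prediction:
        y_hat, z, alpha, m_label = self.forward(batch, training=False)
        return Prediction(
            y_hat=y_hat.data.copy(),
            fused=z.data.copy(),
            alpha=None if alpha is None else alpha.data.copy(),
            aux_logits=None if m_label is None else m_label.data.copy(),
        )


def _bce(p: Tensor, targets: np.ndarray) -> Tensor:
    pc = p.clip(_CLAMP, 1.0 - _CLAMP)
    t = Tensor(targets.astype(np.float64))
    return -(t * pc.log() + (1.0 - t) * (1.0 - pc).log()).mean()


def compute_loss(y_hat: Tensor, aux_logits: Tensor | None,
                 labels: np.ndarray) -> tuple[Tensor, LossValue]:
    """CE + joint-embedding regularizer; the floats satisfy total = ce + joint.

    The regularizer averages, over the O = 2 label classes, the cross-entropy
    between the class indicator y_k and sigma(c_k), where c_k is the
    label-wise max-pooled word-label similarity score.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    ce = _bce(y_hat, labels.astype(np.float64))
    if aux_logits is not None:
        onehot = np.stack([1.0 - labels, labels], axis=1)  # (B, O)
        # mean over batch and classes == (1/O) * sum_k of per-class batch means
        joint = _bce(aux_logits.sigmoid(), onehot)
        total = ce + joint
    else:
        joint = Tensor(0.0)
        total = ce
    return total, LossValue(float(total.data), float(ce.data), float(joint.data))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_ce: float
    train_joint: float
    val_aucpr: float
    val_aucroc: float


@dataclass
class TrainedModel:
    config: ModelConfig
    vocab: Vocabulary
    stats: TrainStats
    net: MortalityNet
    history: list[EpochRecord] = field(default_factory=list)
    split_ids: dict[str, list[str]] = field(default_factory=dict)

    def predict_episodes(self, episodes: list[PatientEpisode],
                         batch_size: int = 64) -> np.ndarray:
        """One probability per episode, order preserved; labels never read."""
        ds = prepare_dataset(episodes, self.config, self.vocab, self.stats,
                             with_labels=False)
        return predict_dataset(self.net, ds, batch_size)

    def explain_episodes(self, episodes: list[PatientEpisode]) -> list[Prediction]:
        ds = prepare_dataset(episodes, self.config, self.vocab, self.stats,
                             with_labels=False)
        out = []
        for i in range(len(ds)):
            out.append(self.net.predict_batch(ds.batch(np.array([i]))))
        return out

    # -- checkpoint I/O ------------------------------------------------------
    def save(self, ckpt_dir: str | Path) -> None:
        ckpt = Path(ckpt_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
        self.config.save(ckpt / "config.json")
        (ckpt / "vocab.json").write_text(json.dumps(self.vocab.to_dict()))
        (ckpt / "stats.json").write_text(json.dumps(self.stats.to_dict()))
        np.savez(ckpt / "params.npz", **self.net.state_arrays())
        with open(ckpt / "history.csv", "w") as f:
            f.write("epoch,train_loss,train_ce,train_joint,val_aucpr,val_aucroc\n")
            for r in self.history:
                f.write(f"{r.epoch},{r.train_loss:.6f},{r.train_ce:.6f},"
                        f"{r.train_joint:.6f},{r.val_aucpr:.6f},{r.val_aucroc:.6f}\n")
        (ckpt / "splits.json").write_text(json.dumps(self.split_ids))

    @classmethod
    def load(cls, ckpt_dir: str | Path) -> "TrainedModel":
        ckpt = Path(ckpt_dir)
        if not ckpt.exists():
            raise FileNotFoundError(f"checkpoint directory not found: {ckpt}")
        config = ModelConfig.load(ckpt / "config.json")
        vocab = Vocabulary.from_dict(json.loads((ckpt / "vocab.json").read_text()))
        stats = TrainStats.from_dict(json.loads((ckpt / "stats.json").read_text()))
        net = MortalityNet(config, len(vocab))
        with np.load(ckpt / "params.npz") as z:
            net.load_state_arrays(dict(z))
        split_ids = {}
        if (ckpt / "splits.json").exists():
            split_ids = json.loads((ckpt / "splits.json").read_text())
        return cls(config, vocab, stats, net, history=[], split_ids=split_ids)


def predict_dataset(net: MortalityNet, ds: Dataset, batch_size: int = 64) -> np.ndarray:
    probs = np.zeros(len(ds))
    for lo in range(0, len(ds), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(ds)))
        probs[idx] = net.predict_batch(ds.batch(idx)).y_hat
    return probs


def stratified_split(
    episodes: list[PatientEpisode], seed: int,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> tuple[list[PatientEpisode], list[PatientEpisode], list[PatientEpisode]]:
    labels = np.array([ep.label for ep in episodes])
    idx = np.arange(len(episodes))
    holdout = fractions[1] + fractions[2]
    tr, rest = train_test_split(idx, test_size=holdout, stratify=labels[idx],
                                random_state=seed % (2**32))
    val, test = train_test_split(rest, test_size=fractions[2] / holdout,
                                 stratify=labels[rest], random_state=(seed + 1) % (2**32))
    pick = lambda ii: [episodes[i] for i in sorted(ii)]
    return pick(tr), pick(val), pick(test)


def train(
    episodes: list[PatientEpisode],
    config: ModelConfig,
    pretrained_embeddings: "tuple[list[str], np.ndarray] | None" = None,
) -> TrainedModel:
    """Fit one model variant on a labeled cohort.

    Applies the cohort filters (idempotent), splits 70/15/15 stratified by
    label, fits vocabulary and scaling statistics on the training split only,
    and optimizes the combined loss with Adam, early-stopping on validation
    AUCPR and restoring the best-validation parameters.
    """
    episodes = filter_cohort(episodes)
    if not episodes:
        raise ValueError("no episodes left after cohort filters")
    labels = {ep.label for ep in episodes}
    if labels <= {0} or labels <= {1}:
        raise ValueError("training requires both label classes; got single-class cohort")

    tr, val, test = stratified_split(episodes, config.seed)
    vocab = build_vocab(tr, config)
    stats = training_stats(tr, config)

    emb_matrix = None
    if pretrained_embeddings is not None:
        from .embeddings import build_embedding_matrix
        tokens, vectors = pretrained_embeddings
        emb_matrix = build_embedding_matrix(vocab, dict(zip(tokens, vectors)),
                                            config.embed_dim,
                                            np.random.default_rng(config.seed))

    ds_tr = prepare_dataset(tr, config, vocab, stats)
    ds_val = prepare_dataset(val, config, vocab, stats)

    net = MortalityNet(config, len(vocab), pretrained_embeddings=emb_matrix)
    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 2)

    history: list[EpochRecord] = []
    best_state: dict[str, np.ndarray] | None = None
    best_pr = -np.inf
    stall = 0
    n = len(ds_tr)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        tot = ce = joint = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            batch = ds_tr.batch(idx)
            y_hat, _, _, m_label = net.forward(batch, training=True)
            loss_t, loss_v = compute_loss(y_hat, m_label, batch["labels"])
            opt.zero_grad()
            loss_t.backward()
            opt.step()
            tot += loss_v.total
            ce += loss_v.ce_term
            joint += loss_v.joint_term
            n_batches += 1
        val_probs = predict_dataset(net, ds_val)
        val_pr = aucpr(val_probs, ds_val.labels)
        try:
            val_roc = aucroc(val_probs, ds_val.labels)
        except ValueError:
            val_roc = float("nan")
        rec = EpochRecord(epoch, tot / n_batches, ce / n_batches,
                          joint / n_batches, val_pr, val_roc)
        history.append(rec)
        logger.info("epoch %d loss %.4f val AUCPR %.4f AUCROC %.4f",
                    epoch, rec.train_loss, val_pr, val_roc)
        if val_pr > best_pr + 1e-12:
            best_pr = val_pr
            best_state = net.state_arrays()
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_rounds:
                logger.info("early stop at epoch %d", epoch)
                break
    if best_state is not None:
        net.load_state_arrays(best_state)
    split_ids = {"train": [ep.stay_id for ep in tr],
                 "val": [ep.stay_id for ep in val],
                 "test": [ep.stay_id for ep in test]}
    return TrainedModel(config, vocab, stats, net, history, split_ids)
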