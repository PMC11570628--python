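"""Twin (Siamese) contrastive metric-learning models for MI traces.

Two parameter-sharing encoder branches map each member of a trace pair to
an embedding; the contrastive loss pulls same-compound pairs together
(½·d²) and pushes different-compound pairs beyond a margin
(½·max(0, m − d)², d = Euclidean embedding distance, default m = 0.5).

Two encoders are provided:

* ``twin_nn`` — the 6-layer feed-forward network (input layer plus hidden
  widths 4000, 500, 250, 100 and a 10-d embedding at canonical scale;
  batch norm + ReLU after every linear layer except the last);
* ``twin_dn`` — a 1-D DenseNet-style encoder (dense blocks with channel
  concatenation, transition pooling, global average pooling, linear head).

Training follows the published recipe: pairs loaded in batches with
randomly swapped member order, traces sampled at every 5th frame and
min-max normalized against frozen dataset bounds, Adam at lr 5e-4 with
weight decay 1e-6, batch 32 (twin_nn) or 8 (twin_dn), loss backpropagated
per batch until convergence or the epoch cap.  The whole stack is numpy
and fully seeded, so training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .evaluation import mann_whitney_auroc
from .motion_index import conform_length, normalize_trace, subsample
from .pair_builder import PairDataset

__all__ = [
    "TwinModelConfig",
    "TwinModel",
    "TrainingError",
    "contrastive_loss",
    "contrastive_loss_grad",
    "build_twin_model",
    "train",
    "learned_distance",
    "save_model",
    "load_model",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class TwinModelConfig:
    """Architecture plus training hyperparameters.

    ``input_length`` is the trace length *after* stride subsampling
    (canonical: 101,250 frames / stride 5 = 20,250).  ``batch_size = None``
    resolves to 32 for twin_nn and 8 for twin_dn.
    """

    architecture: str = "twin_nn"
    input_length: int = 20250
    hidden_widths: tuple[int, ...] = (4000, 500, 250, 100)
    embedding_dim: int = 10
    margin: float = 0.5
    learning_rate: float = 5e-4
    weight_decay: float = 1e-6
    batch_size: int | None = None
    max_epochs: int = 100
    patience: int = 10
    subsample_stride: int = 5
    norm_lo: float = 0.0
    norm_hi: float = 6750.0
    seed: int = 0
    dense_block_spec: dict = field(default_factory=lambda: {
        "init_channels": 16, "growth": 12, "layers_per_block": 4,
        "n_blocks": 3, "kernel": 3})

    def __post_init__(self):
        if self.architecture not in ("twin_nn", "twin_dn"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be strictly positive")
        if self.batch_size is None:
            self.batch_size = 32 if self.architecture == "twin_nn" else 8

    @property
    def n_layers(self) -> int:
        """Layer count in the paper's convention (input layer included)."""
        return len(self.hidden_widths) + 2


# ---------------------------------------------------------------------------
# Contrastive loss


def _as_batch(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y[None, :] if y.ndim == 1 else y


def _label_array(label, n: int) -> np.ndarray:
    if isinstance(label, str):
        return np.full(n, 1 if label == "same" else 0, dtype=int)
    return np.asarray(label, dtype=int).reshape(-1)


def contrastive_loss(y1, y2, label, margin: float = 0.5) -> float:
    """½d² for same pairs, ½max(0, margin − d)² for different pairs;
    mean over the batch for batched inputs."""
    y1b, y2b = _as_batch(y1), _as_batch(y2)
    if y1b.shape != y2b.shape:
        raise ValueError(f"embedding shape mismatch: {y1b.shape} vs {y2b.shape}")
    lab = _label_array(label, y1b.shape[0])
    d = np.linalg.norm(y1b - y2b, axis=1)
    loss = np.where(lab == 1, 0.5 * d ** 2, 0.5 * np.maximum(0.0, margin - d) ** 2)
    return float(loss.mean())


def contrastive_loss_grad(y1, y2, label, margin: float = 0.5):
    """Analytic gradient of the (batch-mean) contrastive loss wrt y1 and y2."""
    y1b, y2b = _as_batch(y1), _as_batch(y2)
    lab = _label_array(label, y1b.shape[0])
    diff = y1b - y2b
    d = np.linalg.norm(diff, axis=1)
    n = y1b.shape[0]
    g = np.zeros_like(diff)
    same = lab == 1
    g[same] = diff[same]
    hinge = (~same) & (d < margin) & (d > 0)
    g[hinge] = -((margin - d[hinge]) / d[hinge])[:, None] * diff[hinge]
    g /= n
    if np.asarray(y1).ndim == 1:
        return g[0], -g[0]
    return g, -g


# ---------------------------------------------------------------------------
# Model


class TwinModel:
    """A (possibly trained) twin encoder with frozen preprocessing constants."""

    def __init__(self, config: TwinModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 100]))
        self.net = _build_encoder(config, rng)
        self.trained = False
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": [],
                                                "val_auroc": []}

    # -- preprocessing -----------------------------------------------------
    def preprocess(self, traces: np.ndarray) -> np.ndarray:
        """stride subsample -> min-max normalize -> conform to input_length."""
        arr = np.atleast_2d(np.asarray(traces, dtype=float))
        arr = subsample(arr, self.config.subsample_stride)
        arr = normalize_trace(arr, self.config.norm_lo, self.config.norm_hi)
        arr = conform_length(arr, self.config.input_length)
        return arr.astype(np.float32)

    # -- embedding ---------------------------------------------------------
    def embed(self, traces: np.ndarray, preprocessed: bool = False,
              train_mode: bool = False) -> np.ndarray:
        x = np.atleast_2d(traces).astype(np.float32) if preprocessed \
            else self.preprocess(traces)
        return self.net.forward(x, train=train_mode)

    def distance(self, trace_a: np.ndarray, trace_b: np.ndarray) -> float:
        emb = self.embed(np.stack([np.asarray(trace_a, dtype=float),
                                   np.asarray(trace_b, dtype=float)]))
        return float(np.linalg.norm(emb[0] - emb[1]))

    def embedding_metric(self):
        """Callable(emb_a, emb_b) for use with distance-matrix assembly."""
        return lambda a, b: float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def _build_encoder(config: TwinModelConfig, rng: np.random.Generator) -> _nn.Sequential:
    if config.architecture == "twin_nn":
        layers: list[_nn.Layer] = []
        widths = [config.input_length, *config.hidden_widths]
        for a, b in zip(widths[:-1], widths[1:]):
            layers += [_nn.Linear(a, b, rng), _nn.BatchNorm1d(b), _nn.ReLU()]
        layers.append(_nn.Linear(widths[-1], config.embedding_dim, rng))
        return _nn.Sequential(layers)
    spec = config.dense_block_spec
    layers = [_nn.Reshape1d(),
              _nn.Conv1d(1, spec["init_channels"], spec["kernel"], rng),
              _nn.AvgPool1d(2)]
    c = spec["init_channels"]
    for b in range(spec["n_blocks"]):
        block = _nn.DenseBlock1d(c, spec["growth"], spec["layers_per_block"],
                                 spec["kernel"], rng)
        layers.append(block)
        c = block.c_out
        if b < spec["n_blocks"] - 1:
            trans = _nn.Transition1d(c, c // 2, rng)
            layers.append(trans)
            c = trans.c_out
    layers += [_nn.BatchNorm1d(c), _nn.ReLU(), _nn.GlobalAvgPool1d()]
    final_rng = rng
    layers.append(_nn.Linear(c, config.embedding_dim, final_rng))
    return _nn.Sequential(layers)


def build_twin_model(config: TwinModelConfig) -> TwinModel:
    return TwinModel(config)


def reduced_twin_config(seed: int = 0, architecture: str = "twin_nn",
                        **overrides) -> TwinModelConfig:
    """Desk-scale configuration: 5,000-frame traces, stride-5 input of 1,000
    samples, hidden widths scaled down from the canonical architecture."""
    kwargs = dict(architecture=architecture, input_length=1000,
                  hidden_widths=(600, 300, 150, 75), subsample_stride=5,
                  max_epochs=300, patience=40, seed=seed)
    kwargs.update(overrides)
    return TwinModelConfig(**kwargs)


# ---------------------------------------------------------------------------
# Training


def _pair_distances(model: TwinModel, X: np.ndarray, ia: np.ndarray,
                    ib: np.ndarray, batch: int = 512) -> np.ndarray:
    """Eval-mode embedding distances for an index-pair list."""
    emb = np.empty((X.shape[0], model.config.embedding_dim), dtype=np.float32)
    for s in range(0, X.shape[0], batch):
        emb[s:s + batch] = model.embed(X[s:s + batch], preprocessed=True)
    return np.linalg.norm(emb[ia] - emb[ib], axis=1).astype(float)


def train(model: TwinModel, pair_dataset: PairDataset, trace_table: np.ndarray,
          max_epochs: int | None = None, verbose: bool = False) -> TwinModel:
    """Fit the twin encoder on the train split, early-stopping on the test
    split's loss (patience from config).  Returns the same model, trained."""
    cfg = model.config
    max_epochs = max_epochs or cfg.max_epochs
    X = model.preprocess(trace_table)

    ia_tr, ib_tr, y_tr = pair_dataset.subset("train").arrays()
    if len(ia_tr) == 0:
        raise ValueError("pair dataset has no train split")
    # hold back a seeded 15% of TRAIN pairs as the convergence-monitoring
    # validation set; the drug-held-out test split is never touched here
    split_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 201]))
    val_mask = split_rng.random(len(ia_tr)) < 0.15
    if val_mask.sum() < 10 or (~val_mask).sum() < 10:
        val_mask = np.zeros(len(ia_tr), dtype=bool)
    ia_va, ib_va, y_va = ia_tr[val_mask], ib_tr[val_mask], y_tr[val_mask]
    ia_tr, ib_tr, y_tr = ia_tr[~val_mask], ib_tr[~val_mask], y_tr[~val_mask]
    has_val = len(ia_va) > 0 and len(np.unique(y_va)) == 2

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 200]))
    opt = _nn.Adam(model.net.parameters(), lr=cfg.learning_rate,
                   weight_decay=cfg.weight_decay)
    # early stopping monitors validation pair AUROC: the contrastive val loss
    # can drift up (positives' absolute distances grow) while ranking quality
    # still improves, so loss is recorded but not used for the stop rule
    best_val = -np.inf
    best_state = None
    stale = 0

    for epoch in range(max_epochs):
        order = rng.permutation(len(ia_tr))
        swap = rng.random(len(ia_tr)) < 0.5       # random pair-order swap
        a_idx = np.where(swap, ib_tr, ia_tr)[order]
        b_idx = np.where(swap, ia_tr, ib_tr)[order]
        y_ep = y_tr[order]
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            a = X[a_idx[s:s + cfg.batch_size]]
            b = X[b_idx[s:s + cfg.batch_size]]
            y = y_ep[s:s + cfg.batch_size]
            nb = a.shape[0]
            stacked = np.concatenate([a, b], axis=0)
            out = model.net.forward(stacked, train=True)
            y1, y2 = out[:nb], out[nb:]
            loss = contrastive_loss(y1, y2, y, cfg.margin)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {s // cfg.batch_size} "
                    f"(lr={cfg.learning_rate})")
            g1, g2 = contrastive_loss_grad(y1, y2, y, cfg.margin)
            model.net.zero_grad()
            model.net.backward(np.concatenate([g1, g2], axis=0).astype(np.float32))
            opt.step()
            losses.append(loss)
        model.history["train_loss"].append(float(np.mean(losses)))

        if has_val:
            d_va = _pair_distances(model, X, ia_va, ib_va)
            # the loss depends on embeddings only through their distance, so
            # feed 1-D surrogate embeddings (d, 0) vs (0, 0)
            val_loss = contrastive_loss(
                np.stack([d_va, np.zeros_like(d_va)], axis=1),
                np.zeros((len(d_va), 2)), y_va, cfg.margin)
            val_auroc = mann_whitney_auroc(d_va, y_va)
            model.history["val_loss"].append(float(val_loss))
            model.history["val_auroc"].append(float(val_auroc))
            if verbose:
                print(f"epoch {epoch}: train {model.history['train_loss'][-1]:.4f} "
                      f"val {val_loss:.4f} auroc {val_auroc:.3f}")
            if val_auroc > best_val + 1e-6:
                best_val = val_auroc
                best_state = _snapshot(model)
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        _restore(model, best_state)
    model.trained = True
    return model


def _snapshot(model: TwinModel) -> list[np.ndarray]:
    arrays = [p.copy() for p, _ in model.net.parameters()]
    arrays += [v.copy() for v in model.net.state_arrays().values()]
    return arrays


def _restore(model: TwinModel, arrays: list[np.ndarray]):
    params = [p for p, _ in model.net.parameters()]
    states = list(model.net.state_arrays().values())
    for dst, src in zip(params + states, arrays):
        dst[...] = src


def learned_distance(model: TwinModel, trace_a: np.ndarray, trace_b: np.ndarray) -> float:
    """Euclidean distance between the two trace embeddings (symmetric,
    zero on identical traces)."""
    if not model.trained:
        raise RuntimeError("model is untrained; call train() first")
    return model.distance(trace_a, trace_b)


def evaluate_pairs(model: TwinModel, pair_dataset: PairDataset,
                   trace_table: np.ndarray, split: str = "test"):
    """Embedding distances + labels for one split of a pair dataset."""
    from .evaluation import PairScoreSet
    X = model.preprocess(trace_table)
    ia, ib, y = pair_dataset.subset(split).arrays()
    d = _pair_distances(model, X, ia, ib)
    return PairScoreSet(distances=d, labels=y, metric=model.config.architecture)


# ---------------------------------------------------------------------------
# Checkpointing


def save_model(model: TwinModel, path: str | Path) -> Path:
    path = Path(path)
    arrays = {f"param{i}": p for i, (p, _) in enumerate(model.net.parameters())}
    arrays.update({f"state.{k}": v for k, v in model.net.state_arrays().items()})
    cfg = asdict(model.config)
    cfg["hidden_widths"] = list(cfg["hidden_widths"])
    np.savez(path, __config__=json.dumps(cfg), __trained__=model.trained,
             __history__=json.dumps(model.history), **arrays)
    return path


def load_model(path: str | Path) -> TwinModel:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        cfg_dict["hidden_widths"] = tuple(cfg_dict["hidden_widths"])
        config = TwinModelConfig(**cfg_dict)
        model = TwinModel(config)
        for i, (p, _) in enumerate(model.net.parameters()):
            p[...] = data[f"param{i}"]
        for k, v in model.net.state_arrays().items():
            v[...] = data[f"state.{k}"]
        model.trained = bool(data["__trained__"])
        model.history = json.loads(str(data["__history__"]))
    return model
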