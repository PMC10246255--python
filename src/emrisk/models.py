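"""Sequence classifiers over visit-grouped EMR token sequences.

Three recurrent architectures share one contract (visit-level token
embeddings are sum-pooled per visit, visits feed a recurrent stack, the
final state is read out through a logistic head):

* ``rnn`` — stacked tanh recurrence;
* ``time_aware`` — the same recurrence with the carried state decayed by
  ``exp(-gap_days / time_decay_days)`` before each step, so long silent
  intervals between visits discount the memory (a time-aware LSTM in the
  canonical sense, realised here with a tanh cell);
* ``retain_style`` — reverse-time two-level attention: two recurrent nets
  run over the visit sequence in reverse, producing per-visit scalar
  attention (softmax over visits) and per-dimension gates (tanh), whose
  product with the visit embeddings is pooled into a context vector.

plus ``logistic_baseline`` — an L2-regularized logistic regression on a
bag-of-tokens binary indicator matrix, for performance comparison.

The networks run on a compact reverse-mode automatic-differentiation engine
over NumPy arrays defined at the top of this module; training uses Adam
with early stopping on validation AUROC (``patience`` consecutive epochs
without improvement). Everything is seeded end to end: the same config and
seed reproduce the same weights and the same validation trajectory.

Embedding row 0 is the padding/unknown token and is pinned to zero, which
is what makes occlusion-based feature attribution (masking one token
occurrence to the padding id) remove exactly that occurrence's signal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from .cohort import CohortSample, Vocabulary, split_dataset

ARCHITECTURES = ("rnn", "retain_style", "time_aware", "logistic_baseline")


# ===========================================================================
# reverse-mode autodiff on NumPy arrays
# ===========================================================================

def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph; ``data`` is a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, parents=(), bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._bw = bw

    @property
    def shape(self):
        return self.data.shape

    # -- primitive ops ----------------------------------------------------

    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + o.data, (self, o))
        def bw(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)
        out._bw = bw
        return out

    def __mul__(self, other):
        if isinstance(other, Tensor):
            out = Tensor(self.data * other.data, (self, other))
            a, b = self, other
            def bw(g):
                return (_unbroadcast(g * b.data, a.data.shape),
                        _unbroadcast(g * a.data, b.data.shape))
            out._bw = bw
            return out
        c = np.asarray(other, dtype=np.float64)  # constant: no gradient path
        out = Tensor(self.data * c, (self,))
        out._bw = lambda g: (_unbroadcast(g * c, self.data.shape),)
        return out

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, (self, other))
        a, b = self, other
        def bw(g):
            return g @ b.data.T, a.data.T @ g
        out._bw = bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._bw = lambda g: (g * (1.0 - y * y),)
        return out

    def sum(self, axis):
        out = Tensor(self.data.sum(axis=axis), (self,))
        def bw(g):
            return (np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy(),)
        out._bw = bw
        return out

    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), (self,))
        out._bw = lambda g: (g.reshape(self.data.shape),)
        return out

    # -- autodiff driver ----------------------------------------------------

    def backward(self):
        topo, seen = [], set()
        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)
        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bw(node.grad)):
                parent.grad = g if parent.grad is None else parent.grad + g


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    out = Tensor(weight.data[ids], (weight,))
    def bw(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids, g)
        return (gw,)
    out._bw = bw
    return out


def concat_cols(tensors: list[Tensor]) -> Tensor:
    """Concatenate [B,1] tensors along axis 1 -> [B,T]."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors))
    out._bw = lambda g: tuple(g[:, i:i + 1] for i in range(len(tensors)))
    return out


def col(x: Tensor, t: int) -> Tensor:
    """Column slice x[:, t:t+1] with scatter backward."""
    out = Tensor(x.data[:, t:t + 1], (x,))
    def bw(g):
        gx = np.zeros_like(x.data)
        gx[:, t:t + 1] = g
        return (gx,)
    out._bw = bw
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over axis 1 restricted to positions where mask == 1."""
    z = np.where(mask > 0, scores.data, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)
    out = Tensor(s, (scores,))
    def bw(g):
        dot = (g * s).sum(axis=1, keepdims=True)
        return (s * (g - dot),)
    out._bw = bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy; numerically stable via logaddexp."""
    z, y = logits.data, targets
    loss = np.mean(np.logaddexp(0.0, z) - z * y)
    out = Tensor(loss, (logits,))
    out._bw = lambda g: (g * (expit(z) - y) / z.size,)
    return out


class Adam:
    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


# ===========================================================================
# configuration and encoding
# ===========================================================================

@dataclass
class ModelConfig:
    """Hyperparameter bundle; the structural defaults follow the reference
    configuration (embedding 128, hidden 128, dropout 0.2, 8 layers,
    vocabulary cap 30000, early-stopping patience 3)."""

    architecture: str = "rnn"
    embed_dim: int = 128
    hidden_size: int = 128
    dropout: float = 0.2
    n_layers: int = 8
    vocab_cap: int = 30_000
    patience: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    time_decay_days: float = 90.0
    threshold: float = 0.5
    seed: int = 0
    n_runs: int = 5

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if min(self.embed_dim, self.hidden_size, self.n_layers) < 1:
            raise ValueError("model dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class EncodedDataset:
    """Padded id arrays for a list of cohort samples (pad/unknown id = 0)."""

    ids: np.ndarray          # [N, T, L] int32
    gaps: np.ndarray         # [N, T] float64, days since previous visit
    visit_mask: np.ndarray   # [N, T] float64, 1 for real visits
    labels: np.ndarray       # [N] float64 (1 = case)
    patient_ids: list[str]
    vocab_size: int

    def __len__(self):
        return self.ids.shape[0]

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            self.ids[idx], self.gaps[idx], self.visit_mask[idx], self.labels[idx],
            [self.patient_ids[i] for i in idx], self.vocab_size,
        )


def encode_samples(
    samples: list[CohortSample],
    vocabulary: Vocabulary,
    max_visits: int | None = None,
    max_tokens_per_visit: int | None = None,
) -> EncodedDataset:
    """Encode samples into padded [N, T, L] id arrays (most recent visits kept)."""
    if not samples:
        raise ValueError("no samples to encode")
    T = max(len(s.visits) for s in samples)
    if max_visits is not None:
        T = min(T, max_visits)
    L = max(max(len(toks) for _, toks in s.visits) for s in samples)
    if max_tokens_per_visit is not None:
        L = min(L, max_tokens_per_visit)
    N = len(samples)
    ids = np.zeros((N, T, L), dtype=np.int32)
    gaps = np.zeros((N, T))
    vmask = np.zeros((N, T))
    labels = np.zeros(N)
    for i, s in enumerate(samples):
        visits = s.visits[-T:]
        gap = s.gap_days[-T:]
        gap = [0] + gap[1:] if len(gap) else []
        for t, (_, toks) in enumerate(visits):
            enc = [vocabulary.encode(tok) for tok in toks][:L]
            ids[i, t, :len(enc)] = enc
            gaps[i, t] = gap[t]
            vmask[i, t] = 1.0
        labels[i] = s.y
    return EncodedDataset(ids, gaps, vmask, labels, [s.patient_id for s in samples],
                          vocabulary.size)


# ===========================================================================
# recurrent classifiers
# ===========================================================================

@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_val_auroc: float = float("-inf")

    @property
    def val_auroc_trajectory(self) -> list[float]:
        return [e["val_auroc"] for e in self.epochs]


class SequenceClassifier:
    """Recurrent risk classifier (architectures: rnn / time_aware / retain_style)."""

    def __init__(self, config: ModelConfig, vocab_size: int):
        if config.architecture == "logistic_baseline":
            raise ValueError("use LogisticBaseline for the logistic architecture")
        self.config = config
        self.vocab_size = vocab_size
        self._build_params()

    # -- parameters ---------------------------------------------------------

    def _build_params(self):
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xE]))
        D, H = cfg.embed_dim, cfg.hidden_size

        def init(shape, fan_in):
            return Tensor(rng.standard_normal(shape) / np.sqrt(fan_in))

        self.params: dict[str, Tensor] = {}
        E = init((self.vocab_size, D), D)
        E.data[0] = 0.0  # pad/unknown row pinned to zero
        self.params["E"] = E

        def rnn_stack(prefix, n_layers, d_in):
            for layer in range(n_layers):
                fan = d_in if layer == 0 else H
                self.params[f"{prefix}Wx{layer}"] = init((fan, H), fan)
                self.params[f"{prefix}Wh{layer}"] = init((H, H), H)
                self.params[f"{prefix}b{layer}"] = Tensor(np.zeros(H))

        if cfg.architecture in ("rnn", "time_aware"):
            rnn_stack("", cfg.n_layers, D)
            self.params["w_out"] = Tensor(np.zeros((H, 1)))
            self.params["b_out"] = Tensor(np.zeros(1))
        else:  # retain_style
            rnn_stack("a_", cfg.n_layers, D)
            rnn_stack("g_", cfg.n_layers, D)
            self.params["w_alpha"] = init((H, 1), H)
            self.params["Wb"] = init((H, D), H)
            self.params["bb"] = Tensor(np.zeros(D))
            self.params["w_out"] = Tensor(np.zeros((D, 1)))
            self.params["b_out"] = Tensor(np.zeros(1))

    def _param_list(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward --------------------------------------------------------------

    def _visit_embeddings(self, ids, training, rng) -> list[Tensor]:
        cfg = self.config
        E = self.params["E"]
        vis = []
        for t in range(ids.shape[1]):
            v = embedding(E, ids[:, t, :]).sum(axis=1)  # [B, D]
            if training and cfg.dropout > 0:
                keep = (rng.random(v.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                v = v * keep
            vis.append(v)
        return vis

    def _run_stack(self, seq: list[Tensor], prefix: str, vmask: np.ndarray,
                   decay: np.ndarray | None = None) -> list[Tensor]:
        cfg = self.config
        B = seq[0].shape[0]
        H = cfg.hidden_size
        for layer in range(cfg.n_layers):
            Wx = self.params[f"{prefix}Wx{layer}"]
            Wh = self.params[f"{prefix}Wh{layer}"]
            b = self.params[f"{prefix}b{layer}"]
            h = Tensor(np.zeros((B, H)))
            outs = []
            for t, x in enumerate(seq):
                h_prev = h
                if decay is not None:
                    h_prev = h_prev * decay[:, t:t + 1]
                hn = (x @ Wx + h_prev @ Wh + b).tanh()
                m = vmask[:, t:t + 1]
                h = hn * m + h * (1.0 - m)
                outs.append(h)
            seq = outs
        return seq

    def _forward(self, ids, gaps, vmask, training=False, rng=None) -> Tensor:
        cfg = self.config
        B, T, _ = ids.shape
        vis = self._visit_embeddings(ids, training, rng)
        if cfg.architecture in ("rnn", "time_aware"):
            decay = np.exp(-gaps / cfg.time_decay_days) if cfg.architecture == "time_aware" else None
            seq = self._run_stack(vis, "", vmask, decay)
            logits = seq[-1] @ self.params["w_out"] + self.params["b_out"]
            return logits.reshape((B,))
        # retain_style: reverse-time attention
        rev = vis[::-1]
        rmask = vmask[:, ::-1]
        g_seq = self._run_stack(rev, "a_", rmask)[::-1]
        h_seq = self._run_stack(rev, "g_", rmask)[::-1]
        scores = concat_cols([g @ self.params["w_alpha"] for g in g_seq])  # [B,T]
        alpha = masked_softmax(scores, vmask)
        ctx = Tensor(np.zeros((B, cfg.embed_dim)))
        for t in range(T):
            beta = (h_seq[t] @ self.params["Wb"] + self.params["bb"]).tanh()
            ctx = ctx + col(alpha, t) * beta * vis[t]
        logits = ctx @ self.params["w_out"] + self.params["b_out"]
        return logits.reshape((B,))

    # -- public API -------------------------------------------------------------

    def predict_encoded(self, ids, gaps, vmask) -> np.ndarray:
        """P(case) for already-encoded id arrays (deterministic, no dropout)."""
        if ids.max(initial=0) >= self.vocab_size:
            raise ValueError("token id exceeds the model's vocabulary")
        return expit(self._forward(ids, gaps, vmask).data)

    def predict_proba(self, dataset: EncodedDataset) -> np.ndarray:
        return self.predict_encoded(dataset.ids, dataset.gaps, dataset.visit_mask)

    def fit(self, train: EncodedDataset, val: EncodedDataset) -> TrainingLog:
        cfg = self.config
        if len(np.unique(train.labels)) < 2:
            raise ValueError("training set contains a single class; cannot train")
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF]))
        opt = Adam(self._param_list(), cfg.learning_rate)
        log = TrainingLog()
        best_state = None
        bad = 0
        for epoch in range(1, cfg.max_epochs + 1):
            perm = rng.permutation(len(train))
            losses = []
            for lo in range(0, len(perm), cfg.batch_size):
                idx = perm[lo:lo + cfg.batch_size]
                tmax = max(1, int(train.visit_mask[idx].sum(axis=1).max()))
                ids = train.ids[idx, :tmax]
                loss = bce_with_logits(
                    self._forward(ids, train.gaps[idx, :tmax],
                                  train.visit_mask[idx, :tmax], training=True, rng=rng),
                    train.labels[idx],
                )
                loss.backward()
                opt.step()
                self.params["E"].data[0] = 0.0
                losses.append(float(loss.data))
            val_auroc = _safe_auroc(val.labels, self.predict_proba(val))
            log.epochs.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auroc": val_auroc}
            )
            if val_auroc > log.best_val_auroc:
                log.best_val_auroc = val_auroc
                log.best_epoch = epoch
                best_state = {k: p.data.copy() for k, p in self.params.items()}
                bad = 0
            else:
                bad += 1
                if bad >= cfg.patience:
                    break
        if best_state is not None:
            for k, p in self.params.items():
                p.data = best_state[k]
        return log

    # -- persistence ---------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = sorted(self.params)
        meta = {"architecture": self.config.architecture, "vocab_size": self.vocab_size,
                "config": _config_dict(self.config), "params": names}
        with open(directory / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        for i, name in enumerate(names):
            np.save(directory / f"param_{i:03d}.npy", self.params[name].data)

    @classmethod
    def load(cls, directory) -> "SequenceClassifier":
        directory = Path(directory)
        with open(directory / "meta.json") as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["config"]), meta["vocab_size"])
        for i, name in enumerate(meta["params"]):
            model.params[name] = Tensor(np.load(directory / f"param_{i:03d}.npy"))
        return model


class LogisticBaseline:
    """L2-regularized logistic regression on bag-of-tokens binary indicators."""

    def __init__(self, config: ModelConfig, vocab_size: int):
        self.config = config
        self.vocab_size = vocab_size
        self.clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
        self._fitted = False

    def _design(self, ids: np.ndarray) -> np.ndarray:
        N = ids.shape[0]
        X = np.zeros((N, self.vocab_size))
        flat = ids.reshape(N, -1)
        rows = np.repeat(np.arange(N), flat.shape[1])
        X[rows, flat.ravel()] = 1.0
        X[:, 0] = 0.0  # pad column carries no information
        return X

    def fit(self, train: EncodedDataset, val: EncodedDataset | None = None) -> TrainingLog:
        if len(np.unique(train.labels)) < 2:
            raise ValueError("training set contains a single class; cannot train")
        self.clf.fit(self._design(train.ids), train.labels)
        self._fitted = True
        log = TrainingLog()
        if val is not None:
            log.best_val_auroc = _safe_auroc(val.labels, self.predict_proba(val))
            log.best_epoch = 1
        return log

    def predict_encoded(self, ids, gaps=None, vmask=None) -> np.ndarray:
        if ids.max(initial=0) >= self.vocab_size:
            raise ValueError("token id exceeds the model's vocabulary")
        return self.clf.predict_proba(self._design(ids))[:, 1]

    def predict_proba(self, dataset: EncodedDataset) -> np.ndarray:
        return self.predict_encoded(dataset.ids)

    @property
    def coef_(self) -> np.ndarray:
        return self.clf.coef_[0]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"architecture": "logistic_baseline", "vocab_size": self.vocab_size,
                "config": _config_dict(self.config), "params": ["coef", "intercept"]}
        with open(directory / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        np.save(directory / "param_000.npy", self.clf.coef_)
        np.save(directory / "param_001.npy", self.clf.intercept_)

    @classmethod
    def load(cls, directory) -> "LogisticBaseline":
        directory = Path(directory)
        with open(directory / "meta.json") as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["config"]), meta["vocab_size"])
        model.clf.coef_ = np.load(directory / "param_000.npy")
        model.clf.intercept_ = np.load(directory / "param_001.npy")
        model.clf.classes_ = np.array([0.0, 1.0])
        model._fitted = True
        return model


def _config_dict(config: ModelConfig) -> dict:
    return {k: getattr(config, k) for k in ModelConfig.__dataclass_fields__}


def load_model(directory):
    with open(Path(directory) / "meta.json") as fh:
        meta = json.load(fh)
    if meta["architecture"] == "logistic_baseline":
        return LogisticBaseline.load(directory)
    return SequenceClassifier.load(directory)


# ===========================================================================
# training/evaluation entry points
# ===========================================================================

def train_classifier(train_samples, val_samples, config: ModelConfig,
                     vocabulary: Vocabulary):
    """Train one recurrent classifier; returns (model, training log)."""
    train = encode_samples(train_samples, vocabulary)
    val = encode_samples(val_samples, vocabulary)
    model = SequenceClassifier(config, vocabulary.size)
    log = model.fit(train, val)
    return model, log


def train_logistic_baseline(train_samples, val_samples, config: ModelConfig,
                            vocabulary: Vocabulary):
    train = encode_samples(train_samples, vocabulary)
    val = encode_samples(val_samples, vocabulary)
    model = LogisticBaseline(config, vocabulary.size)
    model.fit(train, val)
    return model


def predict_risk(model, sample: CohortSample, vocabulary: Vocabulary) -> float:
    """P(case within the outcome window) for one sample."""
    enc = encode_samples([sample], vocabulary)
    return float(model.predict_encoded(enc.ids, enc.gaps, enc.visit_mask)[0])


def _safe_auroc(y, p) -> float:
    if len(np.unique(y)) < 2:
        warnings.warn("AUROC undefined on a one-class dataset; reporting NaN")
        return float("nan")
    return float(roc_auc_score(y, p))


def evaluate(model, dataset: EncodedDataset, threshold: float = 0.5) -> dict:
    """Rank-based AUROC plus thresholded precision/recall/F1."""
    p = model.predict_proba(dataset)
    auroc = _safe_auroc(dataset.labels, p)
    pred = (p >= threshold).astype(float)
    precision, recall, f1, _ = precision_recall_fscore_support(
        dataset.labels, pred, average="binary", zero_division=0.0
    )
    return {"auroc": auroc, "precision": float(precision), "recall": float(recall),
            "f1": float(f1), "n": len(dataset)}


@dataclass
class MetricsReport:
    """Per-run metrics plus across-run mean and sample standard deviation."""

    runs: list[dict]
    table: "object" = None  # pandas DataFrame: metrics x (run columns, Average, std)

    def __post_init__(self):
        import pandas as pd

        metrics = ["val_auroc", "test_auroc", "val_precision", "val_recall", "val_f1"]
        data = {str(i + 1): [r[m] for m in metrics] for i, r in enumerate(self.runs)}
        df = pd.DataFrame(data, index=metrics)
        df["Average"] = df.mean(axis=1)
        df["std"] = df[[str(i + 1) for i in range(len(self.runs))]].std(axis=1, ddof=1)
        self.table = df


def repeat_runs(samples, config: ModelConfig, n_runs: int | None = None,
                seed: int = 0, resplit: bool = True, vary_seed: bool = True,
                vocabulary: Vocabulary | None = None) -> MetricsReport:
    """Repeat the split/train/evaluate cycle and report mean +- std metrics.

    ``resplit`` redraws the 8:1:1 split each run; ``vary_seed`` re-seeds
    training. With both off every run is identical and the reported std is 0.
    """
    from .cohort import build_vocabulary

    n_runs = n_runs if n_runs is not None else config.n_runs
    if n_runs < 2:
        raise ValueError("repeat_runs needs n_runs >= 2")
    if vocabulary is None:
        vocabulary = build_vocabulary(samples, max_size=config.vocab_cap)
    runs = []
    for r in range(n_runs):
        split_seed = seed + r if resplit else seed
        train_s, val_s, test_s = split_dataset(samples, seed=split_seed)
        cfg = replace(config, seed=seed + r if vary_seed else seed)
        if cfg.architecture == "logistic_baseline":
            model = train_logistic_baseline(train_s, val_s, cfg, vocabulary)
        else:
            model, _ = train_classifier(train_s, val_s, cfg, vocabulary)
        val = encode_samples(val_s, vocabulary)
        test = encode_samples(test_s, vocabulary)
        val_metrics = evaluate(model, val, threshold=cfg.threshold)
        test_metrics = evaluate(model, test, threshold=cfg.threshold)
        runs.append({
            "run": r + 1,
            "val_auroc": val_metrics["auroc"], "test_auroc": test_metrics["auroc"],
            "val_precision": val_metrics["precision"], "val_recall": val_metrics["recall"],
            "val_f1": val_metrics["f1"],
        })
    return MetricsReport(runs=runs)
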