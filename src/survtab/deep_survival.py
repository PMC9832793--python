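"""Cox-loss neural networks for right-censored tabular data.

Three architectures share a censoring-unbiased training objective, the
negative log of the Breslow-approximation Cox partial likelihood, and a
single linear output node estimating the log-risk function:

* Feedforward -- four fully connected hidden layers of 32 SELU units,
  each followed by dropout and train-time additive Gaussian noise;
* DenseNet-style -- a 4-layer dense block where every layer consumes the
  concatenation of the input and all previous layers' outputs and emits
  ``growth_rate`` new features;
* TabTransformer -- learned per-column embeddings of the binary features
  pass through a stack of multi-head self-attention layers; contextual
  embeddings are flattened and concatenated with layer-normalized
  continuous features before an MLP head.

Training uses Adam.  Full-batch mode computes the exact partial
likelihood (global risk sets); risk-set-batched mode forms risk sets
within each shuffled batch, a documented approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._autograd import Adam, Parameter, Tensor, layer_norm, selu, softmax_lastaxis
from ._coxcore import RiskSetIndex, breslow_neg_log_pl as _breslow_numpy
from .datatypes import FeatureMeta, child_rng

__all__ = [
    "NetworkSpec",
    "breslow_neg_log_pl",
    "build_feedforward",
    "build_densenet",
    "build_tabtransformer",
    "train_risk_model",
    "TrainedRiskModel",
    "overfitting_curves",
]


def breslow_neg_log_pl(log_risks, times, events, normalize: bool = True) -> float:
    """Negative log Breslow-approximation Cox partial likelihood.

    L = -sum over events of [h_i - log sum_{j: t_j >= t_i} exp(h_j)],
    tied event times sharing the full risk set.  Log-sum-exp stabilized.
    With ``normalize`` the loss is divided by the number of events (the
    default, for optimizer scale independence); zero events return 0 with
    a warning (uninformative batch).
    """
    log_risks = np.asarray(log_risks, dtype=float).reshape(-1)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not (len(log_risks) == len(times) == len(events)):
        raise ValueError("log_risks, times and events must have equal length")
    if int(np.sum(events)) == 0:
        warnings.warn("no events in batch: loss is 0 (uninformative)",
                      UserWarning, stacklevel=2)
        return 0.0
    return _breslow_numpy(log_risks, times, events, normalize=normalize)


@dataclass
class NetworkSpec:
    """Architecture and training hyperparameters of a survival network."""

    architecture: str = "feedforward"
    hidden_width: int = 32
    n_hidden: int = 4
    dropout_rate: float = 0.2
    gaussian_noise_std: float = 0.1
    growth_rate: int = 8
    embed_dim: int = 64
    n_transformer_layers: int = 6
    n_heads: int = 8
    ff_mult: int = 2
    head_width: int = 32
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_mode: str = "full"
    batch_size: int = 512
    patience: int | None = None
    loss_normalize: bool = True
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("feedforward", "densenet", "tabtransformer"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        for name in ("hidden_width", "n_hidden", "growth_rate", "embed_dim",
                     "n_transformer_layers", "n_heads", "head_width", "epochs",
                     "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"spec field {name} must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("spec field dropout_rate must lie in [0, 1)")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("spec field embed_dim must be divisible by n_heads")
        if self.batch_mode not in ("full", "risk-set-batched"):
            raise ValueError("spec field batch_mode must be full or risk-set-batched")
        if self.dtype not in ("float64", "float32"):
            raise ValueError("spec field dtype must be float64 or float32")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Dense:
    """Affine layer with LeCun-normal initialization (suits SELU)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(rng.standard_normal((n_in, n_out)) / np.sqrt(n_in))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


def _regularize(x: Tensor, spec: NetworkSpec, train: bool,
                rng: np.random.Generator | None) -> Tensor:
    """Dropout then additive Gaussian noise, train time only."""
    if not train:
        return x
    dt = x.data.dtype
    if spec.dropout_rate > 0:
        keep = (rng.random(x.shape) >= spec.dropout_rate).astype(dt)
        x = x * (keep * dt.type(1.0 / (1.0 - spec.dropout_rate)))
    if spec.gaussian_noise_std > 0:
        x = x + rng.normal(0.0, spec.gaussian_noise_std, size=x.shape).astype(dt)
    return x


class _BaseNet:
    """Common surface of the three architectures (the RiskModel contract)."""

    spec: NetworkSpec
    architecture: str

    def params(self) -> list[Parameter]:
        raise NotImplementedError

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        raise NotImplementedError

    def _finalize_dtype(self) -> None:
        self._dtype = np.float32 if self.spec.dtype == "float32" else np.float64
        for p in self.params():
            p.data = p.data.astype(self._dtype)

    def _cast(self, X) -> np.ndarray:
        return np.asarray(X, dtype=self._dtype)

    def predict(self, X) -> np.ndarray:
        """Deterministic evaluation-mode log-risk scores."""
        out = self.forward(self._cast(X), train=False).data.reshape(-1)
        return out.astype(float)

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))


class FeedforwardNet(_BaseNet):
    architecture = "feedforward"

    def __init__(self, spec: NetworkSpec, n_features: int):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.spec = spec
        self.n_features = n_features
        rng = child_rng(spec.seed, "init", "feedforward")
        widths = [n_features] + [spec.hidden_width] * spec.n_hidden
        self.hidden = [_Dense(widths[i], widths[i + 1], rng)
                       for i in range(spec.n_hidden)]
        self.head = _Dense(spec.hidden_width, 1, rng)
        self._finalize_dtype()

    def params(self):
        out = []
        for layer in self.hidden:
            out += layer.params()
        return out + self.head.params()

    def forward(self, X, train=False, rng=None):
        h = Tensor(self._cast(X))
        for layer in self.hidden:
            h = _regularize(selu(layer(h)), self.spec, train, rng)
        return self.head(h)


class DenseNet(_BaseNet):
    """Densely connected block: each layer sees input + all previous outputs."""

    architecture = "densenet"

    def __init__(self, spec: NetworkSpec, n_features: int):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.spec = spec
        self.n_features = n_features
        rng = child_rng(spec.seed, "init", "densenet")
        g = spec.growth_rate
        self.layers = [_Dense(n_features + g * i, g, rng) for i in range(spec.n_hidden)]
        self.head = _Dense(n_features + g * spec.n_hidden, 1, rng)
        self.layer_input_widths = [n_features + g * i for i in range(spec.n_hidden)]
        self._finalize_dtype()

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out + self.head.params()

    def forward(self, X, train=False, rng=None):
        h = Tensor(self._cast(X))
        acc = h
        for layer in self.layers:
            new = _regularize(selu(layer(acc)), self.spec, train, rng)
            acc = Tensor.concat([acc, new], axis=-1)
        return self.head(acc)


class _TransformerLayer:
    def __init__(self, d: int, n_heads: int, ff_mult: int, rng: np.random.Generator):
        self.d, self.h = d, n_heads
        self.wq = _Dense(d, d, rng)
        self.wk = _Dense(d, d, rng)
        self.wv = _Dense(d, d, rng)
        self.wo = _Dense(d, d, rng)
        self.ff1 = _Dense(d, ff_mult * d, rng)
        self.ff2 = _Dense(ff_mult * d, d, rng)
        self.g1 = Parameter(np.ones(d))
        self.b1 = Parameter(np.zeros(d))
        self.g2 = Parameter(np.ones(d))
        self.b2 = Parameter(np.zeros(d))

    def params(self):
        out = []
        for l in (self.wq, self.wk, self.wv, self.wo, self.ff1, self.ff2):
            out += l.params()
        return out + [self.g1, self.b1, self.g2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        dh = d // self.h

        def split_heads(z: Tensor) -> Tensor:
            return z.reshape(n, t, self.h, dh).transpose((0, 2, 1, 3))

        # fold the 1/sqrt(dh) scale into q: cheaper than scaling the t x t scores
        q = split_heads(self.wq(x)) * float(1.0 / np.sqrt(dh))
        k = split_heads(self.wk(x))
        v = split_heads(self.wv(x))
        scores = q @ k.transpose((0, 1, 3, 2))
        att = softmax_lastaxis(scores)
        ctx = (att @ v).transpose((0, 2, 1, 3)).reshape(n, t, d)
        x = layer_norm(x + self.wo(ctx), self.g1, self.b1)
        x = layer_norm(x + self.ff2(selu(self.ff1(x))), self.g2, self.b2)
        return x


class TabTransformerNet(_BaseNet):
    """Column embeddings + self-attention over the binary features.

    Continuous features bypass the transformer through a layer norm, the
    convention of the original tabular-transformer design; the contextual
    embeddings are flattened and both parts feed an MLP head ending in
    the single linear Cox node.
    """

    architecture = "tabtransformer"

    def __init__(self, spec: NetworkSpec, feature_meta: list[FeatureMeta]):
        self.spec = spec
        self.meta = list(feature_meta)
        self.cat_idx = [i for i, m in enumerate(self.meta) if m.kind == "binary"]
        self.cont_idx = [i for i, m in enumerate(self.meta) if m.kind == "continuous"]
        rng = child_rng(spec.seed, "init", "tabtransformer")
        d = spec.embed_dim
        t = len(self.cat_idx)
        if t == 0:
            warnings.warn("no categorical features: transformer stack skipped, "
                          "model degrades to an MLP on continuous inputs",
                          UserWarning, stacklevel=3)
        # per-column, per-level embeddings; a binary value selects E0 or E1
        self.E0 = Parameter(rng.standard_normal((max(t, 1), d)) / np.sqrt(d))
        self.E1 = Parameter(rng.standard_normal((max(t, 1), d)) / np.sqrt(d))
        self.layers = [
            _TransformerLayer(d, spec.n_heads, spec.ff_mult, rng)
            for _ in range(spec.n_transformer_layers)
        ] if t else []
        nc = len(self.cont_idx)
        self.cont_gamma = Parameter(np.ones(nc)) if nc else None
        self.cont_beta = Parameter(np.zeros(nc)) if nc else None
        head_in = t * d + nc
        self.head1 = _Dense(head_in, spec.head_width, rng)
        self.head2 = _Dense(spec.head_width, 1, rng)
        self._finalize_dtype()

    def params(self):
        out = [self.E0, self.E1] if self.cat_idx else []
        for l in self.layers:
            out += l.params()
        if self.cont_gamma is not None:
            out += [self.cont_gamma, self.cont_beta]
        return out + self.head1.params() + self.head2.params()

    def forward(self, X, train=False, rng=None):
        X = self._cast(X)
        parts = []
        if self.cat_idx:
            xc = Tensor(X[:, self.cat_idx][:, :, None])     # n x t x 1
            tokens = self.E0 + xc * (self.E1 - self.E0)     # n x t x d
            for layer in self.layers:
                tokens = layer(tokens)
            n, t, d = tokens.shape
            parts.append(tokens.reshape(n, t * d))
        if self.cont_idx:
            xq = Tensor(X[:, self.cont_idx])
            parts.append(layer_norm(xq, self.cont_gamma, self.cont_beta))
        h = parts[0] if len(parts) == 1 else Tensor.concat(parts, axis=-1)
        h = _regularize(selu(self.head1(h)), self.spec, train, rng)
        return self.head2(h)

    def permute_categorical(self, perm: list[int]) -> None:
        """Reorder categorical columns, embeddings and the head's flatten blocks.

        After this, feeding inputs with categorical columns permuted by
        ``perm`` reproduces the original output: self-attention is
        permutation-equivariant over tokens, so only the column-tied
        embeddings and the flatten indexing need re-wiring.
        """
        perm = np.asarray(perm)
        self.E0.data = self.E0.data[perm]
        self.E1.data = self.E1.data[perm]
        d = self.spec.embed_dim
        t = len(self.cat_idx)
        block = np.arange(t * d).reshape(t, d)[perm].reshape(-1)
        rows = np.r_[block, t * d + np.arange(len(self.cont_idx))]
        self.head1.W.data = self.head1.W.data[rows]


def build_feedforward(spec: NetworkSpec, n_features: int) -> FeedforwardNet:
    return FeedforwardNet(replace(spec, architecture="feedforward"), n_features)


def build_densenet(spec: NetworkSpec, n_features: int) -> DenseNet:
    return DenseNet(replace(spec, architecture="densenet"), n_features)


def build_tabtransformer(spec: NetworkSpec,
                         feature_meta: list[FeatureMeta]) -> TabTransformerNet:
    return TabTransformerNet(replace(spec, architecture="tabtransformer"), feature_meta)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _loss_graph(h: Tensor, time: np.ndarray, event: np.ndarray,
                normalize: bool) -> Tensor:
    """Breslow negative log PL as an autodiff graph over log-risks h."""
    n = len(time)
    index = RiskSetIndex.build(time, event)
    ev_count_per_group = np.add.reduceat(index.event, index.bounds[:-1])
    keep = ev_count_per_group > 0
    # risk-set membership matrix: group g x subject j, 1 iff t_j >= group time
    starts = index.bounds[:-1][keep]
    R = np.zeros((len(starts), n))
    for gi, s in enumerate(starts):
        R[gi, index.order[s:]] = 1.0
    d_g = ev_count_per_group[keep].astype(float)
    n_ev = float(index.n_events)

    hflat = h.reshape(n)
    c = float(h.data.max())
    e = (hflat - c).exp()
    s = Tensor(R) @ e
    log_terms = (Tensor(d_g) * (s.log() + c)).sum()
    ev = np.zeros(n)
    ev[index.order[index.event == 1]] = 1.0
    event_terms = (Tensor(ev) * hflat).sum()
    loss = log_terms - event_terms
    return loss * (1.0 / n_ev) if normalize else loss


@dataclass
class TrainedRiskModel:
    """A trained network satisfying the RiskModel contract."""

    model: _BaseNet
    spec: NetworkSpec
    history: pd.DataFrame        # columns: epoch, train_loss, valid_loss

    @property
    def architecture(self) -> str:
        return self.model.architecture

    def predict(self, X) -> np.ndarray:
        return self.model.predict(X)

    def save(self, path) -> None:
        """Serialize spec, feature metadata, parameters and loss curves
        as JSON, so the model is replayable and reloadable as text."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        payload = {
            "architecture": self.architecture,
            "spec": asdict(self.spec),
            "feature_meta": [
                {"name": m.name, "kind": m.kind}
                for m in getattr(self.model, "meta", [])
            ],
            "n_features": getattr(self.model, "n_features", None),
            "params": [p.data.tolist() for p in self.model.params()],
            "history": self.history.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "TrainedRiskModel":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        spec = NetworkSpec(**payload["spec"])
        arch = payload["architecture"]
        if arch == "feedforward":
            model = build_feedforward(spec, payload["n_features"])
        elif arch == "densenet":
            model = build_densenet(spec, payload["n_features"])
        else:
            meta = [FeatureMeta(**m) for m in payload["feature_meta"]]
            model = build_tabtransformer(spec, meta)
        for p, data in zip(model.params(), payload["params"]):
            p.data = np.asarray(data, dtype=p.data.dtype).reshape(p.data.shape)
        return cls(model=model, spec=spec,
                   history=pd.DataFrame(payload["history"]))


def train_risk_model(model: _BaseNet, train_data, valid_data,
                     spec: NetworkSpec | None = None) -> TrainedRiskModel:
    """Minimize the Breslow negative log partial likelihood with Adam.

    ``train_data`` / ``valid_data`` are (X, time, event) triples.  Each
    epoch records train and validation loss in deterministic evaluation
    mode.  Fully seeded via ``spec.seed``; optional early stopping on the
    validation loss with ``spec.patience``.
    """
    spec = spec or model.spec
    Xtr, ttr, dtr = (np.asarray(a) for a in train_data)
    Xva, tva, dva = (np.asarray(a) for a in valid_data)
    if int(dtr.sum()) < 1:
        raise ValueError("training data must contain at least one event")
    rng = child_rng(spec.seed, "train", model.architecture)
    opt = Adam(model.params(), lr=spec.learning_rate)
    idx_tr = RiskSetIndex.build(ttr, dtr)
    idx_va = RiskSetIndex.build(tva, dva)
    hist = []
    best = np.inf
    best_state = None
    stale = 0
    n = len(ttr)
    for epoch in range(spec.epochs):
        if spec.batch_mode == "full":
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = [order[i:i + spec.batch_size]
                       for i in range(0, n, spec.batch_size)]
        for b in batches:
            if dtr[b].sum() == 0:
                continue  # uninformative batch
            out = model.forward(Xtr[b], train=True, rng=rng)
            loss = _loss_graph(out, ttr[b], dtr[b], spec.loss_normalize)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        tr_loss = _breslow_numpy(model.predict(Xtr), index=idx_tr, normalize=True)
        va_loss = _breslow_numpy(model.predict(Xva), index=idx_va, normalize=True)
        hist.append((epoch, tr_loss, va_loss))
        if spec.patience is not None:
            if va_loss < best - 1e-9:
                best = va_loss
                best_state = [p.data.copy() for p in model.params()]
                stale = 0
            else:
                stale += 1
                if stale >= spec.patience:
                    break
    if spec.patience is not None and best_state is not None:
        for p, s in zip(model.params(), best_state):
            p.data = s
    history = pd.DataFrame(hist, columns=["epoch", "train_loss", "valid_loss"])
    return TrainedRiskModel(model=model, spec=spec, history=history)


def overfitting_curves(trained: dict[tuple[str, str], TrainedRiskModel]):
    """Tidy per-epoch loss table plus a final train/validation gap summary.

    ``trained`` maps (model name, dataset id) to a trained model.  Returns
    (long_table, gap_summary): the table has one row per model, dataset,
    epoch and split; the summary reports mean(final validation - final
    train loss) per model.
    """
    rows = []
    finals = []
    for (name, dsid), tm in trained.items():
        for _, r in tm.history.iterrows():
            rows.append((name, dsid, int(r.epoch), "train", r.train_loss))
            rows.append((name, dsid, int(r.epoch), "valid", r.valid_loss))
        last = tm.history.iloc[-1]
        finals.append((name, last.valid_loss - last.train_loss))
    table = pd.DataFrame(rows, columns=["model", "dataset", "epoch", "split", "loss"])
    gaps = (pd.DataFrame(finals, columns=["model", "gap"])
            .groupby("model")["gap"].mean().rename("mean_final_gap"))
    return table, gaps
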