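"""The three graph classifiers: GCN, GAT and SAGPool.

Each model maps one subject's brain graph — dense nodal-FC feature matrix
``X`` (one row per region) plus sparse weighted adjacency ``A`` from k-NN
sparsification — to a two-class probability vector via a graph encoder, a
graph-level readout and a softmax head. All forward passes are batched
over subjects: ``X`` is (B, N, F) and ``A`` is (B, N, N).

Architectures (defaults follow the configuration the pipeline was built
around and are all overridable):

GCN
    Two convolution layers (128 and 64 filters) with symmetric
    degree-normalized aggregation over the weighted adjacency with unit
    self-loops, ReLU, dropout 0.3 between the hidden layers, global mean
    readout, linear softmax head.
GAT
    Three attention layers (64 units with 16 heads, 64 x 16, 64 x 1) with
    ELU activations. Attention coefficients are computed per edge (plus
    self-loop) by LeakyReLU scoring and per-node softmax; heads are
    concatenated except in the single-head final layer. Dropout 0.5 on
    attention weights and 0.6 on node features, both training-mode only.
    GAT learns its own edge coefficients and ignores the input weights.
SAGPool
    Three conv/pool blocks of width 64. Each block convolves, scores
    nodes by an auxiliary one-channel graph convolution, retains the top
    ``ceil(keep_ratio * N)`` nodes (keep_ratio 0.8) with tanh-gated
    features, and reads out concatenated mean and max over the survivors.
    A jumping-knowledge sum (optionally concat) aggregates the per-block
    readouts before the fully connected head (dropout 0.2).

Weighted degrees can be non-positive when negative Fisher-z edges
dominate; normalization floors them at 1e-6 rather than failing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .connectome import BrainGraph

_NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults are the study configuration."""

    architecture: str                  # "gcn" | "gat" | "sagpool"
    input_dim: int
    n_classes: int = 2
    seed: int = 0
    # GCN
    gcn_hidden: tuple = (128, 64)
    gcn_dropout: float = 0.3
    # GAT
    gat_units: tuple = (64, 64, 64)
    gat_heads: tuple = (16, 16, 1)
    gat_attn_dropout: float = 0.5
    gat_feat_dropout: float = 0.6
    gat_leaky_slope: float = 0.2
    # SAGPool
    sag_blocks: int = 3
    sag_hidden: int = 64
    sag_keep_ratio: float = 0.8
    sag_dropout: float = 0.2
    sag_jk: str = "sum"                # "sum" | "concat"

    def __post_init__(self):
        if self.architecture not in ("gcn", "gat", "sagpool"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 < self.sag_keep_ratio <= 1.0:
            raise ValueError(
                f"keep-ratio must lie in (0, 1], got {self.sag_keep_ratio}")
        if self.sag_jk not in ("sum", "concat"):
            raise ValueError(f"jumping-knowledge mode must be sum/concat")


def batch_graphs(graphs: list[BrainGraph]) -> tuple[np.ndarray, np.ndarray]:
    """Stack graphs of equal size into (B, N, F) features and (B, N, N)
    adjacency arrays."""
    X = np.stack([g.node_features for g in graphs])
    A = np.stack([g.adjacency() for g in graphs])
    return X, A


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization D^{-1/2} (A + I) D^{-1/2} with unit
    self-loops and weighted degrees (floored at 1e-6)."""
    eye = np.eye(A.shape[-1], dtype=A.dtype)
    Ai = A + eye
    d = Ai.sum(axis=-1)
    dinv = 1.0 / np.sqrt(np.clip(d, 1e-6, None))
    return Ai * dinv[..., :, None] * dinv[..., None, :]


class _Module:
    """Shared parameter bookkeeping and graph-level entry points."""

    config: ModelConfig

    def __init__(self, config: ModelConfig):
        self.config = config
        self._params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)

    def _param(self, name: str, fan_in: int, fan_out: int, shape=None) -> Tensor:
        t = Tensor(ad.glorot_uniform(self._rng, fan_in, fan_out, shape),
                   requires_grad=True)
        self._params[name] = t
        return t

    def _bias(self, name: str, size: int) -> Tensor:
        t = Tensor(np.zeros(size), requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self._params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, t in self._params.items():
            arr = np.asarray(state[k], dtype=float)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()

    # -- persistence: npz array container + YAML config sidecar ------------
    def save(self, path) -> None:
        from pathlib import Path
        path = Path(path)
        np.savez(path, **self.state_dict())
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)

    def astype(self, dtype) -> "_Module":
        """Copy of this model with parameters cast to ``dtype`` (float32
        evaluation halves the memory traffic of large perturbation sweeps)."""
        clone = build_model(self.config)
        for k, t in clone._params.items():
            t.data = self._params[k].data.astype(dtype)
        return clone

    # -- entry points -------------------------------------------------------
    def precompute(self, A: np.ndarray):
        """Architecture-specific static context for a fixed adjacency batch
        (normalized adjacency / attention mask), reusable across forward
        passes that perturb only node features."""
        return normalized_adjacency(A)

    def forward(self, X: np.ndarray, A: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None, ctx=None) -> Tensor:
        """Class probabilities (B, n_classes) as a differentiable tensor."""
        logits = self.logits(X, A, training=training, rng=rng, ctx=ctx)
        return ad.softmax(logits, axis=-1)

    def logits(self, X, A, *, training=False, rng=None, ctx=None) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, graphs: list[BrainGraph],
                      chunk: int = 64) -> np.ndarray:
        """Evaluation-mode probabilities for a list of graphs (chunked,
        no gradient tape)."""
        X, A = batch_graphs(graphs)
        return self.predict_proba_arrays(X, A, chunk=chunk)

    def predict_proba_arrays(self, X: np.ndarray, A: np.ndarray,
                             chunk: int = 64, ctx=None) -> np.ndarray:
        out = []
        with ad.no_grad():
            for lo in range(0, X.shape[0], chunk):
                c = None if ctx is None else ctx[lo:lo + chunk]
                p = self.forward(X[lo:lo + chunk], A[lo:lo + chunk],
                                 training=False, ctx=c)
                out.append(p.data)
        return np.concatenate(out, axis=0)


def load_model(path) -> "_Module":
    """Load a checkpoint saved by :meth:`_Module.save`."""
    from pathlib import Path
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("gcn_hidden", "gat_units", "gat_heads"):
        cfg[key] = tuple(cfg[key])
    model = build_model(ModelConfig(**cfg))
    with np.load(path) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model


class GCNClassifier(_Module):
    """Two-layer graph convolutional classifier."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        h1, h2 = config.gcn_hidden
        f = config.input_dim
        self._param("W1", f, h1)
        self._bias("b1", h1)
        self._param("W2", h1, h2)
        self._bias("b2", h2)
        self._param("Wout", h2, config.n_classes)
        self._bias("bout", config.n_classes)

    def logits(self, X, A, *, training=False, rng=None, ctx=None) -> Tensor:
        p = self._params
        Ahat = Tensor(ctx if ctx is not None else normalized_adjacency(A))
        H = ad.relu(Ahat @ (Tensor(X) @ p["W1"]) + p["b1"])
        H = ad.dropout(H, self.config.gcn_dropout, rng, training)
        H = ad.relu(Ahat @ (H @ p["W2"]) + p["b2"])
        pooled = H.mean(axis=1)                      # global average readout
        return pooled @ p["Wout"] + p["bout"]


class GATClassifier(_Module):
    """Three-layer graph attention classifier with multi-head attention."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        dims = [config.input_dim]
        for units, heads in zip(config.gat_units, config.gat_heads):
            dims.append(units * heads)
        for li, (units, heads) in enumerate(zip(config.gat_units, config.gat_heads)):
            fi = dims[li]
            self._param(f"W{li}", fi, units, shape=(heads, fi, units))
            self._param(f"asrc{li}", units, 1, shape=(heads, units, 1))
            self._param(f"adst{li}", units, 1, shape=(heads, units, 1))
            self._bias(f"b{li}", units * heads)
        self._param("Wout", dims[-1], config.n_classes)
        self._bias("bout", config.n_classes)

    def attention(self, X: np.ndarray, A: np.ndarray, layer: int = 0) -> np.ndarray:
        """Evaluation-mode attention coefficients (B, heads, N, N) of one
        layer, for inspection and testing."""
        with ad.no_grad():
            H = Tensor(X)
            mask = self._mask(A)
            for li in range(layer + 1):
                H, alpha = self._layer(H, mask, li, training=False, rng=None)
        return alpha.data

    @staticmethod
    def _mask(A: np.ndarray) -> np.ndarray:
        """(B, 1, N, N) additive mask: 0 on edges and self-loops, -inf off."""
        eye = np.eye(A.shape[-1], dtype=bool)
        connected = (A != 0) | eye
        return np.where(connected[:, None, :, :], 0.0, _NEG_INF).astype(A.dtype)

    def _layer(self, H: Tensor, mask: np.ndarray, li: int,
               training: bool, rng) -> tuple[Tensor, Tensor]:
        cfg = self.config
        p = self._params
        heads = cfg.gat_heads[li]
        units = cfg.gat_units[li]
        B, N = H.shape[0], H.shape[1]
        Hb = ad.reshape(H, (B, 1, N, H.shape[2]))
        Z = Hb @ p[f"W{li}"]                          # (B, heads, N, units)
        s_src = Z @ p[f"asrc{li}"]                    # (B, heads, N, 1)
        s_dst = Z @ p[f"adst{li}"]
        e = ad.leaky_relu(s_src + ad.swapaxes(s_dst, -1, -2),
                          cfg.gat_leaky_slope)        # e[i, j]: i aggregates j
        alpha = ad.softmax(e + mask, axis=-1)
        alpha_d = ad.dropout(alpha, cfg.gat_attn_dropout, rng, training)
        out = alpha_d @ Z                             # (B, heads, N, units)
        out = ad.reshape(ad.swapaxes(out, 1, 2), (B, N, heads * units))
        out = ad.elu(out + p[f"b{li}"])
        out = ad.dropout(out, cfg.gat_feat_dropout, rng, training)
        return out, alpha

    def precompute(self, A: np.ndarray):
        return self._mask(A)

    def logits(self, X, A, *, training=False, rng=None, ctx=None) -> Tensor:
        mask = ctx if ctx is not None else self._mask(A)
        H = Tensor(X)
        for li in range(len(self.config.gat_units)):
            H, _ = self._layer(H, mask, li, training, rng)
        pooled = H.mean(axis=1)
        return pooled @ self._params["Wout"] + self._params["bout"]


class SAGPoolClassifier(_Module):
    """Hierarchical self-attention graph pooling classifier."""

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        h = config.sag_hidden
        fi = config.input_dim
        for b in range(config.sag_blocks):
            self._param(f"Wc{b}", fi, h)
            self._bias(f"bc{b}", h)
            self._param(f"Ws{b}", h, 1)
            self._bias(f"bs{b}", 1)
            fi = h
        readout_dim = 2 * h
        jk_dim = readout_dim * (config.sag_blocks if config.sag_jk == "concat" else 1)
        self._param("Wfc", jk_dim, h)
        self._bias("bfc", h)
        self._param("Wout", h, config.n_classes)
        self._bias("bout", config.n_classes)

    @staticmethod
    def top_k_indices(scores: np.ndarray, keep_ratio: float) -> np.ndarray:
        """Indices (B, K) of the K = ceil(keep_ratio * N) highest-scoring
        nodes per graph; ties break toward the lower node index. Returned
        sorted by node index to keep node order stable."""
        N = scores.shape[1]
        K = math.ceil(keep_ratio * N)
        # stable argsort of -scores: equal scores keep ascending-index order
        idx = np.argsort(-scores, axis=1, kind="stable")[:, :K]
        return np.sort(idx, axis=1)

    def logits(self, X, A, *, training=False, rng=None, ctx=None) -> Tensor:
        cfg = self.config
        p = self._params
        B = X.shape[0]
        H = Tensor(X)
        A_cur = A
        readouts: list[Tensor] = []
        for b in range(cfg.sag_blocks):
            if b == 0 and ctx is not None:
                Ahat = Tensor(ctx)
            else:
                Ahat = Tensor(normalized_adjacency(A_cur))
            H = ad.relu(Ahat @ (H @ p[f"Wc{b}"]) + p[f"bc{b}"])
            score = Ahat @ (H @ p[f"Ws{b}"]) + p[f"bs{b}"]      # (B, N, 1)
            if cfg.sag_keep_ratio < 1.0:
                idx = self.top_k_indices(score.data[..., 0], cfg.sag_keep_ratio)
                Hk = ad.gather_nodes(H, idx)
                sk = ad.gather_nodes(score, idx)
                batch = np.arange(B)[:, None, None]
                A_cur = A_cur[batch, idx[:, :, None], idx[:, None, :]]
            else:
                Hk, sk = H, score
            H = Hk * ad.tanh(sk)                                 # gate survivors
            readouts.append(ad.concat([H.mean(axis=1), H.max(axis=1)], axis=-1))
        if cfg.sag_jk == "concat":
            jk = ad.concat(readouts, axis=-1)
        else:
            jk = readouts[0]
            for r in readouts[1:]:
                jk = jk + r
        h = ad.relu(jk @ p["Wfc"] + p["bfc"])
        h = ad.dropout(h, cfg.sag_dropout, rng, training)
        return h @ p["Wout"] + p["bout"]


_ARCHS = {"gcn": GCNClassifier, "gat": GATClassifier, "sagpool": SAGPoolClassifier}


def build_model(config: ModelConfig) -> _Module:
    """Instantiate the classifier named by ``config.architecture`` with
    seeded Glorot-uniform initialization."""
    return _ARCHS[config.architecture](config)


def forward_gcn(graphs, model: GCNClassifier) -> np.ndarray:
    """Evaluation-mode class probabilities from a GCN (convenience wrapper)."""
    return model.predict_proba(graphs if isinstance(graphs, list) else [graphs])


def forward_gat(graphs, model: GATClassifier) -> np.ndarray:
    return model.predict_proba(graphs if isinstance(graphs, list) else [graphs])


def forward_sagpool(graphs, model: SAGPoolClassifier) -> np.ndarray:
    return model.predict_proba(graphs if isinstance(graphs, list) else [graphs])
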