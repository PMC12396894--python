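"""Perturbation-based connection importance for trained graph classifiers.

Every unordered region pair (all n(n-1)/2 of them — 4950 for 100 regions)
is probed in turn: its entry in each subject's dense connectivity matrix
is replaced by a fixed extreme value (three times the highest connection
strength observed across all subjects), the model is re-evaluated, and the
influence of the connection is the RMSE between original and perturbed
class-probability outputs, taken over all subjects and both output
dimensions. Influence maps from several trained models are averaged
unweighted, ranked in descending order (ties toward the lexicographically
smaller pair), and the top-k (default 20) connections are extracted.

The perturbation is applied to the node-feature matrix with the sparse
k-NN adjacency held fixed: connections are scored regardless of whether
they appear among any subject's sparse edges, which is only coherent if
the dense feature matrix is the perturbed object. An optional
``rebuild_graph`` mode re-runs the k-NN sparsification on the perturbed
matrix for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectome import BrainGraph, ConnectivityMatrix, ParcelTable, build_graph
from .models import _Module, batch_graphs


def n_connections(n: int) -> int:
    """Number of unordered region pairs, n(n-1)/2."""
    if n < 2:
        raise ValueError(f"need at least 2 regions, got {n}")
    return n * (n - 1) // 2


def all_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered pairs (i, j), i < j, in lexicographic order."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _stack_values(matrices) -> np.ndarray:
    if len(matrices) == 0:
        raise ValueError("at least one subject is required")
    vals = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m)
            for m in matrices]
    return np.stack(vals)


def perturb_value(matrices, base: str = "signed") -> float:
    """The substitution value: 3 x the highest off-diagonal connection
    strength over all subjects (signed maximum by default,
    ``base='absolute'`` uses the magnitude)."""
    V = _stack_values(matrices)
    n = V.shape[-1]
    off = ~np.eye(n, dtype=bool)
    entries = V[:, off]
    m = float(np.abs(entries).max() if base == "absolute" else entries.max())
    if m <= 0:
        warnings.warn("highest connection strength is non-positive; "
                      "perturbation value has the same sign", stacklevel=2)
    return 3.0 * m


def connection_influence(model: _Module, graphs: list[BrainGraph],
                         pair: tuple[int, int], value: float,
                         rebuild_graph: bool = False,
                         k: int | None = None, rank: str = "signed") -> float:
    """RMSE influence of one connection on one trained model.

    Entries (i, j) and (j, i) of every subject's node-feature matrix are
    replaced by ``value`` (adjacency unchanged unless ``rebuild_graph``),
    and the result is sqrt(mean over subjects and output dimensions of the
    squared probability difference).
    """
    i, j = pair
    if i == j:
        raise ValueError("connection endpoints must differ")
    X, A = batch_graphs(graphs)
    p0 = model.predict_proba_arrays(X, A)
    Xp = X.copy()
    Xp[:, i, j] = value
    Xp[:, j, i] = value
    if rebuild_graph:
        if k is None:
            raise ValueError("rebuild_graph requires k")
        rebuilt = [build_graph(ConnectivityMatrix(Xp[s], graphs[s].subject_id), k, rank)
                   for s in range(len(graphs))]
        _, A = batch_graphs(rebuilt)
    p1 = model.predict_proba_arrays(Xp, A)
    return float(np.sqrt(np.mean((p1 - p0) ** 2)))


def _flat_gemm(H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(B, N, f) @ (f, g) as a single GEMM."""
    B, N, f = H.shape
    return (np.ascontiguousarray(H).reshape(B * N, f) @ W).reshape(B, N, -1)


def _gather_rows(T: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """T[b, idx[b]] via flat row offsets (avoids materializing broadcast
    integer index arrays, which dominates on memory-bound hosts)."""
    B, N = T.shape[0], T.shape[1]
    flat = T.reshape(B * N, *T.shape[2:])
    off = (idx + (np.arange(B) * N)[:, None]).ravel()
    return flat[off].reshape(B, idx.shape[1], *T.shape[2:])


def _sagpool_sweep(model, X: np.ndarray, A: np.ndarray,
                   pairs: list, values, pair_chunk: int = 16) -> np.ndarray:
    """Evaluation-only SAGPool sweep exploiting that a single-connection
    perturbation changes the block-1 pre-activations by a rank-2 update.

    Pairs are processed ``pair_chunk`` at a time as one fused batch, the
    first-block convolution is computed once for the whole sweep, and the
    symmetric normalization is folded into the convolution operands
    (D^{-1/2}(A+I)D^{-1/2} M == dinv * (A @ (dinv * M) + dinv * M)) so the
    normalized adjacency is never materialized. Equivalent to the generic
    per-pair forward (tested against it).
    """
    cfg = model.config
    p = {k: t.data for k, t in model._params.items()}
    S, N = X.shape[0], X.shape[1]
    dtype = X.dtype

    def dinv_of(AI_b):
        # AI_b carries unit self-loops, so row sums are already the
        # self-loop-augmented weighted degrees
        d = AI_b.sum(axis=-1)
        return (1.0 / np.sqrt(np.clip(d, 1e-6, None)))[..., None].astype(dtype)

    def conv(AI_b, dinv, M, bias):
        out = AI_b @ (dinv * M)
        out *= dinv
        out += bias
        return out

    def tail(H1, AI_b, dinv1):
        """Blocks 1..B from the block-1 activation, then the head."""
        H, A_cur, dinv = H1, AI_b, dinv1
        readouts = []
        for b in range(cfg.sag_blocks):
            if b > 0:
                dinv = dinv_of(A_cur)
                H = np.maximum(conv(A_cur, dinv, _flat_gemm(H, p[f"Wc{b}"]),
                                    p[f"bc{b}"]), 0.0)
            score = conv(A_cur, dinv, _flat_gemm(H, p[f"Ws{b}"]), p[f"bs{b}"])
            if cfg.sag_keep_ratio < 1.0:
                idx = model.top_k_indices(score[..., 0], cfg.sag_keep_ratio)
                H = _gather_rows(H, idx)
                score = _gather_rows(score, idx)
                bi = np.arange(A_cur.shape[0])[:, None, None]
                A_cur = A_cur[bi, idx[:, :, None], idx[:, None, :]]
            H = H * np.tanh(score)
            readouts.append(np.concatenate([H.mean(axis=1), H.max(axis=1)],
                                           axis=-1))
        if cfg.sag_jk == "concat":
            jk = np.concatenate(readouts, axis=-1)
        else:
            jk = np.sum(readouts, axis=0)
        hid = np.maximum(jk @ p["Wfc"] + p["bfc"], 0.0)
        logits = hid @ p["Wout"] + p["bout"]
        logits = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    AI = A + np.eye(N, dtype=dtype)                 # unit self-loops baked in
    dinv0 = dinv_of(AI)                             # (S, N, 1)
    W1 = p["Wc0"]
    h = W1.shape[1]
    P1 = conv(AI, dinv0, _flat_gemm(X, W1), p["bc0"])
    p0 = tail(np.maximum(P1, 0.0), AI, dinv0).astype(np.float64)

    P = min(pair_chunk, len(pairs))
    AI_tiled = np.tile(AI, (P, 1, 1))
    dinv_tiled = np.tile(dinv0, (P, 1, 1))
    buf = np.empty((P, S, N, h), dtype=P1.dtype)
    out = np.empty(len(pairs))
    for lo in range(0, len(pairs), P):
        chunk = pairs[lo:lo + P]
        for c, (i, j) in enumerate(chunk):
            v = values[lo + c]
            # column i of Ahat, scaled: Ahat[:, n, i] = dinv[n] AI[n, i] dinv[i]
            a = (AI[:, :, i] * dinv0[..., 0]) * (dinv0[:, i] * (v - X[:, i, j])[:, None])
            b = (AI[:, :, j] * dinv0[..., 0]) * (dinv0[:, j] * (v - X[:, j, i])[:, None])
            np.multiply(a[..., None], W1[j], out=buf[c])
            buf[c] += b[..., None] * W1[i]
            buf[c] += P1
        m = len(chunk)
        H1 = np.maximum(buf[:m].reshape(m * S, N, h), 0.0)
        p1 = tail(H1, AI_tiled[:m * S], dinv_tiled[:m * S]).astype(np.float64)
        diff = (p1.reshape(m, S, -1) - p0) ** 2
        out[lo:lo + m] = np.sqrt(diff.mean(axis=(1, 2)))
    return out


@dataclass
class PerturbationScores:
    """Per-pair RMSE influence, per model and averaged across models."""

    pairs: list                 # [(i, j), ...] lexicographic
    per_model: np.ndarray       # (n_models, n_pairs)
    perturb_value: float

    def __post_init__(self):
        self.per_model = np.atleast_2d(np.asarray(self.per_model, dtype=float))
        if self.per_model.shape[1] != len(self.pairs):
            raise ValueError("per_model column count must equal number of pairs")
        if not np.all(np.isfinite(self.per_model)) or np.any(self.per_model < 0):
            raise ValueError("RMSE scores must be finite and nonnegative")

    @property
    def mean_rmse(self) -> np.ndarray:
        return self.per_model.mean(axis=0)

    def mean_map(self) -> dict[tuple[int, int], float]:
        return dict(zip(self.pairs, self.mean_rmse.tolist()))


def perturbation_scores(models, graphs: list[BrainGraph],
                        value: float | None = None,
                        pairs: list[tuple[int, int]] | None = None,
                        per_connection_value: bool = False,
                        perturb_base: str = "signed",
                        dtype=np.float64) -> PerturbationScores:
    """Full perturbation sweep for one or more trained models.

    ``value`` defaults to :func:`perturb_value` over the graphs' dense
    feature matrices; ``per_connection_value=True`` instead uses 3 x the
    per-connection maximum across subjects (an alternative reading of the
    substitution rule, off by default). ``dtype=np.float32`` roughly
    halves the sweep's memory traffic; RMSE values then agree with the
    float64 path to single precision, far below ranking resolution.
    """
    if isinstance(models, _Module):
        models = [models]
    X, A = batch_graphs(graphs)
    X = X.astype(dtype)
    A = A.astype(dtype)
    n = X.shape[-1]
    if pairs is None:
        pairs = all_pairs(n)
    mats = [g.node_features for g in graphs]
    if value is None and not per_connection_value:
        value = perturb_value(mats, base=perturb_base)
    values = np.empty(len(pairs))
    for pi, (i, j) in enumerate(pairs):
        if per_connection_value:
            col = np.abs(X[:, i, j]) if perturb_base == "absolute" else X[:, i, j]
            values[pi] = 3.0 * float(col.max())
        else:
            values[pi] = value
    chunk = max(len(graphs), 1)
    scores = np.zeros((len(models), len(pairs)))
    from .models import SAGPoolClassifier
    for mi, model in enumerate(models):
        model = model.astype(dtype) if dtype != np.float64 else model
        if isinstance(model, SAGPoolClassifier):
            scores[mi] = _sagpool_sweep(model, X, A, pairs, values)
            continue
        ctx = model.precompute(A)  # adjacency is fixed across the sweep
        p0 = model.predict_proba_arrays(X, A, chunk=chunk, ctx=ctx).astype(np.float64)
        for pi, (i, j) in enumerate(pairs):
            v = values[pi]
            oi, oj = X[:, i, j].copy(), X[:, j, i].copy()
            X[:, i, j] = v
            X[:, j, i] = v
            p1 = model.predict_proba_arrays(X, A, chunk=chunk, ctx=ctx).astype(np.float64)
            X[:, i, j] = oi
            X[:, j, i] = oj
            scores[mi, pi] = np.sqrt(np.mean((p1 - p0) ** 2))
    return PerturbationScores(pairs=list(pairs), per_model=scores,
                              perturb_value=float(value) if value is not None else float("nan"))


@dataclass
class ConnectionRanking:
    """Full descending ordering of connections by mean influence."""

    ordered: list               # [((i, j), mean_rmse), ...] descending
    top_k: int = 20

    def top(self, k: int | None = None) -> list:
        k = self.top_k if k is None else k
        return self.ordered[:k]

    def top_pairs(self, k: int | None = None) -> list[tuple[int, int]]:
        return [pair for pair, _ in self.top(k)]


def rank_connections(scores: PerturbationScores, k: int = 20) -> ConnectionRanking:
    """Rank all scored connections by mean RMSE, descending; ties break
    toward the lexicographically smaller pair."""
    n_pairs = len(scores.pairs)
    if not 0 < k <= n_pairs:
        raise ValueError(f"k must lie in [1, {n_pairs}], got {k}")
    mean = scores.mean_rmse
    order = sorted(range(n_pairs), key=lambda idx: (-mean[idx], scores.pairs[idx]))
    ordered = [(scores.pairs[idx], float(mean[idx])) for idx in order]
    return ConnectionRanking(ordered=ordered, top_k=k)


def ranking_to_tsv(ranking: ConnectionRanking, scores: PerturbationScores,
                   table: ParcelTable, path, k: int | None = None) -> None:
    """Ranked-connections TSV with region names, network groups, mean and
    per-model RMSE columns."""
    k = ranking.top_k if k is None else k
    pair_index = {p: idx for idx, p in enumerate(scores.pairs)}
    n_models = scores.per_model.shape[0]
    with open(Path(path), "w") as fh:
        cols = ["rank", "region_i_name", "region_j_name",
                "network_group_i", "network_group_j", "mean_rmse"]
        cols += [f"rmse_model{m}" for m in range(n_models)]
        fh.write("\t".join(cols) + "\n")
        for rank_i, (pair, mean) in enumerate(ranking.top(k), start=1):
            i, j = pair
            row = [str(rank_i), table.names[i], table.names[j],
                   table.network_group[i], table.network_group[j], f"{mean:.10g}"]
            row += [f"{scores.per_model[m, pair_index[pair]]:.10g}"
                    for m in range(n_models)]
            fh.write("\t".join(row) + "\n")
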