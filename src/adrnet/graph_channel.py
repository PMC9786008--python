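"""Graph-isomorphism-network channel over molecular graphs.

Message passing follows the sum-aggregation scheme

    m_u^{t+1} = sum_{v in N(u)} W_t (h_v^t + embed(e_uv))
    h_u^{t+1} = W_t (h_u^t + m_u^{t+1})

where the aggregation and update maps at iteration t share a single square
weight matrix W_t of width ``dim``. Initial node states are the sum of the
atomic-number and chirality embeddings; edge features are the sum of the
bond-type and bond-direction embeddings. After T iterations the graph-level
embedding is the element-wise maximum over node states (max-pool readout).

Three independently parameterized encoders, tagged ``m`` (mutual
information), ``e`` (edge) and ``c`` (context), produce the embeddings
X^m, X^e, X^c that the fusion head consumes. By default each is a seeded
random initialization that is fine-tuned during supervised training;
weights may also be loaded from file, and desk-scale self-supervised
warm-starts for the edge and infomax objectives are available via
:func:`toy_pretrain`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .autodiff import Adam, Tensor, bce_with_logits
from .errors import ConfigurationError
from .featurize import (
    NUM_ATOMIC_NUMBERS,
    NUM_BOND_DIRECTIONS,
    NUM_BOND_TYPES,
    NUM_CHIRALITIES,
    MolecularGraph,
)

ObjectiveTag = Literal["m", "e", "c"]

WEIGHTS_SCHEMA_VERSION = 1

DEFAULT_DIM = 300
DEFAULT_T = 5


@dataclass
class GinParams:
    """All learnable tensors of one GIN encoder.

    ``Ws[t]`` is the (dim, dim) matrix shared by aggregation and update at
    iteration t; the four embedding tables map node/edge attributes to
    width-``dim`` vectors.
    """

    dim: int
    T: int
    Ws: list[Tensor]
    atom_emb: Tensor
    chirality_emb: Tensor
    bond_type_emb: Tensor
    bond_dir_emb: Tensor
    objective_tag: ObjectiveTag = "m"

    def __post_init__(self):
        if self.T < 1:
            raise ConfigurationError(f"T must be >= 1, got {self.T}")
        if len(self.Ws) != self.T:
            raise ConfigurationError(
                f"expected {self.T} weight matrices, got {len(self.Ws)}"
            )
        for t, W in enumerate(self.Ws):
            if W.shape != (self.dim, self.dim):
                raise ConfigurationError(
                    f"W[{t}] has shape {W.shape}, expected {(self.dim, self.dim)}"
                )
        for name, emb, rows in (
            ("atom_emb", self.atom_emb, NUM_ATOMIC_NUMBERS),
            ("chirality_emb", self.chirality_emb, NUM_CHIRALITIES),
            ("bond_type_emb", self.bond_type_emb, NUM_BOND_TYPES),
            ("bond_dir_emb", self.bond_dir_emb, NUM_BOND_DIRECTIONS),
        ):
            if emb.shape != (rows, self.dim):
                raise ConfigurationError(
                    f"{name} has shape {emb.shape}, expected {(rows, self.dim)}"
                )

    def tensors(self) -> list[Tensor]:
        return [
            *self.Ws,
            self.atom_emb,
            self.chirality_emb,
            self.bond_type_emb,
            self.bond_dir_emb,
        ]

    def copy(self) -> "GinParams":
        return replace(
            self,
            Ws=[Tensor(W.data.copy(), requires_grad=True) for W in self.Ws],
            atom_emb=Tensor(self.atom_emb.data.copy(), requires_grad=True),
            chirality_emb=Tensor(self.chirality_emb.data.copy(), requires_grad=True),
            bond_type_emb=Tensor(self.bond_type_emb.data.copy(), requires_grad=True),
            bond_dir_emb=Tensor(self.bond_dir_emb.data.copy(), requires_grad=True),
        )


@dataclass(frozen=True)
class GraphEmbedding:
    """Graph-level vector of width ``dim``, tagged by pretraining objective."""

    vector: np.ndarray
    objective_tag: ObjectiveTag

    def __post_init__(self):
        if not np.all(np.isfinite(self.vector)):
            raise ConfigurationError("graph embedding contains non-finite entries")


def init_gin_params(
    dim: int = DEFAULT_DIM,
    T: int = DEFAULT_T,
    objective_tag: ObjectiveTag = "m",
    seed: int = 0,
    dtype=np.float32,
) -> GinParams:
    """Seeded random initialization of one GIN encoder.

    Weight matrices use a small gaussian scale (std 0.5/sqrt(dim)) so that
    T iterations of the purely linear updates neither explode nor vanish on
    typical molecular graphs.
    """
    rng = np.random.default_rng(seed)

    def mat(rows, cols, std):
        return Tensor(
            rng.normal(0.0, std, size=(rows, cols)).astype(dtype), requires_grad=True
        )

    w_std = 0.5 / np.sqrt(dim)
    emb_std = 0.3
    return GinParams(
        dim=dim,
        T=T,
        Ws=[mat(dim, dim, w_std) for _ in range(T)],
        atom_emb=mat(NUM_ATOMIC_NUMBERS, dim, emb_std),
        chirality_emb=mat(NUM_CHIRALITIES, dim, emb_std),
        bond_type_emb=mat(NUM_BOND_TYPES, dim, emb_std),
        bond_dir_emb=mat(NUM_BOND_DIRECTIONS, dim, emb_std),
        objective_tag=objective_tag,
    )


# ---------------------------------------------------------------------------
# batched graph structure


@dataclass
class BatchedGraphs:
    """Several graphs packed into one disjoint union for vectorized passes."""

    atom_ids: np.ndarray  # (N,)
    chirality_ids: np.ndarray  # (N,)
    src: np.ndarray  # (2E,) directed edge sources
    dst: np.ndarray  # (2E,) directed edge targets
    bond_type_ids: np.ndarray  # (2E,)
    bond_dir_ids: np.ndarray  # (2E,)
    graph_index: np.ndarray  # (N,) graph id per node
    num_graphs: int
    num_nodes: int


def batch_graphs(graphs: Sequence[MolecularGraph]) -> BatchedGraphs:
    atom_ids, chir_ids, gidx = [], [], []
    src, dst, bt, bd = [], [], [], []
    offset = 0
    for g_i, g in enumerate(graphs):
        for a, c in g.node_attrs:
            atom_ids.append(a)
            chir_ids.append(int(c))
            gidx.append(g_i)
        for (u, v), (t, d) in zip(g.edges, g.edge_attrs):
            src.extend((offset + u, offset + v))
            dst.extend((offset + v, offset + u))
            bt.extend((int(t), int(t)))
            bd.extend((int(d), int(d)))
        offset += g.num_nodes
    return BatchedGraphs(
        atom_ids=np.array(atom_ids, dtype=np.int64),
        chirality_ids=np.array(chir_ids, dtype=np.int64),
        src=np.array(src, dtype=np.int64),
        dst=np.array(dst, dtype=np.int64),
        bond_type_ids=np.array(bt, dtype=np.int64),
        bond_dir_ids=np.array(bd, dtype=np.int64),
        graph_index=np.array(gidx, dtype=np.int64),
        num_graphs=len(graphs),
        num_nodes=offset,
    )


def _initial_states(batch: BatchedGraphs, params: GinParams) -> Tensor:
    return params.atom_emb.take_rows(batch.atom_ids) + params.chirality_emb.take_rows(
        batch.chirality_ids
    )


def _edge_features(batch: BatchedGraphs, params: GinParams) -> Tensor:
    return params.bond_type_emb.take_rows(
        batch.bond_type_ids
    ) + params.bond_dir_emb.take_rows(batch.bond_dir_ids)


def _message_pass(
    h: Tensor, batch: BatchedGraphs, edge_feat: Tensor, W: Tensor
) -> Tensor:
    msg = (h.take_rows(batch.src) + edge_feat) @ W
    m = msg.segment_sum(batch.dst, batch.num_nodes)
    return (h + m) @ W


def gin_node_states(batch: BatchedGraphs, params: GinParams) -> Tensor:
    """Run T message-passing iterations; returns (num_nodes, dim) states."""
    h = _initial_states(batch, params)
    edge_feat = _edge_features(batch, params)
    for t in range(params.T):
        h = _message_pass(h, batch, edge_feat, params.Ws[t])
    return h


def gin_encode_batch(batch: BatchedGraphs, params: GinParams) -> Tensor:
    """Graph embeddings for a batch: max-pool readout, (num_graphs, dim)."""
    h = gin_node_states(batch, params)
    return h.segment_max(batch.graph_index, batch.num_graphs)


# ---------------------------------------------------------------------------
# single-graph surface


def gin_message_pass(
    graph: MolecularGraph,
    states: np.ndarray,
    params: GinParams,
    t: int,
) -> np.ndarray:
    """One message-passing iteration on a single graph (numpy in/out)."""
    states = np.asarray(states)
    if states.shape != (graph.num_nodes, params.dim):
        raise ConfigurationError(
            f"states shape {states.shape} does not match "
            f"({graph.num_nodes}, {params.dim})"
        )
    if not 0 <= t < params.T:
        raise ConfigurationError(f"iteration index {t} outside [0, {params.T})")
    batch = batch_graphs([graph])
    h = Tensor(states)
    edge_feat = _edge_features(batch, params)
    return _message_pass(h, batch, edge_feat, params.Ws[t]).data


def gin_encode(graph: MolecularGraph, params: GinParams) -> GraphEmbedding:
    """Encode one molecular graph into a width-``dim`` embedding."""
    batch = batch_graphs([graph])
    out = gin_encode_batch(batch, params)
    return GraphEmbedding(vector=out.data[0].copy(), objective_tag=params.objective_tag)


def encode_three_objectives(
    graph: MolecularGraph,
    params_m: GinParams,
    params_e: GinParams,
    params_c: GinParams,
) -> tuple[GraphEmbedding, GraphEmbedding, GraphEmbedding]:
    """(X^m, X^e, X^c) in that fixed order."""
    return (
        gin_encode(graph, params_m),
        gin_encode(graph, params_e),
        gin_encode(graph, params_c),
    )


# ---------------------------------------------------------------------------
# weight files


def save_weights(params: GinParams, path: str | Path) -> None:
    """Write encoder weights to an .npz file with a JSON schema header."""
    meta = {
        "schema_version": WEIGHTS_SCHEMA_VERSION,
        "dim": params.dim,
        "T": params.T,
        "objective_tag": params.objective_tag,
        "vocab": {
            "atom": NUM_ATOMIC_NUMBERS,
            "chirality": NUM_CHIRALITIES,
            "bond_type": NUM_BOND_TYPES,
            "bond_dir": NUM_BOND_DIRECTIONS,
        },
    }
    arrays = {f"W_{t}": W.data for t, W in enumerate(params.Ws)}
    arrays.update(
        atom_emb=params.atom_emb.data,
        chirality_emb=params.chirality_emb.data,
        bond_type_emb=params.bond_type_emb.data,
        bond_dir_emb=params.bond_dir_emb.data,
    )
    with open(path, "wb") as f:  # plain open: np.savez must not append ".npz"
        np.savez(
            f, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays
        )


def load_weights(path: str | Path) -> GinParams:
    """Load encoder weights; schema mismatches raise ConfigurationError."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"weights file {path} does not exist")
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise IOError(f"could not read weights file {path}: {exc}") from exc
    if "meta" not in data:
        raise ConfigurationError(f"weights file {path} lacks a schema header")
    meta = json.loads(bytes(data["meta"]).decode())
    if meta.get("schema_version") != WEIGHTS_SCHEMA_VERSION:
        raise ConfigurationError(
            f"schema_version mismatch: file has {meta.get('schema_version')}, "
            f"expected {WEIGHTS_SCHEMA_VERSION}"
        )
    vocab = meta.get("vocab", {})
    expected_vocab = {
        "atom": NUM_ATOMIC_NUMBERS,
        "chirality": NUM_CHIRALITIES,
        "bond_type": NUM_BOND_TYPES,
        "bond_dir": NUM_BOND_DIRECTIONS,
    }
    for key, exp in expected_vocab.items():
        if vocab.get(key) != exp:
            raise ConfigurationError(
                f"vocab size mismatch for {key!r}: file has {vocab.get(key)}, "
                f"expected {exp}"
            )
    dim, T = meta["dim"], meta["T"]
    missing = [f"W_{t}" for t in range(T) if f"W_{t}" not in data]
    if missing:
        raise ConfigurationError(f"weights file missing arrays: {missing}")
    for t in range(T):
        if data[f"W_{t}"].shape != (dim, dim):
            raise ConfigurationError(
                f"dim mismatch: W_{t} has shape {data[f'W_{t}'].shape}, "
                f"expected {(dim, dim)}"
            )
    return GinParams(
        dim=dim,
        T=T,
        Ws=[Tensor(data[f"W_{t}"], requires_grad=True) for t in range(T)],
        atom_emb=Tensor(data["atom_emb"], requires_grad=True),
        chirality_emb=Tensor(data["chirality_emb"], requires_grad=True),
        bond_type_emb=Tensor(data["bond_type_emb"], requires_grad=True),
        bond_dir_emb=Tensor(data["bond_dir_emb"], requires_grad=True),
        objective_tag=meta.get("objective_tag", "m"),
    )


# ---------------------------------------------------------------------------
# desk-scale self-supervised warm starts


def _sample_non_edges(
    graph: MolecularGraph, count: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    n = graph.num_nodes
    present = {(min(u, v), max(u, v)) for u, v in graph.edges}
    out: list[tuple[int, int]] = []
    attempts = 0
    while len(out) < count and attempts < 50 * max(count, 1):
        u, v = rng.integers(0, n, size=2)
        attempts += 1
        if u == v:
            continue
        key = (min(u, v), max(u, v))
        if key in present:
            continue
        out.append((int(u), int(v)))
    return out


def toy_pretrain(
    graphs: Sequence[MolecularGraph],
    objective: Literal["edge", "infomax"],
    params: GinParams,
    epochs: int = 50,
    seed: int = 0,
    lr: float = 1e-3,
) -> GinParams:
    """Small self-supervised warm start for a GIN encoder.

    ``edge``: discriminate true bonds from uniformly sampled non-bonded
    atom pairs through node-state dot products. ``infomax``: discriminate
    (node state, own-graph mean summary) pairs from pairings with another
    graph's summary. Both are deliberately desk-scale objectives; the
    ``context`` objective of the full-scale pretraining literature is not
    implemented. Returns a new, updated parameter set; deterministic for a
    given seed. ``epochs=0`` returns an exact copy.
    """
    if objective == "context":
        raise NotImplementedError("the context pretraining objective is not provided")
    if objective not in ("edge", "infomax"):
        raise ConfigurationError(f"unknown pretraining objective {objective!r}")
    if len(graphs) < 2:
        raise ConfigurationError("toy_pretrain requires at least 2 graphs")
    params = params.copy()
    if epochs == 0:
        return params
    rng = np.random.default_rng(seed)
    batch = batch_graphs(list(graphs))
    offsets = np.concatenate(([0], np.cumsum([g.num_nodes for g in graphs])))
    opt = Adam(params.tensors(), lr=lr)
    scale = 1.0 / np.sqrt(params.dim)
    for _ in range(epochs):
        h = gin_node_states(batch, params)
        if objective == "edge":
            pos_u, pos_v, neg_u, neg_v = [], [], [], []
            for g_i, g in enumerate(graphs):
                off = offsets[g_i]
                for u, v in g.edges:
                    pos_u.append(off + u)
                    pos_v.append(off + v)
                for u, v in _sample_non_edges(g, g.num_edges, rng):
                    neg_u.append(off + u)
                    neg_v.append(off + v)
            u_idx = np.array(pos_u + neg_u, dtype=np.int64)
            v_idx = np.array(pos_v + neg_v, dtype=np.int64)
            y = np.concatenate(
                [np.ones(len(pos_u)), np.zeros(len(neg_u))]
            ).astype(h.dtype)
            logits = (h.take_rows(u_idx) * h.take_rows(v_idx)).sum(axis=1) * scale
        else:  # infomax
            summary = h.segment_sum(batch.graph_index, batch.num_graphs) * Tensor(
                (1.0 / np.maximum(np.bincount(batch.graph_index), 1))[:, None].astype(
                    h.dtype
                )
            )
            own = batch.graph_index
            shuffle = rng.permutation(batch.num_graphs)
            # guarantee a different graph for every negative pairing
            clash = shuffle[own] == own
            other = np.where(clash, (shuffle[own] + 1) % batch.num_graphs, shuffle[own])
            pos = (h * summary.take_rows(own)).sum(axis=1) * scale
            neg = (h * summary.take_rows(other)).sum(axis=1) * scale
            from .autodiff import concat as _concat

            logits = _concat([pos, neg], axis=0)
            y = np.concatenate(
                [np.ones(batch.num_nodes), np.zeros(batch.num_nodes)]
            ).astype(h.dtype)
        loss = bce_with_logits(logits, y).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    return params


def edge_discrimination_accuracy(
    graphs: Sequence[MolecularGraph], params: GinParams, seed: int = 0
) -> float:
    """Accuracy of true-edge vs non-edge discrimination (evaluation helper)."""
    rng = np.random.default_rng(seed)
    batch = batch_graphs(list(graphs))
    h = gin_node_states(batch, params).data
    offsets = np.concatenate(([0], np.cumsum([g.num_nodes for g in graphs])))
    scores, labels = [], []
    for g_i, g in enumerate(graphs):
        off = offsets[g_i]
        for u, v in g.edges:
            scores.append(float(h[off + u] @ h[off + v]))
            labels.append(1)
        for u, v in _sample_non_edges(g, g.num_edges, rng):
            scores.append(float(h[off + u] @ h[off + v]))
            labels.append(0)
    scores = np.array(scores)
    labels = np.array(labels)
    preds = (scores >= np.median(scores)).astype(int)
    return float((preds == labels).mean())
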