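"""The two-branch log-IC50 regressor.

Branch 1 (graph): a learned embedding of the (element, hybridization)
vocabulary id is concatenated with the 10 numeric atom features and linearly
projected, then passed through two edge-conditioned graph-attention layers
(ReLU -> batch norm -> dropout after each). Concatenated global mean and max
pooling over final node states yield a 256-dimensional graph embedding.

Branch 2 (descriptors): the normalized 544-vector goes through a
544 -> 256 -> 128 feedforward stack (ReLU, batch norm, dropout 0.3 per layer).

Fusion: [graph 256 | descriptors 128 | molecular size 1] = 385 -> 64 -> 1,
predicting log10 IC50 in nM.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, no_grad, segment_max, segment_mean
from .featurize import (AtomVocab, MolecularGraph, N_DESCRIPTORS,
                        N_EDGE_FEATURES, N_NODE_FEATURES, Normalizer,
                        descriptor_vector, smiles_to_graph)

N_NUMERIC_NODE_FEATURES = N_NODE_FEATURES - 1  # vocab id handled by embedding


@dataclass
class ModelConfig:
    vocab_size: int
    gat_hidden: int = 128
    gat_layers: int = 2
    gat_heads: int = 2
    gat_dropout: float = 0.2
    desc_dims: tuple[int, ...] = (N_DESCRIPTORS, 256, 128)
    desc_dropout: float = 0.3
    head_hidden: int = 64
    head_dropout: float = 0.2
    atom_embed_dim: int = 32
    ablate_descriptors: bool = False
    seed: int = 0

    @property
    def graph_embedding_dim(self) -> int:
        return 2 * self.gat_hidden

    @property
    def fused_dim(self) -> int:
        return self.graph_embedding_dim + self.desc_dims[-1] + 1

    def __post_init__(self):
        self.desc_dims = tuple(self.desc_dims)
        if self.gat_hidden % self.gat_heads != 0:
            raise ValueError("gat_hidden must be divisible by gat_heads")


@dataclass
class GraphBatch:
    """Several molecular graphs packed into one disjoint-union graph."""

    node_vocab_ids: np.ndarray    # (N,)
    node_numeric: np.ndarray      # (N, 10)
    edge_index: np.ndarray        # (2, E) with node indices offset per graph
    edge_features: np.ndarray     # (E, 5)
    graph_ids: np.ndarray         # (N,) which molecule each node belongs to
    n_graphs: int

    @classmethod
    def collate(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        vocab_ids, numeric, edges, efeats, gids = [], [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            if g.n_nodes == 0:
                raise ValueError("graph with zero nodes in batch")
            vocab_ids.append(g.node_vocab_ids)
            numeric.append(g.node_features[:, 1:])
            edges.append(g.edge_index + offset)
            efeats.append(g.edge_features)
            gids.append(np.full(g.n_nodes, gi, dtype=np.int64))
            offset += g.n_nodes
        return cls(
            node_vocab_ids=np.concatenate(vocab_ids),
            node_numeric=np.vstack(numeric),
            edge_index=np.hstack(edges) if edges else np.zeros((2, 0), int),
            edge_features=np.vstack(efeats),
            graph_ids=np.concatenate(gids),
            n_graphs=len(graphs),
        )


class HybridIC50Model(nn.Module):
    """Graph-attention + descriptor fusion regressor for log10 IC50 (nM)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        init_rng = np.random.default_rng(config.seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1]))

        c = config
        head_dim = c.gat_hidden // c.gat_heads
        self.atom_embedding = nn.Embedding(c.vocab_size, c.atom_embed_dim,
                                           init_rng)
        self.node_proj = nn.Linear(c.atom_embed_dim + N_NUMERIC_NODE_FEATURES,
                                   c.gat_hidden, init_rng)
        self.node_proj_norm = nn.BatchNorm1d(c.gat_hidden)
        self.gat_layers = [
            nn.EdgeGATLayer(c.gat_hidden, head_dim, c.gat_heads,
                            N_EDGE_FEATURES, init_rng)
            for _ in range(c.gat_layers)
        ]
        self.gat_norms = [nn.BatchNorm1d(c.gat_hidden)
                          for _ in range(c.gat_layers)]
        self.gat_dropouts = [nn.Dropout(c.gat_dropout, self.dropout_rng)
                             for _ in range(c.gat_layers)]

        dims = c.desc_dims
        self.desc_linears = [nn.Linear(dims[i], dims[i + 1], init_rng)
                             for i in range(len(dims) - 1)]
        self.desc_norms = [nn.BatchNorm1d(d) for d in dims[1:]]
        self.desc_dropouts = [nn.Dropout(c.desc_dropout, self.dropout_rng)
                              for _ in dims[1:]]

        self.head_linear = nn.Linear(c.fused_dim, c.head_hidden, init_rng)
        self.head_norm = nn.BatchNorm1d(c.head_hidden)
        self.head_dropout = nn.Dropout(c.head_dropout, self.dropout_rng)
        self.out_linear = nn.Linear(c.head_hidden, 1, init_rng)

    # -- branches -------------------------------------------------------------

    def encode_graph_batch(self, batch: GraphBatch) -> Tensor:
        """(n_graphs, 2*gat_hidden) graph embeddings (mean-pool | max-pool)."""
        emb = self.atom_embedding(batch.node_vocab_ids)
        x = concat([emb, Tensor(batch.node_numeric)], axis=1)
        x = self.node_proj_norm(self.node_proj(x))
        for gat, norm, drop in zip(self.gat_layers, self.gat_norms,
                                   self.gat_dropouts):
            x = gat(x, batch.edge_index, batch.edge_features)
            x = drop(norm(x.relu()))
        pooled_mean = segment_mean(x, batch.graph_ids, batch.n_graphs)
        pooled_max = segment_max(x, batch.graph_ids, batch.n_graphs)
        return concat([pooled_mean, pooled_max], axis=1)

    def encode_graph(self, graph: MolecularGraph) -> np.ndarray:
        """Deterministic eval-mode embedding of one molecule (length 256)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.encode_graph_batch(GraphBatch.collate([graph]))
        finally:
            if was_training:
                self.train()
        return out.data[0]

    def encode_descriptors(self, vectors: Tensor | np.ndarray) -> Tensor:
        """(B, 128) embeddings of normalized 544-descriptor vectors."""
        x = vectors if isinstance(vectors, Tensor) else Tensor(vectors)
        if x.shape[-1] != self.config.desc_dims[0]:
            raise ValueError(
                f"expected descriptor width {self.config.desc_dims[0]}, "
                f"got {x.shape[-1]}")
        for lin, norm, drop in zip(self.desc_linears, self.desc_norms,
                                   self.desc_dropouts):
            x = drop(norm(lin(x).relu()))
        return x

    def forward(self, batch: GraphBatch, desc: np.ndarray,
                mol_sizes: np.ndarray) -> Tensor:
        """Predicted log10 IC50 for a batch; shape (n_graphs,)."""
        g = self.encode_graph_batch(batch)
        d = self.encode_descriptors(desc)
        if self.config.ablate_descriptors:
            d = d * Tensor(np.zeros(1))
        sizes = Tensor(np.asarray(mol_sizes, dtype=np.float64).reshape(-1, 1))
        fused = concat([g, d, sizes], axis=1)
        h = self.head_dropout(self.head_norm(self.head_linear(fused).relu()))
        return self.out_linear(h).reshape(-1)

    __call__ = forward

    def attention_weights(self) -> list[dict]:
        """Raw attention from the last forward pass, one dict per GAT layer."""
        return [{"edge_index": layer.last_edge_index,
                 "attention": layer.last_attention}
                for layer in self.gat_layers]

    # -- persistence ----------------------------------------------------------

    def _state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, nn.BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays[:len(params)]):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.astype(np.float64).copy()
        rest = arrays[len(params):]
        i = 0
        for m in self.modules():
            if isinstance(m, nn.BatchNorm1d):
                m.running_mean = rest[i].copy()
                m.running_var = rest[i + 1].copy()
                i += 2


@dataclass
class Predictor:
    """A trained model bundled with its vocabulary and normalizer.

    Everything needed to go from bare SMILES to a log10 IC50 prediction.
    """

    model: HybridIC50Model
    vocab: AtomVocab
    normalizer: Normalizer

    def predict_smiles(self, smiles_list: list[str]) -> np.ndarray:
        graphs = [smiles_to_graph(s, self.vocab) for s in smiles_list]
        desc = np.vstack([descriptor_vector(s) for s in smiles_list])
        desc = self.normalizer.apply(desc)
        sizes = np.array([g.mol_size for g in graphs], dtype=np.float64)
        was_training = self.model.training
        self.model.eval()
        try:
            with no_grad():
                preds = self.model(GraphBatch.collate(graphs), desc, sizes)
        finally:
            if was_training:
                self.model.train()
        return preds.data

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "format_version": 1,
            "config": asdict(self.model.config),
            "vocab": self.vocab.to_dict(),
            "normalizer": self.normalizer.to_dict(),
        }
        arrays = {f"arr_{i}": a
                  for i, a in enumerate(self.model._state_arrays())}
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Predictor":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            n = len([k for k in data.files if k.startswith("arr_")])
            arrays = [data[f"arr_{i}"] for i in range(n)]
        cfg_d = meta["config"]
        cfg_d["desc_dims"] = tuple(cfg_d["desc_dims"])
        config = ModelConfig(**cfg_d)
        model = HybridIC50Model(config)
        model.load_state_arrays(arrays)
        model.eval()
        return cls(model=model,
                   vocab=AtomVocab.from_dict(meta["vocab"]),
                   normalizer=Normalizer.from_dict(meta["normalizer"]))
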