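"""Neural-network layers used by the two-branch IC50 regressor.

Everything here is ordinary dense deep-learning machinery expressed on the
package's autodiff tensors: linear layers, a learned embedding table, batch
normalization with running statistics, inverted dropout, and a graph
attention layer whose attention logits are conditioned on edge features.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, segment_softmax, segment_sum


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = Tensor(_kaiming(rng, in_dim, (in_dim, out_dim)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"Linear expected input width {self.in_dim}, got {x.shape[-1]}")
        return x @ self.weight + self.bias


class Embedding(Module):
    """Learned lookup table for categorical ids (the atom-type vocabulary)."""

    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.num_embeddings, self.dim = num_embeddings, dim
        self.weight = Tensor(rng.normal(0.0, 1.0, size=(num_embeddings, dim)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= self.num_embeddings):
            raise ValueError("embedding id out of range")
        return self.weight.gather_rows(ids)


class BatchNorm1d(Module):
    """Batch normalization over axis 0 (samples, or nodes for the graph branch).

    Training uses mini-batch statistics and updates exponential running
    statistics; evaluation uses the running statistics, making eval-mode
    outputs deterministic and batch-size independent.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered ** 2).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbias = n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel() * unbias)
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = ((x - Tensor(self.running_mean))
                    / Tensor(np.sqrt(self.running_var + self.eps)))
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout: identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class EdgeGATLayer(Module):
    """Multi-head graph attention with edge-feature-conditioned logits.

    Each directed edge (s -> t) carries a message ``W h_s``; its attention
    logit is ``LeakyReLU(a_s . Wh_s + a_t . Wh_t + a_e . W_e e_st)``,
    softmax-normalized over the incoming edges of each target node.  Bond
    features therefore modulate how much each neighbor contributes. Self-loops
    (with zero edge features) are added so every node attends to itself and
    isolated atoms (e.g. methane) are well-defined.  Head outputs are
    concatenated: ``out_dim = heads * head_dim``.
    """

    def __init__(self, in_dim: int, head_dim: int, heads: int, edge_dim: int,
                 rng: np.random.Generator, negative_slope: float = 0.2):
        super().__init__()
        self.in_dim, self.head_dim, self.heads = in_dim, head_dim, heads
        self.edge_dim = edge_dim
        self.negative_slope = negative_slope
        hf = heads * head_dim
        self.weight = Tensor(_kaiming(rng, in_dim, (in_dim, hf)),
                             requires_grad=True)
        self.edge_weight = Tensor(_kaiming(rng, edge_dim, (edge_dim, hf)),
                                  requires_grad=True)
        self.att_src = Tensor(_kaiming(rng, head_dim, (heads, head_dim)),
                              requires_grad=True)
        self.att_dst = Tensor(_kaiming(rng, head_dim, (heads, head_dim)),
                              requires_grad=True)
        self.att_edge = Tensor(_kaiming(rng, head_dim, (heads, head_dim)),
                               requires_grad=True)
        self.bias = Tensor(np.zeros(hf), requires_grad=True)
        self.last_attention: np.ndarray | None = None  # (E_with_loops, heads)
        self.last_edge_index: np.ndarray | None = None

    def __call__(self, x: Tensor, edge_index: np.ndarray,
                 edge_attr: np.ndarray) -> Tensor:
        n = x.shape[0]
        if x.shape[1] != self.in_dim:
            raise ValueError(
                f"GAT layer expected node width {self.in_dim}, got {x.shape[1]}")
        # append self-loops with zero bond features
        loops = np.arange(n, dtype=np.int64)
        if edge_index.size:
            src = np.concatenate([edge_index[0], loops])
            dst = np.concatenate([edge_index[1], loops])
            eattr = np.vstack([edge_attr, np.zeros((n, self.edge_dim))])
        else:
            src, dst = loops, loops
            eattr = np.zeros((n, self.edge_dim))
        e = len(src)

        h = (x @ self.weight).reshape(n, self.heads, self.head_dim)
        ep = (Tensor(eattr) @ self.edge_weight).reshape(e, self.heads,
                                                        self.head_dim)
        h_src = h.gather_rows(src)
        h_dst = h.gather_rows(dst)
        logits = ((h_src * self.att_src).sum(axis=2)
                  + (h_dst * self.att_dst).sum(axis=2)
                  + (ep * self.att_edge).sum(axis=2))  # (E, heads)
        logits = logits.leaky_relu(self.negative_slope)
        alpha = segment_softmax(logits, dst, n)  # rows sum to 1 per dst node
        self.last_attention = alpha.data.copy()
        self.last_edge_index = np.vstack([src, dst])
        messages = h_src * alpha.reshape(e, self.heads, 1)
        out = segment_sum(messages, dst, n)  # (n, heads, head_dim)
        return out.reshape(n, self.heads * self.head_dim) + self.bias


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.relu()
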