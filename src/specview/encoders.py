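"""The four view encoders mapping into one shared embedding space.

Molecular graphs pass through a 3-layer graph convolution network,
mean pooling and a 2-layer feed-forward head (``Z_mol``); fingerprints
through a 3-layer MLP (``Z_fp``); spectra and consensus spectra each
through their own copy of a set encoder — a 3-layer per-peak MLP
followed by a 2-head self-attention transformer block with masked mean
pooling (``Z_s``, ``Z_cs``).  All four emit vectors of one shared
dimension, compared downstream by cosine similarity.  An alternative
"binned" spectral mode replaces the set encoders with 3-layer MLPs over
a fixed m/z grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .chemio import (
    EDGE_FEATURE_DIM,
    FINGERPRINT_BITS,
    NODE_FEATURE_DIM,
    MolecularGraph,
)
from .nn import (
    Linear,
    LayerNorm,
    MLP,
    Module,
    Parameter,
    Tensor,
    glorot,
    softmax,
)
from .spectra import PEAK_VECTOR_DIM, NormalizationStats

MASK_BIAS = -1.0e30  # additive attention bias for padded key positions


@dataclass
class EncoderConfig:
    """Architecture hyperparameters shared by all four encoders.

    ``embedding_dim`` is the shared output dimension; ``hidden`` the
    internal width of every stage.  ``spectral_mode`` selects the
    formula-annotated set encoder or the binned-MLP alternative.
    """

    embedding_dim: int = 256
    hidden: int = 512
    n_gcn_layers: int = 3
    n_attention_heads: int = 2
    spectral_mode: Literal["formula", "binned"] = "formula"
    bin_width: float = 1.0
    mz_min: float = 0.0
    mz_max: float = 1000.0

    @property
    def n_bins(self) -> int:
        return math.ceil((self.mz_max - self.mz_min) / self.bin_width)


class GraphEncoder(Module):
    """3-layer GCN, mean pooling, 2-layer feed-forward head.

    Message passing uses the symmetrically normalized adjacency with
    self-loops; each node's input is its atom feature vector concatenated
    with the mean feature vector of its incident bonds, so bond type,
    ring membership, conjugation and stereo inform the convolution.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.hidden
        in_dim = NODE_FEATURE_DIM + EDGE_FEATURE_DIM
        dims = [in_dim] + [h] * cfg.n_gcn_layers
        self.conv = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.head = MLP([h, h, cfg.embedding_dim], rng)

    @staticmethod
    def _inputs(g: MolecularGraph) -> tuple[np.ndarray, np.ndarray]:
        n = g.n_nodes
        adj = np.eye(n)
        edge_sum = np.zeros((n, EDGE_FEATURE_DIM))
        edge_deg = np.zeros(n)
        for k in range(g.edge_index.shape[1]):
            i, j = g.edge_index[0, k], g.edge_index[1, k]
            adj[i, j] = 1.0
            edge_sum[i] += g.edge_features[k]
            edge_deg[i] += 1.0
        mean_edge = edge_sum / np.maximum(edge_deg, 1.0)[:, None]
        deg = adj.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        norm_adj = adj * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
        x = np.concatenate([g.node_features, mean_edge], axis=1)
        return norm_adj, x

    def __call__(self, g: MolecularGraph) -> Tensor:
        norm_adj, x = self._inputs(g)
        a = Tensor(norm_adj)
        h = Tensor(x)
        for layer in self.conv:
            h = layer(a @ h).relu()
        pooled = h.mean(axis=0)
        return self.head(pooled.reshape(1, -1)).reshape(-1)

    def encode_batch(self, graphs: Sequence[MolecularGraph]) -> Tensor:
        return Tensor.stack([self(g) for g in graphs], axis=0)


class FingerprintEncoder(Module):
    """3-layer MLP over the 1024-bit Morgan fingerprint."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.hidden
        self.mlp = MLP([FINGERPRINT_BITS, h, h, cfg.embedding_dim], rng)

    def __call__(self, fp: np.ndarray | Tensor) -> Tensor:
        t = fp if isinstance(fp, Tensor) else Tensor(np.atleast_2d(fp))
        if t.shape[-1] != FINGERPRINT_BITS:
            raise ValueError(
                f"fingerprint length {t.shape[-1]}, expected {FINGERPRINT_BITS}"
            )
        out = self.mlp(t)
        return out.reshape(-1) if np.asarray(fp).ndim == 1 else out

    def encode_batch(self, fps: Sequence[np.ndarray]) -> Tensor:
        return self.mlp(Tensor(np.stack(fps)))


class AttentionBlock(Module):
    """One pre-built transformer encoder block with masked self-attention.

    Peaks are a set: no positional encodings are used, padded key
    positions receive a large negative attention bias, and the residual
    + layer-norm structure acts per position, so the block is equivariant
    to peak order and invariant to the amount of padding.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("hidden dim must divide by head count")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, 2 * dim, rng)
        self.ff2 = Linear(2 * dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        b, p, dim = x.shape
        nh, hd = self.n_heads, self.head_dim

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(b, p, nh, hd).swapaxes(1, 2)  # (b, nh, p, hd)

        q, k, v = split_heads(self.wq(x)), split_heads(self.wk(x)), split_heads(self.wv(x))
        scores = (q @ k.T) * (1.0 / math.sqrt(hd))  # (b, nh, p, p)
        bias = np.where(mask[:, None, None, :] > 0, 0.0, MASK_BIAS)
        attn = softmax(scores + Tensor(bias), axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(b, p, dim)
        x = self.ln1(x + self.wo(ctx))
        x = self.ln2(x + self.ff2(self.ff1(x).relu()))
        return x


class SpectrumEncoder(Module):
    """Per-peak 3-layer MLP, 2-head attention block, masked mean pooling."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.hidden
        self.peak_mlp = MLP([PEAK_VECTOR_DIM, h, h, h], rng)
        self.attention = AttentionBlock(h, cfg.n_attention_heads, rng)
        self.head = Linear(h, cfg.embedding_dim, rng)

    def __call__(self, peaks: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
        """Encode a padded batch ``(B, P, 15)`` with 0/1 mask ``(B, P)``.

        A single spectrum may be passed as ``(P, 15)`` without a mask.
        """
        single = peaks.ndim == 2
        if single:
            peaks = peaks[None]
        b, p, _ = peaks.shape
        if mask is None:
            mask = np.ones((b, p))
        if not mask.any(axis=1).all():
            raise ValueError("cannot encode a spectrum with zero peaks")
        x = self.peak_mlp(Tensor(peaks))
        x = self.attention(x, mask)
        m = Tensor(mask[:, :, None])
        pooled = (x * m).sum(axis=1) / Tensor(mask.sum(axis=1, keepdims=True))
        out = self.head(pooled)
        return out.reshape(-1) if single else out


class BinnedSpectrumEncoder(Module):
    """3-layer MLP over the fixed-grid binned spectrum vector."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.hidden
        self.mlp = MLP([cfg.n_bins, h, h, cfg.embedding_dim], rng)
        self.n_bins = cfg.n_bins

    def __call__(self, bins: np.ndarray) -> Tensor:
        single = bins.ndim == 1
        t = Tensor(np.atleast_2d(bins))
        if t.shape[-1] != self.n_bins:
            raise ValueError(f"expected {self.n_bins} bins, got {t.shape[-1]}")
        out = self.mlp(t)
        return out.reshape(-1) if single else out


VIEWS = ("mol", "fp", "s", "cs")


class MultiViewModel(Module):
    """All four view encoders plus the preprocessing statistics.

    The spectrum and consensus encoders share an architecture but never
    parameters.  The model carries the peak-count normalization
    statistics so a checkpoint is self-contained at inference.
    """

    def __init__(
        self,
        cfg: EncoderConfig,
        stats: NormalizationStats | None = None,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.stats = stats
        self.graph_encoder = GraphEncoder(cfg, rng)
        self.fingerprint_encoder = FingerprintEncoder(cfg, rng)
        if cfg.spectral_mode == "formula":
            self.spectrum_encoder = SpectrumEncoder(cfg, rng)
            self.consensus_encoder = SpectrumEncoder(cfg, rng)
        else:
            self.spectrum_encoder = BinnedSpectrumEncoder(cfg, rng)
            self.consensus_encoder = BinnedSpectrumEncoder(cfg, rng)

    def encoder(self, view: str) -> Module:
        try:
            return {
                "mol": self.graph_encoder,
                "fp": self.fingerprint_encoder,
                "s": self.spectrum_encoder,
                "cs": self.consensus_encoder,
            }[view]
        except KeyError:
            raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.cfg),
            "normalization": self.stats.max_count if self.stats else None,
            "state": {
                view: self.encoder(view).state()
                for view in VIEWS
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MultiViewModel":
        payload = json.loads(Path(path).read_text())
        cfg = EncoderConfig(**payload["config"])
        stats = (
            NormalizationStats(max_count=payload["normalization"])
            if payload["normalization"] is not None
            else None
        )
        model = cls(cfg, stats)
        for view in VIEWS:
            model.encoder(view).load_state(payload["state"][view])
        return model
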