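"""The multimodal affinity network and its ablation variants.

Three feature extractors feed a self-attention fusion layer and a fully
connected regression head:

* a 1D-convolutional tower over the 196 ligand descriptors,
* a 1D-convolutional tower over the 147 pocket CTD descriptors,
* a gated graph sequence network over the spatial complex graph with
  PotentialNet staging — K1 propagation steps along covalent edges only,
  K2 steps along covalent + non-covalent edges, then a gated ligand-only
  gather readout.

Each extractor emits one token; scaled dot-product self-attention over
the tokens balances the three representations before the head predicts
the affinity in pK units.  Ablation variants drop one extractor:
``DeepLI`` (no pocket tower), ``DeepIP`` (no ligand tower), ``DeepLP``
(no interaction graph); attention then runs over the remaining tokens.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from . import nn
from .autodiff import Tensor, concat, softmax, spmm
from .complex_graph import (COVALENT_EDGE_TYPES, EDGE_TYPES, FEATURE_DIM,
                            GRAPH_RECIPE_ID, GraphConfig, SpatialGraph,
                            build_complex_graph)
from .descriptors import (LIGAND_REGISTRY_VERSION, POCKET_REGISTRY_VERSION,
                          ligand_descriptors, pocket_ctd)
from .errors import ConfigError, ShapeError
from .structure_io import ComplexSample

LIG_DIM, POC_DIM = 196, 147

VARIANTS = ("DeepLIP", "DeepLI", "DeepIP", "DeepLP")

#: tokens (modalities) present per variant, in fixed order
VARIANT_TOKENS: Dict[str, Tuple[str, ...]] = {
    "DeepLIP": ("ligand", "interaction", "pocket"),
    "DeepLI": ("ligand", "interaction"),
    "DeepIP": ("interaction", "pocket"),
    "DeepLP": ("ligand", "pocket"),
}


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults are sized for single-CPU training; every field is tunable.
    """
    variant: str = "DeepLIP"
    tower_channels: Tuple[int, int, int] = (16, 32, 64)
    tower_kernels: Tuple[int, int, int] = (3, 3, 3)
    graph_hidden: int = 32
    k1: int = 2                      # covalent-only propagation steps
    k2: int = 2                      # covalent + non-covalent steps
    gather_dim: int = 64
    token_dim: int = 64
    n_heads: int = 1
    head_hidden: Tuple[int, ...] = (128, 32)
    dropout: float = 0.1
    readout: str = "sum"             # ligand-node readout: "sum" or "mean"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        dims = (*self.tower_channels, self.graph_hidden, self.gather_dim,
                self.token_dim, *self.head_hidden)
        if any(d <= 0 for d in dims):
            raise ConfigError("all layer dimensions must be positive")
        if self.k1 < 1 or self.k2 < 1:
            raise ConfigError("k1 and k2 must be >= 1")
        if self.token_dim % self.n_heads != 0:
            raise ConfigError("token_dim must be divisible by n_heads")
        if self.readout not in ("sum", "mean"):
            raise ConfigError(f"unknown readout {self.readout!r}")

    @property
    def tokens(self) -> Tuple[str, ...]:
        return VARIANT_TOKENS[self.variant]


# ---------------------------------------------------------------------------
# Submodules
# ---------------------------------------------------------------------------

class DescriptorTower(nn.Module):
    """Three (conv1d -> batchnorm -> PReLU) blocks over a descriptor
    vector treated as a length-L single-channel signal, mean-pooled over
    positions and projected to the token dimension."""

    def __init__(self, in_len: int, cfg: ModelConfig,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_len = in_len
        chans = (1,) + tuple(cfg.tower_channels)
        blocks = []
        for k in range(3):
            block = nn.Module()
            block.conv = nn.Conv1d(chans[k], chans[k + 1],
                                   cfg.tower_kernels[k], rng, dtype)
            block.bn = nn.BatchNorm1d(chans[k + 1], dtype=dtype)
            block.act = nn.PReLU(dtype)
            blocks.append(block)
        self.blocks = nn.ModuleList(blocks)
        self.proj = nn.Linear(chans[-1], cfg.token_dim, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_len:
            raise ShapeError(f"tower expects length {self.in_len}, "
                             f"got {x.shape[-1]}")
        h = x.reshape(x.shape[0], 1, self.in_len)
        for block in self.blocks:
            h = block.act(block.bn(block.conv(h)))
        return self.proj(h.mean(axis=2))

    __call__ = forward


class _TypedMessages(nn.Module):
    """m_i = sum over edge types t, sum over j->i via t of W_t h_j."""

    def __init__(self, types: Sequence[str], dim: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.types = tuple(types)
        for k, _ in enumerate(self.types):
            setattr(self, f"W{k}", Tensor(
                nn._glorot(rng, (dim, dim), dtype), requires_grad=True))

    def forward(self, h: Tensor, adj: Dict[str, sp.spmatrix]) -> Tensor:
        unknown = set(adj) - set(EDGE_TYPES)
        if unknown:
            raise ConfigError(f"unknown edge types {sorted(unknown)}")
        m = None
        for k, t in enumerate(self.types):
            if t not in adj:
                continue
            part = spmm(adj[t], h) @ getattr(self, f"W{k}")
            m = part if m is None else m + part
        if m is None:  # no active edges at all
            m = h * Tensor(np.zeros((), dtype=h.data.dtype))
        return m

    __call__ = forward


class InteractionGGNN(nn.Module):
    """Gated graph sequence network with PotentialNet staging."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        d = cfg.graph_hidden
        self.k1, self.k2 = cfg.k1, cfg.k2
        self.embed = nn.Linear(FEATURE_DIM, d, rng, dtype)
        self.msg_cov = _TypedMessages(COVALENT_EDGE_TYPES, d, rng, dtype)
        self.gru_cov = nn.GRUUpdate(d, rng, dtype)
        self.msg_all = _TypedMessages(EDGE_TYPES, d, rng, dtype)
        self.gru_all = nn.GRUUpdate(d, rng, dtype)
        self.gate_lin = nn.Linear(2 * d, cfg.gather_dim, rng, dtype)
        self.emb_lin = nn.Linear(d, cfg.gather_dim, rng, dtype)
        self.out_lin = nn.Linear(cfg.gather_dim, cfg.token_dim, rng, dtype)

    def forward(self, node_feats: Tensor, adj: Dict[str, sp.spmatrix],
                readout: sp.spmatrix) -> Tensor:
        h0 = self.embed(node_feats)
        h = h0
        cov = {t: a for t, a in adj.items() if t in COVALENT_EDGE_TYPES}
        for _ in range(self.k1):
            h = self.gru_cov(h, self.msg_cov(h, cov))
        for _ in range(self.k2):
            h = self.gru_all(h, self.msg_all(h, adj))
        gate = self.gate_lin(concat([h, h0], axis=1)).sigmoid()
        per_node = gate * self.emb_lin(h)
        pooled = spmm(readout, per_node)  # ligand-masked readout
        return self.out_lin(pooled)

    __call__ = forward


class AttentionFusion(nn.Module):
    """Scaled dot-product self-attention over the modality tokens."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        d = cfg.token_dim
        self.n_heads = cfg.n_heads
        self.wq = nn.Linear(d, d, rng, dtype)
        self.wk = nn.Linear(d, d, rng, dtype)
        self.wv = nn.Linear(d, d, rng, dtype)

    def forward(self, tokens: Tensor, return_weights: bool = False):
        B, T, d = tokens.shape
        h, dh = self.n_heads, d // self.n_heads

        def split(x):  # (B,T,d) -> (B,h,T,dh)
            return x.reshape(B, T, h, dh).transpose(0, 2, 1, 3)

        q, k, v = (split(f(tokens)) for f in (self.wq, self.wk, self.wv))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        weights = softmax(scores, axis=-1)        # rows sum to 1
        attended = (weights @ v).transpose(0, 2, 1, 3).reshape(B, T * d)
        if return_weights:
            return attended, weights
        return attended

    __call__ = forward


class AffinityNetwork(nn.Module):
    """Full network for one variant (see module docstring)."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD1)))
        tokens = config.tokens
        if "ligand" in tokens:
            self.lig_tower = DescriptorTower(LIG_DIM, config, rng, dtype)
        if "pocket" in tokens:
            self.poc_tower = DescriptorTower(POC_DIM, config, rng, dtype)
        if "interaction" in tokens:
            self.ggnn = InteractionGGNN(config, rng, dtype)
        self.fusion = AttentionFusion(config, rng, dtype)
        head_dims = ((len(tokens) * config.token_dim,)
                     + tuple(config.head_hidden) + (1,))
        layers = []
        for k in range(len(head_dims) - 1):
            layer = nn.Module()
            layer.lin = nn.Linear(head_dims[k], head_dims[k + 1], rng, dtype)
            if k < len(head_dims) - 2:
                layer.act = nn.PReLU(dtype)
                layer.drop = nn.Dropout(config.dropout)
            layers.append(layer)
        self.head = nn.ModuleList(layers)

    def set_rng(self, rng: Optional[np.random.Generator]):
        for mod in self.modules():
            if isinstance(mod, nn.Dropout):
                mod.rng = rng

    def forward(self, batch: Dict, return_features: bool = False):
        tokens = []
        for name in self.config.tokens:
            if name == "ligand":
                tokens.append(self.lig_tower(batch["lig"]))
            elif name == "pocket":
                tokens.append(self.poc_tower(batch["poc"]))
            else:
                tokens.append(self.ggnn(batch["nodes"], batch["adj"],
                                        batch["readout"]))
        B = tokens[0].shape[0]
        d = self.config.token_dim
        stacked = concat([t.reshape(B, 1, d) for t in tokens], axis=1)
        fused, weights = self.fusion(stacked, return_weights=True)
        h = fused
        for k, layer in enumerate(self.head):
            h = layer.lin(h)
            if hasattr(layer, "act"):
                h = layer.drop(layer.act(h))
        pred = h.reshape(B)
        if return_features:
            return pred, {"fused": fused, "attention": weights,
                          "tokens": stacked}
        return pred

    __call__ = forward


# ---------------------------------------------------------------------------
# Featurization & batching
# ---------------------------------------------------------------------------

@dataclass
class GraphArrays:
    node_features: np.ndarray                 # (n, FEATURE_DIM)
    typed: Dict[str, np.ndarray]              # type -> (2, m) (dst, src)
    ligand_mask: np.ndarray                   # bool (n,)

    @classmethod
    def from_graph(cls, g: SpatialGraph) -> "GraphArrays":
        return cls(g.node_features, g.typed_index(), g.ligand_mask)


@dataclass
class FeaturizedSet:
    """Descriptor matrices + per-sample graph arrays for a sample list."""
    ids: List[str]
    lig: np.ndarray                           # (n, 196)
    poc: np.ndarray                           # (n, 147)
    graphs: Optional[List[GraphArrays]]
    labels: Optional[np.ndarray]

    def __len__(self):
        return len(self.ids)


def featurize_samples(samples: Sequence[ComplexSample],
                      graph_config: Optional[GraphConfig] = None,
                      need_graph: bool = True) -> FeaturizedSet:
    graph_config = graph_config or GraphConfig()
    lig = np.stack([ligand_descriptors(s.ligand).values for s in samples])
    poc = np.stack([pocket_ctd(s.pocket.sequence).values for s in samples])
    graphs = None
    if need_graph:
        graphs = [GraphArrays.from_graph(build_complex_graph(s, graph_config))
                  for s in samples]
    labels = None
    if all(s.label is not None for s in samples):
        labels = np.array([s.label for s in samples], dtype=float)
    return FeaturizedSet([s.id for s in samples], lig, poc, graphs, labels)


@dataclass
class Normalization:
    """Z-score statistics learned on the training set."""
    lig_mean: np.ndarray
    lig_sd: np.ndarray
    poc_mean: np.ndarray
    poc_sd: np.ndarray

    @classmethod
    def fit(cls, feats: FeaturizedSet) -> "Normalization":
        def stats(m):
            mean, sd = m.mean(axis=0), m.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)  # constant descriptors
            return mean, sd

        lm, ls = stats(feats.lig)
        pm, ps = stats(feats.poc)
        return cls(lm, ls, pm, ps)


def assemble_batch(feats: FeaturizedSet, idx: Sequence[int],
                   norm: Normalization, config: ModelConfig,
                   dtype=np.float32) -> Dict:
    """Normalize descriptors and block-stack graphs into one batch dict."""
    idx = list(idx)
    batch: Dict = {}
    batch["lig"] = Tensor(((feats.lig[idx] - norm.lig_mean)
                           / norm.lig_sd).astype(dtype))
    batch["poc"] = Tensor(((feats.poc[idx] - norm.poc_mean)
                           / norm.poc_sd).astype(dtype))
    if "interaction" in config.tokens:
        if feats.graphs is None:
            raise ShapeError("variant needs graphs but none were featurized")
        gs = [feats.graphs[i] for i in idx]
        offsets = np.cumsum([0] + [g.node_features.shape[0] for g in gs])
        n_total = int(offsets[-1])
        nodes = np.concatenate([g.node_features for g in gs]).astype(dtype)
        adj: Dict[str, sp.spmatrix] = {}
        for t in EDGE_TYPES:
            rows, cols = [], []
            for g, off in zip(gs, offsets):
                pairs = g.typed[t]
                if pairs.shape[1]:
                    rows.append(pairs[0] + off)
                    cols.append(pairs[1] + off)
            if rows:
                r = np.concatenate(rows)
                c = np.concatenate(cols)
            else:
                r = c = np.zeros(0, dtype=np.intp)
            adj[t] = sp.csr_matrix(
                (np.ones(len(r), dtype=dtype), (r, c)),
                shape=(n_total, n_total))
        rrows, rcols, rvals = [], [], []
        for b, (g, off) in enumerate(zip(gs, offsets)):
            lig_nodes = np.nonzero(g.ligand_mask)[0] + off
            w = 1.0 / lig_nodes.size if config.readout == "mean" else 1.0
            rrows.extend([b] * lig_nodes.size)
            rcols.extend(lig_nodes.tolist())
            rvals.extend([w] * lig_nodes.size)
        batch["nodes"] = Tensor(nodes)
        batch["adj"] = adj
        batch["readout"] = sp.csr_matrix(
            (np.array(rvals, dtype=dtype), (rrows, rcols)),
            shape=(len(gs), n_total))
    return batch


# ---------------------------------------------------------------------------
# Trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained network plus everything needed to reproduce its inputs."""
    config: ModelConfig
    network: AffinityNetwork
    normalization: Normalization
    graph_config: GraphConfig
    train_seed: int
    lig_registry_version: str = LIGAND_REGISTRY_VERSION
    poc_registry_version: str = POCKET_REGISTRY_VERSION
    graph_recipe_id: str = GRAPH_RECIPE_ID

    def predict(self, samples: Sequence[ComplexSample],
                batch_size: int = 128,
                return_features: bool = False):
        """Predicted pK for each sample (inference mode, deterministic)."""
        need_graph = "interaction" in self.config.tokens
        feats = featurize_samples(samples, self.graph_config, need_graph)
        return self.predict_featurized(feats, batch_size, return_features)

    def predict_featurized(self, feats: FeaturizedSet, batch_size: int = 128,
                           return_features: bool = False):
        self.network.eval()
        preds, fused = [], []
        for start in range(0, len(feats), batch_size):
            idx = range(start, min(start + batch_size, len(feats)))
            batch = assemble_batch(feats, idx, self.normalization,
                                   self.config, self.network.dtype)
            if return_features:
                p, extra = self.network(batch, return_features=True)
                fused.append(extra["fused"].data.copy())
            else:
                p = self.network(batch)
            preds.append(np.asarray(p.data, dtype=float).ravel())
        out = np.concatenate(preds)
        if return_features:
            return out, np.concatenate(fused)
        return out

    # -- serialization -------------------------------------------------
    def save(self, path) -> None:
        """Single-archive serialization (numpy .npz)."""
        meta = {
            "config": asdict(self.config),
            "graph_config": asdict(self.graph_config),
            "train_seed": self.train_seed,
            "lig_registry_version": self.lig_registry_version,
            "poc_registry_version": self.poc_registry_version,
            "graph_recipe_id": self.graph_recipe_id,
        }
        arrays = {f"param:{k}": v for k, v in
                  self.network.state_dict().items()}
        arrays.update({
            "norm:lig_mean": self.normalization.lig_mean,
            "norm:lig_sd": self.normalization.lig_sd,
            "norm:poc_mean": self.normalization.poc_mean,
            "norm:poc_sd": self.normalization.poc_sd,
        })
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            config = ModelConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["config"].items()})
            network = AffinityNetwork(config, seed=meta["train_seed"])
            state = {k[len("param:"):]: data[k] for k in data.files
                     if k.startswith("param:")}
            network.load_state_dict(state)
            norm = Normalization(
                data["norm:lig_mean"], data["norm:lig_sd"],
                data["norm:poc_mean"], data["norm:poc_sd"])
            gc = GraphConfig(**meta["graph_config"])
        return cls(config, network, norm, gc, meta["train_seed"],
                   meta["lig_registry_version"],
                   meta["poc_registry_version"], meta["graph_recipe_id"])


def deeplip_forward(sample: ComplexSample, model: TrainedModel) -> float:
    """Predicted pK of one complex under the full model."""
    if model.config.variant != "DeepLIP":
        raise ConfigError(f"model variant is {model.config.variant!r}, "
                          "expected DeepLIP")
    return float(model.predict([sample])[0])


def ablation_forward(variant: str, sample: ComplexSample,
                     model: TrainedModel) -> float:
    """Predicted pK of one complex under an ablation variant."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}")
    if model.config.variant != variant:
        raise ConfigError(f"model variant is {model.config.variant!r}, "
                          f"expected {variant!r}")
    return float(model.predict([sample])[0])
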