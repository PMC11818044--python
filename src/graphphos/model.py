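"""The two-branch phosphosite classifier.

Branch one is a two-layer GraphSAGE over the residue contact graph: each
layer averages a node's neighbor features, concatenates the node's own
representation, applies a trainable affine map and ReLU, and normalizes
each node row (L2 by default).  Two layers give every S/T/Y site a
receptive field of its second-order structural neighborhood.

Branch two projects per-residue protein-language-model embeddings through
two 1-D convolution blocks down to the same width (57).

The two branch outputs are concatenated at the S/T/Y rows only and passed
through a two-layer feed-forward head with a sigmoid output; a site is
called phosphorylated when its probability is >= 0.5 (ties positive).
Either branch can be ablated, which zero-removes its columns from the
head input while leaving everything else untouched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .feature_encoding import FEATURE_WIDTH, FeatureMatrix
from .plm_projection import (DEFAULT_HIDDEN, DEFAULT_KERNELS, EmbeddingMatrix,
                             cnn_branch, init_conv_params)
from .structure_graph import ContactGraph

CHECKPOINT_FORMAT_VERSION = 1
STY = frozenset("STY")
UNKNOWN_LABEL = -1
DECISION_THRESHOLD = 0.5


@dataclass
class ModelConfig:
    """Architecture and ablation switches.

    ``use_sage=False`` reproduces the "w/o SAGE" ablation (structure blind);
    ``use_plm_cnn=False`` the "w/o ProtBERT-CNN" ablation (embedding blind).
    """

    use_sage: bool = True
    use_plm_cnn: bool = True
    sage_layers: int = 2
    sage_hidden: int = 57
    cnn_hidden: int = DEFAULT_HIDDEN
    cnn_out: int = 57
    cnn_kernels: tuple = DEFAULT_KERNELS
    head_hidden: int = 64
    aggregator: str = "mean"
    norm: str = "l2_node"          # GraphSAGE layer normalization
    cnn_norm: str = "batch"        # conv block normalization
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.use_sage or self.use_plm_cnn):
            raise ValueError("at least one branch must be enabled")
        if self.aggregator != "mean":
            raise ValueError("only the mean aggregator is supported")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.cnn_kernels = tuple(int(k) for k in self.cnn_kernels)

    @property
    def head_in_dim(self) -> int:
        dim = 0
        if self.use_sage:
            dim += self.sage_hidden
        if self.use_plm_cnn:
            dim += self.cnn_out
        return dim


@dataclass
class SiteSet:
    """S/T/Y residue indices with binary phosphorylation labels.

    ``labels`` entries are 0, 1, or UNKNOWN_LABEL (-1) for unannotated sites.
    """

    protein_id: str
    site_indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.site_indices = np.asarray(self.site_indices, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.site_indices.shape != self.labels.shape:
            raise ValueError("site_indices and labels must be parallel")
        if len(self.site_indices) and np.any(np.diff(self.site_indices) <= 0):
            raise ValueError("site_indices must be strictly increasing")
        bad = set(np.unique(self.labels)) - {0, 1, UNKNOWN_LABEL}
        if bad:
            raise ValueError(f"labels must be 0/1/{UNKNOWN_LABEL}, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.site_indices)

    def validate_against(self, sequence: str) -> None:
        for idx in self.site_indices:
            if sequence[idx].upper() not in STY:
                raise ValueError(
                    f"{self.protein_id}: site {idx} is {sequence[idx]!r}, not S/T/Y")


@dataclass
class PredictionResult:
    protein_id: str
    site_indices: np.ndarray
    probabilities: np.ndarray

    @property
    def calls(self) -> np.ndarray:
        return (self.probabilities >= DECISION_THRESHOLD).astype(int)


def sites_from_sequence(protein_id: str, sequence: str,
                        labels: Optional[dict[int, int]] = None) -> SiteSet:
    """All S/T/Y positions of a sequence, labeled from a {index: 0/1} mapping."""
    idx = np.array([i for i, aa in enumerate(sequence.upper()) if aa in STY],
                   dtype=np.intp)
    lab = np.full(len(idx), UNKNOWN_LABEL, dtype=np.intp)
    if labels:
        for row, i in enumerate(idx):
            if int(i) in labels:
                lab[row] = labels[int(i)]
    return SiteSet(protein_id=protein_id, site_indices=idx, labels=lab)


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True)


def init_params(config: ModelConfig, feature_dim: int = FEATURE_WIDTH,
                emb_dim: int = 64) -> dict[str, Tensor]:
    """Seeded Glorot initialization for every enabled component."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}
    if config.use_sage:
        widths = [feature_dim] + [config.sage_hidden] * config.sage_layers
        for layer in range(config.sage_layers):
            f_in, f_out = widths[layer], widths[layer + 1]
            params[f"sage.w{layer}"] = _glorot(rng, 2 * f_in, f_out)
            params[f"sage.b{layer}"] = Tensor(np.zeros(f_out), requires_grad=True)
            if config.norm == "batch":
                params[f"sage.g{layer}"] = Tensor(np.ones(f_out), requires_grad=True)
                params[f"sage.beta{layer}"] = Tensor(np.zeros(f_out), requires_grad=True)
    if config.use_plm_cnn:
        params.update(init_conv_params(rng, emb_dim, hidden=config.cnn_hidden,
                                       out_dim=config.cnn_out,
                                       kernels=config.cnn_kernels,
                                       norm=config.cnn_norm))
    params["head.w1"] = _glorot(rng, config.head_in_dim, config.head_hidden)
    params["head.b1"] = Tensor(np.zeros(config.head_hidden), requires_grad=True)
    params["head.w2"] = _glorot(rng, config.head_hidden, 1)
    params["head.b2"] = Tensor(np.zeros(1), requires_grad=True)
    return params


# ---------------------------------------------------------------------------
# GraphSAGE branch
# ---------------------------------------------------------------------------

def _sage_layer_tensor(h: Tensor, agg_matrix: Tensor, weight: Tensor,
                       bias: Optional[Tensor], norm: str,
                       gamma: Optional[Tensor] = None,
                       beta: Optional[Tensor] = None) -> Tensor:
    neigh = ad.matmul(agg_matrix, h)                  # mean over neighbors
    z = ad.matmul(ad.concat([h, neigh], axis=1), weight)
    if bias is not None:
        z = ad.add(z, bias)
    z = ad.relu(z)
    if norm == "l2_node":
        z = ad.row_l2_normalize(z)
    elif norm == "batch":
        z = ad.batch_norm(z, gamma, beta)
    elif norm != "none":
        raise ValueError(f"unknown norm {norm!r}")
    return z


def sage_layer(node_features: np.ndarray, graph: ContactGraph,
               weight: np.ndarray, bias: Optional[np.ndarray] = None,
               norm: str = "l2_node") -> np.ndarray:
    """Single GraphSAGE update (numpy-facing).

    For each node v: a = mean of neighbor rows (zero if isolated),
    z = ReLU(concat(h_v, a) @ W + b), then per-row L2 normalization
    (``norm="l2_node"``) or none.
    """
    features = np.asarray(node_features, dtype=np.float64)
    if features.shape[0] != graph.n_nodes:
        raise ValueError(
            f"feature rows ({features.shape[0]}) != graph nodes ({graph.n_nodes})")
    if weight.shape[0] != 2 * features.shape[1]:
        raise ValueError(
            f"weight must have {2 * features.shape[1]} rows, got {weight.shape[0]}")
    out = _sage_layer_tensor(
        Tensor(features), Tensor(graph.mean_aggregation_matrix()), Tensor(weight),
        None if bias is None else Tensor(bias), norm)
    return out.data


def _sage_branch_tensor(features: Tensor, agg_matrix: Tensor,
                        params: dict[str, Tensor], config: ModelConfig) -> Tensor:
    h = features
    for layer in range(config.sage_layers):
        h = _sage_layer_tensor(
            h, agg_matrix, params[f"sage.w{layer}"], params[f"sage.b{layer}"],
            config.norm, params.get(f"sage.g{layer}"), params.get(f"sage.beta{layer}"))
    return h


def sage_branch(features: np.ndarray, graph: ContactGraph,
                params: dict[str, Tensor], config: ModelConfig) -> np.ndarray:
    """Stacked GraphSAGE layers (second-order neighborhood aggregation)."""
    if not config.use_sage:
        raise ValueError("sage branch called with use_sage=False")
    out = _sage_branch_tensor(Tensor(np.asarray(features, dtype=np.float64)),
                              Tensor(graph.mean_aggregation_matrix()), params, config)
    return out.data


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

def forward_logits(features, graph: ContactGraph, embeddings, site_indices,
                   params: dict[str, Tensor], config: ModelConfig,
                   train_rng: Optional[np.random.Generator] = None) -> Tensor:
    """Site logits as an autodiff Tensor (training entry point)."""
    site_indices = np.asarray(site_indices, dtype=np.intp)
    if len(site_indices) == 0:
        raise ValueError("no S/T/Y residues to score")
    feats = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    emb = embeddings.values if isinstance(embeddings, EmbeddingMatrix) else embeddings

    branch_rows = []
    if config.use_sage:
        if feats.shape[0] != graph.n_nodes:
            raise ValueError(
                f"feature rows ({feats.shape[0]}) != graph nodes ({graph.n_nodes})")
        sage_out = _sage_branch_tensor(Tensor(feats),
                                       Tensor(graph.mean_aggregation_matrix()),
                                       params, config)
        branch_rows.append(ad.take_rows(sage_out, site_indices))
    if config.use_plm_cnn:
        emb = np.asarray(emb, dtype=np.float64)
        if feats is not None and emb.shape[0] != feats.shape[0]:
            raise ValueError(
                f"embedding rows ({emb.shape[0]}) != feature rows ({feats.shape[0]})")
        cnn_out = cnn_branch(Tensor(emb), params, kernels=config.cnn_kernels,
                             norm=config.cnn_norm)
        branch_rows.append(ad.take_rows(cnn_out, site_indices))

    m = branch_rows[0] if len(branch_rows) == 1 else ad.concat(branch_rows, axis=1)
    if config.dropout > 0.0 and train_rng is not None:
        m = ad.dropout(m, config.dropout, train_rng)
    h = ad.relu(ad.add(ad.matmul(m, params["head.w1"]), params["head.b1"]))
    return ad.add(ad.matmul(h, params["head.w2"]), params["head.b2"])


def forward(features, graph: ContactGraph, embeddings, site_set: SiteSet,
            params: dict[str, Tensor], config: ModelConfig) -> PredictionResult:
    """Predict phosphorylation probabilities at the S/T/Y sites of one protein."""
    logits = forward_logits(features, graph, embeddings, site_set.site_indices,
                            params, config)
    probs = 1.0 / (1.0 + np.exp(-logits.data[:, 0]))
    return PredictionResult(protein_id=site_set.protein_id,
                            site_indices=site_set.site_indices.copy(),
                            probabilities=probs)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict[str, Tensor], config: ModelConfig,
                    extra: Optional[dict] = None) -> None:
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(config), "extra": extra or {}}
    arrays = {f"param/{k}": p.data for k, p in params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        cfg_dict = meta["config"]
        cfg_dict["cnn_kernels"] = tuple(cfg_dict["cnn_kernels"])
        config = ModelConfig(**cfg_dict)
        params = {k[len("param/"):]: Tensor(data[k], requires_grad=True)
                  for k in data.files if k.startswith("param/")}
    return params, config, meta.get("extra", {})
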