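"""Protein-language-model embeddings and their 1-D CNN projection to 57 dims.

Embeddings arrive through a pluggable provider.  The ``protbert`` provider
wraps the pretrained ProtBERT encoder (1024-dim per residue) when the
`transformers` stack and its weights are available; the ``hashstub``
provider is a fully offline, deterministic stand-in that maps each residue
and a +/-k window of its neighbors through a seeded hash to a dense
vector.  The stub keeps the whole pipeline runnable and testable with no
downloads while preserving the properties the model relies on: one row per
residue, determinism, and strictly local sequence context.

The projection itself is two 1-D convolutions along the sequence axis
(p -> hidden -> 57), each followed by a normalization step and ReLU, with
symmetric zero padding so sequence length is preserved.  Convolution is
expressed as a sum of row-shifted affine maps, which makes it a pure
composition of autodiff primitives and hence trainable jointly with the
rest of the network.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol

import h5py
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DEFAULT_KERNELS = (9, 7)
DEFAULT_HIDDEN = 128
PROJECTION_WIDTH = 57


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding rows for one protein."""

    protein_id: str
    values: np.ndarray
    provider_tag: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError(f"embeddings must be (L, p), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embeddings must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


class EmbeddingProvider(Protocol):
    name: str
    dim: int

    def __call__(self, sequence: str) -> np.ndarray: ...


def _hash_vector(seed: int, key: str, dim: int) -> np.ndarray:
    digest = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return rng.standard_normal(dim)


@dataclass
class HashStubProvider:
    """Deterministic offline embedding stub.

    Row i is the superposition of hashed (residue, offset) vectors over the
    window [i-k, i+k], scaled by 1/sqrt(window size).  Rows therefore depend
    only on their local window, and identical (seed, sequence) pairs give
    bitwise-identical matrices.
    """

    dim: int = 64
    window: int = 0
    seed: int = 0
    name: str = "hashstub"

    _cache: dict = field(default_factory=dict, repr=False)

    def _vector(self, aa: str, offset: int) -> np.ndarray:
        key = (aa, offset)
        if key not in self._cache:
            self._cache[key] = _hash_vector(self.seed, f"{aa}@{offset}", self.dim)
        return self._cache[key]

    def __call__(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("sequence must be non-empty")
        seq = sequence.upper()
        L = len(seq)
        out = np.zeros((L, self.dim))
        for i in range(L):
            offs = [o for o in range(-self.window, self.window + 1) if 0 <= i + o < L]
            for o in offs:
                out[i] += self._vector(seq[i + o], o)
            out[i] /= np.sqrt(len(offs))
        return out


@dataclass
class ProtBertProvider:
    """Wraps the pretrained ProtBERT encoder (1024-dim per residue).

    Special tokens are stripped so that row i corresponds to residue i.
    Requires the `transformers` package and downloaded weights.
    """

    model_name: str = "Rostlab/prot_bert"
    name: str = "protbert"
    dim: int = 1024

    def __post_init__(self):
        try:
            import transformers  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the protbert provider needs the `transformers` package and "
                "pretrained weights; for offline use choose the `hashstub` provider"
            ) from exc

    def __call__(self, sequence: str) -> np.ndarray:  # pragma: no cover - needs weights
        from transformers import AutoModel, AutoTokenizer

        tokenizer = AutoTokenizer.from_pretrained(self.model_name, do_lower_case=False)
        model = AutoModel.from_pretrained(self.model_name)
        spaced = " ".join(sequence.upper())
        inputs = tokenizer(spaced, return_tensors="pt")
        hidden = model(**inputs).last_hidden_state[0].detach().numpy()
        return hidden[1:len(sequence) + 1].astype(np.float64)  # strip [CLS]/[SEP]


PROVIDERS = {"hashstub": HashStubProvider, "protbert": ProtBertProvider}


def get_provider(name: str, **kwargs) -> EmbeddingProvider:
    if name not in PROVIDERS:
        raise ValueError(f"unknown provider {name!r}; choose from {sorted(PROVIDERS)}")
    return PROVIDERS[name](**kwargs)


def embed_sequence(provider: EmbeddingProvider, sequence: str,
                   protein_id: str = "") -> EmbeddingMatrix:
    values = provider(sequence)
    if values.shape[0] != len(sequence):
        raise ValueError(
            f"provider returned {values.shape[0]} rows for a length-{len(sequence)} sequence")
    return EmbeddingMatrix(protein_id=protein_id, values=values,
                           provider_tag=provider.name)


# ---------------------------------------------------------------------------
# 1-D convolution projection
# ---------------------------------------------------------------------------

def conv1d(x: Tensor, weight: Tensor, bias: Tensor, kernel_size: int) -> Tensor:
    """Length-preserving 1-D convolution along the row (sequence) axis.

    ``weight`` has shape (kernel_size * in_channels, out_channels): the
    output is sum_o shift(x, o) @ W_o + b with symmetric zero padding.
    """
    in_ch = x.shape[1]
    if weight.shape != (kernel_size * in_ch, weight.shape[1]):
        raise ValueError(
            f"conv weight must be ({kernel_size * in_ch}, out), got {weight.shape}")
    half = kernel_size // 2
    shifted = [ad.shift_rows(x, o) for o in range(half, half - kernel_size, -1)]
    stacked = ad.concat(shifted, axis=1)
    return ad.add(ad.matmul(stacked, weight), bias)


def init_conv_params(rng: np.random.Generator, in_dim: int,
                     hidden: int = DEFAULT_HIDDEN,
                     out_dim: int = PROJECTION_WIDTH,
                     kernels: tuple[int, int] = DEFAULT_KERNELS,
                     norm: str = "batch") -> dict[str, Tensor]:
    """Glorot-initialized parameters for the two-conv projection."""
    k1, k2 = kernels

    def glorot(fan_in, fan_out):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)),
                      requires_grad=True)

    params = {
        "cnn.w1": glorot(k1 * in_dim, hidden),
        "cnn.b1": Tensor(np.zeros(hidden), requires_grad=True),
        "cnn.w2": glorot(k2 * hidden, out_dim),
        "cnn.b2": Tensor(np.zeros(out_dim), requires_grad=True),
    }
    if norm in ("batch", "layer"):
        params["cnn.g1"] = Tensor(np.ones(hidden), requires_grad=True)
        params["cnn.beta1"] = Tensor(np.zeros(hidden), requires_grad=True)
        params["cnn.g2"] = Tensor(np.ones(out_dim), requires_grad=True)
        params["cnn.beta2"] = Tensor(np.zeros(out_dim), requires_grad=True)
    return params


def cnn_branch(emb: Tensor, params: dict[str, Tensor],
               kernels: tuple[int, int] = DEFAULT_KERNELS,
               norm: str = "batch") -> Tensor:
    """Two conv blocks (conv -> normalization -> ReLU), p -> hidden -> 57."""
    k1, k2 = kernels
    h = conv1d(emb, params["cnn.w1"], params["cnn.b1"], k1)
    h = _normalize(h, params.get("cnn.g1"), params.get("cnn.beta1"), norm)
    h = ad.relu(h)
    h = conv1d(h, params["cnn.w2"], params["cnn.b2"], k2)
    h = _normalize(h, params.get("cnn.g2"), params.get("cnn.beta2"), norm)
    return ad.relu(h)


def _normalize(x: Tensor, gamma, beta, norm: str) -> Tensor:
    if norm == "none" or gamma is None:
        return x
    if norm == "batch":
        return ad.batch_norm(x, gamma, beta)
    if norm == "layer":
        return ad.layer_norm(x, gamma, beta)
    raise ValueError(f"unknown norm {norm!r}")


def project_embeddings(emb, params: dict[str, Tensor],
                       kernels: tuple[int, int] = DEFAULT_KERNELS,
                       norm: str = "batch") -> np.ndarray:
    """Numpy-facing projection: L x p embeddings -> L x 57 features."""
    values = emb.values if isinstance(emb, EmbeddingMatrix) else np.asarray(emb)
    out = cnn_branch(Tensor(values), params, kernels=kernels, norm=norm)
    return out.data


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def save_embeddings(path, matrices: Iterable[EmbeddingMatrix]) -> None:
    """HDF5 container: one dataset per protein id, shape (L, p)."""
    with h5py.File(path, "w") as fh:
        for m in matrices:
            ds = fh.create_dataset(m.protein_id, data=m.values)
            ds.attrs["provider"] = m.provider_tag


def load_embeddings(path) -> dict[str, EmbeddingMatrix]:
    out = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            out[pid] = EmbeddingMatrix(
                protein_id=pid, values=fh[pid][()],
                provider_tag=fh[pid].attrs.get("provider", "unknown"))
    return out
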