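"""Deep-feature embedding contract for the 224×224 tumor crop.

The DLR pipeline consumes a fixed-length embedding (2048 values, named
``DL_1`` .. ``DL_2048``) of the normalized tumor crop — the dimensionality
of a ResNet-50 global-average-pooled feature vector.  The default embedder
here is a deterministic stub: the crop is average-pooled to 16×16, flattened
and passed through a seeded random linear projection followed by tanh.  It
needs no weights or downloads, preserves coarse texture information, and
honours the same input/output contract a pretrained backbone adapter would.

A real-backbone adapter can be registered via :func:`register_embedder`;
none ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Embedder", "make_stub_embedder", "embed", "feature_names", "register_embedder"]


@dataclass
class Embedder:
    """A named, fixed-dimension image-to-vector map."""

    name: str
    dim: int
    fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    input_size: int = 224
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")


_REGISTRY: dict[str, Callable[..., Embedder]] = {}


def register_embedder(name: str, factory: Callable[..., Embedder]) -> None:
    """Register an embedder factory (plug-in point for real backbones)."""
    _REGISTRY[name] = factory


def _block_pool(img: np.ndarray, out: int = 16) -> np.ndarray:
    h, w = img.shape
    bh, bw = h // out, w // out
    trimmed = img[: bh * out, : bw * out]
    return trimmed.reshape(out, bh, out, bw).mean(axis=(1, 3))


def make_stub_embedder(seed: int = 0, dim: int = 2048, input_size: int = 224) -> Embedder:
    """Deterministic stub: 16×16 average pool → seeded projection → tanh."""
    rng = np.random.default_rng(seed)
    pooled = 16 * 16
    w = rng.standard_normal((dim, pooled)) / np.sqrt(pooled)

    def fn(img: np.ndarray) -> np.ndarray:
        pooled_img = _block_pool(img, 16).ravel()
        return np.tanh(w @ pooled_img)

    return Embedder(name=f"stub-seed{seed}", dim=dim, fn=fn, input_size=input_size)


def make_embedder(name: str = "stub", **kwargs) -> Embedder:
    if name == "stub":
        return make_stub_embedder(**kwargs)
    if name in _REGISTRY:
        return _REGISTRY[name](**kwargs)
    raise ValueError(f"unknown embedder {name!r}")


def embed(image: np.ndarray, embedder: Embedder) -> np.ndarray:
    """Embed a single 2D crop; returns a finite vector of ``embedder.dim``."""
    img = np.asarray(image, dtype=np.float64)
    if img.shape != (embedder.input_size, embedder.input_size):
        raise ValueError(
            f"expected a {embedder.input_size}×{embedder.input_size} image, got {img.shape}"
        )
    vec = np.asarray(embedder.fn(img), dtype=np.float64)
    if vec.shape != (embedder.dim,):
        raise ValueError("embedder returned a vector of the wrong length")
    if not np.all(np.isfinite(vec)):
        raise ValueError("embedding contains non-finite values")
    return vec


def feature_names(dim: int = 2048) -> list[str]:
    """Canonical DL feature names ``DL_1`` .. ``DL_<dim>`` (1-based)."""
    return [f"DL_{i}" for i in range(1, dim + 1)]
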