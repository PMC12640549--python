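"""Histology-patch extraction and pluggable morphology embedding.

Per-spot square patches are cropped from the full-resolution histology image
and mapped to a spots x F feature matrix by an *embedder*: any callable that
deterministically maps an image stack to an (N, F) real matrix. Users can
plug in a pretrained vision backbone; the packaged
:class:`HistogramProjectionEmbedder` is a weight-free deterministic embedder
(256-bin grayscale intensity histogram followed by a fixed seeded random
projection to 1000 dimensions) that satisfies the same contract without any
downloaded weights. Features are then PCA-reduced (default top 100
dimensions) before entering the morphology weight W_m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .data import pca_reduce
from .errors import ContractError, ParameterError

__all__ = [
    "PatchStack",
    "MorphologyFeatures",
    "HistogramProjectionEmbedder",
    "extract_spot_patches",
    "embed_patches",
    "reduce_features",
    "read_features_tsv",
    "write_features_tsv",
]

DEFAULT_PATCH_SIDE = 64
DEFAULT_EMBED_DIM = 1000
DEFAULT_REDUCED_DIM = 100
_STUB_SEED = 991236803  # fixed: the stub projection is part of the contract


@dataclass
class PatchStack:
    """One square image patch per spot, in spot order."""

    patches: np.ndarray  # (N, side, side) or (N, side, side, C)
    source_coords: np.ndarray  # (N, 2)
    patch_side: int
    value_range: str  # "uint8" for [0, 255], "unit" for [0, 1]

    @property
    def n(self) -> int:
        return self.patches.shape[0]


@dataclass
class MorphologyFeatures:
    """Embedder output (N x F) with optional PCA-reduced representation."""

    values: np.ndarray
    embedder_id: str
    reduced: np.ndarray | None = None


def extract_spot_patches(image: np.ndarray, coords: np.ndarray,
                         patch_side: int = DEFAULT_PATCH_SIDE) -> PatchStack:
    """Square crops centered on each spot; out-of-bounds regions zero-padded.

    ``coords`` are (row, col) pixel positions; a spot at (r, c) with side s
    yields the crop rows r - s//2 .. r - s//2 + s - 1 (likewise columns).
    """
    if patch_side <= 0:
        raise ParameterError("patch_side must be positive")
    image = np.asarray(image)
    coords = np.asarray(coords, dtype=float)
    h, w = image.shape[:2]
    extra = image.shape[2:]
    n = coords.shape[0]
    patches = np.zeros((n, patch_side, patch_side) + extra, dtype=float)
    half = patch_side // 2
    for s in range(n):
        r0 = int(round(coords[s, 0])) - half
        c0 = int(round(coords[s, 1])) - half
        rs, re = max(r0, 0), min(r0 + patch_side, h)
        cs, ce = max(c0, 0), min(c0 + patch_side, w)
        if rs < re and cs < ce:
            patches[s, rs - r0:re - r0, cs - c0:ce - c0] = image[rs:re, cs:ce]
    vr = "unit" if np.issubdtype(image.dtype, np.floating) and image.max(initial=0) <= 1 \
        else "uint8"
    return PatchStack(patches, coords, patch_side, vr)


class HistogramProjectionEmbedder:
    """Deterministic weight-free patch embedder.

    Each patch is converted to grayscale, binned into a normalized 256-bin
    intensity histogram, and projected to ``out_dim`` features with a fixed
    seeded Gaussian random matrix. Coarse intensity differences between
    tissue regions survive the projection; the output is bit-identical
    across runs.
    """

    def __init__(self, out_dim: int = DEFAULT_EMBED_DIM):
        self.out_dim = int(out_dim)
        rng = np.random.default_rng(_STUB_SEED)
        self._projection = rng.standard_normal((256, self.out_dim)) / np.sqrt(256)
        self.embedder_id = f"histogram-projection-{self.out_dim}"

    def __call__(self, stack: PatchStack) -> np.ndarray:
        p = stack.patches
        if p.ndim == 4:  # average channels to grayscale
            p = p.mean(axis=-1)
        scale = 255.0 if stack.value_range == "unit" else 1.0
        flat = np.clip(p * scale, 0, 255).reshape(p.shape[0], -1)
        bins = np.minimum(flat.astype(int), 255)
        hist = np.zeros((p.shape[0], 256))
        for s in range(p.shape[0]):
            hist[s] = np.bincount(bins[s], minlength=256)
        hist /= hist.sum(axis=1, keepdims=True)
        return hist @ self._projection


def embed_patches(patches: PatchStack,
                  embedder: Callable[[PatchStack], np.ndarray] | None = None
                  ) -> MorphologyFeatures:
    """Apply an embedder to a patch stack, preserving spot order."""
    if embedder is None:
        embedder = HistogramProjectionEmbedder()
    values = np.asarray(embedder(patches), dtype=float)
    if values.ndim != 2 or values.shape[0] != patches.n:
        raise ContractError(
            f"embedder returned shape {values.shape}; expected ({patches.n}, F)")
    embedder_id = getattr(embedder, "embedder_id", type(embedder).__name__)
    return MorphologyFeatures(values, embedder_id)


def reduce_features(feat: MorphologyFeatures,
                    n_components: int = DEFAULT_REDUCED_DIM) -> MorphologyFeatures:
    """Fill the ``reduced`` field with PCA scores of the embedder output."""
    pm = pca_reduce(feat.values, n_components)
    return MorphologyFeatures(feat.values, feat.embedder_id, reduced=pm.values)


def write_features_tsv(path, spot_ids, values: np.ndarray) -> None:
    df = pd.DataFrame(values, index=np.asarray(spot_ids, dtype=str))
    df.index.name = "spot_id"
    df.to_csv(path, sep="\t")


def read_features_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.index.astype(str).to_numpy(), df.to_numpy(float)
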