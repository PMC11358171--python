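"""Patch embeddings through pluggable backends.

The default backend is a deterministic seeded random projection of
downsampled patch pixels — a stand-in for a pretrained CNN's penultimate
layer that needs no weight download and keeps decoding tests stable (the
map is linear, so nearby patches embed nearby). A CNN backend hook exists
but raises a capability error in environments without torch/torchvision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from gazesal.patches import PatchSequence

DEFAULT_OUTPUT_DIM = 4096


class BackendUnavailableError(RuntimeError):
    """Raised when an embedding backend's runtime dependencies are missing."""


class EmbeddingBackend:
    """Interface: map a (w, w, 3) patch in [0, 1] to a fixed-length vector."""

    name: str
    output_dim: int
    deterministic: bool

    def embed(self, patch: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class RandomProjectionBackend(EmbeddingBackend):
    """Seeded Gaussian random projection of mean-downsampled pixels.

    The patch is resized to ``input_size`` x ``input_size`` (bilinear),
    flattened, and multiplied by a fixed N(0, 1/n_in) matrix. A zero
    patch maps to the zero vector (the backend's baseline).
    """

    output_dim: int = DEFAULT_OUTPUT_DIM
    input_size: int = 16
    seed: int = 0
    name: str = "random-projection"
    deterministic: bool = True
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.output_dim < 1 or self.input_size < 1:
            raise ValueError("output_dim and input_size must be positive")
        n_in = self.input_size * self.input_size * 3
        rng = np.random.default_rng(self.seed)
        self._matrix = rng.standard_normal((self.output_dim, n_in)) / np.sqrt(n_in)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def preprocess(self, patch: np.ndarray) -> np.ndarray:
        small = resize(
            np.asarray(patch, dtype=float),
            (self.input_size, self.input_size, 3),
            order=1,
            mode="edge",
            anti_aliasing=False,
        )
        return small.ravel()

    def embed(self, patch: np.ndarray) -> np.ndarray:
        return self._matrix @ self.preprocess(patch)


@dataclass
class CNNBackend(EmbeddingBackend):
    """Pretrained-CNN penultimate-layer backend (requires torch + weights)."""

    output_dim: int = DEFAULT_OUTPUT_DIM
    name: str = "cnn-fc7"
    deterministic: bool = True

    def embed(self, patch: np.ndarray) -> np.ndarray:
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "CNN backend needs torch/torchvision (and a weight download); "
                "use RandomProjectionBackend instead"
            ) from exc
        raise NotImplementedError("CNN forward pass not wired in this build")


def default_backend(output_dim: int = DEFAULT_OUTPUT_DIM, seed: int = 0) -> EmbeddingBackend:
    return RandomProjectionBackend(output_dim=output_dim, seed=seed)


def embed_patch(patch: np.ndarray, backend: EmbeddingBackend) -> np.ndarray:
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"patch must be (w, w, 3), got {patch.shape}")
    vec = backend.embed(patch)
    if vec.shape != (backend.output_dim,):
        raise RuntimeError(
            f"backend {backend.name!r} returned shape {vec.shape}, "
            f"expected ({backend.output_dim},)"
        )
    return vec


def embed_sequence(seq: PatchSequence, backend: EmbeddingBackend) -> np.ndarray:
    """Concatenate per-frame embeddings in frame order; invalid frames are zero.

    The sequence is expected to be frame-downsampled already (the
    pipeline samples one frame in ten before embedding).
    """
    T = len(seq)
    row = np.zeros(T * backend.output_dim)
    for t in range(T):
        if not seq.valid[t]:
            continue
        row[t * backend.output_dim : (t + 1) * backend.output_dim] = embed_patch(
            seq.patches[t], backend
        )
    return row


@dataclass
class FeatureMatrix:
    """Participants x (frames x dim) feature values for one clip and stream."""

    values: np.ndarray  # (n_participants, n_frames * dim)
    participant_ids: list[str]
    frame_index: np.ndarray  # original frame indices of the columns' frames
    dim: int
    stream: str  # "saliency" | "embedding" | "combined"

    def __post_init__(self) -> None:
        n_cols = self.values.shape[1]
        if n_cols != len(self.frame_index) * self.dim:
            raise ValueError("values width must equal n_frames * dim")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def as_tensor(self) -> np.ndarray:
        """(n_participants, n_frames, dim) view."""
        return self.values.reshape(len(self.participant_ids), self.n_frames, self.dim)
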