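"""Episode construction: M-way K-shot task sampling and data sources.

Meta-training consumes *episodes*: an ordered online stream of ``M * K``
labeled examples (K per class from M classes drawn without replacement from a
class pool) plus a disjoint query set of ``Q`` examples per class.  Labels
inside an episode are relabeled ``0 .. M-1``.  Sources with many classes
(the handwritten-character benchmark has 47) keep the task distribution
diverse across episodes.

Two sources are provided:

* :func:`load_idx_source` reads the IDX image/label file format used by the
  MNIST-family datasets from local files (nothing is downloaded);
* :func:`make_synthetic_source` generates a class-prototype-plus-noise pool
  with the same statistical role and interface, so every experiment runs
  without any dataset on disk.  A synthetic source can be materialized to
  IDX files (:func:`materialize_idx`) for interchangeability.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class EpisodeTask:
    """One M-way task: an ordered train stream and a held-out query set."""

    X_train: np.ndarray       # (M*K, d), values in [0, 1]
    y_train: np.ndarray       # (M*K,), labels 0..M-1
    X_query: np.ndarray       # (M*Q, d)
    y_query: np.ndarray       # (M*Q,)
    class_ids: np.ndarray     # the M source classes behind labels 0..M-1


@dataclass
class DatasetSource:
    """In-memory pool of flattened images with integer class labels."""

    images: np.ndarray        # (N, d) float in [0, 1]
    labels: np.ndarray        # (N,) int

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 2 or len(self.images) != len(self.labels):
            raise ValueError("images must be (N, d) with one label per row")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    @property
    def input_dim(self) -> int:
        return self.images.shape[1]


def sample_episode(source: DatasetSource, M: int, K: int, Q: int, seed: int) -> EpisodeTask:
    """Draw an M-way episode with K train and Q query items per class.

    Classes are drawn without replacement from the source pool, items without
    replacement within each class; train and query items are disjoint.  The
    train stream is shuffled once with the episode seed (the online loop then
    consumes it in order).  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(source.labels)
    if len(classes) < M:
        raise ValueError(f"source has {len(classes)} classes, episode needs {M}")
    chosen = rng.choice(classes, size=M, replace=False)
    X_tr, y_tr, X_q, y_q = [], [], [], []
    for new_label, c in enumerate(chosen):
        idx = np.flatnonzero(source.labels == c)
        if len(idx) < K + Q:
            raise ValueError(f"class {c} has {len(idx)} items, episode needs {K + Q}")
        picked = rng.choice(idx, size=K + Q, replace=False)
        X_tr.append(source.images[picked[:K]])
        y_tr.append(np.full(K, new_label))
        X_q.append(source.images[picked[K:]])
        y_q.append(np.full(Q, new_label))
    X_tr = np.concatenate(X_tr)
    y_tr = np.concatenate(y_tr)
    order = rng.permutation(len(y_tr))
    return EpisodeTask(X_train=X_tr[order], y_train=y_tr[order],
                       X_query=np.concatenate(X_q), y_query=np.concatenate(y_q),
                       class_ids=np.asarray(chosen))


def episode_sampler(source: DatasetSource, M: int, K: int, Q: int):
    """Bind a source and episode shape into a ``sampler(seed)`` callable."""
    def sampler(seed: int) -> EpisodeTask:
        return sample_episode(source, M, K, Q, seed)
    return sampler


# ---------------------------------------------------------------------------
# Synthetic source
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTaskSpec:
    """Generator settings for a prototype-plus-noise class pool.

    Each class has a fixed prototype pattern; samples are the prototype plus
    elementwise Gaussian noise, clipped to [0, 1].  ``gaussian_prototypes``
    draws dense uniform prototypes; ``blob_glyphs`` places a few Gaussian
    bumps on the (square) pixel grid, giving sparse glyph-like images closer
    in spirit to handwritten characters.
    """

    class_pool_size: int = 47
    input_dim: int = 784
    prototype_scale: float = 1.0
    noise_scale: float = 0.2
    structure: str = "gaussian_prototypes"
    n_per_class: int = 120

    def __post_init__(self):
        if self.class_pool_size < 20:
            raise ValueError("class pool must have at least 20 classes")
        if self.input_dim <= 0 or self.n_per_class <= 0:
            raise ValueError("input_dim and n_per_class must be positive")
        if self.prototype_scale <= 0 or self.noise_scale < 0:
            raise ValueError("prototype_scale must be > 0 and noise_scale >= 0")
        if self.structure not in ("gaussian_prototypes", "blob_glyphs"):
            raise ValueError(f"unknown structure {self.structure!r}")


def class_prototypes(spec: SyntheticTaskSpec, seed: int) -> np.ndarray:
    """Deterministic per-class prototype patterns, shape (C, d), in [0, 1]."""
    rng = np.random.default_rng(seed)
    C, dim = spec.class_pool_size, spec.input_dim
    if spec.structure == "gaussian_prototypes":
        protos = spec.prototype_scale * rng.uniform(0.0, 1.0, size=(C, dim))
        return np.clip(protos, 0.0, 1.0)
    side = int(round(np.sqrt(dim)))
    if side * side != dim:
        raise ValueError("blob_glyphs requires a square input_dim")
    jj, kk = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    protos = np.zeros((C, side, side))
    n_blobs = 4
    sigma = max(side / 8.0, 1.0)
    for c in range(C):
        centers = rng.uniform(0, side, size=(n_blobs, 2))
        for cy, cx in centers:
            protos[c] += np.exp(-((jj - cy) ** 2 + (kk - cx) ** 2) / (2 * sigma ** 2))
    protos *= spec.prototype_scale / protos.max(axis=(1, 2), keepdims=True)
    return np.clip(protos.reshape(C, dim), 0.0, 1.0)


def make_synthetic_source(spec: SyntheticTaskSpec, seed: int) -> DatasetSource:
    """Materialize a synthetic class pool as an in-memory dataset source."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 7)).generate_state(1)[0])
    protos = class_prototypes(spec, seed)
    C, dim = protos.shape
    n = spec.n_per_class
    noise = rng.standard_normal((C, n, dim)) * spec.noise_scale
    images = np.clip(protos[:, None, :] + noise, 0.0, 1.0).reshape(C * n, dim)
    labels = np.repeat(np.arange(C), n)
    return DatasetSource(images=images, labels=labels)


# ---------------------------------------------------------------------------
# IDX file format (MNIST-family on-disk layout)
# ---------------------------------------------------------------------------

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def write_idx_images(path, images: np.ndarray) -> None:
    """Write uint8 images of shape (N, rows, cols) in IDX3 format."""
    images = np.ascontiguousarray(images, dtype=np.uint8)
    if images.ndim != 3:
        raise ValueError("images must be (N, rows, cols)")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, *images.shape))
        fh.write(images.tobytes())


def write_idx_labels(path, labels: np.ndarray) -> None:
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, len(labels)))
        fh.write(labels.tobytes())


def read_idx_images(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">IIII", fh.read(16))
        if magic != _IDX_IMAGES_MAGIC:
            raise ValueError(f"{path}: not an IDX image file (magic {magic:#x})")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    return data.reshape(n, rows, cols)


def read_idx_labels(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic, n = struct.unpack(">II", fh.read(8))
        if magic != _IDX_LABELS_MAGIC:
            raise ValueError(f"{path}: not an IDX label file (magic {magic:#x})")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    if len(data) != n:
        raise ValueError(f"{path}: header promises {n} labels, file has {len(data)}")
    return data.astype(int)


def load_idx_source(images_path, labels_path, transpose: bool = False) -> DatasetSource:
    """Load an IDX image/label pair, flatten, and scale pixels to [0, 1].

    ``transpose`` applies the per-image transpose some distributions of the
    extended handwritten-character dataset require; it is irrelevant for
    fully connected networks (a fixed pixel permutation) but kept for
    reproducibility of visualizations.
    """
    images = read_idx_images(images_path)
    if transpose:
        images = images.transpose(0, 2, 1)
    labels = read_idx_labels(labels_path)
    flat = images.reshape(len(images), -1).astype(float) / 255.0
    return DatasetSource(images=flat, labels=labels)


def materialize_idx(source: DatasetSource, out_dir, side: int = None) -> dict:
    """Write a source to IDX files (plus a JSON manifest); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dim = source.input_dim
    side = side or int(round(np.sqrt(dim)))
    if side * side != dim:
        raise ValueError("input_dim is not square; pass side explicitly")
    images = np.clip(np.round(source.images * 255.0), 0, 255).astype(np.uint8)
    paths = {"images": str(out / "images-idx3-ubyte"),
             "labels": str(out / "labels-idx1-ubyte"),
             "manifest": str(out / "manifest.json")}
    write_idx_images(paths["images"], images.reshape(-1, side, side))
    write_idx_labels(paths["labels"], source.labels)
    with open(paths["manifest"], "w") as fh:
        json.dump({"n_items": len(source.labels), "n_classes": int(source.n_classes),
                   "side": side}, fh, indent=2)
    return paths
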