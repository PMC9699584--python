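"""Synthetic paired two-modality embedding generator.

Stands in for frozen modality encoders (an infrared sleep-video encoder and
an EEG encoder) by emulating the structure their outputs are assumed to
have: five sleep-stage clusters in a shared latent space, instance-level
pairing between modalities, a modality gap realised as two different fixed
linear views of the shared latent, and independent per-modality noise.

Each clip ``i`` has a latent ``z_i = prototype[y_i] + spread * eps`` and the
two modality rows are unit-normalised linear images of the same latent:

    video_i = normalise(A_v z_i + sigma * eps_v)
    eeg_i   = normalise(A_e z_i + sigma * eps_e)

with ``A_v, A_e`` drawn once from the seed. Prototypes are mutually
orthogonal unit directions scaled by a separation constant, so class
separation is controlled independently of the noise scales.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SLEEP_STAGES",
    "SyntheticConfig",
    "PairedEmbeddingDataset",
    "generate_paired_embeddings",
    "split_dataset",
    "write_dataset",
    "read_dataset",
    "largest_remainder_allocation",
]

#: Five-class sleep-stage vocabulary: wake, light sleep (N1, N2), deep
#: sleep (N3) and REM.
SLEEP_STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

FORMAT_VERSION = "1"


class DatasetFormatError(ValueError):
    """A dataset container on disk is malformed or internally inconsistent."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the paired-embedding generator.

    Parameters
    ----------
    n_clips
        Number of synchronized clip pairs to generate.
    n_classes
        Number of sleep-stage clusters (at most ``len(SLEEP_STAGES)``).
    class_proportions
        Probability vector over classes; defaults to uniform.
    latent_dim
        Dimension of the shared latent space.
    embed_dim
        Output embedding dimension per modality.
    within_class_spread
        Standard deviation of latent noise around each class prototype.
    modality_noise
        Standard deviation of additive noise applied independently per
        modality, per embedding coordinate.
    class_separation
        Scale of the (unit, mutually orthogonal) class prototypes.
    seed
        Seed controlling prototypes, modality maps and all noise draws.
    """

    n_clips: int
    n_classes: int = 5
    class_proportions: tuple[float, ...] | None = None
    latent_dim: int = 16
    embed_dim: int = 512
    within_class_spread: float = 0.1
    modality_noise: float = 0.02
    class_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clips < 0:
            raise ValueError(f"n_clips must be nonnegative, got {self.n_clips}")
        if not 1 <= self.n_classes <= len(SLEEP_STAGES):
            raise ValueError(
                f"n_classes must be in [1, {len(SLEEP_STAGES)}], got {self.n_classes}"
            )
        if self.latent_dim < 1 or self.embed_dim < 1:
            raise ValueError("latent_dim and embed_dim must be >= 1")
        for name in ("within_class_spread", "modality_noise", "class_separation"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        props = self.class_proportions
        if props is None:
            props = tuple([1.0 / self.n_classes] * self.n_classes)
            object.__setattr__(self, "class_proportions", props)
        props = tuple(float(p) for p in props)
        object.__setattr__(self, "class_proportions", props)
        if len(props) != self.n_classes:
            raise ValueError(
                f"class_proportions has length {len(props)}, expected {self.n_classes}"
            )
        if any(not math.isfinite(p) or p < 0 for p in props):
            raise ValueError("class_proportions must be finite and nonnegative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {sum(props)!r}")
        if self.n_clips < self.n_classes and all(p > 0 for p in props):
            raise ValueError(
                f"n_clips={self.n_clips} < n_classes={self.n_classes} with all "
                "proportions positive: at least one clip per class is required"
            )

    @property
    def labels_vocabulary(self) -> tuple[str, ...]:
        return SLEEP_STAGES[: self.n_classes]


@dataclass
class PairedEmbeddingDataset:
    """Index-aligned per-clip embeddings for both modalities plus labels.

    Row ``i`` of ``video_embeddings``, row ``i`` of ``eeg_embeddings`` and
    ``labels[i]`` all refer to the same synchronized 30-second clip.
    """

    video_embeddings: np.ndarray
    eeg_embeddings: np.ndarray
    labels: np.ndarray
    clip_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.video_embeddings = np.asarray(self.video_embeddings, dtype=np.float64)
        self.eeg_embeddings = np.asarray(self.eeg_embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.video_embeddings.ndim != 2 or self.eeg_embeddings.ndim != 2:
            raise DatasetFormatError("embedding matrices must be 2-D")
        if self.video_embeddings.shape != self.eeg_embeddings.shape:
            raise DatasetFormatError(
                "modality row/column mismatch: video has shape "
                f"{self.video_embeddings.shape}, eeg has shape "
                f"{self.eeg_embeddings.shape}"
            )
        n = self.video_embeddings.shape[0]
        if self.labels.shape != (n,):
            raise DatasetFormatError(
                f"labels has length {self.labels.shape}, expected ({n},)"
            )
        if self.clip_ids is None:
            self.clip_ids = np.array([f"clip-{i:06d}" for i in range(n)], dtype=object)
        else:
            self.clip_ids = np.asarray(self.clip_ids, dtype=object)
        if self.clip_ids.shape != (n,):
            raise DatasetFormatError(f"clip_ids must have length {n}")
        if len(set(self.clip_ids.tolist())) != n:
            raise DatasetFormatError("clip_ids must be unique")
        if not (
            np.all(np.isfinite(self.video_embeddings))
            and np.all(np.isfinite(self.eeg_embeddings))
        ):
            raise DatasetFormatError("embeddings contain non-finite values")

    def __len__(self) -> int:
        return self.video_embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.video_embeddings.shape[1]

    def subset(self, indices: np.ndarray) -> "PairedEmbeddingDataset":
        indices = np.asarray(indices)
        return PairedEmbeddingDataset(
            video_embeddings=self.video_embeddings[indices],
            eeg_embeddings=self.eeg_embeddings[indices],
            labels=self.labels[indices],
            clip_ids=self.clip_ids[indices],
        )

    def equals(self, other: "PairedEmbeddingDataset") -> bool:
        return (
            np.array_equal(self.video_embeddings, other.video_embeddings)
            and np.array_equal(self.eeg_embeddings, other.eeg_embeddings)
            and self.labels.tolist() == other.labels.tolist()
            and self.clip_ids.tolist() == other.clip_ids.tolist()
        )


def largest_remainder_allocation(proportions: np.ndarray, total: int) -> np.ndarray:
    """Hamilton apportionment of ``total`` items over ``proportions``.

    Deterministic and exact: floors the ideal quotas, then hands the
    leftover units to the largest fractional remainders (ties to the
    lower index).
    """
    proportions = np.asarray(proportions, dtype=np.float64)
    quotas = proportions * total
    counts = np.floor(quotas).astype(int)
    remainder = total - int(counts.sum())
    if remainder > 0:
        frac = quotas - np.floor(quotas)
        # stable sort descending by fraction, ties broken by smaller index
        order = np.argsort(-frac, kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return x / norms


def _class_prototypes(rng: np.random.Generator, n_classes: int, latent_dim: int,
                      separation: float) -> np.ndarray:
    raw = rng.standard_normal((latent_dim, max(n_classes, 1)))
    if latent_dim >= n_classes:
        q, _ = np.linalg.qr(raw)
        protos = q[:, :n_classes].T
    else:  # cannot be mutually orthogonal; fall back to unit directions
        protos = _unit_rows(raw.T[:n_classes])
    return separation * protos


def generate_paired_embeddings(
    cfg: SyntheticConfig,
    modality_maps: tuple[np.ndarray, np.ndarray] | None = None,
) -> PairedEmbeddingDataset:
    """Generate a paired two-modality dataset from ``cfg``.

    Fully reproducible: the same config yields bit-identical datasets.
    ``modality_maps`` overrides the seeded random linear views ``(A_v, A_e)``
    — useful for controlled experiments (e.g. identity maps make the two
    modalities coincide in the noise-free limit).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = largest_remainder_allocation(np.asarray(cfg.class_proportions), cfg.n_clips)

    protos = _class_prototypes(rng, cfg.n_classes, cfg.latent_dim, cfg.class_separation)
    if modality_maps is None:
        scale = 1.0 / np.sqrt(cfg.latent_dim)
        a_v = rng.standard_normal((cfg.latent_dim, cfg.embed_dim)) * scale
        a_e = rng.standard_normal((cfg.latent_dim, cfg.embed_dim)) * scale
    else:
        a_v, a_e = modality_maps
        a_v = np.asarray(a_v, dtype=np.float64)
        a_e = np.asarray(a_e, dtype=np.float64)
        if a_v.shape != (cfg.latent_dim, cfg.embed_dim) or a_e.shape != a_v.shape:
            raise ValueError(
                "modality maps must have shape "
                f"({cfg.latent_dim}, {cfg.embed_dim})"
            )

    class_idx = np.repeat(np.arange(cfg.n_classes), counts)
    n = cfg.n_clips
    z = protos[class_idx] + cfg.within_class_spread * rng.standard_normal(
        (n, cfg.latent_dim)
    )
    video = z @ a_v + cfg.modality_noise * rng.standard_normal((n, cfg.embed_dim))
    eeg = z @ a_e + cfg.modality_noise * rng.standard_normal((n, cfg.embed_dim))

    vocab = np.array(cfg.labels_vocabulary, dtype=object)
    return PairedEmbeddingDataset(
        video_embeddings=_unit_rows(video),
        eeg_embeddings=_unit_rows(eeg),
        labels=vocab[class_idx],
        clip_ids=np.array([f"clip-{i:06d}" for i in range(n)], dtype=object),
    )


def split_dataset(
    ds: PairedEmbeddingDataset, n_query: int, n_train: int, seed: int
) -> tuple[PairedEmbeddingDataset, PairedEmbeddingDataset, PairedEmbeddingDataset]:
    """Split into (train, query, gallery).

    The query set is disjoint from the gallery; the gallery (the retrieval
    "database") is every non-query clip; the training set is sampled from
    the gallery without replacement. Seeded and reproducible.
    """
    n = len(ds)
    if n_query < 0 or n_train < 0:
        raise ValueError("split sizes must be nonnegative")
    if n_query >= n and n > 0 or (n == 0 and n_query > 0):
        raise ValueError(f"n_query={n_query} must leave a nonempty gallery (N={n})")
    if n_train > n - n_query:
        raise ValueError(
            f"n_train={n_train} exceeds gallery size {n - n_query}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    query_idx = np.sort(perm[:n_query])
    gallery_idx = np.sort(perm[n_query:])
    train_idx = np.sort(rng.choice(gallery_idx, size=n_train, replace=False))
    return ds.subset(train_idx), ds.subset(query_idx), ds.subset(gallery_idx)


# ---------------------------------------------------------------------------
# On-disk container: TSV triplet + JSON manifest
# ---------------------------------------------------------------------------

def write_dataset(ds: PairedEmbeddingDataset, path: str | Path) -> None:
    """Write a dataset directory: video.tsv, eeg.tsv, labels.tsv, manifest.json.

    Embedding rows are tab-separated floats at full float64 precision
    (``repr`` round-trip), one row per clip; labels.tsv holds
    ``clip_id<TAB>label`` per clip.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, mat in (("video.tsv", ds.video_embeddings), ("eeg.tsv", ds.eeg_embeddings)):
        with open(path / name, "w") as fh:
            for row in mat:
                fh.write("\t".join(repr(float(x)) for x in row))
                fh.write("\n")
    with open(path / "labels.tsv", "w") as fh:
        for cid, lab in zip(ds.clip_ids, ds.labels):
            fh.write(f"{cid}\t{lab}\n")
    manifest = {
        "n": len(ds),
        "dim": ds.dim if len(ds) else 0,
        "format_version": FORMAT_VERSION,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def _read_matrix(path: Path, expected_dim: int | None) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                row = [float(tok) for tok in line.split("\t")]
            except ValueError as exc:
                raise DatasetFormatError(
                    f"{path.name}: unparseable value in record {lineno}: {exc}"
                ) from None
            if rows and len(row) != len(rows[0]):
                raise DatasetFormatError(
                    f"{path.name}: record {lineno} has {len(row)} columns, "
                    f"expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        return np.zeros((0, expected_dim or 0), dtype=np.float64)
    return np.asarray(rows, dtype=np.float64)


def read_dataset(path: str | Path) -> PairedEmbeddingDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise DatasetFormatError(f"missing manifest.json in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if str(manifest.get("format_version")) != FORMAT_VERSION:
        raise DatasetFormatError(
            f"unsupported dataset format_version {manifest.get('format_version')!r}"
        )
    video = _read_matrix(path / "video.tsv", manifest.get("dim"))
    eeg = _read_matrix(path / "eeg.tsv", manifest.get("dim"))
    if video.shape[0] != eeg.shape[0]:
        raise DatasetFormatError(
            f"modality row-count mismatch: video.tsv has {video.shape[0]} rows, "
            f"eeg.tsv has {eeg.shape[0]}"
        )
    ids: list[str] = []
    labels: list[str] = []
    with open(path / "labels.tsv") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetFormatError(
                    f"labels.tsv: record {lineno} is not 'clip_id<TAB>label'"
                )
            ids.append(parts[0])
            labels.append(parts[1])
    if len(ids) != video.shape[0]:
        raise DatasetFormatError(
            f"labels.tsv has {len(ids)} records, embeddings have {video.shape[0]} rows"
        )
    if int(manifest.get("n", -1)) != video.shape[0]:
        raise DatasetFormatError(
            f"manifest n={manifest.get('n')} disagrees with {video.shape[0]} data rows"
        )
    return PairedEmbeddingDataset(
        video_embeddings=video,
        eeg_embeddings=eeg,
        labels=np.array(labels, dtype=object),
        clip_ids=np.array(ids, dtype=object),
    )
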