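"""Binary hash-code bank: build, persist, and rank by Hamming distance.

After training, every gallery clip gets one *joint* binary code
B_i = sign((fv(v_i) + fe(e_i)) / 2) computed in inference mode; queries
are encoded with the querying modality's network alone and binarized by
sign before comparison. Codes are stored bit-packed in little-endian
64-bit words (-1 -> 0, +1 -> 1, row-major), so a Hamming distance is an
XOR plus popcount, and ranking a gallery is a stable ascending sort of
integer distances (ties keep the original gallery order).

Bank file layout (binary, versioned): magic ``CCHB``, a version byte, a
length-prefixed JSON header ``{n, code_length, n_words, modality_tag,
format_version}``, the packed code block, then length-prefixed JSON
tables of clip ids and labels.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import HashingNetwork
from .objectives import binarize_joint
from .synthetic import PairedEmbeddingDataset

__all__ = [
    "BinaryCodeBank",
    "BankIntegrityError",
    "BankVersionError",
    "pack_codes",
    "unpack_codes",
    "build_bank",
    "encode_query",
    "hamming_distance",
    "rank_gallery",
    "RetrievalResult",
    "save_bank",
    "load_bank",
]

_MAGIC = b"CCHB"
_VERSION = 1
FORMAT_VERSION = "1"


class BankIntegrityError(ValueError):
    """A bank file is corrupted, truncated, or internally inconsistent."""


class BankVersionError(ValueError):
    """A bank file was written by an incompatible format version."""


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack sign codes [N x L] in {-1,+1} into uint64 words [N x ceil(L/64)].

    Bit j of word w holds code column ``64*w + j`` (-1 -> 0, +1 -> 1);
    pad bits beyond L are zero.
    """
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise ValueError("codes must be a 2-D sign matrix")
    if codes.size and not np.all(np.isin(codes, (-1, 1))):
        raise ValueError("codes entries must be in {-1, +1}")
    n, length = codes.shape
    n_words = max((length + 63) // 64, 1)
    bits = (codes > 0).astype(np.uint8)
    padded = np.zeros((n, n_words * 64), dtype=np.uint8)
    padded[:, :length] = bits
    words = np.zeros((n, n_words), dtype=np.uint64)
    weights = (np.uint64(1) << np.arange(64, dtype=np.uint64))
    for w in range(n_words):
        words[:, w] = padded[:, w * 64:(w + 1) * 64].astype(np.uint64) @ weights
    return words


def unpack_codes(words: np.ndarray, code_length: int) -> np.ndarray:
    """Inverse of :func:`pack_codes`: [N x W] uint64 -> [N x L] in {-1,+1}."""
    words = np.asarray(words, dtype=np.uint64)
    n, n_words = words.shape
    bits = np.zeros((n, n_words * 64), dtype=np.uint8)
    for w in range(n_words):
        col = words[:, w]
        for j in range(64):
            bits[:, w * 64 + j] = (col >> np.uint64(j)) & np.uint64(1)
    out = bits[:, :code_length].astype(np.int8)
    return (out * 2 - 1).astype(np.int8)


@dataclass
class BinaryCodeBank:
    """Packed {-1,+1}^L codes for a retrieval gallery, with labels and ids."""

    packed_codes: np.ndarray
    code_length: int
    labels: np.ndarray
    clip_ids: np.ndarray
    modality_tag: str = "joint"
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        self.packed_codes = np.asarray(self.packed_codes, dtype=np.uint64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.clip_ids = np.asarray(self.clip_ids, dtype=object)
        if self.packed_codes.ndim != 2:
            raise ValueError("packed_codes must be 2-D")
        n_words = max((self.code_length + 63) // 64, 1)
        if self.packed_codes.shape[1] != n_words:
            raise ValueError(
                f"packed_codes has {self.packed_codes.shape[1]} words per code, "
                f"expected {n_words} for L={self.code_length}"
            )
        n = self.packed_codes.shape[0]
        if self.labels.shape != (n,) or self.clip_ids.shape != (n,):
            raise ValueError("labels and clip_ids must match the number of codes")
        if self.modality_tag not in ("joint", "video", "eeg"):
            raise ValueError(f"unknown modality_tag {self.modality_tag!r}")
        # pad bits beyond L must be zero
        tail = self.code_length % 64
        if tail and n:
            mask = ~((np.uint64(1) << np.uint64(tail)) - np.uint64(1))
            if np.any(self.packed_codes[:, -1] & mask):
                raise ValueError("pad bits beyond code_length must be zero")

    def __len__(self) -> int:
        return self.packed_codes.shape[0]

    def codes(self) -> np.ndarray:
        """Unpacked [N x L] sign codes."""
        return unpack_codes(self.packed_codes, self.code_length)


@dataclass
class RetrievalResult:
    """One query's ranked gallery identifiers with ascending Hamming distances."""

    query_id: str
    ranked_ids: list[str]
    distances: list[int]

    def __post_init__(self) -> None:
        if len(self.ranked_ids) != len(self.distances):
            raise ValueError("ranked_ids and distances must have equal length")
        if any(b < a for a, b in zip(self.distances, self.distances[1:])):
            raise ValueError("distances must be non-decreasing")
        if len(set(self.ranked_ids)) != len(self.ranked_ids):
            raise ValueError("ranked ids must be unique")


def build_bank(
    net_v: HashingNetwork,
    net_e: HashingNetwork,
    gallery: PairedEmbeddingDataset,
) -> BinaryCodeBank:
    """Joint binary codes for every gallery clip, packed with labels/ids."""
    if len(gallery) == 0:
        raise ValueError("gallery must be nonempty")
    if net_v.spec.code_length != net_e.spec.code_length:
        raise ValueError("the two networks must share a code length")
    fv = net_v.forward(gallery.video_embeddings)
    fe = net_e.forward(gallery.eeg_embeddings)
    joint = binarize_joint(fv, fe)
    return BinaryCodeBank(
        packed_codes=pack_codes(joint),
        code_length=net_v.spec.code_length,
        labels=gallery.labels.copy(),
        clip_ids=gallery.clip_ids.copy(),
        modality_tag="joint",
    )


def encode_query(net: HashingNetwork, embedding: np.ndarray) -> np.ndarray:
    """Binarized code(s) for query embedding(s): sign of the network output
    with sign(0) = +1. A 1-D input yields a 1-D {-1,+1}^L code."""
    emb = np.asarray(embedding, dtype=np.float64)
    single = emb.ndim == 1
    out = net.forward(emb)
    codes = np.where(out >= 0.0, 1, -1).astype(np.int8)
    return codes[0] if single else codes


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Number of disagreeing positions between two {-1,+1} codes."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"code length mismatch: {a.size} vs {b.size}")
    return int(np.count_nonzero(a != b))


def _packed_distances(query_words: np.ndarray, bank_words: np.ndarray) -> np.ndarray:
    xor = np.bitwise_xor(bank_words, query_words[None, :])
    return np.bitwise_count(xor).sum(axis=1).astype(np.int64)


def rank_gallery(
    query_code: np.ndarray,
    bank: BinaryCodeBank,
    top_k: int,
    query_id: str = "query",
) -> RetrievalResult:
    """Rank the bank by ascending Hamming distance to ``query_code``.

    Uses packed-word popcount; ties keep the original gallery order
    (stable sort); the list is truncated to ``top_k``.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if len(bank) == 0:
        raise ValueError("cannot rank an empty bank")
    query_code = np.asarray(query_code).ravel()
    if query_code.size != bank.code_length:
        raise ValueError(
            f"query code length {query_code.size} != bank code length "
            f"{bank.code_length}"
        )
    qwords = pack_codes(query_code[None, :])[0]
    dists = _packed_distances(qwords, bank.packed_codes)
    order = np.argsort(dists, kind="stable")[:top_k]
    return RetrievalResult(
        query_id=query_id,
        ranked_ids=[str(bank.clip_ids[i]) for i in order],
        distances=[int(dists[i]) for i in order],
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_bank(bank: BinaryCodeBank, path: str | Path) -> None:
    """Write the bank to ``path`` in the versioned CCHB binary format."""
    path = Path(path)
    header = {
        "n": len(bank),
        "code_length": bank.code_length,
        "n_words": bank.packed_codes.shape[1],
        "modality_tag": bank.modality_tag,
        "format_version": bank.format_version,
    }
    header_bytes = json.dumps(header, sort_keys=True).encode()
    ids_bytes = json.dumps(bank.clip_ids.tolist()).encode()
    labels_bytes = json.dumps(bank.labels.tolist()).encode()
    code_bytes = np.ascontiguousarray(bank.packed_codes, dtype="<u8").tobytes()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<B", _VERSION))
        fh.write(struct.pack("<I", len(header_bytes)))
        fh.write(header_bytes)
        fh.write(code_bytes)
        fh.write(struct.pack("<I", len(ids_bytes)))
        fh.write(ids_bytes)
        fh.write(struct.pack("<I", len(labels_bytes)))
        fh.write(labels_bytes)


def _read_exact(fh, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise BankIntegrityError(f"truncated bank file while reading {what}")
    return data


def load_bank(path: str | Path) -> BinaryCodeBank:
    """Read a bank written by :func:`save_bank`, validating magic/version."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise BankIntegrityError(
                f"bad magic {magic!r}: not a CCHB bank file"
            )
        (version,) = struct.unpack("<B", _read_exact(fh, 1, "version"))
        if version != _VERSION:
            raise BankVersionError(
                f"bank format version {version} is not supported (expected {_VERSION})"
            )
        (hlen,) = struct.unpack("<I", _read_exact(fh, 4, "header length"))
        try:
            header = json.loads(_read_exact(fh, hlen, "header"))
        except json.JSONDecodeError as exc:
            raise BankIntegrityError(f"corrupt bank header: {exc}") from None
        n, n_words = int(header["n"]), int(header["n_words"])
        code_bytes = _read_exact(fh, n * n_words * 8, "code block")
        packed = np.frombuffer(code_bytes, dtype="<u8").reshape(n, n_words)
        (ilen,) = struct.unpack("<I", _read_exact(fh, 4, "id-table length"))
        ids = json.loads(_read_exact(fh, ilen, "id table"))
        (llen,) = struct.unpack("<I", _read_exact(fh, 4, "label-table length"))
        labels = json.loads(_read_exact(fh, llen, "label table"))
    if len(ids) != n or len(labels) != n:
        raise BankIntegrityError("id/label table length disagrees with header")
    return BinaryCodeBank(
        packed_codes=packed.astype(np.uint64),
        code_length=int(header["code_length"]),
        labels=np.array(labels, dtype=object),
        clip_ids=np.array(ids, dtype=object),
        modality_tag=str(header["modality_tag"]),
        format_version=str(header["format_version"]),
    )
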