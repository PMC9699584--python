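"""Retrieval quality metrics: average precision and MAP@N.

For a ranked list truncated at N, an item is relevant iff its sleep-stage
label equals the query's label. Average precision is

    AP = (1 / R) * sum_k P(k) * rel(k),

with P(k) the precision at cut-off k and rel(k) the 0/1 relevance of the
k-th item. By default R counts the relevant items *within the evaluated
(truncated) list* — the prevailing MAP@N convention in the hashing
retrieval literature; counting all relevant gallery items instead is
available via ``rk_mode="gallery"``. A query with no relevant item in its
list scores 0. MAP is the unweighted mean of per-query APs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codebank import BinaryCodeBank, RetrievalResult, encode_query, pack_codes, _packed_distances
from .network import HashingNetwork
from .synthetic import PairedEmbeddingDataset

__all__ = [
    "EvalConfig",
    "average_precision",
    "map_at_n",
    "evaluate_cross_modal",
    "permutation_chance_map",
    "DIRECTIONS",
]

DIRECTIONS = ("video2eeg", "eeg2video")


class DataIntegrityError(KeyError):
    """A ranked identifier cannot be resolved to a gallery label."""


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings: the cut-off N (default 1000, the large-scale
    convention; desk-scale runs use 100) and the R convention for AP."""

    cutoff_n: int = 1000
    rk_mode: str = "within_topk"

    def __post_init__(self) -> None:
        if self.cutoff_n < 1:
            raise ValueError(f"cutoff_n must be >= 1, got {self.cutoff_n}")
        if self.rk_mode not in ("within_topk", "gallery"):
            raise ValueError(f"unknown rk_mode {self.rk_mode!r}")


def average_precision(
    relevance: Sequence[int] | np.ndarray,
    n_relevant_total: int | None = None,
) -> float:
    """AP of one 0/1 relevance sequence (already truncated to the cut-off).

    ``n_relevant_total`` overrides the normaliser R (used for the
    all-relevant-in-gallery convention); by default R is the number of
    relevant items in the sequence itself. No relevant items -> 0.0.
    """
    rel = np.asarray(relevance, dtype=np.float64).ravel()
    if rel.size and not np.all(np.isin(rel, (0.0, 1.0))):
        raise ValueError("relevance entries must be 0 or 1")
    n_rel = int(rel.sum())
    r = n_rel if n_relevant_total is None else int(n_relevant_total)
    if n_rel == 0 or r == 0:
        return 0.0
    cum = np.cumsum(rel)
    k = np.arange(1, rel.size + 1)
    precision_at_hits = (cum / k) * rel
    return float(precision_at_hits.sum() / r)


def map_at_n(
    results: Iterable[RetrievalResult],
    query_labels: Mapping[str, str],
    gallery_labels: Mapping[str, str],
    cfg: EvalConfig,
) -> float:
    """Mean AP over queries; relevance is same-label, lists truncated to N."""
    gallery_counts: Counter | None = None
    if cfg.rk_mode == "gallery":
        gallery_counts = Counter(gallery_labels.values())
    aps = []
    for res in results:
        try:
            qlabel = query_labels[res.query_id]
        except KeyError:
            raise DataIntegrityError(
                f"query id {res.query_id!r} has no label"
            ) from None
        rel = []
        for gid in res.ranked_ids[: cfg.cutoff_n]:
            try:
                rel.append(1 if gallery_labels[gid] == qlabel else 0)
            except KeyError:
                raise DataIntegrityError(
                    f"ranked id {gid!r} is not in the gallery label table"
                ) from None
        total = gallery_counts.get(qlabel, 0) if gallery_counts is not None else None
        aps.append(average_precision(rel, n_relevant_total=total))
    if not aps:
        raise ValueError("map_at_n needs at least one query result")
    return float(np.mean(aps))


def evaluate_cross_modal(
    net_v: HashingNetwork,
    net_e: HashingNetwork,
    query_ds: PairedEmbeddingDataset,
    bank: BinaryCodeBank,
    direction: str,
    cfg: EvalConfig,
) -> float:
    """MAP@N for one retrieval direction against the joint code bank.

    ``video2eeg`` encodes the queries' video embeddings with the video
    network; ``eeg2video`` encodes the EEG embeddings with the EEG network.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    net = net_v if direction == "video2eeg" else net_e
    if net.spec.code_length != bank.code_length:
        raise ValueError(
            f"code-length mismatch: network L={net.spec.code_length}, "
            f"bank L={bank.code_length}"
        )
    emb = (
        query_ds.video_embeddings if direction == "video2eeg"
        else query_ds.eeg_embeddings
    )
    codes = encode_query(net, emb)
    packed = pack_codes(codes)
    gallery_labels = {str(i): str(l) for i, l in zip(bank.clip_ids, bank.labels)}
    query_labels = {str(i): str(l) for i, l in zip(query_ds.clip_ids, query_ds.labels)}

    gallery_counts = Counter(gallery_labels.values()) if cfg.rk_mode == "gallery" else None
    labels_arr = np.asarray([str(l) for l in bank.labels], dtype=object)
    aps = []
    for qi in range(len(query_ds)):
        dists = _packed_distances(packed[qi], bank.packed_codes)
        order = np.argsort(dists, kind="stable")[: cfg.cutoff_n]
        qlabel = str(query_ds.labels[qi])
        rel = (labels_arr[order] == qlabel).astype(int)
        total = gallery_counts.get(qlabel, 0) if gallery_counts is not None else None
        aps.append(average_precision(rel, n_relevant_total=total))
    return float(np.mean(aps))


def permutation_chance_map(
    query_labels: Sequence[str],
    gallery_labels: Sequence[str],
    cutoff_n: int,
    n_permutations: int = 20,
    seed: int = 0,
) -> float:
    """Monte-Carlo chance level of MAP@N for a label distribution.

    Ranks the gallery in a uniformly random order for every query and
    permutation, then averages the resulting MAP — the retrieval score an
    uninformative encoder is expected to produce.
    """
    rng = np.random.default_rng(seed)
    gal = np.asarray([str(l) for l in gallery_labels], dtype=object)
    maps = []
    for _ in range(n_permutations):
        aps = []
        for ql in query_labels:
            order = rng.permutation(gal.size)[:cutoff_n]
            rel = (gal[order] == str(ql)).astype(int)
            aps.append(average_precision(rel))
        maps.append(np.mean(aps))
    return float(np.mean(maps))
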