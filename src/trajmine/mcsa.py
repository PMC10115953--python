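"""Multi-channel sequence analysis: LCS dissimilarities, Ward clustering, ASW.

The dissimilarity between two state sequences is the longest-common-
subsequence (LCS) distance ``|x| + |y| - 2 L``, an indel-only edit distance
that tolerates position shifts (e.g. SSRI-SNRI-SSRI and SNRI-SSRI-SNRI are
close although they differ at every position). Two multi-channel modes are
provided:

* ``sum`` (default) — the per-channel LCS distances added over the three
  channels; decomposable and integer-valued.
* ``composite`` — optimal matching on composite daily states with
  substitution cost 2 per differing channel and indel cost 3 (the
  LCS-equivalent costs per channel, summed).

Clustering is Ward-linkage agglomeration on the dissimilarity matrix
(Lance-Williams recurrence on squared dissimilarities, Ward.D2-style, with
deterministic lowest-index tie-breaking), assessed by the average silhouette
width (ASW); an ASW of 0.51 or above is conventionally read as a reasonable
partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._lcs import (
    composite_om_distance,
    lcs_length,
    lcs_length_naive,
    pairwise_lcs_matrix,
)
from .sequences import CHANNELS, MultiChannelSequence

ASW_REASONABLE = 0.51

__all__ = [
    "DissimilarityMatrix",
    "PartitionQuality",
    "lcs_distance",
    "multichannel_distance",
    "distance_matrix",
    "ward_cluster",
    "cut_tree",
    "silhouette_asw",
    "scan_partitions",
    "ASW_REASONABLE",
]


@dataclass
class DissimilarityMatrix:
    values: np.ndarray  # (n, n) symmetric, zero diagonal
    ids: list[str]
    mode: str = "sum"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("id vector length must match matrix order")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def save(self, path: str | Path) -> None:
        """Dense binary matrix plus a JSON sidecar with ids, mode and checksum."""
        import hashlib

        path = Path(path)
        with open(path, "wb") as fh:
            np.save(fh, self.values)
        digest = hashlib.sha256(self.values.tobytes()).hexdigest()
        sidecar = {"ids": self.ids, "mode": self.mode, "sha256": digest}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "DissimilarityMatrix":
        path = Path(path)
        values = np.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values=values, ids=meta["ids"], mode=meta["mode"])


@dataclass(frozen=True)
class PartitionQuality:
    k: int
    asw: float
    sizes: tuple[int, ...]

    def __post_init__(self):
        assert -1.0 <= self.asw <= 1.0
        assert all(s > 0 for s in self.sizes)

    @property
    def reasonable(self) -> bool:
        return self.asw >= ASW_REASONABLE


def _encode(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    alphabet = {s: i for i, s in enumerate(dict.fromkeys(list(x) + list(y)))}
    if not alphabet:
        raise ValueError("empty alphabet: both sequences are empty")
    xa = np.array([alphabet[s] for s in x], dtype=np.int16)
    ya = np.array([alphabet[s] for s in y], dtype=np.int16)
    return xa, ya


def lcs_distance(x: Sequence, y: Sequence) -> float:
    """LCS distance |x| + |y| - 2 L between two state sequences."""
    xa, ya = _encode(x, y)
    return float(len(xa) + len(ya) - 2 * int(lcs_length(xa, ya)))


def lcs_distance_naive(x: Sequence, y: Sequence) -> float:
    """Same quantity via the textbook quadratic DP (oracle path)."""
    xa, ya = _encode(x, y)
    return float(len(xa) + len(ya) - 2 * int(lcs_length_naive(xa, ya)))


def _stack(seq: MultiChannelSequence) -> np.ndarray:
    return np.stack([seq.class_seq, seq.step_seq, seq.poly_seq]).astype(np.int16)


def multichannel_distance(
    a: MultiChannelSequence, b: MultiChannelSequence, mode: str = "sum"
) -> float:
    """Joint three-channel dissimilarity between two patients."""
    if mode == "sum":
        return (
            lcs_distance(a.class_seq, b.class_seq)
            + lcs_distance(a.step_seq, b.step_seq)
            + lcs_distance(a.poly_seq, b.poly_seq)
        )
    if mode == "composite":
        return float(composite_om_distance(_stack(a), _stack(b), 3.0))
    raise ValueError(f"unknown mode {mode!r}; expected 'sum' or 'composite'")


def distance_matrix(
    sequences: Sequence[MultiChannelSequence],
    mode: str = "sum",
    progress_logger: Callable[[str], None] | None = None,
) -> DissimilarityMatrix:
    """All-pairs multi-channel dissimilarities.

    In ``sum`` mode each channel is deduplicated first (daily treatment
    sequences repeat heavily across patients), the unique-pair LCS matrix is
    computed with the run-length-accelerated kernel, and per-channel results
    are broadcast back and added. Deterministic regardless of scheduling.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.patient_id for s in sequences]
    n = len(sequences)
    if mode == "sum":
        total = np.zeros((n, n), dtype=np.float64)
        for channel in CHANNELS:
            arr = np.stack([getattr(s, f"{channel}_seq") for s in sequences]).astype(np.int16)
            uniq, inverse = np.unique(arr, axis=0, return_inverse=True)
            if progress_logger:
                progress_logger(f"channel {channel}: {uniq.shape[0]} distinct sequences")
            dm = pairwise_lcs_matrix(uniq)
            total += dm[np.ix_(inverse, inverse)]
        np.fill_diagonal(total, 0.0)
        return DissimilarityMatrix(values=total, ids=ids, mode=mode)
    if mode == "composite":
        stacks = np.stack([_stack(s) for s in sequences])
        out = np.zeros((n, n), dtype=np.float64)
        for i in range(n):
            for j in range(i + 1, n):
                d = composite_om_distance(stacks[i], stacks[j], 3.0)
                out[i, j] = out[j, i] = d
        if progress_logger:
            progress_logger(f"composite mode: {n * (n - 1) // 2} pairs")
        return DissimilarityMatrix(values=out, ids=ids, mode=mode)
    raise ValueError(f"unknown mode {mode!r}")


def ward_cluster(matrix: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    """Ward-linkage agglomeration on a precomputed dissimilarity matrix.

    Lance-Williams recurrence on squared dissimilarities; merge heights are
    the square roots of the updated Ward criterion (Ward.D2 convention). Ties
    break deterministically toward the lowest pair index. Returns a linkage
    matrix in the conventional (n-1, 4) format: left id, right id, height,
    merged size.
    """
    D = matrix.values if isinstance(matrix, DissimilarityMatrix) else np.asarray(matrix, float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations to cluster")
    S = D.astype(np.float64) ** 2
    work = S.copy()
    np.fill_diagonal(work, np.inf)
    sizes = np.ones(n)
    cid = np.arange(n)
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        flat = int(np.argmin(work))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h2 = work[i, j]
        Z[step] = (cid[i], cid[j], np.sqrt(h2), sizes[i] + sizes[j])
        ni, nj = sizes[i], sizes[j]
        k = active.copy()
        k[i] = k[j] = False
        nk = sizes[k]
        new = ((ni + nk) * work[i, k] + (nj + nk) * work[j, k] - nk * h2) / (ni + nj + nk)
        work[i, k] = new
        work[k, i] = new
        work[j, :] = np.inf
        work[:, j] = np.inf
        sizes[i] += sizes[j]
        active[j] = False
        cid[i] = n + step
    return Z


def cut_tree(dendrogram: np.ndarray, k: int) -> np.ndarray:
    """Cut the dendrogram into k clusters, labelled 1..k by decreasing size."""
    from scipy.cluster.hierarchy import cut_tree as _scipy_cut

    n = dendrogram.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = _scipy_cut(dendrogram, n_clusters=k).ravel()
    order = sorted(
        np.unique(raw), key=lambda c: (-int(np.sum(raw == c)), int(np.argmax(raw == c)))
    )
    relabel = {c: rank + 1 for rank, c in enumerate(order)}
    return np.array([relabel[c] for c in raw], dtype=np.int64)


def silhouette_asw(matrix: DissimilarityMatrix | np.ndarray, labels) -> PartitionQuality:
    """Average silhouette width of a partition on a precomputed matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a the mean within-cluster
    dissimilarity (self excluded) and b the smallest mean dissimilarity to
    another cluster; singletons take s(i) = 0.
    """
    D = matrix.values if isinstance(matrix, DissimilarityMatrix) else np.asarray(matrix, float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = D.shape[0]
    s = np.zeros(n)
    masks = {c: labels == c for c in clusters}
    for i in range(n):
        own = masks[labels[i]]
        size = int(own.sum())
        if size == 1:
            continue  # singleton convention: s(i) = 0
        a = D[i, own].sum() / (size - 1)
        b = min(D[i, masks[c]].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    sizes = tuple(int(masks[c].sum()) for c in clusters)
    return PartitionQuality(k=int(clusters.size), asw=float(s.mean()), sizes=sizes)


def scan_partitions(
    dendrogram: np.ndarray,
    matrix: DissimilarityMatrix | np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
) -> list[PartitionQuality]:
    """ASW and cluster sizes for each k in [k_min, k_max].

    Selection of the final partition stays a user decision, balancing
    homogeneity (ASW), cluster sizes, and interpretability.
    """
    n = dendrogram.shape[0] + 1
    out = []
    for k in range(k_min, min(k_max, n) + 1):
        labels = cut_tree(dendrogram, k)
        out.append(silhouette_asw(matrix, labels))
    return out
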