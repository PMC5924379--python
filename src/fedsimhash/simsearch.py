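"""Plaintext hash-code similarity search and kappa-NN prediction.

Per-domain similarity between two patients is the normalized inner product
of their +-1 code blocks, ``s_k = h_u^T h_v / b_k`` in [-1, 1]; the
overall similarity is the mean over the K domains, which both ranks
patients and says *why* they are similar (which domains agree). Ranking
for kappa-NN uses the hamming distance over the concatenated b = sum b_k
bits, linked to similarity by the identity ``s = 1 - 2 d_H / b``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fedsimhash.errors import ConfigurationError, DimensionError, FormatError


def _check_code(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h)
    if h.size and not np.all(np.isin(h, (-1, 1))):
        raise FormatError("hash codes must have entries in {-1, +1}")
    return h.astype(int)


@dataclass(frozen=True)
class SimilarityScore:
    """Overall similarity plus the per-domain breakdown (all in [-1, 1])."""

    value: float
    by_domain: dict[str, float]


@dataclass(frozen=True)
class NeighborResult:
    """kappa-NN outcome for one query: sorted neighbors and the vote."""

    query_id: str
    neighbors: tuple[tuple[str, int, float], ...]  # (ref id, d_H, similarity)
    vote_probability: float


def domain_similarity(h_u: np.ndarray, h_v: np.ndarray) -> float:
    """Normalized inner product of two single-domain codes: in [-1, 1]."""
    h_u, h_v = _check_code(h_u), _check_code(h_v)
    if h_u.shape != h_v.shape:
        raise DimensionError(f"code lengths differ: {h_u.shape} vs {h_v.shape}")
    b_k = h_u.size
    return float(h_u @ h_v) / b_k


def overall_similarity(
    codes_u: dict[str, np.ndarray], codes_v: dict[str, np.ndarray]
) -> SimilarityScore:
    """Mean of the K per-domain similarities."""
    if set(codes_u) != set(codes_v):
        raise DimensionError(f"domain sets differ: {sorted(codes_u)} vs {sorted(codes_v)}")
    by_domain = {tag: domain_similarity(codes_u[tag], codes_v[tag]) for tag in codes_u}
    return SimilarityScore(value=float(np.mean(list(by_domain.values()))), by_domain=by_domain)


def hamming_distance(h_u: np.ndarray, h_v: np.ndarray) -> int:
    """Number of positions where two +-1 codes differ."""
    h_u, h_v = _check_code(h_u), _check_code(h_v)
    if h_u.shape != h_v.shape:
        raise DimensionError(f"code lengths differ: {h_u.shape} vs {h_v.shape}")
    return int(np.sum(h_u != h_v))


def concatenated_hamming(
    codes_u: dict[str, np.ndarray], codes_v: dict[str, np.ndarray]
) -> int:
    """Hamming distance over the concatenated b = sum b_k bits."""
    if set(codes_u) != set(codes_v):
        raise DimensionError("domain sets differ")
    return sum(hamming_distance(codes_u[tag], codes_v[tag]) for tag in sorted(codes_u))


def knn_predict(
    query_codes: dict[str, np.ndarray],
    ref_codes: dict[str, np.ndarray],
    ref_ids: Sequence[str],
    ref_labels: Sequence[int],
    kappa: int,
    query_id: str = "query",
) -> NeighborResult:
    """kappa-NN vote over concatenated-hamming neighbors.

    ``ref_codes[tag]`` is a (b_k, N) matrix. The vote probability is the
    fraction of positive labels among the kappa nearest references;
    distance ties are broken by reference id ascending, which makes the
    result invariant to reference ordering.
    """
    if kappa < 1:
        raise ConfigurationError(f"kappa must be >= 1, got {kappa}")
    tags = sorted(ref_codes)
    if set(query_codes) != set(tags):
        raise DimensionError("query and reference domain sets differ")
    n = ref_codes[tags[0]].shape[1]
    if kappa > n:
        raise ConfigurationError(f"kappa={kappa} exceeds {n} references")
    q = np.concatenate([_check_code(np.ravel(query_codes[t])) for t in tags])
    refs = np.concatenate([_check_code(ref_codes[t]) for t in tags], axis=0)
    b = q.size
    dists = np.sum(refs != q[:, None], axis=0)
    order = sorted(range(n), key=lambda j: (dists[j], str(ref_ids[j])))
    labels = np.asarray(ref_labels, dtype=int)
    top = order[:kappa]
    neighbors = tuple(
        (str(ref_ids[j]), int(dists[j]), 1.0 - 2.0 * dists[j] / b) for j in order
    )
    vote = float(np.mean(labels[top]))
    return NeighborResult(query_id=query_id, neighbors=neighbors, vote_probability=vote)


def knn_vote_matrix(
    query_codes: dict[str, np.ndarray],
    ref_codes: dict[str, np.ndarray],
    ref_labels: Sequence[int],
    kappa: int,
) -> np.ndarray:
    """Vectorized kappa-NN vote probabilities for a batch of query columns.

    Same semantics as :func:`knn_predict` with reference ids taken as
    their column indices (so ties break by column order).
    """
    tags = sorted(ref_codes)
    Qm = np.concatenate([np.atleast_2d(query_codes[t]) for t in tags], axis=0)
    Rm = np.concatenate([np.atleast_2d(ref_codes[t]) for t in tags], axis=0)
    labels = np.asarray(ref_labels, dtype=float)
    b, nq = Qm.shape
    # d_H = (b - h_u . h_v) / 2 for +-1 codes
    inner = Rm.T @ Qm
    dists = (b - inner) / 2.0
    # stable argsort on distance = tie-break by reference index
    order = np.argsort(dists, axis=0, kind="stable")[:kappa]
    return labels[order].mean(axis=0)
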