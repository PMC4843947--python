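"""Structural path classification of region pairs.

A tractography-derived streamline-count matrix is binarized at a minimum
streamline threshold; every unordered region pair is then labelled by the
shortest path length between the two regions in the resulting undirected
unweighted graph:

====== ===================== ====
length meaning               code
====== ===================== ====
1      primary (direct)      1
2      secondary             2
3      tertiary              3
>= 4   higher-order          4
inf    disconnected          0
====== ===================== ====

The diagonal carries code 0 and is excluded from every tally. Streamline
counts are used only for thresholding: after binarization the graph is
undirected and unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .errors import ParameterError, ValidationError

DISCONNECTED, PRIMARY, SECONDARY, TERTIARY, HIGHER = 0, 1, 2, 3, 4
CLASS_NAMES = {
    PRIMARY: "primary",
    SECONDARY: "secondary",
    TERTIARY: "tertiary",
    HIGHER: "higher",
    DISCONNECTED: "disconnected",
}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}
# tie-break / reporting order: lower path order first, disconnected last
CLASS_ORDER = (PRIMARY, SECONDARY, TERTIARY, HIGHER, DISCONNECTED)


def binarize_streamlines(counts: np.ndarray, min_streamlines: int = 1) -> np.ndarray:
    """Binarize a streamline-count matrix at a minimum-count threshold.

    An edge is present iff ``counts[i, j] >= min_streamlines``. Raising
    the threshold can only remove edges (monotone).
    """
    if min_streamlines < 1:
        raise ParameterError("min_streamlines must be >= 1")
    counts = np.asarray(counts)
    _check_square_symmetric(counts)
    adj = (counts >= min_streamlines).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def classify_paths(adj: np.ndarray) -> np.ndarray:
    """Label every region pair by shortest structural path length.

    Breadth-first search from every node (unweighted shortest paths);
    disconnected pairs receive the ``disconnected`` label, never an
    exception.
    """
    adj = np.asarray(adj)
    _check_square_symmetric(adj)
    dist = shortest_path(adj != 0, method="D", unweighted=True, directed=False)
    pcm = np.full(adj.shape, HIGHER, dtype=np.int8)
    pcm[np.isinf(dist)] = DISCONNECTED
    pcm[dist == 1] = PRIMARY
    pcm[dist == 2] = SECONDARY
    pcm[dist == 3] = TERTIARY
    np.fill_diagonal(pcm, 0)
    return pcm


def _upper_values(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def apply_higher_policy(pcm: np.ndarray, policy: str) -> np.ndarray:
    """Return a copy with higher-order pairs merged into tertiary if asked."""
    if policy == "separate":
        return pcm
    if policy == "merge_into_tertiary":
        out = pcm.copy()
        out[out == HIGHER] = TERTIARY
        return out
    raise ParameterError(f"unknown higher_order_policy {policy!r}")


def path_class_proportions(pcm: np.ndarray, policy: str = "separate") -> dict[str, float]:
    """Proportion of each class over all N(N-1)/2 unordered pairs."""
    vals = _upper_values(apply_higher_policy(np.asarray(pcm), policy))
    n_pairs = vals.size
    props = {
        CLASS_NAMES[c]: float(np.count_nonzero(vals == c)) / n_pairs
        for c in CLASS_ORDER
    }
    if policy == "merge_into_tertiary":
        props.pop("higher")
    return props


def consensus_path_class(pcms: list[np.ndarray]) -> np.ndarray:
    """Per-pair modal class across subjects.

    Ties are broken toward the lower path order
    (primary < secondary < tertiary < higher < disconnected).
    """
    if not pcms:
        raise ParameterError("consensus requires at least one class matrix")
    stack = np.stack([np.asarray(p) for p in pcms])
    if not all(p.shape == stack[0].shape for p in stack):
        raise ValidationError("class matrices differ in size")
    n = stack.shape[1]
    out = np.zeros((n, n), dtype=np.int8)
    # iterate classes in tie-break order so the first argmax hit wins
    counts = np.stack([(stack == c).sum(axis=0) for c in CLASS_ORDER])
    winner = np.argmax(counts, axis=0)  # index into CLASS_ORDER
    out = np.array(CLASS_ORDER, dtype=np.int8)[winner]
    np.fill_diagonal(out, 0)
    return out


@dataclass
class AgreementResult:
    """Pairwise label agreement between two path-class matrices.

    ``per_class_union`` divides agreed pairs of a class by the pairs
    holding that label in either matrix; ``per_class_conditional``
    divides by the pairs holding it in the first matrix only. Both are
    reported because published agreement percentages rarely state the
    denominator.
    """

    n_pairs: int
    n_agreed: int
    fraction: float
    per_class_union: dict[str, float]
    per_class_conditional: dict[str, float]


def class_agreement(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Count region pairs labelled identically in two classifications."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    va, vb = _upper_values(a), _upper_values(b)
    agreed = va == vb
    union: dict[str, float] = {}
    cond: dict[str, float] = {}
    for c in CLASS_ORDER:
        in_a, in_b = va == c, vb == c
        both = int(np.count_nonzero(in_a & in_b))
        n_union = int(np.count_nonzero(in_a | in_b))
        union[CLASS_NAMES[c]] = both / n_union if n_union else float("nan")
        n_a = int(np.count_nonzero(in_a))
        cond[CLASS_NAMES[c]] = both / n_a if n_a else float("nan")
    return AgreementResult(
        n_pairs=int(va.size),
        n_agreed=int(np.count_nonzero(agreed)),
        fraction=float(np.count_nonzero(agreed)) / va.size,
        per_class_union=union,
        per_class_conditional=cond,
    )


def _check_square_symmetric(mat: np.ndarray) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"matrix is not square: shape {mat.shape}")
    if not np.array_equal(mat, mat.T):
        raise ValidationError("matrix is not symmetric")
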