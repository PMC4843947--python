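"""Functional Connectivity Entropy (FCE).

FCE is the Shannon entropy of the histogram of pairwise functional
connectivity values over a set of links: the probability that a link
drawn at random falls in each of B equal-width bins, plugged into
H = -sum p_k log p_k. Higher FCE means the strength of connectivity is
less predictable across the link set. Here the link set is either the
whole brain (all off-diagonal pairs) or one structural path class
(primary / secondary / tertiary / higher), so the statistic measures how
variable connectivity is *within* each level of structural constraint.

The plug-in (maximum-likelihood) estimator is the default; a
Miller-Madow bias correction (+ (K-1)/(2 n ln base) with K occupied
bins) is available because the tertiary stratum is small (~3% of 4,005
pairs, on the order of a hundred links).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .structural import (
    CLASS_NAMES,
    CLASS_ORDER,
    DISCONNECTED,
    HIGHER,
    TERTIARY,
    apply_higher_policy,
)

WHOLE_BRAIN = "whole_brain"


@dataclass(frozen=True)
class BinSpec:
    """Equal-width histogram bins over [lo, hi].

    Bins are left-closed, right-open, except the last which includes
    ``hi``.
    """

    n_bins: int = 100
    lo: float = -1.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if not self.lo < self.hi:
            raise ParameterError("bin range must satisfy lo < hi")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)


@dataclass
class FCEResult:
    """Entropy of one link stratum of one subject."""

    stratum: str
    entropy: float
    n_links: int
    bins: BinSpec
    defined: bool = True
    subject_id: str | None = None
    log_base: float = 2.0
    estimator: str = "plugin"
    transform: str = "raw_r"
    extra: dict = field(default_factory=dict)


def fc_histogram(values: np.ndarray, bins: BinSpec) -> np.ndarray:
    """Normalised histogram (probability vector) of FC values.

    Values outside [lo, hi] are an error, not silently clamped.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValidationError("cannot histogram an empty value list")
    out = values[(values < bins.lo) | (values > bins.hi)]
    if out.size:
        raise ValidationError(
            f"value {out[0]!r} outside bin range [{bins.lo}, {bins.hi}]"
        )
    counts, _ = np.histogram(values, bins=bins.edges)
    return counts / values.size


def shannon_entropy(p: np.ndarray, log_base: float = 2.0) -> float:
    """H = -sum p_k log(p_k); zero-mass bins contribute nothing."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValidationError("negative probability mass")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(log_base))).sum())


def entropy_of_values(
    values: np.ndarray,
    bins: BinSpec,
    log_base: float = 2.0,
    estimator: str = "plugin",
) -> float:
    """Histogram entropy of a value list, with optional bias correction."""
    p = fc_histogram(values, bins)
    h = shannon_entropy(p, log_base=log_base)
    if estimator == "miller_madow":
        k_occupied = int(np.count_nonzero(p))
        h += (k_occupied - 1) / (2.0 * len(np.ravel(values)) * np.log(log_base))
    elif estimator != "plugin":
        raise ParameterError(f"unknown estimator {estimator!r}")
    return h


def stratum_values(fc: np.ndarray, pcm: np.ndarray, stratum: str, policy: str = "separate") -> np.ndarray:
    """FC values of the upper-triangle pairs belonging to one stratum.

    ``whole_brain`` takes every off-diagonal pair regardless of class
    (including disconnected); class strata exclude disconnected pairs.
    """
    fc, pcm = np.asarray(fc), np.asarray(pcm)
    if fc.shape != pcm.shape:
        raise ValidationError(f"FC {fc.shape} and class matrix {pcm.shape} differ")
    iu = np.triu_indices(fc.shape[0], k=1)
    if stratum == WHOLE_BRAIN:
        return fc[iu]
    pcm = apply_higher_policy(pcm, policy)
    try:
        code = {v: k for k, v in CLASS_NAMES.items()}[stratum]
    except KeyError:
        raise ParameterError(f"unknown stratum {stratum!r}") from None
    mask = pcm[iu] == code
    return fc[iu][mask]


def fce_by_stratum(
    fc: np.ndarray,
    pcm: np.ndarray,
    bins: BinSpec = BinSpec(),
    policy: str = "separate",
    log_base: float = 2.0,
    estimator: str = "plugin",
    subject_id: str | None = None,
    transform: str = "raw_r",
) -> list[FCEResult]:
    """FCE of the whole brain and of every structural path class.

    Strata with fewer than 2 links yield a flagged undefined result
    (``defined=False``, NaN entropy) rather than an exception; such
    rows are excluded from group statistics downstream.
    """
    strata = [WHOLE_BRAIN] + [
        CLASS_NAMES[c] for c in CLASS_ORDER if c != DISCONNECTED
    ]
    if policy == "merge_into_tertiary":
        strata.remove(CLASS_NAMES[HIGHER])
    results = []
    for stratum in strata:
        vals = stratum_values(fc, pcm, stratum, policy=policy)
        if vals.size < 2:
            results.append(
                FCEResult(
                    stratum=stratum,
                    entropy=float("nan"),
                    n_links=int(vals.size),
                    bins=bins,
                    defined=False,
                    subject_id=subject_id,
                    log_base=log_base,
                    estimator=estimator,
                    transform=transform,
                )
            )
            continue
        h = entropy_of_values(vals, bins, log_base=log_base, estimator=estimator)
        results.append(
            FCEResult(
                stratum=stratum,
                entropy=h,
                n_links=int(vals.size),
                bins=bins,
                defined=True,
                subject_id=subject_id,
                log_base=log_base,
                estimator=estimator,
                transform=transform,
            )
        )
    return results
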