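"""Functional connectivity from regional time series.

Pearson product-moment correlation between every pair of regional BOLD
series; inputs are assumed fully preprocessed (band-pass, nuisance
regression are upstream). An optional value transform (|r| or Fisher z)
is applied before entropy estimation.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError, ValidationError

FISHER_CLIP = 1.0 - 1e-7


def pearson_fc(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a T x N time-series table.

    Symmetrized by averaging with its transpose; unit diagonal.
    Raises if any region has zero variance (correlation undefined).
    """
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2:
        raise ValidationError("time series must be a T x N table")
    if ts.shape[0] < 3:
        raise ValidationError("need at least 3 time points for a correlation")
    if not np.all(np.isfinite(ts)):
        raise ValidationError("time series contains non-finite values")
    sd = ts.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(f"zero-variance region(s): {flat.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def transform_fc(fc: np.ndarray, transform: str = "raw_r") -> np.ndarray:
    """Map correlation values onto the scale entering the histogram.

    ``raw_r`` is the identity, ``abs_r`` the elementwise absolute value,
    ``fisher_z`` atanh with |r| clipped to 1 - 1e-7.
    """
    fc = np.asarray(fc, dtype=np.float64)
    if transform == "raw_r":
        return fc
    if transform == "abs_r":
        return np.abs(fc)
    if transform == "fisher_z":
        return np.arctanh(np.clip(fc, -FISHER_CLIP, FISHER_CLIP))
    raise ParameterError(f"unknown fc transform {transform!r}")
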