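"""Pipeline configuration: the analysis choices the method leaves open.

Every run is parameterised by a :class:`PipelineConfig`; the effective
configuration is written next to the outputs so that the streamline
threshold, the histogram bin scheme and the entropy base used for a given
result are always recoverable.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError

HIGHER_ORDER_POLICIES = ("separate", "merge_into_tertiary")
RESIDUALIZE_MODES = ("per_group", "pooled")
FC_TRANSFORMS = ("raw_r", "abs_r", "fisher_z")
ESTIMATORS = ("plugin", "miller_madow")


@dataclass
class PipelineConfig:
    """Tunable parameters of the path-class / entropy pipeline.

    Parameters
    ----------
    min_streamlines:
        Smallest streamline count treated as a structural edge when
        binarizing the tractography matrix. The base definition is 1
        ("one or more streamlines"); 1-3 is the sensitivity sweep.
    n_bins, bin_lo, bin_hi:
        Equal-width histogram over ``[bin_lo, bin_hi]`` used for the
        entropy of the connectivity distribution.
    log_base:
        Entropy logarithm base; 2 gives bits.
    duration_cutoff:
        Illness-duration split (years) between early and late stage.
    higher_order_policy:
        How pairs at shortest path length >= 4 are treated: kept as a
        distinct ``higher`` stratum, or merged into tertiary.
    fc_transform:
        Value scale entering the histogram: raw Pearson r, |r|, or
        Fisher z.
    estimator:
        ``plugin`` maximum-likelihood entropy, or ``miller_madow`` with
        the (K-1)/(2n) small-sample bias correction.
    residualize_mode:
        ``per_group`` removes age/sex/dose within each group with a
        degrees-of-freedom variance correction (calibrated group tests);
        ``pooled`` fits one regression across all subjects. Pooled
        coding lets the dose column — zero for every control — absorb
        part of any true group difference, which makes the group test
        conservative; it is kept for comparability.
    seed:
        RNG seed for any stochastic step (simulation, permutations).
    """

    min_streamlines: int = 1
    n_bins: int = 100
    bin_lo: float = -1.0
    bin_hi: float = 1.0
    log_base: float = 2.0
    duration_cutoff: float = 5.0
    higher_order_policy: str = "separate"
    fc_transform: str = "raw_r"
    estimator: str = "plugin"
    residualize_mode: str = "per_group"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_streamlines < 1:
            raise ParameterError("min_streamlines must be >= 1")
        if self.min_streamlines > 3:
            warnings.warn(
                "min_streamlines outside the usual 1-3 sensitivity range",
                stacklevel=2,
            )
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if not self.bin_lo < self.bin_hi:
            raise ParameterError("bin range must satisfy lo < hi")
        if self.log_base <= 1.0:
            raise ParameterError("log_base must be > 1")
        if self.higher_order_policy not in HIGHER_ORDER_POLICIES:
            raise ParameterError(
                f"higher_order_policy must be one of {HIGHER_ORDER_POLICIES}"
            )
        if self.fc_transform not in FC_TRANSFORMS:
            raise ParameterError(f"fc_transform must be one of {FC_TRANSFORMS}")
        if self.estimator not in ESTIMATORS:
            raise ParameterError(f"estimator must be one of {ESTIMATORS}")
        if self.residualize_mode not in RESIDUALIZE_MODES:
            raise ParameterError(f"residualize_mode must be one of {RESIDUALIZE_MODES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        """Write the effective configuration as a flat YAML mapping."""
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"config file {path} is not a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
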