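"""End-to-end orchestration: raw matrices -> path classes -> FCE -> stats.

Functions here accept plain mappings ``subject_id -> ndarray`` so the
same code path serves in-memory synthetic cohorts and matrices loaded
from disk.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .entropy import BinSpec, fce_by_stratum
from .fc import pearson_fc, transform_fc
from .stats import run_full_comparison
from .structural import (
    binarize_streamlines,
    class_agreement,
    classify_paths,
    consensus_path_class,
    path_class_proportions,
)


def classify_cohort(
    streamlines: Mapping[str, np.ndarray], min_streamlines: int = 1
) -> dict[str, np.ndarray]:
    """Binarize and path-classify every subject's streamline matrix."""
    return {
        sid: classify_paths(binarize_streamlines(counts, min_streamlines))
        for sid, counts in streamlines.items()
    }


def fc_cohort(
    timeseries: Mapping[str, np.ndarray], transform: str = "raw_r"
) -> dict[str, np.ndarray]:
    """Per-subject transformed functional-connectivity matrices."""
    return {sid: transform_fc(pearson_fc(ts), transform) for sid, ts in timeseries.items()}


def compute_fce_table(
    fcs: Mapping[str, np.ndarray],
    pcms: Mapping[str, np.ndarray],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Long table of per-subject, per-stratum entropies.

    Columns: subject_id, stratum, entropy_bits, n_links, defined,
    n_bins, bin_lo, bin_hi, transform, estimator.
    """
    config = config or PipelineConfig()
    bins = BinSpec(config.n_bins, config.bin_lo, config.bin_hi)
    rows = []
    for sid in fcs:
        for res in fce_by_stratum(
            fcs[sid],
            pcms[sid],
            bins=bins,
            policy=config.higher_order_policy,
            log_base=config.log_base,
            estimator=config.estimator,
            subject_id=sid,
            transform=config.fc_transform,
        ):
            rows.append(
                {
                    "subject_id": sid,
                    "stratum": res.stratum,
                    "entropy_bits": res.entropy,
                    "n_links": res.n_links,
                    "defined": res.defined,
                    "n_bins": bins.n_bins,
                    "bin_lo": bins.lo,
                    "bin_hi": bins.hi,
                    "transform": res.transform,
                    "estimator": res.estimator,
                }
            )
    return pd.DataFrame(rows)


def run_study(
    table: pd.DataFrame,
    streamlines: Mapping[str, np.ndarray],
    timeseries: Mapping[str, np.ndarray],
    config: PipelineConfig | None = None,
) -> dict:
    """Full pipeline on one cohort; returns the intermediate artifacts.

    Keys: ``pcms``, ``fcs``, ``fce_table``, ``report``, plus group
    consensus class matrices and their agreement.
    """
    config = config or PipelineConfig()
    pcms = classify_cohort(streamlines, config.min_streamlines)
    fcs = fc_cohort(timeseries, config.fc_transform)
    fce_table = compute_fce_table(fcs, pcms, config)
    report = run_full_comparison(table, fce_table, config)
    patients = table.loc[table["group"] == "patient", "subject_id"]
    controls = table.loc[table["group"] == "control", "subject_id"]
    out: dict = {
        "pcms": pcms,
        "fcs": fcs,
        "fce_table": fce_table,
        "report": report,
        "config": config,
    }
    if len(patients) and len(controls):
        cons_p = consensus_path_class([pcms[s] for s in patients])
        cons_c = consensus_path_class([pcms[s] for s in controls])
        out["consensus_patient"] = cons_p
        out["consensus_control"] = cons_c
        out["consensus_agreement"] = class_agreement(cons_c, cons_p)
        out["proportions_control"] = _mean_proportions(
            [pcms[s] for s in controls], config.higher_order_policy
        )
        out["proportions_patient"] = _mean_proportions(
            [pcms[s] for s in patients], config.higher_order_policy
        )
    return out


def _mean_proportions(pcms: list[np.ndarray], policy: str) -> dict[str, float]:
    """Per-subject class proportions averaged over a group."""
    dicts = [path_class_proportions(p, policy) for p in pcms]
    return {k: float(np.mean([d[k] for d in dicts])) for k in dicts[0]}


@dataclass
class ThresholdSensitivity:
    """Re-analysis under each minimum-streamline threshold."""

    thresholds: tuple[int, ...]
    proportions: dict[int, dict[str, float]]  # mean per-subject class mix
    reports: dict[int, pd.DataFrame]
    agreement: pd.DataFrame  # mean per-subject pairwise class agreement


def threshold_sensitivity(
    table: pd.DataFrame,
    streamlines: Mapping[str, np.ndarray],
    timeseries: Mapping[str, np.ndarray],
    config: PipelineConfig | None = None,
    thresholds: tuple[int, ...] = (1, 2, 3),
) -> ThresholdSensitivity:
    """Rerun classification -> FCE -> comparison at each threshold.

    FC matrices are computed once; only the structural side changes
    with the threshold. The agreement table holds, for each pair of
    thresholds, the mean over subjects of the fraction of region pairs
    keeping the same class.
    """
    config = config or PipelineConfig()
    fcs = fc_cohort(timeseries, config.fc_transform)
    pcms_by_t = {t: classify_cohort(streamlines, t) for t in thresholds}
    proportions, reports = {}, {}
    for t in thresholds:
        pcms = pcms_by_t[t]
        proportions[t] = _mean_proportions(list(pcms.values()), config.higher_order_policy)
        fce_table = compute_fce_table(fcs, pcms, config)
        reports[t] = run_full_comparison(table, fce_table, config)
    rows = []
    for t1, t2 in combinations(thresholds, 2):
        fracs = [
            class_agreement(pcms_by_t[t1][sid], pcms_by_t[t2][sid]).fraction
            for sid in streamlines
        ]
        rows.append({"threshold_a": t1, "threshold_b": t2, "mean_agreement": float(np.mean(fracs))})
    return ThresholdSensitivity(
        thresholds=tuple(thresholds),
        proportions=proportions,
        reports=reports,
        agreement=pd.DataFrame(rows),
    )
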