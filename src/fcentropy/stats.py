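"""Group statistics on per-subject FCE values.

The analysis mirrors a standard case-control neuroimaging workflow:
per-subject stratum entropies are residualized against age, sex and
antipsychotic dose by ordinary least squares (grand mean re-added so
group means stay on the entropy scale), patients are split into early
and late illness-duration strata, each patient stratum is compared with
its control set by a two-sample t test with Cohen's d, and entropy is
correlated with total symptom score within each patient stratum. No
multiple-testing correction is applied; the report carries the number
of tests run so users can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .errors import ParameterError, ValidationError

FCE_STRATA_DEFAULT = ("whole_brain", "primary", "secondary", "tertiary")


def residualize(
    values: np.ndarray, covariates: np.ndarray, df_correct: bool = False
) -> np.ndarray:
    """OLS residuals of ``values`` on covariate columns, plus grand mean.

    The design gets an intercept; residuals are orthogonal to every
    covariate column, and the grand mean is re-added so that group means
    of the residualized values remain interpretable on the original
    scale. An all-constant covariate column (e.g. dose when only
    controls are present) is dropped rather than treated as collinear
    with the intercept.

    With ``df_correct`` the centred residuals are rescaled by
    sqrt((n-1)/(n-k)) for k fitted parameters, so their sample variance
    is an unbiased estimate of the noise variance — needed when a
    two-sample test is run on residuals fitted within each group.
    """
    y = np.asarray(values, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if X.shape[0] != y.size:
        X = X.T
    if X.shape[0] != y.size:
        raise ValidationError("covariate rows do not match number of subjects")
    keep = np.ptp(X, axis=0) > 0
    X = X[:, keep]
    design = np.column_stack([np.ones_like(y), X])
    if y.size < X.shape[1] + 2:
        raise ParameterError(
            f"need at least {X.shape[1] + 2} subjects for {X.shape[1]} covariates"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValidationError(f"rank-deficient covariate design; collinear columns {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if df_correct:
        resid = resid * np.sqrt((y.size - 1) / (y.size - design.shape[1]))
    return resid + y.mean()


def _collinear_columns(design: np.ndarray) -> list[int]:
    bad = []
    for j in range(1, design.shape[1]):
        others = np.delete(design, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, design[:, j], rcond=None)
        if np.allclose(others @ proj, design[:, j]):
            bad.append(j - 1)  # covariate index, intercept excluded
    return bad


@dataclass
class GroupComparison:
    """Two-sample comparison of one FCE stratum."""

    stratum: str
    mean_control: float
    mean_patient: float
    t_stat: float
    p_value: float
    cohen_d: float
    direction: int  # sign of mean_patient - mean_control
    n_control: int
    n_patient: int


def compare_groups(
    control: np.ndarray,
    patient: np.ndarray,
    stratum: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Student t test (pooled variance by default) and Cohen's d.

    d is the absolute standardized mean difference with the pooled
    (n-1) standard deviation; the direction of the difference is carried
    separately as the sign of (patient mean - control mean).
    """
    x = np.asarray(control, dtype=np.float64).ravel()
    y = np.asarray(patient, dtype=np.float64).ravel()
    if x.size < 2 or y.size < 2:
        raise ParameterError("each group needs at least 2 subjects")
    sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
    pooled = np.sqrt(((x.size - 1) * sx2 + (y.size - 1) * sy2) / (x.size + y.size - 2))
    if pooled == 0:
        raise ValidationError("zero pooled variance: groups are both constant")
    t, p = sps.ttest_ind(y, x, equal_var=not welch)
    diff = y.mean() - x.mean()
    return GroupComparison(
        stratum=stratum,
        mean_control=float(x.mean()),
        mean_patient=float(y.mean()),
        t_stat=float(t),
        p_value=float(p),
        cohen_d=float(abs(diff) / pooled),
        direction=int(np.sign(diff)),
        n_control=int(x.size),
        n_patient=int(y.size),
    )


def correlate_with_symptoms(fce: np.ndarray, sspi: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of patient FCE with total symptom score.

    p is two-tailed from the t transform of r with n-2 degrees of
    freedom.
    """
    x = np.asarray(fce, dtype=np.float64).ravel()
    y = np.asarray(sspi, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValidationError("FCE and symptom vectors differ in length")
    if x.size < 3:
        raise ParameterError("need at least 3 patients for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def add_duration_stratum(cohort: pd.DataFrame, cutoff: float = 5.0) -> pd.DataFrame:
    """Label patients early (< cutoff years) or late (>= cutoff)."""
    out = cohort.copy()
    is_patient = out["group"] == "patient"
    out["duration_stratum"] = pd.NA
    out.loc[is_patient & (out["duration"] < cutoff), "duration_stratum"] = "early"
    out.loc[is_patient & (out["duration"] >= cutoff), "duration_stratum"] = "late"
    return out


def _covariate_design(sub: pd.DataFrame) -> np.ndarray:
    sex = (sub["sex"] == "M").astype(float).to_numpy()
    return np.column_stack(
        [sub["age"].to_numpy(float), sex, sub["dose"].fillna(0.0).to_numpy(float)]
    )


def run_full_comparison(
    cohort: pd.DataFrame,
    fce_table: pd.DataFrame,
    config: PipelineConfig | None = None,
    fce_strata: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Residualized group comparisons and symptom correlations.

    For each illness-duration stratum (early / late) against its control
    set and for each FCE stratum, FCE is residualized on age, sex and
    dose pooled over the subjects entering that comparison, compared
    between groups, and correlated with the symptom score among
    patients. A duration stratum with fewer than 2 patients is flagged
    (``ok = False``) and the other blocks still run.

    ``fce_table`` needs columns subject_id, stratum, entropy (or
    entropy_bits) and optionally ``defined``. If the cohort carries a
    ``control_subset`` column ({early, late, both}), each comparison
    uses only the controls matched to that duration stratum.
    """
    config = config or PipelineConfig()
    fce_table = fce_table.rename(columns={"entropy_bits": "entropy"})
    known = set(fce_table["subject_id"])
    absent = sorted(set(cohort["subject_id"]) - known)
    if absent:
        raise ValidationError(f"subjects missing from FCE table: {absent}")
    if "defined" in fce_table.columns:
        fce_table = fce_table[fce_table["defined"].astype(bool)]
    cohort = add_duration_stratum(cohort, cutoff=config.duration_cutoff)
    if fce_strata is None:
        present = fce_table["stratum"].unique().tolist()
        fce_strata = tuple(s for s in FCE_STRATA_DEFAULT if s in present)

    rows = []
    for dur in ("early", "late"):
        patients = cohort[(cohort["group"] == "patient") & (cohort["duration_stratum"] == dur)]
        controls = cohort[cohort["group"] == "control"]
        if "control_subset" in cohort.columns:
            controls = controls[controls["control_subset"].isin([dur, "both"])]
        for stratum in fce_strata:
            # subjects whose entropy is undefined for this stratum
            # (fewer than 2 links) are dropped from this block only
            ent_all = fce_table[fce_table["stratum"] == stratum].set_index("subject_id")["entropy"]
            sub = pd.concat([controls, patients])
            sub = sub[sub["subject_id"].isin(ent_all.index)]
            n_c = int((sub["group"] == "control").sum())
            n_p = int((sub["group"] == "patient").sum())
            ok = n_c >= 2 and n_p >= 2
            row: dict = {
                "duration_stratum": dur,
                "stratum": stratum,
                "ok": ok,
                "n_control": n_c,
                "n_patient": n_p,
            }
            if ok:
                ent = ent_all.reindex(sub["subject_id"]).to_numpy()
                design = _covariate_design(sub)
                is_pat = (sub["group"] == "patient").to_numpy()
                try:
                    if config.residualize_mode == "per_group":
                        resid = np.empty_like(ent)
                        for mask in (is_pat, ~is_pat):
                            resid[mask] = residualize(
                                ent[mask], design[mask], df_correct=True
                            )
                    else:
                        resid = residualize(ent, design)
                except ParameterError as exc:
                    # a group too small to support its covariate fit is
                    # flagged, not fatal to the other blocks
                    row["ok"] = False
                    row["note"] = str(exc)
                    rows.append(row)
                    continue
                cmp_ = compare_groups(resid[~is_pat], resid[is_pat], stratum=stratum)
                row.update(
                    mean_control=cmp_.mean_control,
                    mean_patient=cmp_.mean_patient,
                    t_stat=cmp_.t_stat,
                    p_value=cmp_.p_value,
                    cohen_d=cmp_.cohen_d,
                    direction=cmp_.direction,
                )
                sspi = sub.loc[is_pat, "symptom_score"].to_numpy(float)
                pat_resid = resid[is_pat]
                if n_p >= 3 and np.ptp(sspi) > 0 and np.ptp(pat_resid) > 0:
                    r, p = correlate_with_symptoms(pat_resid, sspi)
                    row.update(symptom_r=r, symptom_p=p)
            rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["n_tests"] = int(report["ok"].sum())
    report.attrs["config"] = config.to_dict()
    return report


def permutation_null_rate(
    cohort: pd.DataFrame,
    fce_table: pd.DataFrame,
    config: PipelineConfig | None = None,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Empirical type-I error rate under label permutation.

    Subject metadata rows (group, duration, covariates, symptoms) are
    randomly reassigned to subjects' entropy profiles; the full
    comparison is rerun per permutation and the fraction of nominal
    ``p < alpha`` results returned. On a cohort with no designed group
    effects this estimates the size of the test battery.
    """
    rng = np.random.default_rng(rng)
    ids = cohort["subject_id"].to_numpy()
    hits, total = 0, 0
    for _ in range(n_permutations):
        perm = cohort.copy()
        perm["subject_id"] = rng.permutation(ids)
        rep = run_full_comparison(perm, fce_table, config)
        p = rep.loc[rep["ok"], "p_value"].to_numpy()
        hits += int((p < alpha).sum())
        total += p.size
    return hits / total
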