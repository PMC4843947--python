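"""Synthetic cohort generator with known ground truth.

Every stage of the pipeline is testable without imaging data: the
generator produces, per subject, (i) a structural streamline-count
matrix from a spatial random-graph model, (ii) regional time series
drawn from a Gaussian whose correlation structure is organised by the
subject's own structural path classes, and (iii) metadata (group, age,
sex, dose, illness duration, symptom score) with designed group and
covariate effects.

Structural model
----------------
Nodes are placed uniformly in the unit cube; the probability of an edge
between nodes i and j is ``min(1, c * a_i a_j * exp(-d_ij / decay))``
where d_ij is Euclidean distance and a_i are lognormal node
propensities. The global scale c is calibrated by bisection so the
realized edge density (the primary-pair fraction) matches the target.
The propensity spread creates weakly connected peripheral nodes, which
is what produces a realistic few percent of tertiary (path length 3)
pairs; a pure distance-decay graph at the same density has almost none.
Within a cohort the template (positions, propensities, probabilities)
is shared and each subject is an independent Bernoulli realization of
it, so path classes are highly — not perfectly — consistent across
subjects. Components are bridged through their spatially closest pair
so every network is connected. Streamline counts on present edges are
negative binomial (floored at 1).

Functional model
----------------
Per-pair target correlations are drawn from Normal(mu_class,
sigma_class) truncated to (-0.99, 0.99) — direct pairs strongest, then
secondary, then tertiary — then the matrix is projected to the nearest
symmetric positive-definite correlation matrix (eigenvalue clipping and
re-normalisation to unit diagonal). sigma_class is the entropy handle:
widening the class's correlation distribution raises that stratum's
FCE. Group membership, age, sex, dose and a latent per-patient severity
all shift sigma_class linearly; severity also generates the symptom
score, so entropy-symptom correlations of a configured sign are
recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .structural import classify_paths
from . import io as fio

CLASS_STRATA = ("primary", "secondary", "tertiary")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the cohort the method was designed for: a
    90-region parcellation whose pair classes split roughly 28% primary
    / 69% secondary / 3% tertiary, 32 controls and 34 patients (split
    17 early / 17 late stage at the 5-year duration cutoff), age about
    34 +/- 9 years, mostly-male samples, chlorpromazine-equivalent
    doses of a few hundred mg/day for patients, and a mean total
    symptom score near 12. The per-class sigma shifts encode the
    designed group effects: early-stage secondary widening + tertiary
    narrowing, late-stage narrowing of every class with tertiary by far
    the largest.
    """

    n_regions: int = 90
    n_timepoints: int = 240
    n_controls: int = 32
    n_early: int = 17
    n_late: int = 17
    # structural model
    target_primary: float = 0.278
    propensity_sigma: float = 0.8
    distance_decay: float = 0.25
    streamline_mean: float = 30.0
    streamline_dispersion: float = 0.5
    # functional model: class means (direct > one-step > two-step)
    mu: dict = field(
        default_factory=lambda: {"primary": 0.45, "secondary": 0.25, "tertiary": 0.10}
    )
    # control-group spread per class (the entropy handle)
    sigma: dict = field(
        default_factory=lambda: {"primary": 0.075, "secondary": 0.075, "tertiary": 0.17}
    )
    # designed group effects: additive shifts of sigma per class.
    # Early stage: secondary widening, tertiary narrowing, primary null;
    # late stage: every class narrows, tertiary by far the most.
    early_shift: dict = field(
        default_factory=lambda: {"primary": 0.0, "secondary": 0.016, "tertiary": -0.026}
    )
    late_shift: dict = field(
        default_factory=lambda: {"primary": -0.010, "secondary": -0.013, "tertiary": -0.092}
    )
    # linear nuisance effects of covariates on every class sigma
    age_slope: float = -3.0e-4  # per year, centred at age 34
    sex_slope: float = 5.0e-3  # male vs female
    dose_slope: float = -2.0e-6  # per CPZ-equivalent mg/day
    # latent severity: sigma coupling (per group) and symptom loading.
    # Coupling acts on the listed classes only: the tertiary narrowing is
    # designed as severity-invariant, with symptom burden tracking the
    # structurally constrained (primary/secondary) spreads.
    severity_coupling_early: float = 0.015
    severity_coupling_late: float = -0.015
    severity_coupling_classes: tuple = ("primary", "secondary")
    sspi_loading: float = 0.8
    sspi_mean: float = 11.8
    sspi_sd: float = 7.7
    # covariate marginals
    age_mean: float = 34.0
    age_sd: float = 9.0
    male_fraction: float = 0.72
    dose_log_mean: float = 6.0  # log CPZ mg/day
    dose_log_sd: float = 0.9
    sigma_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_primary <= 1.0:
            raise ParameterError("target_primary must lie in (0, 1]")
        for name in CLASS_STRATA:
            if not -1.0 < self.mu[name] < 1.0:
                raise ParameterError(f"mu[{name}] must lie in (-1, 1)")
            if self.sigma[name] <= 0:
                raise ParameterError(f"sigma[{name}] must be positive")
        if self.n_timepoints < 3:
            raise ParameterError("n_timepoints must be >= 3")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _calibrate_scale(base: np.ndarray, target: float) -> float:
    """Bisection on the global probability scale c so that the expected
    edge density mean(min(1, c*base)) equals the target."""
    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if np.mean(np.minimum(1.0, mid * base)) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _bridge_components(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Connect disconnected components through their closest node pair."""
    from scipy.sparse.csgraph import connected_components

    adj = adj.copy()
    while True:
        n_comp, labels = connected_components(adj != 0, directed=False)
        if n_comp == 1:
            return adj
        main = labels == np.bincount(labels).argmax()
        other = ~main
        sub = dist[np.ix_(other, main)]
        i_o, j_m = np.unravel_index(np.argmin(sub), sub.shape)
        i = np.flatnonzero(other)[i_o]
        j = np.flatnonzero(main)[j_m]
        adj[i, j] = adj[j, i] = 1


def network_template(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cohort-level anatomy: per-pair edge probabilities and distances.

    Node positions and connection propensities define a shared template;
    individual subjects are independent Bernoulli realizations of the
    same probabilities, which is what makes path classes largely (but
    not perfectly) consistent across subjects and groups.
    """
    n = config.n_regions
    pos = rng.uniform(size=(n, 3))
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    prop = rng.lognormal(0.0, config.propensity_sigma, size=n)
    iu = np.triu_indices(n, k=1)
    base = np.outer(prop, prop)[iu] * np.exp(-dist[iu] / config.distance_decay)
    scale = _calibrate_scale(base, config.target_primary)
    p_edge = np.minimum(1.0, scale * base)
    return p_edge, dist


def realize_network(
    p_edge: np.ndarray,
    dist: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's streamline-count matrix and true path-class matrix
    drawn from a template's edge probabilities."""
    n = config.n_regions
    iu = np.triu_indices(n, k=1)
    edge = rng.uniform(size=p_edge.shape) < p_edge
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu] = edge
    adj += adj.T
    adj = _bridge_components(adj, dist)
    # negative-binomial streamline counts on present edges, floored at 1
    k = config.streamline_dispersion
    p_nb = k / (k + config.streamline_mean)
    counts = np.zeros((n, n), dtype=np.int64)
    present = np.flatnonzero(adj[iu])
    draws = np.maximum(1, rng.negative_binomial(k, p_nb, size=present.size))
    vals = np.zeros(iu[0].size, dtype=np.int64)
    vals[present] = draws
    counts[iu] = vals
    counts += counts.T
    return counts, classify_paths(adj)


def generate_structural_network(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A standalone subject: fresh template plus one realization."""
    p_edge, dist = network_template(config, rng)
    return realize_network(p_edge, dist, config, rng)


def _class_params(pcm_codes: np.ndarray, per_class: dict) -> np.ndarray:
    """Map per-pair class codes to parameter values; higher-order and
    disconnected pairs fall back to the tertiary value."""
    lut = np.empty(5)
    lut[0] = per_class.get("disconnected", per_class["tertiary"])
    lut[1] = per_class["primary"]
    lut[2] = per_class["secondary"]
    lut[3] = per_class["tertiary"]
    lut[4] = per_class.get("higher", per_class["tertiary"])
    return lut[pcm_codes]


def draw_target_correlations(
    pcm: np.ndarray, mu: dict, sigma: dict, rng: np.random.Generator
) -> np.ndarray:
    """Per-pair target correlations Normal(mu_class, sigma_class),
    truncated to (-0.99, 0.99) by redraw; unit diagonal, symmetric."""
    pcm = np.asarray(pcm)
    n = pcm.shape[0]
    iu = np.triu_indices(n, k=1)
    m = _class_params(pcm[iu], mu)
    s = _class_params(pcm[iu], sigma)
    vals = rng.normal(m, s)
    for _ in range(20):
        out = (vals <= -0.99) | (vals >= 0.99)
        if not out.any():
            break
        vals[out] = rng.normal(m[out], s[out])
    vals = np.clip(vals, -0.989, 0.989)
    target = np.eye(n)
    target[iu] = vals
    return target + target.T - np.eye(n)


def build_target_covariance(
    pcm: np.ndarray,
    mu: dict,
    sigma: dict,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Class-structured correlation matrix, projected to SPD.

    Off-diagonal targets are Normal(mu_class, sigma_class) truncated to
    (-0.99, 0.99); eigenvalues are clipped at 1e-6 and the result
    re-normalised to unit diagonal. Returns the matrix and the mean
    absolute off-diagonal change introduced by the projection.
    """
    target = draw_target_correlations(pcm, mu, sigma, rng)
    n = target.shape[0]
    iu = np.triu_indices(n, k=1)
    w, v = np.linalg.eigh(target)
    w = np.maximum(w, 1e-6)
    proj = (v * w) @ v.T
    d = np.sqrt(np.diag(proj))
    proj = proj / np.outer(d, d)
    proj = 0.5 * (proj + proj.T)
    if np.linalg.eigvalsh(proj).min() <= 0:
        raise ValidationError("SPD projection failed to produce a positive matrix")
    distortion = float(np.mean(np.abs(proj[iu] - target[iu])))
    return proj, distortion


def sample_timeseries(
    cov: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """T i.i.d. draws from a zero-mean Gaussian with the given covariance."""
    cov = np.asarray(cov, dtype=np.float64)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("covariance is not symmetric positive definite") from exc
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    return z @ chol.T


@dataclass
class Cohort:
    """In-memory synthetic cohort plus its ground truth."""

    table: pd.DataFrame
    streamlines: dict[str, np.ndarray]
    timeseries: dict[str, np.ndarray]
    truth: dict
    config: SimulationConfig
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_cohort(out / "cohort.csv", self.table)
        for sid, counts in self.streamlines.items():
            fio.write_matrix(out / f"streamlines_{sid}.tsv", counts, integer=True)
        for sid, ts in self.timeseries.items():
            fio.write_matrix(out / f"timeseries_{sid}.tsv", ts)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for sid, pcm in self.truth["path_class"].items():
            fio.write_matrix(truth_dir / f"path_class_{sid}.tsv", pcm, integer=True)
        scalars = {
            "seed": self.seed,
            "class_sigma": {
                sid: {k: float(v) for k, v in d.items()}
                for sid, d in self.truth["class_sigma"].items()
            },
            "severity": {k: float(v) for k, v in self.truth["severity"].items()},
            "projection_distortion": {
                k: float(v) for k, v in self.truth["projection_distortion"].items()
            },
        }
        (truth_dir / "truth.json").write_text(json.dumps(scalars, indent=1))
        cfg = {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in self.config.to_dict().items()
        }
        (out / "simulation_config.json").write_text(json.dumps(cfg, indent=1))


def _subject_sigma(config: SimulationConfig, group: str, stage: str | None,
                   age: float, male: int, dose: float, severity: float) -> dict:
    shift = {"primary": 0.0, "secondary": 0.0, "tertiary": 0.0}
    coupling = 0.0
    if stage == "early":
        shift = config.early_shift
        coupling = config.severity_coupling_early
    elif stage == "late":
        shift = config.late_shift
        coupling = config.severity_coupling_late
    nuisance = (
        config.age_slope * (age - config.age_mean)
        + config.sex_slope * male
        + config.dose_slope * dose
    )
    return {
        c: max(
            config.sigma_floor,
            config.sigma[c]
            + shift.get(c, 0.0)
            + nuisance
            + (coupling * severity if c in config.severity_coupling_classes else 0.0),
        )
        for c in CLASS_STRATA
    }


def generate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort with designed group effects.

    All subjects share one anatomical template (node positions and
    connection propensities); each gets their own Bernoulli realisation
    of its edge probabilities, so path classes are highly but not
    perfectly consistent across subjects. The class-structured
    covariance uses the subject's true path classes with sigmas shifted
    by group, covariates and latent severity.
    """
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    p_edge, dist = network_template(config, rng)
    plan = (
        [("control", None)] * config.n_controls
        + [("patient", "early")] * config.n_early
        + [("patient", "late")] * config.n_late
    )
    rows = []
    streamlines: dict[str, np.ndarray] = {}
    timeseries: dict[str, np.ndarray] = {}
    truth = {
        "path_class": {},
        "class_sigma": {},
        "severity": {},
        "projection_distortion": {},
    }
    for idx, (group, stage) in enumerate(plan):
        sid = f"S{idx:03d}"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 65.0))
        male = int(rng.uniform() < config.male_fraction)
        if group == "patient":
            dose = float(rng.lognormal(config.dose_log_mean, config.dose_log_sd))
            severity = float(rng.standard_normal())
            noise = float(rng.standard_normal())
            sspi = max(
                0.0,
                config.sspi_mean
                + config.sspi_sd
                * (
                    config.sspi_loading * severity
                    + np.sqrt(1.0 - config.sspi_loading**2) * noise
                ),
            )
            duration = (
                float(rng.uniform(0.5, 4.5))
                if stage == "early"
                else float(rng.uniform(5.5, 25.0))
            )
        else:
            dose, severity, sspi, duration = 0.0, 0.0, np.nan, np.nan
        sig = _subject_sigma(config, group, stage, age, male, dose, severity)
        counts, pcm = realize_network(p_edge, dist, config, rng)
        cov, distortion = build_target_covariance(pcm, config.mu, sig, rng)
        ts = sample_timeseries(cov, config.n_timepoints, rng)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": age,
                "sex": "M" if male else "F",
                "dose": dose,
                "duration": duration,
                "symptom_score": sspi,
            }
        )
        streamlines[sid] = counts
        timeseries[sid] = ts
        truth["path_class"][sid] = pcm
        truth["class_sigma"][sid] = sig
        truth["severity"][sid] = severity
        truth["projection_distortion"][sid] = distortion
    return Cohort(
        table=pd.DataFrame(rows),
        streamlines=streamlines,
        timeseries=timeseries,
        truth=truth,
        config=config,
        seed=seed,
    )
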