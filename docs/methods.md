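# Methods

## Structural path classification

Per subject the input is an N×N matrix of streamline counts between
parcellation regions (N = 90 for the AAL scheme used throughout the
defaults). An edge exists where the count reaches `min_streamlines`
(default 1, i.e. "one or more streamlines"; the 1–3 sweep is the
standard sensitivity analysis). After binarization the graph is
undirected and unweighted — counts influence nothing but the threshold.

Every unordered pair is labelled by its shortest path length, computed
by breadth-first search from each node (`scipy.sparse.csgraph`):
length 1 → primary, 2 → secondary, 3 → tertiary, ≥ 4 → higher-order,
unreachable → disconnected. Disconnected pairs are a label, never an
exception. The integer coding in files is 0 = disconnected, 1–3 =
primary–tertiary, 4 = higher; the diagonal is written as 0 and excluded
from every tally, so class counts always sum to N(N−1)/2.

Higher-order pairs (a fraction of a percent in realistic networks) can
be kept as their own stratum or merged into tertiary
(`higher_order_policy`); both are supported because studies rarely state
the treatment of such pairs, and results must record which was used.

Group consensus matrices take the per-pair modal class across subjects,
ties broken toward the lower path order — the conservative choice for a
structure-constrained interpretation; the tie-break is deterministic and
recorded here. Between-group agreement is reported as the count and
fraction of pairs with equal labels, plus two per-class variants whose
denominators differ: agreed-in-both / labelled-in-either (union) and
agreed-in-both / labelled-in-first (conditional). Published agreement
percentages rarely state the denominator, so both are computed and
labelled rather than guessing.

## Functional connectivity and entropy

FC is the Pearson correlation of regional time series, symmetrized by
averaging and clipped to [−1, 1]; zero-variance regions are a named
error. Band-pass filtering and nuisance-signal regression are upstream
of this package — its inputs are assumed to be fully preprocessed
regional series. The value scale entering the entropy is configurable
(`fc_transform`): raw r (default), |r|, or Fisher z (atanh, |r| clipped
at 1 − 1e−7). Raw r is the default because the statistic is meant to
capture bidirectional deviations — both strengthened and weakened
links — which |r| would fold together.

FCE of a link set is the Shannon entropy of its binned value
distribution: `n_bins` equal-width bins (default 100) over
[`bin_lo`, `bin_hi`] (default [−1, 1]), left-closed right-open with the
last bin closed; values outside the range are an error rather than
silently clamped. The default estimator is the plug-in
(maximum-likelihood) histogram entropy in bits. An optional
Miller–Madow correction (+ (K−1)/(2 n ln 2), K = occupied bins) exists
because the tertiary stratum is small (~3% of 4,005 ≈ 10² links) and
the plug-in estimator's negative bias varies with link count across
subjects. The defaults are the simplest reproducible choice; bin count,
range, base and estimator are all recorded in every output row.

Strata with fewer than two links yield a flagged undefined entropy
(`defined = False`), excluded from group statistics — the entropy of a
single value is degenerately 0 and would distort group means. The
whole-brain stratum always uses all off-diagonal pairs, including
disconnected ones; class strata exclude disconnected pairs.

Useful identities asserted in the test suite: 0 ≤ H ≤ log₂ B with the
maximum iff the histogram is uniform; refining bins (doubling B) never
decreases H; stratum entropies are invariant to consistent region
relabelling.

## Group statistics

Patients split into early (< 5 years illness duration) and late
(≥ 5 years) strata; each is compared with the control set (optionally a
matched subset via a `control_subset` column) for each FCE stratum.

Age, sex and chlorpromazine-equivalent dose are removed by ordinary
least squares before comparison. Two codings are implemented:

- **per_group** (default): each group is residualized against its own
  covariates (dose is constant 0 in controls and drops out), the
  centred residuals are rescaled by √((n−1)/(n−k)) so their sample
  variance estimates the noise variance without the fitted-parameter
  deflation, and each group's mean is re-added. This keeps any true
  between-group difference intact and gives a calibrated test: under
  label permutation of an effect-free synthetic cohort the battery's
  empirical type-I rate is ≈ 0.05.
- **pooled**: one regression across all subjects with dose coded 0 for
  controls. Because the dose column then nearly coincides with the
  group indicator, residualization absorbs most of any true group
  difference; the same permutation experiment yields a type-I rate of
  ≈ 0.002 — severely conservative. It is retained for comparability
  with analyses that used pooled coding, but it is not the default.

The comparison itself is a pooled-variance Student t (Welch by flag),
two-tailed p, and Cohen's d = |mean difference| / pooled SD (n−1
variances) with the direction carried separately as the sign of
(patient − control). Symptom correlations are Pearson r between
residualized FCE and the total symptom score within a patient stratum,
p from the t transform with n−2 df. No multiple-testing correction is
applied; the report records the number of tests so users can apply
their own.

A duration stratum too small for its covariate fit (fewer than k+2
subjects) is flagged `ok = False` with a note; the remaining blocks
still run.

The permutation calibration utility (`stats.permutation_null_rate`)
reassigns whole metadata rows to entropy profiles, rerunning the full
residualization + test battery per permutation, which is the
appropriate null for the combined procedure rather than for the t test
alone.

## Synthetic cohort generator

The generator exists so every pipeline stage can be tested against
known ground truth; its defaults emulate the study design the method
targets: 32 controls and 34 patients (17 early / 17 late), 90 regions,
240 time points, ages ≈ N(34, 9²) truncated to [18, 65], ~72% male,
log-normal patient doses (median ≈ 400 mg/day CPZ), symptom scores with
mean 11.8 and SD 7.7.

**Anatomy.** One cohort-level template is drawn: node positions uniform
in the unit cube, lognormal node propensities aᵢ (spread 0.8), edge
probability min(1, c·aᵢaⱼ·exp(−dᵢⱼ/0.25)) with the global scale c set
by bisection so the expected edge density equals the target primary
fraction (0.278). Each subject is an independent Bernoulli realization
of those probabilities, bridged to connectivity through the spatially
closest pair if components arise; streamline counts on present edges
are negative binomial (mean 30, dispersion 0.5, floored at 1).

Two modelling points deserve emphasis. First, a pure distance-decay
graph at 27.8% density yields almost no tertiary pairs (~0.25%); the
propensity heterogeneity creates weakly connected peripheral regions
and with it a realistic ~3% tertiary fraction. Second, the shared
template is what makes path classes consistent across subjects: with
fully independent per-subject anatomy the group consensus matrix
degenerates to the modal class (secondary) almost everywhere and
between-group agreement becomes meaningless, whereas under the shared
template the two groups' consensus matrices agree on ≈ 95% of pairs
with the tertiary class — rare and fragile — agreeing least, the
qualitative pattern seen in real cohorts.

**Function.** Per-pair target correlations are drawn
N(μ_class, σ_class) truncated to (−0.99, 0.99), with
μ_primary = 0.45 > μ_secondary = 0.25 > μ_tertiary = 0.10 (direct links
are strongest) and σ_class the entropy handle. The target matrix is
projected to the nearest symmetric positive-definite correlation matrix
(eigenvalues clipped at 1e−6, re-normalized to unit diagonal); the mean
absolute off-diagonal change is reported per subject and stays below
0.05 at the defaults — this bound is why the base spreads are moderate
(σ = 0.075 for primary/secondary, 0.17 for tertiary): the projection
increasingly shrinks wide independent spreads as total off-diagonal
variance grows. Time series are T i.i.d. draws from the zero-mean
Gaussian with that correlation (Cholesky); no hemodynamic model is
attempted because the pipeline consumes correlations only.

**Designed effects.** A subject's σ_class is the control base plus a
group shift, linear covariate terms (age −3e−4/yr, sex +5e−3, dose
−2e−6/mg) and, for patients, a latent standard-normal severity coupled
at ±0.015 to the primary and secondary spreads (positive in early,
negative in late stage); the same severity generates the symptom score
(loading 0.8). Severity deliberately does not touch the tertiary
spread: the tertiary effect is designed as severity-invariant, so
symptom correlations arise only through structurally constrained links.
The default shifts — early {0, +0.016, −0.026}, late {−0.010, −0.013,
−0.092} for {primary, secondary, tertiary} — were calibrated once,
against the analysis pipeline at its default settings, to reproduce the
canonical effect pattern: early-stage secondary widening (d ≈ 1.2) and
tertiary narrowing (d ≈ 1.5), late-stage narrowing of everything with
tertiary dominant (d ≈ 4.8, secondary ≈ 1.4, primary ≈ 1.1), positive
early / negative late symptom coupling. The late primary effect is
sized at d ≈ 1 rather than trend-level so that its sign is reliably
recoverable at 17 subjects per group (a trend-sized d ≈ 0.4 has only
~90% sign-recovery probability at that n).

**What the generator does not emulate.** Head motion, physiological
noise, hemodynamics, spatial smoothness, nonstationary connectivity,
and anatomically meaningful region identities are all absent. Passing
tests therefore demonstrate that the *pipeline* recovers what the
forward model puts in — not that the biological claims hold; the
generator is a correctness instrument, not a brain model. Two known
artifacts: (i) entropy is concave in σ, so the severity-coupling
variance biases coupled strata's mean FCE slightly downward in
patients, giving the designed-null early primary stratum a small
(|d| ≈ 0.4) negative tendency; (ii) between-group dose differences
cannot be removed by per-group residualization, which is why the dose
slope default is small.

## Numerical choices and degenerate inputs

- Bisection for the edge-probability scale runs 200 halvings in log
  space on [1e−12, 1e12]; the realized primary fraction then varies
  binomially around the target (SD ≈ 0.007 at N = 90).
- SPD projection failure (non-positive matrix after clipping and
  re-normalization) raises with diagnostics; it does not occur at
  supported settings.
- Fisher z clips |r| at 1 − 1e−7; histogram range errors are raised,
  not clamped; probability vectors must sum to 1 within 1e−9.
- Asymmetric or negative streamline matrices, NaN time series, and
  rank-deficient covariate designs are all named errors at read or
  call time, before any computation.
- Determinism: a cohort is a pure function of (config, seed); CLI runs
  with fixed seed and inputs produce byte-identical numeric outputs.

## Problem sizes used in the shipped tests

The acceptance-style tests run the classifier oracle comparison on 200
random graphs (N ≤ 30), the type-I calibration on one 66-subject null
cohort with 1,000 label permutations, and the effect-recovery check on
200 replicate cohorts per scenario at 17 subjects per group with the
default 90-region, 240-volume forward model; the acceptance script uses
100 replicates per scenario. These sizes give the sign-recovery and
calibration estimates quoted above with Monte-Carlo error well inside
the asserted margins while keeping a full run in the minutes range.
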