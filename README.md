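# fcentropy

Structure-constrained functional connectivity entropy for brain
connectomes.

## The problem

Resting-state functional MRI gives, for every pair of brain regions, a
Pearson correlation between their activity time series (functional
connectivity, FC). Diffusion tractography gives, for the same regions,
whether white-matter streamlines directly connect them. Region pairs can
therefore be stratified by how much anatomy constrains their
interaction: **primary** paths (a direct tract, shortest path length 1
in the binarized streamline graph), **secondary** (one intermediate
region, length 2) and **tertiary** (two intermediates, length 3). In a
90-region parcellation (AAL) there are exactly 90·89/2 = 4,005 pairs,
of which roughly 28% are primary, 69% secondary and 3% tertiary.

**Functional Connectivity Entropy (FCE)** measures how *unpredictable*
connectivity strength is across a set of links: bin the FC values of
the link set into B equal-width bins over [−1, 1] (default B = 100) and
take the Shannon entropy of the resulting distribution,

&nbsp;&nbsp;&nbsp;&nbsp;H = −Σₖ pₖ log₂ pₖ  (bits, 0 ≤ H ≤ log₂ B),

where pₖ is the fraction of links falling in bin k. High FCE means the
link set's connectivity strengths are spread widely (less predictable);
low FCE means they cluster tightly. Computed whole-brain and within
each structural path class, FCE asks *where* — at which level of
structural constraint — connectivity becomes disordered, which is of
particular interest in psychotic illness where structure–function
coupling is thought to degrade with illness duration.

The package implements the full analysis as a tested pipeline:

- `structural` — binarize streamline-count matrices at a minimum
  streamline threshold (1–3 sweep), classify all pairs by BFS shortest
  path, group consensus matrices, between-group class agreement;
- `fc` / `entropy` — Pearson FC, optional |r| / Fisher-z transforms,
  binned Shannon entropy per stratum (plug-in or Miller–Madow);
- `stats` — residualization of age/sex/antipsychotic-dose effects,
  Student t + Cohen's d group comparisons split by illness duration
  (early < 5 years vs late), FCE–symptom-score correlations,
  permutation type-I calibration, threshold sensitivity;
- `simulate` — a synthetic-cohort generator with known ground truth:
  shared anatomical template with per-subject network realizations,
  class-structured SPD-projected target covariances, Gaussian time
  series, and designed per-class entropy effects;
- `io` / `cli` — delimited-text matrices, cohort CSV, YAML config, and
  a thin `fcentropy` command with `simulate / classify / fce / compare
  / report` subcommands.

## Worked example

```python
from fcentropy import SimulationConfig, generate_cohort, run_study

cfg = SimulationConfig(n_controls=17, n_early=17, n_late=17)
cohort = generate_cohort(cfg, seed=1)
study = run_study(cohort.table, cohort.streamlines, cohort.timeseries)
print(study["report"][["duration_stratum", "stratum", "cohen_d",
                       "direction", "p_value", "symptom_r"]].round(3))
```

prints (see `examples/03_group_comparison.py`):

```
duration_stratum     stratum  cohen_d  direction  p_value  symptom_r
           early whole_brain    0.366          1    0.294      0.433
           early     primary    0.284          1    0.414      0.367
           early   secondary    1.447          1    0.000      0.530
           early    tertiary    1.140         -1    0.002      0.087
            late whole_brain    1.351         -1    0.000     -0.520
            late     primary    1.401         -1    0.000     -0.684
            late   secondary    2.135         -1    0.000     -0.546
            late    tertiary    3.054         -1    0.000      0.220
```

Each row compares one patient duration stratum against controls for one
link stratum after removing age, sex and dose: `direction` is the sign
of (patient mean − control mean) FCE, `cohen_d` the standardized
magnitude, and `symptom_r` the correlation between residualized FCE and
total symptom score among those patients. This cohort was generated
with the default designed effects — early-stage secondary widening and
tertiary narrowing with positive symptom coupling, late-stage narrowing
everywhere (tertiary largest) with negative coupling — and the report
recovers exactly that pattern. The same run reports the two groups'
consensus path classes agreeing on 3810 of the 4,005 region pairs.

The other examples cover path classification on the worked
four-region chain (`examples/01_...`), single-subject entropy
(`examples/02_...`) and the streamline-threshold sweep
(`examples/04_...`).

## Command line

```sh
fcentropy simulate --out cohort/ --seed 7
fcentropy classify --cohort cohort/cohort.csv --data-dir cohort/ \
    --min-streamlines 2 --out classes/
fcentropy fce --cohort cohort/cohort.csv --data-dir cohort/ \
    --class-dir classes/ --bins 100 --out fce/
fcentropy compare --cohort cohort/cohort.csv --fce-table fce/fce.csv --out stats/
fcentropy report --cohort cohort/cohort.csv --data-dir cohort/ --out report/
```

Every run writes `effective_config.yml` and `run.log` beside its
outputs so the threshold, bin scheme and seed behind any result are
recorded.

## Documentation

`docs/methods.md` describes the model, the synthetic-data generator and
every numerical choice in detail.
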