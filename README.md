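# pmtdsim

Covariate-aware Bayesian dose-finding designs with personalised-MTD
operating-characteristics simulation.

The package implements a family of model-based Phase I designs built on the
two-parameter Bayesian logistic regression model (BLRM) on the
log-dose-ratio scale, extended with linear covariate effects:

* **blrm** — covariate-free reference design; one shared dose per cohort,
  allocated to the dose whose posterior-mean DLT probability is closest to
  the target rate (ties upward).
* **blrmc** — covariate-extended model with flat N(0, 4) coefficient
  priors; each patient is allocated to their estimated personalised MTD.
* **lasso** — Laplace shrinkage priors on the coefficients with one
  penalisation parameter per covariate group (continuous / binary) under an
  InverseGamma(δ, δ) hyperprior.
* **spike_slab** — two-component normal mixture priors with
  Beta-distributed mixture weights (soft variable selection).
* **cchange** — starts covariate-free and includes a covariate
  permanently once the fraction of enrolled patients whose recommended
  dose changes between the models with and without it exceeds a threshold.

Scenario truths (logistic or Emax dose-toxicity, normal / Bernoulli /
correlated-normal covariates) are calibrated so that toxicity probabilities
*averaged over the covariate distribution* match a target marginal curve; a
bundled table provides the five standard marginal rows (one per dose being
the MTD).

Two posterior engines are available: a deterministic prior-anchored /
mode-centred grid quadrature (models with at most one covariate) and an
adaptive random-walk Metropolis sampler (all prior variants, with split-R̂
diagnostics). Every simulation is bit-for-bit reproducible from its seed,
and the covariate/outcome random streams are design-independent, so trial
paths of different designs are comparable patient by patient.

## Library quick start

```python
from pmtdsim import DesignSpec, run_trial, run_oc
from pmtdsim.fixtures import build_truths

truths = {k: r.truth for k, r in build_truths().items()}   # five scenarios
design = DesignSpec(method="blrm")                         # tau=0.25, N=30, cohorts of 3
result = run_oc(truths, design, n_sim=200, master_seed=1)
print(result.per_scenario)       # arithmetic averages over trials
print(result.summary)            # geometric mean (MTD metrics), arithmetic (overdose)
```

Per-trial metrics: percentage of enrolled patients allocated to /
above their true personalised MTD (`mtd_trial`, `ov_trial`), and the same
for 100 fresh post-trial patients scored with the trial's final model
(`mtd_add`, `ov_add`).

## Command line

```sh
pmtdsim scenarios --out out/scen                 # dose-probability + pMTD tables
pmtdsim run-trial --design-file design.yaml --seed 7 --out out/trial
pmtdsim oc --design-file design.yaml --n-sim 200 --seed 1 --out out/oc
pmtdsim calibrate --config calib.yaml --seed 0 --out out/calib
```

Scenario and design configurations are YAML; see `tests/test_cli.py` for
minimal examples. All outputs are CSV/JSON with a config hash recorded in
the manifest.

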