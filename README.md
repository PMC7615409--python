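# factormr

Factor-based conditional inference for *cis*-Mendelian randomization from
two-sample GWAS summary statistics.

Variants in a single gene region are highly correlated; instead of pruning
them, `factormr` estimates `r` latent genetic factors from the variant
covariance matrix (principal components of var(Z)) and uses them as
instruments for a single exposure–outcome pair. Because those factors can be
weak instruments, the package centres on inference that stays valid under
weak identification:

- **F-LIML** — limited-information maximum likelihood point estimation on the
  factor-level moment conditions, with Wald confidence intervals (closed-form
  minimizer; the weighting matrix is a scalar multiple of the factor
  covariance).
- **F-AR / F-LM / F-CLR** — identification-robust tests of `H0: theta =
  theta0` and confidence sets by test inversion. The CLR conditional p-value
  is computed by 1-D quadrature (Monte-Carlo cross-check included).
- **S-LIML** — LIML on the subset of factors that survive a relevance
  pre-test, with a Monte-Carlo conditional test that controls the *selective*
  type-I error (the screening step is part of the null distribution), and
  selective confidence intervals by inversion with common random numbers.
- **Simulator** — block-structured synthetic regions, Assumption-style
  Gaussian summary-statistic draws, sample-size calibration to a target
  first-stage F, pleiotropy and LD-mismeasurement perturbations (Models 1–5),
  and a Monte-Carlo driver producing rejection/bias/RMSE tables.
- **IO layer** — TSV summary-statistic reading with configurable column maps,
  allele harmonization (sign flips, palindromic drops), LD matrix readers
  (square and long format), HWE variances from allele frequencies, and the
  logit-to-linear transform for binary outcomes.

## CLI

```sh
# eigen-spectrum of an LD matrix (gap ratios, cumulative shares, optional scree PNG)
factormr factors --ld ld.tsv [--variances variances.tsv] [--scree scree.png]

# end-to-end analysis: read -> harmonize -> factors -> inference
factormr analyze \
    --exposure exposure.tsv --outcome outcome.tsv --ld ld.tsv \
    --variances variances.tsv --r 14 \
    --method fliml --method fclr --method sliml \
    --nu 0.01 --alpha 0.05 --seed 1 --out results.tsv

# Monte-Carlo study from a YAML design
factormr simulate --config design.yaml --out results.tsv
```

Summary-statistic TSVs need columns `variant_id`, `position`,
`effect_allele`, `other_allele`, `beta`, `se`, `n` (renameable via the
Python API's column map). For binary outcomes pass `--case-fraction` to
convert logit betas to the linear scale. Variant variances come from a
two-column TSV or from allele frequencies (`--frequencies`, HWE 2f(1−f)).

A minimal simulation design:

```yaml
model: 1          # 1-5; 2/3 add tau, 4 kappa0, 5 kappa2
p: 60
r_true: 5
f_target: [2, 20]
theta_grid: [0.0]
reps: 2000
seed: 1
methods: [fliml, far, flm, fclr, sliml]
```

## Python API sketch

```python
import factormr as fm

ld = fm.read_ld_matrix("ld.tsv")
exposure = fm.read_summary_associations("exposure.tsv")
outcome = fm.read_summary_associations("outcome.tsv")
harmonized = fm.harmonize(exposure, outcome, ld)
data, varz = fm.build_summary_dataset(harmonized, variances, var_x=1.0, var_y=1.0)

loadings = fm.estimate_loadings(varz, r=14)
ms = fm.build_moment_system(data, loadings, varz)

fit = fm.fit_fliml(ms)                      # point estimate + Wald CI
cs = fm.invert_test("clr", ms)              # robust confidence set
sel = fm.pretest_factors(ms, nu=0.01)       # relevance screening
sfit = fm.fit_sliml(ms, sel)
sci = fm.selective_ci(sfit, ms, seed=1)     # selective CI
```

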