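# ithshift

Multiregion tumor sequencing reads several regions of one tumor and asks how
its mutations are distributed among them: *ubiquitous* mutations (present in
every region) mark the founding clone, while *shared* and *private*
mutations chart later subclonal growth. Whether that intratumor
heterogeneity is driven by Darwinian selection (subclones with driver
mutations sweeping to high frequency) or accumulates neutrally is a central
question in early tumor evolution — and answering it from whole-exome data
requires correcting variant allele frequencies (VAFs) for tumor purity,
read depth and local copy number, and correcting per-case counts for
unequal region numbers.

`ithshift` is a Python library and CLI for that analysis, aimed at cancer
genomicists comparing multiregion cohorts (its motivating contrast:
precancerous colorectal lesions, "PCRC", vs advanced colorectal cancers,
"ACRC"). It provides:

* **Mutation profiles** — variant admission (caller flag plus >10 reads in
  every region), false-negative rescue (tumor VAF ≥ 0.05, normal VAF ≤
  0.01, Fisher's exact p ≤ 0.05), ubiquitous/shared/private categorization,
  heatmap ordering and PCA-based region colors, and purity estimation
  (2 × median ubiquitous VAF).
* **Downsampling correction** — ubiquitous/heterogeneous alteration counts
  recomputed over every 4-region subset of a case, with medians at both
  levels, so cases with 4 and 21 regions are comparable.
* **Arm-level CNA profiles** — segments covering >50% of a chromosome arm
  are arm-level; per-region presence uses a length-weighted mean
  |log2R| > 0.15 rule with re-examination of regions the caller missed.
* **Hierarchical Bayesian models** (scikit-learn-style estimators, fitted
  by a built-in slice-within-Gibbs sampler with split-R̂ diagnostics):

  - `AlterationCountModel` — counts by tumor stage:
    `n_ij ~ Poisson(exp(β_t(ij) + r_ij))`;
  - `VafCategoryModel` — reads by mutation category:
    `b_ijk ~ Binomial(d_ijk, logistic(β_t(ijk) + r_ijk) · TC_ij)`;
  - `CcfCategoryModel` — cancer cell fractions via
    `P = TC·C / ((1−TC)·2 + TC·CN)` with `C = logistic(β + r)`;

  all with Cauchy priors on group means (`β_t ~ Cauchy(β, τ)`,
  `β ~ Cauchy(0, 1)`, `τ ~ Half-Cauchy(1)`) and nested Cauchy residuals per
  case/sample/mutation with Half-Cauchy scale hyper-priors.
* **Frequentist comparisons** — two-sided Fisher's exact test for driver
  trunk-vs-branch enrichment, Wilcoxon rank tests, six-class mutation
  spectra.
* **A synthetic-cohort generator** with known clonal truth, emitting the
  pipeline's input formats under *darwinian* and *neutral* regimes, so
  every stage has a recovery test.

See `docs/methods.md` for model details, conventions and limitations.

## Worked example

Simulate a mini two-cohort study (3 darwinian PCRC cases vs 3 neutral ACRC
cases, ~80 mutations per region) and run the full pipeline:

```python
import json
from ithshift.io import load_config
from ithshift.pipeline import run_pipeline

cfg = load_config()
cfg["simulate"] = {
    "enabled": True, "n_pcrc_cases": 3, "n_acrc_cases": 3,
    "pcrc_samples_per_case": [4, 5], "acrc_samples_per_case": [4, 5],
    "stage_means": {"adenoma": 80.0, "carcinoma": 80.0, "ACRC": 80.0},
    "n_driver_mutations": [14, 18],
}
cfg["mcmc"].update({"n_chains": 2, "n_burnin": 400, "n_total": 600})
manifest = run_pipeline(cfg, outdir="example_run", seed=7)
print(json.dumps(manifest.summary, indent=2, default=str))
```

Key lines of the printed summary (about a minute on one CPU):

```
"corrected_shared_median": {"PCRC": 32.0, "ACRC": 10.0}
"driver_table": {"PCRC": [21, 23], "ACRC": [3, 45]}
"fisher_driver_p": 7.989475532691121e-06
"p_internal_branch_pcrc_gt_acrc": 1.0
```

and `example_run/bayes_vaf.tsv` holds the per-category posterior of the
corrected mean VAF:

```
               group     mean   median    ci2.5   ci97.5
ACRC:external_branch 0.100916 0.100720 0.094413 0.107711
ACRC:internal_branch 0.182665 0.182747 0.170762 0.193721
          ACRC:trunk 0.499296 0.499022 0.494310 0.506408
PCRC:external_branch 0.130067 0.130049 0.121429 0.138341
PCRC:internal_branch 0.400429 0.400467 0.393538 0.408428
          PCRC:trunk 0.507459 0.505804 0.499919 0.523792
```

Reading the numbers: trunk mutations in both cohorts sit near the expected
corrected VAF of 0.5 (one mutant allele in a diploid founding clone);
internal-branch (shared-subclone) mutations sit much higher in the
darwinian cohort (0.40 vs 0.18) — the selective-sweep signature — and the
driver table shows the matching subclonal-driver enrichment (21/44 branch
drivers vs 3/48, Fisher p ≈ 8e-6). The corrected shared-mutation medians
(32 vs 10) show the same contrast at the count level. All three are true by
construction in the simulator, which is the point: the pipeline recovers
them from read counts alone.

The same stages are available as CLI subcommands:

```bash
ithshift simulate --out sim/ --seed 7
ithshift profile --in sim/variants.tsv --samples sim/samples.tsv --out profiles/
ithshift downsample --in profiles/PCRC01.tsv --k 4 --out counts.tsv
ithshift cna --segments sim/segments.tsv --out arm_calls.tsv
ithshift bayes-vaf --in sim/variants.tsv --samples sim/samples.tsv --out vaf.tsv
ithshift run --out full_run/ --seed 7
```

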