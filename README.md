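# agecurve

Age-trajectory analysis of cross-sectional transcriptome cohorts.

Population-based expression studies sample hundreds of subjects across a
broad adult age range, usually unevenly: elderly subjects are
under-represented and a linear model misses changes that concentrate late in
life. `agecurve` implements the full analysis for this setting:

1. **Sample weighting.** Each sample *i* receives weight `w_i = 1/N_i`,
   where `N_i` counts the samples within ±5 years of its age (a moving
   window, closed bounds), downsizing over-represented ages.
2. **Per-probe quadratic trend fit.** For probe *i* and sample *j* at age
   `x_j`, `E_ij = α_i + β_i x_j + γ_i x_j² + ε_ij`, fitted by weighted least
   squares with the weights in the loss.
3. **Age-association test.** The quadratic model is tested against the
   intercept-only null with `F = ((RSS₀ − RSS₁)/2)/(RSS₁/(n−3))`. Unweighted
   fits use the exact F(2, n−3) p-value; weighted fits keep the same
   statistic but take its p-value from the statistic's exact finite-sample
   null law (seeded Monte Carlo through the fixed design geometry), because
   1/N window weights are not inverse error variances and the naive F
   reference is badly anti-conservative (see `docs/methods.md`).
4. **Filtering.** Benjamini–Hochberg FDR < 0.05 and absolute fold change
   `|FC| = 2^{|Δ|} ≥ 1.2`, with Δ the net change of the smoothed (fitted)
   trajectory across the age range.
5. **Clustering and age-position.** Significant smoothed trajectories are
   mean-centered and clustered by K-means — Euclidean distance for the
   major trends (redundant clusters merged at centroid correlation ≥ 0.9,
   singletons dropped), and absolute-correlation distance
   `1 − |pearson|` to unite mirrored profiles. The **age-position** — the
   age where the opposite inclinations conjoin — is read off as the
   crossing of the two sign-group mean trajectories.
6. **Replication machinery.** Weighted-vs-unweighted comparison, age-range
   matching between two cohorts, gene-level overlap with direction
   concordance, and age-split re-analysis.

A synthetic cohort generator (`agecurve.synthetic`) plants null, linear,
hinge and quadratic log2 trajectories with known change points, noise and
demographics modeled on two real blood cohorts (RS-like: n=762, ages 46–89,
right-skewed; SHIP-like: n=991, ages 21–81, even), so the entire pipeline is
testable without downloading any data.

## Worked example

```python
import numpy as np
from agecurve import (AnalysisConfig, CohortSpec, collapse_to_genes,
                      filter_probes, overlap_significant, run_pipeline,
                      simulate_platform_pair)

rs   = CohortSpec.rs_like(seed=1, n_probes=2000, frac_signal=0.2)
ship = CohortSpec.ship_like(seed=2, n_probes=2400, frac_signal=0.2)
ds_rs, _, annot_rs, ds_ship, _, annot_ship = simulate_platform_pair(
    rs, ship, shared_gene_fraction=0.9,
    change_point=65.0, delta=np.log2(1.5), noise_sd=0.5)

res_rs   = run_pipeline(ds_rs,   AnalysisConfig(random_seed=1))
res_ship = run_pipeline(ds_ship, AnalysisConfig(random_seed=1))
print(res_rs.summary["n_pass_both"], res_rs.summary["age_position"]["age"])
print(res_ship.summary["n_pass_both"], res_ship.summary["age_position"]["age"])
```

prints (seed 1):

```
384 72.238445186998
398 61.25998546694569
```

384 of 2000 RS-like probes (198 up, 186 down) and 398 of 2400 SHIP-like
probes pass FDR < 0.05 and |FC| ≥ 1.2 — close to the planted 20% signal
fraction. Both cohorts resolve into rising and falling major trends. The
detected age-position differs between the cohorts even though both carry
the same planted change point at 65: the conjunction of two mirrored fitted
parabolas sits at the in-range zero of the centered fit, which depends on
the cohort's age range (61.3 y for ages 21–81, 72.2 y for ages 46–89). This
systematic displacement is a property of quadratic smoothing and is
quantified in `docs/methods.md`. Overlapping the two significant gene sets:

```python
sig_rs, _   = filter_probes(res_rs.fit.table, 0.05, 1.2)
sig_ship, _ = filter_probes(res_ship.fit.table, 0.05, 1.2)
ov = overlap_significant(collapse_to_genes(sig_rs, annot_rs)[0],
                         collapse_to_genes(sig_ship, annot_ship)[0])
print(ov.overlap_count, ov.concordant_count)   # -> 359 353
```

359 genes replicate across the two platforms and 353 of them change in the
same direction.

## Command line

```sh
agecurve simulate --preset rs-like --seed 1 --out-dir sim/
agecurve run sim/expression.tsv sim/metadata.tsv --seed 1 --out-dir out/
agecurve split sim/expression.tsv sim/metadata.tsv --cutoff 65 --out-dir split/
```

`run` writes `results.tsv` (per-probe coefficients, p/q-values, fold
changes, cluster labels), `volcano.tsv`, `weights.tsv`, `clusters.tsv` and
`summary.json`; every file carries the config hash and seed, and reruns
with the same seed are byte-identical.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full analysis from scratch: it simulates the RS-like/SHIP-like
platform pair above, executes the complete pipeline on both cohorts
(weighting, calibrated weighted fits, FDR+FC filtering, trend clustering,
age-position detection) and the cross-cohort gene overlap, writing the
report JSON to `--out` and a human-readable run summary next to it.
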