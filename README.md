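# antpolyandry

Queen mating-frequency and paternity-skew analysis for highly polyandrous
social insects, built around the army ant case: colonies headed by a
single wingless queen that mates with on the order of 10–25 males.
Because males are haploid, a sample of diploid worker genotypes at a
handful of polymorphic microsatellite loci lets both parental genotypes
be deduced directly — the queen must contribute one allele to every
worker at every locus, and whatever remains is a father's haplotype.

The package takes a worker genotype table (or simulates colonies with
known ground truth), reconstructs queens and patrilines, and computes
the statistics a polyandry study reports:

- **Paternity frequencies** — observed patriline count `k_obs`; the
  sample-size-corrected `k_est = k_obs (1 + e^{-n/k_obs})`, which adds
  the expected Poisson zero class of unsampled patrilines; and the
  effective paternity `m_e` (Starr's `1/Σ p_i²` and the Nielsen
  small-sample-corrected form `(n−1)² / [(n+1)(n−2) Σ p_i² + 3 − n]`).
- **Paternity skew** — Nonacs' binomial B-index
  `B = Σ (p_i − 1/k)² − (1 − 1/k)/n` with one-tailed p-values from
  uniform-multinomial simulation, and Pamilo's S-index
  `S = (k_obs − m_e)/(k_obs − 1)` with case-specific Monte-Carlo 95%
  null intervals (each worker equally likely to belong to any observed
  patriline).
- **Colony and population structure** — Nei heterozygosities,
  `F_IS = 1 − H_O/H_S`, multi-locus Weir–Cockerham θ treating colonies
  as subpopulations, and Queller–Goodnight regression relatedness
  (`r_ww`, `r_qm`, `r_mm`) with delete-one-locus jackknife SEs, tested
  against the haplodiploid pedigree expectation
  `g_ww = 0.25 + 0.5/m_e`.
- **Cross-species comparative fits** — phylogenetic GLS (Brownian
  covariance, ML, likelihood-ratio slope tests) of skew on paternity
  frequency, with randomized-S null slope intervals, plus a χ²/inertia
  correspondence analysis of patriline-rank × species tables.

A synthetic-colony generator (Dirichlet-multinomial paternity,
Balding–Nichols substructure) provides ground truth for every stage, so
all estimators are validated by parameter recovery.

## Worked example

Simulate three colonies of a queen with 18 mates (100 workers sampled
per colony, 10 loci, mild substructure), then run the full analysis:

```python
from antpolyandry import RunConfig, SimulationConfig, run_pipeline

cfg = RunConfig(
    simulation=SimulationConfig(n_loci=10, alleles_per_locus=8, k_mates=18,
                                n_workers=100, missing_rate=0.02,
                                n_colonies=3, divergence=0.05, seed=0),
    seed=42, out_dir="demo_run",
)
result = run_pipeline(cfg)
```

which prints (via the per-colony rows in `result.colonies` and
`result.popgen`):

```
sim1: n=100 k_obs=17 k_est=17.05 m_e=16.34 B=0.0022 (p=0.258) S=0.041
sim2: n=100 k_obs=18 k_est=18.07 m_e=15.09 B=0.0104 (p=0.008) S=0.171
sim3: n=100 k_obs=17 k_est=17.05 m_e=11.20 B=0.0300 (p=0.001) S=0.362
F_IS = 0.047 (t=1.32, p=0.218)
F_ST = 0.008 +- 0.018 (one-tailed p=0.334)
sim1: r_ww=0.218 g_ww=0.285 r_qm=-0.034 r_mm=-0.007
sim2: r_ww=0.331 g_ww=0.288 r_qm=0.087 r_mm=0.050
sim3: r_ww=0.421 g_ww=0.299 r_qm=0.124 r_mm=0.010
```

Reading this: all three queens are extremely polyandrous (17–18
patrilines observed; `k_est ≈ k_obs` says the 100-worker samples missed
almost nothing). Colony `sim3` shows significant paternity skew (B-index
p = 0.001, S = 0.36), the others progressively less. Worker relatedness
sits near the outbred pedigree expectation `g_ww ≈ 0.28–0.30`, queens
are unrelated to their mates (`r_qm ≈ 0`), and there is no detectable
inbreeding or strong substructure — the genetic signature of extreme
polyandry doing its job. The non-detection error (probability two males
share a full multilocus haplotype, here ~5×10⁻⁷) is also reported per
colony.

The same stages are exposed on the command line
(`antpolyandry simulate | infer | estimate | skew | run`); ten reference
colony summaries of five Neotropical army ant species ship in
`antpolyandry.datasets` as worked inputs for the estimators.

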