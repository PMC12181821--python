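# griefnet

Comorbidity and symptom-network analysis of prolonged grief disorder
(PGD) and complex PTSD (cPTSD) for bereaved, trauma-exposed samples —
a reusable, tested Python implementation of the full analysis pipeline:
ICD-11 probable-diagnosis scoring, multiple imputation, pooled
prevalence and correlations, ordinal regularized partial-correlation
networks, bridge centrality, and bootstrap stability. A synthetic
cohort generator emulates the study design (N ≈ 92 participants,
TGI-SR+ / CAPS-5 / COPISAC instruments, item-level missingness), so the
entire pipeline runs and is tested without access to confidential
clinical data.

Intended users: clinical researchers and methodologists who analyze
symptom-level comorbidity with network models on small, multiply
imputed ordinal datasets.

## The model

Symptom ratings are treated as ordinal manifestations of latent
Gaussian variables. For 13 symptom nodes (7 PGD symptoms, 6 cPTSD
symptom clusters), pairwise **polychoric correlations** are estimated
by two-step maximum likelihood and assembled into S. The network is the
**graphical lasso** estimate

  Θ̂(λ) = argmax_Θ  log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|

with edge weights given by partial correlations
ω_ij = −Θ̂_ij / √(Θ̂_ii Θ̂_jj). The penalty is selected over a
100-point path by the extended BIC,

  EBIC(λ) = −n·(log det Θ̂ − tr(SΘ̂)) + E·log n + 4·E·γ·log p,  γ = 0.5,

where E is the number of selected edges. Multiply imputed datasets
(FCS with predictive mean matching, m = 20) are **stacked**: one network
is estimated on the concatenated data with the effective sample size
held at the original N. Node importance uses **strength** (sum of
absolute incident weights) and **bridge strength** (sum over edges
crossing the PGD ↔ cPTSD community boundary). Robustness uses
bootstrap-then-impute percentile CIs for edges and the case-dropping
subset bootstrap with **CS-coefficients** (the largest fraction of
participants that can be dropped while subset centralities still
correlate ≥ 0.7 with the full sample in ≥ 95% of bootstraps).

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The numbered scripts under `analysis/` run the pipeline end to end on a
synthetic study-scale cohort and write tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_impute.py          --seed 1
python analysis/03_prevalence_comorbidity.py --seed 1
python analysis/04_network.py         --seed 1
python analysis/05_centrality.py      --seed 1
python analysis/06_stability.py       --seed 1 --n-boot 50
```

Output from this run:

```
simulated N=92 cohort (seed 1): true network has 39/78 edges, overall item missingness 3.1%
imputed 105 missing cells x 20 datasets (10 FCS sweeps)
pooled probable prevalence (N=92, m=20): PGD 26.09%, PTSD 19.78%, cPTSD 12.88%
among probable PGD cases: 33.54% comorbid PTSD, 13.75% comorbid cPTSD
TGI-SR+ omega (pooled): 0.842
stacked EBICglasso network (gamma=0.5, effective n=92): 0/78 edges, density 0.00
```

Reading this: just over a quarter of the synthetic cohort meets the
probable ICD-11 PGD algorithm (a core grief symptom plus an
accompanying symptom and impairment, all rated ≥ 4, loss > 6 months
ago), and a third of those also meet PTSD criteria. The selected
network at N = 92 is empty: with γ = 0.5 the selector is deliberately
conservative, and the generator's ground-truth weights (shrunk by the
positive-definiteness repair) sit below what 92 observations can
detect — at n = 500 the same pipeline recovers the strong edges with
high specificity (see the acceptance metrics below).

Library use mirrors the scripts:

```python
from griefnet.synthetic import generate_instrument_cohort
from griefnet.imputation import ImputationConfig, fcs_impute
from griefnet.network import estimate_network_stacked

cohort = generate_instrument_cohort(92, seed=1)
stack = fcs_impute(cohort.items, ImputationConfig(m=20, seed=1))
net = estimate_network_stacked(stack, n_effective=92)
```

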