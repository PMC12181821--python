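# Methods

This package re-implements, as a tested pipeline over synthetic data, a
comorbidity and symptom-network analysis of prolonged grief disorder
(PGD) and complex PTSD (cPTSD) in a treatment-seeking sample assessed
with the TGI-SR+ (22 grief items, rated 1–5), the CAPS-5 ICD-11 item
subset (rated 0–4) and the COPISAC complex-PTSD add-on (CO1–CO5, rated
0–4). The pipeline has five stages: multiple imputation of item-level
missingness, probable-diagnosis scoring with pooled prevalence,
ordinal partial-correlation network estimation, strength / bridge
centrality, and bootstrap stability.

## Generative model for synthetic cohorts

Because the clinical data are confidential, every stage is exercised
against a synthetic cohort whose structure mirrors the study's:

* **Ground-truth network.** The 13 network nodes (7 PGD symptoms: Pr,
  Ye, AL, BA, ML, Nu, PD; 6 cPTSD symptom clusters: Re, Av, Th, ad,
  NSC, DR) follow a latent Gaussian graphical model. A target edge set
  of exactly `round(density · 78)` pairs receives partial correlations
  drawn uniformly in `[weight_low, weight_high]`; the implied
  unit-diagonal precision matrix is repaired to positive definiteness
  by diagonal inflation (δ doubling from 0.01 until the smallest
  eigenvalue is ≥ 1e−6) followed by rescaling to unit diagonal. The
  repair preserves the edge support exactly but shrinks weight
  magnitudes — at density 0.5 with weights up to 0.49 the realized
  partial correlations top out near 0.21. Defaults (`density=0.5`,
  weights in `[−0.04, 0.49]`, N=92) reproduce the regime of the
  analyzed sample.
* **Ordinal discretization.** Latent draws from the standardized
  inverse precision are cut at per-node thresholds. Defaults are
  equiprobable categories (5 for single items, 9 for two-item cluster
  sums); the study reports no item marginals, so these cannot be
  calibrated against it.
* **Item reconstruction.** Single-item nodes map directly onto their
  item; two-item cluster sums are split uniformly into two in-range
  items, so the node table rebuilt downstream reproduces the sampled
  node codes exactly. Items outside the network load on one shared
  severity factor (default loading 0.7, a typical magnitude for items
  of a common symptom instrument) plus unique noise. Months since loss
  are log-normal (median ≈ 74 months, matching a mean time since loss
  of roughly 8 years with wide spread); bereavement and Criterion-A
  trauma flags default to 1 because the study sampled bereaved,
  trauma-exposed participants.
* **Missingness.** Per-scale MCAR masking at rates inside the study's
  0.8%–5.7% band (defaults: TGI 0.8%, CAPS 5.7%, COPISAC 3%), or MAR
  with a logistic dependence on a named fully observed covariate whose
  intercept is calibrated by root finding to hit the target rate.

What the generator does **not** emulate: sociodemographics, interpreter
or translation effects, cultural response styles, clinician-rating
dynamics, and real item marginals. Passing tests therefore demonstrate
correctness of the algorithms under the stated latent-Gaussian ordinal
model, not agreement with the clinical sample's point estimates.

## Diagnostic scoring

Probable diagnoses follow the instruments' algorithms: PGD requires
bereavement, a core symptom (longing or preoccupation), one of ten
accompanying symptoms and functional impairment — each rated ≥ 4 — plus
a loss more than 6 months ago. ICD-11 PTSD requires one symptom per
cluster (re-experiencing, avoidance, current threat) plus impairment,
each rated ≥ 2, a Criterion-A trauma and symptom duration beyond a
couple of weeks. cPTSD adds the three disturbances-in-self-organization
(DSO) gates and supersedes PTSD (no double diagnosis). Design choices
where the sources leave room:

* DSO severity defaults to CO1+CO2+CO3; CAPS 13 (also mapped to the
  relationship-disturbance criterion) can be added via
  `InstrumentSpec(include_caps13_in_dso=True)`.
* CAPS 22 is consumed as a 0/1 "duration satisfied" gate, not a
  severity rating.
* Unknown months-since-loss never defaults silently; callers must
  impute or supply a documented floor (the study could establish a
  12-month floor from biographical information).

McDonald's ω comes from a one-factor maximum-likelihood factor model on
standardized items, ω = (Σλ)² / ((Σλ)² + Σψ), with Heywood cases
clipped at zero.

## Multiple imputation

Fully conditional specification with m=20 chains and 10 sweeps in fixed
left-to-right column order (determinism). Non-dichotomous variables use
predictive mean matching: coefficients drawn from the normal
approximation to the Bayesian linear-regression posterior (residual
variance from its scaled inverse-χ² draw), five nearest-predicted-mean
donors, one copied uniformly. Dichotomous variables use logistic
imputation with an asymptotic-posterior draw; separation falls back to
a ridge-penalized fit and a degenerate observed class imputes itself.
Each conditional model uses the (default 15) predictors with highest
absolute Spearman correlation on pairwise-complete data — a cap chosen
because the study had far more items than participants. Rubin's rules
pool estimates; correlations pool on the Fisher-z scale with variance
1/(n−3).

## Network estimation

Polychoric correlations are estimated pairwise by two-step maximum
likelihood: thresholds from marginal cumulative proportions, then the
latent correlation maximizing the bivariate-normal cell-probability
likelihood over (−0.999, 0.999). Rectangle probabilities are evaluated
exactly through Owen's T function (vectorized; cross-checked against
`scipy.stats.multivariate_normal`). Cell frequencies are normalized so
the objective is invariant to duplicated rows — this makes stacked
estimation with identical imputations exactly equal to single-dataset
estimation. The assembled matrix is repaired to positive definiteness
by eigenvalue clipping at 1e−6 and rescaling to unit diagonal.

The graphical lasso maximizes `log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|`
by Friedman-style block coordinate descent; convergence is declared
when a sweep moves no covariance entry by more than 1e−9 and the
duality gap of the returned precision is verified below 1e−6. λ = 0
returns `inv(S)` exactly. Model selection runs 100 log-spaced penalties
from λ_max = max off-diagonal |S| down to 0.01·λ_max and picks the
minimum of EBIC = −n(log det Θ − tr(SΘ)) + E log n + 4Eγ log p with
γ = 0.5 (ties go to the smallest penalty — the densest candidate — for
determinism). Multiply imputed data are stacked: all m completed
datasets concatenated, one polychoric matrix, one selection, with the
effective sample size fixed at the original N (stacking reuses each
participant m times and carries no additional information).

"Mean edge weight" is reported both over all node pairs and over
selected edges; the all-pairs version is the headline because the two
conventions differ exactly when the network is sparse.

## Centrality

Strength is the sum of absolute incident edge weights; bridge strength
sums only edges crossing between the two theoretical communities, the
7 PGD symptoms versus the 6 cPTSD clusters (not a PTSD/DSO split —
cPTSD subsumes the PTSD symptoms). Absolute values are the default
convention (a signed variant is available); z-standardized versions are
exported alongside raw sums since published centrality plots do not
always state their scaling.

## Stability

Edge-weight uncertainty uses bootstrap-then-impute: resample N
participants with replacement from the original incomplete data,
multiply impute each bootstrap sample, re-estimate the stacked network,
and take percentile CIs of the replicate edge weights (percentile
rather than BCa, the convention of the widely used network-bootstrap
tooling). Replicates
whose resample makes a node constant are redrawn and counted.
Centrality robustness uses the case-dropping subset bootstrap with
integer drop counts sampled uniformly between 5% and 75% of N —
integer granularity matters because CS-coefficients at N=92 move in
1/92 steps. The CS-coefficient is the largest drop fraction k/N such
that at every level k′ ≤ k at least 95% of replicates correlate ≥ 0.7
with the full-sample centralities; requiring all smaller levels to pass
keeps the definition monotone and immune to single-level flukes. Each
subset is re-imputed, consistent with treating the imputation as part
of the estimator.

Full-scale profiles (1000 bootstraps × 20 imputations) re-run the whole
imputation-plus-estimation pipeline per replicate and are
cluster-scale; `n_boot` and `m_per_boot` scale down without changing
the algorithm. The shipped analysis scripts and the acceptance script
use reduced profiles (B≈100–200, m_per_boot 1–2, bootstrap cohorts of
n=300) chosen as the package's default desk-scale configuration; tests
state their profile explicitly.

## Numerical choices and degenerate inputs

* Latent thresholds beyond ±8 SD are clipped (the affected tail mass is
  below 1e−15).
* Polychoric optimization is bounded at |ρ| ≤ 0.999; a duplicated
  column therefore returns 0.999 rather than diverging. Constant
  columns raise, naming the node.
* PMM with a singular design falls back to a small ridge penalty with a
  warning; donor pools larger than the observed count raise.
* Zero-variance centrality vectors yield undefined correlations; these
  replicates are recorded as missing and excluded from CS-coefficients
  with a warning.
* All randomness flows from one integer seed through named substreams
  (CRC-hashed), so individual stages are reproducible even when run in
  isolation.

## Known limitations

* The positive-definiteness repair shrinks strong weight/density
  combinations; generated networks at density 0.5 cannot carry partial
  correlations near 0.49, so absolute edge-weight magnitudes of the
  study are not reproducible, only the structural regime.
* Polychoric estimation is pairwise two-step, not full-information ML;
  the subsequent eigenvalue repair can perturb individual entries.
* At N≈92 with γ=0.5 the selector is deliberately conservative; on
  synthetic data in this regime it frequently returns an empty or
  near-empty network, which is the expected behavior of the selector at
  this signal-to-sample ratio, not an implementation artifact.
* The FCS implementation supports PMM and logistic steps only — no
  passive imputation, interactions, or multilevel structure.
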