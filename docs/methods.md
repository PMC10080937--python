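# Methods

## Model structure and assumptions

The model is a single-period, two-strategy decision tree for a cohort of
healthy school-age children followed for six months. The root chance node
of each strategy splits on whether the child experiences at least one
acute respiratory infection (ARI) over the horizon; each branch then
splits on survival, giving four terminal states: death after ARI, survival
after ARI, survival without ARI, and death from all causes. The only
structural difference between strategies is the ARI probability, which the
supplemented arm multiplies by the relative risk RR. There are no cycles,
no discounting (the horizon is half a year), and probabilities are
cohort-level, not individual trajectories.

Conventions where the source material for this class of model leaves
choices open, adopted once and used everywhere:

- **Utilities.** ARI-free survivors carry utility weight 1 for the whole
  period, ARI survivors 1 − d (d = episode disutility), deaths 0. The
  reported "QALY" is this expected utility weight, *not* multiplied by the
  half-year horizon; that matches the ≈0.99 magnitudes conventionally
  printed for this model. `scale_by_horizon` (default off) multiplies by
  horizon_days/365 for true QALY accounting.
- **Costs.** Decedents on the ARI branch accrue the full episode cost;
  all-cause deaths on the ARI-free branch accrue no disease cost. The
  supplementation cost c_vd·t_vd accrues in full on every terminal of the
  supplemented strategy, deaths included.
- **Episode duration.** The ARI cost enters per day ($880) while results
  are per person, so a costed episode length is required; the default is
  10 days (0.22 × 880 × 10 = $1,936 per unsupplemented child, consistent
  with the reported per-person cost magnitude). `episode_days` is a
  first-class input, never hard-coded.
- **Supplementation duration** defaults to the 182-day horizon (trials
  supplemented daily for 6–12 months).

## Parameters

| name | meaning | default | uncertainty |
|---|---|---|---|
| p_ari | P(≥1 ARI) over 6 months | 0.22 | beta, SD 0.005 |
| rr_vitd | relative risk of ARI, supplemented | 0.71 | lognormal, log-SD 0.11 |
| m_ari | death given ARI | 0.0001 | beta, SD 0.000029 |
| m_all | all-cause death, ARI-free branch | 0.0008 | beta, SD 0.00022 |
| du_ari | utility decrement during ARI | 0.06 | beta, SD 0.015 |
| c_ari_day | ARI cost per day (2020 USD) | 880 | gamma, SD 222 |
| c_vitd_day | vitamin D3 400 IU daily cost (USD) | 0.08 | gamma, SD 0.02 |
| episode_days | costed episode length (days) | 10 | — |
| suppl_days | supplementation duration (days) | 182 | — |
| wtp | willingness-to-pay per QALY (USD) | 19,000 | — |

Beta and gamma distributions are fitted by method of moments from the
(mean, SD) pairs; only the families and SDs are reported for this model,
so moment matching is the natural parameterization. The relative risk's
"SD 0.11" is read as a **log-scale** SD about a median of 0.71:
exp(ln 0.71 ± 1.96·0.11) ≈ (0.57, 0.88) reproduces the lower limit of the
meta-analytic confidence interval the point estimate comes from, which
confirms the log-scale reading; a beta distribution was rejected for the
relative risk because its support cannot represent RR > 1. The all-cause
mortality 0.0008 is applied on the ARI-free branch only (its placement is
otherwise ambiguous; applying it there keeps the four-state partition
exhaustive).

## Sensitivity analyses

**One-way (tornado).** Each uncertain parameter moves to the bounds of the
equal-tailed 95% interval of its own uncertainty distribution (the source
ranges are unstated, so the PSA distributions supply them), all others at
base values; the default metric is incremental NMB at the configured WTP,
which captures both the cost and the QALY channel. Bounds are truncated to
the parameter's support, and the RR upper bound is clipped so p·RR ≤ 1.
Entries sort by descending output range, ties alphabetically.

**Probabilistic (second-order Monte Carlo).** Default 10,000 replications.
Parameters are sampled mutually independently, parameter-major with one
numpy Generator stream per parameter keyed by (run seed, SHA-256 digest of
the parameter name), so draws are reproducible bitwise and adding a
parameter never perturbs another's stream. Both strategies share each
draw's values (common random numbers). Draws with p·RR > 1 — possible
because the lognormal RR is unbounded — have the supplemented-arm ARI
probability capped at 1 and are counted (`n_capped`); rejection resampling
is available via `resample_infeasible`. The tree is rebuilt and rolled
back for every draw; the closed-form increment identities are used only as
an independent cross-check in the tests.

CEAC: at each λ the intervention's acceptability is the fraction of draws
with λ·ΔQ − ΔC > 0; exact ties count for the comparator (conservative
toward the intervention), so the two curves sum to 1 by construction. The
frontier reports, at each λ, the strategy with maximal mean NMB and that
strategy's CEAC value. CE-plane quadrant shares classify (ΔQ, ΔC) sign
pairs; boundary points go to the adjacent quadrant clockwise (+ΔQ axis →
SE, +ΔC axis → NE, −ΔQ axis → NW, −ΔC axis → SW, origin → NE), recorded in
output metadata. Default WTP grid: 0–60,000 in steps of 500.

## Numerical choices

- Chance-node probabilities must sum to 1 within 1e−12; path-probability
  mass conservation is asserted at the same tolerance.
- Roll-back vs path-enumeration agreement is required to 1e−9 relative;
  engine vs closed-form increments to 1e−12 on utility (magnitude ≤ 1) and
  to 1e−12 relative to the roll-back cost magnitude on cost, which is the
  double-precision resolution limit for sums in the 10⁴ USD range.
- Tornado quantiles use exact scipy quantile functions (z = 1.959964 for
  95%), not the rounded z = 1.96.
- CSV output prints money to 2 decimals and probabilities/utilities to 6;
  JSON keeps full precision. All tabular outputs carry a provenance header
  (config hash, seed, n).

## Synthetic scenarios and what the tests show

`scenario_gen` produces random parameter tables with the same statistical
structure as the real input set — beta-uncertain probabilities,
gamma-uncertain costs, a lognormal relative risk — over ranges that
bracket the published values (p_ari ∈ [0.05, 0.5], RR ∈ [0.4, 1.2]
including harmful RR > 1, episode costs spanning two orders of magnitude),
plus random chance-node trees (depth ≤ 4, branching ≤ 4) with
flat-Dirichlet branch probabilities for the roll-back oracle, the analytic
null scenario (RR = 1, zero supplement cost, increments exactly 0), and a
moment-recovery report that flags sampler deviations beyond 4 SE.

These scenarios exercise the *arithmetic* of the model under its stated
distributional assumptions. They do not emulate parameter correlation
(e.g., between ARI risk and cost), heterogeneity across ages or settings,
or sampling noise in the source estimates themselves, so passing tests
validate the implementation of the model, not the model's fidelity to any
particular population.

Test and script problem sizes — 1,000 random trees and tables for the
oracle suites, 10,000 PSA replications — match the analysis defaults and
run in seconds.

## Known limitations

- Two strategies only; no efficiency frontier over many comparators.
- Single-period tree: no recurrence, seasonality or multi-cycle dynamics.
- Parameters are sampled independently; no correlation structure or EVPI.
- The per-person cost level depends on the assumed 10-day costed episode;
  the dominance *direction* is insensitive to it above the ≈$228 episode
  cost threshold, but reported cost magnitudes are conditional on it.
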