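# vitd-cua

Decision-analytic cost-utility model of daily vitamin D supplementation for
preventing acute respiratory infections (ARI) in healthy school-age
children, built for health-economics practitioners who want the full
analysis — base case, deterministic and probabilistic sensitivity analysis —
as tested, scriptable Python rather than a spreadsheet.

## The model

Two strategies (vitamin D3 400 IU daily vs no supplementation) are compared
over a six-month horizon with a single-period decision tree over four
terminal health states: death after ARI, survival after ARI, survival
without ARI, and death from all causes. With baseline ARI probability *p*,
relative risk *RR* under supplementation, ARI case fatality *m₁*, all-cause
death probability *m₀* on the ARI-free branch, and disutility *d* during an
ARI episode, each strategy's expected cost *C* and expected utility weight
*Q* come from rolling the tree back; the supplemented arm uses ARI
probability *p·RR* and carries the supplementation cost on every terminal.
The increments have closed forms

```
ΔQ = p(1−RR)[(1−m₀) − (1−m₁)(1−d)]
ΔC = c_vd·t_vd − p(1−RR)·c_ari·t_ep
```

(c_vd, t_vd: supplement daily cost and duration; c_ari, t_ep: ARI daily cost
and costed episode length), which serve as an independent oracle for the
tree engine. Strategies are compared by net monetary benefit
NMB = λ·Q − C at willingness-to-pay λ, with dominance/ICER classification.
Uncertainty propagates by one-way tornado analysis over each parameter's
95% interval and by second-order Monte Carlo simulation (default 10,000
replications; beta uncertainty for probabilities and the disutility, gamma
for costs, lognormal for the relative risk), summarized as the
cost-effectiveness plane, acceptability curve (CEAC) and acceptability
frontier.

## Worked example

```python
import vitd_cua as v

table = v.default_table()          # published base-case inputs
result = v.evaluate_base_case(table)
print(result.comparator)           # no supplementation
print(result.intervention)         # vitamin D
print(result.classification.kind, round(result.savings, 2))
```

prints

```
StrategyResult(name='no-supplementation', expected_cost=1936.0, expected_qaly=0.98615532)
StrategyResult(name='vitamin-D', expected_cost=1389.1200000000001, expected_qaly=0.9899382771999999)
intervention-dominant 546.88
```

At base-case inputs the supplemented strategy costs $546.88 less per child
and yields 0.0038 more QALYs (0.99 vs 0.98 at two decimals), so it
dominates absolutely and no ICER applies. The episode-cost threshold above
which supplementation is cost-saving is
`v.dominance_threshold_episode_cost(table)` ≈ $228.21.

The same analyses are available from the shell:

```
vitd-cua base-case                 # incremental cost-utility table (CSV + JSON)
vitd-cua tornado --metric delta_cost
vitd-cua psa --n 10000 --seed 7 --out draws.csv
vitd-cua ceac --grid 0:60000:500
vitd-cua plane --wtp 19000
vitd-cua fixtures --seed 1 --out fixtures/
```

Every command accepts `--config <file>` (JSON; the bundled default is
`src/vitd_cua/data/base_case.json`) and writes a provenance manifest next
to its outputs; identical config and seed give byte-identical numeric
output.

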