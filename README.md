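# cvdabm

Agent-based simulation of how the four major behavioural cardiovascular
risk factors — smoking, harmful alcohol use, poor diet and physical
inactivity — spread through the social networks of a city-scale adult
population, and of the fatal CVD events that follow.

It is aimed at public-health modellers who want to test network-mediated
interventions (for example, workplace programmes promoting diet or
activity) before committing to them, on populations of 10⁴–10⁶ agents.

## Model

Agents (adults 18–89 with age, sex, IMD decile) are connected by four
relationship types in a strict hierarchy, marriage ≻ household ≻
friendship ≻ workplace — each pair holds at most its highest tie. The
friendship layer is a Newman–Watts–Strogatz small-world graph (mean degree
6, 7% of agents excluded); workplaces are contact-group cliques over the
employed.

Behaviours have adoption levels ℓ ∈ {0, 1, 2} (higher = riskier) and
spread by a modified linear threshold rule: agent *v* with threshold
θ_v ~ N(0.8, 0.05) truncated to (0, 1) adopts, for each behaviour *b*,
a level from

&nbsp;&nbsp;E = { ℓ : Σ_{u ∈ N(v), level_b(u) = ℓ} w(rel(u, v), b, ℓ) > θ_v },

keeping its current level if E is empty and sampling ℓ ∈ E with
probability proportional to the influence sums otherwise. Smoking level 0
("never smoked") is never re-adoptable. Updates are synchronous with
snapshot semantics.

Annual CVD risk is a QRISK-style survival form, risk₁₀ = 1 − s0^exp(lp(age)),
per sex, multiplied by four behaviour-level factors and divided by 10;
events are fatal and remove the agent and its edges. Reports give incident
cases, person-years and rates per 1,000 person-years by five-year age group
(25–84) and sex.

The 36 relationship-influence strengths w are calibrated against observed
incidence by random-restart hill climbing (±U(0, 0.05) proposals,
accept-if-better, failure-driven restarts, five refinement rounds
re-centred on the incumbent ± 0.1; full protocol 500 × 100 × 5 = 250,000
parameter sets). The calibrated strengths ship as defaults.

All inputs are plain CSV files; `cvdabm.generate_fixture_parameters` writes
a complete synthetic parameter directory, so everything builds and runs
with no external data. Real demographic/risk CSVs can be dropped in with
the same schemas (see `docs/methods.md`).

## Worked example

```python
import cvdabm as c

params = c.generate_fixture_parameters(seed=1)       # synthetic England-like inputs
cfg = c.SimulationConfig(target_population=20_000, steps=10, seed=1, replicates=4)
agg = c.aggregate_runs(c.run_replicates(cfg, params))
print(agg.totals.round(2).to_string(index=False))
```

```
   sex  incident_cases_mean  incident_cases_sd  person_years_mean  person_years_sd  rate_mean  rate_sd
female              1278.50              32.78           82113.75           292.47      15.57     0.42
  male              1975.25              24.60           78438.75           184.98      25.18     0.37
```

Over ten simulated years of a 20,000-agent synthetic cohort, women
experience on average 1,278.5 fatal CVD events across 82,114 person-years
at risk (ages 25–84), i.e. 15.6 events per 1,000 person-years; men 25.2.
The standard deviations are across the four replicate populations. These
rates reflect the synthetic fixture inputs; reproducing observed incidence
for a real population requires supplying its parameter CSVs in place of
the fixture.

The same from the shell, plus an intervention:

```bash
cvdabm fixture --out params/ --seed 1
cvdabm simulate  --params params/ --population 20000 --steps 10 --replicates 4 --seed 1 --out base.csv
cvdabm intervene --params params/ --behaviours diet,inactivity --adoption 1.0 \
                 --contact-mean 21 --population 20000 --replicates 4 --seed 1 --out intervened.csv
cvdabm calibrate --params params/ --searches 10 --iterations 40 --rounds 3 --out influence.csv
```

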