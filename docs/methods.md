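# Methods

`cvdabm` simulates how four behavioural cardiovascular risk factors —
smoking, harmful alcohol use, poor diet and physical inactivity — spread
through the social networks of a city-scale adult population, and how the
resulting behaviour mix translates into fatal CVD events over a ten-year
horizon. This note records the model, its assumptions, the parameters that
matter, and the design choices made where more than one reasonable
convention exists.

## Population and networks

Agents are adults aged 18–89 with age, sex and an IMD decile (Index of
Multiple Deprivation, the English area-deprivation measure used as
socio-economic status). The population is generated household-by-household:
a focal adult is drawn from the joint (age, sex) distribution; marriage is
decided by an (age, sex) probability; a spouse's sex is decided first by
the same-sex-marriage fraction and their age then drawn from the
age-assortative conditional; further adults fill the household up to a size
drawn from the household-size distribution (the couple counts toward it; a
sampled size smaller than the members already present keeps them). All
household members share the focal agent's IMD decile. Generation stops
after the household in which the target size N is reached, so the realised
population overshoots by at most max household size − 1.

Four relationship types form a strict hierarchy, marriage ≻ household ≻
friendship ≻ workplace; any pair of agents holds at most the highest
applicable tie, so relationship influence is never cumulative across types.
Households are cliques (with the spousal pair carrying a marriage edge).
The friendship layer is a Newman–Watts–Strogatz small-world graph
(Barabási–Albert optional) over a random 93% of agents — the default 7%
exclusion models adults without close friends, who still hold household and
workplace ties. NWS uses ring degree k = round(mean degree 6) and shortcut
probability p = 0.01: NWS only adds edges, so a small p keeps the realised
mean degree ≈ k(1+p) ≈ 6. BA uses m = round(k/2), giving mean degree ≈ 2m.
Workplace contact groups partition the employed agents (employment is
Bernoulli in age, sex and IMD): a workplace-size category is sampled, the
group size is round(Normal(category mean, sd)) with a floor of 2, and
groups are filled from a shuffled list until everyone is assigned — only
the final group can fall short of its sampled size. The group-size sd is
not pinned down by any external convention; the default is mean/4,
exposed in the configuration. Contact means may be per-category (fixture
default 4/8/15/21) or fixed for a whole scenario (4 or 21 are the two
canonical settings).

## Behaviour spread

Each behaviour has ordinal adoption levels 0/1/2 (higher = riskier),
initialised from prevalence by (age, sex). Spread follows a modified
linear-threshold rule. Each agent has one scalar threshold drawn from
Normal(0.8, 0.05) truncated to (0, 1) by resampling (a threshold outside
(0, 1) is meaningless against influence sums bounded below by 0). Per
yearly step, the influence arriving at an agent is summed per (behaviour,
level) over neighbours' levels *at the start of the step* — 12 totals. For
each behaviour, levels whose total strictly exceeds the threshold are
candidates: none → keep the current level; one → adopt it; several → adopt
with probability proportional to the totals. "Exceeds" is strict; ties at
exactly the threshold are measure-zero under the Gaussian and strictness is
documented for reproducibility. Influence toward the agent's own current
level re-adopts it (a no-op), the natural fixed point. Smoking level 0
means "never smoked": it is removed from the candidate set of any agent
that has ever smoked *before* tie-breaking, so a never-adoptable level
cannot absorb tie-break probability mass.

The population step is two-phase (compute all updates from the snapshot,
then commit), and the per-(agent, behaviour) uniforms are drawn in agent-id
order from a (seed, step)-keyed generator, so the committed state is
independent of processing order and bit-reproducible.

## CVD risk

The ten-year baseline risk uses the survival form of QRISK-style scores,
risk = 1 − s0^exp(lp), per sex, with the linear predictor built from age
terms only (intercept, age−60, (age−60)²/100); the default clinical values
for BMI, cholesterol ratio and blood pressure are treated as folded into
the coefficients. Real QRISK core coefficients can be supplied through
`baseline_risk.csv`; the fixture ships synthetic coefficients of the same
functional form (women s0 = 0.93, age slope 0.089; men s0 = 0.88, slope
0.091, intercept 0.05), chosen so that risk rises roughly 1.5× per five
years of age and men exceed women at every age, matching the qualitative
epidemiology. The baseline is multiplied by one user-defined factor per
behaviour, keyed by (level, age band, sex) with half-open bands [lo, hi);
behaviour history carries no duration effect. The product is divided by 10
to give the annual event probability, clamped to [0, 1]. Risk applies only
at ages 25–84 (the validity window of the underlying score); younger and
older agents have probability 0 and accrue no person-years.

## Simulation loop and accounting

Per yearly step: (1) influence from the snapshot, (2–3) levels resolved and
committed simultaneously, (4) annual probabilities, (5) Bernoulli event
test, (6) agents with an event are removed with all their edges (every
event is fatal; the population is a closed cohort — no births, migration or
new ties). Ages advance by one year at the end of the step. A living agent
aged 25–84 at the start of a step contributes one person-year to its
current five-year age group, *including the year of its event* (full-year
attribution fits annual discrete steps), and incident cases are binned by
age at the start of the event step. Rates are cases / person-years × 1,000;
a zero person-year stratum yields an undefined-rate marker, not a number.
Replicates ("unseeded" runs) use seeds derived from one master seed by
replicate index; aggregation reports per-cell means and population
standard deviations. Formatted output rounds to one decimal; raw values
are retained.

Workplace influence is 0 by default. An intervention marks a uniformly
random fraction of workplace groups (the adoption rate) as adopting;
workplace edges inside adopting groups exert, for the targeted behaviours
at levels 0 and 1, half the friendship strength (the fraction is
configurable). Sensitivity scenarios "maximise" influence by setting the
marriage/household/friendship strengths of a (behaviour, level) to 1.0 —
the natural maximum of the [0, 1] strength scale, which a single neighbour
already pushes past any truncated-Gaussian threshold.

## Calibration

The 36 free strengths (3 relationships × 4 behaviours × 3 levels; workplace
is excluded and fixed at 0) are fitted by random-restart hill climbing.
Fitness is the mean over n simulations (default 5) of the summed absolute
difference between simulated and observed rates over the 24 (age group,
sex) cells; empty cells count their full observed rate. Proposals perturb
every entry by an independent ±U(0, 0.05), clamped to [0, 1]; only strict
improvements are accepted. The restart probability is
min(0.02 × consecutive failures, 0.5), resetting on improvement — the
increase-on-failure behaviour is specified, the schedule itself is a
package choice exposed in the API. The initial sampling range is the full
[0, 1] strength domain. The search runs in rounds (full protocol: 500
searches × 100 iterations × 5 rounds = 250,000 parameter sets), each round
re-centring the range to the incumbent best ± 0.1. The population size per
fitness simulation is configurable (CLI default 50K) since no external
convention fixes it.

## Synthetic fixture

The fixture generator emulates broad English patterns without transcribing
any real dataset: a declining adult age pyramid, marriage probability
rising through the thirties (slightly later for men), Gaussian age
assortativity of spouses (±2-year mean offset by sex), UK-like household
sizes (30% single, 40% couple), near-uniform IMD deciles, employment
peaking at ~80% in working ages, behaviour prevalence varying smoothly
with age and sex, and behaviour multipliers whose level-2 relative risks
shrink with age. The shipped influence strengths are the calibrated
defaults, and the observed-rate table is the published fatal-CVD incidence
of the QRISK derivation cohort. The seed drives small smooth jitters, so
different seeds give different but always schema-valid parameter sets.

What the fixture does *not* reproduce: real English marginals or their
correlations; a spouse conditional exactly consistent with the (age, sex)
marginal (so the generated population's marginal deviates slightly from
`age_sex.csv` whenever marriage is on — the marginal-recovery test
therefore runs with marriage disabled); realistic behaviour-transition
dynamics (under the default strengths the synthetic prevalence mix drifts
toward level 2 over a decade, which inflates fixture incidence rates above
England values). Passing tests therefore demonstrate the correctness of
the machinery — generation, hierarchy, spread rules, accounting, search —
not the empirical calibration of any real population; reproducing
published incidence requires supplying the real parameter CSVs.

## Problem sizes and numerics

Tests and the acceptance script use reduced scales chosen as the package's
own defaults for desk verification: structural network checks on 10K-agent
populations, baseline/intervention comparisons at 20K agents × 10 steps
with 4 replicates, scalability across 10K/20K/40K, and calibration checks
on a 6-variable surrogate at 10 searches × 40 iterations × 3 rounds. At
the published example scale of 10 × 20 × 2 the surrogate optimum was
recovered within 0.05 per coordinate in only a small minority of seeded
runs, so the reduced scale above (1,200 evaluations, still 200× below the
full protocol) is used as the smallest scale at which recovery is reliably
≥ 90%. Probability distributions must sum to 1 within 1e-9 per
conditioning cell; CSV round-trips are exact (shortest-repr floats).
Degenerate inputs are handled explicitly: empty distribution support is a
configuration error, exclusion fraction 1 yields no friendship edges, a
zero-employment population yields no workplace groups, and an empty living
population yields undefined prevalence.

## Known limitations

Closed cohort (no entry, no re-partnering, static networks apart from
death); children and over-89s excluded; every CVD event fatal; no
duration-dependent behaviour effects; single scalar threshold per agent
applied to all twelve behaviour-level decisions (the description of the
threshold is singular; per-behaviour thresholds would be a one-line
extension and are flagged for sensitivity exploration); optional risk-score
modifiers (ethnicity, comorbidities) ignored.
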