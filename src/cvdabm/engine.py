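"""Simulation engine: yearly loop, person-time accounting and interventions.

Each step of a run: (1) incoming influence is computed from the start-of-
step snapshot, (2-3) behaviour levels are resolved and committed
simultaneously, (4) annual event probabilities are computed from the
baseline risk and behaviour multipliers, (5) each agent is Bernoulli-tested,
(6) agents with an event are removed together with all their edges.  Ages
advance one year at the end of each step.  A living agent aged 25-84 at the
start of a step contributes one person-year to its current five-year age
group, including the year of its event; incident cases are binned by age at
the start of the event step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    AGE_GROUPS,
    BEHAVIOURS,
    InfluenceMatrix,
    ParameterSet,
    SEXES,
)
from .population import Population, RelationshipGraph, WORKPLACE, generate_population
from .risk import (
    BaselineRiskModel,
    RISK_AGE_MAX,
    RISK_AGE_MIN,
    RiskMultiplierTable,
    annual_probabilities,
)
from .spread import Layer, build_layers, step_all_behaviours
from scipy import sparse

_N_GROUPS = len(AGE_GROUPS)


@dataclass
class InterventionSpec:
    """A workplace intervention activating influence in adopting groups."""

    behaviours: tuple[str, ...]          # subset of {"diet", "inactivity"}
    adoption_rate: float                 # fraction of workplace groups adopting
    workplace_strength_fraction: float = 0.5  # of the friendship strength
    levels: tuple[int, ...] = (0, 1)

    def __post_init__(self):
        if not 0.0 <= self.adoption_rate <= 1.0:
            raise ValueError("adoption_rate must be in [0, 1]")
        if not 0.0 <= self.workplace_strength_fraction <= 1.0:
            raise ValueError("workplace_strength_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    target_population: int = 350_000
    steps: int = 10
    seed: int = 0
    replicates: int = 100
    contact_mean: float | None = None    # None -> per-category means from workplace.csv
    intervention: InterventionSpec | None = None

    def __post_init__(self):
        if self.steps < 1 or self.replicates < 1:
            raise ValueError("steps and replicates must be >= 1")


@dataclass
class MetricsReport:
    """Incidence by age group and sex, plus end-of-run behaviour prevalence."""

    by_stratum: pd.DataFrame             # age_group, sex, incident_cases, person_years, rate
    totals: pd.DataFrame                 # sex, incident_cases, person_years, rate
    level2_prevalence: dict[str, float] | None
    n_initial: int
    n_survivors: int

    @property
    def total_cases(self) -> float:
        return float(self.totals["incident_cases"].sum())


def compute_rate(cases: float, person_years: float):
    """Incidence per 1,000 person-years; None when person-years is zero."""
    if person_years == 0:
        return None
    return cases / person_years * 1000.0


def level2_prevalence(population: Population) -> dict[str, float] | None:
    """Fraction of living agents at level 2, per behaviour (None if none live)."""
    alive = population.alive
    n = int(alive.sum())
    if n == 0:
        return None
    return {
        beh: float((population.levels[alive, b] == 2).sum()) / n
        for b, beh in enumerate(BEHAVIOURS)
    }


@dataclass
class InterventionAssignment:
    """Which workplace groups adopt, and the strengths their edges carry."""

    adopting: np.ndarray                 # indices into the workplace-group list
    strengths: np.ndarray                # (behaviour, level) strengths for adopting groups

    def group_strengths(self, group_index: int) -> np.ndarray:
        """Effective workplace strengths for one group (zeros if not adopting)."""
        if group_index in set(self.adopting.tolist()):
            return self.strengths
        return np.zeros_like(self.strengths)


def apply_workplace_intervention(
    matrix: InfluenceMatrix,
    spec: InterventionSpec,
    groups: list[np.ndarray],
    rng: np.random.Generator,
) -> InterventionAssignment:
    """Mark a random fraction of workplace groups as adopting.

    Within adopting groups, workplace edges exert
    ``workplace_strength_fraction x friendship strength`` for the targeted
    (behaviour, level) pairs; all other workplace strengths stay at the
    matrix's base values (zero by default).
    """
    n_adopt = int(round(spec.adoption_rate * len(groups)))
    adopting = np.sort(rng.choice(len(groups), size=n_adopt, replace=False))
    strengths = np.zeros((len(BEHAVIOURS), 3))
    for beh in spec.behaviours:
        b = BEHAVIOURS.index(beh)
        for lvl in spec.levels:
            strengths[b, lvl] = (
                spec.workplace_strength_fraction * matrix.strength("friendship", beh, lvl)
            )
    return InterventionAssignment(adopting=adopting, strengths=strengths)


def maximise_influence(
    matrix: InfluenceMatrix, behaviour: str, level: int
) -> InfluenceMatrix:
    """Sensitivity scenario: set marriage/household/friendship strengths to 1.

    ``behaviour`` may be one of the four behaviours or ``"all"``; ``level``
    is 0 (minimum risk) or 2 (maximum risk).  With strength 1.0 a single
    neighbour exceeds any threshold drawn from the truncated Gaussian.
    """
    m = matrix.copy()
    behs = BEHAVIOURS if behaviour == "all" else (behaviour,)
    for beh in behs:
        for rel in ("marriage", "household", "friendship"):
            m.set_strength(rel, beh, level, 1.0)
    return m


def _intervention_layer(
    graph: RelationshipGraph,
    assignment: InterventionAssignment,
    n: int,
) -> Layer:
    """Adjacency over workplace edges inside adopting groups only."""
    rows, cols = [], []
    for gi in assignment.adopting:
        group = graph.workplace_groups[gi]
        for i in range(group.size):
            a = int(group[i])
            for j in range(i + 1, group.size):
                b = int(group[j])
                if graph.relationship(a, b) == "workplace":
                    rows += [a, b]
                    cols += [b, a]
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return Layer(adj, assignment.strengths.copy())


def _age_group_index(ages: np.ndarray) -> np.ndarray:
    """Five-year age-group index for ages 25-84 (-1 outside)."""
    idx = (ages - RISK_AGE_MIN) // 5
    idx[(ages < RISK_AGE_MIN) | (ages > RISK_AGE_MAX)] = -1
    return idx


def run_simulation(
    config: SimulationConfig,
    params: ParameterSet,
    seed: int | None = None,
    population: Population | None = None,
    graph: RelationshipGraph | None = None,
) -> MetricsReport:
    """One full simulation: generate a population and run the yearly loop.

    All randomness derives from ``seed`` (default ``config.seed``) through
    purpose-keyed streams, so a fixed (config, params, seed) triple gives a
    bit-identical report.  A pre-built population/graph pair may be supplied
    for controlled experiments.
    """
    if seed is None:
        seed = config.seed
    if population is None or graph is None:
        rng_pop = np.random.default_rng([int(seed), 0])
        population, graph = generate_population(
            config.target_population, params, rng_pop, contact_mean=config.contact_mean
        )
    n = population.n

    layers = build_layers(graph, params.influence, n)
    if config.intervention is not None:
        rng_int = np.random.default_rng([int(seed), 3])
        assignment = apply_workplace_intervention(
            params.influence, config.intervention, graph.workplace_groups, rng_int
        )
        layers.append(_intervention_layer(graph, assignment, n))

    model = BaselineRiskModel.from_frame(params.baseline_risk)
    table = RiskMultiplierTable.from_frame(params.multipliers)

    cases = np.zeros((_N_GROUPS, 2))
    person_years = np.zeros((_N_GROUPS, 2))

    for step in range(config.steps):
        grp = _age_group_index(population.age)
        at_risk = population.alive & (grp >= 0)
        np.add.at(person_years, (grp[at_risk], population.sex[at_risk]), 1.0)

        rng_beh = np.random.default_rng([int(seed), 1, step])
        step_all_behaviours(population, None, None, rng_beh, layers=layers)

        p = annual_probabilities(population, model, table)
        rng_evt = np.random.default_rng([int(seed), 2, step])
        u = rng_evt.random(n)
        events = population.alive & (u < p)

        np.add.at(cases, (grp[events], population.sex[events]), 1.0)
        population.alive[events] = False
        for i in np.flatnonzero(events):
            graph.remove_agent(int(i))

        population.age += 1

    rows = []
    for g, group in enumerate(AGE_GROUPS):
        for s, sex in enumerate(SEXES):
            rate = compute_rate(cases[g, s], person_years[g, s])
            rows.append(
                {
                    "age_group": group,
                    "sex": sex,
                    "incident_cases": cases[g, s],
                    "person_years": person_years[g, s],
                    "rate": np.nan if rate is None else rate,
                }
            )
    by_stratum = pd.DataFrame(rows)
    tot_rows = []
    for s, sex in enumerate(SEXES):
        c, py = cases[:, s].sum(), person_years[:, s].sum()
        rate = compute_rate(c, py)
        tot_rows.append(
            {
                "sex": sex,
                "incident_cases": c,
                "person_years": py,
                "rate": np.nan if rate is None else rate,
            }
        )
    totals = pd.DataFrame(tot_rows)

    return MetricsReport(
        by_stratum=by_stratum,
        totals=totals,
        level2_prevalence=level2_prevalence(population),
        n_initial=n,
        n_survivors=population.n_alive,
    )


def _derived_seed(master: int, replicate: int) -> int:
    return int(np.random.SeedSequence([int(master), int(replicate)]).generate_state(1)[0] % 2**31)


def run_replicates(
    config: SimulationConfig, params: ParameterSet, progress: bool = False
) -> list[MetricsReport]:
    """Run ``config.replicates`` simulations with replicate-derived seeds.

    Each replicate generates a fresh population; seeds derive from the
    master seed by replicate index so the experiment is reproducible
    without correlated streams.
    """
    reports = []
    for rep in range(config.replicates):
        reports.append(run_simulation(config, params, seed=_derived_seed(config.seed, rep)))
        if progress:
            print(f"replicate {rep + 1}/{config.replicates} done")
    return reports


@dataclass
class AggregateReport:
    by_stratum: pd.DataFrame   # mean and sd per (age_group, sex) cell
    totals: pd.DataFrame       # mean and sd per sex
    level2_prevalence: pd.DataFrame  # behaviour, mean, sd
    n_replicates: int


def aggregate_runs(reports: list[MetricsReport]) -> AggregateReport:
    """Per-cell arithmetic mean and population standard deviation."""
    if not reports:
        raise ValueError("need at least one report")
    ref = reports[0].by_stratum[["age_group", "sex"]]
    for r in reports[1:]:
        if not r.by_stratum[["age_group", "sex"]].equals(ref):
            raise ValueError("reports have mismatched strata")

    def agg(frames: list[pd.DataFrame], keys: list[str], cols: list[str]) -> pd.DataFrame:
        stacked = np.stack([f[cols].to_numpy(float) for f in frames])
        out = frames[0][keys].copy()
        for j, c in enumerate(cols):
            out[f"{c}_mean"] = stacked[:, :, j].mean(axis=0)
            out[f"{c}_sd"] = stacked[:, :, j].std(axis=0)  # population sd
        return out

    cols = ["incident_cases", "person_years", "rate"]
    by_stratum = agg([r.by_stratum for r in reports], ["age_group", "sex"], cols)
    totals = agg([r.totals for r in reports], ["sex"], cols)

    prev = np.array(
        [[r.level2_prevalence[b] for b in BEHAVIOURS] for r in reports if r.level2_prevalence]
    )
    level2 = pd.DataFrame(
        {"behaviour": BEHAVIOURS, "mean": prev.mean(axis=0), "sd": prev.std(axis=0)}
    )
    return AggregateReport(
        by_stratum=by_stratum,
        totals=totals,
        level2_prevalence=level2,
        n_replicates=len(reports),
    )
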