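"""Synthetic population and social-network generation.

A population is built household-by-household (sampling a focal adult, an
optional spouse, and further adult household members) until the target size
is reached, then a small-world friendship network and workplace contact
groups are layered on top.  Relationships obey a strict hierarchy
marriage > household > friendship > workplace: any agent pair holds at most
one relationship, the highest-ranked that applies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .parameters import (
    AGE_MAX,
    AGE_MIN,
    BEHAVIOURS,
    ConfigurationError,
    ParameterSet,
    RELATIONSHIPS,
    SEXES,
)

MARRIAGE, HOUSEHOLD, FRIENDSHIP, WORKPLACE = range(4)  # rank order: lower wins

_N_AGES = AGE_MAX - AGE_MIN + 1


@dataclass
class Agent:
    """Read-only view of one agent's attributes."""

    id: int
    age: int
    sex: str
    imd: int
    employed: bool
    threshold: float
    level: dict[str, int]
    ever_smoked: bool
    alive: bool


class Population:
    """Column-oriented store of agent attributes.

    ``sex`` is coded 0 = female, 1 = male; ``levels`` has one int8 column
    per behaviour in the order smoking, alcohol, diet, inactivity.
    """

    def __init__(self, age, sex, imd):
        self.age = np.asarray(age, dtype=np.int32)
        self.sex = np.asarray(sex, dtype=np.int8)
        self.imd = np.asarray(imd, dtype=np.int8)
        n = self.n
        self.employed = np.zeros(n, dtype=bool)
        self.threshold = np.full(n, np.nan)
        self.levels = np.zeros((n, len(BEHAVIOURS)), dtype=np.int8)
        self.ever_smoked = np.zeros(n, dtype=bool)
        self.alive = np.ones(n, dtype=bool)

    @property
    def n(self) -> int:
        return self.age.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def agent(self, i: int) -> Agent:
        return Agent(
            id=i,
            age=int(self.age[i]),
            sex=SEXES[self.sex[i]],
            imd=int(self.imd[i]),
            employed=bool(self.employed[i]),
            threshold=float(self.threshold[i]),
            level={b: int(self.levels[i, j]) for j, b in enumerate(BEHAVIOURS)},
            ever_smoked=bool(self.ever_smoked[i]),
            alive=bool(self.alive[i]),
        )


class RelationshipGraph:
    """Undirected typed graph holding at most one relationship per pair.

    ``add_relationship`` enforces the hierarchy: if a pair already holds a
    relationship, the higher-ranked (lower code) one is kept.
    """

    def __init__(self):
        self._adj: dict[int, dict[int, int]] = {}
        self.workplace_groups: list[np.ndarray] = []

    def add_relationship(self, a: int, b: int, rel: int) -> bool:
        """Record a relationship; returns True if ``rel`` is now stored."""
        if a == b:
            raise ValueError("self-edges are not allowed")
        existing = self._adj.get(a, {}).get(b)
        if existing is not None and existing <= rel:
            return False
        self._adj.setdefault(a, {})[b] = rel
        self._adj.setdefault(b, {})[a] = rel
        return True

    def has_edge(self, a: int, b: int) -> bool:
        return b in self._adj.get(a, {})

    def relationship(self, a: int, b: int) -> str | None:
        rel = self._adj.get(a, {}).get(b)
        return None if rel is None else RELATIONSHIPS[rel]

    def neighbors(self, a: int) -> dict[int, int]:
        return self._adj.get(a, {})

    def edges(self):
        """Yield (a, b, relationship code) with a < b."""
        for a, nbrs in self._adj.items():
            for b, rel in nbrs.items():
                if a < b:
                    yield a, b, rel

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def degree(self, a: int) -> int:
        return len(self._adj.get(a, {}))

    def remove_agent(self, a: int) -> None:
        for b in list(self._adj.get(a, {})):
            del self._adj[b][a]
        self._adj.pop(a, None)

    def to_sparse(self, rel: int, n: int) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency of one relationship type."""
        rows, cols = [], []
        for a, b, r in self.edges():
            if r == rel:
                rows += [a, b]
                cols += [b, a]
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


class _Categorical:
    """Sampling from a fixed discrete distribution via inverse CDF."""

    def __init__(self, values, probabilities):
        self.values = np.asarray(values)
        p = np.asarray(probabilities, dtype=float)
        total = p.sum()
        if total <= 0 or self.values.size == 0:
            raise ConfigurationError("degenerate distribution with empty support")
        self.cum = np.cumsum(p / total)

    def sample(self, rng: np.random.Generator):
        i = int(np.searchsorted(self.cum, rng.random(), side="right"))
        return self.values[min(i, self.values.size - 1)]

    def sample_n(self, rng: np.random.Generator, n: int):
        idx = np.searchsorted(self.cum, rng.random(n), side="right")
        return self.values[np.minimum(idx, self.values.size - 1)]


class _Samplers:
    """Distribution tables of a ParameterSet compiled into fast lookups."""

    def __init__(self, params: ParameterSet):
        df = params.age_sex
        self.age_sex = _Categorical(
            [(int(a), SEXES.index(s)) for a, s in zip(df["age"], df["sex"])],
            df["probability"].to_numpy(),
        )

        self.marriage_p = np.zeros((_N_AGES, 2))
        for _, row in params.marriage.iterrows():
            self.marriage_p[int(row["age"]) - AGE_MIN, SEXES.index(row["sex"])] = row["probability"]

        # spouse age conditional, indexed by (proband age, proband sex, spouse sex)
        self.spouse: dict[tuple[int, int, int], _Categorical] = {}
        for (p_age, p_sex, s_sex), grp in params.spouse.groupby(
            ["proband_age", "proband_sex", "spouse_sex"]
        ):
            self.spouse[(int(p_age), SEXES.index(p_sex), SEXES.index(s_sex))] = _Categorical(
                grp["spouse_age"].to_numpy(int), grp["probability"].to_numpy()
            )

        hs = params.household_size
        self.household_size = _Categorical(hs["size"].to_numpy(int), hs["probability"].to_numpy())
        self.max_household_size = int(hs.loc[hs["probability"] > 0, "size"].max())

        self.imd: dict[tuple[int, int], _Categorical] = {}
        for (age, sex), grp in params.imd.groupby(["age", "sex"]):
            self.imd[(int(age), SEXES.index(sex))] = _Categorical(
                grp["decile"].to_numpy(int), grp["probability"].to_numpy()
            )

        self.employment_p = np.zeros((_N_AGES, 2, 10))
        for _, row in params.employment.iterrows():
            self.employment_p[
                int(row["age"]) - AGE_MIN, SEXES.index(row["sex"]), int(row["decile"]) - 1
            ] = row["probability"]

        # prevalence CDF over levels, per (behaviour, sex, age)
        self.prevalence_cdf = np.zeros((len(BEHAVIOURS), 2, _N_AGES, 3))
        pv = params.prevalence
        b_idx = pv["behaviour"].map({b: i for i, b in enumerate(BEHAVIOURS)}).to_numpy()
        s_idx = pv["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()
        a_idx = pv["age"].to_numpy(int) - AGE_MIN
        l_idx = pv["level"].to_numpy(int)
        p = np.zeros_like(self.prevalence_cdf)
        p[b_idx, s_idx, a_idx, l_idx] = pv["probability"].to_numpy()
        self.prevalence_cdf = np.cumsum(p, axis=-1)

        wp = params.workplace
        self.workplace_category = _Categorical(
            np.arange(len(wp)), wp["probability"].to_numpy()
        )
        self.contact_means = wp["contact_mean"].to_numpy(float)


def _sample_thresholds(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, 1) by resampling."""
    t = rng.normal(mean, sd, n)
    bad = (t <= 0) | (t >= 1)
    while bad.any():
        t[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (t <= 0) | (t >= 1)
    return t


def generate_households(
    target_size: int, params: ParameterSet, rng: np.random.Generator
) -> tuple[Population, RelationshipGraph]:
    """Generate agents household-by-household with marriage + household edges.

    Households are produced sequentially until the target population size is
    reached mid-household, so the final count N satisfies
    ``target_size <= N <= target_size + max_household_size - 1``.  All
    members of a household share the IMD decile sampled for its focal agent.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    s = _Samplers(params)

    ages: list[int] = []
    sexes: list[int] = []
    imds: list[int] = []
    graph = RelationshipGraph()
    n = 0

    while n < target_size:
        age0, sex0 = s.age_sex.sample(rng)
        members = [n]
        ages.append(age0)
        sexes.append(sex0)
        n += 1

        if rng.random() < s.marriage_p[age0 - AGE_MIN, sex0]:
            same = rng.random() < params.same_sex_marriage_fraction
            s_sex = sex0 if same else 1 - sex0
            sampler = s.spouse.get((age0, sex0, s_sex))
            if sampler is None:
                raise ConfigurationError(
                    f"spouse distribution has empty support for proband age {age0}"
                )
            s_age = int(sampler.sample(rng))
            members.append(n)
            ages.append(s_age)
            sexes.append(s_sex)
            graph.add_relationship(members[0], members[1], MARRIAGE)
            n += 1

        size = int(s.household_size.sample(rng))
        while len(members) < size:
            age_i, sex_i = s.age_sex.sample(rng)
            members.append(n)
            ages.append(age_i)
            sexes.append(sex_i)
            n += 1

        hh_imd = int(s.imd[(age0, sex0)].sample(rng))
        imds.extend([hh_imd] * len(members))

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                graph.add_relationship(members[i], members[j], HOUSEHOLD)

    pop = Population(ages, sexes, imds)

    # vectorised attribute sampling (employment, thresholds, behaviour levels)
    a_idx = pop.age - AGE_MIN
    p_emp = s.employment_p[a_idx, pop.sex, pop.imd - 1]
    pop.employed = rng.random(pop.n) < p_emp
    pop.threshold = _sample_thresholds(pop.n, params.threshold_mean, params.threshold_sd, rng)
    for b in range(len(BEHAVIOURS)):
        cdf = s.prevalence_cdf[b, pop.sex, a_idx]  # (n, 3)
        u = rng.random(pop.n)
        pop.levels[:, b] = (cdf < u[:, None]).sum(axis=1)
    pop.ever_smoked = pop.levels[:, 0] > 0
    return pop, graph


def build_friendship_network(
    population: Population,
    graph: RelationshipGraph,
    params: ParameterSet,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Overlay a friendship network, excluding a fraction of agents.

    A Newman-Watts-Strogatz small-world graph (or Barabasi-Albert graph)
    is generated over the included agents; generated edges that duplicate a
    marriage or household pair are dropped to enforce the hierarchy.
    Returns the friendship edges actually added.
    """
    n = population.n
    n_excluded = int(round(params.friendship_exclusion_fraction * n))
    perm = rng.permutation(n)
    included = perm[n_excluded:]
    n_inc = included.size
    if n_inc == 0:
        return []

    k = int(round(params.friendship_mean_degree))
    seed = int(rng.integers(2**31))
    if params.friendship_generator == "NWS":
        if n_inc <= k:
            raise ConfigurationError(
                f"included agents ({n_inc}) too few for ring degree {k}"
            )
        g = nx.newman_watts_strogatz_graph(n_inc, k, params.nws_shortcut_probability, seed=seed)
    elif params.friendship_generator == "BA":
        m = max(1, int(round(k / 2)))
        if n_inc <= m:
            raise ConfigurationError(
                f"included agents ({n_inc}) too few for attachment parameter {m}"
            )
        g = nx.barabasi_albert_graph(n_inc, m, seed=seed)
    else:
        raise ConfigurationError(
            f"unknown friendship generator {params.friendship_generator!r}"
        )

    added = []
    for u, v in g.edges():
        a, b = int(included[u]), int(included[v])
        if graph.has_edge(a, b):
            continue  # marriage/household outranks friendship
        graph.add_relationship(a, b, FRIENDSHIP)
        added.append((a, b))
    return added


def assign_workplaces(
    population: Population,
    graph: RelationshipGraph,
    params: ParameterSet,
    rng: np.random.Generator,
    contact_mean: float | None = None,
) -> list[np.ndarray]:
    """Partition employed agents into workplace contact groups.

    Group sizes are drawn as round(Normal(mean, sd)) with a minimum of 2,
    where the mean comes from the sampled workplace-size category (or a
    fixed ``contact_mean``) and sd defaults to mean/4.  Groups are filled
    until every employed agent is assigned; the final group may fall short
    of its sampled size.  Group cliques are typed workplace except for
    pairs already holding a higher relationship.
    """
    if contact_mean is not None and contact_mean <= 0:
        raise ConfigurationError("contact_mean must be positive")
    s = _Samplers(params)
    employed = np.flatnonzero(population.employed & population.alive)
    employed = rng.permutation(employed)

    groups: list[np.ndarray] = []
    pos = 0
    while pos < employed.size:
        if contact_mean is not None:
            mean = float(contact_mean)
        else:
            cat = int(s.workplace_category.sample(rng))
            mean = float(s.contact_means[cat])
        sd = params.contact_group_sd if params.contact_group_sd is not None else mean / 4.0
        size = max(2, int(round(rng.normal(mean, sd))))
        group = employed[pos:pos + size]
        pos += size
        groups.append(group)
        for i in range(group.size):
            for j in range(i + 1, group.size):
                a, b = int(group[i]), int(group[j])
                if not graph.has_edge(a, b):
                    graph.add_relationship(a, b, WORKPLACE)

    graph.workplace_groups = groups
    return groups


def generate_population(
    target_size: int,
    params: ParameterSet,
    seed: int | np.random.Generator,
    contact_mean: float | None = None,
) -> tuple[Population, RelationshipGraph]:
    """Full population build: households, friendships, workplaces."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop, graph = generate_households(target_size, params, rng)
    build_friendship_network(pop, graph, params, rng)
    assign_workplaces(pop, graph, params, rng, contact_mean=contact_mean)
    return pop, graph


def save_population(
    population: Population, graph: RelationshipGraph, directory: str | os.PathLike
) -> None:
    """Dump a population as ``agents.csv`` + ``edges.csv`` (ordered by id)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    agents = pd.DataFrame(
        {
            "id": np.arange(population.n),
            "age": population.age,
            "sex": [SEXES[i] for i in population.sex],
            "imd": population.imd,
            "employed": population.employed.astype(int),
            "threshold": population.threshold,
            **{b: population.levels[:, j] for j, b in enumerate(BEHAVIOURS)},
        }
    )
    agents.to_csv(directory / "agents.csv", index=False, float_format="%.17g")
    rows = sorted((a, b, RELATIONSHIPS[r]) for a, b, r in graph.edges())
    edges = pd.DataFrame(rows, columns=["id_a", "id_b", "relationship"])
    edges.to_csv(directory / "edges.csv", index=False)


def load_population(directory: str | os.PathLike) -> tuple[Population, RelationshipGraph]:
    directory = Path(directory)
    agents = pd.read_csv(directory / "agents.csv")
    pop = Population(
        agents["age"].to_numpy(),
        agents["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy(),
        agents["imd"].to_numpy(),
    )
    pop.employed = agents["employed"].to_numpy(bool)
    pop.threshold = agents["threshold"].to_numpy(float)
    for j, b in enumerate(BEHAVIOURS):
        pop.levels[:, j] = agents[b].to_numpy()
    pop.ever_smoked = pop.levels[:, 0] > 0
    graph = RelationshipGraph()
    edges = pd.read_csv(directory / "edges.csv")
    rel_code = {r: i for i, r in enumerate(RELATIONSHIPS)}
    for _, row in edges.iterrows():
        graph.add_relationship(int(row["id_a"]), int(row["id_b"]), rel_code[row["relationship"]])
    return pop, graph
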