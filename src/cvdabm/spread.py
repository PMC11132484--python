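"""Behaviour spread: a modified linear-threshold model.

Each agent carries one scalar threshold.  In a yearly step the influence
incoming to an agent is summed per (behaviour, level) over its neighbours'
levels *as of the start of the step* -- 12 totals per agent.  For each
behaviour, levels whose total strictly exceeds the threshold are candidates:
none means the current level is kept, one is adopted outright, several are
resolved by a draw weighted proportionally to their influence totals.
Smoking level 0 ("never smoked") can never be (re-)adopted by an agent that
has ever smoked.

The whole-population step is two-phase (compute, then commit) so the result
does not depend on the order agents are processed; per-step randomness is
drawn in agent-id order from the step's generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .parameters import BEHAVIOURS, InfluenceMatrix, LEVELS, RELATIONSHIPS
from .population import Population, RelationshipGraph

SMOKING = BEHAVIOURS.index("smoking")

_N_B = len(BEHAVIOURS)
_N_L = len(LEVELS)


@dataclass
class Layer:
    """One influence layer: an adjacency and its (behaviour, level) strengths."""

    adjacency: sparse.csr_matrix
    strengths: np.ndarray  # shape (4, 3)


def build_layers(
    graph: RelationshipGraph, matrix: InfluenceMatrix, n: int
) -> list[Layer]:
    """One layer per relationship type, with that relationship's strengths."""
    return [
        Layer(graph.to_sparse(r, n), matrix.data[r].copy())
        for r in range(len(RELATIONSHIPS))
    ]


def incoming_influence(
    agent: int,
    graph: RelationshipGraph,
    current_levels: np.ndarray,
    matrix: InfluenceMatrix,
    alive: np.ndarray | None = None,
) -> np.ndarray:
    """Summed incoming influence for one agent, shape (behaviour, level).

    ``current_levels`` is the (n, 4) level snapshot from the start of the
    step.  An isolated agent receives all zeros.
    """
    infl = np.zeros((_N_B, _N_L))
    for nbr, rel in graph.neighbors(agent).items():
        if alive is not None and not alive[nbr]:
            continue
        for b in range(_N_B):
            lvl = current_levels[nbr, b]
            infl[b, lvl] += matrix.data[rel, b, lvl]
    return infl


def resolve_level(
    behaviour: str,
    influence_vector: np.ndarray,
    threshold: float,
    current_level: int,
    ever_smoked: bool,
    rng: np.random.Generator,
) -> int:
    """Resolve one agent's next level of one behaviour.

    Candidate set E = levels whose influence strictly exceeds the threshold.
    Empty E keeps the current level; otherwise the new level is drawn with
    probability proportional to influence among E (a single candidate is
    adopted with certainty).  For smoking, level 0 is removed from E first
    whenever the agent has ever smoked.
    """
    vec = np.asarray(influence_vector, dtype=float)
    exceed = vec > threshold
    if behaviour == "smoking" and ever_smoked:
        exceed[0] = False
    if not exceed.any():
        return int(current_level)
    w = np.where(exceed, vec, 0.0)
    cum = np.cumsum(w)
    r = rng.random() * cum[-1]
    return int((cum <= r).sum())


def step_all_behaviours(
    population: Population,
    graph: RelationshipGraph | None,
    matrix: InfluenceMatrix | None,
    rng: np.random.Generator,
    layers: list[Layer] | None = None,
    commit: bool = True,
) -> np.ndarray:
    """Synchronised update of every living agent's four behaviour levels.

    All influence is computed from the pre-step snapshot, then committed
    atomically; the committed state is invariant to agent processing order
    because the per-(agent, behaviour) uniforms are indexed by agent id.
    Pass prebuilt ``layers`` to avoid rebuilding adjacency each step (they
    take precedence over ``graph``/``matrix``).
    """
    n = population.n
    if layers is None:
        if graph is None or matrix is None:
            raise ValueError("either layers or (graph, matrix) must be given")
        layers = build_layers(graph, matrix, n)

    levels = population.levels
    alive = population.alive

    infl = np.zeros((n, _N_B, _N_L))
    for layer in layers:
        for b in range(_N_B):
            for l in range(_N_L):
                s = layer.strengths[b, l]
                if s == 0.0:
                    continue
                src = ((levels[:, b] == l) & alive).astype(float)
                infl[:, b, l] += s * (layer.adjacency @ src)

    u = rng.random((n, _N_B))

    exceed = infl > population.threshold[:, None, None]
    exceed[:, SMOKING, 0] &= ~population.ever_smoked
    w = np.where(exceed, infl, 0.0)
    cum = np.cumsum(w, axis=-1)
    r = u * cum[:, :, -1]
    chosen = (cum <= r[:, :, None]).sum(axis=-1)
    any_candidate = exceed.any(axis=-1)

    new_levels = np.where(any_candidate & alive[:, None], chosen, levels).astype(np.int8)
    if commit:
        population.levels = new_levels
        population.ever_smoked |= new_levels[:, SMOKING] > 0
    return new_levels
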