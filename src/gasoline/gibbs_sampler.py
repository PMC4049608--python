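"""Markov-chain Monte-Carlo samplers for seed search and column extension.

Both samplers share one transition engine: the chain state is one protein
per network; each update picks a network uniformly at random, scores every
candidate of that network's pool conditioned on the other ``N-1`` state
entries, and resamples the entry from the normalized scores.  The best state
ever visited (by sum-of-pairs score) is returned.

Candidate scores are *products* over the partner entries, so a candidate
with no similarity to some partner scores exactly 0.  Because cross-network
similarity is sparse, an all-zero score vector is common early in a run; the
samplers then fall back to a graded ladder — sum of similarities to the
partners, then uniform — which keeps the chain ergodic and lets it assemble
a mutually similar column one coordinate at a time (see docs/methods.md).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from itertools import accumulate
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_model import AlignmentState, GasolineError, LocalAlignment, Network, SimilarityStore

logger = logging.getLogger(__name__)

__all__ = [
    "OrderedPool",
    "bootstrap_candidate_score",
    "transition_distribution",
    "gibbs_bootstrap",
    "sum_of_pairs_orthology",
    "topology_vector",
    "topology_pair_score",
    "extension_candidate_score",
    "gibbs_extend",
    "sum_of_pairs_extension",
]


class OrderedPool:
    """Ordered candidate pool with O(1) membership, removal and uniform draw.

    Removal is lazy; the backing list is compacted once more than half of it
    is dead, so uniform rejection sampling stays O(1) amortized.  Iteration
    order (of live items) is the original insertion order — the source of
    the package's determinism under a fixed seed.
    """

    __slots__ = ("_items", "_alive")

    def __init__(self, items: Sequence[str]):
        self._items: List[str] = list(items)
        self._alive = set(self._items)
        if len(self._alive) != len(self._items):
            raise GasolineError("duplicate items in candidate pool")

    def __len__(self) -> int:
        return len(self._alive)

    def __contains__(self, x: str) -> bool:
        return x in self._alive

    def remove(self, x: str) -> None:
        self._alive.discard(x)
        if len(self._items) > 16 and len(self._alive) * 2 < len(self._items):
            self._items = [y for y in self._items if y in self._alive]

    def sample_uniform(self, rng: np.random.Generator) -> str:
        if not self._alive:
            raise GasolineError("cannot sample from an empty pool")
        while True:
            x = self._items[int(rng.integers(len(self._items)))]
            if x in self._alive:
                return x

    def live(self) -> List[str]:
        return [y for y in self._items if y in self._alive]

    @property
    def alive(self) -> set:
        """The live-membership set (read-only use in hot loops)."""
        return self._alive


def _weighted_pick(rng: np.random.Generator, items: Sequence[str],
                   weights: Sequence[float]) -> str:
    """Draw one item from the transition distribution of its scores."""
    cum = list(accumulate(transition_distribution(weights)))
    return items[bisect_right(cum, rng.random() * cum[-1])]


# ---------------------------------------------------------------------------
# Bootstrap (seed search)
# ---------------------------------------------------------------------------


def bootstrap_candidate_score(
    x_prime: str,
    state: Sequence[str],
    i: int,
    sim: SimilarityStore,
    species: Sequence[str],
) -> float:
    """Product of similarity scores between ``x_prime`` (network ``i``) and
    every other state entry; 0 as soon as any factor is 0."""
    prod = 1.0
    for j, y in enumerate(state):
        if j == i:
            continue
        s = sim.score(species[i], x_prime, species[j], y)
        if s == 0.0:
            return 0.0
        prod *= s
    return prod


def transition_distribution(scores: Sequence[float]) -> List[float]:
    """Normalize non-negative candidate scores into a probability vector.

    An all-zero vector falls back to the uniform distribution so the chain
    never deadlocks.
    """
    if len(scores) == 0:
        raise GasolineError("empty candidate list")
    total = float(sum(scores))
    if total <= 0.0:
        p = 1.0 / len(scores)
        return [p] * len(scores)
    return [s / total for s in scores]


def sum_of_pairs_orthology(state: Sequence[str], sim: SimilarityStore,
                           species: Sequence[str]) -> float:
    """Sum of ``S`` over all unordered network pairs of a column."""
    total = 0.0
    n = len(state)
    for i in range(n):
        for j in range(i + 1, n):
            total += sim.score(species[i], state[i], species[j], state[j])
    return total


def _candidate_products(
    i: int,
    state: Sequence[str],
    sim: SimilarityStore,
    species: Sequence[str],
    pool,
) -> Tuple[List[str], List[float]]:
    """Candidates of network ``i`` with a nonzero all-partners product.

    Equivalent to scoring the whole pool (absent pairs contribute factor 0,
    hence probability 0) but touches only the intersection of the partners'
    partner lists.
    """
    partner_maps: List[Dict[str, float]] = []
    for j, y in enumerate(state):
        if j == i:
            continue
        d = sim.partners(species[j], y, species[i])
        if not d:
            return [], []
        partner_maps.append(d)
    partner_maps.sort(key=len)
    base = partner_maps[0]
    rest = partner_maps[1:]
    items: List[str] = []
    weights: List[float] = []
    for x, s0 in base.items():
        if x not in pool:
            continue
        prod = s0
        ok = True
        for d in rest:
            s = d.get(x, 0.0)
            if s == 0.0:
                ok = False
                break
            prod *= s
        if ok:
            items.append(x)
            weights.append(prod)
    return items, weights


def _candidate_sums(
    i: int,
    state: Sequence[str],
    sim: SimilarityStore,
    species: Sequence[str],
    pool,
) -> Tuple[List[str], List[float]]:
    """Fallback scores: sum of similarities to the partner entries."""
    sums: Dict[str, float] = {}
    for j, y in enumerate(state):
        if j == i:
            continue
        for x, s in sim.partners(species[j], y, species[i]).items():
            if x in pool:
                sums[x] = sums.get(x, 0.0) + s
    return list(sums.keys()), list(sums.values())


def gibbs_bootstrap(
    marked: Sequence,
    sim: SimilarityStore,
    networks: Sequence[Network],
    iter_seed: int,
    rng: np.random.Generator,
) -> Optional[AlignmentState]:
    """Seed search: sample columns from the marked sets, return the visited
    state with the highest sum-of-pairs similarity.

    ``marked`` holds one candidate pool per network (any object supporting
    ``__len__``, ``__contains__``, ``sample_uniform``); returns ``None``
    when some pool is empty ("no seeds").
    """
    pools = [m if isinstance(m, OrderedPool) else OrderedPool(m) for m in marked]
    if any(len(p) == 0 for p in pools):
        return None
    species = [net.species_id for net in networks]
    n = len(pools)
    members = [p.alive for p in pools]
    state: List[str] = [p.sample_uniform(rng) for p in pools]
    # incremental sum-of-pairs bookkeeping: only the resampled coordinate's
    # pair terms change between sweeps
    pair = [[0.0] * n for _ in range(n)]
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            t = sim.score(species[a], state[a], species[b], state[b])
            pair[a][b] = pair[b][a] = t
            total += t
    best = list(state)
    best_sop = total
    for _ in range(iter_seed):
        i = int(rng.integers(n))
        items, weights = _candidate_products(i, state, sim, species, members[i])
        if not items:
            items, weights = _candidate_sums(i, state, sim, species, members[i])
        if items:
            state[i] = _weighted_pick(rng, items, weights)
        else:
            state[i] = pools[i].sample_uniform(rng)
        for j in range(n):
            if j != i:
                t = sim.score(species[i], state[i], species[j], state[j])
                total += t - pair[i][j]
                pair[i][j] = pair[j][i] = t
        if total > best_sop + 1e-12:  # first-visited wins on ties
            best_sop = total
            best = list(state)
    return AlignmentState(tuple(best), best_sop)


# ---------------------------------------------------------------------------
# Topology vectors and extension sampler
# ---------------------------------------------------------------------------


def topology_vector(x: str, row_proteins: Sequence[str], network: Network) -> List[float]:
    """Weights of the edges from ``x`` to each aligned protein of its own
    network, in column order; 0 where there is no edge (and at ``x`` itself)."""
    nbrs = network.neighbors(x)
    return [0.0 if y == x else nbrs.get(y, 0.0) for y in row_proteins]


def topology_pair_score(u_vec: Sequence[float], v_vec: Sequence[float]) -> float:
    """Scalar product of two topology vectors."""
    if len(u_vec) != len(v_vec):
        raise GasolineError(
            f"topology vector length mismatch: {len(u_vec)} vs {len(v_vec)}"
        )
    return sum(a * b for a, b in zip(u_vec, v_vec))


def extension_candidate_score(
    x_prime: str,
    state: Sequence[str],
    i: int,
    alignment: LocalAlignment,
    sim: SimilarityStore,
) -> float:
    """Combined orthology x topology score of an extension candidate.

    ``Orth`` is the all-partners product as in the bootstrap; ``Topo`` is the
    sum over partners of the scalar products of topology vectors taken
    against each network's own aligned row.
    """
    species = [net.species_id for net in alignment.networks]
    orth = bootstrap_candidate_score(x_prime, state, i, sim, species)
    if orth == 0.0:
        return 0.0
    vec_x = topology_vector(x_prime, alignment.rows[i], alignment.networks[i])
    topo = 0.0
    for j, y in enumerate(state):
        if j == i:
            continue
        vec_y = topology_vector(y, alignment.rows[j], alignment.networks[j])
        topo += topology_pair_score(vec_x, vec_y)
    return orth * topo


def sum_of_pairs_extension(
    state: Sequence[str],
    alignment: LocalAlignment,
    sim: SimilarityStore,
) -> float:
    """Sum over unordered pairs of ``S(s_i, s_j) * <vec_i, vec_j>`` for a
    candidate extension column."""
    species = [net.species_id for net in alignment.networks]
    vecs = [
        topology_vector(x, alignment.rows[i], alignment.networks[i])
        for i, x in enumerate(state)
    ]
    total = 0.0
    n = len(state)
    for i in range(n):
        for j in range(i + 1, n):
            s = sim.score(species[i], state[i], species[j], state[j])
            if s:
                total += s * topology_pair_score(vecs[i], vecs[j])
    return total


def _topo_map(x: str, row_proteins: Sequence[str], network) -> Dict[int, float]:
    """Sparse topology vector: {column index: edge weight}, self omitted."""
    nbrs = network.neighbors(x)
    out: Dict[int, float] = {}
    if len(nbrs) < len(row_proteins):
        pos = {y: k for k, y in enumerate(row_proteins)}
        for y, w in nbrs.items():
            k = pos.get(y)
            if k is not None and y != x:
                out[k] = w
    else:
        for k, y in enumerate(row_proteins):
            if y != x:
                w = nbrs.get(y, 0.0)
                if w:
                    out[k] = w
    return out


def _sparse_dot(u: Dict[int, float], v: Dict[int, float]) -> float:
    if len(u) > len(v):
        u, v = v, u
    return sum(w * v[k] for k, w in u.items() if k in v)


def gibbs_extend(
    alignment: LocalAlignment,
    adjacent: Sequence[Sequence[str]],
    sim: SimilarityStore,
    iter_extend: int,
    rng: np.random.Generator,
) -> Optional[AlignmentState]:
    """Extension-column search over the adjacent sets.

    Same chain mechanics as :func:`gibbs_bootstrap`, with candidates scored
    by orthology x topology; returns the visited column maximizing
    :func:`sum_of_pairs_extension`, or ``None`` if some adjacent set is
    empty ("cannot extend").

    Topology vectors of the state entries are cached sparsely and the
    pairwise sum-of-pairs matrix is updated incrementally — the rows of the
    alignment are frozen for the duration of one extension step, so only
    the resampled coordinate's terms change.
    """
    if any(len(a) == 0 for a in adjacent):
        return None
    networks = alignment.networks
    species = [net.species_id for net in networks]
    n = len(adjacent)
    pools = [a if isinstance(a, OrderedPool) else OrderedPool(a) for a in adjacent]
    members = [p.alive for p in pools]
    state: List[str] = [p.sample_uniform(rng) for p in pools]
    # rows are frozen during one extension step, so candidate topology
    # vectors are constants: cache them per protein
    vec_caches: List[Dict[str, Dict[int, float]]] = [{} for _ in range(n)]

    def get_vec(i: int, x: str) -> Dict[int, float]:
        cache = vec_caches[i]
        v = cache.get(x)
        if v is None:
            v = _topo_map(x, alignment.rows[i], networks[i])
            cache[x] = v
        return v

    vecs: List[Dict[int, float]] = [get_vec(i, x) for i, x in enumerate(state)]

    def pair_term(a: int, b: int) -> float:
        if not vecs[a] or not vecs[b]:
            return 0.0
        s = sim.score(species[a], state[a], species[b], state[b])
        if not s:
            return 0.0
        return s * _sparse_dot(vecs[a], vecs[b])

    pair = [[0.0] * n for _ in range(n)]
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            t = pair_term(a, b)
            pair[a][b] = pair[b][a] = t
            total += t

    best = list(state)
    best_sop = total
    for _ in range(iter_extend):
        i = int(rng.integers(n))
        items, weights = _candidate_products(i, state, sim, species, members[i])
        if items:
            # multiply each orthology product by the candidate's topology term
            scored_items: List[str] = []
            scored_weights: List[float] = []
            for x, orth in zip(items, weights):
                vec_x = get_vec(i, x)
                if vec_x:
                    topo = 0.0
                    for j in range(n):
                        if j != i and vecs[j]:
                            topo += _sparse_dot(vec_x, vecs[j])
                    if topo > 0.0:
                        scored_items.append(x)
                        scored_weights.append(orth * topo)
            if scored_items:
                state[i] = _weighted_pick(rng, scored_items, scored_weights)
            else:  # all topology terms zero: fall back to orthology alone
                state[i] = _weighted_pick(rng, items, weights)
        else:
            items, weights = _candidate_sums(i, state, sim, species, members[i])
            if items:
                state[i] = _weighted_pick(rng, items, weights)
            else:
                state[i] = pools[i].sample_uniform(rng)
        vecs[i] = get_vec(i, state[i])
        for j in range(n):
            if j != i:
                t = pair_term(i, j)
                total += t - pair[i][j]
                pair[i][j] = pair[j][i] = t
        if total > best_sop + 1e-12:
            best_sop = total
            best = list(state)
    return AlignmentState(tuple(best), best_sop)
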