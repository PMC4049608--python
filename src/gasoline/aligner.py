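"""Seed marking, the extend/remove iterative phase, and the outer loop.

The aligner grows each seed column into a conserved module by alternating
two moves: *extension* (append the best column found by the extension
sampler, kept only while every within-column pair is in orthology relation
and the mean degree ratio strictly increases) and *removal* (delete the
column with minimum Goodness, allowing the chain to escape local maxima of
the degree ratio).  The outer loop repeats bootstrap + iterative phase,
retiring each used seed, until some marked set is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .core_model import (
    AlignmentState,
    LocalAlignment,
    MarkedSets,
    Network,
    NoSeedsError,
    Params,
    SimilarityStore,
)
from .gibbs_sampler import OrderedPool, gibbs_bootstrap, gibbs_extend

logger = logging.getLogger(__name__)

#: tolerance for the strict degree-ratio increase test
RATIO_TOL = 1e-12

__all__ = [
    "DegreeRatioReport",
    "mark_candidate_seeds",
    "degree_ratio",
    "adjacent_sets",
    "extend_until_stall",
    "goodness_node",
    "goodness_column",
    "remove_worst_column",
    "run_iterative_phase",
    "run_gasoline",
]


@dataclass
class DegreeRatioReport:
    """Per-network and mean degree ratio of an aligned subgraph set.

    The per-network ratio is (internal edges) / (sum of full-network degrees
    of the subgraph nodes), hence at most 0.5, with equality exactly for an
    isolated module.
    """

    per_network: List[float]
    mean: float


def mark_candidate_seeds(
    networks: Sequence[Network],
    sim: SimilarityStore,
    t_deg: int = 1,
) -> MarkedSets:
    """Mark seed candidates: degree >= ``t_deg`` and at least one similarity
    partner in every other network.

    ``t_deg=1`` applies no degree filtering beyond requiring an interaction.
    Raises :class:`NoSeedsError` naming the first network whose marked set
    comes out empty.
    """
    species = [net.species_id for net in networks]
    marked: List[List[str]] = []
    for i, net in enumerate(networks):
        mi = [
            x
            for x in sorted(net.nodes)
            if net.degree(x) >= t_deg
            and all(
                sim.has_any_partner(species[i], x, species[j])
                for j in range(len(networks))
                if j != i
            )
        ]
        if not mi:
            raise NoSeedsError(f"network {net.species_id!r} has no alignable seed proteins")
        marked.append(mi)
    return MarkedSets(marked)


def degree_ratio(alignment: LocalAlignment, networks: Sequence[Network]) -> DegreeRatioReport:
    """Degree ratio of each aligned subgraph and their arithmetic mean."""
    per = []
    for i, net in enumerate(networks):
        row = alignment.rows[i]
        row_set = alignment.row_set(i)
        internal2 = 0  # twice the internal edge count
        deg_sum = 0
        for u in row:
            deg_sum += net.degree(u)
            nbrs = net.neighbors(u)
            if len(nbrs) <= len(row_set):
                internal2 += sum(1 for v in nbrs if v in row_set)
            else:
                internal2 += sum(1 for v in row_set if v in nbrs)
        per.append((internal2 / 2) / deg_sum if deg_sum > 0 else 0.0)
    return DegreeRatioReport(per, sum(per) / len(per))


def adjacent_sets(alignment: LocalAlignment, networks: Sequence[Network]) -> List[List[str]]:
    """Per network, the nodes adjacent to the aligned subgraph, minus the
    subgraph itself (sorted for determinism)."""
    out: List[List[str]] = []
    for i, net in enumerate(networks):
        row_set = alignment.row_set(i)
        adj: Set[str] = set()
        for u in alignment.rows[i]:
            adj.update(net.neighbors(u))
        adj -= row_set
        out.append(sorted(adj))
    return out


def _column_orthology_ok(column: Sequence[str], sim: SimilarityStore,
                         species: Sequence[str]) -> bool:
    """Stopping condition (i): every within-column pair has S > 0."""
    n = len(column)
    for i in range(n):
        for j in range(i + 1, n):
            if sim.score(species[i], column[i], species[j], column[j]) == 0.0:
                return False
    return True


def extend_until_stall(
    alignment: LocalAlignment,
    networks: Sequence[Network],
    sim: SimilarityStore,
    params: Params,
    rng: np.random.Generator,
) -> LocalAlignment:
    """Append extension columns while they keep the alignment orthologous and
    strictly raise the mean degree ratio; stop at the first rejection.

    Mutates and returns ``alignment``.
    """
    species = [net.species_id for net in networks]
    iter_extend = params.resolved_iter_extend(len(networks))
    current_ratio = degree_ratio(alignment, networks).mean
    while True:
        adj = adjacent_sets(alignment, networks)
        if any(len(a) == 0 for a in adj):
            return alignment
        column_state = gibbs_extend(alignment, adj, sim, iter_extend, rng)
        if column_state is None:
            return alignment
        column = column_state.proteins
        if not _column_orthology_ok(column, sim, species):
            return alignment
        alignment.append_column(column)
        new_ratio = degree_ratio(alignment, networks).mean
        if new_ratio > current_ratio + RATIO_TOL:
            current_ratio = new_ratio
            logger.debug("extension accepted: m=%d mean_ratio=%.4f",
                         alignment.size, new_ratio)
        else:
            alignment.pop_column()
            return alignment


def goodness_node(x: str, row_proteins: Sequence[str], network: Network) -> float:
    """Internal degree of ``x`` within the aligned subgraph over its full
    network degree; 0 for an isolated node."""
    deg = network.degree(x)
    if deg == 0:
        return 0.0
    nbrs = network.neighbors(x)
    internal = sum(1 for y in row_proteins if y != x and y in nbrs)
    return internal / deg


def goodness_column(col_index: int, alignment: LocalAlignment,
                    networks: Sequence[Network]) -> float:
    """Product over networks of the node Goodness scores of one column."""
    prod = 1.0
    column = alignment.columns[col_index]
    for i, net in enumerate(networks):
        g = goodness_node(column[i], alignment.rows[i], net)
        if g == 0.0:
            return 0.0
        prod *= g
    return prod


def remove_worst_column(
    alignment: LocalAlignment,
    networks: Sequence[Network],
    protect: Optional[int] = None,
) -> LocalAlignment:
    """Delete the column with minimum Goodness (ties: lowest index).

    A single-column alignment is returned unchanged (the seed is never
    deleted).  ``protect`` shields one column index from removal *on ties*
    only; a strictly minimal protected column is still removed.  Mutates and
    returns ``alignment``; the removed proteins stay eligible for future
    extensions.
    """
    if alignment.size < 2:
        return alignment
    scores = [goodness_column(k, alignment, networks) for k in range(alignment.size)]
    worst = min(scores)
    tied = [k for k, s in enumerate(scores) if s == worst]
    if len(tied) > 1 and protect in tied:
        tied.remove(protect)
    logger.debug("removal: column %d (goodness=%.4f) of %d", tied[0], worst,
                 alignment.size)
    alignment.pop_column(tied[0])
    return alignment


def run_iterative_phase(
    seed_state: AlignmentState,
    networks: Sequence[Network],
    sim: SimilarityStore,
    params: Params,
    rng: np.random.Generator,
) -> LocalAlignment:
    """Grow one seed column into a local alignment.

    Runs ``iter_phase`` rounds of extend-until-stall followed by one removal
    (skipped while the alignment has <= 2 columns); returns the best
    alignment seen, keyed lexicographically on (mean degree ratio, size).
    """
    alignment = LocalAlignment(networks, [tuple(seed_state.proteins)], seed_column_index=0)
    seed_proteins = alignment.seed_proteins
    best: Optional[LocalAlignment] = None
    best_key: Tuple[float, int] = (-1.0, 0)

    def consider(aln: LocalAlignment) -> None:
        nonlocal best, best_key
        key = (degree_ratio(aln, networks).mean, aln.size)
        if key > best_key:
            best_key = key
            best = aln.copy()

    consider(alignment)
    for _ in range(params.iter_phase):
        extend_until_stall(alignment, networks, sim, params, rng)
        consider(alignment)
        if alignment.size > 2:
            remove_worst_column(alignment, networks, protect=alignment.seed_column_index)
            consider(alignment)
    assert best is not None
    best.seed_proteins = seed_proteins
    return best


def run_gasoline(
    networks: Sequence[Network],
    sim: SimilarityStore,
    params: Params,
    rng: np.random.Generator,
) -> List[LocalAlignment]:
    """Full outer loop: bootstrap a seed, run the iterative phase, retire the
    seed proteins from the marked sets, repeat until some set is empty.

    Returns the raw (unranked, unfiltered-by-overlap) alignments with at
    least ``params.min_size`` columns.  Terminates because each round
    removes one protein from every marked set.
    """
    marked = mark_candidate_seeds(networks, sim, params.t_deg)
    pools = [OrderedPool(m) for m in marked.sets]
    iter_seed = params.resolved_iter_seed(len(networks))
    raw: List[LocalAlignment] = []
    n_rounds = 0
    while all(len(p) > 0 for p in pools):
        seed = gibbs_bootstrap(pools, sim, networks, iter_seed, rng)
        if seed is None:
            break
        alignment = run_iterative_phase(seed, networks, sim, params, rng)
        if alignment.size >= params.min_size:
            raw.append(alignment)
        for p, x in zip(pools, seed.proteins):
            p.remove(x)
        n_rounds += 1
        if n_rounds % 200 == 0:
            logger.info(
                "outer round %d: %d raw alignments, pool sizes %s",
                n_rounds, len(raw), [len(p) for p in pools],
            )
    logger.info("outer loop finished after %d rounds with %d raw alignments",
                n_rounds, len(raw))
    return raw
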