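"""Index of Structural Conservation (ISC), ranking, and overlap filtering.

The ISC of an alignment compares, for every pair of networks, the wiring of
the two aligned subgraphs position by position: for each column the two
matched proteins' topology vectors (edge weights to the rest of their own
subgraph, self position 0) are reduced to the fraction of positions that are
both zero or both nonzero — the conserved links.  Averaging over columns
gives a pairwise structural similarity in [0, 1]; summing over network pairs
and dividing by C(N, 2) yields ISC, which is exactly 1 for N perfectly
aligned cliques.
"""

from __future__ import annotations

from typing import List, Sequence

from .core_model import GasolineError, LocalAlignment, Network, Params
from .gibbs_sampler import topology_vector

__all__ = [
    "conserved_fraction",
    "pairwise_structural_similarity",
    "isc",
    "overlap_fraction",
    "rank_and_filter",
]


def conserved_fraction(u_vec: Sequence[float], v_vec: Sequence[float]) -> float:
    """Fraction of positions where the two topology vectors are both zero or
    both nonzero."""
    if len(u_vec) != len(v_vec):
        raise GasolineError("topology vector length mismatch")
    m = len(u_vec)
    agree = sum(1 for a, b in zip(u_vec, v_vec) if (a == 0.0) == (b == 0.0))
    return agree / m


def _row_vectors(alignment: LocalAlignment, i: int) -> List[List[float]]:
    net = alignment.networks[i]
    row = alignment.rows[i]
    return [topology_vector(x, row, net) for x in row]


def pairwise_structural_similarity(
    row_i: int,
    row_j: int,
    alignment: LocalAlignment,
    networks: Sequence[Network] = (),
) -> float:
    """Mean over the m matched node pairs of their conserved-link fraction."""
    vecs_i = _row_vectors(alignment, row_i)
    vecs_j = _row_vectors(alignment, row_j)
    m = alignment.size
    return sum(conserved_fraction(vecs_i[k], vecs_j[k]) for k in range(m)) / m


def isc(alignment: LocalAlignment, networks: Sequence[Network] = ()) -> float:
    """Normalized sum-of-pairs structural similarity, in [0, 1]."""
    n = alignment.n_networks
    if n < 2:
        raise GasolineError("ISC needs at least 2 networks")
    vecs = [_row_vectors(alignment, i) for i in range(n)]
    m = alignment.size
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(conserved_fraction(vecs[i][k], vecs[j][k]) for k in range(m)) / m
    return total / (n * (n - 1) / 2)


def overlap_fraction(
    candidate: LocalAlignment,
    accepted: Sequence[LocalAlignment],
) -> float:
    """Mean over networks of the fraction of the candidate's row proteins
    already used by the accepted alignments."""
    n = candidate.n_networks
    seen = [set() for _ in range(n)]
    for aln in accepted:
        for i in range(n):
            seen[i].update(aln.rows[i])
    return _overlap_against(candidate, seen)


def _overlap_against(candidate: LocalAlignment, seen: Sequence[set]) -> float:
    n = candidate.n_networks
    o = 0.0
    for i in range(n):
        row = candidate.rows[i]
        o += sum(1 for x in row if x in seen[i]) / len(row)
    return o / n


def rank_and_filter(
    raw: Sequence[LocalAlignment],
    networks: Sequence[Network],
    params: Params,
) -> List[LocalAlignment]:
    """Sort raw alignments by (size desc, ISC desc), then sweep in order
    keeping an alignment iff its mean overlap against the kept set is at
    most ``params.max_overlap`` and its size is at least ``params.min_size``.

    Ranks (1-based) are assigned after filtering; ISC is filled in on every
    input alignment as a side effect.
    """
    for aln in raw:
        if aln.isc is None:
            aln.isc = isc(aln, networks)
    ordered = sorted(raw, key=lambda a: (-a.size, -(a.isc or 0.0)))
    kept: List[LocalAlignment] = []
    seen = [set() for _ in range(len(networks))]
    for aln in ordered:
        if aln.size < params.min_size:
            continue
        if _overlap_against(aln, seen) > params.max_overlap:
            continue
        kept.append(aln)
        for i in range(len(networks)):
            seen[i].update(aln.rows[i])
    for rank, aln in enumerate(kept, start=1):
        aln.rank = rank
    return kept
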