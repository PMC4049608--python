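"""Synthetic network-family generator with ground-truth functional groups.

Families of protein-interaction networks are evolved from a common ancestor
along a phylogeny whose branch weights are *node counts*: each child network
is a copy of its parent grown by that many nodes under one of three growth
models —

* **DMC** (duplication-mutation-complementation): a duplicate inherits its
  anchor's neighborhood; each shared neighbor loses one of the two redundant
  links with probability ``q_mod``; the anchor-duplicate link appears with
  probability ``q_con``;
* **DMR** (duplication with random mutations): inherited links are lost
  independently with probability ``q_del`` and random links to non-neighbors
  appear with per-pair probability ``q_new / n``;
* **CG** (crystal growth): each new node attaches with a fixed edge budget,
  the first endpoint drawn uniformly from unsaturated nodes and the rest
  from the neighborhood of already-chosen endpoints, mimicking accretion on
  a module surface.

Every protein carries a *functional group*: the lineage of one ancestral
(root-network) node.  Duplicates inherit their anchor's group; nodes born
after the root (CG accretion) found new groups.  Cross-network proteins of
equal group are orthologs — the evaluation oracle — and the similarity
simulator draws their scores from an ortholog distribution (log-normal on
the bit-score scale, shiftable by a bias term) against a background
distribution for sampled non-ortholog decoy pairs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import networkx as nx
import numpy as np

from .core_model import GasolineError, Network, SimilarityStore, write_network

__all__ = [
    "GrowthParams",
    "ScoreModel",
    "PhylogenySpec",
    "FamilyGroundTruth",
    "pairwise_spec",
    "four_way_spec",
    "eight_way_spec",
    "grow_dmc",
    "grow_dmr",
    "grow_cg",
    "generate_family",
    "simulate_similarities",
    "write_family",
]

GROWTH_MODELS = ("DMC", "DMR", "CG")


@dataclass
class GrowthParams:
    """Parameters of the three network growth models."""

    model: str = "CG"
    q_con: float = 0.1  # DMC: anchor-duplicate link probability
    q_mod: float = 0.4  # DMC: per-shared-neighbor modification probability
    q_del: float = 0.4  # DMR: inherited-edge loss probability
    q_new: float = 0.1  # DMR: expected number of random new links
    cg_avg_degree: int = 5  # CG: edges per new node
    cg_max_degree: int = 10  # CG: saturation cap for first-endpoint choice

    def __post_init__(self) -> None:
        self.model = self.model.upper()
        if self.model not in GROWTH_MODELS:
            raise GasolineError(f"unknown growth model {self.model!r}")
        for name in ("q_con", "q_mod", "q_del"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise GasolineError(f"{name}={v} outside [0, 1]")


@dataclass
class ScoreModel:
    """Similarity-score simulator settings (bit-score scale).

    Ortholog and background scores are log-normal with medians
    ``ortholog_loc`` and ``background_loc`` and a shared log-scale ``sigma``;
    ``bias`` is added to ortholog draws (negative values penalize sequence
    similarity, positive values enhance it); draws truncated at 0 are
    treated as absent pairs.  ``decoy_rate`` non-ortholog partners are
    sampled per protein.
    """

    ortholog_loc: float = 100.0
    background_loc: float = 40.0
    sigma: float = 0.3
    bias: float = 0.0
    decoy_rate: int = 5


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class _TreeNode:
    name: Optional[str]
    weight: int  # nodes added along the branch leading here (root: 0)
    children: List["_TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhylogenySpec:
    """Rooted phylogeny with integer branch weights = node counts added."""

    root: _TreeNode
    ancestor_size: int

    def leaves(self) -> List[_TreeNode]:
        out: List[_TreeNode] = []

        def walk(node: _TreeNode) -> None:
            if node.is_leaf():
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    @staticmethod
    def from_newick(newick: str, ancestor_size: int) -> "PhylogenySpec":
        """Parse a Newick string; branch lengths are node-count weights."""
        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(node) -> _TreeNode:
            name = node.taxon.label if node.taxon is not None else node.label
            weight = int(round(node.edge.length)) if node.edge.length is not None else 0
            if weight < 0:
                raise GasolineError("branch weights must be >= 0")
            return _TreeNode(name, weight, [convert(c) for c in node.child_nodes()])

        return PhylogenySpec(convert(tree.seed_node), ancestor_size)


def _leaf(name: str, w: int) -> _TreeNode:
    return _TreeNode(name, w)


def pairwise_spec(ancestor_size: int = 1000, branch_weight: int = 500) -> PhylogenySpec:
    """2-way family: two leaves directly below the ancestor."""
    root = _TreeNode(None, 0, [_leaf("A", branch_weight), _leaf("B", branch_weight)])
    return PhylogenySpec(root, ancestor_size)


def four_way_spec(ancestor_size: int = 2000, branch_weight: int = 500) -> PhylogenySpec:
    """4-way family: balanced two-level tree."""
    root = _TreeNode(None, 0, [
        _TreeNode(None, branch_weight, [_leaf("A", branch_weight), _leaf("B", branch_weight)]),
        _TreeNode(None, branch_weight, [_leaf("C", branch_weight), _leaf("D", branch_weight)]),
    ])
    return PhylogenySpec(root, ancestor_size)


def eight_way_spec(ancestor_size: int = 3000, branch_weight: int = 500) -> PhylogenySpec:
    """8-way family: balanced three-level binary tree, leaves A..H."""
    names = iter("ABCDEFGH")

    def cherry() -> _TreeNode:
        return _TreeNode(None, branch_weight,
                         [_leaf(next(names), branch_weight), _leaf(next(names), branch_weight)])

    root = _TreeNode(None, 0, [
        _TreeNode(None, branch_weight, [cherry(), cherry()]),
        _TreeNode(None, branch_weight, [cherry(), cherry()]),
    ])
    return PhylogenySpec(root, ancestor_size)


# ---------------------------------------------------------------------------
# Growth models
# ---------------------------------------------------------------------------


def _new_node(g: nx.Graph) -> str:
    c = g.graph.get("next_node", g.number_of_nodes())
    while f"p{c}" in g:
        c += 1
    g.graph["next_node"] = c + 1
    return f"p{c}"


def _new_group(g: nx.Graph) -> Optional[int]:
    if "next_group" not in g.graph:
        return None
    gid = g.graph["next_group"]
    g.graph["next_group"] = gid + 1
    return gid


def _pick_node(g: nx.Graph, rng: np.random.Generator, nodes: Optional[List[str]] = None) -> str:
    pool = nodes if nodes is not None else list(g.nodes)
    return pool[int(rng.integers(len(pool)))]


def grow_dmc(network: Network, n_add: int, q_con: float, q_mod: float,
             rng: np.random.Generator) -> Network:
    """Duplication-mutation-complementation growth; returns a grown copy."""
    if network.number_of_nodes() < 2:
        raise GasolineError("DMC growth needs at least 2 nodes")
    g = network.graph.copy()
    for _ in range(n_add):
        nodes = list(g.nodes)
        u = nodes[int(rng.integers(len(nodes)))]
        v = _new_node(g)
        g.add_node(v, **g.nodes[u])  # duplicate inherits the anchor's group
        shared = list(g.neighbors(u))
        for w in shared:
            g.add_edge(v, w, weight=1.0)
        for w in shared:
            if rng.random() < q_mod:
                if rng.random() < 0.5:
                    g.remove_edge(u, w)
                else:
                    g.remove_edge(v, w)
        if rng.random() < q_con:
            g.add_edge(u, v, weight=1.0)
    return Network(network.species_id, g)


def grow_dmr(network: Network, n_add: int, q_del: float, q_new: float,
             rng: np.random.Generator) -> Network:
    """Duplication with random mutations; returns a grown copy."""
    if network.number_of_nodes() < 2:
        raise GasolineError("DMR growth needs at least 2 nodes")
    g = network.graph.copy()
    for _ in range(n_add):
        nodes = list(g.nodes)
        u = nodes[int(rng.integers(len(nodes)))]
        v = _new_node(g)
        g.add_node(v, **g.nodes[u])
        kept = [w for w in g.neighbors(u) if rng.random() >= q_del]
        for w in kept:
            g.add_edge(v, w, weight=1.0)
        n_cur = g.number_of_nodes()
        non_neighbors = [z for z in nodes if z not in kept]
        if non_neighbors and q_new > 0:
            p = min(q_new / n_cur, 1.0)
            k = rng.binomial(len(non_neighbors), p)
            if k > 0:
                idx = rng.choice(len(non_neighbors), size=int(k), replace=False)
                for t in sorted(int(i) for i in idx):
                    g.add_edge(v, non_neighbors[t], weight=1.0)
    return Network(network.species_id, g)


def grow_cg(network: Network, n_add: int, cg_avg_degree: int,
            rng: np.random.Generator, cg_max_degree: int = 10) -> Network:
    """Crystal-growth accretion; returns a grown copy.

    Each new node spends a budget of ``cg_avg_degree`` edges: the first
    endpoint is uniform among existing nodes with degree below the
    saturation cap (or among all nodes if every one is saturated), and each
    further endpoint is drawn from the current neighbors of the endpoints
    chosen so far, falling back to a uniform unused node when that surface
    is exhausted.
    """
    if cg_avg_degree >= network.number_of_nodes():
        raise GasolineError("cg_avg_degree must be smaller than the current node count")
    g = network.graph.copy()
    for _ in range(n_add):
        v = _new_node(g)
        chosen: List[str] = []
        chosen_set = set()
        unsaturated = [x for x in g.nodes if g.degree(x) < cg_max_degree]
        first = _pick_node(g, rng, unsaturated if unsaturated else None)
        chosen.append(first)
        chosen_set.add(first)
        while len(chosen) < cg_avg_degree:
            surface = sorted(
                {w for x in chosen for w in g.neighbors(x)} - chosen_set
            )
            if surface:
                nxt = surface[int(rng.integers(len(surface)))]
            else:
                candidates = [x for x in g.nodes if x not in chosen_set]
                nxt = candidates[int(rng.integers(len(candidates)))]
            chosen.append(nxt)
            chosen_set.add(nxt)
        gid = _new_group(g)
        if gid is not None:
            g.add_node(v, group=gid)
        else:
            g.add_node(v)
        for x in chosen:
            g.add_edge(v, x, weight=1.0)
    return Network(network.species_id, g)


def _grow(network: Network, n_add: int, gp: GrowthParams,
          rng: np.random.Generator) -> Network:
    if n_add == 0:
        return network.copy()
    if gp.model == "DMC":
        return grow_dmc(network, n_add, gp.q_con, gp.q_mod, rng)
    if gp.model == "DMR":
        return grow_dmr(network, n_add, gp.q_del, gp.q_new, rng)
    return grow_cg(network, n_add, gp.cg_avg_degree, rng, gp.cg_max_degree)


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------


@dataclass
class FamilyGroundTruth:
    """Ancestral-lineage functional group of every leaf protein."""

    groups: Dict[Tuple[str, str], int]

    def group_of(self, species: str, protein: str) -> int:
        return self.groups[(species, protein)]

    def as_frozensets(self) -> Dict[Tuple[str, str], FrozenSet[str]]:
        return {k: frozenset({str(v)}) for k, v in self.groups.items()}


def _seed_graph(rng: np.random.Generator, n: int = 10) -> nx.Graph:
    """Small connected random seed: a random recursive tree plus extra edges."""
    g = nx.Graph()
    g.add_node("p0")
    for i in range(1, n):
        j = int(rng.integers(i))
        g.add_edge(f"p{i}", f"p{j}", weight=1.0)
    extra = 0
    while extra < n // 2:
        a, b = rng.integers(n), rng.integers(n)
        if a != b and not g.has_edge(f"p{a}", f"p{b}"):
            g.add_edge(f"p{a}", f"p{b}", weight=1.0)
            extra += 1
    g.graph["next_node"] = n
    return g


def generate_family(
    phylo: PhylogenySpec,
    gp: GrowthParams,
    rng: np.random.Generator,
) -> Tuple[List[Network], FamilyGroundTruth]:
    """Evolve the phylogeny's leaf networks from a common ancestor.

    The ancestor is grown from a 10-node seed to ``phylo.ancestor_size``
    nodes with the chosen model; each ancestral protein then founds its own
    functional group, and every branch grows an independent copy of the
    parent by the branch-weight number of nodes.  Leaf node IDs are prefixed
    with the species name so a family's files are unambiguous.
    """
    seed = _seed_graph(rng)
    ancestor = _grow(Network("ancestor", seed), phylo.ancestor_size - seed.number_of_nodes(),
                     gp, rng).graph
    for gid, x in enumerate(sorted(ancestor.nodes)):
        ancestor.nodes[x]["group"] = gid
    ancestor.graph["next_group"] = ancestor.number_of_nodes()

    leaves: List[Network] = []
    truth: Dict[Tuple[str, str], int] = {}

    def walk(node: _TreeNode, parent_graph: nx.Graph) -> None:
        grown = _grow(Network("tmp", parent_graph), node.weight, gp, rng).graph
        if node.is_leaf():
            species = node.name or f"L{len(leaves)}"
            mapping = {x: f"{species}_{x}" for x in grown.nodes}
            leaf_graph = nx.relabel_nodes(grown, mapping, copy=True)
            leaves.append(Network(species, leaf_graph))
            for x in grown.nodes:
                truth[(species, mapping[x])] = int(grown.nodes[x]["group"])
        else:
            for child in node.children:
                walk(child, grown)

    for child in phylo.root.children:
        walk(child, ancestor)
    if not phylo.root.children:  # degenerate: the root itself is the family
        walk(phylo.root, ancestor)
    return leaves, FamilyGroundTruth(truth)


# ---------------------------------------------------------------------------
# Similarity simulation
# ---------------------------------------------------------------------------


def _draw(rng: np.random.Generator, loc: float, sigma: float, shift: float = 0.0) -> float:
    """One log-normal score with median ``loc``, shifted and truncated at 0."""
    s = float(rng.lognormal(math.log(loc), sigma)) + shift
    return s if s > 0.0 else 0.0


def simulate_similarities(
    leaves: Sequence[Network],
    truth: FamilyGroundTruth,
    sm: ScoreModel,
    rng: np.random.Generator,
) -> SimilarityStore:
    """Ortholog-biased similarity scores for a generated family.

    Every cross-network same-group pair receives an ortholog-distribution
    score (plus ``sm.bias``, truncated at 0 = absent); ``sm.decoy_rate``
    random different-group partners per protein receive background scores.
    """
    store = SimilarityStore(mode="bitscore")
    by_group: Dict[int, Dict[str, List[str]]] = {}
    for (species, protein), gid in truth.groups.items():
        by_group.setdefault(gid, {}).setdefault(species, []).append(protein)
    species_ids = [net.species_id for net in leaves]
    node_lists = {net.species_id: sorted(net.nodes) for net in leaves}

    for gid in sorted(by_group):
        members = by_group[gid]
        present = [s for s in species_ids if s in members]
        for a_idx in range(len(present)):
            for b_idx in range(a_idx + 1, len(present)):
                sa, sb = present[a_idx], present[b_idx]
                for x in sorted(members[sa]):
                    for y in sorted(members[sb]):
                        s = _draw(rng, sm.ortholog_loc, sm.sigma, sm.bias)
                        if s > 0.0:
                            store.add(sa, x, sb, y, s)

    if sm.decoy_rate > 0 and len(leaves) > 1:
        for sa in species_ids:
            others = [s for s in species_ids if s != sa]
            for x in node_lists[sa]:
                gx = truth.groups[(sa, x)]
                for _ in range(sm.decoy_rate):
                    sb = others[int(rng.integers(len(others)))]
                    for _attempt in range(8):
                        y = node_lists[sb][int(rng.integers(len(node_lists[sb])))]
                        if truth.groups[(sb, y)] != gx:
                            break
                    else:
                        continue
                    s = _draw(rng, sm.background_loc, sm.sigma)
                    if s > 0.0:
                        store.add(sa, x, sb, y, s)
    return store


def write_family(
    outdir: str,
    leaves: Sequence[Network],
    truth: FamilyGroundTruth,
    sim: Optional[SimilarityStore] = None,
) -> None:
    """Emit the family in the formats the readers consume: one edge-list TSV
    per leaf, ``groups.tsv``, and optionally ``similarity.tsv``."""
    os.makedirs(outdir, exist_ok=True)
    for net in leaves:
        write_network(net, os.path.join(outdir, f"{net.species_id}.tsv"))
    with open(os.path.join(outdir, "groups.tsv"), "wt", encoding="utf-8") as fh:
        for (species, protein), gid in sorted(truth.groups.items()):
            fh.write(f"{protein}\t{gid}\n")
    if sim is not None:
        with open(os.path.join(outdir, "similarity.tsv"), "wt", encoding="utf-8") as fh:
            rows = sorted(sim.iter_pairs())
            for na, a, nb, b, s in rows:
                fh.write(f"{a}\t{b}\t{s:.6g}\n")
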