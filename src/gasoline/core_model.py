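"""Domain types and file I/O for local multiple network alignment.

The central objects are :class:`Network` (one species' weighted, undirected
protein-interaction graph), :class:`SimilarityStore` (sparse symmetric
cross-network protein similarity, the score ``S(x, y)`` every sampler
consumes), :class:`AlignmentState` (one protein per network, a single column)
and :class:`LocalAlignment` (an ``N x m`` matrix of aligned proteins together
with the induced subgraphs).

File dialects understood here:

* edge-list TSV: ``node_a<TAB>node_b[<TAB>weight]`` — weight defaults to 1.0;
* BLAST tabular ``-outfmt 6`` (12 columns; columns 11-12 are E-value and bit
  score) or a generic 3-column ``x<TAB>y<TAB>score`` TSV for similarities;
* groups TSV: ``protein<TAB>group1,group2,...``;
* the alignment block format written by :func:`write_alignments`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

logger = logging.getLogger(__name__)

#: E-value used in place of an exact zero before inversion (keeps the score
#: finite while preserving the ranking of near-identical sequences).
EVALUE_FLOOR = 1e-180

SIM_MODES = ("bitscore", "inverse_evalue", "jaccard")


class GasolineError(Exception):
    """Base class for errors raised by this package."""


class ParseError(GasolineError):
    """A line of an input file could not be parsed."""


class ValidationError(GasolineError):
    """An input value violates a domain invariant."""


class EmptySimilarityError(GasolineError):
    """Every similarity pair was filtered out or unresolvable."""


class NoSeedsError(GasolineError):
    """A network contributes no candidate seed protein."""


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class Network:
    """Undirected weighted interaction graph of a single species.

    Backed by a :class:`networkx.Graph`; edge weights live in ``(0, 1]`` and
    are interpreted as interaction confidences.  A plain dict-of-dict
    adjacency view is cached for the samplers' hot loops.
    """

    __slots__ = ("species_id", "graph", "_adj")

    def __init__(self, species_id: str, graph: Optional[nx.Graph] = None):
        self.species_id = species_id
        self.graph = graph if graph is not None else nx.Graph()
        self._adj: Optional[Dict[str, Dict[str, float]]] = None

    # -- construction -------------------------------------------------------

    def add_node(self, x: str) -> None:
        self.graph.add_node(x)
        self._adj = None

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValidationError(f"self-loop ({u},{v}) not allowed")
        if not (0.0 < weight <= 1.0):
            raise ValidationError(f"edge weight {weight!r} outside (0, 1]")
        self.graph.add_edge(u, v, weight=float(weight))
        self._adj = None

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def adj(self) -> Dict[str, Dict[str, float]]:
        """Plain ``{u: {v: weight}}`` adjacency; rebuilt after mutation."""
        if self._adj is None:
            self._adj = {
                u: {v: d["weight"] for v, d in nbrs.items()}
                for u, nbrs in self.graph.adjacency()
            }
        return self._adj

    def has_node(self, x: str) -> bool:
        return self.graph.has_node(x)

    def degree(self, x: str) -> int:
        return self.graph.degree(x)

    def weight(self, u: str, v: str) -> float:
        """Edge weight, 0.0 if the edge is absent."""
        nbrs = self.adj.get(u)
        if not nbrs:
            return 0.0
        return nbrs.get(v, 0.0)

    def neighbors(self, x: str) -> Dict[str, float]:
        return self.adj.get(x, {})

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "Network":
        return Network(self.species_id, self.graph.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Network({self.species_id!r}, n={self.number_of_nodes()}, "
            f"m={self.number_of_edges()})"
        )


def read_network(path: str, species_id: str) -> Network:
    """Read an edge-list TSV into a :class:`Network`.

    Rows are ``node_a<TAB>node_b[<TAB>weight]``.  A missing weight column
    means weight 1.0 (unweighted input).  Symmetric duplicate rows collapse
    to one undirected edge (the first weight seen wins); self-loops are
    dropped with a warning but their node is kept.
    """
    net = Network(species_id)
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate space-separated input
                parts = line.split()
            if len(parts) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: unparseable weight {parts[2]!r}") from exc
            else:
                w = 1.0
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"{path}:{lineno}: weight {w} outside (0, 1]")
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                net.add_node(u)
                continue
            if not net.graph.has_edge(u, v):
                net.add_edge(u, v, w)
    return net


def write_network(net: Network, path: str) -> None:
    """Write a network back to edge-list TSV (canonical: sorted endpoints)."""
    with open(path, "wt", encoding="utf-8") as fh:
        # the dialect has no isolated-node row; degree-0 nodes are omitted
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            fh.write(f"{u}\t{v}\t{net.weight(u, v):g}\n")


# ---------------------------------------------------------------------------
# SimilarityStore
# ---------------------------------------------------------------------------


class SimilarityStore:
    """Sparse symmetric cross-network protein similarity ``S(x, y)``.

    Scores are keyed by ``(species, protein)`` on both sides; a pair that was
    never stored scores 0.  ``partners(net_a, a, net_b)`` returns the mapping
    ``{b: S(a, b)}`` of all stored partners of ``a`` inside network ``net_b``
    — the access pattern of both Gibbs samplers.
    """

    def __init__(self, mode: str = "bitscore"):
        if mode not in SIM_MODES:
            raise ValidationError(f"unknown similarity mode {mode!r}")
        self.mode = mode
        # species -> protein -> other_species -> {other_protein: score}
        self._by_net: Dict[str, Dict[str, Dict[str, Dict[str, float]]]] = {}
        self._n_pairs = 0

    _EMPTY: Dict[str, float] = {}

    def add(self, net_a: str, a: str, net_b: str, b: str, score: float) -> None:
        if net_a == net_b:
            raise ValidationError("similarity is defined between distinct networks only")
        if score < 0:
            raise ValidationError(f"similarity score {score} < 0")
        if self.mode == "jaccard" and score > 1.0:
            raise ValidationError(f"jaccard score {score} > 1")
        if score == 0.0:
            return  # absent pair already scores 0
        for na, xa, nb, xb in ((net_a, a, net_b, b), (net_b, b, net_a, a)):
            d = self._by_net.setdefault(na, {}).setdefault(xa, {}).setdefault(nb, {})
            if xb not in d:
                self._n_pairs += 1  # counts directed entries; /2 for pairs
            d[xb] = float(score)

    def score(self, net_a: str, a: str, net_b: str, b: str) -> float:
        return self.partners(net_a, a, net_b).get(b, 0.0)

    def partners(self, net_a: str, a: str, net_b: str) -> Dict[str, float]:
        try:
            return self._by_net[net_a][a][net_b]
        except KeyError:
            return self._EMPTY

    def has_any_partner(self, net_a: str, a: str, net_b: str) -> bool:
        return bool(self.partners(net_a, a, net_b))

    def __len__(self) -> int:
        """Number of stored unordered pairs."""
        return self._n_pairs // 2

    def iter_pairs(self) -> Iterator[Tuple[str, str, str, str, float]]:
        """Yield each unordered pair once as ``(net_a, a, net_b, b, score)``."""
        for na, by_prot in self._by_net.items():
            for a, by_other in by_prot.items():
                for nb, d in by_other.items():
                    if na < nb or (na == nb):  # na == nb impossible by construction
                        for b, s in d.items():
                            yield na, a, nb, b, s


def jaccard_similarity(groups_x: Set, groups_y: Set) -> float:
    """Jaccard index of two annotation sets: ``|x & y| / |x | y|``; 0 when
    both are empty."""
    union = len(groups_x | groups_y)
    if union == 0:
        return 0.0
    return len(groups_x & groups_y) / union


def read_similarity(
    path: str,
    networks: Sequence[Network],
    mode: str = "bitscore",
    evalue_cutoff: float = 1e-10,
) -> SimilarityStore:
    """Load cross-network similarities from BLAST tabular or 3-column TSV.

    12-column rows are treated as BLAST ``-outfmt 6`` (columns 11-12 =
    E-value, bit score): pairs with ``evalue > evalue_cutoff`` are dropped,
    and in ``inverse_evalue`` mode the score is ``1/evalue`` with exact zeros
    floored at ``EVALUE_FLOOR``.  3-column rows carry the final score
    directly.  Proteins must resolve to exactly one network; unresolvable or
    within-network pairs are skipped with a warning.
    """
    membership: Dict[str, List[str]] = {}
    for net in networks:
        for x in net.nodes:
            membership.setdefault(x, []).append(net.species_id)

    def resolve(x: str) -> Optional[str]:
        nets = membership.get(x)
        if nets is None or len(nets) != 1:
            return None
        return nets[0]

    store = SimilarityStore(mode=mode)
    n_skipped = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 12:
                x, y = parts[0], parts[1]
                try:
                    evalue = float(parts[10])
                    bitscore = float(parts[11])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad evalue/bitscore") from exc
                if evalue > evalue_cutoff:
                    continue
                if mode == "inverse_evalue":
                    score = 1.0 / max(evalue, EVALUE_FLOOR)
                else:
                    score = bitscore
            elif len(parts) == 3:
                x, y = parts[0], parts[1]
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: unparseable score {parts[2]!r}") from exc
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 (generic) or 12 (BLAST) columns, got {len(parts)}"
                )
            net_x, net_y = resolve(x), resolve(y)
            if net_x is None or net_y is None:
                logger.warning("%s:%d: unknown or ambiguous protein in pair (%s, %s); skipped",
                               path, lineno, x, y)
                n_skipped += 1
                continue
            if net_x == net_y:
                logger.warning("%s:%d: within-network pair (%s, %s); skipped", path, lineno, x, y)
                n_skipped += 1
                continue
            store.add(net_x, x, net_y, y, score)
    if len(store) == 0:
        raise EmptySimilarityError(
            f"{path}: empty similarity (all pairs filtered or unresolvable; {n_skipped} skipped)"
        )
    return store


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------


@dataclass
class AlignmentState:
    """One protein per network — a single column / Gibbs-chain state."""

    proteins: Tuple[str, ...]
    score: Optional[float] = None

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class MarkedSets:
    """Per-network candidate seed proteins (ordered for determinism)."""

    sets: List[List[str]]

    def __getitem__(self, i: int) -> List[str]:
        return self.sets[i]

    def __len__(self) -> int:
        return len(self.sets)


class LocalAlignment:
    """An ``N x m`` matrix of aligned proteins.

    Row ``i`` holds the ``m`` proteins of network ``i`` (the nodes of its
    aligned subgraph), column ``k`` is one equivalence class.  Mutation is
    column-wise (append / delete), mirroring the extension and removal steps.
    """

    def __init__(
        self,
        networks: Sequence[Network],
        columns: Iterable[Tuple[str, ...]],
        seed_column_index: Optional[int] = 0,
    ):
        self.networks = list(networks)
        self.columns: List[Tuple[str, ...]] = [tuple(c) for c in columns]
        n = len(self.networks)
        for c in self.columns:
            if len(c) != n:
                raise ValidationError(f"column {c!r} has {len(c)} entries for {n} networks")
        self.rows: List[List[str]] = [[c[i] for c in self.columns] for i in range(n)]
        self._row_sets: List[Set[str]] = [set(r) for r in self.rows]
        for i, r in enumerate(self.rows):
            if len(self._row_sets[i]) != len(r):
                raise ValidationError(f"duplicate protein in row {i}")
        self.seed_column_index = seed_column_index
        #: original seed column proteins, kept even if the seed is removed
        self.seed_proteins: Optional[Tuple[str, ...]] = (
            self.columns[seed_column_index] if seed_column_index is not None and self.columns else None
        )
        self.isc: Optional[float] = None
        self.rank: Optional[int] = None

    # -- shape --------------------------------------------------------------

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def size(self) -> int:
        """Number of columns m."""
        return len(self.columns)

    def row_set(self, i: int) -> Set[str]:
        return self._row_sets[i]

    # -- mutation -----------------------------------------------------------

    def append_column(self, column: Tuple[str, ...]) -> None:
        column = tuple(column)
        for i, x in enumerate(column):
            if x in self._row_sets[i]:
                raise ValidationError(f"protein {x!r} already in row {i}")
        self.columns.append(column)
        for i, x in enumerate(column):
            self.rows[i].append(x)
            self._row_sets[i].add(x)

    def pop_column(self, k: int = -1) -> Tuple[str, ...]:
        column = self.columns.pop(k)
        k_pos = k if k >= 0 else len(self.columns)
        for i, x in enumerate(column):
            del self.rows[i][k_pos]
            self._row_sets[i].discard(x)
        if self.seed_column_index is not None:
            if k_pos == self.seed_column_index:
                self.seed_column_index = None
            elif k_pos < self.seed_column_index:
                self.seed_column_index -= 1
        return column

    def copy(self) -> "LocalAlignment":
        dup = LocalAlignment(self.networks, self.columns, seed_column_index=None)
        dup.seed_column_index = self.seed_column_index
        dup.seed_proteins = self.seed_proteins
        dup.isc = self.isc
        dup.rank = self.rank
        return dup

    # -- induced structure ---------------------------------------------------

    def induced_edges(self, i: int) -> List[Tuple[str, str, float]]:
        """Edges of network ``i`` among the proteins of row ``i``."""
        net = self.networks[i]
        row = self.rows[i]
        row_set = self._row_sets[i]
        out = []
        for u in row:
            for v, w in net.neighbors(u).items():
                if v in row_set and u < v:
                    out.append((u, v, w))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LocalAlignment(N={self.n_networks}, m={self.size})"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class Params:
    """Tunable knobs of the full pipeline.

    ``iter_seed`` / ``iter_extend`` default to ``100*N`` / ``50*N`` single-
    position Gibbs updates when left as ``None`` (burn-in scales with the
    state dimension).  ``t_deg=1`` disables seed-degree filtering,
    ``max_overlap=0.5`` and ``min_size=1`` follow the published defaults.
    """

    iter_seed: Optional[int] = None
    iter_extend: Optional[int] = None
    iter_phase: int = 3
    t_deg: int = 1
    max_overlap: float = 0.5
    min_size: int = 1
    sim_mode: str = "bitscore"
    evalue_cutoff: float = 1e-10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("iter_seed", "iter_extend"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.iter_phase < 1:
            raise ValidationError("iter_phase must be >= 1")
        if self.t_deg < 1:
            raise ValidationError("t_deg must be >= 1")
        if not (0.0 <= self.max_overlap <= 1.0):
            raise ValidationError("max_overlap must be in [0, 1]")
        if self.min_size < 1:
            raise ValidationError("min_size must be >= 1")
        if self.sim_mode not in SIM_MODES:
            raise ValidationError(f"unknown sim_mode {self.sim_mode!r}")

    def resolved_iter_seed(self, n_networks: int) -> int:
        return self.iter_seed if self.iter_seed is not None else 100 * n_networks

    def resolved_iter_extend(self, n_networks: int) -> int:
        return self.iter_extend if self.iter_extend is not None else 50 * n_networks


# ---------------------------------------------------------------------------
# Alignment output format
# ---------------------------------------------------------------------------

_FORMAT_LINE = "# gasoline alignments v1"


def write_alignments(alignments: Sequence[LocalAlignment], path: str,
                     header_extra: Optional[Mapping[str, object]] = None) -> None:
    """Write ranked alignments as TSV blocks.

    Each block: ``#alignment <rank> size=<m> ISC=<isc>`` followed by one row
    per network (``species_id`` then the ``m`` proteins in column order).
    Deterministic given the same input list.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_FORMAT_LINE + "\n")
        if header_extra:
            for k in sorted(header_extra):
                fh.write(f"# {k}={header_extra[k]}\n")
        for idx, aln in enumerate(alignments, start=1):
            rank = aln.rank if aln.rank is not None else idx
            isc = aln.isc if aln.isc is not None else float("nan")
            fh.write(f"#alignment {rank} size={aln.size} ISC={isc:.3f}\n")
            for i, net in enumerate(aln.networks):
                fh.write("\t".join([net.species_id] + aln.rows[i]) + "\n")


@dataclass
class AlignmentRecord:
    """Parsed block of the alignment TSV (no network objects attached)."""

    rank: int
    isc: float
    species_ids: List[str]
    rows: List[List[str]]

    @property
    def size(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def columns(self) -> List[Tuple[str, ...]]:
        return [tuple(r[k] for r in self.rows) for k in range(self.size)]


def read_alignments(path: str) -> List[AlignmentRecord]:
    """Parse a file written by :func:`write_alignments`."""
    records: List[AlignmentRecord] = []
    current: Optional[AlignmentRecord] = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#alignment"):
                parts = line.split()
                try:
                    rank = int(parts[1])
                    kv = dict(p.split("=", 1) for p in parts[2:])
                    isc = float(kv.get("ISC", "nan"))
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad alignment header") from exc
                current = AlignmentRecord(rank=rank, isc=isc, species_ids=[], rows=[])
                records.append(current)
            elif line.startswith("#"):
                continue
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: data row before any alignment header")
                parts = line.split("\t")
                current.species_ids.append(parts[0])
                current.rows.append(parts[1:])
    return records


def read_groups(path: str) -> Dict[str, frozenset]:
    """Read ``protein<TAB>group1,group2,...`` into ``{protein: frozenset}``."""
    out: Dict[str, frozenset] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            groups = frozenset(g for g in parts[1].split(",") if g)
            out[parts[0]] = groups
    return out
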