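"""Alignment-quality metrics over predicted equivalence classes.

An equivalence class is one column of a kept alignment: a set of proteins
from different networks mapped together.  Against a ground truth of
functional-group labels the metrics are:

* **SPE** (specificity): fraction of classes whose members all agree — in
  single-group mode all members carry the same label, in multi-group mode
  they share at least one group;
* **CN** (correct nodes): total members of correct classes;
* **MNE** (mean normalized entropy): per class, the entropy of the member
  distribution over the groups present, normalized by ``log d`` so a class
  uniform over ``d > 1`` groups scores 1 and a pure class 0; averaged;
* **MGC** (mean group consistency): per class, the Jaccard-style ratio of
  the groups shared by *every* member over the groups carried by *any*
  member; averaged.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

from .core_model import GasolineError, LocalAlignment

__all__ = [
    "EquivalenceClass",
    "extract_classes",
    "classes_from_records",
    "specificity",
    "correct_nodes",
    "mean_normalized_entropy",
    "mean_group_consistency",
    "require_all_species",
]

GroupMap = Mapping[Tuple[str, str], FrozenSet[str]]


@dataclass(frozen=True)
class EquivalenceClass:
    """One alignment column: ``(species, protein)`` members plus provenance."""

    members: Tuple[Tuple[str, str], ...]
    rank: int = 0
    column: int = 0

    def __len__(self) -> int:
        return len(self.members)


def extract_classes(ranked: Sequence[LocalAlignment]) -> List[EquivalenceClass]:
    """One class per column of each kept alignment, in rank/column order."""
    out: List[EquivalenceClass] = []
    for idx, aln in enumerate(ranked, start=1):
        rank = aln.rank if aln.rank is not None else idx
        species = [net.species_id for net in aln.networks]
        for k, col in enumerate(aln.columns):
            out.append(EquivalenceClass(tuple(zip(species, col)), rank=rank, column=k))
    return out


def classes_from_records(records) -> List[EquivalenceClass]:
    """Classes from parsed :class:`~gasoline.core_model.AlignmentRecord`."""
    out: List[EquivalenceClass] = []
    for rec in records:
        for k, col in enumerate(rec.columns):
            out.append(EquivalenceClass(tuple(zip(rec.species_ids, col)),
                                        rank=rec.rank, column=k))
    return out


def _member_groups(cls: EquivalenceClass, groups: GroupMap) -> List[FrozenSet[str]]:
    return [groups.get(m, frozenset()) for m in cls.members]


def _is_multi_group(groups: GroupMap) -> bool:
    return any(len(g) > 1 for g in groups.values())


def _is_correct(cls: EquivalenceClass, groups: GroupMap, multi: bool) -> bool:
    gs = _member_groups(cls, groups)
    if any(not g for g in gs):
        return False
    if multi:
        return bool(frozenset.intersection(*gs))
    return len({_single_label(g) for g in gs}) == 1


def specificity(classes: Sequence[EquivalenceClass], groups: GroupMap,
                multi: bool | None = None) -> float:
    """Fraction of correct equivalence classes.

    ``multi=None`` auto-selects the mode from the shape of ``groups``
    (any multi-label protein switches to shared-group correctness).
    """
    if not classes:
        raise GasolineError("no classes to score")
    if multi is None:
        multi = _is_multi_group(groups)
    return sum(_is_correct(c, groups, multi) for c in classes) / len(classes)


def correct_nodes(classes: Sequence[EquivalenceClass], groups: GroupMap,
                  multi: bool | None = None) -> int:
    """Total number of proteins in correct classes."""
    if multi is None:
        multi = _is_multi_group(groups)
    return sum(len(c) for c in classes if _is_correct(c, groups, multi))


def _single_label(g: FrozenSet[str]) -> str:
    # MNE is a single-label metric; a multi-label member contributes its
    # lexicographically smallest label (never triggered on synthetic truth).
    return min(g)


def mean_normalized_entropy(classes: Sequence[EquivalenceClass], groups: GroupMap) -> float:
    """Mean over classes of the normalized group entropy.

    Per class: ``H = -(1/ln d) * sum_i p_i ln p_i`` with ``p_i`` the member
    fraction in group ``i`` and ``d`` the number of distinct groups present;
    a pure class has entropy 0, a uniform split over ``d > 1`` groups 1.
    """
    if not classes:
        raise GasolineError("no classes to score")
    total = 0.0
    for cls in classes:
        counts = Counter(_single_label(g) if g else "__unlabeled__"
                         for g in _member_groups(cls, groups))
        d = len(counts)
        if d <= 1:
            continue  # contributes 0
        n = len(cls)
        h = -sum((c / n) * math.log(c / n) for c in counts.values())
        total += h / math.log(d)
    return total / len(classes)


def mean_group_consistency(classes: Sequence[EquivalenceClass], groups: GroupMap) -> float:
    """Mean over classes of |shared groups| / |all groups carried|."""
    if not classes:
        raise GasolineError("no classes to score")
    total = 0.0
    for cls in classes:
        gs = _member_groups(cls, groups)
        union = frozenset().union(*gs)
        if not union or any(not g for g in gs):
            continue  # a member without annotation: class contributes 0
        total += len(frozenset.intersection(*gs)) / len(union)
    return total / len(classes)


def require_all_species(classes: Sequence[EquivalenceClass],
                        species: Sequence[str]) -> List[EquivalenceClass]:
    """Keep only classes containing at least one protein of every species
    (used to compare against many-to-many aligners; one-to-one columns
    always pass)."""
    wanted = set(species)
    return [c for c in classes
            if wanted <= {s for s, _ in c.members}]
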