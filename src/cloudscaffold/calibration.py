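"""Split-and-classify validation of scaffolding runs.

Large, trusted scaffolds are cut *in silico* into fixed-size child
pieces (a fixed amount of non-N sequence per child), alignments and
masks are lifted into the child coordinate system, and the scaffolder is
run on the children.  Because the original order and orientation of the
children is known, every join the scaffolder makes — and every join it
fails to make — can be labelled, yielding empirical type 1 (false join)
and type 2 (missed join) error rates for a given parameter setting.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Mapping, Sequence

from cloudscaffold.io_formats import AlignmentRecord, ScaffoldSequence
from cloudscaffold.repeat_mask import GenomicIntervalSet
from cloudscaffold.scaffolder import ScaffoldPath

__all__ = [
    "ChildRecord",
    "LiftTable",
    "JoinClassification",
    "split_scaffolds",
    "lift_alignments",
    "lift_intervals",
    "classify_joins",
    "error_rates",
]

CORRECT = "correct"
TYPE1 = "type1"
TYPE2 = "type2"
IGNORED = "ignored"


@dataclasses.dataclass(frozen=True, slots=True)
class ChildRecord:
    child_id: str
    parent_id: str
    parent_offset: int  # start of the child within the parent, bp
    length: int
    index_in_parent: int
    is_terminal: bool  # first or last piece of its parent


class LiftTable:
    """Child-to-parent bookkeeping for a split assembly."""

    def __init__(self, children: Sequence[ChildRecord]) -> None:
        self._by_child: dict[str, ChildRecord] = {}
        self._by_parent: dict[str, list[ChildRecord]] = {}
        for child in children:
            if child.child_id in self._by_child:
                raise ValueError(f"duplicate child id {child.child_id!r}")
            self._by_child[child.child_id] = child
            self._by_parent.setdefault(child.parent_id, []).append(child)
        for parent, kids in self._by_parent.items():
            kids.sort(key=lambda c: c.index_in_parent)
            indices = [c.index_in_parent for c in kids]
            if indices != list(range(len(kids))):
                raise ValueError(f"non-consecutive child indices for {parent!r}")

    def child(self, child_id: str) -> ChildRecord:
        if child_id not in self._by_child:
            raise KeyError(f"unknown child scaffold {child_id!r}")
        return self._by_child[child_id]

    def children_of(self, parent_id: str) -> list[ChildRecord]:
        return list(self._by_parent.get(parent_id, []))

    def parents(self) -> list[str]:
        return sorted(self._by_parent)

    def __len__(self) -> int:
        return len(self._by_child)

    def locate(self, parent_id: str, pos: int) -> ChildRecord:
        """The child whose parent interval contains ``pos``."""
        kids = self._by_parent.get(parent_id)
        if not kids:
            raise KeyError(f"unknown parent scaffold {parent_id!r}")
        for child in kids:
            if child.parent_offset <= pos < child.parent_offset + child.length:
                return child
        # Past-the-end positions clamp to the last child.
        return kids[-1]

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """All (child, next child) pairs within each parent."""
        pairs = []
        for parent in self.parents():
            kids = self._by_parent[parent]
            pairs.extend(
                (kids[i].child_id, kids[i + 1].child_id)
                for i in range(len(kids) - 1)
            )
        return pairs


@dataclasses.dataclass(frozen=True, slots=True)
class JoinClassification:
    category: str  # correct | type1 | type2 | ignored
    members: tuple[str, str]


def split_scaffolds(
    assembly: Iterable[ScaffoldSequence],
    min_parent_len: int = 500_000,
    child_non_n: int = 50_000,
) -> tuple[list[ScaffoldSequence], LiftTable]:
    """Cut large scaffolds into children of fixed non-N content.

    Scaffolds whose total length (gaps included) is at least
    ``min_parent_len`` are split so that every child except the final
    one contains exactly ``child_non_n`` non-N bases.  A cut never falls
    inside an N run: a gap is attached to the child holding the non-N
    base that precedes it, so concatenating a parent's children in index
    order reproduces the parent byte-exactly.  Shorter scaffolds pass
    through unsplit as their own single child.
    """
    children: list[ScaffoldSequence] = []
    table_rows: list[ChildRecord] = []
    for scaf in assembly:
        seq = scaf.sequence
        if len(seq) < min_parent_len:
            children.append(scaf)
            table_rows.append(
                ChildRecord(scaf.scaffold_id, scaf.scaffold_id, 0, len(seq), 0, True)
            )
            continue
        cuts = _cut_points(seq, child_non_n)
        n_kids = len(cuts) - 1
        for idx in range(n_kids):
            start, end = cuts[idx], cuts[idx + 1]
            child_id = f"{scaf.scaffold_id}.{idx}"
            children.append(ScaffoldSequence(child_id, seq[start:end]))
            table_rows.append(
                ChildRecord(
                    child_id,
                    scaf.scaffold_id,
                    start,
                    end - start,
                    idx,
                    idx == 0 or idx == n_kids - 1,
                )
            )
    return children, LiftTable(table_rows)


def _cut_points(seq: str, child_non_n: int) -> list[int]:
    """Cut coordinates such that each piece except the last holds exactly
    ``child_non_n`` non-N bases and no cut lands inside an N run."""
    cuts = [0]
    non_n_seen = 0
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] != "N":
            non_n_seen += 1
            if non_n_seen == child_non_n:
                # Attach any following N run to this child.
                j = i + 1
                while j < n and seq[j] == "N":
                    j += 1
                if j < n:  # a final cut at n would create an empty child
                    cuts.append(j)
                non_n_seen = 0
                i = j
                continue
        i += 1
    cuts.append(n)
    return cuts


def lift_alignments(
    records: Iterable[AlignmentRecord], table: LiftTable
) -> list[AlignmentRecord]:
    """Reassign reads to child scaffolds by their leftmost coordinate.

    A read spanning a cut stays with the child containing its leftmost
    base; its aligned span is clipped to the child end so coordinates
    stay valid.
    """
    out: list[AlignmentRecord] = []
    for rec in records:
        child = table.locate(rec.scaffold_id, rec.pos)
        new_pos = rec.pos - child.parent_offset
        span = min(rec.aligned_length, child.length - new_pos)
        out.append(
            dataclasses.replace(
                rec,
                scaffold_id=child.child_id,
                pos=new_pos,
                aligned_length=max(span, 1) if not rec.is_unmapped else 0,
            )
        )
    return out


def lift_intervals(
    intervals: GenomicIntervalSet, table: LiftTable
) -> GenomicIntervalSet:
    """Project a mask into child coordinates, splitting at cut points."""
    out = GenomicIntervalSet()
    for parent in intervals.scaffolds():
        kids = table.children_of(parent)
        if not kids:
            raise KeyError(f"unknown parent scaffold {parent!r}")
        for start, end in intervals.intervals(parent):
            for child in kids:
                c_start = child.parent_offset
                c_end = c_start + child.length
                lo, hi = max(start, c_start), min(end, c_end)
                if lo < hi:
                    out.add(child.child_id, lo - c_start, hi - c_start)
    return out


def classify_joins(
    paths: Sequence[ScaffoldPath], table: LiftTable
) -> list[JoinClassification]:
    """Label every made join and every missed adjacency.

    Made joins (consecutive path members) fall into three mutually
    exclusive categories: *correct* — adjacent children of one parent;
    *ignored* — two terminal pieces of different parents, unverifiable
    from the known ordering; *type1* — everything else, including
    nonadjacent same-parent pairs, cross-parent pairs with at most one
    terminal member, and joins to unsplit small scaffolds.  Every
    adjacent same-parent pair that was not joined to each other is
    emitted as a *type2* miss.
    """
    out: list[JoinClassification] = []
    made: set[frozenset[str]] = set()
    for path in paths:
        for a, b in path.joins:
            ca, cb = table.child(a), table.child(b)
            made.add(frozenset((a, b)))
            if ca.parent_id == cb.parent_id:
                if abs(ca.index_in_parent - cb.index_in_parent) == 1:
                    category = CORRECT
                else:
                    category = TYPE1
            elif ca.is_terminal and cb.is_terminal:
                category = IGNORED
            else:
                category = TYPE1
            out.append(JoinClassification(category, (a, b)))
    for a, b in table.adjacent_pairs():
        if frozenset((a, b)) not in made:
            out.append(JoinClassification(TYPE2, (a, b)))
    return out


def error_rates(
    classifications: Sequence[JoinClassification],
) -> tuple[float, float]:
    """Type 1 and type 2 linking error rates, as percentages.

    type1 rate = type1 / (correct + type1): the fraction of verifiable
    made joins that contradict the truth ordering.  type2 rate =
    type2 / (correct + type2): the fraction of expected joins that were
    not made.  Ignored joins appear in neither denominator.  Rounded to
    two decimals.
    """
    counts = Counter(c.category for c in classifications)
    made_denom = counts[CORRECT] + counts[TYPE1]
    expected_denom = counts[CORRECT] + counts[TYPE2]
    if made_denom == 0 or expected_denom == 0:
        raise ValueError("no classified joins to compute rates from")
    return (
        round(100.0 * counts[TYPE1] / made_denom, 2),
        round(100.0 * counts[TYPE2] / expected_denom, 2),
    )
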