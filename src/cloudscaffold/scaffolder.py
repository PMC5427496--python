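"""Overlap-layout-consensus scaffolding over barcode shared fractions.

Nodes are terminal windows of draft scaffolds, grown inward until they
hold a fixed amount of unmasked sequence.  Each node collects the set of
pool barcodes whose trusted reads land in its unmasked territory.  For
an ordered node pair (a, b) the shared fraction |A n B| / |A| measures
how surprising their barcode overlap is; a normal distribution fitted to
each node's shared-fraction sample over all other nodes converts an
observed fraction into a link score, -log10 of the upper-tail
probability.  Pairs scoring above a global threshold become weighted
edges; a greedy layout accepts edges in descending weight (each scaffold
end used at most once, no cycles) and the consensus step concatenates
chain members with N spacers.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from cloudscaffold.io_formats import AlignmentRecord, ScaffoldSequence
from cloudscaffold.repeat_mask import GenomicIntervalSet

__all__ = [
    "FIVE_PRIME",
    "THREE_PRIME",
    "GraphNode",
    "LinkEdge",
    "ScaffoldPath",
    "define_nodes",
    "assign_barcodes",
    "filter_nodes_by_barcode_count",
    "shared_fraction",
    "fit_fraction_distribution",
    "link_score",
    "compute_link_scores",
    "calibrate_threshold",
    "build_graph",
    "greedy_layout",
    "consensus",
    "scaffold_assembly",
    "reverse_complement",
]

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(slots=True)
class GraphNode:
    """A terminal window of a draft scaffold carrying a barcode set."""

    scaffold_id: str
    which_end: str  # FIVE_PRIME or THREE_PRIME
    span: tuple[int, int]  # 0-based half-open, touches the scaffold end
    unmasked_bases: int
    barcodes: set[str] = dataclasses.field(default_factory=set)

    @property
    def key(self) -> tuple[str, str]:
        return (self.scaffold_id, self.which_end)


@dataclasses.dataclass(frozen=True, slots=True)
class LinkEdge:
    """An undirected scored link between two scaffold-end nodes."""

    node_a: tuple[str, str]
    node_b: tuple[str, str]
    shared_count: int
    fraction_ab: float
    fraction_ba: float
    score: float


@dataclasses.dataclass(frozen=True, slots=True)
class ScaffoldPath:
    """An ordered, oriented chain of scaffolds (True = forward)."""

    members: tuple[tuple[str, bool], ...]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def joins(self) -> list[tuple[str, str]]:
        """Unordered scaffold pairs joined along this path."""
        return [
            (self.members[i][0], self.members[i + 1][0])
            for i in range(len(self.members) - 1)
        ]


def _grow_window(
    scaffold: str,
    length: int,
    mask: GenomicIntervalSet,
    from_start: bool,
    target_unmasked: int,
    max_span: int,
) -> tuple[tuple[int, int], int]:
    """Extend a terminal window inward until it holds ``target_unmasked``
    unmasked bases or spans ``max_span`` bp, whichever happens first."""
    cap = min(max_span, length)
    if from_start:
        lo, hi = 0, cap
        unmasked_at = lambda x: x - mask.overlap_length(scaffold, 0, x)
    else:
        lo, hi = length - cap, length
        unmasked_at = lambda x: (length - x) - mask.overlap_length(
            scaffold, x, length
        )
    total_unmasked = (
        unmasked_at(hi) if from_start else unmasked_at(lo)
    )
    if total_unmasked < target_unmasked:
        span = (0, cap) if from_start else (length - cap, length)
        return span, total_unmasked
    # Binary search the minimal span reaching the target (monotone).
    if from_start:
        a, b = 0, cap
        while a < b:
            mid = (a + b) // 2
            if unmasked_at(mid) >= target_unmasked:
                b = mid
            else:
                a = mid + 1
        return (0, a), target_unmasked
    a, b = length - cap, length
    while a < b:
        mid = (a + b) // 2
        if unmasked_at(mid) >= target_unmasked:
            a = mid + 1
        else:
            b = mid
    return (a - 1, length), unmasked_at(a - 1)


def define_nodes(
    scaffold_lengths: Mapping[str, int],
    mask: GenomicIntervalSet,
    E: int = 10_000,
    o: int = 50_000,
    m: int = 5_000,
) -> list[GraphNode]:
    """Build the two terminal-window nodes of each qualifying scaffold.

    Scaffolds shorter than ``m`` bp contribute no nodes: with sparse
    read coverage the shortest elements cannot accumulate enough barcode
    assignments for statistical power.  Each window grows inward from
    its scaffold end until it contains ``E`` unmasked bases, but never
    spans more than ``o`` bp.  ``mask`` must be normalized.
    """
    nodes: list[GraphNode] = []
    for scaffold in sorted(scaffold_lengths):
        length = scaffold_lengths[scaffold]
        if length < m:
            continue
        span5, un5 = _grow_window(scaffold, length, mask, True, E, o)
        span3, un3 = _grow_window(scaffold, length, mask, False, E, o)
        nodes.append(GraphNode(scaffold, FIVE_PRIME, span5, un5))
        nodes.append(GraphNode(scaffold, THREE_PRIME, span3, un3))
    return nodes


def assign_barcodes(
    nodes: list[GraphNode],
    records: Iterable[AlignmentRecord],
    mask: GenomicIntervalSet,
) -> list[GraphNode]:
    """Assign each barcode to every node where it has >=1 trusted read.

    A read counts toward a node when its leftmost position falls inside
    the node span and outside the mask.  Records must already have
    passed the alignment and barcode filters.  Both nodes of a short
    scaffold may overlap, in which case one read can feed both.
    """
    by_scaffold: dict[str, list[GraphNode]] = {}
    for node in nodes:
        by_scaffold.setdefault(node.scaffold_id, []).append(node)
    for rec in records:
        if rec.barcode is None:
            continue
        candidates = by_scaffold.get(rec.scaffold_id)
        if not candidates:
            continue
        hit = [
            n for n in candidates if n.span[0] <= rec.pos < n.span[1]
        ]
        if hit and not mask.covered(rec.scaffold_id, rec.pos):
            for node in hit:
                node.barcodes.add(rec.barcode)
    return nodes


def filter_nodes_by_barcode_count(
    nodes: list[GraphNode], D: float = 0.985
) -> tuple[list[GraphNode], int]:
    """Clip the upper tail of the node barcode-count distribution.

    Nodes whose barcode sets are implausibly large sit in repetitive or
    collapsed territory and generate promiscuous links.  The realized
    integer cutoff is the smallest count c such that the fraction of
    nodes with count < c is at least ``D``; nodes with count >= c are
    removed (ties at the cutoff retained).  Returns (kept nodes, cutoff).
    """
    if not 0.5 < D <= 1.0:
        raise ValueError(f"D must lie in (0.5, 1], got {D}")
    if not nodes:
        return [], 0
    counts = sorted(len(n.barcodes) for n in nodes)
    k = math.ceil(D * len(counts))
    cutoff = counts[k - 1] + 1
    return [n for n in nodes if len(n.barcodes) < cutoff], cutoff


def shared_fraction(a: GraphNode, b: GraphNode) -> tuple[float, float, int]:
    """Ordered shared fractions (|AnB|/|A|, |AnB|/|B|) and the overlap."""
    if not a.barcodes or not b.barcodes:
        raise ValueError("shared fraction undefined for an empty barcode set")
    shared = len(a.barcodes & b.barcodes)
    return shared / len(a.barcodes), shared / len(b.barcodes), shared


def fit_fraction_distribution(sample: Sequence[float]) -> tuple[float, float]:
    """Fit (mu, sigma) of a normal to a node's shared-fraction sample.

    Raises
    ------
    ValueError
        If the sample has fewer than two values or zero variance; such a
        node is excluded from scoring rather than given an artificial
        variance floor.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two shared-fraction observations")
    mu = float(arr.mean())
    sigma = float(arr.std())
    if sigma <= 0.0:
        raise ValueError("degenerate fit: zero variance in shared fractions")
    return mu, sigma


def link_score(mu: float, sigma: float, observed: float) -> float:
    """-log10 upper-tail probability of ``observed`` under Normal(mu, sigma).

    Monotone in the observed fraction: a larger shared fraction can
    never score lower.  Computed via the log survival function so deep
    tails stay finite and accurate.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(-stats.norm.logsf(observed, loc=mu, scale=sigma) / math.log(10))


def compute_link_scores(
    nodes: list[GraphNode],
) -> tuple[list[GraphNode], np.ndarray, np.ndarray, np.ndarray]:
    """All ordered pair scores for nodes with usable barcode sets.

    Returns (scored nodes, shared-count matrix, fraction matrix, combined
    score matrix).  The combined score of an unordered pair is the
    arithmetic mean of its two ordered scores.  Nodes with empty barcode
    sets or degenerate (zero-variance) shared-fraction distributions are
    dropped before scoring.
    """
    usable = [n for n in nodes if n.barcodes]
    n = len(usable)
    if n < 3:
        return usable, np.zeros((n, n)), np.zeros((n, n)), np.zeros((n, n))

    barcode_index: dict[str, list[int]] = {}
    for i, node in enumerate(usable):
        for bc in node.barcodes:
            barcode_index.setdefault(bc, []).append(i)
    shared = np.zeros((n, n), dtype=np.int64)
    for members in barcode_index.values():
        if len(members) > 1:
            idx = np.array(members)
            shared[np.ix_(idx, idx)] += 1
    np.fill_diagonal(shared, 0)

    sizes = np.array([len(node.barcodes) for node in usable], dtype=float)
    fractions = shared / sizes[:, None]  # fractions[i, j] = |Bi n Bj| / |Bi|

    # Per-node normal fit over its fractions against all other nodes.
    mask_off = ~np.eye(n, dtype=bool)
    mu = np.array([fractions[i][mask_off[i]].mean() for i in range(n)])
    sigma = np.array([fractions[i][mask_off[i]].std() for i in range(n)])
    good = sigma > 0

    ordered = np.full((n, n), np.nan)
    log10 = math.log(10)
    for i in range(n):
        if not good[i]:
            continue
        ordered[i] = -stats.norm.logsf(
            fractions[i], loc=mu[i], scale=sigma[i]
        ) / log10
    combined = (ordered + ordered.T) / 2.0  # nan where either fit failed
    np.fill_diagonal(combined, np.nan)
    return usable, shared, fractions, combined


def calibrate_threshold(
    shared: np.ndarray, combined: np.ndarray, percentile: float = 99.0
) -> float:
    """Global link-score threshold from coincidentally-sharing pairs.

    One shared barcode between two nodes is common by chance and never
    evidence of proximity; the threshold is set at the given percentile
    of the combined scores of all single-shared-barcode pairs, so such
    pairs fall below it.
    """
    iu = np.triu_indices(shared.shape[0], k=1)
    scores = combined[iu]
    singles = scores[(shared[iu] == 1) & np.isfinite(scores)]
    if singles.size == 0:
        low = scores[(shared[iu] <= 1) & np.isfinite(scores)]
        if low.size == 0:
            return 0.0
        return float(np.percentile(low, percentile))
    return float(np.percentile(singles, percentile))


def build_graph(
    nodes: list[GraphNode],
    shared: np.ndarray,
    fractions: np.ndarray,
    combined: np.ndarray,
    threshold: float,
) -> list[LinkEdge]:
    """Edges for node pairs whose combined score exceeds the threshold.

    The two ends of the same scaffold are never linked to each other.
    """
    edges: list[LinkEdge] = []
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if nodes[i].scaffold_id == nodes[j].scaffold_id:
                continue
            score = combined[i, j]
            if np.isfinite(score) and score > threshold:
                edges.append(
                    LinkEdge(
                        node_a=nodes[i].key,
                        node_b=nodes[j].key,
                        shared_count=int(shared[i, j]),
                        fraction_ab=float(fractions[i, j]),
                        fraction_ba=float(fractions[j, i]),
                        score=float(score),
                    )
                )
    return edges


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


def greedy_layout(
    edges: Sequence[LinkEdge], scaffold_ids: Iterable[str]
) -> list[ScaffoldPath]:
    """Linearize the link graph by greedy edge acceptance.

    Edges are visited in descending weight (ties broken by node keys for
    determinism).  An edge is accepted iff both of its scaffold-end
    nodes are still unused and the two scaffolds are not already in the
    same chain (no cycles).  Accepted edges define joins; every chain
    becomes one path, every unjoined scaffold a singleton path.
    """
    order = sorted(edges, key=lambda e: (-e.score, e.node_a, e.node_b))
    used_ends: set[tuple[str, str]] = set()
    uf = _UnionFind()
    partner: dict[tuple[str, str], tuple[str, str]] = {}
    for edge in order:
        a, b = edge.node_a, edge.node_b
        if a in used_ends or b in used_ends:
            continue
        if uf.find(a[0]) == uf.find(b[0]):
            continue
        used_ends.update((a, b))
        partner[a] = b
        partner[b] = a
        uf.union(a[0], b[0])

    all_ids = sorted(set(scaffold_ids))
    paths: list[ScaffoldPath] = []
    emitted: set[str] = set()
    for scaffold in all_ids:
        if scaffold in emitted:
            continue
        n_joined = sum(
            1 for end in (FIVE_PRIME, THREE_PRIME) if (scaffold, end) in partner
        )
        if n_joined == 0:
            emitted.add(scaffold)
            paths.append(ScaffoldPath(((scaffold, True),)))
            continue
        if n_joined == 2:
            continue  # interior of a chain; reached from a terminus
        # Chain terminus: orientation chosen so we exit via the joined end.
        exit_end = (
            THREE_PRIME if (scaffold, THREE_PRIME) in partner else FIVE_PRIME
        )
        members: list[tuple[str, bool]] = [(scaffold, exit_end == THREE_PRIME)]
        emitted.add(scaffold)
        current = (scaffold, exit_end)
        while current in partner:
            nxt_scaffold, entry_end = partner[current]
            forward = entry_end == FIVE_PRIME
            members.append((nxt_scaffold, forward))
            emitted.add(nxt_scaffold)
            exit_end = THREE_PRIME if forward else FIVE_PRIME
            current = (nxt_scaffold, exit_end)
        paths.append(_canonical(tuple(members)))
    return paths


def _canonical(members: tuple[tuple[str, bool], ...]) -> ScaffoldPath:
    """Pick one of a chain's two equivalent directions deterministically:
    prefer starting with a forward-oriented member, then the smaller id."""
    rev = tuple((sid, not fwd) for sid, fwd in reversed(members))
    fwd_first = members[0][1]
    rev_first = rev[0][1]
    if fwd_first and not rev_first:
        return ScaffoldPath(members)
    if rev_first and not fwd_first:
        return ScaffoldPath(rev)
    return ScaffoldPath(min(members, rev))


def consensus(
    paths: Sequence[ScaffoldPath],
    assembly: Mapping[str, str],
    gap_n: int = 100,
) -> list[ScaffoldSequence]:
    """Concatenate each chain into one sequence with N spacers.

    Reverse-oriented members are reverse-complemented.  Singleton paths
    pass through unchanged under their original id; joined sequences get
    an id recording the ordered, oriented components.
    """
    out: list[ScaffoldSequence] = []
    spacer = "N" * gap_n
    for path in paths:
        for sid, _ in path.members:
            if sid not in assembly:
                raise KeyError(f"scaffold {sid!r} missing from assembly")
        if len(path) == 1:
            sid = path.members[0][0]
            out.append(ScaffoldSequence(sid, assembly[sid]))
            continue
        pieces = [
            assembly[sid] if fwd else reverse_complement(assembly[sid])
            for sid, fwd in path.members
        ]
        new_id = "join|" + "|".join(
            f"{sid}{'+' if fwd else '-'}" for sid, fwd in path.members
        )
        out.append(ScaffoldSequence(new_id, spacer.join(pieces)))
    return out


def scaffold_assembly(
    scaffold_lengths: Mapping[str, int],
    records: Iterable[AlignmentRecord],
    mask: GenomicIntervalSet,
    E: int = 10_000,
    o: int = 50_000,
    m: int = 5_000,
    D: float = 0.985,
    threshold: float | None = None,
) -> tuple[list[ScaffoldPath], list[LinkEdge], dict]:
    """Run the full node / score / threshold / layout pipeline.

    ``records`` must already be alignment- and barcode-filtered.  When
    ``threshold`` is None it is calibrated from the single-shared-barcode
    score distribution (see :func:`calibrate_threshold`).  Returns the
    layout paths, accepted-candidate edges, and a run report with the
    realized parameters and counts.
    """
    nodes = define_nodes(scaffold_lengths, mask, E=E, o=o, m=m)
    nodes = assign_barcodes(nodes, records, mask)
    kept, cutoff = filter_nodes_by_barcode_count(nodes, D=D)
    scored, shared, fractions, combined = compute_link_scores(kept)
    if threshold is None:
        threshold = calibrate_threshold(shared, combined)
    edges = build_graph(scored, shared, fractions, combined, threshold)
    paths = greedy_layout(edges, scaffold_lengths.keys())
    report = {
        "n_scaffolds": len(scaffold_lengths),
        "n_nodes": len(nodes),
        "n_nodes_after_clip": len(kept),
        "barcode_count_cutoff": cutoff,
        "n_scored_nodes": len(scored),
        "threshold": threshold,
        "n_edges": len(edges),
        "n_joins": sum(len(p) - 1 for p in paths),
        "E": E, "o": o, "m": m, "D": D,
    }
    return paths, edges, report
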