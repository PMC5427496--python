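"""Node definition, link scoring, greedy layout and consensus."""

import math

import numpy as np
import pytest

from cloudscaffold.repeat_mask import GenomicIntervalSet
from cloudscaffold.scaffolder import (
    FIVE_PRIME,
    THREE_PRIME,
    GraphNode,
    LinkEdge,
    ScaffoldPath,
    calibrate_threshold,
    compute_link_scores,
    consensus,
    define_nodes,
    filter_nodes_by_barcode_count,
    fit_fraction_distribution,
    greedy_layout,
    link_score,
    reverse_complement,
    scaffold_assembly,
    shared_fraction,
)

EMPTY_MASK = GenomicIntervalSet()


def node(sid, end=FIVE_PRIME, barcodes=(), span=(0, 10_000)):
    return GraphNode(sid, end, span, span[1] - span[0], set(barcodes))


class TestDefineNodes:
    def test_short_scaffolds_skipped(self):
        assert define_nodes({"s": 4_999}, EMPTY_MASK) == []
        assert len(define_nodes({"s": 5_000}, EMPTY_MASK)) == 2

    def test_unmasked_scaffold_gets_minimal_windows(self):
        five, three = define_nodes({"s": 100_000}, EMPTY_MASK)
        assert (five.which_end, five.span) == (FIVE_PRIME, (0, 10_000))
        assert (three.which_end, three.span) == (THREE_PRIME, (90_000, 100_000))
        assert five.unmasked_bases == three.unmasked_bases == 10_000

    def test_masked_prefix_grows_window(self):
        mask = GenomicIntervalSet({"s": [(0, 5_000)]})
        five, _ = define_nodes({"s": 100_000}, mask)
        assert five.span == (0, 15_000)
        assert five.unmasked_bases == 10_000

    def test_window_capped_at_o(self):
        mask = GenomicIntervalSet({"s": [(0, 45_000)]})
        five, _ = define_nodes({"s": 100_000}, mask, o=50_000)
        assert five.span == (0, 50_000)
        assert five.unmasked_bases == 5_000

    def test_whole_scaffold_window_when_shorter_than_cap(self):
        five, three = define_nodes({"s": 8_000}, EMPTY_MASK)
        assert five.span == (0, 8_000) and three.span == (0, 8_000)


class TestBarcodeCountClip:
    def _nodes(self, counts):
        return [
            node(f"s{i}", barcodes=[f"b{i}_{j}" for j in range(c)])
            for i, c in enumerate(counts)
        ]

    def test_quantile_convention_on_one_to_thousand(self):
        nodes = self._nodes(range(1, 1001))
        kept, cutoff = filter_nodes_by_barcode_count(nodes, D=0.985)
        assert cutoff == 986
        assert len(nodes) - len(kept) == 15

    def test_d_equal_one_removes_nothing(self):
        nodes = self._nodes(range(1, 101))
        kept, cutoff = filter_nodes_by_barcode_count(nodes, D=1.0)
        assert len(kept) == 100 and cutoff == 101

    def test_all_equal_counts_removes_nothing(self):
        nodes = self._nodes([7] * 40)
        kept, cutoff = filter_nodes_by_barcode_count(nodes)
        assert len(kept) == 40 and cutoff == 8

    def test_rejects_bad_quantile(self):
        with pytest.raises(ValueError):
            filter_nodes_by_barcode_count([], D=0.3)


class TestSharedFraction:
    def test_asymmetric_fractions(self):
        a = node("a", barcodes={"a", "b", "c", "d"})
        b = node("b", barcodes={"a", "b"})
        assert shared_fraction(a, b) == (0.5, 1.0, 2)
        assert shared_fraction(b, a) == (1.0, 0.5, 2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            shared_fraction(node("a"), node("b", barcodes={"x"}))


def erfc_tail_score(mu, sigma, x):
    """Independent oracle: -log10 of the normal upper tail via erfc."""
    z = (x - mu) / (sigma * math.sqrt(2))
    return -math.log10(0.5 * math.erfc(z))


class TestLinkScore:
    def test_at_the_mean(self):
        assert link_score(0.1, 0.05, 0.1) == pytest.approx(
            -math.log10(0.5), abs=1e-12
        )

    @pytest.mark.parametrize("z", [-1.0, 0.0, 0.5, 2.0, 4.0])
    def test_matches_erfc_oracle(self, z):
        mu, sigma = 0.02, 0.015
        x = mu + z * sigma
        assert link_score(mu, sigma, x) == pytest.approx(
            erfc_tail_score(mu, sigma, x), rel=1e-9
        )

    def test_monotone_in_observation(self):
        xs = np.linspace(-0.2, 1.2, 57)
        scores = [link_score(0.05, 0.02, x) for x in xs]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_deep_tail_stays_finite(self):
        assert math.isfinite(link_score(0.01, 0.005, 1.0))

    def test_fit_rejects_degenerate_samples(self):
        with pytest.raises(ValueError):
            fit_fraction_distribution([0.1])
        with pytest.raises(ValueError):
            fit_fraction_distribution([0.5, 0.5, 0.5])
        mu, sigma = fit_fraction_distribution([0.0, 0.1])
        assert mu == pytest.approx(0.05) and sigma == pytest.approx(0.05)


class TestComputeLinkScores:
    def _nodes(self):
        # s1 and s2 share heavily; s3/s4 provide background.
        return [
            node("s1", barcodes={"a", "b", "c", "d", "e"}),
            node("s2", barcodes={"a", "b", "c", "d", "f"}),
            node("s3", barcodes={"g", "h"}),
            node("s4", barcodes={"i", "j", "g"}),
        ]

    def test_shared_matrix_and_fractions(self):
        usable, shared, fractions, combined = compute_link_scores(self._nodes())
        assert shared[0, 1] == 4 and shared[1, 0] == 4
        assert fractions[0, 1] == pytest.approx(4 / 5)
        assert fractions[2, 3] == pytest.approx(1 / 2)
        assert np.all(np.diag(shared) == 0)

    def test_combined_is_symmetric(self):
        _, _, _, combined = compute_link_scores(self._nodes())
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(combined[off], combined.T[off], equal_nan=True)

    def test_true_pair_outranks_background(self):
        _, _, _, combined = compute_link_scores(self._nodes())
        # s1's heavy overlap with s2 must outrank its null pairings.
        assert combined[0, 1] > combined[0, 2]
        assert combined[0, 1] > combined[0, 3]

    def test_fewer_than_three_nodes_scores_nothing(self):
        usable, shared, _, combined = compute_link_scores(self._nodes()[:2])
        assert shared.shape == (2, 2) and not combined.any()

    def test_threshold_from_single_shared_pairs(self):
        shared = np.array([[0, 1, 5], [1, 0, 1], [5, 1, 0]])
        combined = np.array(
            [[np.nan, 0.4, 3.0], [0.4, np.nan, 0.6], [3.0, 0.6, np.nan]]
        )
        threshold = calibrate_threshold(shared, combined)
        assert 0.4 <= threshold <= 0.6
        assert threshold < 3.0

    def test_threshold_empty_matrix_is_zero(self):
        z = np.zeros((0, 0))
        assert calibrate_threshold(z, z) == 0.0


def edge(a, b, score, shared=10):
    return LinkEdge(a, b, shared, 0.5, 0.5, score)


A3 = ("A", THREE_PRIME)
A5 = ("A", FIVE_PRIME)
B3 = ("B", THREE_PRIME)
B5 = ("B", FIVE_PRIME)
C3 = ("C", THREE_PRIME)
C5 = ("C", FIVE_PRIME)


class TestGreedyLayout:
    def test_chain_of_three(self):
        paths = greedy_layout(
            [edge(A3, B5, 5.0), edge(B3, C5, 4.0)], ["A", "B", "C"]
        )
        (path,) = paths
        assert path.members == (("A", True), ("B", True), ("C", True))

    def test_end_reuse_blocked(self):
        paths = greedy_layout(
            [edge(A3, B5, 5.0), edge(A3, C5, 4.0)], ["A", "B", "C"]
        )
        by_len = sorted(paths, key=len)
        assert by_len[0].members == (("C", True),)
        assert by_len[1].members == (("A", True), ("B", True))

    def test_cycle_rejected(self):
        paths = greedy_layout(
            [edge(A3, B5, 5.0), edge(B3, A5, 4.0)], ["A", "B"]
        )
        (path,) = paths
        assert path.members == (("A", True), ("B", True))

    def test_reverse_orientation_from_end_polarity(self):
        # Exiting A through its five-prime end flips A; entering B through
        # its three-prime end flips B.
        (path,) = greedy_layout([edge(A5, B3, 2.0)], ["A", "B"])
        assert path.members in {
            (("A", False), ("B", False)),
            (("B", True), ("A", True)),
        }

    def test_no_edges_all_singletons(self):
        paths = greedy_layout([], ["A", "B"])
        assert [p.members for p in paths] == [(("A", True),), (("B", True),)]

    def test_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            ids = [f"s{i}" for i in range(int(rng.integers(2, 7)))]
            ends = [(s, e) for s in ids for e in (FIVE_PRIME, THREE_PRIME)]
            n_edges = int(rng.integers(0, 9))
            edges = []
            seen = set()
            for _ in range(n_edges):
                i, j = rng.choice(len(ends), size=2, replace=False)
                a, b = sorted((ends[i], ends[j]))
                if a[0] == b[0] or (a, b) in seen:
                    continue
                seen.add((a, b))
                edges.append(edge(a, b, float(rng.integers(1, 100))))
            expected = self._oracle_joins(edges)
            paths = greedy_layout(edges, ids)
            got = {frozenset(j) for p in paths for j in p.joins}
            assert got == expected
            # Every scaffold appears exactly once across all paths.
            flat = [sid for p in paths for sid, _ in p.members]
            assert sorted(flat) == sorted(ids)

    @staticmethod
    def _oracle_joins(edges):
        """Re-derive the accepted join set with naive bookkeeping."""
        order = sorted(edges, key=lambda e: (-e.score, e.node_a, e.node_b))
        used, comp = set(), {}
        accepted = set()

        def root(x):
            while comp.get(x, x) != x:
                x = comp[x]
            return x

        for e in order:
            a, b = e.node_a, e.node_b
            if a in used or b in used:
                continue
            ra, rb = root(a[0]), root(b[0])
            if ra == rb:
                continue
            comp[ra] = rb
            used.update((a, b))
            accepted.add(frozenset((a[0], b[0])))
        return accepted


class TestConsensus:
    ASSEMBLY = {"A": "ACGTACGT", "B": "ACCT", "C": "GG"}

    def test_reverse_complement(self):
        assert reverse_complement("ACCT") == "AGGT"
        assert reverse_complement("") == ""

    def test_join_with_spacer_and_orientation(self):
        path = ScaffoldPath((("A", True), ("B", False)))
        (out,) = consensus([path], self.ASSEMBLY, gap_n=3)
        assert out.scaffold_id == "join|A+|B-"
        assert out.sequence == "ACGTACGT" + "NNN" + "AGGT"

    def test_singleton_passthrough(self):
        (out,) = consensus([ScaffoldPath((("C", True),))], self.ASSEMBLY)
        assert (out.scaffold_id, out.sequence) == ("C", "GG")

    def test_missing_member_raises(self):
        with pytest.raises(KeyError):
            consensus([ScaffoldPath((("Z", True),))], self.ASSEMBLY)

    def test_total_sequence_conserved(self):
        paths = greedy_layout([edge(A3, B5, 2.0)], ["A", "B", "C"])
        out = consensus(paths, self.ASSEMBLY, gap_n=100)
        non_n = sum(len(s.sequence) - s.sequence.count("N") for s in out)
        orig = sum(
            len(s) - s.count("N") for s in self.ASSEMBLY.values()
        )
        assert non_n == orig


class TestEndToEnd:
    def test_recovers_most_true_adjacencies(self, small_problem):
        truth = small_problem["truth"]
        paths, edges, report = scaffold_assembly(
            truth.piece_lengths(),
            small_problem["kept"],
            small_problem["mask"],
        )
        made = {frozenset(j) for p in paths for j in p.joins}
        true_adj = truth.true_adjacencies()
        recovered = len(made & true_adj)
        assert recovered / len(true_adj) >= 0.6
        false_joins = len(made - true_adj)
        assert false_joins <= 0.15 * max(len(made), 1)
        assert report["threshold"] > 0
        assert report["n_joins"] == len(made)
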