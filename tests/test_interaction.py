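"""Clique-based interaction alignment against an exhaustive-enumeration oracle."""

import itertools

import numpy as np
import pytest

from motifcompare import (
    InteractionGraph,
    ScoringParams,
    align_interactions,
    build_compatibility_graph,
    interaction_match_score,
)
from motifcompare.interaction import PairEdge, StackEdge

PARAMS = ScoringParams()


# ----------------------------------------------------------------- oracle

def oracle_best_score(A: InteractionGraph, B: InteractionGraph, params=PARAMS):
    """Exhaustive enumeration of all order-consistent one-to-one matchings.

    Independent of the clique search: recurses over A's nodes in order,
    assigning each to an unused B node of the mapped segment without crossing
    previously assigned matches of the same segment pair.
    """
    pairA = {(e.u, e.v): e for e in A.pair_edges}
    pairB = {(e.u, e.v): e for e in B.pair_edges}
    stackA = {(e.u, e.v): e for e in A.stack_edges}
    stackB = {(e.u, e.v): e for e in B.stack_edges}

    def matching_score(matches):
        score = sum(
            params.seq_match if A.bases[u] == B.bases[v] else params.seq_mismatch
            for u, v in matches
        )
        for (u1, v1), (u2, v2) in itertools.combinations(matches, 2):
            ka, kb = tuple(sorted((u1, u2))), tuple(sorted((v1, v2)))
            if ka in pairA and kb in pairB:
                score += interaction_match_score(pairA[ka], pairB[kb], params)
            if ka in stackA and kb in stackB:
                score += interaction_match_score(stackA[ka], stackB[kb], params)
        return score

    ka, kb = A.n_segments, B.n_segments
    if ka <= kb:
        mappings = [dict(enumerate(p)) for p in itertools.permutations(range(kb), ka)]
    else:
        mappings = []
        for sel in itertools.permutations(range(ka), kb):
            mappings.append({a: b for b, a in enumerate(sel)})

    best = 0.0
    for seg_map in mappings:
        b_by_seg = {}
        for v in range(len(B)):
            b_by_seg.setdefault(B.seg_of[v], []).append(v)

        def recurse(u, used, last_in_seg, matches):
            nonlocal best
            if u == len(A):
                best = max(best, matching_score(matches))
                return
            recurse(u + 1, used, last_in_seg, matches)  # leave u unmatched
            sa = A.seg_of[u]
            if sa not in seg_map:
                return
            for v in b_by_seg.get(seg_map[sa], []):
                if v in used or v <= last_in_seg.get(sa, -1):
                    continue
                recurse(u + 1, used | {v}, {**last_in_seg, sa: v}, matches + [(u, v)])

        recurse(0, frozenset(), {}, [])
    return best


def random_graph(rng, n_min=3, n_max=8, segments=True) -> InteractionGraph:
    n = int(rng.integers(n_min, n_max + 1))
    bases = [str(b) for b in rng.choice(list("ACGU"), size=n)]
    if segments and n >= 4 and rng.random() < 0.5:
        split = int(rng.integers(2, n - 1))
        seg_of = [0] * split + [1] * (n - split)
    else:
        seg_of = [0] * n
    classes = ["cWW", "tHS", "cSS", "tWH", "cHH"]
    pairs, stacks = [], []
    used = set()
    for _ in range(int(rng.integers(0, 4))):
        u, v = sorted(rng.choice(n, size=2, replace=False).tolist())
        if (u, v) in used:
            continue
        used.add((u, v))
        lab = classes[int(rng.integers(len(classes)))]
        orientation = "cis" if lab[0] == "c" else "trans"
        pairs.append(PairEdge(u, v, lab[1], lab[2], orientation))
    for _ in range(int(rng.integers(0, 3))):
        u = int(rng.integers(0, n - 1))
        if (u, u + 1) not in used:
            used.add((u, u + 1))
            stacks.append(StackEdge(u, u + 1))
    return InteractionGraph(bases, seg_of, pairs, stacks)


# ------------------------------------------------------------ match scores

@pytest.mark.parametrize(
    "ea,eb,expected",
    [
        (PairEdge(0, 1, "W", "W", "cis"), PairEdge(0, 1, "W", "W", "cis"),
         PARAMS.pair_full),
        # symmetric endpoint flip still counts as a full class match
        (PairEdge(0, 1, "H", "S", "trans"), PairEdge(0, 1, "S", "H", "trans"),
         PARAMS.pair_full),
        (PairEdge(0, 1, "W", "W", "cis"), PairEdge(0, 1, "H", "S", "trans"), 0.0),
        # one shared edge with matching orientation: partial credit
        (PairEdge(0, 1, "W", "H", "cis"), PairEdge(0, 1, "W", "W", "cis"),
         PARAMS.pair_partial),
        # same edges but opposite orientation: no credit
        (PairEdge(0, 1, "W", "W", "cis"), PairEdge(0, 1, "W", "W", "trans"), 0.0),
        (StackEdge(0, 1, "upward"), StackEdge(0, 1, "outward"), PARAMS.stack),
        (PairEdge(0, 1, "W", "W", "cis"), StackEdge(0, 1), 0.0),
    ],
)
def test_interaction_match_score_classes(ea, eb, expected):
    assert interaction_match_score(ea, eb, PARAMS) == expected


# ------------------------------------------------------------- alignments

def test_self_alignment_is_identity_with_full_length():
    g = InteractionGraph(
        list("GAGA"), [0, 0, 1, 1],
        [PairEdge(0, 3, "H", "S", "trans"), PairEdge(1, 2, "W", "W", "cis")],
        [StackEdge(0, 1)],
    )
    aln = align_interactions(g, g, PARAMS)
    assert aln.matches == [(0, 0), (1, 1), (2, 2), (3, 3)]
    assert aln.aligned_length == len(g)
    assert aln.matched_pairs == len(g.pair_edges)
    assert aln.matched_stacks == len(g.stack_edges)


def test_single_shared_pair_without_sequence_identity():
    # two 4-nt motifs share exactly one trans Hoogsteen/Sugar pair and have
    # disjoint sequences: the alignment is exactly that pair's two matches
    a = InteractionGraph(list("GGGG"), [0] * 4, [PairEdge(1, 2, "H", "S", "trans")], [])
    b = InteractionGraph(list("UUUU"), [0] * 4, [PairEdge(0, 3, "H", "S", "trans")], [])
    aln = align_interactions(a, b, PARAMS)
    assert aln.matches == [(1, 0), (2, 3)]
    assert aln.score == pytest.approx(PARAMS.pair_full)
    assert aln.matched_pairs == 1
    assert oracle_best_score(a, b) == pytest.approx(aln.score)


def test_score_matches_exhaustive_oracle_on_random_small_graphs():
    rng = np.random.default_rng(42)
    for _ in range(25):
        a, b = random_graph(rng), random_graph(rng)
        aln = align_interactions(a, b, PARAMS)
        assert aln.score == pytest.approx(oracle_best_score(a, b)), (a, b)


def test_alignment_score_is_symmetric():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a, b = random_graph(rng), random_graph(rng)
        sab = align_interactions(a, b, PARAMS).score
        sba = align_interactions(b, a, PARAMS).score
        assert sab == pytest.approx(sba)


def test_adding_a_shared_interaction_never_decreases_score():
    rng = np.random.default_rng(11)
    for _ in range(10):
        a, b = random_graph(rng, n_min=4), random_graph(rng, n_min=4)
        base = align_interactions(a, b, PARAMS).score
        ua, va = sorted(rng.choice(len(a), 2, replace=False).tolist())
        ub, vb = sorted(rng.choice(len(b), 2, replace=False).tolist())
        extra_a = PairEdge(ua, va, "S", "S", "cis")
        extra_b = PairEdge(ub, vb, "S", "S", "cis")
        a2 = InteractionGraph(a.bases, a.seg_of, a.pair_edges + [extra_a], a.stack_edges)
        b2 = InteractionGraph(b.bases, b.seg_of, b.pair_edges + [extra_b], b.stack_edges)
        assert align_interactions(a2, b2, PARAMS).score >= base - 1e-9


def test_self_alignment_dominates_cross_alignments():
    rng = np.random.default_rng(13)
    for _ in range(10):
        a, b = random_graph(rng), random_graph(rng)
        saa = align_interactions(a, a, PARAMS).score
        sab = align_interactions(a, b, PARAMS).score
        assert saa >= sab - 1e-9


def test_aligned_length_bounded_by_smaller_motif():
    rng = np.random.default_rng(17)
    for _ in range(10):
        a, b = random_graph(rng), random_graph(rng)
        aln = align_interactions(a, b, PARAMS)
        assert aln.aligned_length <= min(len(a), len(b))


def test_empty_graph_gives_empty_alignment():
    g = InteractionGraph([], [], [], [])
    aln = align_interactions(g, g, PARAMS)
    assert aln.score == 0.0 and aln.matches == []


def test_alignment_is_deterministic():
    rng = np.random.default_rng(23)
    a, b = random_graph(rng), random_graph(rng)
    results = {tuple(align_interactions(a, b, PARAMS).matches) for _ in range(5)}
    assert len(results) == 1


# ------------------------------------------------- compatibility graph view

def test_compatibility_graph_vertex_count_without_pruning():
    a = InteractionGraph(list("ACG"), [0] * 3, [], [])
    b = InteractionGraph(list("ACGU"), [0] * 4, [], [])
    g = build_compatibility_graph(a, b, PARAMS)
    assert g.number_of_nodes() == len(a) * len(b)


def test_identity_triple_is_mutually_compatible():
    a = InteractionGraph(list("ACG"), [0] * 3, [PairEdge(0, 2, "W", "W", "cis")], [])
    g = build_compatibility_graph(a, a, PARAMS)
    trio = [(0, 0), (1, 1), (2, 2)]
    for x, y in itertools.combinations(trio, 2):
        assert g.has_edge(x, y)
    assert g.edges[(0, 0), (2, 2)]["weight"] == PARAMS.pair_full


def test_crossing_candidates_are_not_connected():
    a = InteractionGraph(list("AC"), [0, 0], [], [])
    g = build_compatibility_graph(a, a, PARAMS)
    assert not g.has_edge((0, 1), (1, 0))
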