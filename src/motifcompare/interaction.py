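"""Local, order-aware alignment of two motifs' base-interaction graphs.

A motif is viewed as an ordered list of nucleotides (concatenated strand
segments) carrying base-pair and stacking edges.  Aligning two motifs means
choosing a one-to-one, within-segment order-preserving correspondence of
nucleotides that maximizes the sum of interaction-match scores plus a small
sequence-identity bonus.  The optimum is a maximum-weight clique on the
match-compatibility graph: vertices are candidate matches ``(u, v)``, edges
connect candidates that can coexist, vertex weights carry the sequence bonus
and edge weights the interaction-match scores.

The search is exact for motif sizes in scope.  It exploits the score
structure: only candidates whose nucleotides both carry interactions can earn
edge weights, so those are enumerated by branch-and-bound, and once they are
all decided the best completion by sequence-bonus-only matches is a
non-crossing maximum-weight matching per segment pair, solved by dynamic
programming.  A greedy fallback (clearly non-exact) exists for very large
inputs.  Among equal-score optima the aligner is parsimonious: matches that
contribute nothing to the score are pruned, so the alignment covers only the
region with interaction or sequence support (self-alignments still cover the
whole motif, every position carrying the identity bonus).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .annotation import AnnotationSet
from .io import MotifInstance

_EPS = 1e-9


@dataclass(frozen=True)
class PairEdge:
    """A base-pair edge between two node indices (u < v in node order)."""

    u: int
    v: int
    edge_u: str
    edge_v: str
    orientation: str

    @property
    def kind(self) -> str:
        return "pair"


@dataclass(frozen=True)
class StackEdge:
    u: int
    v: int
    stack_kind: str = "unspecified"

    @property
    def kind(self) -> str:
        return "stack"


@dataclass
class ScoringParams:
    """Interaction-alignment scoring weights (score units are arbitrary)."""

    pair_full: float = 3.0
    pair_partial: float = 1.0
    stack: float = 0.5
    seq_match: float = 0.3
    seq_mismatch: float = 0.0
    #: switch to a greedy (non-exact) search above this many
    #: interaction-capable candidates
    greedy_above: int = 400
    #: branch-and-bound node budget; when exhausted the best alignment found
    #: so far is returned (never reached at the motif sizes in scope except
    #: for pathological all-against-all partial-match inputs)
    search_budget: int = 200_000


@dataclass
class InteractionGraph:
    """Ordered nucleotides of one motif plus interaction edges on indices."""

    bases: list[str]
    seg_of: list[int]  # segment index of each node
    pair_edges: list[PairEdge]
    stack_edges: list[StackEdge]
    motif_id: str = ""

    def __post_init__(self):
        n = len(self.bases)
        for e in itertools.chain(self.pair_edges, self.stack_edges):
            if not (0 <= e.u < n and 0 <= e.v < n and e.u != e.v):
                raise ValueError(f"edge endpoints out of range: {e}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n_segments(self) -> int:
        return max(self.seg_of) + 1 if self.seg_of else 0


@dataclass
class InteractionAlignment:
    matches: list[tuple[int, int]]
    score: float
    aligned_length: int
    matched_pairs: int
    matched_stacks: int
    segment_mapping: tuple[int, ...] = ()


def build_interaction_graph(motif: MotifInstance, ann: AnnotationSet) -> InteractionGraph:
    """Index a motif's nucleotides and restrict annotations to them."""
    nts = motif.nucleotides
    index = {nt.rid: k for k, nt in enumerate(nts)}
    seg_of = [s for s, seg in enumerate(motif.segments) for _ in seg]
    pairs = [
        PairEdge(*sorted((index[p.i], index[p.j])),
                 p.edge_i if index[p.i] < index[p.j] else p.edge_j,
                 p.edge_j if index[p.i] < index[p.j] else p.edge_i,
                 p.orientation)
        for p in ann.pairs
        if p.i in index and p.j in index
    ]
    stacks = [
        StackEdge(*sorted((index[s.i], index[s.j])), s.kind)
        for s in ann.stacks
        if s.i in index and s.j in index
    ]
    bases = [nt.base if len(nt.base) == 1 else "N" for nt in nts]
    return InteractionGraph(bases, seg_of, sorted(pairs, key=lambda e: (e.u, e.v)),
                            sorted(stacks, key=lambda e: (e.u, e.v)), motif.motif_id)


def interaction_match_score(e_a, e_b, params: ScoringParams) -> float:
    """Score for matching one interaction of A against one of B.

    Full class match (both edges and orientation equal, allowing the symmetric
    endpoint flip) earns ``pair_full``; same orientation with exactly one
    matching edge earns ``pair_partial``; stack-stack earns ``stack``
    regardless of kind; anything else scores 0.
    """
    if e_a.kind != e_b.kind:
        return 0.0
    if e_a.kind == "stack":
        return params.stack
    if e_a.orientation != e_b.orientation:
        return 0.0
    straight = (e_a.edge_u == e_b.edge_u) + (e_a.edge_v == e_b.edge_v)
    flipped = (e_a.edge_u == e_b.edge_v) + (e_a.edge_v == e_b.edge_u)
    hits = max(straight, flipped)
    if hits == 2:
        return params.pair_full
    if hits == 1:
        return params.pair_partial
    return 0.0


def _seq_bonus(base_a: str, base_b: str, params: ScoringParams) -> float:
    return params.seq_match if base_a == base_b else params.seq_mismatch


def build_compatibility_graph(
    A: InteractionGraph,
    B: InteractionGraph,
    params: ScoringParams | None = None,
    segment_mapping: tuple[int, ...] | None = None,
    prune: bool = False,
) -> nx.Graph:
    """Explicit match-compatibility graph for one segment-to-segment mapping.

    Vertices are all candidate matches ``(u, v)`` (``|A| x |B|`` of them when
    pruning is off); an edge joins two candidates iff they can coexist:
    distinct rows and columns, and order preserved within corresponding
    segments.  Vertex attribute ``seq_bonus`` and edge attribute ``weight``
    (interaction-match score, 0 when no compatible interactions) carry the
    scoring information.
    """
    params = params or ScoringParams()
    if segment_mapping is None:
        k = min(A.n_segments, B.n_segments)
        segment_mapping = tuple(range(k))
    pairA = {(e.u, e.v): e for e in A.pair_edges}
    pairB = {(e.u, e.v): e for e in B.pair_edges}
    stackA = {(e.u, e.v): e for e in A.stack_edges}
    stackB = {(e.u, e.v): e for e in B.stack_edges}
    interacting_a = {x for e in A.pair_edges + A.stack_edges for x in (e.u, e.v)}
    interacting_b = {x for e in B.pair_edges + B.stack_edges for x in (e.u, e.v)}

    g = nx.Graph()
    seg_map = dict(enumerate(segment_mapping))
    cands = []
    for u in range(len(A)):
        sa = A.seg_of[u]
        if sa not in seg_map:
            continue
        for v in range(len(B)):
            if B.seg_of[v] != seg_map[sa]:
                continue
            bonus = _seq_bonus(A.bases[u], B.bases[v], params)
            if prune and bonus <= 0 and not (u in interacting_a and v in interacting_b):
                continue
            cands.append((u, v))
            g.add_node((u, v), seq_bonus=bonus)
    for (u1, v1), (u2, v2) in itertools.combinations(cands, 2):
        if u1 == u2 or v1 == v2:
            continue
        if A.seg_of[u1] == A.seg_of[u2] and (u1 - u2) * (v1 - v2) < 0:
            continue  # crossing within a segment pair
        w = 0.0
        ka, kb = tuple(sorted((u1, u2))), tuple(sorted((v1, v2)))
        if ka in pairA and kb in pairB:
            w += interaction_match_score(pairA[ka], pairB[kb], params)
        if ka in stackA and kb in stackB:
            w += interaction_match_score(stackA[ka], stackB[kb], params)
        g.add_edge((u1, v1), (u2, v2), weight=w)
    return g


def _segment_mappings(ka: int, kb: int):
    """All injective assignments between segment index sets (smaller into larger)."""
    if ka <= kb:
        for perm in itertools.permutations(range(kb), ka):
            yield tuple(perm)
    else:
        # map a subset of A's segments onto all of B's
        for sel in itertools.permutations(range(ka), kb):
            mapping = {a: b for b, a in enumerate(sel)}
            yield tuple(mapping.get(a, -1) for a in range(ka))


class _SegGrid:
    """One segment pair's candidate grid for the sequence-completion DP."""

    def __init__(self, rows: list[int], cols: list[int]):
        self.rows = rows  # A node indices, ascending
        self.cols = cols  # B node indices, ascending
        self.row_pos = {u: i for i, u in enumerate(rows)}
        self.col_pos = {v: j for j, v in enumerate(cols)}


class _MatchSearch:
    """Exact maximum-weight search over candidate matches (see module docs)."""

    def __init__(self, cands, vertex_w, edge_w, compat_mask, pot, is_inter, grids,
                 grid_cell, budget=200_000):
        self.cands = cands
        self.vertex_w = vertex_w
        self.edge_w = edge_w
        self.compat_mask = compat_mask
        self.pot = pot
        self.grids = grids
        self.grid_cell = grid_cell  # cand index -> (grid_id, row, col) or None
        self.budget = budget
        self.nodes = 0
        self.i_order = sorted(
            (i for i in range(len(cands)) if is_inter[i]),
            key=lambda i: (-pot[i], cands[i]),
        )
        self.I_mask = 0
        for i in self.i_order:
            self.I_mask |= 1 << i
        self.S_mask = ((1 << len(cands)) - 1) & ~self.I_mask
        self.best_score = -1.0
        self.best_set: list[int] = []
        self.seq_upper, _ = self._completion(self.S_mask)

    def _completion(self, s_mask: int) -> tuple[float, list[int]]:
        """Best non-crossing set of sequence-only matches from ``s_mask``."""
        total = 0.0
        chosen: list[int] = []
        cells: list[list[list[tuple[float, int]]]] = [
            [[None] * len(g.cols) for _ in g.rows] for g in self.grids
        ]
        m = s_mask
        while m:
            low = m & -m
            i = low.bit_length() - 1
            m ^= low
            gid, r, c = self.grid_cell[i]
            cells[gid][r][c] = (self.vertex_w[i], i)
        for gid, g in enumerate(self.grids):
            n, mm = len(g.rows), len(g.cols)
            if n == 0 or mm == 0:
                continue
            dp = [[0.0] * (mm + 1) for _ in range(n + 1)]
            for r in range(1, n + 1):
                dr, dr1 = dp[r], dp[r - 1]
                cr = cells[gid][r - 1]
                for c in range(1, mm + 1):
                    best = dr1[c] if dr1[c] >= dr[c - 1] else dr[c - 1]
                    cell = cr[c - 1]
                    if cell is not None:
                        cand = dr1[c - 1] + cell[0]
                        if cand > best:
                            best = cand
                    dr[c] = best
            total += dp[n][mm]
            r, c = n, mm
            while r > 0 and c > 0:
                if dp[r][c] == dp[r - 1][c]:
                    r -= 1
                elif dp[r][c] == dp[r][c - 1]:
                    c -= 1
                else:
                    chosen.append(cells[gid][r - 1][c - 1][1])
                    r -= 1
                    c -= 1
        return total, chosen

    def run(self) -> tuple[list[int], float]:
        full = (1 << len(self.cands)) - 1
        self._expand([], 0.0, full)
        return self.best_set, self.best_score

    def _expand(self, chosen: list[int], score: float, avail: int) -> None:
        while True:
            self.nodes += 1
            if self.nodes > self.budget:
                return
            i_avail = avail & self.I_mask
            if not i_avail:
                comp_score, comp_cells = self._completion(avail & self.S_mask)
                total = score + comp_score
                if total > self.best_score + _EPS:
                    self.best_score = total
                    self.best_set = chosen + comp_cells
                return
            # bound: at most one candidate per A-node and per B-node can be
            # chosen, so aggregate remaining potential row- and column-wise
            row_best: dict[int, float] = {}
            col_best: dict[int, float] = {}
            c = -1
            for i in self.i_order:
                if i_avail >> i & 1:
                    if c < 0:
                        c = i
                    u, v = self.cands[i]
                    p = self.pot[i]
                    if p > row_best.get(u, 0.0):
                        row_best[u] = p
                    if p > col_best.get(v, 0.0):
                        col_best[v] = p
            pot_left = min(sum(row_best.values()), sum(col_best.values()))
            if score + pot_left + self.seq_upper <= self.best_score + _EPS:
                return
            gain = self.vertex_w[c] + sum(
                self.edge_w.get((c, x) if c < x else (x, c), 0.0) for x in chosen
            )
            self._expand(chosen + [c], score + gain, avail & self.compat_mask[c])
            avail &= ~(1 << c)


def _greedy_search(cands, vertex_w, edge_w, compat_mask, pot):
    """Heuristic fallback for very large candidate sets (non-exact)."""
    order = sorted(range(len(cands)), key=lambda i: (-pot[i], cands[i]))
    chosen: list[int] = []
    score = 0.0
    avail = (1 << len(cands)) - 1
    for c in order:
        if not (avail >> c & 1):
            continue
        gain = vertex_w[c] + sum(
            edge_w.get((c, x) if c < x else (x, c), 0.0) for x in chosen
        )
        if gain > 0:
            chosen.append(c)
            score += gain
            avail &= compat_mask[c]
    return chosen, score


def _align_for_mapping(A, B, params, segment_mapping):
    pairA = {(e.u, e.v): e for e in A.pair_edges}
    pairB = {(e.u, e.v): e for e in B.pair_edges}
    stackA = {(e.u, e.v): e for e in A.stack_edges}
    stackB = {(e.u, e.v): e for e in B.stack_edges}
    interacting_a = {x for e in A.pair_edges + A.stack_edges for x in (e.u, e.v)}
    interacting_b = {x for e in B.pair_edges + B.stack_edges for x in (e.u, e.v)}
    seg_map = dict(enumerate(segment_mapping))

    # best realizable match score of each interaction against the other graph
    edges_a = A.pair_edges + A.stack_edges
    edges_b = B.pair_edges + B.stack_edges
    best_vs_b = {
        e: max((interaction_match_score(e, f, params) for f in edges_b), default=0.0)
        for e in edges_a
    }
    best_vs_a = {
        f: max((interaction_match_score(e, f, params) for e in edges_a), default=0.0)
        for f in edges_b
    }
    cap_a = {u: sum(best_vs_b[e] for e in edges_a if u in (e.u, e.v))
             for u in range(len(A))}
    cap_b = {v: sum(best_vs_a[f] for f in edges_b if v in (f.u, f.v))
             for v in range(len(B))}

    # candidate pruning: a match can only ever contribute if it carries a
    # positive sequence bonus or can realize an interaction match
    cands: list[tuple[int, int]] = []
    is_inter: list[bool] = []
    for u in range(len(A)):
        sa = A.seg_of[u]
        if seg_map.get(sa, -1) < 0:
            continue
        for v in range(len(B)):
            if B.seg_of[v] != seg_map[sa]:
                continue
            inter = (
                u in interacting_a and v in interacting_b
                and min(cap_a[u], cap_b[v]) > 0
            )
            if inter or _seq_bonus(A.bases[u], B.bases[v], params) > 0:
                cands.append((u, v))
                is_inter.append(inter)

    vertex_w = [_seq_bonus(A.bases[u], B.bases[v], params) for u, v in cands]

    # admissible potential: each realized interaction match is charged half to
    # each of its two endpoint candidates, capped by what either side's
    # interactions can actually score against the other graph
    pot = [
        vertex_w[i] + (0.5 * min(cap_a[u], cap_b[v]) if is_inter[i] else 0.0)
        for i, (u, v) in enumerate(cands)
    ]

    nc = len(cands)
    compat_mask = [0] * nc
    edge_w: dict[tuple[int, int], float] = {}
    for i in range(nc):
        u1, v1 = cands[i]
        for j in range(i + 1, nc):
            u2, v2 = cands[j]
            if u1 == u2 or v1 == v2:
                continue
            if A.seg_of[u1] == A.seg_of[u2] and (u1 - u2) * (v1 - v2) < 0:
                continue
            compat_mask[i] |= 1 << j
            compat_mask[j] |= 1 << i
            if is_inter[i] and is_inter[j]:
                w = 0.0
                ka, kb = tuple(sorted((u1, u2))), tuple(sorted((v1, v2)))
                if ka in pairA and kb in pairB:
                    w += interaction_match_score(pairA[ka], pairB[kb], params)
                if ka in stackA and kb in stackB:
                    w += interaction_match_score(stackA[ka], stackB[kb], params)
                if w > 0:
                    edge_w[(i, j)] = w

    # per-segment-pair grids for the sequence-completion DP
    grids: list[_SegGrid] = []
    grid_of_seg: dict[int, int] = {}
    for sa in sorted(seg_map):
        if seg_map[sa] < 0:
            continue
        rows = [u for u in range(len(A)) if A.seg_of[u] == sa]
        cols = [v for v in range(len(B)) if B.seg_of[v] == seg_map[sa]]
        grid_of_seg[sa] = len(grids)
        grids.append(_SegGrid(rows, cols))
    grid_cell = []
    for i, (u, v) in enumerate(cands):
        g = grids[grid_of_seg[A.seg_of[u]]]
        grid_cell.append((grid_of_seg[A.seg_of[u]], g.row_pos[u], g.col_pos[v]))

    n_inter = sum(is_inter)
    if n_inter > params.greedy_above:
        chosen, score = _greedy_search(cands, vertex_w, edge_w, compat_mask, pot)
    else:
        chosen, score = _MatchSearch(
            cands, vertex_w, edge_w, compat_mask, pot, is_inter, grids, grid_cell,
            params.search_budget,
        ).run()

    # parsimony: drop matches contributing nothing to the score
    chosen_set = set(chosen)
    kept = []
    for c in sorted(chosen_set):
        contrib = vertex_w[c] + sum(
            edge_w.get((c, x) if c < x else (x, c), 0.0) for x in chosen_set if x != c
        )
        if contrib > _EPS:
            kept.append(c)

    matches = sorted(cands[c] for c in kept)
    kept_list = sorted(kept)
    matched_pairs = matched_stacks = 0
    for a_idx in range(len(kept_list)):
        i = kept_list[a_idx]
        u1, v1 = cands[i]
        for j in kept_list[a_idx + 1:]:
            u2, v2 = cands[j]
            ka, kb = tuple(sorted((u1, u2))), tuple(sorted((v1, v2)))
            if ka in pairA and kb in pairB and \
                    interaction_match_score(pairA[ka], pairB[kb], params) > 0:
                matched_pairs += 1
            if ka in stackA and kb in stackB:
                matched_stacks += 1
    return InteractionAlignment(
        matches, max(score, 0.0), len(matches), matched_pairs, matched_stacks,
        segment_mapping,
    )


def align_interactions(
    A: InteractionGraph, B: InteractionGraph, params: ScoringParams | None = None
) -> InteractionAlignment:
    """Optimal local alignment of two interaction graphs.

    The segment-to-segment correspondence is chosen to maximize the score over
    all injective assignments (internal loops have two, hairpins one,
    multiloops a few).  Deterministic: fixed enumeration and search order.
    """
    params = params or ScoringParams()
    if len(A) == 0 or len(B) == 0:
        return InteractionAlignment([], 0.0, 0, 0, 0)
    best: InteractionAlignment | None = None
    for mapping in _segment_mappings(A.n_segments, B.n_segments):
        aln = _align_for_mapping(A, B, params, mapping)
        if best is None or aln.score > best.score + _EPS:
            best = aln
    return best
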