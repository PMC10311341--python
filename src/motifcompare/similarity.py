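"""Family-level similarity statistics and the motif-family similarity graph.

Pipeline core: every motif pair (intra- and inter-family) is aligned in one of
two modes (``interaction`` or ``coordinate``) and reduced to a
:class:`PairRecord` carrying the aligned length and the RMSD over per-
nucleotide centroids of backbone+ribose heavy atoms.  Per family, instances
that align poorly with the rest of their own family are filtered by z-score;
the mean intra-family aligned length becomes the family's alignment-length
threshold.  An inter-family pair qualifies ("best-aligned") when its aligned
length meets both families' thresholds and its RMSD is at or below the mode's
cutoff (1.0 Å interaction, 1.5 Å coordinate by default).  Family pairs whose
participating-instance percentage reaches the participation threshold (20% by
default, taking the minimum over the two families) are connected by a solid
edge in the similarity graph; pairs with some but fewer participants get a
dotted edge.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import networkx as nx

from .coordinate import superposed_rmsd
from .errors import ContractError, UndefinedRMSDError
from .io import MotifInstance
from .version import __version__

#: heavy atoms of the backbone and the sugar ribose (RMSD atom scope)
BACKBONE_RIBOSE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"
)

DEFAULT_RMSD_CUTOFFS = {"interaction": 1.0, "coordinate": 1.5}
DEFAULT_PCT_THRESHOLD = 20.0
DEFAULT_ZSCORE_CUTOFF = -2.0


@dataclass
class PairRecord:
    """One aligned motif pair; the unit of the family-level statistics."""

    motif_a: str
    motif_b: str
    family_a: str
    family_b: str
    mode: str
    aligned_length: float
    rmsd: float
    score_or_tm: float

    def __post_init__(self):
        if self.aligned_length < 0:
            raise ContractError("aligned_length must be >= 0")
        if self.aligned_length >= 1 and self.rmsd < 0:
            raise ContractError("rmsd must be >= 0")

    @property
    def family_key(self) -> tuple[str, str]:
        return tuple(sorted((self.family_a, self.family_b)))

    def is_intra(self) -> bool:
        return self.family_a == self.family_b


@dataclass
class FamilyThresholds:
    """Average intra-family aligned length; undefined for singleton families."""

    family: str
    length_threshold: float | None
    n_instances: int = 0


@dataclass
class OutlierReport:
    motif_id: str
    zscore: float
    removed: bool


@dataclass
class SimilarityEdge:
    family_a: str
    family_b: str
    avg_rmsd: float
    avg_length: float
    pct_a: float
    pct_b: float
    label_pct: float
    status: str  # solid | dotted
    n_pairs: int = 0


@dataclass
class SimilarityGraph:
    """Families as nodes, labeled similarity edges between them."""

    nodes: dict[str, int]  # family -> instance count (post filter)
    edges: list[SimilarityEdge]
    mode: str
    parameters: dict = field(default_factory=dict)

    def solid_edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((e.family_a, e.family_b)))
                for e in self.edges if e.status == "solid"}

    def edge(self, fam_a: str, fam_b: str) -> SimilarityEdge | None:
        key = tuple(sorted((fam_a, fam_b)))
        for e in self.edges:
            if tuple(sorted((e.family_a, e.family_b))) == key:
                return e
        return None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(mode=self.mode, **{k: str(v) for k, v in self.parameters.items()})
        for family in sorted(self.nodes):
            g.add_node(family, count=self.nodes[family])
        for e in sorted(self.edges, key=lambda e: (e.family_a, e.family_b)):
            g.add_edge(
                e.family_a, e.family_b,
                avg_rmsd=round(e.avg_rmsd, 4), avg_length=round(e.avg_length, 4),
                pct_a=round(e.pct_a, 4), pct_b=round(e.pct_b, 4),
                label_pct=round(e.label_pct, 4), status=e.status, n_pairs=e.n_pairs,
            )
        return g


def nucleotide_centroid(nt, atom_scope=BACKBONE_RIBOSE_ATOMS) -> np.ndarray | None:
    coords = [nt.atoms[a] for a in atom_scope if a in nt.atoms]
    if not coords:
        return None
    return np.mean(coords, axis=0)


def aligned_rmsd(
    matches: list[tuple[int, int]],
    motifA: MotifInstance,
    motifB: MotifInstance,
    atom_scope=BACKBONE_RIBOSE_ATOMS,
) -> float:
    """RMSD over per-nucleotide heavy-atom centroids of the matched pairs.

    For each matched nucleotide pair the centroid of its backbone+ribose heavy
    atoms is taken; the two centroid sets are optimally superposed and
    RMSD = sqrt((1/N) sum d_i^2) is returned over the N matched centroids.
    Matched pairs in which either side has no scope atoms are skipped with a
    warning.
    """
    if not matches:
        raise ContractError("aligned_rmsd requires >= 1 matched nucleotide")
    nts_a = motifA.nucleotides
    nts_b = motifB.nucleotides
    P, Q = [], []
    for u, v in matches:
        ca = nucleotide_centroid(nts_a[u], atom_scope)
        cb = nucleotide_centroid(nts_b[v], atom_scope)
        if ca is None or cb is None:
            warnings.warn(
                f"match ({u},{v}) skipped: no atoms in scope "
                f"({motifA.motif_id} vs {motifB.motif_id})",
                stacklevel=2,
            )
            continue
        P.append(ca)
        Q.append(cb)
    if not P:
        raise UndefinedRMSDError(
            f"no usable atom pairs between {motifA.motif_id} and {motifB.motif_id}"
        )
    return superposed_rmsd(np.array(P), np.array(Q))


def zscore_filter(
    motif_ids: list[str],
    intra_records: list[PairRecord],
    cutoff: float = DEFAULT_ZSCORE_CUTOFF,
) -> list[OutlierReport]:
    """Flag family members that align poorly with the rest of their family.

    Each instance is summarized by its mean alignment score (interaction mode)
    or mean TM-score (coordinate mode) against all same-family partners; the
    family-wide z-score of that summary decides removal (z < cutoff).
    Families with fewer than three instances are not filtered.
    """
    if len(motif_ids) < 3:
        return [OutlierReport(m, 0.0, False) for m in motif_ids]
    sums: dict[str, list[float]] = {m: [] for m in motif_ids}
    for r in intra_records:
        if r.motif_a in sums and r.motif_b in sums:
            sums[r.motif_a].append(r.score_or_tm)
            sums[r.motif_b].append(r.score_or_tm)
    summary = {m: (float(np.mean(v)) if v else 0.0) for m, v in sums.items()}
    values = np.array([summary[m] for m in motif_ids])
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        warnings.warn("zscore_filter: zero variance, no instances removed", stacklevel=2)
        return [OutlierReport(m, 0.0, False) for m in motif_ids]
    mean = float(np.mean(values))
    return [
        OutlierReport(m, z := (summary[m] - mean) / sd, z < cutoff) for m in motif_ids
    ]


def family_length_threshold(
    family: str, intra_records: list[PairRecord], n_instances: int = 0
) -> FamilyThresholds:
    """Mean aligned length over all intra-family pairs (post outlier filter)."""
    lengths = [r.aligned_length for r in intra_records
               if r.is_intra() and r.family_a == family]
    if not lengths:
        return FamilyThresholds(family, None, n_instances)
    return FamilyThresholds(family, float(np.mean(lengths)), n_instances)


def select_best_pairs(
    inter_records: list[PairRecord],
    thr_a: FamilyThresholds,
    thr_b: FamilyThresholds,
    rmsd_cutoff: float,
) -> list[PairRecord]:
    """Best-aligned inter-family pairs: long enough for both families, low RMSD.

    A record qualifies iff aligned_length >= max of the two family thresholds
    (unrounded) and rmsd <= rmsd_cutoff.  Pairs involving a family with an
    undefined (singleton) threshold never qualify.
    """
    keys = {r.family_key for r in inter_records}
    if len(keys) > 1:
        raise ContractError("select_best_pairs: records span multiple family pairs")
    if thr_a.length_threshold is None or thr_b.length_threshold is None:
        return []
    need = max(thr_a.length_threshold, thr_b.length_threshold)
    return [
        r for r in inter_records
        if r.aligned_length >= need and r.rmsd <= rmsd_cutoff
    ]


def participation(
    best_pairs: list[PairRecord],
    family_a: str,
    family_b: str,
    size_a: int,
    size_b: int,
) -> tuple[float, float, float]:
    """Percentage of each family's instances appearing in the selected pairs.

    Returns (pct_a, pct_b, label_pct) with label_pct = min of the two; sizes
    are the post-filter family sizes.
    """
    if size_a < 1 or size_b < 1:
        raise ContractError("participation: family sizes must be >= 1")
    in_a = {r.motif_a if r.family_a == family_a else r.motif_b for r in best_pairs
            if family_a in (r.family_a, r.family_b)}
    in_b = {r.motif_a if r.family_a == family_b else r.motif_b for r in best_pairs
            if family_b in (r.family_a, r.family_b)}
    pct_a = 100.0 * len(in_a) / size_a
    pct_b = 100.0 * len(in_b) / size_b
    return pct_a, pct_b, min(pct_a, pct_b)


def build_similarity_graph(
    records: list[PairRecord],
    family_sizes: dict[str, int],
    mode: str,
    rmsd_cutoff: float | None = None,
    pct_threshold: float = DEFAULT_PCT_THRESHOLD,
    thresholds: dict[str, FamilyThresholds] | None = None,
) -> SimilarityGraph:
    """Assemble the similarity graph from pair records of one mode.

    ``records`` holds both intra-family records (used for the length
    thresholds unless precomputed ``thresholds`` are given) and inter-family
    records.  For every unordered family pair the best-aligned pairs are
    selected and the participation percentages computed; edges become solid at
    ``label_pct >= pct_threshold``, dotted below (absent when no pair
    qualifies).  Invariant to family input order.
    """
    if len(family_sizes) < 2:
        raise ContractError("similarity graph needs >= 2 families")
    if rmsd_cutoff is None:
        rmsd_cutoff = DEFAULT_RMSD_CUTOFFS.get(mode, 1.0)
    records = [r for r in records if r.mode == mode]
    if thresholds is None:
        thresholds = {
            fam: family_length_threshold(
                fam, [r for r in records if r.is_intra() and r.family_a == fam],
                family_sizes[fam],
            )
            for fam in family_sizes
        }
    inter: dict[tuple[str, str], list[PairRecord]] = {}
    for r in records:
        if not r.is_intra():
            inter.setdefault(r.family_key, []).append(r)

    edges = []
    for (fa, fb), recs in sorted(inter.items()):
        best = select_best_pairs(recs, thresholds[fa], thresholds[fb], rmsd_cutoff)
        if not best:
            continue
        pct_a, pct_b, label = participation(best, fa, fb, family_sizes[fa], family_sizes[fb])
        if label <= 0:
            continue
        edges.append(
            SimilarityEdge(
                fa, fb,
                avg_rmsd=float(np.mean([r.rmsd for r in best])),
                avg_length=float(np.mean([r.aligned_length for r in best])),
                pct_a=pct_a, pct_b=pct_b, label_pct=label,
                status="solid" if label >= pct_threshold else "dotted",
                n_pairs=len(best),
            )
        )
    return SimilarityGraph(
        dict(sorted(family_sizes.items())), edges, mode,
        {"rmsd_cutoff": rmsd_cutoff, "pct_threshold": pct_threshold},
    )


def _dot_lines(g: SimilarityGraph) -> list[str]:
    lines = [f'graph motif_similarity {{  // mode={g.mode} v{__version__}']
    for fam in sorted(g.nodes):
        lines.append(f'  "{fam}" [label="{fam}\\n({g.nodes[fam]})"];')
    for e in sorted(g.edges, key=lambda e: (e.family_a, e.family_b)):
        style = "solid" if e.status == "solid" else "dashed"
        label = f"{e.avg_rmsd:.2f} Å / {e.avg_length:.1f} nt / {e.label_pct:.1f}%"
        lines.append(
            f'  "{e.family_a}" -- "{e.family_b}" [style={style}, label="{label}"];'
        )
    lines.append("}")
    return lines


def export_graph(g: SimilarityGraph, path: str | Path, format: str = "DOT") -> None:
    """Serialize the graph deterministically as DOT, GraphML, or JSON."""
    path = Path(path)
    fmt = format.upper()
    if fmt == "DOT":
        path.write_text("\n".join(_dot_lines(g)) + "\n")
    elif fmt == "GRAPHML":
        nx.write_graphml(g.to_networkx(), str(path))
    elif fmt == "JSON":
        payload = {
            "mode": g.mode,
            "parameters": g.parameters,
            "nodes": [{"family": f, "count": c} for f, c in sorted(g.nodes.items())],
            "edges": [asdict(e) for e in sorted(g.edges, key=lambda e: (e.family_a, e.family_b))],
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ContractError(f"unknown export format {format!r} (DOT|GraphML|JSON)")


def load_graph_json(path: str | Path) -> SimilarityGraph:
    """Inverse of :func:`export_graph` for the JSON format."""
    payload = json.loads(Path(path).read_text())
    return SimilarityGraph(
        {n["family"]: n["count"] for n in payload["nodes"]},
        [SimilarityEdge(**e) for e in payload["edges"]],
        payload["mode"],
        payload["parameters"],
    )
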