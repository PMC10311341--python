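"""RMSD over aligned nucleotides, outlier filtering, thresholds and the graph."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motifcompare import (
    FamilyThresholds,
    PairRecord,
    aligned_rmsd,
    build_similarity_graph,
    export_graph,
    family_length_threshold,
    load_graph_json,
    participation,
    select_best_pairs,
    zscore_filter,
)
from motifcompare.errors import ContractError

from conftest import make_motif_full_atoms


def rec(a, b, fa, fb, length, rmsd, score=1.0, mode="interaction"):
    return PairRecord(a, b, fa, fb, mode, length, rmsd, score)


# ------------------------------------------------------------------- RMSD

def test_self_alignment_rmsd_is_zero():
    m = make_motif_full_atoms(np.random.default_rng(0).normal(size=(6, 3)) * 7)
    matches = [(i, i) for i in range(6)]
    assert aligned_rmsd(matches, m, m) == pytest.approx(0.0, abs=1e-12)


def test_rmsd_invariant_under_rigid_motion():
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(7, 3)) * 6
    a = make_motif_full_atoms(coords)
    R = Rotation.from_euler("zyx", [40, -20, 75], degrees=True).as_matrix()
    b = make_motif_full_atoms(coords @ R.T + np.array([3.0, -8.0, 1.0]), motif_id="m2")
    matches = [(i, i) for i in range(7)]
    assert aligned_rmsd(matches, a, b) == pytest.approx(0.0, abs=1e-9)


def test_radial_expansion_fixture_gives_unit_rmsd():
    # equilateral triangle expanded radially by exactly 1 Å per vertex:
    # the optimal superposition is the identity, every centroid moves 1 Å,
    # so RMSD = sqrt(mean(1^2)) = 1
    angles = np.deg2rad([0, 120, 240])
    r = 6.0
    P = np.stack([r * np.cos(angles), r * np.sin(angles), np.zeros(3)], axis=1)
    Q = P * (r + 1.0) / r
    a = make_motif_full_atoms(P)
    b = make_motif_full_atoms(Q, motif_id="m2")
    matches = [(i, i) for i in range(3)]
    assert aligned_rmsd(matches, a, b) == pytest.approx(1.0, abs=1e-9)


def test_rmsd_requires_at_least_one_match():
    m = make_motif_full_atoms(np.eye(3) * 4)
    with pytest.raises(ContractError):
        aligned_rmsd([], m, m)


# ---------------------------------------------------------- outlier filter

def intra_records(summaries, family="F"):
    """Clone family records where each instance's pair scores average to
    the requested per-instance summary (star construction)."""
    ids = sorted(summaries)
    records = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            score = (summaries[a] + summaries[b]) / 2
            records.append(rec(a, b, family, family, 10, 0.1, score))
    return records


def test_identical_instances_have_zero_z_and_no_removals():
    ids = [f"m{i}" for i in range(5)]
    recs = [rec(a, b, "F", "F", 10, 0.0, 5.0)
            for i, a in enumerate(ids) for b in ids[i + 1:]]
    with pytest.warns(UserWarning, match="zero variance"):
        reports = zscore_filter(ids, recs)
    assert all(r.zscore == 0.0 and not r.removed for r in reports)


def test_planted_low_scoring_instance_is_the_unique_removal():
    summaries = {f"m{i}": 0.95 for i in range(9)}
    summaries["out"] = 0.2
    reports = zscore_filter(sorted(summaries), intra_records(summaries), cutoff=-2.0)
    removed = [r.motif_id for r in reports if r.removed]
    assert removed == ["out"]


def test_families_of_two_are_not_filtered():
    reports = zscore_filter(["a", "b"], [rec("a", "b", "F", "F", 5, 0.1, 1.0)])
    assert all(not r.removed for r in reports)


# ---------------------------------------------------- thresholds, selection

def test_length_threshold_is_mean_of_intra_pairs():
    recs = [rec("a", "b", "F", "F", 8, 0.1), rec("a", "c", "F", "F", 10, 0.1),
            rec("b", "c", "F", "F", 12, 0.1)]
    assert family_length_threshold("F", recs).length_threshold == pytest.approx(10.0)
    single = [rec("a", "b", "F", "F", 7, 0.1)]
    assert family_length_threshold("F", single).length_threshold == pytest.approx(7.0)


def test_singleton_family_threshold_undefined_blocks_selection():
    thr = family_length_threshold("F", [])
    assert thr.length_threshold is None
    out = select_best_pairs([rec("a", "x", "F", "G", 12, 0.5)],
                            thr, FamilyThresholds("G", 10.0), 1.0)
    assert out == []


@pytest.mark.parametrize(
    "length,rmsd,kept",
    [
        (12, 0.8, True),    # passes both thresholds and the cutoff
        (12, 1.2, False),   # RMSD beyond cutoff
        (10.5, 0.8, False),  # fails the larger of the two thresholds
    ],
)
def test_best_pair_selection_rules(length, rmsd, kept):
    records = [rec("a", "x", "F", "G", length, rmsd)]
    out = select_best_pairs(
        records, FamilyThresholds("F", 10.0), FamilyThresholds("G", 11.0), 1.0
    )
    assert (out == records) is kept


def test_participation_counts_distinct_instances():
    pairs = [rec(f"a{i}", "x0", "F", "G", 12, 0.5) for i in range(3)]
    pairs += [rec("a0", "x1", "F", "G", 12, 0.5)]
    pct_a, pct_b, label = participation(pairs, "F", "G", 10, 4)
    assert pct_a == pytest.approx(30.0)
    assert pct_b == pytest.approx(50.0)
    assert label == pytest.approx(30.0)


def test_participation_of_empty_selection_is_zero():
    assert participation([], "F", "G", 5, 5) == (0.0, 0.0, 0.0)


# ------------------------------------------------------------------- graph

def clone_world():
    """Two families of mutual clones + an unrelated third family."""
    records = []
    fams = {"F1": [f"f{i}" for i in range(5)], "F2": [f"g{i}" for i in range(5)],
            "F3": [f"h{i}" for i in range(5)]}
    for fam, ids in fams.items():
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                records.append(rec(a, b, fam, fam, 10, 0.05, 5.0))
    for a in fams["F1"]:
        for b in fams["F2"]:
            records.append(rec(a, b, "F1", "F2", 10, 0.1, 4.0))
    for a in fams["F1"]:
        for b in fams["F3"]:
            records.append(rec(a, b, "F1", "F3", 3, 2.5, 0.5))
    for a in fams["F2"]:
        for b in fams["F3"]:
            records.append(rec(a, b, "F2", "F3", 3, 2.8, 0.5))
    sizes = {f: len(ids) for f, ids in fams.items()}
    return records, sizes


def test_clone_families_get_one_solid_edge_at_full_participation():
    records, sizes = clone_world()
    g = build_similarity_graph(records, sizes, "interaction", 1.0, 20.0)
    assert g.solid_edges() == {("F1", "F2")}
    edge = g.edge("F1", "F2")
    assert edge.label_pct == pytest.approx(100.0)
    assert edge.avg_rmsd == pytest.approx(0.1)


def test_unreachable_pct_threshold_leaves_no_solid_edges():
    records, sizes = clone_world()
    g = build_similarity_graph(records, sizes, "interaction", 1.0, pct_threshold=101)
    assert g.solid_edges() == set()
    assert {e.status for e in g.edges} <= {"dotted"}


def test_graph_invariant_to_family_input_order():
    records, sizes = clone_world()
    g1 = build_similarity_graph(records, sizes, "interaction", 1.0)
    g2 = build_similarity_graph(
        list(reversed(records)), dict(reversed(list(sizes.items()))),
        "interaction", 1.0,
    )
    assert g1.solid_edges() == g2.solid_edges()
    assert g1.nodes == g2.nodes


def test_threshold_monotonicity_on_random_records():
    rng = np.random.default_rng(3)
    fams = {f"F{k}": [f"F{k}_m{i}" for i in range(4)] for k in range(3)}
    records = []
    for fam, ids in fams.items():
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                records.append(rec(a, b, fam, fam, rng.uniform(5, 9), rng.uniform(0, 1)))
    fam_names = sorted(fams)
    for x in range(len(fam_names)):
        for y in range(x + 1, len(fam_names)):
            for a in fams[fam_names[x]]:
                for b in fams[fam_names[y]]:
                    records.append(rec(a, b, fam_names[x], fam_names[y],
                                       rng.uniform(4, 12), rng.uniform(0, 2.5)))
    sizes = {f: 4 for f in fams}
    solid_sets = [
        build_similarity_graph(records, sizes, "interaction", cutoff, 20.0).solid_edges()
        for cutoff in (0.5, 1.0, 1.5, 2.0)
    ]
    for lo, hi in zip(solid_sets, solid_sets[1:]):
        assert lo <= hi  # raising the RMSD cutoff never shrinks the solid set
    pct_sets = [
        build_similarity_graph(records, sizes, "interaction", 1.5, pct).solid_edges()
        for pct in (10, 20, 50, 90)
    ]
    for hi, lo in zip(pct_sets, pct_sets[1:]):
        assert lo <= hi  # raising the participation threshold never grows it


# ------------------------------------------------------------------ export

def test_dot_export_styles_and_determinism(tmp_path):
    records, sizes = clone_world()
    g = build_similarity_graph(records, sizes, "interaction", 1.0)
    p1, p2 = tmp_path / "a.dot", tmp_path / "b.dot"
    export_graph(g, p1, "DOT")
    export_graph(g, p2, "DOT")
    assert p1.read_bytes() == p2.read_bytes()
    text = p1.read_text()
    assert 'style=solid' in text and '"F1" -- "F2"' in text


def test_json_round_trip_preserves_graph(tmp_path):
    records, sizes = clone_world()
    g = build_similarity_graph(records, sizes, "interaction", 1.0)
    path = tmp_path / "g.json"
    export_graph(g, path, "JSON")
    back = load_graph_json(path)
    assert back.nodes == g.nodes
    assert back.mode == g.mode
    assert [e.__dict__ for e in back.edges] == [e.__dict__ for e in g.edges]


def test_graphml_export_is_parseable(tmp_path):
    import networkx as nx

    records, sizes = clone_world()
    g = build_similarity_graph(records, sizes, "interaction", 1.0)
    path = tmp_path / "g.graphml"
    export_graph(g, path, "GraphML")
    back = nx.read_graphml(path)
    assert set(back.nodes) == set(g.nodes)


def test_unknown_export_format_rejected(tmp_path):
    records, sizes = clone_world()
    g = build_similarity_graph(records, sizes, "interaction", 1.0)
    with pytest.raises(ContractError):
        export_graph(g, tmp_path / "g.xyz", "XYZ")
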