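"""Kabsch superposition, TM-score and the iterative coordinate aligner."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from motifcompare import (
    AlignParams,
    align_coordinates,
    default_d0,
    kabsch,
    superposed_rmsd,
    tm_score,
)
from motifcompare.coordinate import Superposition, _dp_align
from motifcompare.errors import ContractError, DegenerateGeometryError, TooShortError
from motifcompare.synthetic import template_coords

from conftest import make_motif


def numeric_min_rmsd(P, Q):
    """Independent oracle: direct numerical minimization over rigid motions."""

    def objective(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        d = P @ R.T + x[3:] - Q
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best = np.inf
    for trial in range(4):
        x0 = np.concatenate([np.random.default_rng(trial).normal(size=3) * 2,
                             Q.mean(axis=0) - P.mean(axis=0)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        best = min(best, res.fun)
    return best


# -------------------------------------------------------------------- kabsch

def test_kabsch_identity():
    P = np.random.default_rng(0).normal(size=(6, 3))
    sup = kabsch(P, P)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(sup.translation, 0, atol=1e-12)


def test_kabsch_recovers_constructed_transform():
    rng = np.random.default_rng(1)
    P = rng.normal(size=(8, 3)) * 5
    R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    t = np.array([1.0, 2.0, 3.0])
    Q = P @ R90.T + t
    sup = kabsch(P, Q)
    np.testing.assert_allclose(sup.rotation, R90, atol=1e-9)
    np.testing.assert_allclose(sup.translation, t, atol=1e-9)
    assert superposed_rmsd(P, Q) < 1e-9


def test_kabsch_matches_numerical_minimizer_on_random_clouds():
    rng = np.random.default_rng(2)
    for _ in range(5):
        P = rng.normal(size=(10, 3)) * 4
        Q = rng.normal(size=(10, 3)) * 4
        ours = superposed_rmsd(P, Q)
        oracle = numeric_min_rmsd(P, Q)
        assert ours <= oracle + 1e-6


def test_kabsch_agrees_with_scipy_align_vectors():
    rng = np.random.default_rng(12)
    for _ in range(10):
        n = int(rng.integers(3, 20))
        P = rng.normal(size=(n, 3)) * 5
        Q = rng.normal(size=(n, 3)) * 5
        _, rssd = Rotation.align_vectors(Q - Q.mean(axis=0), P - P.mean(axis=0))
        assert superposed_rmsd(P, Q) == pytest.approx(rssd / np.sqrt(n), abs=1e-9)


def test_kabsch_enforces_proper_rotation_on_mirrored_input():
    rng = np.random.default_rng(3)
    P = rng.normal(size=(7, 3))
    Q = P.copy()
    Q[:, 0] *= -1  # reflection
    sup = kabsch(P, Q)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)


@pytest.mark.parametrize(
    "P,Q,exc",
    [
        (np.zeros((2, 3)), np.zeros((2, 3)), DegenerateGeometryError),
        (np.outer(np.arange(5.0), [1, 0, 0]), np.outer(np.arange(5.0), [1, 0, 0]),
         DegenerateGeometryError),
        (np.zeros((4, 3)), np.zeros((5, 3)), ContractError),
    ],
)
def test_kabsch_rejects_degenerate_input(P, Q, exc):
    with pytest.raises(exc):
        kabsch(P, Q)


# ------------------------------------------------------------------ tm-score

def test_tm_score_perfect_self_match_is_one():
    coords = np.random.default_rng(4).normal(size=(9, 3)) * 6
    matches = [(i, i) for i in range(9)]
    sup = Superposition(np.eye(3), np.zeros(3))
    assert tm_score(matches, coords, coords, sup, 9, default_d0(9)) == pytest.approx(1.0)


def test_tm_score_single_match_at_d0_is_half():
    d0 = 3.7
    A = np.array([[0.0, 0.0, 0.0]])
    B = np.array([[d0, 0.0, 0.0]])
    sup = Superposition(np.eye(3), np.zeros(3))
    assert tm_score([(0, 0)], A, B, sup, 1, d0) == pytest.approx(0.5)


def test_tm_score_equals_direct_formula_on_random_case():
    rng = np.random.default_rng(5)
    A = rng.normal(size=(7, 3)) * 5
    B = rng.normal(size=(7, 3)) * 5
    matches = [(0, 2), (3, 4), (5, 6)]
    sup = Superposition(Rotation.from_euler("x", 30, degrees=True).as_matrix(),
                        np.array([0.3, -1.0, 2.0]))
    d0 = 3.2
    expected = sum(
        1.0 / (1.0 + np.sum((sup.apply(A[u][None])[0] - B[v]) ** 2) / d0**2)
        for u, v in matches
    ) / 5
    assert tm_score(matches, A, B, sup, 5, d0) == pytest.approx(expected)


def test_d0_formula_and_floor():
    # short motifs sit on the floor; the formula takes over for long ones
    assert default_d0(5) == 3.0
    assert default_d0(100) == pytest.approx(0.6 * np.sqrt(99.5) - 2.5)


# ------------------------------------------------------------- DP optimality

def score_of_path(matches, affinity, gap):
    """End-gap-free score of a monotone match list (for the DP cross-check)."""
    total = 0.0
    prev = None
    for u, v in matches:
        total += affinity[u, v]
        if prev is not None:
            total += gap * (u - prev[0] - 1) + gap * (v - prev[1] - 1)
        prev = (u, v)
    return total


def oracle_best_path(affinity, gap):
    """Exhaustive search over monotone match sets (tiny matrices only)."""
    n, m = affinity.shape
    best = 0.0

    def recurse(i, j, matches):
        nonlocal best
        best = max(best, score_of_path(matches, affinity, gap))
        for u in range(i, n):
            for v in range(j, m):
                recurse(u + 1, v + 1, matches + [(u, v)])

    recurse(0, 0, [])
    return best


def test_dp_step_is_optimal_for_its_affinity_matrix():
    rng = np.random.default_rng(6)
    for _ in range(10):
        aff = rng.uniform(0, 1, size=(5, 4))
        matches = _dp_align(aff, -0.6)
        assert score_of_path(matches, aff, -0.6) == pytest.approx(
            oracle_best_path(aff, -0.6)
        )


# ------------------------------------------------------------ full alignment

def _loop_motif(seed=0, n=12, noise=0.0, **kwargs):
    coords = template_coords(
        {"helix_radius": 8.0, "helix_rise": 2.8, "helix_twist_deg": 40.0}
    )[:n]
    if noise:
        coords = coords + np.random.default_rng(seed).normal(0, noise, coords.shape)
    return make_motif(coords, **kwargs)


def test_self_alignment_has_unit_tm_and_identity_matches():
    m = _loop_motif()
    aln = align_coordinates(m, m)
    assert aln.tm_score == pytest.approx(1.0, abs=1e-9)
    assert aln.matches == [(i, i) for i in range(len(m))]


def test_noisy_self_alignment_recovers_identity():
    a = _loop_motif()
    b = _loop_motif(seed=9, noise=0.1, motif_id="m2")
    aln = align_coordinates(a, b)
    assert aln.matches == [(i, i) for i in range(len(a))]
    assert aln.tm_score > 0.95


def test_unrelated_random_walks_score_below_noisy_self_pairs():
    rng = np.random.default_rng(10)
    walk_scores = []
    for _ in range(3):
        w1 = make_motif(np.cumsum(rng.normal(0, 3, size=(10, 3)), axis=0))
        w2 = make_motif(np.cumsum(rng.normal(0, 3, size=(10, 3)), axis=0))
        walk_scores.append(align_coordinates(w1, w2).tm_score)
    noisy_scores = []
    for s in range(3):
        a = _loop_motif()
        b = _loop_motif(seed=20 + s, noise=0.1, motif_id="m2")
        noisy_scores.append(align_coordinates(a, b).tm_score)
    assert max(walk_scores) < min(noisy_scores)


def test_rigid_motion_invariance():
    a = _loop_motif()
    b = _loop_motif(seed=30, noise=0.15, motif_id="m2")
    ref = align_coordinates(a, b)
    R = Rotation.from_euler("xyz", [31, -57, 112], degrees=True).as_matrix()
    t = np.array([12.0, -4.0, 7.5])
    moved = make_motif(
        np.array([nt.atoms["C3'"] for nt in b.nucleotides]) @ R.T + t, motif_id="m3"
    )
    got = align_coordinates(a, moved)
    assert got.matches == ref.matches
    assert got.tm_score == pytest.approx(ref.tm_score, abs=1e-6)


def test_too_short_motif_rejected():
    m = make_motif(np.random.default_rng(11).normal(size=(2, 3)))
    with pytest.raises(TooShortError):
        align_coordinates(m, m)
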