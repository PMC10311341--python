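"""Global 3D alignment of two motifs by iterative superposition + DP.

The aligner optimizes a TM-score-type objective: a length-normalized sum of
``1/(1+(d_i/d0)^2)`` over matched nucleotides, where distances are measured
between representative backbone atoms (C3' by default, falling back to P and
then C1') after rigid superposition.  Starting from gapless threadings and
short fragment seeds, the algorithm alternates least-squares superposition on
the current match set with a global dynamic-programming pass over the
TM-score affinity matrix until the match set is stable.  The procedure is
deterministic: no randomness, fixed seed and iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateGeometryError, TooShortError
from .io import MotifInstance

REPRESENTATIVE_ATOMS = ("C3'", "P", "C1'")


@dataclass
class Superposition:
    """Rigid transform q ~ R p + t minimizing least-squares deviation."""

    rotation: np.ndarray  # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector, Å

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class AlignParams:
    """Tunables of the coordinate aligner."""

    gap_penalty: float = -0.6
    max_iterations: int = 30
    fragment_length: int = 4
    fragment_stride: int = 2
    d0_floor: float = 3.0
    representative_atoms: tuple = REPRESENTATIVE_ATOMS


@dataclass
class CoordinateAlignment:
    """Result of a coordinate-based alignment."""

    matches: list[tuple[int, int]]
    tm_score: float
    aligned_length: int
    superposition: Superposition
    L_target: int
    d0: float


def _superpose_unchecked(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Least-squares rigid transform (no degeneracy guard; used internally)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return Superposition(R, t)


def kabsch(P: np.ndarray, Q: np.ndarray) -> Superposition:
    """Optimal rigid superposition of point set P onto Q (Kabsch algorithm).

    Minimizes sum ||R p_i + t - q_i||^2 with a proper rotation (reflections
    corrected through the SVD sign trick).  Requires at least three
    non-collinear points in each set.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ContractError("kabsch: P and Q must be equal-shape (N, 3) arrays")
    if len(P) < 3:
        raise DegenerateGeometryError(f"kabsch needs >= 3 points, got {len(P)}")
    for name, X in (("P", P), ("Q", Q)):
        if np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-8) < 2:
            raise DegenerateGeometryError(f"kabsch: point set {name} is collinear")
    return _superpose_unchecked(P, Q)


def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between P and Q after optimal superposition (any N >= 1)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if len(P) == 0:
        raise ContractError("superposed_rmsd: empty point sets")
    sup = _superpose_unchecked(P, Q)
    d = sup.apply(P) - Q
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def default_d0(L_target: int, floor: float = 3.0) -> float:
    """TM-score distance scale as a function of normalization length.

    Follows the RNA variant of the TM-score convention,
    ``d0 = 0.6 sqrt(L - 0.5) - 2.5``, floored so that short motifs (where the
    formula goes non-positive) keep a usable scale.
    """
    if L_target < 1:
        raise ContractError("L_target must be >= 1")
    return max(floor, 0.6 * np.sqrt(max(L_target - 0.5, 0.0)) - 2.5)


def tm_score(
    matches: list[tuple[int, int]],
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    superposition: Superposition,
    L_target: int,
    d0: float,
) -> float:
    """Length-normalized similarity: (1/L_target) sum 1/(1+(d_i/d0)^2)."""
    if d0 <= 0:
        raise ContractError("d0 must be positive")
    if L_target < 1:
        raise ContractError("L_target must be >= 1")
    if not matches:
        return 0.0
    ia = [m[0] for m in matches]
    ib = [m[1] for m in matches]
    moved = superposition.apply(np.asarray(coordsA, dtype=float)[ia])
    d2 = np.sum((moved - np.asarray(coordsB, dtype=float)[ib]) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / d0**2)) / L_target)


def representative_coords(
    motif: MotifInstance, atoms: tuple = REPRESENTATIVE_ATOMS
) -> np.ndarray:
    """One representative backbone coordinate per nucleotide."""
    coords = []
    for nt in motif.nucleotides:
        for name in atoms:
            if name in nt.atoms:
                coords.append(nt.atoms[name])
                break
        else:
            raise ContractError(
                f"nucleotide {nt.rid} of {motif.motif_id} has none of {atoms}"
            )
    return np.array(coords, dtype=float)


def _dp_align(affinity: np.ndarray, gap: float) -> list[tuple[int, int]]:
    """Global alignment over an affinity matrix with free end gaps.

    Interior gaps cost ``gap`` per skipped position; ties prefer the diagonal,
    then advancing in A, for determinism.
    """
    n, m = affinity.shape
    aff = affinity.tolist()
    prev = [0.0] * (m + 1)  # free end gaps: first row/column zero
    ptr_rows = []
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        prow = [0] * (m + 1)  # 1 diag, 2 up, 3 left
        arow = aff[i - 1]
        last_row = i == n
        for j in range(1, m + 1):
            best = prev[j - 1] + arow[j - 1]
            p = 1
            up = prev[j] + (gap if j < m else 0.0)
            if up > best:
                best, p = up, 2
            left = cur[j - 1] + (gap if not last_row else 0.0)
            if left > best:
                best, p = left, 3
            cur[j], prow[j] = best, p
        ptr_rows.append(prow)
        prev = cur
    matches = []
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr_rows[i - 1][j]
        if p == 1:
            matches.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    matches.reverse()
    return matches


def _seed_matchings(n: int, m: int, params: AlignParams) -> list[list[tuple[int, int]]]:
    seeds = []
    # gapless threadings at every offset with >= 3 overlapping positions
    for off in range(-(n - 3), m - 2):
        pairs = [(i, i + off) for i in range(n) if 0 <= i + off < m]
        if len(pairs) >= 3:
            seeds.append(pairs)
    # short fragment seeds
    f = params.fragment_length
    for i in range(0, n - f + 1, params.fragment_stride):
        for j in range(0, m - f + 1, params.fragment_stride):
            seeds.append([(i + k, j + k) for k in range(f)])
    return seeds


def align_coordinates(
    A: MotifInstance, B: MotifInstance, params: AlignParams | None = None
) -> CoordinateAlignment:
    """Sequence-order-preserving global 3D alignment of two motifs.

    Every position is subject to matching; unmatched positions are penalized
    only through the TM-score normalization by ``L_target`` (length of the
    shorter motif, which keeps the score symmetric between the two inputs).
    """
    params = params or AlignParams()
    ca = representative_coords(A, params.representative_atoms)
    cb = representative_coords(B, params.representative_atoms)
    n, m = len(ca), len(cb)
    if n < 3 or m < 3:
        raise TooShortError("coordinate alignment needs motifs of >= 3 nucleotides")
    L_target = min(n, m)
    d0 = default_d0(L_target, params.d0_floor)

    best: CoordinateAlignment | None = None
    seen: set[tuple] = set()  # match sets already iterated (any seed)
    for seed in _seed_matchings(n, m, params):
        matches = seed
        for _ in range(params.max_iterations):
            if len(matches) < 3:
                break
            key = tuple(matches)
            if key in seen:  # deterministic continuation already explored
                break
            seen.add(key)
            ia = [p[0] for p in matches]
            ib = [p[1] for p in matches]
            sup = _superpose_unchecked(ca[ia], cb[ib])
            score = tm_score(matches, ca, cb, sup, L_target, d0)
            if best is None or score > best.tm_score + 1e-12:
                best = CoordinateAlignment(
                    list(matches), score, len(matches), sup, L_target, d0
                )
            moved = sup.apply(ca)
            diff = moved[:, None, :] - cb[None, :, :]
            affinity = 1.0 / (1.0 + np.sum(diff * diff, axis=2) / d0**2)
            matches = _dp_align(affinity, params.gap_penalty)
    if best is None:  # every seed degenerate; cannot happen for n, m >= 3
        raise TooShortError("no usable alignment seed")
    return best
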