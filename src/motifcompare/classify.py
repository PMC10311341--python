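"""Utility analysis: can a simple classifier tell motif families apart?

Structural similarity between families should hurt family prediction.  To
quantify that, each motif is described by alignment-derived features against
one representative motif per family (interaction mode: alignment score,
aligned length, RMSD, matched base pairs, matched stackings; coordinate mode:
aligned length, RMSD, TM-score), and Gaussian naive Bayes classifiers are
evaluated with repeated stratified 3-fold cross-validation — binary
one-family-vs-rest models with random undersampling of the majority class,
plus a multiclass variant without undersampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler

from .annotation import AnnotationSet, motif_interactions
from .coordinate import AlignParams, align_coordinates
from .errors import ContractError
from .interaction import ScoringParams, align_interactions, build_interaction_graph
from .io import MotifInstance
from .similarity import PairRecord, aligned_rmsd

INTERACTION_FEATURES = ("score", "length", "rmsd", "pairs", "stacks")
COORDINATE_FEATURES = ("length", "rmsd", "tm")


@dataclass
class RepresentativeChoice:
    family: str
    motif_id: str
    criterion_score: float


@dataclass
class CVReport:
    """Cross-validation outcome; metrics are percentages over 15 runs."""

    model: str
    runs: list[dict]
    mean_accuracy: float
    mean_sensitivity: float | None = None
    mean_specificity: float | None = None
    #: (|Class 1|, |Class 0|) after undersampling; binary reports only
    class_sizes: tuple[int, int] | None = None


def select_representative(
    family: str, motif_ids: list[str], records: list[PairRecord]
) -> RepresentativeChoice:
    """The instance that best aligns with all other instances of its family.

    Best = highest mean alignment score (or TM-score) against same-family
    partners; ties prefer the lowest mean RMSD, then the lexicographically
    smallest id.
    """
    if len(motif_ids) < 2:
        raise ContractError(f"family {family} has < 2 instances; no representative")
    ids = set(motif_ids)
    scores: dict[str, list[float]] = {m: [] for m in motif_ids}
    rmsds: dict[str, list[float]] = {m: [] for m in motif_ids}
    for r in records:
        if r.motif_a in ids and r.motif_b in ids:
            for m in (r.motif_a, r.motif_b):
                scores[m].append(r.score_or_tm)
                if np.isfinite(r.rmsd):
                    rmsds[m].append(r.rmsd)

    def key(m):
        ms = float(np.mean(scores[m])) if scores[m] else 0.0
        mr = float(np.mean(rmsds[m])) if rmsds[m] else np.inf
        return (-ms, mr, m)

    best = min(motif_ids, key=key)
    return RepresentativeChoice(
        family, best, float(np.mean(scores[best])) if scores[best] else 0.0
    )


def build_features(
    motifs: dict[str, MotifInstance],
    representatives: dict[str, str],
    mode: str,
    ann_by_motif: dict[str, AnnotationSet] | None = None,
    scoring: ScoringParams | None = None,
    align_params: AlignParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature table: one row per motif, one block per representative family.

    Returns (features, family labels).  Rows whose alignment against any
    representative fails (no usable match) are dropped with a warning.
    """
    feats = INTERACTION_FEATURES if mode == "interaction" else COORDINATE_FEATURES
    rep_fams = sorted(representatives)
    columns = [f"{fam}_{f}" for fam in rep_fams for f in feats]
    if mode == "interaction":
        scoring = scoring or ScoringParams()
        graphs = {
            mid: build_interaction_graph(
                m, motif_interactions(ann_by_motif[mid], m)
            )
            for mid, m in motifs.items()
        }
    else:
        align_params = align_params or AlignParams()

    rows, labels, index = [], [], []
    for mid in sorted(motifs):
        motif = motifs[mid]
        row = []
        ok = True
        for fam in rep_fams:
            rep = motifs[representatives[fam]]
            if mode == "interaction":
                aln = align_interactions(graphs[mid], graphs[representatives[fam]], scoring)
                if not aln.matches:
                    ok = False
                    break
                rmsd = aligned_rmsd(aln.matches, motif, rep)
                row += [aln.score, aln.aligned_length, rmsd,
                        aln.matched_pairs, aln.matched_stacks]
            else:
                aln = align_coordinates(motif, rep, align_params)
                if not aln.matches:
                    ok = False
                    break
                rmsd = aligned_rmsd(aln.matches, motif, rep)
                row += [aln.aligned_length, rmsd, aln.tm_score]
        if not ok:
            warnings.warn(f"motif {mid}: alignment against a representative "
                          f"failed; row excluded", stacklevel=2)
            continue
        rows.append(row)
        labels.append(motif.family)
        index.append(mid)
    X = pd.DataFrame(rows, columns=columns, index=index)
    y = pd.Series(labels, index=index, name="family")
    return X, y


def _run_cv(X, y01, seed, n_splits, n_repeats, var_smoothing):
    cv = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=seed
    )
    runs = []
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y01)
    for train, test in cv.split(Xv, yv):
        clf = GaussianNB(var_smoothing=var_smoothing)
        clf.fit(Xv[train], yv[train])
        pred = clf.predict(Xv[test])
        truth = yv[test]
        acc = 100.0 * float(np.mean(pred == truth))
        run = {"accuracy": acc}
        if set(np.unique(yv)) == {0, 1}:
            pos, neg = truth == 1, truth == 0
            run["sensitivity"] = 100.0 * float(np.mean(pred[pos] == 1)) if pos.any() else np.nan
            run["specificity"] = 100.0 * float(np.mean(pred[neg] == 0)) if neg.any() else np.nan
        runs.append(run)
    return runs


def evaluate_binary(
    X: pd.DataFrame,
    y: pd.Series,
    positive_family: str,
    seed: int,
    n_splits: int = 3,
    n_repeats: int = 5,
    var_smoothing: float = 1e-9,
    undersample_per_repeat: bool = False,
) -> CVReport:
    """One-vs-rest Gaussian naive Bayes with class balancing.

    Class 1 = ``positive_family``, Class 0 = everything else, undersampled to
    the positive-class size with a seeded RNG (drawn once per report by
    default).  Metrics are averaged over n_splits x n_repeats runs:
    accuracy, sensitivity (Class 1 recall) and specificity (Class 0 recall).
    """
    pos_idx = y.index[y == positive_family]
    neg_idx = y.index[y != positive_family]
    if len(pos_idx) < 2 * n_splits:
        raise ContractError(
            f"positive family {positive_family} has {len(pos_idx)} members; "
            f"needs at least {2 * n_splits} for stratified {n_splits}-fold CV"
        )
    if len(neg_idx) < len(pos_idx):
        raise ContractError("negative pool smaller than positive class")
    rng = np.random.default_rng(seed)

    def subsample():
        chosen = rng.choice(np.asarray(neg_idx), size=len(pos_idx), replace=False)
        idx = list(pos_idx) + sorted(chosen.tolist())
        Xb = X.loc[idx]
        yb = (y.loc[idx] == positive_family).astype(int)
        return Xb, yb

    if undersample_per_repeat:
        runs = []
        for rep in range(n_repeats):
            Xb, yb = subsample()
            runs += _run_cv(Xb, yb, seed + rep, n_splits, 1, var_smoothing)
    else:
        Xb, yb = subsample()
        runs = _run_cv(Xb, yb, seed, n_splits, n_repeats, var_smoothing)
    sizes = (int((yb == 1).sum()), int((yb == 0).sum()))
    return CVReport(
        positive_family,
        runs,
        float(np.mean([r["accuracy"] for r in runs])),
        float(np.nanmean([r["sensitivity"] for r in runs])),
        float(np.nanmean([r["specificity"] for r in runs])),
        sizes,
    )


def evaluate_multiclass(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int,
    n_splits: int = 3,
    n_repeats: int = 5,
    var_smoothing: float = 1e-9,
) -> CVReport:
    """Multiclass Gaussian naive Bayes under the same CV protocol.

    No undersampling; stratified folds keep the class ratios.  Reports mean
    accuracy over the 15 runs.
    """
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2 * n_splits:
        raise ContractError(
            f"multiclass evaluation needs >= 2 families with >= {2 * n_splits} "
            f"members each (got {counts.to_dict()})"
        )
    codes = pd.Categorical(y).codes
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    Xv = np.asarray(X, dtype=float)
    runs = []
    for train, test in cv.split(Xv, codes):
        clf = GaussianNB(var_smoothing=var_smoothing)
        clf.fit(Xv[train], codes[train])
        acc = 100.0 * float(np.mean(clf.predict(Xv[test]) == codes[test]))
        runs.append({"accuracy": acc})
    return CVReport("multiclass", runs, float(np.mean([r["accuracy"] for r in runs])))


def pca_projection(X: pd.DataFrame) -> pd.DataFrame:
    """First two principal components of the standardized feature table."""
    if len(X) < 3 or X.shape[1] < 2:
        raise ContractError("pca_projection needs >= 3 motifs and >= 2 features")
    variances = X.var(axis=0)
    keep = variances[variances > 0].index
    if len(keep) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(keep)} constant feature(s) before PCA",
            stacklevel=2,
        )
    if len(keep) < 2:
        raise ContractError("fewer than 2 non-constant features for PCA")
    Z = StandardScaler().fit_transform(X[keep])
    pcs = PCA(n_components=2, svd_solver="full").fit_transform(Z)
    return pd.DataFrame(pcs, columns=["PC1", "PC2"], index=X.index)
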