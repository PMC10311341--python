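"""End-to-end comparison pipeline: locations + structures + annotations in,
similarity graphs and similar-instance lists out.

Stages (logged at INFO):

1. parse the motif-location list and load each referenced structure;
2. materialize motifs (HETATM-containing motifs are excluded);
3. read and merge the two annotation sources per structure;
4. align every motif pair per mode (interaction and/or coordinate) and reduce
   each to a :class:`~motifcompare.similarity.PairRecord`;
5. z-score-filter poorly aligning family members, derive family length
   thresholds, select best pairs, and build the similarity graph.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import similarity as sim
from .annotation import (
    AnnotationSet,
    merge_annotations,
    motif_interactions,
    read_dssr_annotations,
    read_fr3d_annotations,
)
from .coordinate import AlignParams, align_coordinates
from .errors import MotifCompareError
from .interaction import InteractionGraph, ScoringParams, align_interactions, build_interaction_graph
from .io import (
    MotifInstance,
    load_structure,
    parse_motif_locations,
    materialize_motif,
    write_similar_instances,
)
from .similarity import (
    FamilyThresholds,
    OutlierReport,
    PairRecord,
    SimilarityGraph,
    aligned_rmsd,
    build_similarity_graph,
    family_length_threshold,
    select_best_pairs,
    zscore_filter,
)
from .version import __version__

logger = logging.getLogger("motifcompare")

MODES = ("interaction", "coordinate")


@dataclass
class PipelineConfig:
    """All pipeline tunables; mirrors the CLI flags."""

    modes: tuple[str, ...] = MODES
    rmsd_cutoffs: dict = field(
        default_factory=lambda: dict(sim.DEFAULT_RMSD_CUTOFFS)
    )
    pct_threshold: float = sim.DEFAULT_PCT_THRESHOLD
    zscore_cutoff: float = sim.DEFAULT_ZSCORE_CUTOFF
    scoring: ScoringParams = field(default_factory=ScoringParams)
    align_params: AlignParams = field(default_factory=AlignParams)
    family_filter: set[str] | None = None


@dataclass
class ModeResult:
    """Everything computed for one alignment mode."""

    mode: str
    records: list[PairRecord]
    outliers: dict[str, list[OutlierReport]]
    removed: set[str]
    thresholds: dict[str, FamilyThresholds]
    family_sizes: dict[str, int]            # post-filter
    graph: SimilarityGraph

    def best_pairs(self, fam_a: str, fam_b: str) -> list[PairRecord]:
        key = tuple(sorted((fam_a, fam_b)))
        recs = [r for r in self.records if r.family_key == key and not r.is_intra()]
        if not recs:
            return []
        cutoff = self.graph.parameters["rmsd_cutoff"]
        return select_best_pairs(
            recs, self.thresholds[key[0]], self.thresholds[key[1]], cutoff
        )


@dataclass
class RunResult:
    motifs: dict[str, MotifInstance]
    excluded: dict[str, str]                 # motif_id -> reason
    by_mode: dict[str, ModeResult]
    config: PipelineConfig


def load_corpus(
    locations: str | Path,
    structures_dir: str | Path,
    annotations_dir: str | Path,
    family_filter: set[str] | None = None,
) -> tuple[dict[str, MotifInstance], dict[str, str], dict[str, AnnotationSet]]:
    """Load and materialize all motifs plus one merged annotation set each.

    Returns (usable motifs by id, excluded motifs with reasons, merged
    annotations keyed by motif id).
    """
    structures_dir = Path(structures_dir)
    annotations_dir = Path(annotations_dir)
    stubs = parse_motif_locations(locations, family_filter)
    logger.info("parsed %d motif locations", len(stubs))

    structures: dict[str, object] = {}
    merged_ann: dict[str, AnnotationSet] = {}
    motifs: dict[str, MotifInstance] = {}
    excluded: dict[str, str] = {}
    for stub in stubs:
        pid = stub.pdb_id
        if pid not in structures:
            path = None
            for ext in (".pdb", ".cif", ".mmcif"):
                for cand in (pid + ext, pid.lower() + ext, pid.upper() + ext):
                    if (structures_dir / cand).exists():
                        path = structures_dir / cand
                        break
                if path:
                    break
            if path is None:
                raise MotifCompareError(f"no structure file for {pid} in {structures_dir}")
            structures[pid] = load_structure(path)
            merged_ann[pid] = _load_annotations(annotations_dir, pid)
        motif = materialize_motif(stub, structures[pid])
        if motif.excluded:
            excluded[motif.motif_id] = motif.exclusion_reason
            logger.info("excluding %s: %s", motif.motif_id, motif.exclusion_reason)
        else:
            motifs[motif.motif_id] = motif
    logger.info("materialized %d motifs (%d excluded)", len(motifs), len(excluded))
    ann_by_motif = {
        mid: merged_ann[m.pdb_id] for mid, m in motifs.items()
    }
    return motifs, excluded, ann_by_motif


def _load_annotations(annotations_dir: Path, pdb_id: str) -> AnnotationSet:
    sets = []
    for suffix, reader in ((".dssr", read_dssr_annotations), (".fr3d", read_fr3d_annotations)):
        for cand in (pdb_id + suffix, pdb_id.lower() + suffix):
            path = annotations_dir / cand
            if path.exists():
                sets.append(reader(path, pdb_id))
                break
    if not sets:
        logger.warning("no annotations for %s; motifs get sequence-only graphs", pdb_id)
        return AnnotationSet(pdb_id, set(), set())
    if len(sets) == 1:
        return sets[0]
    return merge_annotations(sets[0], sets[1])


def _interaction_record(
    ga: InteractionGraph, gb: InteractionGraph,
    ma: MotifInstance, mb: MotifInstance, scoring: ScoringParams,
) -> PairRecord:
    aln = align_interactions(ga, gb, scoring)
    rmsd = aligned_rmsd(aln.matches, ma, mb) if aln.matches else float("nan")
    return PairRecord(
        ma.motif_id, mb.motif_id, ma.family, mb.family, "interaction",
        aln.aligned_length, rmsd, aln.score,
    )


def _coordinate_record(
    ma: MotifInstance, mb: MotifInstance, params: AlignParams
) -> PairRecord:
    aln = align_coordinates(ma, mb, params)
    rmsd = aligned_rmsd(aln.matches, ma, mb) if aln.matches else float("nan")
    return PairRecord(
        ma.motif_id, mb.motif_id, ma.family, mb.family, "coordinate",
        aln.aligned_length, rmsd, aln.tm_score,
    )


def compute_pair_records(
    motifs: dict[str, MotifInstance],
    ann_by_motif: dict[str, AnnotationSet],
    mode: str,
    config: PipelineConfig,
) -> list[PairRecord]:
    """All-pairs alignment records (intra and inter family) for one mode."""
    ids = sorted(motifs)
    records = []
    graphs = {}
    if mode == "interaction":
        graphs = {
            mid: build_interaction_graph(
                motifs[mid], motif_interactions(ann_by_motif[mid], motifs[mid])
            )
            for mid in ids
        }
    for ia, ib in itertools.combinations(ids, 2):
        ma, mb = motifs[ia], motifs[ib]
        if mode == "interaction":
            records.append(
                _interaction_record(graphs[ia], graphs[ib], ma, mb, config.scoring)
            )
        elif mode == "coordinate":
            records.append(_coordinate_record(ma, mb, config.align_params))
        else:
            raise MotifCompareError(f"unknown mode {mode!r}")
    logger.info("%s mode: %d pair records", mode, len(records))
    return records


def analyze_mode(
    motifs: dict[str, MotifInstance],
    records: list[PairRecord],
    mode: str,
    config: PipelineConfig,
) -> ModeResult:
    """Outlier filter + thresholds + similarity graph for precomputed records."""
    families: dict[str, list[str]] = {}
    for mid, m in sorted(motifs.items()):
        families.setdefault(m.family, []).append(mid)

    outliers: dict[str, list[OutlierReport]] = {}
    removed: set[str] = set()
    for fam, ids in families.items():
        intra = [r for r in records if r.is_intra() and r.family_a == fam]
        reports = zscore_filter(ids, intra, config.zscore_cutoff)
        outliers[fam] = reports
        removed.update(r.motif_id for r in reports if r.removed)
    if removed:
        logger.info("%s mode: removed %d outlier instances", mode, len(removed))
    kept_records = [
        r for r in records if r.motif_a not in removed and r.motif_b not in removed
    ]
    family_sizes = {
        fam: len([m for m in ids if m not in removed]) for fam, ids in families.items()
    }
    thresholds = {
        fam: family_length_threshold(
            fam,
            [r for r in kept_records if r.is_intra() and r.family_a == fam],
            family_sizes[fam],
        )
        for fam in families
    }
    graph = build_similarity_graph(
        kept_records, family_sizes, mode,
        config.rmsd_cutoffs.get(mode), config.pct_threshold, thresholds,
    )
    return ModeResult(mode, kept_records, outliers, removed, thresholds,
                      family_sizes, graph)


def run_compare(
    locations: str | Path,
    structures_dir: str | Path,
    annotations_dir: str | Path,
    config: PipelineConfig | None = None,
) -> RunResult:
    """Run the full comparison pipeline on a corpus on disk."""
    config = config or PipelineConfig()
    motifs, excluded, ann_by_motif = load_corpus(
        locations, structures_dir, annotations_dir, config.family_filter
    )
    by_mode = {}
    for mode in config.modes:
        records = compute_pair_records(motifs, ann_by_motif, mode, config)
        by_mode[mode] = analyze_mode(motifs, records, mode, config)
    return RunResult(motifs, excluded, by_mode, config)


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    """Write graphs, per-family-pair similar-instance TSVs and a run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "version": __version__,
        "parameters": {
            "modes": list(result.config.modes),
            "rmsd_cutoffs": result.config.rmsd_cutoffs,
            "pct_threshold": result.config.pct_threshold,
            "zscore_cutoff": result.config.zscore_cutoff,
        },
        "n_motifs": len(result.motifs),
        "excluded": result.excluded,
        "modes": {},
    }
    for mode, mres in result.by_mode.items():
        for fmt, ext in (("DOT", "dot"), ("GraphML", "graphml"), ("JSON", "json")):
            sim.export_graph(mres.graph, out_dir / f"similarity_{mode}.{ext}", fmt)
        fams = sorted(mres.family_sizes)
        for fa, fb in itertools.combinations(fams, 2):
            best = mres.best_pairs(fa, fb)
            if best:
                write_similar_instances(
                    best, out_dir / f"similar_{mode}_{fa}_{fb}.tsv",
                    parameters=f"mode={mode} rmsd_cutoff="
                    f"{mres.graph.parameters['rmsd_cutoff']}",
                )
        report["modes"][mode] = {
            "removed_outliers": sorted(mres.removed),
            "thresholds": {
                f: t.length_threshold for f, t in sorted(mres.thresholds.items())
            },
            "family_sizes": mres.family_sizes,
            "solid_edges": sorted(map(list, mres.graph.solid_edges())),
        }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    logger.info("outputs written to %s", out_dir)
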