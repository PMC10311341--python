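"""Shared fixtures: in-memory motif builders and a session-scoped planted corpus."""

from __future__ import annotations

import numpy as np
import pytest

from motifcompare import (
    MotifInstance,
    Nucleotide,
    PipelineConfig,
    ResidueID,
    default_family_specs,
    default_planted,
    generate_corpus,
    run_compare,
)
from motifcompare.similarity import BACKBONE_RIBOSE_ATOMS

#: seed of the study corpus used by the end-to-end suites
CORPUS_SEED = 7


def make_motif(
    coords,
    bases: str | None = None,
    motif_id: str = "m1",
    family: str = "FAM",
    segments: tuple[int, ...] | None = None,
    atom_names: tuple[str, ...] = ("C3'", "C1'", "P"),
) -> MotifInstance:
    """Build a motif from per-nucleotide base points.

    Each nucleotide gets a few atoms at small fixed offsets from its base
    point so that centroids and representative atoms are well defined.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    bases = bases or "A" * n
    segments = segments or (n,)
    offsets = {name: np.array([0.1 * k, 0.05 * k, -0.1 * k])
               for k, name in enumerate(atom_names)}
    assert sum(segments) == n
    segs = []
    pos = 0
    for s, seg_len in enumerate(segments):
        seg = []
        for i in range(seg_len):
            rid = ResidueID("A", 100 * s + pos + 1)
            atoms = {name: coords[pos] + off for name, off in offsets.items()}
            seg.append(Nucleotide(rid, bases[pos], atoms))
            pos += 1
        segs.append(seg)
    return MotifInstance(motif_id, family, "XXXX", segs)


def make_motif_full_atoms(coords, **kwargs) -> MotifInstance:
    """Motif whose nucleotides carry the full backbone+ribose atom scope."""
    return make_motif(coords, atom_names=BACKBONE_RIBOSE_ATOMS, **kwargs)


@pytest.fixture(scope="session")
def planted_corpus(tmp_path_factory):
    """The default six-family study corpus with all three planted relations."""
    out = tmp_path_factory.mktemp("corpus")
    return generate_corpus(
        default_family_specs(n_instances=10), default_planted(),
        seed=CORPUS_SEED, out_dir=out,
    )


@pytest.fixture(scope="session")
def pipeline_result(planted_corpus):
    """Full two-mode pipeline run on the study corpus (computed once)."""
    return run_compare(
        planted_corpus.locations_path,
        planted_corpus.structures_dir,
        planted_corpus.annotations_dir,
        PipelineConfig(),
    )


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A light corpus (3 instances per family) for I/O-level tests."""
    out = tmp_path_factory.mktemp("small_corpus")
    return generate_corpus(
        default_family_specs(n_instances=3), default_planted(),
        seed=3, out_dir=out,
    )
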