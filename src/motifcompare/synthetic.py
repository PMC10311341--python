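"""Synthetic motif corpora with controlled, planted cross-family structure.

The generator emulates the three inputs of the pipeline — structure files,
two base-interaction annotation dialects, and a motif-location list — so that
every other module is testable without downloading anything.

Each synthetic family is an internal-loop motif of two 7-nucleotide strands
laid out on a family-specific helical backbone (radius, rise, twist, a kink
of the second strand, and a family origin offset that keeps the families'
frames apart).  The first two positions of strand 1 (and the last two of
strand 2) form the family *core*: two family-signature base pairs with a
conserved purine sequence.  The remaining five positions of each strand form
the *slot*, which normally carries a random sequence and no interactions.

A :class:`PlantedSimilarity` injects shared structure into a chosen fraction
of two families' instances:

* ``interaction``: the slot receives a dedicated set of base-pair classes, a
  conserved pyrimidine sequence, and the slot block's own local geometry —
  shared between the two families but embedded in each family's otherwise
  divergent frame (shared interactions with shared local shape, different
  global shapes);
* ``coordinate``: the whole instance's coordinates are replaced by a shared
  template (same global shape), while the interactions stay family-typical;
* ``both``: the shared sub-motif is the whole instance — coordinates,
  sequence and all base-pair classes are replaced by the relation's shared
  template, so the planted subsets agree in both viewpoints.

Backbone + ribose heavy atoms only are generated (the RMSD atom scope); base
rings are omitted, so these fixtures are not physical RNA and are labeled
synthetic throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ContractError
from .io import MotifInstance, Nucleotide, ResidueID
from .version import __version__

STRAND_LEN = 7
CORE_LEN = 2
SLOT_LEN = STRAND_LEN - CORE_LEN

#: local heavy-atom offsets (Å) applied around each nucleotide's base point
_ATOM_OFFSETS = {
    "P": (-1.2, 0.8, -0.5), "OP1": (-2.1, 1.5, -0.3), "OP2": (-1.4, 0.2, -1.8),
    "O5'": (-0.7, -0.3, 0.6), "C5'": (0.2, -1.0, 1.0), "C4'": (0.9, -0.2, 1.4),
    "O4'": (1.8, 0.4, 0.9), "C3'": (0.6, 0.7, 2.2), "O3'": (1.1, 1.9, 2.5),
    "C2'": (1.6, -0.5, 2.4), "O2'": (2.7, -0.2, 2.8), "C1'": (2.2, 0.9, 1.7),
}

#: family-signature base-pair classes, cycled over families
_CLASS_PALETTE = ["cWW", "tHH", "cSS", "tWW", "cHH", "tSS"]
#: classes reserved for planted shared sub-motifs, cycled over relations
_PLANTED_CLASSES = ["cWH", "tWS", "cHS"]
#: conserved core sequences (strand-1 half, strand-2 half), chosen so that
#: planted family pairs share no in-order core subsequence
_CORE_SEQS = [("AA", "AA"), ("GG", "GG"), ("AG", "GA"),
              ("GA", "AG"), ("AA", "GG"), ("GG", "AA")]


@dataclass
class SyntheticFamilySpec:
    """Parameters of one synthetic motif family."""

    name: str
    n_instances: int = 10
    helix_radius: float = 8.0
    helix_rise: float = 2.8
    helix_twist_deg: float = 40.0
    kink_deg: float = 0.0          # bend of strand 2 relative to strand 1
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    signature_class: str = "cWW"   # Leontis-Westhof class of the core pairs
    core_seq: tuple[str, str] = ("AA", "AA")
    coordinate_noise_sd: float = 0.12
    stacking: bool = False         # annotate within-strand stackings

    def __post_init__(self):
        if self.n_instances < 1:
            raise ContractError("n_instances must be >= 1")
        if self.coordinate_noise_sd < 0:
            raise ContractError("coordinate_noise_sd must be >= 0")


@dataclass
class PlantedSimilarity:
    """A shared sub-structure planted into a fraction of two families."""

    family_a: str
    family_b: str
    shared_mode: str               # interaction | coordinate | both
    participation_a: float
    participation_b: float

    def __post_init__(self):
        if self.shared_mode not in ("interaction", "coordinate", "both"):
            raise ContractError(f"unknown shared_mode {self.shared_mode!r}")
        for frac in (self.participation_a, self.participation_b):
            if not 0.0 <= frac <= 1.0:
                raise ContractError("participation fractions must lie in [0, 1]")


@dataclass
class CorpusManifest:
    """Ground truth and file locations of one generated corpus."""

    out_dir: str
    locations_path: str
    structures_dir: str
    annotations_dir: str
    seed: int
    families: dict[str, list[str]]                 # family -> motif ids
    planted: dict[str, dict]                       # relation key -> ground truth
    disagreement_rate: float
    n_flipped_annotations: int


def _rotation_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _strand_points(spec_like: dict, antiparallel: bool) -> np.ndarray:
    """Base points of one strand on the family helix."""
    r = spec_like["helix_radius"]
    rise = spec_like["helix_rise"]
    twist = np.deg2rad(spec_like["helix_twist_deg"])
    idx = np.arange(STRAND_LEN)
    phase = np.pi if antiparallel else 0.0
    z = (STRAND_LEN - 1 - idx) * rise if antiparallel else idx * rise
    pts = np.stack(
        [r * np.cos(phase + idx * twist), r * np.sin(phase + idx * twist), z], axis=1
    )
    if antiparallel and spec_like.get("kink_deg", 0.0):
        center = pts.mean(axis=0)
        pts = (pts - center) @ _rotation_y(np.deg2rad(spec_like["kink_deg"])).T + center
    return pts


def template_coords(spec_like: dict) -> np.ndarray:
    """(2*STRAND_LEN, 3) base points for both strands of a template."""
    s1 = _strand_points(spec_like, antiparallel=False)
    s2 = _strand_points(spec_like, antiparallel=True) + np.array(
        [2.2 * spec_like["helix_radius"], 0.0, 0.0]
    )
    return np.vstack([s1, s2]) + np.asarray(spec_like.get("origin", (0, 0, 0)), float)


def _slot_indices() -> list[int]:
    """Node indices (concatenated strand order) belonging to the slot."""
    return list(range(CORE_LEN, STRAND_LEN)) + list(range(STRAND_LEN, STRAND_LEN + SLOT_LEN))


def _pair_partners() -> list[tuple[int, int]]:
    """Antiparallel pairing: strand-1 position i pairs strand-2 position L-1-i."""
    return [(i, 2 * STRAND_LEN - 1 - i) for i in range(STRAND_LEN)]


def core_pair_indices() -> list[tuple[int, int]]:
    return _pair_partners()[:CORE_LEN]


def slot_pair_indices() -> list[tuple[int, int]]:
    return _pair_partners()[CORE_LEN:]


def _relation_template(rel_index: int) -> dict:
    """Shared-geometry parameters of one planted relation (no family offset)."""
    return {
        "helix_radius": 9.5 + 0.8 * rel_index,
        "helix_rise": 3.0 + 0.15 * rel_index,
        "helix_twist_deg": 46.0 + 9.0 * rel_index,
        "kink_deg": 18.0 + 7.0 * rel_index,
        "origin": (0.0, 0.0, 0.0),
    }


def perturb(instance: MotifInstance, noise_sd: float, seed: int) -> MotifInstance:
    """Copy of ``instance`` with isotropic Gaussian noise on every atom."""
    if noise_sd < 0:
        raise ContractError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    segments = []
    for seg in instance.segments:
        new_seg = []
        for nt in seg:
            atoms = {
                name: xyz + rng.normal(0.0, noise_sd, 3)
                for name, xyz in nt.atoms.items()
            }
            new_seg.append(Nucleotide(nt.rid, nt.base, atoms, nt.is_het, nt.modified))
        segments.append(new_seg)
    return MotifInstance(
        instance.motif_id, instance.family, instance.pdb_id, segments,
        instance.source_file,
    )


def _class_split(label: str) -> tuple[str, str, str]:
    orientation = "cis" if label[0] == "c" else "trans"
    return label[1], label[2], orientation


def _flip_orientation(label: str) -> str:
    return ("t" if label[0] == "c" else "c") + label[1:]


@dataclass
class _Instance:
    motif_id: str
    family: str
    pdb_id: str
    bases: list[str]
    coords: np.ndarray             # (14, 3) base points, pre-noise
    pairs: list[tuple[int, int, str]]   # (node_u, node_v, class label)
    stacks: list[tuple[int, int]]
    planted_in: list[str] = field(default_factory=list)


def _seg_residue_ids(pdb_id: str) -> list[ResidueID]:
    # strand 1: chain A residues 1..7; strand 2: chain A residues 21..27
    return [ResidueID("A", n) for n in range(1, STRAND_LEN + 1)] + [
        ResidueID("A", n) for n in range(21, 21 + STRAND_LEN)
    ]


def _write_structure_pdb(inst: _Instance, noise_sd: float, rng, path: Path) -> None:
    rids = _seg_residue_ids(inst.pdb_id)
    lines = [
        f"REMARK 300 motifcompare v{__version__} synthetic structure",
        f"REMARK 300 instance {inst.motif_id} family {inst.family}",
    ]
    serial = 0
    for k, rid in enumerate(rids):
        base_point = inst.coords[k]
        for name, off in _ATOM_OFFSETS.items():
            serial += 1
            xyz = base_point + np.asarray(off) + rng.normal(0.0, noise_sd, 3)
            xyz = np.round(xyz, 3)
            atom_name = f" {name:<3}" if len(name) < 4 else name
            element = name[0] if name[0].isalpha() else name[1]
            lines.append(
                f"ATOM  {serial:>5} {atom_name} {inst.bases[k]:>3} {rid.chain_id}"
                f"{rid.seq_num:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_annotations(
    inst: _Instance, ann_dir: Path, disagreement_rate: float, rng
) -> int:
    """Write DSSR-style and FR3D-style files; returns number of planted flips."""
    rids = _seg_residue_ids(inst.pdb_id)

    def dssr_res(k: int) -> str:
        return f"A.{inst.bases[k]}{rids[k].seq_num}"

    def fr3d_res(k: int) -> str:
        return f"{inst.pdb_id}|1|A|{inst.bases[k]}|{rids[k].seq_num}"

    dssr, fr3d = [], []
    flipped = 0
    for u, v, label in inst.pairs:
        dssr.append(f"{dssr_res(u)} {dssr_res(v)} {label}")
        out_label = label
        if disagreement_rate > 0 and rng.random() < disagreement_rate:
            out_label = _flip_orientation(label)
            flipped += 1
        fr3d.append(f"{fr3d_res(u)} {fr3d_res(v)} {out_label}")
    for u, v in inst.stacks:
        dssr.append(f"{dssr_res(u)} {dssr_res(v)} stack:upward")
        fr3d.append(f"{fr3d_res(u)} {fr3d_res(v)} s35")
    (ann_dir / f"{inst.pdb_id}.dssr").write_text("\n".join(dssr) + "\n")
    (ann_dir / f"{inst.pdb_id}.fr3d").write_text("\n".join(fr3d) + "\n")
    return flipped


def default_family_specs(
    n_families: int = 6, n_instances: int = 10, noise_sd: float = 0.12
) -> list[SyntheticFamilySpec]:
    """The standard study families: geometrically well-separated internal loops."""
    specs = []
    for i in range(n_families):
        specs.append(
            SyntheticFamilySpec(
                name=f"IL{chr(ord('A') + i)}",
                n_instances=n_instances,
                helix_radius=6.5 + 1.3 * i,
                helix_rise=2.5 + 0.22 * i,
                helix_twist_deg=30.0 + 14.0 * i,
                kink_deg=55.0 * (i % 3),
                origin=(18.0 * i, 7.0 * (i % 2), -5.0 * i),
                signature_class=_CLASS_PALETTE[i % len(_CLASS_PALETTE)],
                core_seq=_CORE_SEQS[i % len(_CORE_SEQS)],
                coordinate_noise_sd=noise_sd,
            )
        )
    return specs


def default_planted() -> list[PlantedSimilarity]:
    """The standard planted design: interaction-only, coordinate-only, both."""
    return [
        PlantedSimilarity("ILA", "ILB", "interaction", 0.3, 0.3),
        PlantedSimilarity("ILC", "ILD", "coordinate", 0.3, 0.3),
        PlantedSimilarity("ILE", "ILF", "both", 0.5, 0.5),
    ]


def generate_corpus(
    specs: list[SyntheticFamilySpec],
    planted: list[PlantedSimilarity],
    seed: int,
    out_dir: str | Path,
    disagreement_rate: float = 0.1,
) -> CorpusManifest:
    """Generate structures, annotations and locations for a planted corpus.

    Deterministic for a given seed (byte-identical output).  Every instance
    becomes one single-chain structure file (``structures/<id>.pdb``) with two
    residue ranges 1-7 and 21-27, one annotation file per dialect under
    ``annotations/``, one line in ``locations.in``, and an entry in
    ``manifest.json`` recording the planted ground truth.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ContractError("family names must be unique")
    by_name = {s.name: s for s in specs}
    for rel in planted:
        for fam in (rel.family_a, rel.family_b):
            if fam not in by_name:
                raise ContractError(f"planted relation references unknown family {fam}")

    out_dir = Path(out_dir)
    structures = out_dir / "structures"
    annotations = out_dir / "annotations"
    structures.mkdir(parents=True, exist_ok=True)
    annotations.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- build plain family instances
    instances: list[_Instance] = []
    families: dict[str, list[str]] = {}
    counter = 0
    for spec in specs:
        fam_coords = template_coords(asdict(spec))
        ei, ej, orient = _class_split(spec.signature_class)
        families[spec.name] = []
        for _ in range(spec.n_instances):
            counter += 1
            pdb_id = f"S{counter:04d}"
            motif_id = f"{spec.name}_{counter:04d}"
            bases = list(spec.core_seq[0])
            bases += [str(rng.choice(list("ACGU"))) for _ in range(SLOT_LEN)]
            bases += [str(rng.choice(list("ACGU"))) for _ in range(SLOT_LEN)]
            bases += list(spec.core_seq[1])
            # strand 2 runs 5'->3'; its core positions are the LAST two nodes
            pairs = [
                (u, v, spec.signature_class) for u, v in core_pair_indices()
            ]
            stacks = []
            if spec.stacking:
                stacks = [(k, k + 1) for k in range(STRAND_LEN - 1)] + [
                    (STRAND_LEN + k, STRAND_LEN + k + 1) for k in range(STRAND_LEN - 1)
                ]
            instances.append(
                _Instance(motif_id, spec.name, pdb_id, bases,
                          fam_coords.copy(), pairs, stacks)
            )
            families[spec.name].append(motif_id)
    by_id = {inst.motif_id: inst for inst in instances}

    # --- plant shared structure
    planted_truth: dict[str, dict] = {}
    for rel_index, rel in enumerate(planted):
        shared = template_coords(_relation_template(rel_index))
        slot_idx = _slot_indices()
        label = _PLANTED_CLASSES[rel_index % len(_PLANTED_CLASSES)]
        rel_rng = np.random.default_rng(seed + 1000 + rel_index)
        slot_seq = [str(c) for c in rel_rng.choice(list("CU"), size=len(slot_idx))]
        full_seq = [str(c) for c in rel_rng.choice(list("CU"), size=2 * STRAND_LEN)]
        chosen: dict[str, list[str]] = {}
        for fam, frac in ((rel.family_a, rel.participation_a),
                          (rel.family_b, rel.participation_b)):
            ids = families[fam]
            k = int(round(frac * len(ids)))
            sel = sorted(rng.choice(ids, size=k, replace=False).tolist())
            chosen[fam] = sel
            for mid in sel:
                inst = by_id[mid]
                inst.planted_in.append(f"{rel.family_a}-{rel.family_b}")
                if rel.shared_mode == "interaction":
                    # shared slot: interactions + sequence + local geometry
                    for pos, si in enumerate(slot_idx):
                        inst.coords[si] = shared[si]
                        inst.bases[si] = slot_seq[pos]
                    inst.pairs = [p for p in inst.pairs
                                  if (p[0], p[1]) not in slot_pair_indices()]
                    inst.pairs += [(u, v, label) for u, v in slot_pair_indices()]
                elif rel.shared_mode == "coordinate":
                    # shared global shape, family-typical interactions
                    inst.coords = shared.copy()
                else:  # both: the shared sub-motif is the whole instance
                    inst.coords = shared.copy()
                    inst.bases = list(full_seq)
                    inst.pairs = [(u, v, label) for u, v in _pair_partners()]
        planted_truth[f"{rel.family_a}-{rel.family_b}"] = {
            "mode": rel.shared_mode,
            "participation_a": rel.participation_a,
            "participation_b": rel.participation_b,
            "members": chosen,
        }

    # --- serialize
    loc_lines = [f"# motifcompare v{__version__} synthetic motif locations"]
    n_flipped = 0
    for inst in instances:
        spec = by_name[inst.family]
        _write_structure_pdb(inst, spec.coordinate_noise_sd, rng,
                             structures / f"{inst.pdb_id}.pdb")
        n_flipped += _write_annotations(inst, annotations, disagreement_rate, rng)
        loc_lines.append(
            f"{inst.motif_id} {inst.family} {inst.pdb_id} A 1-{STRAND_LEN},21-{20 + STRAND_LEN}"
        )
    locations = out_dir / "locations.in"
    locations.write_text("\n".join(loc_lines) + "\n")

    manifest = CorpusManifest(
        str(out_dir), str(locations), str(structures), str(annotations),
        seed, families, planted_truth, disagreement_rate, n_flipped,
    )
    # the on-disk manifest uses relative paths so a corpus is byte-identical
    # for a given seed regardless of where it is generated
    payload = asdict(manifest)
    payload.update(out_dir=".", locations_path="locations.in",
                   structures_dir="structures", annotations_dir="annotations")
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2) + "\n")
    return manifest
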