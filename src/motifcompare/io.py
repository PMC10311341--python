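"""Input/output for motif locations, structure coordinates and result lists.

The pipeline touches four external formats:

* motif-location lists (one motif per line: ``[motif_id] family pdb_id chain
  ranges``, ranges being comma-separated 1-based closed intervals in author
  numbering, e.g. ``10-14,30-33`` or ``B:5-8`` for a segment on another chain);
* structure coordinate files, PDB or mmCIF, read through gemmi;
* per-motif partial PDB files (single model, single chain, atom serials from 1)
  consumed by the coordinate aligner;
* tab-separated similar-instance lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    ContractError,
    LocationParseError,
    MissingResidueError,
    StructureError,
)
from .version import __version__

#: residue names accepted as standard RNA/DNA nucleotides
_STANDARD_BASES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "DA": "A", "DC": "C", "DG": "G", "DT": "U", "DU": "U",
}
_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True, order=True)
class ResidueID:
    """Author-numbering address of one residue: (chain, seq_num, icode).

    Insertion codes sort after the un-coded residue of the same number,
    alphabetically, which the default field order of this dataclass provides
    (``icode`` is stored as ``""`` when absent).
    """

    chain_id: str
    seq_num: int
    icode: str = ""

    def __post_init__(self):
        if not self.chain_id:
            raise ContractError("ResidueID.chain_id must be non-empty")

    def __str__(self) -> str:
        ic = f"^{self.icode}" if self.icode else ""
        return f"{self.chain_id}.{self.seq_num}{ic}"


@dataclass
class Nucleotide:
    """One residue with its heavy-atom coordinates (Å).

    ``base`` is the one-letter parent code for standard and modified
    nucleotides, or the raw residue name for non-nucleotide HETATM residues
    (kept so that motifs covering ligands can be flagged for exclusion).
    """

    rid: ResidueID
    base: str
    atoms: dict[str, np.ndarray]
    is_het: bool = False
    modified: bool = False
    is_nucleotide: bool = True

    def __post_init__(self):
        for name, xyz in self.atoms.items():
            if not np.all(np.isfinite(xyz)):
                raise ContractError(f"non-finite coordinates for atom {name} of {self.rid}")


@dataclass
class MotifStub:
    """A motif location before coordinates are attached."""

    motif_id: str
    family: str
    pdb_id: str
    ranges: list[tuple[str, int, int]]  # (chain, first, last), closed, 1-based
    source_file: str = ""
    line_number: int = 0


@dataclass
class MotifInstance:
    """One loop motif: ordered strand segments of nucleotides plus a family label."""

    motif_id: str
    family: str
    pdb_id: str
    segments: list[list[Nucleotide]]
    source_file: str = ""
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if not self.segments or any(len(s) == 0 for s in self.segments):
            raise ContractError(f"motif {self.motif_id}: every segment must be non-empty")

    @property
    def nucleotides(self) -> list[Nucleotide]:
        """Concatenated segments in order."""
        return [nt for seg in self.segments for nt in seg]

    def __len__(self) -> int:
        return sum(len(s) for s in self.segments)

    @property
    def sequence(self) -> str:
        return "".join(nt.base if len(nt.base) == 1 else "N" for nt in self.nucleotides)


class Structure:
    """Nucleotides of one coordinate file keyed by :class:`ResidueID`."""

    def __init__(self, structure_id: str, residues: dict[ResidueID, Nucleotide]):
        self.structure_id = structure_id
        self.residues = residues

    def __getitem__(self, rid: ResidueID) -> Nucleotide:
        return self.residues[rid]

    def __contains__(self, rid: ResidueID) -> bool:
        return rid in self.residues

    def __len__(self) -> int:
        return len(self.residues)

    def in_range(self, chain: str, first: int, last: int) -> list[Nucleotide]:
        """Residues of ``chain`` with first <= seq_num <= last, in chain order."""
        picked = [
            nt
            for rid, nt in self.residues.items()
            if rid.chain_id == chain and first <= rid.seq_num <= last
        ]
        picked.sort(key=lambda nt: nt.rid)
        return picked


def _parse_range(token: str, default_chain: str) -> tuple[str, int, int]:
    chain = default_chain
    if ":" in token:
        chain, token = token.split(":", 1)
    try:
        lo, hi = token.split("-", 1)
        first, last = int(lo), int(hi)
    except ValueError as exc:
        raise ValueError(f"malformed range {token!r}") from exc
    if first > last or not chain:
        raise ValueError(f"malformed range {token!r}")
    return chain, first, last


def parse_motif_locations(
    path: str | Path, family_filter: set[str] | None = None
) -> list[MotifStub]:
    """Read a motif-location list into stubs (ids and ranges, no coordinates).

    Records are whitespace-separated; an explicit motif id in a leading fifth
    column is optional and otherwise synthesised from the location itself.
    Records whose family is outside ``family_filter`` are dropped.  A
    duplicated motif id is an error; a malformed range reports its line number.
    """
    path = Path(path)
    stubs: list[MotifStub] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) == 5:
                motif_id, family, pdb_id, chain, ranges_s = fields
            elif len(fields) == 4:
                family, pdb_id, chain, ranges_s = fields
                motif_id = f"{family}:{pdb_id}:{chain}:{ranges_s}"
            else:
                raise LocationParseError(
                    f"expected 4 or 5 whitespace-separated fields, got {len(fields)}",
                    lineno,
                )
            try:
                ranges = [_parse_range(tok, chain) for tok in ranges_s.split(",") if tok]
            except ValueError as exc:
                raise LocationParseError(str(exc), lineno) from exc
            if not ranges:
                raise LocationParseError("record has no residue ranges", lineno)
            if motif_id in seen:
                raise LocationParseError(
                    f"duplicate motif_id {motif_id!r} (first seen on line {seen[motif_id]})",
                    lineno,
                )
            seen[motif_id] = lineno
            if family_filter is not None and family not in family_filter:
                continue
            stubs.append(
                MotifStub(motif_id, family, pdb_id, ranges, str(path), lineno)
            )
    if not stubs:
        warnings.warn(f"no motif locations read from {path}", stacklevel=2)
    return stubs


def _residue_to_nucleotide(chain_name: str, res: gemmi.Residue) -> Nucleotide | None:
    name = res.name.strip().upper()
    if name in _WATER_NAMES:
        return None
    atoms: dict[str, np.ndarray] = {}
    for atom in res:
        if atom.name in atoms:  # first altloc wins
            continue
        atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    rid = ResidueID(chain_name, res.seqid.num, (res.seqid.icode or " ").strip())
    is_het = res.het_flag == "H"
    if name in _STANDARD_BASES:
        return Nucleotide(rid, _STANDARD_BASES[name], atoms, is_het=is_het)
    info = gemmi.find_tabulated_residue(name)
    if (info is not None and info.is_nucleic_acid()) or "C1'" in atoms:
        one = info.one_letter_code.upper() if info is not None else "N"
        base = one if one.isalpha() else "N"
        return Nucleotide(rid, base, atoms, is_het=is_het, modified=True)
    # non-nucleotide HETATM (ligand etc.) -- kept so motif exclusion can trigger
    return Nucleotide(rid, name, atoms, is_het=is_het, is_nucleotide=False)


def load_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a table of nucleotides (model 1 only)."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: structure contains no models")
    st.setup_entities()
    model = st[0]
    residues: dict[ResidueID, Nucleotide] = {}
    n_nucleic = 0
    for chain in model:
        for res in chain:
            nt = _residue_to_nucleotide(chain.name, res)
            if nt is None:
                continue
            residues[nt.rid] = nt
            if nt.is_nucleotide:
                n_nucleic += 1
    if n_nucleic == 0:
        raise StructureError(f"{path}: no nucleic-acid residues found")
    structure_id = st.name.strip() or path.stem
    return Structure(structure_id.upper(), residues)


def materialize_motif(stub: MotifStub, structure: Structure) -> MotifInstance:
    """Fill a stub's segments with nucleotides from ``structure``.

    Each range becomes one segment in chain order.  A seq_num inside a range
    with no residue in the structure raises :class:`MissingResidueError`.
    Motifs containing any HETATM-origin residue are marked ``excluded`` (they
    are kept in the corpus listing but take no part in alignments).
    """
    segments: list[list[Nucleotide]] = []
    for chain, first, last in stub.ranges:
        seg = structure.in_range(chain, first, last)
        present = {nt.rid.seq_num for nt in seg}
        for num in range(first, last + 1):
            if num not in present:
                raise MissingResidueError(
                    f"motif {stub.motif_id}: residue {ResidueID(chain, num)} "
                    f"not found in structure {structure.structure_id}"
                )
        segments.append(seg)
    motif = MotifInstance(
        stub.motif_id, stub.family, stub.pdb_id, segments, stub.source_file
    )
    het = [str(nt.rid) for nt in motif.nucleotides if nt.is_het]
    if het:
        motif.excluded = True
        motif.exclusion_reason = f"HETATM residues in motif region: {', '.join(het)}"
    return motif


def _format_atom_name(name: str) -> str:
    # conventional PDB padding: 1-char element names start in column 14
    return f" {name:<3}" if len(name) < 4 else name[:4]


def write_partial_pdb(motif: MotifInstance, path: str | Path) -> dict[ResidueID, int]:
    """Write the motif as a single-chain, single-model PDB file.

    All segments are re-homed to one output chain ``A`` with residues
    renumbered from 1 in segment order (the coordinate aligner consumes
    first-chain-only files).  Returns the bijective map from original
    :class:`ResidueID` to the new residue number.
    """
    path = Path(path)
    mapping: dict[ResidueID, int] = {}
    lines = [
        f"REMARK 300 motifcompare v{__version__} partial structure",
        f"REMARK 300 motif {motif.motif_id} family {motif.family} pdb {motif.pdb_id}",
    ]
    serial = 0
    new_num = 0
    for seg in motif.segments:
        for nt in seg:
            new_num += 1
            mapping[nt.rid] = new_num
            resname = nt.base if len(nt.base) <= 3 else nt.base[:3]
            for name, xyz in nt.atoms.items():
                serial += 1
                element = name[0] if name[0].isalpha() else name[1]
                lines.append(
                    f"ATOM  {serial:>5} {_format_atom_name(name)} {resname:>3} A"
                    f"{new_num:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2}"
                )
    lines.append("END")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise StructureError(f"cannot write partial PDB to {path}: {exc}") from exc
    assert len(set(mapping.values())) == len(mapping), "renumbering must be a bijection"
    return mapping


def write_similar_instances(pairs: list, path: str | Path, parameters: str = "") -> None:
    """Write one family pair's similar-instance list as TSV.

    All records must share the same unordered family pair and mode.  Lines are
    sorted by RMSD ascending, ties broken lexicographically by motif ids.
    """
    path = Path(path)
    keys = {(frozenset((p.family_a, p.family_b)), p.mode) for p in pairs}
    if len(keys) > 1:
        raise ContractError("write_similar_instances: mixed family pairs or modes")
    header = [
        f"# motifcompare v{__version__} similar instances",
        f"# parameters: {parameters}" if parameters else "# parameters: defaults",
        "motif_a\tmotif_b\taligned_length\trmsd",
    ]
    body = [
        f"{p.motif_a}\t{p.motif_b}\t{p.aligned_length:g}\t{p.rmsd:.4f}"
        for p in sorted(pairs, key=lambda p: (p.rmsd, p.motif_a, p.motif_b))
    ]
    path.write_text("\n".join(header + body) + "\n")
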