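"""Base-pair and stacking annotations, and merging of two annotation sources.

Base pairs carry Leontis-Westhof classes: the interacting edge of each base
(W = Watson-Crick, H = Hoogsteen, S = Sugar) plus the cis/trans orientation of
the glycosidic bonds, written ``cWW``, ``tHS``, ...  Two annotation dialects
are read:

* DSSR-style listings, one interaction per line: ``A.G10 A.A25 tHS``
  (``chain.base+number``, insertion codes appended as ``^A``), stackings as
  ``A.G10 A.G11 stack`` or ``stack:upward``;
* FR3D-style unit-id listings: ``1ABC|1|A|G|10 1ABC|1|A|A|25 tHS`` with an
  optional sixth unit-id field for the insertion code.

Merging takes the union of agreeing interactions and resolves conflicts (two
classes reported at the same residue pair, or one nucleotide edge claimed by
two partners) in favour of the interaction class that occurs most often among
the source-agreeing interactions of the same chain.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import ContractError
from .io import MotifInstance, ResidueID

EDGES = ("W", "H", "S")
ORIENTATIONS = ("cis", "trans")

_STACK_KINDS = {
    "stack": "unspecified",
    "s35": "upward",
    "s53": "downward",
    "s33": "inward",
    "s55": "outward",
}
_FLIP_STACK = {
    "upward": "downward",
    "downward": "upward",
    "inward": "inward",
    "outward": "outward",
    "unspecified": "unspecified",
}


@dataclass(frozen=True)
class BasePair:
    """One base pair with endpoints in canonical (i < j) storage order."""

    i: ResidueID
    j: ResidueID
    edge_i: str
    edge_j: str
    orientation: str
    source: str = "merged"

    def __post_init__(self):
        if self.i == self.j:
            raise ContractError(f"base pair with identical endpoints {self.i}")
        if self.edge_i not in EDGES or self.edge_j not in EDGES:
            raise ContractError(f"unknown edge in {self.edge_i}/{self.edge_j}")
        if self.orientation not in ORIENTATIONS:
            raise ContractError(f"unknown orientation {self.orientation!r}")
        if self.j < self.i:  # canonicalize: swap endpoints and their edges
            i, j, ei, ej = self.j, self.i, self.edge_j, self.edge_i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)
            object.__setattr__(self, "edge_i", ei)
            object.__setattr__(self, "edge_j", ej)

    @property
    def class_label(self) -> str:
        return ("c" if self.orientation == "cis" else "t") + self.edge_i + self.edge_j

    @property
    def key(self) -> tuple[ResidueID, ResidueID]:
        return (self.i, self.j)


@dataclass(frozen=True)
class Stacking:
    """One base stacking; directional kinds flip when endpoints are swapped."""

    i: ResidueID
    j: ResidueID
    kind: str = "unspecified"
    source: str = "merged"

    def __post_init__(self):
        if self.i == self.j:
            raise ContractError(f"stacking with identical endpoints {self.i}")
        if self.kind not in _FLIP_STACK:
            raise ContractError(f"unknown stacking kind {self.kind!r}")
        if self.j < self.i:
            i, j = self.j, self.i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)
            object.__setattr__(self, "kind", _FLIP_STACK[self.kind])

    @property
    def key(self) -> tuple[ResidueID, ResidueID]:
        return (self.i, self.j)


@dataclass
class AnnotationSet:
    """All pair/stack annotations of one structure, with source provenance."""

    structure_id: str
    pairs: set[BasePair]
    stacks: set[Stacking]

    def restricted_to(self, rids: set[ResidueID]) -> "AnnotationSet":
        return AnnotationSet(
            self.structure_id,
            {p for p in self.pairs if p.i in rids and p.j in rids},
            {s for s in self.stacks if s.i in rids and s.j in rids},
        )


_DSSR_RES = re.compile(r"^(?P<chain>[^.]+)\.(?P<base>[A-Za-z]+)(?P<num>-?\d+)(\^(?P<icode>\w))?$")


def _parse_dssr_residue(token: str) -> ResidueID:
    m = _DSSR_RES.match(token)
    if not m:
        raise ContractError(f"cannot parse DSSR-style residue token {token!r}")
    return ResidueID(m.group("chain"), int(m.group("num")), m.group("icode") or "")


def _parse_unit_id(token: str) -> ResidueID:
    fields = token.split("|")
    if len(fields) < 5:
        raise ContractError(f"cannot parse unit-id token {token!r}")
    icode = fields[5] if len(fields) > 5 else ""
    return ResidueID(fields[2], int(fields[4]), icode)


def _parse_interaction_line(
    res_a: ResidueID, res_b: ResidueID, kind_token: str, source: str
) -> BasePair | Stacking:
    tok = kind_token.strip()
    low = tok.lower()
    if low in _STACK_KINDS:
        return Stacking(res_a, res_b, _STACK_KINDS[low], source)
    if low.startswith("stack:"):
        kind = low.split(":", 1)[1]
        if kind not in _FLIP_STACK:
            raise ContractError(f"unknown stacking kind {kind!r}")
        return Stacking(res_a, res_b, kind, source)
    if len(tok) == 3 and tok[0] in "ct" and tok[1].upper() in EDGES and tok[2].upper() in EDGES:
        orientation = "cis" if tok[0] == "c" else "trans"
        return BasePair(res_a, res_b, tok[1].upper(), tok[2].upper(), orientation, source)
    raise ContractError(f"cannot parse interaction class token {kind_token!r}")


def _read_annotation_file(path, structure_id, residue_parser, source) -> AnnotationSet:
    pairs: set[BasePair] = set()
    stacks: set[Stacking] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ContractError(f"{path}: expected 3 fields, got {len(fields)}: {raw!r}")
        a = residue_parser(fields[0])
        b = residue_parser(fields[1])
        inter = _parse_interaction_line(a, b, fields[2], source)
        if isinstance(inter, BasePair):
            pairs.add(inter)
        else:
            stacks.add(inter)
    return AnnotationSet(structure_id, pairs, stacks)


def read_dssr_annotations(path: str | Path, structure_id: str) -> AnnotationSet:
    """Read a DSSR-style pair/stack listing."""
    return _read_annotation_file(path, structure_id, _parse_dssr_residue, "DSSR")


def read_fr3d_annotations(path: str | Path, structure_id: str) -> AnnotationSet:
    """Read an FR3D-style unit-id pair/stack listing."""
    return _read_annotation_file(path, structure_id, _parse_unit_id, "FR3D")


def class_counts(context: AnnotationSet, chain_id: str | None = None) -> Counter:
    """Occurrences of each interaction class among ``context``'s annotations.

    When ``chain_id`` is given, only interactions whose first endpoint lies on
    that chain are counted (conflict frequencies are chain-local).
    """
    counts: Counter = Counter()
    for p in context.pairs:
        if chain_id is None or p.i.chain_id == chain_id:
            counts[p.class_label] += 1
    for s in context.stacks:
        if chain_id is None or s.i.chain_id == chain_id:
            counts["stack:" + s.kind] += 1
    return counts


def _choose(group: list, context: AnnotationSet, precounts: Counter | None):
    """Pick the winner of one conflict group by chain-wide class frequency."""
    if not group:
        raise ContractError("resolve_conflicts: empty conflict group")

    def label(x):
        return x.class_label if isinstance(x, BasePair) else "stack:" + x.kind

    def rank(x):
        chain = x.i.chain_id
        counts = precounts if precounts is not None else class_counts(context, chain)
        return (-counts[label(x)], 0 if x.source == "both" else 1, label(x))

    return min(sorted(group, key=lambda x: (label(x), x.i, x.j)), key=rank)


def resolve_conflicts(
    conflict_groups: list[list[BasePair]],
    chain_context: AnnotationSet,
    precomputed_counts: Counter | None = None,
) -> list[BasePair]:
    """Resolve each conflicting group to one interaction.

    Within a group the interaction whose (edge x edge x orientation) class is
    most frequent among the chain's agreeing interactions wins; ties prefer
    interactions asserted by both sources, then the lexicographically smaller
    class label.  Deterministic by construction.
    """
    return [_choose(g, chain_context, precomputed_counts) for g in conflict_groups]


def merge_annotations(
    a: AnnotationSet,
    b: AnnotationSet,
    precomputed_counts: Counter | None = None,
) -> AnnotationSet:
    """Merge two annotation sources for the same structure.

    Agreeing interactions are unioned (source ``both``); interactions seen by
    only one source are kept with their provenance; conflicts are resolved by
    :func:`resolve_conflicts`.  ``precomputed_counts`` substitutes corpus-wide
    class counts for the per-chain counts when supplied.
    """
    if a.structure_id != b.structure_id:
        raise ContractError(
            f"cannot merge annotations of {a.structure_id} with {b.structure_id}"
        )

    # --- pairs: group by unordered endpoint pair
    by_key: dict = defaultdict(dict)
    for p in a.pairs | b.pairs:
        cls = (p.edge_i, p.edge_j, p.orientation)
        sources = by_key[p.key].setdefault(cls, set())
        sources.add(p.source)

    agreeing: set[BasePair] = set()
    candidates: list[BasePair] = []
    site_conflicts: list[list[BasePair]] = []
    for key in sorted(by_key, key=lambda k: (k[0], k[1])):
        variants = []
        for (ei, ej, orient), sources in sorted(by_key[key].items()):
            src = "both" if len(sources) > 1 else next(iter(sources))
            variants.append(BasePair(key[0], key[1], ei, ej, orient, src))
        if len(variants) == 1:
            candidates.append(variants[0])
            if variants[0].source == "both":
                agreeing.add(variants[0])
        else:
            site_conflicts.append(variants)

    # --- stackings: group first so agreeing stacks join the frequency context
    stack_by_key: dict = defaultdict(dict)
    for s in a.stacks | b.stacks:
        stack_by_key[s.key].setdefault(s.kind, set()).add(s.source)
    stack_variants: dict = {}
    agreeing_stacks: set[Stacking] = set()
    for key in sorted(stack_by_key, key=lambda k: (k[0], k[1])):
        variants = []
        for kind, sources in sorted(stack_by_key[key].items()):
            src = "both" if len(sources) > 1 else next(iter(sources))
            variants.append(Stacking(key[0], key[1], kind, src))
        stack_variants[key] = variants
        if len(variants) == 1 and variants[0].source == "both":
            agreeing_stacks.add(variants[0])

    agree_ctx = AnnotationSet(a.structure_id, set(agreeing), agreeing_stacks)
    resolved = resolve_conflicts(site_conflicts, agree_ctx, precomputed_counts)
    candidates.extend(resolved)

    # --- enforce one partner per nucleotide edge
    by_edge: dict = defaultdict(list)
    for p in candidates:
        by_edge[(p.i, p.edge_i)].append(p)
        by_edge[(p.j, p.edge_j)].append(p)
    dropped: set[BasePair] = set()
    for edge_key in sorted(by_edge, key=lambda k: (k[0], k[1])):
        claimants = [p for p in by_edge[edge_key] if p not in dropped]
        if len(claimants) > 1:
            keep = _choose(claimants, agree_ctx, precomputed_counts)
            dropped.update(p for p in claimants if p != keep)
    pairs = {replace(p, source="both" if p.source == "both" else p.source)
             for p in candidates if p not in dropped}

    # --- stackings: same frequency rule on kind mismatches
    stacks: set[Stacking] = set()
    for key in sorted(stack_variants, key=lambda k: (k[0], k[1])):
        variants = stack_variants[key]
        if len(variants) == 1:
            stacks.add(variants[0])
        else:
            stacks.add(_choose(variants, agree_ctx, precomputed_counts))

    return AnnotationSet(a.structure_id, pairs, stacks)


def motif_interactions(ann: AnnotationSet, motif: MotifInstance) -> AnnotationSet:
    """Annotations restricted to interactions with both endpoints in the motif."""
    rids = {nt.rid for nt in motif.nucleotides}
    return ann.restricted_to(rids)


def write_motif_interactions(
    motif: MotifInstance, ann: AnnotationSet, path: str | Path
) -> None:
    """Write the per-motif interaction file (sequence line + interaction lines).

    Indices in interaction lines refer to 0-based positions in the
    concatenated segment order; segment boundaries are recorded on the header.
    """
    index = {nt.rid: k for k, nt in enumerate(motif.nucleotides)}
    restricted = motif_interactions(ann, motif)
    seg_lengths = ",".join(str(len(s)) for s in motif.segments)
    lines = [f">{motif.motif_id} {motif.family} segments={seg_lengths}", motif.sequence]
    for p in sorted(restricted.pairs, key=lambda p: (p.i, p.j)):
        lines.append(f"{index[p.i]} {index[p.j]} {p.class_label}")
    for s in sorted(restricted.stacks, key=lambda s: (s.i, s.j)):
        lines.append(f"{index[s.i]} {index[s.j]} stack:{s.kind}")
    Path(path).write_text("\n".join(lines) + "\n")
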