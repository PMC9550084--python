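"""Structure input, unit/fragment selection, and the effective-atom reduction.

A *structural unit* is the set of residues the 3D Gaussian hydrophobicity
field is fitted on: a complex, a single chain, or an explicitly given
residue range (a domain or an intrinsically disordered region).  Each
residue is reduced to one *effective atom* at the unweighted mean of its
atom coordinates; all downstream statistics operate on that point cloud.

PDB and mmCIF parsing is delegated to :mod:`gemmi`; only the first model
of multi-model (e.g. NMR) files is used and a single alternate-location
conformer is kept, so results are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueId",
    "UnitSelection",
    "EffectiveAtomSet",
    "DisulfideBond",
    "StructureError",
    "SelectionError",
    "load_structure",
    "select_unit",
    "effective_atoms",
    "detect_disulfides",
    "write_effective_pdb",
    "MODIFIED_RESIDUE_PARENTS",
    "WATER_NAMES",
]


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


class SelectionError(KeyError):
    """Raised when a chain or residue selection cannot be resolved."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


# Modified residues folded into their parent standard residue when the
# hydrophobicity scale is looked up.  User-extensible via the mapping
# argument of effective_atoms().
MODIFIED_RESIDUE_PARENTS = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "HYP": "PRO",  # 4-hydroxyproline
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "MLY": "LYS",  # N-methyl-lysine
    "CSO": "CYS",  # S-hydroxycysteine
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class ResidueId(NamedTuple):
    """Author-numbering identity of a residue (chain, number, insertion code)."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.number}{self.icode}"


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Å
    altloc: str = ""


@dataclass
class Residue:
    number: int
    icode: str
    name: str
    atoms: list[Atom]
    het: bool = False

    def rid(self, chain: str) -> ResidueId:
        return ResidueId(chain, self.number, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue]


@dataclass
class Structure:
    identifier: str
    chains: list[Chain]

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise SelectionError(
            f"chain {chain_id!r} not found; available: "
            f"{[c.id for c in self.chains]}"
        )


@dataclass
class UnitSelection:
    """A resolved structural-unit or fragment selection.

    ``residue_range`` is inclusive in author numbering, exactly as ranges
    are printed in structure tables (e.g. 100-116 means 17 residues on a
    gap-free chain).  Residues missing from the coordinate file inside the
    range are skipped and reported in ``skipped``.
    """

    structure_id: str
    chains: list[str]
    residue_range: Optional[tuple[int, int]]
    resolved: list[ResidueId]
    skipped: list[ResidueId] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.resolved)


@dataclass
class EffectiveAtomSet:
    """One point per residue at the mean of its atom coordinates."""

    residue_ids: list[ResidueId]
    positions: np.ndarray  # (N, 3) Å
    residue_names: list[str]

    @property
    def n(self) -> int:
        return len(self.residue_ids)

    def subset(self, mask: np.ndarray) -> "EffectiveAtomSet":
        idx = np.flatnonzero(mask)
        return EffectiveAtomSet(
            residue_ids=[self.residue_ids[i] for i in idx],
            positions=self.positions[idx],
            residue_names=[self.residue_names[i] for i in idx],
        )


@dataclass
class DisulfideBond:
    cys_a: ResidueId
    cys_b: ResidueId
    sg_distance: float
    # inclusive author-number range covered by the bond (same chain only)
    fragment: Optional[tuple[int, int]] = None


_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def load_structure(path: str | Path, format: str = "auto",
                   altloc: str = "A", model: int = 0) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only one model is kept (``model`` is a 0-based index, default the
    first — the deterministic choice for NMR ensembles).  Atoms whose
    alternate-location id is neither blank nor ``altloc`` are dropped,
    so each residue carries a single conformer.  Author residue
    numbering and insertion codes are preserved verbatim.
    """
    path = Path(path)
    if format not in _FORMAT_MAP:
        raise ValueError(f"unknown format {format!r}; use pdb, mmcif or auto")
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: structure contains no models")
    if not 0 <= model < len(st):
        raise StructureError(
            f"{path}: model index {model} out of range (has {len(st)})"
        )

    chains: list[Chain] = []
    for ch in st[model]:
        residues: list[Residue] = []
        for res in ch:
            atoms = []
            for at in res:
                if at.altloc not in ("", "\0", altloc):
                    continue
                pos = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
                if not np.all(np.isfinite(pos)):
                    continue
                atoms.append(Atom(at.name, at.element.name, pos, at.altloc))
            if atoms:
                residues.append(
                    Residue(
                        number=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        name=res.name.strip(),
                        atoms=atoms,
                        het=(res.het_flag == "H"),
                    )
                )
        if residues:
            chains.append(Chain(ch.name, residues))
    structure = Structure(identifier=st.name or path.stem, chains=chains)
    if not structure.chains:
        raise StructureError(f"{path}: no residues with atoms found")
    return structure


def select_unit(
    structure: Structure,
    chains: Optional[Sequence[str]] = None,
    residue_range: Optional[tuple[int, int]] = None,
) -> UnitSelection:
    """Resolve a structural unit: chains and an optional inclusive range.

    The range is inclusive in author numbering and applied per chain.
    Both endpoints must exist in at least one selected chain; author
    numbers inside the range that are absent from the file are recorded
    as ``skipped`` (unresolved residues are common inside IDRs).
    """
    chain_ids = list(chains) if chains else [c.id for c in structure.chains]
    selected = [structure.chain(cid) for cid in chain_ids]

    resolved: list[ResidueId] = []
    skipped: list[ResidueId] = []
    if residue_range is None:
        for ch in selected:
            resolved.extend(r.rid(ch.id) for r in ch.residues)
    else:
        start, end = residue_range
        if start > end:
            raise SelectionError(f"bad range {start}-{end}: start > end")
        endpoint_hits = {start: False, end: False}
        for ch in selected:
            present = {r.number for r in ch.residues}
            for num in (start, end):
                if num in present:
                    endpoint_hits[num] = True
            for r in ch.residues:
                if start <= r.number <= end:
                    resolved.append(r.rid(ch.id))
            for num in range(start, end + 1):
                if num not in present:
                    skipped.append(ResidueId(ch.id, num))
        missing = [n for n, hit in endpoint_hits.items() if not hit]
        if missing:
            avail = sorted({r.number for ch in selected for r in ch.residues})
            raise SelectionError(
                f"range endpoint(s) {missing} not found in chains "
                f"{chain_ids}; author numbers span "
                f"{avail[0]}..{avail[-1]}" if avail else "no residues"
            )
    if len(resolved) < 2:
        raise SelectionError(
            f"selection resolves to {len(resolved)} residue(s); need >= 2"
        )
    return UnitSelection(
        structure_id=structure.identifier,
        chains=chain_ids,
        residue_range=residue_range,
        resolved=resolved,
        skipped=skipped,
    )


def effective_atoms(
    structure: Structure,
    selection: UnitSelection,
    mapping: Optional[dict[str, str]] = None,
    include_het: bool = False,
) -> EffectiveAtomSet:
    """Reduce each selected residue to its effective atom.

    The effective atom is the unweighted arithmetic mean of all the
    residue's atom coordinates (hydrogens included when present in the
    file).  Waters are always excluded; other heteroresidues are kept
    only if mapped to a parent standard residue (``mapping``, default
    :data:`MODIFIED_RESIDUE_PARENTS`) or if ``include_het`` is set.
    """
    if mapping is None:
        mapping = MODIFIED_RESIDUE_PARENTS
    wanted = set(selection.resolved)
    rids: list[ResidueId] = []
    names: list[str] = []
    points: list[np.ndarray] = []
    for ch in structure.chains:
        for res in ch.residues:
            rid = res.rid(ch.id)
            if rid not in wanted:
                continue
            if res.name in WATER_NAMES:
                continue
            name = res.name
            if res.het and name not in mapping and not include_het:
                continue
            name = mapping.get(name, name)
            if not res.atoms:
                raise StructureError(f"residue {rid} has no atoms")
            coords = np.stack([a.pos for a in res.atoms])
            rids.append(rid)
            names.append(name)
            points.append(coords.mean(axis=0))
    if not points:
        raise SelectionError("selection yielded no usable residues")
    return EffectiveAtomSet(rids, np.stack(points), names)


def detect_disulfides(structure: Structure,
                      threshold: float = 2.3) -> list[DisulfideBond]:
    """Find CYS SG-SG pairs within ``threshold`` Å (default 2.3 Å).

    Each intra-chain bond also carries the inclusive author-number
    fragment (min, max) it covers, the notation used when reporting the
    hydrophobic-core status of disulfide-clamped chain segments.
    """
    sg: list[tuple[ResidueId, np.ndarray]] = []
    for ch in structure.chains:
        for res in ch.residues:
            if res.name not in ("CYS", "SEC"):
                continue
            for at in res.atoms:
                if at.name in ("SG", "SE"):
                    sg.append((res.rid(ch.id), at.pos))
                    break
    bonds: list[DisulfideBond] = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            rid_a, pa = sg[i]
            rid_b, pb = sg[j]
            if rid_a == rid_b:
                continue
            d = float(math.dist(pa, pb))
            if d <= threshold:
                frag = None
                if rid_a.chain == rid_b.chain:
                    lo, hi = sorted((rid_a.number, rid_b.number))
                    frag = (lo, hi)
                bonds.append(DisulfideBond(rid_a, rid_b, d, frag))
    bonds.sort(key=lambda b: (b.cys_a.chain, b.cys_a.number, b.cys_b.number))
    return bonds


def write_effective_pdb(atoms: EffectiveAtomSet, path: str | Path) -> None:
    """Write the effective-atom set as a CA-only fixed-column PDB file."""
    lines = []
    for serial, (rid, name, pos) in enumerate(
        zip(atoms.residue_ids, atoms.residue_names, atoms.positions), start=1
    ):
        lines.append(
            f"ATOM  {serial:5d}  CA  {name:>3s} {rid.chain[:1] or 'A'}"
            f"{rid.number:4d}{rid.icode[:1] or ' '}   "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
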