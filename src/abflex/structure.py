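"""Antibody Fv structures under the Chothia numbering convention.

The central container is :class:`AntibodyStructure`, an ordered list of
:class:`AtomRecord` objects carrying coordinates, B-factors and Chothia
residue identifiers (number + insertion code).  Structures are expected to
arrive already Chothia-numbered (as SAbDab files and antibody homology
models do); this module validates and slices but never renumbers.

Region definitions follow the Chothia CDR table used throughout the
analysis: L1 24-34, L2 50-56, L3 89-97 on the light chain; H1 26-35,
H2 50-56, H3 95-102 on the heavy chain; VH spans heavy 1-112 and VL spans
light 1-108 (the Fv truncation limits).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "AntibodyStructure",
    "RegionSelector",
    "REGIONS",
    "BACKBONE_ATOMS",
    "PDBParseError",
    "parse_antibody_structure",
    "parse_antibody_models",
    "truncate_to_fv",
    "select_region",
    "write_pdb",
    "loop_length",
]

#: Backbone atoms used for pebble collection and RMSD work.
BACKBONE_ATOMS = frozenset({"N", "CA", "C"})

#: Chothia region spans as (chain, first residue, last residue), inclusive.
REGIONS: dict[str, tuple[str, int, int]] = {
    "L1": ("L", 24, 34),
    "L2": ("L", 50, 56),
    "L3": ("L", 89, 97),
    "H1": ("H", 26, 35),
    "H2": ("H", 50, 56),
    "H3": ("H", 95, 102),
    "VH": ("H", 1, 112),
    "VL": ("L", 1, 108),
    # Heavy-chain framework: VH minus the three heavy CDRs.
    "FR_H": ("H", 1, 112),
}

_CDR_H = ((26, 35), (50, 56), (95, 102))


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of an antibody structure.

    Coordinates are in Angstrom, ``b_factor`` in Angstrom^2 and must be
    non-negative, ``occupancy`` is a fraction.  ``insertion_code`` is a
    single letter or ``""`` for un-inserted residues.
    """

    atom_name: str
    element: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    position: np.ndarray
    b_factor: float
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not np.isfinite(self.b_factor) or self.b_factor < 0:
            raise ValueError(f"atom {self.atom_name}: b_factor must be finite and >= 0")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class AntibodyStructure:
    """An ordered collection of atoms from one model of an Fv structure."""

    atoms: list[AtomRecord]
    model_id: int = 1
    numbering_scheme: str = field(default="chothia")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped by residue, in first-appearance order."""
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def validate(self) -> None:
        """Check the structural invariants the pipeline relies on.

        Requires at least one heavy-chain residue inside the CDR-H3 span
        and uniqueness of atoms within each residue.
        """
        seen: set[tuple[str, int, str, str]] = set()
        has_h3 = False
        for a in self.atoms:
            key = (*a.residue_key, a.atom_name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)
            if a.chain_id == "H" and 95 <= a.residue_number <= 102:
                has_h3 = True
        if not has_h3:
            raise ValueError("structure has no heavy-chain residues in the CDR-H3 span 95-102")


@dataclass(frozen=True)
class RegionSelector:
    """A named Chothia region with its inclusive (chain, start, end) span."""

    region_id: str
    span: tuple[str, int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.span is None:
            try:
                object.__setattr__(self, "span", REGIONS[self.region_id])
            except KeyError:
                raise ValueError(f"unknown region {self.region_id!r}; known: {sorted(REGIONS)}")

    def contains(self, atom: AtomRecord) -> bool:
        chain, start, end = self.span
        if atom.chain_id != chain or not (start <= atom.residue_number <= end):
            return False
        if self.region_id == "FR_H":
            return not any(lo <= atom.residue_number <= hi for lo, hi in _CDR_H)
        return True


# ---------------------------------------------------------------------------
# Parsing and writing


def _structure_from_gemmi_model(model: gemmi.Model, model_id: int) -> AntibodyStructure:
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            # Alternate locations: keep the highest-occupancy conformer of
            # each atom name (ties go to the first seen).
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > prev.occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                atoms.append(
                    AtomRecord(
                        atom_name=name,
                        element=at.element.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=res.seqid.icode.strip(),
                        residue_name=res.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_factor=max(at.b_iso, 0.0),
                        occupancy=at.occ,
                    )
                )
    return AntibodyStructure(atoms=atoms, model_id=model_id)


def _read_gemmi(pdb_text: str) -> gemmi.Structure:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                raise PDBParseError(f"malformed ATOM record at line {lineno}: {line!r}")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    return st


def parse_antibody_models(pdb_text: str) -> list[AntibodyStructure]:
    """Parse PDB text into one :class:`AntibodyStructure` per MODEL block."""
    st = _read_gemmi(pdb_text)
    models = [
        _structure_from_gemmi_model(m, int(m.num) if m.num > 0 else i + 1)
        for i, m in enumerate(st)
    ]
    models = [m for m in models if m.atoms]
    if not models:
        raise PDBParseError("no ATOM records for any chain found in PDB text")
    return models


def parse_antibody_structure(pdb_text: str, model_id: int | None = None) -> AntibodyStructure:
    """Parse one model from PDB text (the first, unless ``model_id`` is given)."""
    models = parse_antibody_models(pdb_text)
    if model_id is None:
        return models[0]
    for m in models:
        if m.model_id == model_id:
            return m
    raise PDBParseError(
        f"model {model_id} not present; available models: {[m.model_id for m in models]}"
    )


_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {elem:>2s}"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB column rule: 1-2 letter element symbols start in column 14 unless
    # the name is 4 characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(structures: AntibodyStructure | Sequence[AntibodyStructure]) -> str:
    """Render one or more models as standard PDB text.

    Multiple structures are wrapped in MODEL/ENDMDL blocks sharing one file,
    the layout used for conformational ensembles.
    """
    if isinstance(structures, AntibodyStructure):
        models: Sequence[AntibodyStructure] = [structures]
    else:
        models = list(structures)
    multi = len(models) > 1
    ids = [s.model_id for s in models]
    if len(set(ids)) != len(ids):  # colliding ids: renumber sequentially
        ids = list(range(1, len(models) + 1))
    lines: list[str] = []
    for s, mid in zip(models, ids):
        if multi:
            lines.append(f"MODEL     {mid:>4d}")
        for i, a in enumerate(s.atoms, start=1):
            lines.append(
                _PDB_ATOM_FMT.format(
                    serial=i,
                    name=_format_atom_name(a.atom_name, a.element),
                    alt=" ",
                    res=a.residue_name,
                    chain=a.chain_id,
                    resnum=a.residue_number,
                    icode=a.insertion_code or " ",
                    x=a.position[0],
                    y=a.position[1],
                    z=a.position[2],
                    occ=a.occupancy,
                    b=a.b_factor,
                    elem=a.element,
                )
            )
        lines.append("ENDMDL" if multi else "TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Slicing


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def truncate_to_fv(s: AntibodyStructure) -> AntibodyStructure:
    """Restrict a structure to the Fv region.

    Keeps light-chain residues 1-108 and heavy-chain residues 1-112 only;
    every other chain (antigen, duplicates) and all hetero content (waters,
    ions, ligands) is dropped.  Atom order is preserved, so the operation is
    idempotent.
    """
    kept = []
    for a in s.atoms:
        if a.residue_name not in _STANDARD_AA:
            continue
        if a.chain_id == "H" and 1 <= a.residue_number <= 112:
            kept.append(a)
        elif a.chain_id == "L" and 1 <= a.residue_number <= 108:
            kept.append(a)
    if not kept:
        raise ValueError("no Fv content: nothing left after truncation to L 1-108 / H 1-112")
    return AntibodyStructure(atoms=kept, model_id=s.model_id)


def select_region(
    s: AntibodyStructure,
    region: RegionSelector | str,
    atom_filter: Iterable[str] | None = None,
) -> list[AtomRecord]:
    """Atoms of ``s`` falling in a Chothia region, in structure order.

    Insertion-coded residues inside the numeric span (e.g. 100A, 100B within
    H3) are included.  ``atom_filter`` restricts the result to the named
    atoms, e.g. ``{"N", "CA", "C"}`` for the loop backbone.
    """
    if isinstance(region, str):
        region = RegionSelector(region)
    names = set(atom_filter) if atom_filter is not None else None
    out = [a for a in s.atoms if region.contains(a) and (names is None or a.atom_name in names)]
    if not out:
        chain, start, end = region.span
        avail = sorted({(a.chain_id, a.residue_number) for a in s.atoms})
        raise ValueError(
            f"region {region.region_id} ({chain} {start}-{end}) selects no atoms; "
            f"available residues: {avail[:40]}"
        )
    return out


def loop_length(s: AntibodyStructure, region: RegionSelector | str = "H3") -> int:
    """Number of residues present in a region, insertion codes included."""
    if isinstance(region, str):
        region = RegionSelector(region)
    return len({a.residue_key for a in s.atoms if region.contains(a)})
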