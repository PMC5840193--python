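"""Molecular constraint networks for body-bar rigidity analysis.

A structure is converted into a multigraph whose bodies are atoms and whose
edges carry 2, 5 or 6 bars:

===============================  =====  =========================================
edge kind                        bars   examples
===============================  =====  =========================================
``covalent_rotatable``           5      N-CA (phi), CA-C (psi), chi bonds, S-S
``covalent_locked``              6      peptide C-N (omega), C=O, sp2 rings,
                                        bonds to hydrogen
``hbond``                        5      hydrogen bond, kept while its energy
                                        is at or below the dilution cutoff
``tether``                       2      hydrophobic C/S contact
===============================  =====  =========================================

Hydrogen bonds are scored with a Mayo-style energy: a 12-10 radial well of
depth ``V0 = 8`` kcal/mol at donor--acceptor distance ``R0 = 2.8`` A,
modulated by an angular factor in ``[0, 1]`` built from the donor-H-acceptor
angle and the H-acceptor-base angle relative to the acceptor's
hybridization ideal.  Salt bridges get a flat -10 kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import AntibodyStructure, AtomRecord

__all__ = [
    "HydrogenBond",
    "ConstraintEdge",
    "ConstraintNetwork",
    "hbond_energy",
    "detect_hbonds",
    "detect_tethers",
    "build_constraint_network",
    "covalent_bonds",
    "add_polar_hydrogens",
    "MissingHydrogensError",
]

V0 = 8.0  # kcal/mol, well depth of the hydrogen-bond radial term
R0 = 2.8  # A, equilibrium donor-acceptor distance
SALT_BRIDGE_ENERGY = -10.0  # kcal/mol, flat
MAX_DA = 3.6  # A, donor-acceptor screen
MAX_HA = 2.6  # A, hydrogen-acceptor screen
MIN_DHA_DEG = 110.0  # donor-H-acceptor angle screen
TETHER_SLOP = 0.25  # A added to the vdW sum for hydrophobic tethers
_VDW = {"C": 1.7, "S": 1.8}

BARS = {"covalent_rotatable": 5, "covalent_locked": 6, "hbond": 5, "tether": 2}


class MissingHydrogensError(ValueError):
    """Structure has no polar hydrogens and placement fallback is disabled."""


@dataclass(frozen=True)
class HydrogenBond:
    """A detected hydrogen bond, atoms given as indices into the structure."""

    donor: int
    hydrogen: int
    acceptor: int
    energy: float  # kcal/mol, <= 0 for accepted bonds


@dataclass(frozen=True)
class ConstraintEdge:
    i: int
    j: int
    bars: int
    kind: str
    energy: float | None = None


@dataclass
class ConstraintNetwork:
    """Bodies (atoms) plus the bar-weighted constraint multiset."""

    atoms: list[AtomRecord]
    edges: list[ConstraintEdge]

    @property
    def n_bodies(self) -> int:
        return len(self.atoms)

    def bar_triples(self) -> list[tuple[int, int, int]]:
        return [(e.i, e.j, e.bars) for e in self.edges]

    def to_text(self) -> str:
        """Edge-list serialization used for debugging and oracle cross-checks."""
        lines = [f"# bodies {self.n_bodies}"]
        for e in self.edges:
            en = "" if e.energy is None else f" {e.energy:.6f}"
            lines.append(f"{e.i} {e.j} {e.bars} {e.kind}{en}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Residue covalent templates (heavy atoms; hydrogens attach by distance).
# Each entry: (atom1, atom2, locked).  Locked bonds are double bonds, sp2
# ring bonds and other dihedral-locked linkages and carry 6 bars; the rest
# are rotatable single bonds with 5 bars.

_BB = [("N", "CA", False), ("CA", "C", False), ("C", "O", True), ("C", "OXT", True)]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, bool]]] = {
    "GLY": [],
    "ALA": [("CA", "CB", False)],
    "SER": [("CA", "CB", False), ("CB", "OG", False)],
    "CYS": [("CA", "CB", False), ("CB", "SG", False)],
    "THR": [("CA", "CB", False), ("CB", "OG1", False), ("CB", "CG2", False)],
    "VAL": [("CA", "CB", False), ("CB", "CG1", False), ("CB", "CG2", False)],
    "LEU": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", False), ("CG", "CD2", False)],
    "ILE": [("CA", "CB", False), ("CB", "CG1", False), ("CB", "CG2", False), ("CG1", "CD1", False)],
    "MET": [("CA", "CB", False), ("CB", "CG", False), ("CG", "SD", False), ("SD", "CE", False)],
    "PRO": [("CA", "CB", True), ("CB", "CG", True), ("CG", "CD", True), ("CD", "N", True)],
    "PHE": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True), ("CD1", "CE1", True),
            ("CE1", "CZ", True), ("CZ", "CE2", True), ("CE2", "CD2", True), ("CD2", "CG", True)],
    "TYR": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True), ("CD1", "CE1", True),
            ("CE1", "CZ", True), ("CZ", "CE2", True), ("CE2", "CD2", True), ("CD2", "CG", True),
            ("CZ", "OH", False)],
    "TRP": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True), ("CD1", "NE1", True),
            ("NE1", "CE2", True), ("CE2", "CD2", True), ("CD2", "CG", True), ("CE2", "CZ2", True),
            ("CZ2", "CH2", True), ("CH2", "CZ3", True), ("CZ3", "CE3", True), ("CE3", "CD2", True)],
    "HIS": [("CA", "CB", False), ("CB", "CG", False), ("CG", "ND1", True), ("ND1", "CE1", True),
            ("CE1", "NE2", True), ("NE2", "CD2", True), ("CD2", "CG", True)],
    "ASP": [("CA", "CB", False), ("CB", "CG", False), ("CG", "OD1", True), ("CG", "OD2", True)],
    "ASN": [("CA", "CB", False), ("CB", "CG", False), ("CG", "OD1", True), ("CG", "ND2", True)],
    "GLU": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False), ("CD", "OE1", True),
            ("CD", "OE2", True)],
    "GLN": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False), ("CD", "OE1", True),
            ("CD", "NE2", True)],
    "LYS": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False), ("CD", "CE", False),
            ("CE", "NZ", False)],
    "ARG": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False), ("CD", "NE", False),
            ("NE", "CZ", True), ("CZ", "NH1", True), ("CZ", "NH2", True)],
}

_SALT_DONORS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("HIS", "ND1"), ("HIS", "NE2")}
_SALT_ACCEPTORS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

_PEPTIDE_MAX = 2.0  # A, sanity bound on C(i)-N(i+1)
_SS_MAX = 2.5  # A, disulfide SG-SG
_H_ATTACH_MAX = 1.3  # A, hydrogen to parent heavy atom


def covalent_bonds(s: AntibodyStructure) -> list[tuple[int, int, bool]]:
    """Covalent bond list ``(i, j, locked)`` from residue templates.

    Adds inter-residue peptide links (locked) between consecutive residues
    whose C-N distance is below 2 A, disulfides (rotatable) between SG pairs
    below 2.5 A, and attaches every hydrogen to its nearest heavy atom
    within 1.3 A as a locked bond.
    """
    bonds: list[tuple[int, int, bool]] = []
    residues = s.residues()
    index: dict[tuple[tuple[str, int, str], str], int] = {}
    for i, a in enumerate(s.atoms):
        index.setdefault((a.residue_key, a.atom_name), i)

    for key, atoms in residues.items():
        name = atoms[0].residue_name
        if name not in RESIDUE_TEMPLATES:
            raise ValueError(f"no covalent template for residue {name} at {key}")
        for a1, a2, locked in _BB + RESIDUE_TEMPLATES[name]:
            i = index.get((key, a1))
            j = index.get((key, a2))
            if i is not None and j is not None:
                bonds.append((i, j, locked))

    # peptide links between consecutive residues of the same chain
    keys = list(residues)
    for k0, k1 in zip(keys, keys[1:]):
        if k0[0] != k1[0]:
            continue
        i = index.get((k0, "C"))
        j = index.get((k1, "N"))
        if i is not None and j is not None:
            d = float(np.linalg.norm(s.atoms[i].position - s.atoms[j].position))
            if d <= _PEPTIDE_MAX:
                bonds.append((i, j, True))

    # disulfides
    sgs = [i for i, a in enumerate(s.atoms) if a.atom_name == "SG"]
    for x in range(len(sgs)):
        for y in range(x + 1, len(sgs)):
            i, j = sgs[x], sgs[y]
            if np.linalg.norm(s.atoms[i].position - s.atoms[j].position) <= _SS_MAX:
                bonds.append((i, j, False))

    # hydrogens: nearest heavy atom within reach, locked
    heavy = [i for i, a in enumerate(s.atoms) if a.element != "H"]
    hydro = [i for i, a in enumerate(s.atoms) if a.element == "H"]
    if hydro and heavy:
        tree = cKDTree(np.array([s.atoms[i].position for i in heavy]))
        for h in hydro:
            d, k = tree.query(s.atoms[h].position, k=1)
            if d <= _H_ATTACH_MAX:
                bonds.append((heavy[int(k)], h, True))
    return bonds


def _adjacency(n: int, bonds: Iterable[tuple[int, int, bool]]) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _within_bond_distance(adj: list[list[int]], start: int, maxdepth: int) -> set[int]:
    seen = {start}
    frontier = [start]
    for _ in range(maxdepth):
        nxt = []
        for x in frontier:
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    nxt.append(y)
        frontier = nxt
    return seen


# ---------------------------------------------------------------------------
# Hydrogen-bond energy and detection


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-8 or nv < 1e-8:
        raise ValueError("degenerate geometry: coincident atoms in angle evaluation")
    return float(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))


def hbond_energy(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    acceptor_base: np.ndarray | None = None,
    acceptor_sp2: bool = True,
) -> float:
    """Mayo-style hydrogen-bond energy in kcal/mol.

    ``E = V0 * (5 (R0/R_DA)^12 - 6 (R0/R_DA)^10) * F`` with the angular
    factor ``F = cos^2(theta_DHA) * cos^2(phi - phi0)`` clamped to [0, 1];
    ``phi`` is the H-acceptor-base angle and ``phi0`` the hybridization
    ideal (120 deg for sp2 acceptors, 109.5 deg for sp3).  Without an
    acceptor base only the theta term is applied.  At ideal geometry and
    ``R_DA = R0`` the energy is exactly ``-V0``; it decays to zero at long
    range.
    """
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    r_da = float(np.linalg.norm(donor - acceptor))
    if r_da < 1e-8:
        raise ValueError("degenerate geometry: donor and acceptor coincide")
    ratio = R0 / r_da
    radial = V0 * (5.0 * ratio**12 - 6.0 * ratio**10)
    theta = _angle(donor, hydrogen, acceptor)
    f = math.cos(theta) ** 2
    if acceptor_base is not None:
        phi = _angle(hydrogen, acceptor, np.asarray(acceptor_base, float))
        phi0 = math.radians(120.0 if acceptor_sp2 else 109.47)
        f *= math.cos(phi - phi0) ** 2
    return radial * min(max(f, 0.0), 1.0)


def add_polar_hydrogens(s: AntibodyStructure) -> AntibodyStructure:
    """Place backbone amide hydrogens by ideal in-plane geometry.

    Fallback for structures deposited without hydrogens: H is set 1.01 A
    from N along the direction opposing the bisector of the N-CA and N-C'
    bonds (trans-amide plane).  Prolines and chain-start nitrogens are
    skipped.  Side-chain protonation is not attempted.
    """
    residues = list(s.residues().items())
    new_atoms = list(s.atoms)
    for (key, atoms), prev in zip(residues, [None] + residues[:-1]):
        if atoms[0].residue_name == "PRO" or prev is None or prev[0][0] != key[0]:
            continue
        names = {a.atom_name: a for a in atoms}
        prev_names = {a.atom_name: a for a in prev[1]}
        if "N" not in names or "CA" not in names or "C" not in prev_names:
            continue
        if any(a.atom_name == "H" for a in atoms):
            continue
        n = names["N"].position
        u = (prev_names["C"].position - n)
        v = (names["CA"].position - n)
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        d = -(u + v)
        d /= np.linalg.norm(d)
        new_atoms.append(
            AtomRecord("H", "H", key[0], key[1], key[2], atoms[0].residue_name,
                       n + 1.01 * d, b_factor=names["N"].b_factor,
                       occupancy=names["N"].occupancy)
        )
    return AntibodyStructure(atoms=new_atoms, model_id=s.model_id)


def detect_hbonds(
    s: AntibodyStructure,
    place_missing_hydrogens: bool = False,
) -> list[HydrogenBond]:
    """Find hydrogen bonds passing the geometric screens.

    Screens: donor-acceptor <= 3.6 A, hydrogen-acceptor <= 2.6 A,
    donor-H-acceptor angle >= 110 deg, donor and acceptor separated by more
    than three covalent bonds, and a negative energy.  Salt bridges between
    Lys/Arg/His nitrogens and Asp/Glu carboxylates are assigned a flat
    -10 kcal/mol.  The list is sorted strongest (most negative) first.

    Raises :class:`MissingHydrogensError` if the structure carries no
    hydrogens and the in-plane placement fallback is disabled.
    """
    if not any(a.element == "H" for a in s.atoms):
        if not place_missing_hydrogens:
            raise MissingHydrogensError(
                "structure has no hydrogens; protonate it or pass place_missing_hydrogens=True"
            )
        s = add_polar_hydrogens(s)
        if not any(a.element == "H" for a in s.atoms):
            return []

    bonds = covalent_bonds(s)
    adj = _adjacency(len(s.atoms), bonds)
    pos = s.coords()

    donors: list[tuple[int, int]] = []  # (heavy donor, hydrogen)
    for i, j, _ in bonds:
        ai, aj = s.atoms[i], s.atoms[j]
        if aj.element == "H" and ai.element in ("N", "O", "S"):
            donors.append((i, j))
        elif ai.element == "H" and aj.element in ("N", "O", "S"):
            donors.append((j, i))
    acceptors = [i for i, a in enumerate(s.atoms) if a.element in ("N", "O", "S")]
    if not donors or not acceptors:
        return []

    acc_tree = cKDTree(pos[acceptors])
    found: list[HydrogenBond] = []
    for d, h in donors:
        near = _within_bond_distance(adj, d, 3)
        for k in acc_tree.query_ball_point(pos[d], MAX_DA):
            a = acceptors[k]
            if a in near or a == h:
                continue
            if np.linalg.norm(pos[d] - pos[a]) > MAX_DA:
                continue
            if np.linalg.norm(pos[h] - pos[a]) > MAX_HA:
                continue
            if math.degrees(_angle(pos[d], pos[h], pos[a])) < MIN_DHA_DEG:
                continue
            ad, aa = s.atoms[d], s.atoms[a]
            if ((ad.residue_name, ad.atom_name) in _SALT_DONORS
                    and (aa.residue_name, aa.atom_name) in _SALT_ACCEPTORS):
                found.append(HydrogenBond(d, h, a, SALT_BRIDGE_ENERGY))
                continue
            base = next((x for x in adj[a] if s.atoms[x].element != "H"), None)
            energy = hbond_energy(
                pos[d], pos[h], pos[a],
                acceptor_base=None if base is None else pos[base],
                acceptor_sp2=_acceptor_is_sp2(s, a, adj),
            )
            if energy < 0.0:
                found.append(HydrogenBond(d, h, a, energy))
    found.sort(key=lambda b: (b.energy, b.donor, b.acceptor))
    return found


def _acceptor_is_sp2(s: AntibodyStructure, a: int, adj: list[list[int]]) -> bool:
    atom = s.atoms[a]
    if atom.element == "O" and any(s.atoms[x].element == "C" for x in adj[a]):
        return True  # carbonyl / carboxylate / amide oxygen
    return atom.atom_name in {"ND1", "NE2", "NE1", "O"}


def detect_tethers(s: AntibodyStructure) -> list[ConstraintEdge]:
    """Hydrophobic tethers: C/S pairs within the vdW sum plus 0.25 A.

    Pairs from the same residue or within three covalent bonds are skipped
    (those contacts are already fixed by the covalent network).  Each tether
    contributes a 2-bar edge.
    """
    bonds = covalent_bonds(s)
    adj = _adjacency(len(s.atoms), bonds)
    idx = [i for i, a in enumerate(s.atoms) if a.element in ("C", "S")]
    if len(idx) < 2:
        return []
    pos = s.coords()[idx]
    tree = cKDTree(pos)
    maxcut = 2 * _VDW["S"] + TETHER_SLOP
    out: list[ConstraintEdge] = []
    for x, y in sorted(tree.query_pairs(maxcut)):
        i, j = idx[x], idx[y]
        ai, aj = s.atoms[i], s.atoms[j]
        if ai.residue_key == aj.residue_key:
            continue
        cut = _VDW[ai.element] + _VDW[aj.element] + TETHER_SLOP
        if np.linalg.norm(ai.position - aj.position) > cut:
            continue
        if j in _within_bond_distance(adj, i, 3):
            continue
        out.append(ConstraintEdge(i, j, BARS["tether"], "tether"))
    return out


def build_constraint_network(
    s: AntibodyStructure,
    cutoff: float,
    hbonds: Sequence[HydrogenBond] | None = None,
    tethers: Sequence[ConstraintEdge] | None = None,
    place_missing_hydrogens: bool = False,
) -> ConstraintNetwork:
    """Assemble the constraint multigraph at a hydrogen-bond energy cutoff.

    Covalent topology and hydrophobic tethers are always present; a
    hydrogen bond enters iff its energy is at or below ``cutoff`` (bonds
    weaker than the cutoff are diluted away).  Pre-computed ``hbonds`` /
    ``tethers`` may be passed to avoid re-detection during a sweep.
    """
    if cutoff > 0:
        raise ValueError(f"cutoff must be <= 0 kcal/mol, got {cutoff}")
    edges: list[ConstraintEdge] = []
    for i, j, locked in covalent_bonds(s):
        kind = "covalent_locked" if locked else "covalent_rotatable"
        edges.append(ConstraintEdge(i, j, BARS[kind], kind))
    if tethers is None:
        tethers = detect_tethers(s)
    edges.extend(tethers)
    if hbonds is None:
        hbonds = detect_hbonds(s, place_missing_hydrogens=place_missing_hydrogens)
    for hb in hbonds:
        if hb.energy <= cutoff:
            edges.append(ConstraintEdge(hb.hydrogen, hb.acceptor, BARS["hbond"], "hbond", hb.energy))
    return ConstraintNetwork(atoms=list(s.atoms), edges=edges)
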