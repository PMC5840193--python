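"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three data classes the analysis consumes:

* :func:`make_toy_loop` -- an ideal-geometry polypeptide "CDR-H3" loop
  (Chothia-numbered H 95-102 with insertion codes beyond length 8)
  attached to a short scaffold segment, with a programmable backbone
  hydrogen-bond network: each planned bond is realized geometrically, by
  optimizing the intervening phi/psi torsions until the Mayo energy of the
  donor-H/acceptor pair matches the requested value, so that hydrogen-bond
  detection recovers exactly the plan.  The ground-truth record carries the
  theoretical DOF maximum ``2L + 6`` and the cutoffs at which the dilution
  profile must step.
* :func:`make_bfactor_cohort` -- cohorts of minimal C-alpha-only V_H
  structures whose CDR-H3 B-factors are shifted by a controllable number
  of chain SDs in one group, for calibration and power studies of the
  cohort statistics.
* :func:`make_ensemble` -- multi-frame coordinate ensembles around a base
  structure with per-region Gaussian jitter, or a multi-conformer mode with
  well-separated clusters for testing representative selection.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import network as net
from .ensembles import CoordinateEnsemble
from .structure import AntibodyStructure, AtomRecord

__all__ = [
    "ToyLoopSpec",
    "ToyLoopTruth",
    "ToyLoopError",
    "chothia_h3_numbers",
    "make_toy_loop",
    "make_bfactor_cohort",
    "make_ensemble",
]


class ToyLoopError(ValueError):
    """The requested hydrogen-bond plan cannot be realized geometrically."""


# ideal backbone geometry (lengths in A, angles in degrees)
_B_NCA, _B_CAC, _B_CN, _B_CO, _B_NH, _B_CACB = 1.458, 1.525, 1.329, 1.231, 1.010, 1.521
_A_CNCA, _A_NCAC, _A_CACN, _A_CACO, _A_CNH, _A_NCACB = 121.7, 111.2, 116.2, 120.8, 119.0, 110.4


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float,
           torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame: position D from A-B-C internal coords."""
    theta = math.radians(theta_deg)
    tors = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(theta), r * math.sin(theta) * math.cos(tors),
                  r * math.sin(theta) * math.sin(tors)])
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass(frozen=True)
class ToyLoopSpec:
    """Recipe for a synthetic loop with a known hydrogen-bond network.

    ``hbond_plan`` lists ``(donor_residue, acceptor_residue, energy)``
    with residues as 1-based loop indices: the backbone amide N-H of the
    donor residue donates to the backbone carbonyl O of the acceptor
    residue.  Energies must lie in [-7, 0).  ``scaffold_len`` residues
    precede the loop (numbered below Chothia 95).
    """

    loop_length: int
    scaffold_len: int = 2
    hbond_plan: tuple[tuple[int, int, float], ...] = ()
    bfactor_base: float = 20.0
    bfactor_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loop_length < 1:
            raise ValueError("loop_length must be >= 1")
        if self.scaffold_len < 1:
            raise ValueError("scaffold_len must be >= 1")
        for d, a, e in self.hbond_plan:
            if not (1 <= d <= self.loop_length and 1 <= a <= self.loop_length):
                raise ValueError(f"plan bond ({d},{a}) outside loop 1..{self.loop_length}")
            if not (-7.0 <= e < 0.0):
                raise ValueError(f"plan energy {e} outside [-7, 0)")
            if abs(d - a) < 2:
                raise ToyLoopError(
                    f"donor/acceptor pair ({d},{a}) out of reach: separated by < 2 residues"
                )


@dataclass
class ToyLoopTruth:
    """Everything needed to predict pipeline outputs without running it."""

    loop_len: int
    max_dof: int  # 2L + 6
    bond_energies: list[float]  # planned energies, strongest first
    loop_residue_keys: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def step_cutoffs(self) -> list[float]:
        """Cutoffs at which the DOF profile steps (one per distinct energy)."""
        return sorted(set(self.bond_energies))


def chothia_h3_numbers(length: int) -> list[tuple[int, str]]:
    """Chothia numbering for a CDR-H3 of the given length.

    Length 8 maps to 95..102; longer loops insert lettered residues after
    100 (100A, 100B, ...); shorter loops run 95..94+length.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length <= 8:
        return [(95 + i, "") for i in range(length)]
    nums = [(n, "") for n in range(95, 101)]
    nums += [(100, chr(ord("A") + i)) for i in range(length - 8)]
    nums += [(101, ""), (102, "")]
    return nums


def _build_chain(n_res: int, phi: np.ndarray, psi: np.ndarray,
                 with_cb: np.ndarray) -> dict[tuple[int, str], np.ndarray]:
    """Ideal-geometry backbone from torsions; returns atom -> position.

    Residues are 0-indexed; omega is fixed trans (180 deg).  ``with_cb``
    flags which residues get a C-beta (alanine vs glycine).  Amide H is
    placed in the peptide plane, trans to the carbonyl O, from residue 1 on.
    """
    pos: dict[tuple[int, str], np.ndarray] = {}
    # seed residue 0
    pos[(0, "N")] = np.zeros(3)
    pos[(0, "CA")] = np.array([_B_NCA, 0.0, 0.0])
    pos[(0, "C")] = _place(np.array([0.0, 1.0, 0.0]), pos[(0, "N")], pos[(0, "CA")],
                           _B_CAC, _A_NCAC, phi[0])
    for i in range(n_res):
        n, ca, c = pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")]
        if i + 1 < n_res:
            nn = _place(n, ca, c, _B_CN, _A_CACN, psi[i])
            pos[(i + 1, "N")] = nn
            pos[(i + 1, "CA")] = _place(ca, c, nn, _B_NCA, _A_CNCA, 180.0)  # omega trans
            pos[(i + 1, "C")] = _place(c, nn, pos[(i + 1, "CA")], _B_CAC, _A_NCAC, phi[i + 1])
            pos[(i, "O")] = _place(nn, ca, c, _B_CO, _A_CACO, 180.0)  # anti to next N... via improper
            # H on next residue's N, trans to this carbonyl O (in-plane)
            pos[(i + 1, "H")] = _place(ca, c, nn, _B_NH, _A_CNH, 0.0)
        else:
            pos[(i, "O")] = _place(n, ca, c, _B_CO, _A_CACO, psi[i] + 180.0)
        if with_cb[i]:
            pos[(i, "CB")] = _place(c, n, ca, _B_CACB, _A_NCACB, -122.6)
    return pos


def _fix_terminal_o(pos, i, n_res):  # pragma: no cover - helper kept for clarity
    return pos


def _chain_to_structure(spec: ToyLoopSpec, pos: dict, names: list[str],
                        numbering: list[tuple[int, str]],
                        bfac: dict[int, float]) -> AntibodyStructure:
    atoms: list[AtomRecord] = []
    n_res = spec.scaffold_len + spec.loop_length
    order = ["N", "H", "CA", "CB", "C", "O"]
    for i in range(n_res):
        num, icode = numbering[i]
        for name in order:
            if (i, name) not in pos:
                continue
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=name[0],
                    chain_id="H",
                    residue_number=num,
                    insertion_code=icode,
                    residue_name=names[i],
                    position=pos[(i, name)].copy(),
                    b_factor=bfac[i],
                )
            )
    return AntibodyStructure(atoms=atoms, model_id=1)


def make_toy_loop(spec: ToyLoopSpec) -> tuple[AntibodyStructure, ToyLoopTruth]:
    """Build the loop and verify its hydrogen-bond network against the plan.

    The chain starts fully extended (phi = psi = 180 deg).  For each
    planned bond the torsions of the residues between donor and acceptor
    are optimized so that the donor-H ... acceptor-O geometry reproduces
    the requested Mayo energy with near-ideal angles, while keeping every
    unplanned polar pair outside the detection screens and every carbon
    pair outside tether range on the loop.  The result is validated by
    running the actual detectors; any discrepancy raises
    :class:`ToyLoopError` (infeasible plan).
    """
    n_res = spec.scaffold_len + spec.loop_length
    loop0 = spec.scaffold_len  # 0-based index of first loop residue
    # glycine at engineered-bond sites, alanine elsewhere
    special = {loop0 + d - 1 for d, _, _ in spec.hbond_plan}
    special |= {loop0 + a - 1 for _, a, _ in spec.hbond_plan}
    names = ["GLY" if i in special else "ALA" for i in range(n_res)]
    with_cb = np.array([nm == "ALA" for nm in names])

    scaffold_first = 95 - spec.scaffold_len
    numbering = [(scaffold_first + i, "") for i in range(spec.scaffold_len)]
    numbering += chothia_h3_numbers(spec.loop_length)

    phi = np.full(n_res, 180.0)
    psi = np.full(n_res, 180.0)

    bonds = [(loop0 + d - 1, loop0 + a - 1, e) for d, a, e in spec.hbond_plan]
    if bonds:
        phi, psi = _engineer_bonds(spec, n_res, phi, psi, with_cb, bonds)

    pos = _build_chain(n_res, phi, psi, with_cb)
    rng = np.random.default_rng(spec.seed)
    bfac = {i: float(max(spec.bfactor_base + spec.bfactor_sd * rng.standard_normal(), 0.1))
            for i in range(n_res)}
    s = _chain_to_structure(spec, pos, names, numbering, bfac)

    truth = ToyLoopTruth(
        loop_len=spec.loop_length,
        max_dof=2 * spec.loop_length + 6,
        bond_energies=sorted(e for _, _, e in spec.hbond_plan),
        loop_residue_keys=[("H", n, ic) for n, ic in numbering[spec.scaffold_len:]],
    )
    _verify_toy_loop(s, spec, truth, numbering)
    return s, truth


def _bond_atoms(pos: dict, di: int, ai: int):
    return pos.get((di, "H")), pos.get((di, "N")), pos.get((ai, "O")), pos.get((ai, "C"))


def _engineer_bonds(spec: ToyLoopSpec, n_res, phi0, psi0, with_cb, bonds):
    """Realize the planned bonds by bending the chain, one bond at a time.

    Each bond adjusts only the phi/psi torsions of the residues between its
    donor and acceptor, so the windows of different bonds must not overlap;
    the chain outside a window keeps its current conformation.  Guard terms
    keep every unplanned polar pair and every loop carbon pair outside the
    detection and tether screens globally.
    """
    windows = sorted((min(di, ai), max(di, ai)) for di, ai, _ in bonds)
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 <= a1:
            raise ToyLoopError(
                f"bond windows {a0}-{a1} and {b0}-{b1} overlap; plan infeasible"
            )
    planned = {(di, ai) for di, ai, _ in bonds}
    # fixed atom ordering so guard pairs can be evaluated vectorized
    probe = _build_chain(n_res, phi0, psi0, with_cb)
    atom_keys = list(probe)
    key_index = {k: i for i, k in enumerate(atom_keys)}
    guard = [(key_index[a], key_index[b], thr)
             for a, b, thr in _guard_pairs(n_res, with_cb, planned)
             if a in key_index and b in key_index]
    gi = np.array([g[0] for g in guard], dtype=int)
    gj = np.array([g[1] for g in guard], dtype=int)
    gt = np.array([g[2] for g in guard])

    phi = phi0.copy()
    psi = psi0.copy()
    rng = np.random.default_rng(spec.seed + 7)

    for di, ai, energy in sorted(bonds, key=lambda b: min(b[0], b[1])):
        lo, hi = min(di, ai), max(di, ai)
        var_keys = [(i, kind) for i in range(max(lo, 1), hi + 1) for kind in ("phi", "psi")]

        theta_target = math.pi  # bent-geometry retries lower this

        def residuals(x: np.ndarray) -> np.ndarray:
            for val, (i, kind) in zip(x, var_keys):
                (phi if kind == "phi" else psi)[i] = val
            pos = _build_chain(n_res, phi, psi, with_cb)
            h, n, o, c = _bond_atoms(pos, di, ai)
            if h is None:
                raise ToyLoopError(f"donor residue {di} has no amide hydrogen")
            r_da = float(np.linalg.norm(n - o))
            theta = _angle3(n, h, o)
            phi_ab = _angle3(h, o, c)
            if r_da < 2.2:  # keep the r^-12 wall out of the line search
                e_act = 50.0
            else:
                e_act = min(net.hbond_energy(n, h, o, acceptor_base=c, acceptor_sp2=True), 50.0)
            r_ha = float(np.linalg.norm(h - o))
            # energy drives; angles only need to stay clear of the
            # detection screens (weak bonds live at off-ideal geometry)
            res = [
                20.0 * (e_act - energy),
                0.3 * (theta - theta_target),
                0.3 * (phi_ab - math.radians(120.0)),
                5.0 * max(0.0, math.radians(125.0) - theta),
                5.0 * max(0.0, r_da - 3.5),
                5.0 * max(0.0, r_ha - 2.5),
            ]
            p = np.stack([pos[k] for k in atom_keys])
            d = np.linalg.norm(p[gi] - p[gj], axis=1)
            res.extend(3.0 * np.maximum(0.0, gt - d))
            return np.asarray(res)

        # start from a helical turn inside the window: the classic i -> i-4
        # amide-to-carbonyl geometry is nearly feasible from there; weak
        # bonds may need a bent donor angle, tried on retry
        sol = None
        for attempt, th_deg in enumerate((180.0, 145.0, 180.0, 135.0)):
            theta_target = math.radians(th_deg)
            x0 = np.array(
                [(-60.0 if kind == "phi" else -45.0) + (3.0 + 4.0 * attempt)
                 * rng.standard_normal() for _, kind in var_keys]
            )
            sol = least_squares(residuals, x0, method="lm", max_nfev=800)
            energy_err = abs(sol.fun[0]) / 20.0
            screen_viol = float(np.max(np.abs(sol.fun[3:6])))
            if energy_err <= 0.05 and screen_viol <= 0.1:
                break
        else:
            raise ToyLoopError(
                f"bond ({di - spec.scaffold_len + 1},{ai - spec.scaffold_len + 1}) at "
                f"{energy} kcal/mol not realizable: energy off by {energy_err:.3g}, "
                f"screen violation {screen_viol:.3g}"
            )
        for val, (i, kind) in zip(sol.x, var_keys):
            (phi if kind == "phi" else psi)[i] = val
    return phi, psi


def _guard_pairs(n_res, with_cb, planned):
    """Atom pairs that must stay outside detection/tether range."""
    pairs = []
    donors = [(i, "N") for i in range(1, n_res)]
    acceptors = [(i, "O") for i in range(n_res)]
    for i, an in donors:
        for j, bn in acceptors:
            if (i, j) in planned or abs(i - j) <= 1:
                continue
            pairs.append(((i, an), (j, bn), 3.75))
    carbons = [(i, nm) for i in range(n_res) for nm in ("CA", "C", "CB")
               if nm != "CB" or with_cb[i]]
    for x in range(len(carbons)):
        for y in range(x + 1, len(carbons)):
            (i, an), (j, bn) = carbons[x], carbons[y]
            if abs(i - j) <= 1:
                continue
            pairs.append(((i, an), (j, bn), 3.80))
    return pairs


def _angle3(a, b, c) -> float:
    u = a - b
    v = c - b
    return float(np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))


def _verify_toy_loop(s: AntibodyStructure, spec: ToyLoopSpec, truth: ToyLoopTruth,
                     numbering) -> None:
    detected = net.detect_hbonds(s) if any(a.element == "H" for a in s.atoms) else []
    res_of_atom = {}
    keys = list(s.residues())
    key_index = {k: i for i, k in enumerate(keys)}
    for a in s.atoms:
        res_of_atom[id(a)] = key_index[a.residue_key]
    got = {}
    for hb in detected:
        d = res_of_atom[id(s.atoms[hb.donor])] - spec.scaffold_len + 1
        ac = res_of_atom[id(s.atoms[hb.acceptor])] - spec.scaffold_len + 1
        got[(d, ac)] = hb.energy
    want = {(d, a): e for d, a, e in spec.hbond_plan}
    if set(got) != set(want):
        raise ToyLoopError(
            f"plan not realized: wanted bonds {sorted(want)}, detector found {sorted(got)}"
        )
    for k, e in want.items():
        if abs(got[k] - e) > 0.1:
            raise ToyLoopError(f"bond {k}: energy {got[k]:.3f} misses plan {e:.3f} by > 0.1")
    loop_keys = set(truth.loop_residue_keys)
    for t in net.detect_tethers(s):
        if s.atoms[t.i].residue_key in loop_keys or s.atoms[t.j].residue_key in loop_keys:
            raise ToyLoopError("stray hydrophobic tether touches the loop; plan infeasible")


# ---------------------------------------------------------------------------
# B-factor cohorts


def make_bfactor_cohort(
    n_naive: int,
    n_mature: int,
    shift: float,
    seed: int = 0,
    base_b: float = 20.0,
    sd_b: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, AntibodyStructure]]:
    """Two cohorts of C-alpha-only V_H structures with a known loop shift.

    Every structure has heavy-chain residues 1..112 with i.i.d. normal
    B-factors; in the *naive* group the CDR-H3 residues (95-102) are
    shifted upward by ``shift`` chain SDs (naive loops more mobile).  The
    true group difference is ``shift`` in z-units before sampling noise.
    Returns the cohort manifest and the structures keyed by id.
    """
    if n_naive < 1 or n_mature < 1:
        raise ValueError("cohort sizes must be >= 1")
    rng = np.random.default_rng(seed)
    structures: dict[str, AntibodyStructure] = {}
    rows = []
    for group, count, delta in (("naive", n_naive, shift), ("mature", n_mature, 0.0)):
        for k in range(count):
            ab_id = f"{group}_{k:04d}"
            b = base_b + sd_b * rng.standard_normal(112)
            atoms = []
            for i in range(112):
                num = i + 1
                bf = b[i] + (delta * sd_b if 95 <= num <= 102 else 0.0)
                atoms.append(
                    AtomRecord("CA", "C", "H", num, "", "ALA",
                               np.array([3.8 * i, 0.0, 0.0]), max(float(bf), 0.0))
                )
            structures[ab_id] = AntibodyStructure(atoms=atoms, model_id=1)
            rows.append({"id": ab_id, "path": "", "maturity": group, "bound": "unbound",
                         "heavy_germline_seq": "", "light_germline_seq": ""})
    return pd.DataFrame(rows), structures


# ---------------------------------------------------------------------------
# Coordinate ensembles


def make_ensemble(
    base: AntibodyStructure,
    jitter: float | dict[str, float],
    n_frames: int,
    seed: int = 0,
    n_conformers: int = 0,
    conformer_spread: float = 8.0,
) -> tuple[CoordinateEnsemble, np.ndarray]:
    """Frames around a base structure with controllable fluctuation.

    ``jitter`` is an isotropic Gaussian sigma in A, either one scalar for
    all atoms or a mapping of region name to sigma (atoms outside all named
    regions stay fixed).  With ``n_conformers > 0`` the frames instead
    cycle through that many well-separated rigid displacements of the
    CDR-H3 (plus the jitter), producing ground-truth cluster labels.
    Returns the ensemble (reference = base coordinates) and the per-frame
    conformer labels (zeros in plain jitter mode).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    coords = base.coords()
    n_atoms = len(base.atoms)
    sigma = np.zeros(n_atoms)
    if isinstance(jitter, dict):
        from .structure import RegionSelector

        for region, sg in jitter.items():
            sel = RegionSelector(region)
            for i, a in enumerate(base.atoms):
                if sel.contains(a):
                    sigma[i] = sg
    else:
        sigma[:] = float(jitter)

    labels = np.zeros(n_frames, dtype=int)
    offsets = np.zeros((max(n_conformers, 1), n_atoms, 3))
    if n_conformers > 0:
        from .structure import RegionSelector

        h3 = RegionSelector("H3")
        mask = np.array([h3.contains(a) for a in base.atoms])
        directions = rng.standard_normal((n_conformers, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        for c in range(n_conformers):
            offsets[c, mask] = conformer_spread * (c + 1) / n_conformers * directions[c]
        labels = np.arange(n_frames) % n_conformers

    frames = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        noise = rng.standard_normal((n_atoms, 3)) * sigma[:, None]
        frames[f] = coords + offsets[labels[f]] + noise
    ens = CoordinateEnsemble(frames=frames, roster=list(base.atoms), reference=coords)
    return ens, labels
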