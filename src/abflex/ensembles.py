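"""Trajectory-style ensemble analysis: superposition, RMSD, RMSF, clustering.

A :class:`CoordinateEnsemble` is a stack of frames sharing one atom roster,
typically read from a multi-model PDB standing in for an MD trajectory.
Frames are compared to a reference structure after least-squares rigid
superposition (Kabsch).  Two flavours of fluctuation are provided:

* the distance-based RMSF -- after whole-Fv C-alpha superposition, take for
  each residue the time series of distances between the frame C-alpha and
  the reference C-alpha, and report the SD of that series (population
  variance over frames);
* the conventional per-coordinate RMSF (``conventional=True``), the root
  mean square deviation of the C-alpha position from its time average.

Representative conformers are picked by k-medoids clustering of the
pairwise C-alpha + C-beta RMSD matrix: the medoid frames of the largest
clusters, ordered by cluster size (ties to the lower frame index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import AntibodyStructure, RegionSelector

__all__ = [
    "CoordinateEnsemble",
    "superpose",
    "region_rmsd",
    "rmsf",
    "select_representatives",
]


@dataclass
class CoordinateEnsemble:
    """Frames x atoms x 3 coordinates over a shared atom roster."""

    frames: np.ndarray  # (F, A, 3)
    roster: list  # AtomRecord per atom column
    reference: np.ndarray | None = None  # (A, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must have shape (F, A, 3) with F >= 1")
        if self.frames.shape[1] != len(self.roster):
            raise ValueError("frame width does not match the atom roster")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def atom_indices(self, region: str | RegionSelector | None = None,
                     atom_names: set[str] | None = None) -> np.ndarray:
        sel = RegionSelector(region) if isinstance(region, str) else region
        idx = [
            i
            for i, a in enumerate(self.roster)
            if (sel is None or sel.contains(a))
            and (atom_names is None or a.atom_name in atom_names)
        ]
        if not idx:
            raise ValueError(f"selection {region!r}/{atom_names!r} matches no atoms")
        return np.array(idx, dtype=int)

    @classmethod
    def from_structures(
        cls,
        structures: list[AntibodyStructure],
        reference: AntibodyStructure | None = None,
    ) -> "CoordinateEnsemble":
        if not structures:
            raise ValueError("no structures supplied")
        roster0 = [(a.residue_key, a.atom_name) for a in structures[0].atoms]
        for s in structures[1:]:
            if [(a.residue_key, a.atom_name) for a in s.atoms] != roster0:
                raise ValueError("ensemble members do not share one atom roster")
        frames = np.stack([s.coords() for s in structures])
        ref = None
        if reference is not None:
            if [(a.residue_key, a.atom_name) for a in reference.atoms] != roster0:
                raise ValueError("reference roster differs from the ensemble roster")
            ref = reference.coords()
        return cls(frames=frames, roster=list(structures[0].atoms), reference=ref)


def superpose(
    mobile: np.ndarray, reference: np.ndarray, fit_atoms: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(R, t, rmsd)`` with a proper rotation (det +1) such that
    ``mobile @ R.T + t`` best fits ``reference`` over ``fit_atoms`` (all
    atoms when omitted); ``rmsd`` is evaluated over the fit atoms.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    fit = np.arange(len(mobile)) if fit_atoms is None else np.asarray(fit_atoms, int)
    if fit.size < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    x = mobile[fit]
    y = reference[fit]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, sv, vt = np.linalg.svd(h)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise ValueError("degenerate fit geometry: fit atoms are (nearly) collinear")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = yc - rot @ xc
    fitted = x @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, t, rmsd


def region_rmsd(
    ensemble: CoordinateEnsemble,
    fit_region: str | RegionSelector = "FR_H",
    measure_region: str | RegionSelector = "H3",
) -> float:
    """Time-averaged C-alpha RMSD of a region after fitting on another.

    Each frame is superposed on the reference over the fit region's
    C-alpha atoms (heavy-chain framework by default), the C-alpha RMSD of
    the measured region (CDR-H3 by default) is evaluated, and the
    per-frame values are averaged.
    """
    if ensemble.reference is None:
        raise ValueError("ensemble has no reference structure")
    fit_idx = ensemble.atom_indices(fit_region, {"CA"})
    mea_idx = ensemble.atom_indices(measure_region, {"CA"})
    ref = ensemble.reference
    vals = []
    for frame in ensemble.frames:
        rot, t, _ = superpose(frame, ref, fit_idx)
        moved = frame[mea_idx] @ rot.T + t
        vals.append(np.sqrt(np.mean(np.sum((moved - ref[mea_idx]) ** 2, axis=1))))
    return float(np.mean(vals))


def rmsf(
    ensemble: CoordinateEnsemble,
    fit_region: str | RegionSelector | None = None,
    conventional: bool = False,
    presuperpose: bool = True,
) -> tuple[list, np.ndarray]:
    """Per-residue C-alpha fluctuation against the reference.

    With ``presuperpose`` each frame is first fitted to the reference over
    all C-alpha atoms of ``fit_region`` (whole roster when None).  The
    default measure is the SD over frames of the C-alpha
    distance-to-reference series (population variance); ``conventional``
    switches to the usual per-coordinate fluctuation about the time-mean
    position.  Returns residue keys and the fluctuation array; a
    single-frame ensemble yields zeros.
    """
    if ensemble.reference is None:
        raise ValueError("ensemble has no reference structure")
    ca_idx = ensemble.atom_indices(None, {"CA"})
    fit_idx = ca_idx if fit_region is None else ensemble.atom_indices(fit_region, {"CA"})
    ref = ensemble.reference
    frames = []
    for frame in ensemble.frames:
        if presuperpose:
            rot, t, _ = superpose(frame, ref, fit_idx)
            frames.append(frame[ca_idx] @ rot.T + t)
        else:
            frames.append(frame[ca_idx])
    stack = np.stack(frames)  # (F, n_ca, 3)
    if conventional:
        mean_pos = stack.mean(axis=0)
        flucts = np.sqrt(np.mean(np.sum((stack - mean_pos) ** 2, axis=2), axis=0))
    else:
        dist = np.linalg.norm(stack - ref[ca_idx], axis=2)  # (F, n_ca)
        flucts = dist.std(axis=0)  # population SD of the distance series
    keys = [ensemble.roster[i].residue_key for i in ca_idx]
    return keys, flucts


def _pairwise_rmsd(ensemble: CoordinateEnsemble, idx: np.ndarray) -> np.ndarray:
    f = ensemble.n_frames
    mat = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            _, _, r = superpose(ensemble.frames[i], ensemble.frames[j], idx)
            mat[i, j] = mat[j, i] = r
    return mat


def select_representatives(
    ensemble: CoordinateEnsemble,
    n_clusters: int = 20,
    n_reps: int = 10,
) -> list[int]:
    """Medoid frames of the largest clusters of a trajectory.

    Frames are clustered into ``n_clusters`` groups by k-medoids on the
    pairwise C-alpha + C-beta RMSD matrix (deterministic: medoid-of-all
    then farthest-first seeding, Voronoi reassignment until stable).  The
    medoids of the ``n_reps`` largest clusters are returned ordered by
    cluster size descending, ties broken toward the lower frame index.
    """
    f = ensemble.n_frames
    if f < n_clusters:
        raise ValueError(f"{f} frames cannot form {n_clusters} clusters")
    idx = ensemble.atom_indices(None, {"CA", "CB"})
    dist = _pairwise_rmsd(ensemble, idx)

    # deterministic seeding: global medoid, then farthest-first
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < n_clusters:
        d_min = dist[:, medoids].min(axis=1)
        d_min[medoids] = -1.0
        medoids.append(int(np.argmax(d_min)))

    for _ in range(100):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = []
        for c in range(n_clusters):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                new_medoids.append(medoids[c])
                continue
            inner = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(inner)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    sizes = [(int(np.sum(assign == c)), medoids[c]) for c in range(n_clusters)]
    sizes = [t for t in sizes if t[0] > 0]  # a cluster that owns no frame is not a cluster
    sizes.sort(key=lambda t: (-t[0], t[1]))
    return [m for _, m in sizes[: min(n_reps, n_clusters)]]
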