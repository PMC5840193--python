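"""Superposition, region RMSD, RMSF and representative selection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from abflex.ensembles import (
    CoordinateEnsemble,
    region_rmsd,
    rmsf,
    select_representatives,
    superpose,
)
from abflex.structure import AntibodyStructure, AtomRecord
from abflex.synth import ToyLoopSpec, make_ensemble, make_toy_loop


def _random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
    t = rng.uniform(-5, 5, 3)
    return rot, t


class TestSuperpose:
    def test_identity_on_self(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 3))
        rot, t, rms = superpose(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        assert rms == pytest.approx(0.0, abs=1e-10)

    def test_exact_recovery_of_rigid_transform(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((15, 3))
        rot0, t0 = _random_rigid(rng)
        moved = x @ rot0.T + t0
        rot, t, rms = superpose(moved, x)
        assert rms == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_brute_force_rotation_search(self):
        """Kabsch RMSD equals a direct numeric minimum over rotations."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 3))
        y = x + 0.3 * rng.standard_normal((20, 3))
        _, _, rms = superpose(x, y)

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)

        def objective(v):
            r = Rotation.from_rotvec(v).as_matrix()
            return np.sqrt(np.mean(np.sum((xc @ r.T - yc) ** 2, axis=1)))

        best = min(
            minimize(objective, v0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000}).fun
            for v0 in [np.zeros(3), np.array([0.1, -0.2, 0.3]), np.array([1.0, 1.0, -1.0])]
        )
        assert rms == pytest.approx(best, abs=1e-6)

    def test_rmsd_invariant_under_rigid_motion_of_mobile(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((12, 3))
        _, _, rms0 = superpose(x, y)
        rot0, t0 = _random_rigid(rng)
        _, _, rms1 = superpose(x @ rot0.T + t0, y)
        assert rms1 == pytest.approx(rms0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


@pytest.fixture(scope="module")
def fv_like():
    """A structure with framework and loop residues for region selections."""
    atoms = []
    for i in range(30):
        num = 80 + i  # spans framework (80-94, 103-109) and H3 (95-102)
        atoms.append(
            AtomRecord("CA", "C", "H", num, "", "GLY",
                       np.array([3.8 * i, np.sin(i), np.cos(i)]), 10.0)
        )
    return AntibodyStructure(atoms=atoms)


class TestRegionRmsd:
    def test_identical_frames_give_zero(self, fv_like):
        coords = fv_like.coords()
        ens = CoordinateEnsemble(np.stack([coords] * 4), list(fv_like.atoms), coords)
        assert region_rmsd(ens) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_loop_displacement_measured_exactly(self, fv_like):
        coords = fv_like.coords()
        moved = coords.copy()
        h3 = [i for i, a in enumerate(fv_like.atoms) if 95 <= a.residue_number <= 102]
        moved[h3] += np.array([0.0, 2.0, 0.0])
        ens = CoordinateEnsemble(np.stack([moved] * 3), list(fv_like.atoms), coords)
        assert region_rmsd(ens, "FR_H", "H3") == pytest.approx(2.0, abs=1e-9)

    def test_equals_composed_per_frame_loop(self, fv_like):
        rng = np.random.default_rng(11)
        coords = fv_like.coords()
        frames = coords + 0.4 * rng.standard_normal((5, *coords.shape))
        ens = CoordinateEnsemble(frames, list(fv_like.atoms), coords)
        got = region_rmsd(ens, "FR_H", "H3")
        fit_idx = ens.atom_indices("FR_H", {"CA"})
        mea_idx = ens.atom_indices("H3", {"CA"})
        vals = []
        for f in frames:
            rot, t, _ = superpose(f, coords, fit_idx)
            vals.append(np.sqrt(np.mean(np.sum((f[mea_idx] @ rot.T + t - coords[mea_idx]) ** 2,
                                               axis=1))))
        assert got == pytest.approx(float(np.mean(vals)), abs=1e-12)


class TestRmsf:
    def test_zero_for_identical_frames(self, fv_like):
        coords = fv_like.coords()
        ens = CoordinateEnsemble(np.stack([coords] * 6), list(fv_like.atoms), coords)
        _, fl = rmsf(ens)
        np.testing.assert_allclose(fl, 0.0, atol=1e-12)

    def test_two_frame_distance_series_gives_half_d(self, fv_like):
        """Distances {0, d} to the reference give SD d/2 (population)."""
        coords = fv_like.coords()
        moved = coords.copy()
        moved[5] += np.array([0.0, 0.0, 1.6])
        ens = CoordinateEnsemble(np.stack([coords, moved]), list(fv_like.atoms), coords)
        _, fl = rmsf(ens, presuperpose=False)
        assert fl[5] == pytest.approx(0.8, abs=1e-9)

    def test_isotropic_jitter_matches_analytic_sd(self):
        """Gaussian jitter of scale sigma on one region: the distance to the
        reference is a 3D Maxwell variable whose SD is known in closed form."""
        base, _ = make_toy_loop(ToyLoopSpec(loop_length=10, seed=8))
        sigma = 0.5
        ens, _ = make_ensemble(base, jitter={"H3": sigma}, n_frames=4000, seed=13)
        keys, fl = rmsf(ens, presuperpose=False)
        h3 = [i for i, k in enumerate(keys) if 95 <= k[1] <= 102]
        fr = [i for i, k in enumerate(keys) if k[1] < 95]
        maxwell_sd = sigma * np.sqrt(3 - 8 / np.pi)
        assert np.mean(fl[h3]) == pytest.approx(maxwell_sd, rel=0.05)
        np.testing.assert_allclose(fl[fr], 0.0, atol=1e-12)

    def test_invariant_under_global_rigid_motion(self, fv_like):
        rng = np.random.default_rng(21)
        coords = fv_like.coords()
        frames = coords + 0.3 * rng.standard_normal((8, *coords.shape))
        ens1 = CoordinateEnsemble(frames, list(fv_like.atoms), coords)
        rot0, t0 = _random_rigid(rng)
        ens2 = CoordinateEnsemble(frames @ rot0.T + t0, list(fv_like.atoms),
                                  coords @ rot0.T + t0)
        _, f1 = rmsf(ens1)
        _, f2 = rmsf(ens2)
        np.testing.assert_allclose(f1, f2, atol=1e-9)


class TestRepresentatives:
    def test_recovers_known_conformer_partition(self):
        base, _ = make_toy_loop(ToyLoopSpec(loop_length=10, seed=8))
        ens, labels = make_ensemble(base, jitter=0.05, n_frames=100, seed=3,
                                    n_conformers=5)
        reps = select_representatives(ens, n_clusters=5, n_reps=5)
        assert sorted(labels[reps]) == [0, 1, 2, 3, 4]

    def test_all_frames_identical_collapses_to_lowest_index(self, fv_like):
        coords = fv_like.coords()
        ens = CoordinateEnsemble(np.stack([coords] * 6), list(fv_like.atoms), coords)
        reps = select_representatives(ens, n_clusters=3, n_reps=3)
        assert reps[0] == 0

    def test_everything_distinct_returns_all_frames(self, fv_like):
        rng = np.random.default_rng(30)
        coords = fv_like.coords()
        frames = np.stack([coords + 2.0 * k * rng.standard_normal(coords.shape)
                           for k in range(1, 5)])
        ens = CoordinateEnsemble(frames, list(fv_like.atoms), coords)
        reps = select_representatives(ens, n_clusters=4, n_reps=4)
        assert sorted(reps) == [0, 1, 2, 3]

    def test_deterministic(self):
        base, _ = make_toy_loop(ToyLoopSpec(loop_length=8, seed=8))
        ens, _ = make_ensemble(base, jitter=0.3, n_frames=30, seed=5)
        r1 = select_representatives(ens, n_clusters=6, n_reps=3)
        r2 = select_representatives(ens, n_clusters=6, n_reps=3)
        assert r1 == r2

    def test_too_few_frames_rejected(self, fv_like):
        coords = fv_like.coords()
        ens = CoordinateEnsemble(np.stack([coords] * 3), list(fv_like.atoms), coords)
        with pytest.raises(ValueError):
            select_representatives(ens, n_clusters=5)
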