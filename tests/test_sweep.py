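"""Dilution sweep, DOF scaling and AUC summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from abflex.structure import parse_antibody_structure, write_pdb
from abflex.sweep import (
    EnsembleProfile,
    area_under_curve,
    cohort_auc,
    cohort_summary,
    default_grid,
    dof_profile,
    scale_dof,
    sweep_dof,
    sweep_dof_naive,
)


class TestScaleDof:
    def test_theoretical_maximum_scales_to_one(self):
        assert scale_dof(26, 10) == 1.0

    def test_zero_dof(self):
        assert scale_dof(0, 12) == 0.0

    def test_fraction(self):
        # 6/(2*12+6) = 0.2: the typical loop fraction with all bonds intact
        assert scale_dof(6, 12) == pytest.approx(0.2)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            scale_dof(5, 0)


class TestAreaUnderCurve:
    def test_rectangle_only(self):
        assert area_under_curve([(0.0, 1.0), (-7.0, 1.0)]) == -7.0

    def test_triangle_only(self):
        assert area_under_curve([(0.0, 0.0), (-1.0, 1.0)]) == -0.5

    def test_matches_trapezoid_oracle_on_random_polylines(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = np.sort(rng.uniform(-7, 0, 701))[::-1]
            y = rng.uniform(0, 2, 701)
            ours = area_under_curve(x, y)
            ref = np.trapezoid(y, x)
            assert ours == pytest.approx(ref, rel=1e-12)

    @given(st.floats(-5, 5), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_linearity(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(-7, 0, 50))[::-1]
        y = rng.uniform(0, 1, 50)
        assert area_under_curve(x, scale * y) == pytest.approx(
            scale * area_under_curve(x, y), abs=1e-9
        )

    def test_too_few_or_repeated_x_rejected(self):
        with pytest.raises(ValueError):
            area_under_curve([(0.0, 1.0)])
        with pytest.raises(ValueError):
            area_under_curve([(0.0, 1.0), (0.0, 2.0), (-1.0, 1.0)])


def test_default_grid_is_701_points_inclusive():
    g = default_grid()
    assert g.size == 701
    assert g[0] == 0.0 and g[-1] == -7.0
    assert np.allclose(np.diff(g), -0.01)


class TestSweep:
    def test_unbonded_loop_flat_at_theoretical_maximum(self, loop_plain):
        s, truth = loop_plain
        prof = sweep_dof(s)
        assert np.all(prof.dof == truth.max_dof)
        assert np.allclose(prof.sdof, 1.0)

    def test_step_exactly_at_planned_energy(self, loop_bonded):
        s, truth = loop_bonded
        prof = sweep_dof(s)
        changes = prof.cutoffs[1:][np.diff(prof.dof) != 0]
        assert len(changes) == 1
        assert changes[0] == pytest.approx(-4.0, abs=0.011)
        assert prof.dof[-1] == truth.max_dof  # all bonds diluted at -7

    def test_steps_at_both_energies(self, loop_two_energy):
        s, truth = loop_two_energy
        prof = sweep_dof(s)
        changes = prof.cutoffs[1:][np.diff(prof.dof) != 0]
        np.testing.assert_allclose(sorted(changes), sorted(truth.step_cutoffs), atol=0.011)

    def test_dof_non_decreasing_as_cutoff_decreases(self, sweep_loops):
        for s, _ in sweep_loops:
            prof = sweep_dof(s)
            assert np.all(np.diff(prof.dof) >= 0)  # cutoffs stored descending

    def test_incremental_equals_naive_rebuild(self, loop_bonded):
        s, _ = loop_bonded
        grid = default_grid(0, -7, 0.05)
        a = sweep_dof(s, grid=grid)
        b = sweep_dof_naive(s, grid=grid)
        assert np.array_equal(a.dof, b.dof)


class TestEnsembleProfile:
    def test_identical_members_have_zero_sd(self, loop_plain):
        s, _ = loop_plain
        prof = dof_profile([s, s, s])
        assert np.all(prof.dof_sd == 0)
        assert prof.n_members == 3

    def test_mean_within_member_envelope(self, loop_bonded, loop_plain):
        sb, _ = loop_bonded
        prof = dof_profile([sb, sb])
        lo = np.min([m.dof for m in prof.members], axis=0)
        hi = np.max([m.dof for m in prof.members], axis=0)
        assert np.all(prof.dof_mean >= lo) and np.all(prof.dof_mean <= hi)

    def test_differing_lengths_rejected(self, loop_plain, loop_two_energy):
        with pytest.raises(ValueError, match="loop length"):
            dof_profile([loop_plain[0], loop_two_energy[0]])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            dof_profile([])

    def test_multimodel_pdb_roundtrip_profile(self, loop_plain):
        s, truth = loop_plain
        text = write_pdb(s)
        s2 = parse_antibody_structure(text)
        prof = dof_profile([s2], grid=default_grid(0, -7, 0.5))
        assert np.all(prof.dof_mean == truth.max_dof)


def _flat_profile(value, loop_len, n=3):
    grid = default_grid()
    dof = np.full(grid.size, value * (2 * loop_len + 6))
    return EnsembleProfile(cutoffs=grid, dof_mean=dof, dof_sd=np.zeros(grid.size),
                           loop_len=loop_len, n_members=n)


class TestCohortAuc:
    def _manifest(self, ids, maturity):
        return pd.DataFrame(
            {"id": ids, "maturity": maturity, "bound": "unbound", "path": ""}
        )

    def test_flat_unit_profiles_give_minus_seven(self):
        profiles = {f"ab{i}": _flat_profile(1.0, 10) for i in range(4)}
        man = self._manifest(list(profiles), ["naive", "naive", "mature", "mature"])
        table = cohort_auc(profiles, man)
        assert np.allclose(table["auc"], -7.0)
        summary = cohort_summary(table)
        assert np.allclose(summary["sd"], 0.0)

    def test_known_sdof_offset_shifts_auc_linearly(self):
        delta = 0.25
        profiles = {"a": _flat_profile(1.0, 10), "b": _flat_profile(1.0 - delta, 10)}
        man = self._manifest(["a", "b"], ["naive", "mature"])
        table = cohort_auc(profiles, man).set_index("id")
        assert table.loc["b", "auc"] - table.loc["a", "auc"] == pytest.approx(7 * delta)

    def test_single_antibody_cohort(self):
        profiles = {"solo": _flat_profile(0.5, 8)}
        table = cohort_auc(profiles, self._manifest(["solo"], ["naive"]))
        summary = cohort_summary(table)
        assert summary.loc[0, "mean"] == pytest.approx(table.loc[0, "auc"])
        assert summary.loc[0, "sd"] == 0.0

    def test_missing_profile_listed(self):
        with pytest.raises(KeyError, match="ghost"):
            cohort_auc({}, self._manifest(["ghost"], ["naive"]))
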