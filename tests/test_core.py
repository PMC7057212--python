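"""Comparison metrics, origin-shift searches and merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasecluster.core import (
    DegenerateWeightError,
    IndexingError,
    InsufficientLayerError,
    WrongAlgorithmError,
    apply_shift,
    best_shift,
    best_shift_discrete,
    best_shift_fft,
    best_shift_sparse,
    delta_phi,
    mapcc,
    merge_sets,
    referential_cluster,
    wmpd,
)
from phasecluster.phase_io import PhaseSet
from phasecluster.symmetry import load_space_group, shifts_equivalent
from phasecluster.synthetic import make_partial_solution, make_toy_structure

from conftest import make_random_phase_set

CELL = (10.0, 10.0, 10.0, 90.0, 90.0, 90.0)


def _noisy_copy(ps, sigma, seed, id="noisy"):
    rng = np.random.default_rng(seed)
    return ps.replace(id=id, phi=(ps.phi + rng.normal(0, sigma, len(ps))) % 360.0)


class TestDeltaPhi:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(10.0, 350.0, 20.0), (42.0, 42.0, 0.0), (0.0, 180.0, 180.0), (359.0, 1.0, 2.0)],
    )
    def test_examples(self, a, b, expected):
        assert delta_phi(a, b) == pytest.approx(expected)

    @given(
        st.floats(min_value=-720, max_value=720),
        st.floats(min_value=-720, max_value=720),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_symmetry(self, a, b):
        d = delta_phi(a, b)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(delta_phi(b, a))
        assert delta_phi(a + 360.0, b) == pytest.approx(d, abs=1e-6)


class TestWmpd:
    def test_identical_sets_zero(self, truth_p212121):
        assert wmpd(truth_p212121, truth_p212121) == 0.0

    def test_uncorrelated_near_90(self):
        a = make_random_phase_set(6000, 1, "a")
        vals = [
            wmpd(a, a.replace(id="b", phi=np.random.default_rng(s).random(6000) * 360.0))
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(90.0, abs=2.0)

    def test_hand_computed_three_reflections(self):
        # w = fom1*fom2*F^2 = (1, 1, 2); dphi = (10, 20, 40) -> 27.5
        hkl = [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        F = np.array([1.0, 1.0, np.sqrt(2.0)])
        a = PhaseSet("a", CELL, "P1", hkl, F, [1, 1, 1], [0.0, 0.0, 0.0])
        b = PhaseSet("b", CELL, "P1", hkl, F, [1, 1, 1], [10.0, 20.0, 40.0])
        assert wmpd(a, b) == pytest.approx(27.5)

    def test_mismatched_indexing_rejected(self, truth_p212121):
        other = truth_p212121.replace(hkl=truth_p212121.hkl[::-1].copy())
        with pytest.raises(IndexingError):
            wmpd(truth_p212121, other)

    def test_degenerate_weights(self):
        a = PhaseSet("a", CELL, "P1", [[1, 0, 0]], [1.0], [0.0], [0.0])
        b = PhaseSet("b", CELL, "P1", [[1, 0, 0]], [1.0], [0.5], [10.0])
        with pytest.raises(DegenerateWeightError):
            wmpd(a, b)

    def test_invariant_under_simultaneous_shift(self, truth_c2):
        noisy = _noisy_copy(truth_c2, 25.0, 5)
        t = (0.5, 0.31, 0.0)
        assert wmpd(apply_shift(truth_c2, t), apply_shift(noisy, t)) == pytest.approx(
            wmpd(truth_c2, noisy), abs=1e-9
        )

    def test_monotone_in_phase_noise(self, truth_p212121):
        values = [
            np.mean([wmpd(truth_p212121, _noisy_copy(truth_p212121, s, seed))
                     for seed in range(5)])
            for s in (0.0, 15.0, 30.0, 50.0, 70.0, 90.0)
        ]
        assert all(x < y for x, y in zip(values, values[1:]))


class TestMapcc:
    def test_identity_is_one(self, truth_p212121):
        assert mapcc(truth_p212121, truth_p212121) == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_near_zero(self):
        a = make_random_phase_set(6000, 3, "a")
        b = a.replace(id="b", phi=np.random.default_rng(4).random(6000) * 360.0)
        assert mapcc(a, b) == pytest.approx(0.0, abs=0.03)

    def test_matches_real_space_map_correlation(self):
        """Reciprocal-space mapCC equals the correlation of the gridded maps."""
        rng = np.random.default_rng(8)
        n = 60
        hkl = make_random_phase_set(n, 0).hkl
        a = PhaseSet("a", CELL, "P1", hkl, rng.lognormal(0, 0.4, n),
                     rng.uniform(0.3, 1.0, n), rng.random(n) * 360)
        b = PhaseSet("b", CELL, "P1", hkl, a.F.copy(),
                     rng.uniform(0.3, 1.0, n), (a.phi + rng.normal(0, 60, n)) % 360)
        m = 24
        x = np.arange(m) / m
        gx, gy, gz = np.meshgrid(x, x, x, indexing="ij")

        def density(ps):
            rho = np.zeros((m, m, m))
            for (h, k, l), F, fom, phi in zip(ps.hkl, ps.F, ps.fom, ps.phi):
                arg = 2 * np.pi * (h * gx + k * gy + l * gz) - np.radians(phi)
                rho += 2.0 * fom * F * np.cos(arg)  # reflection + Friedel mate
            return rho.ravel()

        oracle = np.corrcoef(density(a), density(b))[0, 1]
        assert mapcc(a, b) == pytest.approx(oracle, abs=1e-3)


class TestApplyShift:
    def test_zero_shift_identity(self, truth_p212121):
        out = apply_shift(truth_p212121, (0, 0, 0))
        np.testing.assert_allclose(out.phi, truth_p212121.phi)

    def test_half_shift_flips_h100(self):
        ps = PhaseSet("x", CELL, "P1", [[1, 0, 0]], [1.0], [1.0], [0.0])
        assert apply_shift(ps, (0.5, 0, 0)).phi[0] == pytest.approx(180.0)

    def test_inverse(self, truth_c2):
        t = np.array([0.2, 0.7, 0.11])
        back = apply_shift(apply_shift(truth_c2, t), -t)
        dphi = np.abs((back.phi - truth_c2.phi + 180.0) % 360.0 - 180.0)
        assert dphi.max() < 1e-9


class TestBestShiftDiscrete:
    def test_constructed_shift_recovered(self, truth_p212121):
        sg = load_space_group("P212121")
        target = (0.5, 0.0, 0.5)
        moved = apply_shift(truth_p212121, target)
        res = best_shift_discrete(truth_p212121, moved, sg)
        # recovering means undoing: returned shift is -target mod 1
        assert shifts_equivalent(res.shift, (0.5, 0.0, 0.5), sg)
        assert res.wmpd < 1e-6
        assert res.algorithm == "discrete"

    def test_identity_pair(self, truth_p212121):
        res = best_shift_discrete(truth_p212121, truth_p212121, load_space_group("P212121"))
        assert res.shift == (0.0, 0.0, 0.0)
        assert res.wmpd == 0.0
        assert res.mapcc == pytest.approx(1.0)

    def test_noisy_pair_matches_exhaustive_enumeration(self, truth_p212121):
        sg = load_space_group("P212121")
        rng = np.random.default_rng(9)
        target = sg.discrete_shifts[5]
        noisy = _noisy_copy(apply_shift(truth_p212121, target), 30.0, 10)
        res = best_shift_discrete(truth_p212121, noisy, sg)
        # independent enumeration over all 8 shifts
        oracle = min(
            ((d, wmpd(truth_p212121, apply_shift(noisy, d))) for d in sg.discrete_shifts),
            key=lambda kv: kv[1],
        )
        assert res.shift == tuple(oracle[0])
        assert res.wmpd == pytest.approx(oracle[1])

    def test_polar_group_rejected(self, truth_c2):
        with pytest.raises(WrongAlgorithmError):
            best_shift_discrete(truth_c2, truth_c2, load_space_group("C2"))


class TestBestShiftPolar:
    def test_sparse_c2_construction(self, truth_c2):
        sg = load_space_group("C2")
        target = (0.5, 0.237, 0.0)
        moved = apply_shift(truth_c2, target)
        res = best_shift_sparse(truth_c2, moved, sg)
        assert shifts_equivalent(res.shift, np.negative(target) % 1.0, sg, tol=0.002)
        assert res.wmpd < 0.5

    def test_sparse_identity(self, truth_c2):
        res = best_shift_sparse(truth_c2, truth_c2, load_space_group("C2"))
        assert res.wmpd < 1e-6
        assert shifts_equivalent(res.shift, (0, 0, 0), load_space_group("C2"), tol=1e-4)

    def test_sparse_p21_half_polar_shift_wrap(self):
        model = make_toy_structure("P21", 20, seed=21)
        from phasecluster.phase_io import phases_from_model

        truth = phases_from_model(model, 2.5)
        sg = load_space_group("P21")
        moved = apply_shift(truth, (0.0, 0.5, 0.0))
        res = best_shift_sparse(truth, moved, sg)
        assert shifts_equivalent(res.shift, (0.0, 0.5, 0.0), sg, tol=0.002)

    def test_sparse_rejects_nonpolar(self, truth_p212121):
        with pytest.raises(WrongAlgorithmError):
            best_shift_sparse(truth_p212121, truth_p212121, load_space_group("P212121"))

    def test_sparse_insufficient_layer(self, truth_c2):
        sg = load_space_group("C2")
        mask = truth_c2.hkl[:, 1] != 1
        pruned = truth_c2.replace(
            hkl=truth_c2.hkl[mask], F=truth_c2.F[mask],
            fom=truth_c2.fom[mask], phi=truth_c2.phi[mask],
        )
        with pytest.raises(InsufficientLayerError):
            best_shift_sparse(pruned, pruned, sg)

    def test_fft_p1_construction(self, truth_p1):
        sg = load_space_group("P1")
        target = np.array([0.13, 0.41, 0.77])
        moved = apply_shift(truth_p1, target)
        res = best_shift_fft(truth_p1, moved, sg, grid=64)
        assert shifts_equivalent(res.shift, (-target) % 1.0, sg, tol=0.002)
        assert res.wmpd < 0.5

    def test_fft_identity(self, truth_p1):
        res = best_shift_fft(truth_p1, truth_p1, load_space_group("P1"))
        assert res.wmpd < 1e-3
        assert shifts_equivalent(res.shift, (0, 0, 0), load_space_group("P1"), tol=1e-3)

    def test_fft_grid_validation(self, truth_p1):
        with pytest.raises(ValueError, match="power of two"):
            best_shift_fft(truth_p1, truth_p1, load_space_group("P1"), grid=48)

    def test_fft_sparse_agree_on_noisy_c2_pairs(self, truth_c2):
        sg = load_space_group("C2")
        rng = np.random.default_rng(0)
        for trial in range(10):
            target = (
                0.5 * rng.integers(2), rng.random(), 0.5 * rng.integers(2)
            )
            moved = _noisy_copy(apply_shift(truth_c2, target), 20.0, 100 + trial)
            r_sp = best_shift_sparse(truth_c2, moved, sg)
            r_fft = best_shift_fft(truth_c2, moved, sg)
            assert shifts_equivalent(r_sp.shift, r_fft.shift, sg, tol=0.005)
            assert r_sp.wmpd == pytest.approx(r_fft.wmpd, abs=0.1)

    def test_symmetric_in_arguments(self, truth_c2):
        noisy = _noisy_copy(truth_c2, 30.0, 77)
        moved = apply_shift(noisy, (0.5, 0.62, 0.0))
        sg = load_space_group("C2")
        ab = best_shift(truth_c2, moved, sg)
        ba = best_shift(moved, truth_c2, sg)
        assert ab.wmpd == pytest.approx(ba.wmpd, abs=0.1)


class TestMergeSets:
    def test_merge_with_self_identity(self, truth_p212121):
        from phasecluster.core import ComparisonResult

        res = ComparisonResult(0.0, 1.0, (0.0, 0.0, 0.0), len(truth_p212121), "discrete")
        merged = merge_sets(truth_p212121, [(truth_p212121.replace(id="b"), res)], 60.0)
        dphi = np.abs((merged.phase_set.phi - truth_p212121.phi + 180) % 360 - 180)
        assert dphi.max() < 1e-9
        np.testing.assert_allclose(merged.phase_set.fom, truth_p212121.fom, atol=1e-12)

    def test_circular_mean_of_two_phases(self):
        from phasecluster.core import ComparisonResult

        a = PhaseSet("a", CELL, "P1", [[1, 0, 0]], [1.0], [1.0], [0.0])
        b = PhaseSet("b", CELL, "P1", [[1, 0, 0]], [1.0], [1.0], [90.0])
        res = ComparisonResult(0.0, 1.0, (0.0, 0.0, 0.0), 1, "discrete")
        merged = merge_sets(a, [(b, res)], 60.0)
        assert merged.phase_set.phi[0] == pytest.approx(45.0)

    def test_antipodal_phases_cancel_fom(self):
        from phasecluster.core import ComparisonResult

        a = PhaseSet("a", CELL, "P1", [[1, 0, 0]], [1.0], [1.0], [0.0])
        b = PhaseSet("b", CELL, "P1", [[1, 0, 0]], [1.0], [1.0], [180.0])
        res = ComparisonResult(0.0, 1.0, (0.0, 0.0, 0.0), 1, "discrete")
        merged = merge_sets(a, [(b, res)], 60.0)
        assert merged.phase_set.fom[0] < 1e-9

    def test_divergent_amplitudes_rejected(self, truth_p212121):
        from phasecluster.core import ComparisonResult

        other = truth_p212121.replace(id="b", F=truth_p212121.F * 2.0)
        res = ComparisonResult(0.0, 1.0, (0.0, 0.0, 0.0), len(other), "discrete")
        with pytest.raises(ValueError, match="amplitudes"):
            merge_sets(truth_p212121, [(other, res)], 60.0)

    def test_empty_members_returns_reference(self, truth_p212121):
        merged = merge_sets(truth_p212121, [], 60.0)
        assert merged.size == 1
        assert merged.phase_set.id == truth_p212121.id


class TestReferentialCluster:
    def test_identical_copies_form_one_cluster(self, truth_p212121):
        copies = [truth_p212121.replace(id=f"s{i}") for i in range(5)]
        clusters, leftovers = referential_cluster(copies, "P212121", 60.0)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == [f"s{i}" for i in range(5)]
        assert not leftovers
        assert clusters[0].members[1].wmpd_to_reference < 1e-9

    def test_two_families_separate(self, model_p212121, truth_p212121):
        rng = np.random.default_rng(3)
        famA = [_noisy_copy(truth_p212121, 25.0, 200 + i, f"a{i}") for i in range(4)]
        other = truth_p212121.replace(
            phi=rng.random(len(truth_p212121)) * 360.0
        )
        famB = [_noisy_copy(other, 25.0, 300 + i, f"b{i}") for i in range(4)]
        clusters, leftovers = referential_cluster(famA + famB, "P212121", 60.0)
        assert len(clusters) == 2
        assert sorted(clusters[0].member_ids) == [f"a{i}" for i in range(4)]
        assert sorted(clusters[1].member_ids) == [f"b{i}" for i in range(4)]

    def test_seq_continue_skips_unrelated_heads(self, truth_p212121):
        rng = np.random.default_rng(4)
        n = len(truth_p212121)
        singles = [
            truth_p212121.replace(id=f"junk{i}", phi=rng.random(n) * 360.0)
            for i in range(3)
        ]
        family = [_noisy_copy(truth_p212121, 20.0, 400 + i, f"fam{i}") for i in range(3)]
        clusters, leftovers = referential_cluster(
            singles + family, "P212121", 60.0, seq_continue=True
        )
        multi = [c for c in clusters if c.size > 1]
        assert len(multi) == 1
        assert sorted(multi[0].member_ids) == ["fam0", "fam1", "fam2"]
        assert set(leftovers) == {"junk0", "junk1", "junk2"}

    def test_empty_input(self):
        clusters, leftovers = referential_cluster([], "P212121", 60.0)
        assert clusters == [] and leftovers == []
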