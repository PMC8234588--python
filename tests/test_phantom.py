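"""Phantom generator: geometry, FA targets, noise model, longitudinal evolution."""

import dataclasses

import numpy as np
import pytest

import ichwm
from ichwm.phantom import PhantomError


class TestGenerateTensorField:
    def test_true_fa_in_unit_interval_no_nan(self, small_phantom):
        _, _, gt = small_phantom
        assert np.all(np.isfinite(gt.true_fa_map))
        assert gt.true_fa_map.min() >= 0.0 and gt.true_fa_map.max() <= 1.0

    def test_lesion_and_shell_disjoint(self, small_phantom):
        _, _, gt = small_phantom
        assert not np.any(gt.lesion_mask_true & gt.perilesional_shell_mask)

    def test_hematoma_volume_matches_voxel_count(self, small_phantom):
        spec, _, gt = small_phantom
        assert gt.true_hematoma_volume_ml == pytest.approx(
            gt.lesion_mask_true.sum() * spec.voxel_volume_ml)

    def test_voxelized_volume_close_to_analytic_sphere(self, small_layout):
        # radius 10.6 mm sphere: (4/3)π(1.06)³ ≈ 4.99 mL
        spec = ichwm.phantom_spec(small_layout, hematoma_volume_ml=None)
        spec = dataclasses.replace(
            spec, hematoma=ichwm.Hematoma(small_layout.hematoma_center(), 10.6))
        _, gt = ichwm.generate_tensor_field(spec)
        analytic = 4.0 / 3.0 * np.pi * 1.06 ** 3
        assert gt.true_hematoma_volume_ml == pytest.approx(analytic, rel=0.05)

    def test_core_fa_hits_target(self, small_phantom):
        spec, _, gt = small_phantom
        core_mean = gt.true_fa_map[gt.lesion_mask_true].mean()
        assert 0.13 <= core_mean <= 0.17    # target 0.15 ± 0.02

    def test_unattenuated_shell_preserves_bundle_fa(self, small_layout):
        spec = ichwm.phantom_spec(small_layout, hematoma_volume_ml=3.0,
                                  attenuation=1.0, noise_sigma=0.0)
        _, gt = ichwm.generate_tensor_field(spec)
        wm_fa = ichwm.fractional_anisotropy(*ichwm.phantom.WM_EIGENVALUES)
        shell_wm = gt.wm_mask & gt.perilesional_shell_mask
        assert shell_wm.any()
        assert np.allclose(gt.true_fa_map[shell_wm], wm_fa, atol=1e-12)

    def test_stronger_attenuation_strictly_reduces_shell_fa(self, small_layout):
        means = []
        for f in (0.8, 0.5, 0.2):
            spec = ichwm.phantom_spec(small_layout, 3.0, attenuation=f)
            _, gt = ichwm.generate_tensor_field(spec)
            shell_wm = gt.wm_mask & gt.perilesional_shell_mask
            means.append(gt.true_fa_map[shell_wm].mean())
        assert means[0] > means[1] > means[2]

    def test_rejects_hematoma_on_grid_boundary(self, small_layout):
        spec = ichwm.phantom_spec(small_layout, hematoma_volume_ml=None)
        with pytest.raises(PhantomError):
            dataclasses.replace(spec, hematoma=ichwm.Hematoma((2.0, 27.5, 28.75), 5.0))

    def test_rejects_empty_bundle_list(self, small_layout):
        spec = ichwm.phantom_spec(small_layout, 3.0)
        spec = dataclasses.replace(spec, wm_bundles=())
        with pytest.raises(PhantomError):
            ichwm.generate_tensor_field(spec)

    def test_hematoma_eigenvalues_exact(self):
        for target in (0.1, 0.15, 0.2):
            lam = ichwm.hematoma_eigenvalues(target, 0.8e-3)
            assert ichwm.fractional_anisotropy(*lam) == pytest.approx(target, abs=1e-9)
            assert ichwm.mean_diffusivity(*lam) == pytest.approx(0.8e-3, rel=1e-12)


class TestSimulateDwi:
    def test_isotropic_signal_closed_form(self, scheme):
        d = 1.0e-3
        field = ichwm.TensorField.from_matrices(np.eye(3)[None, None, None] * d)
        dwi = ichwm.simulate_dwi(field, scheme, 1000.0, 0.0)
        expected = 1000.0 * np.exp(-scheme.b_values * d)
        assert np.allclose(dwi.data[0, 0, 0], expected, rtol=1e-12)

    def test_b0_signal_is_s0_for_any_tensor(self, scheme):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((3, 3))
        D = (A @ A.T) * 1e-4
        field = ichwm.TensorField.from_matrices(D[None, None, None])
        dwi = ichwm.simulate_dwi(field, scheme, 777.0, 0.0)
        assert np.allclose(dwi.data[0, 0, 0, scheme.b0_mask], 777.0)

    def test_rician_bias_positive(self, scheme):
        """Mean of many Rician draws exceeds the noiseless signal (Monte Carlo)."""
        d, s0, sigma = 1.0e-3, 1000.0, 50.0
        field = ichwm.TensorField.from_matrices(
            np.broadcast_to(np.eye(3) * d, (100, 100, 1, 3, 3)).copy())
        dwi = ichwm.simulate_dwi(field, scheme, s0, sigma, seed=123)
        j = int(np.argmax(scheme.b_values))           # weakest signal, biggest bias
        noiseless = s0 * np.exp(-scheme.b_values[j] * d)
        assert dwi.data[..., j].mean() > noiseless

    def test_reproducible_under_seed(self, scheme):
        field = ichwm.TensorField.from_matrices(
            np.broadcast_to(np.eye(3) * 1e-3, (4, 4, 2, 3, 3)).copy())
        a = ichwm.simulate_dwi(field, scheme, 1000.0, 30.0, seed=9)
        b = ichwm.simulate_dwi(field, scheme, 1000.0, 30.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_rejects_negative_eigenvalues(self, scheme):
        field = ichwm.TensorField.from_matrices(
            (np.diag([1.0, 1.0, -0.5]) * 1e-3)[None, None, None])
        with pytest.raises(ValueError):
            ichwm.simulate_dwi(field, scheme, 1000.0, 0.0)

    def test_rejects_negative_sigma(self, scheme):
        field = ichwm.TensorField.from_matrices(np.eye(3)[None, None, None] * 1e-3)
        with pytest.raises(ValueError):
            ichwm.simulate_dwi(field, scheme, 1000.0, -1.0)


class TestRoundTrip:
    def test_noiseless_roundtrip_reproduces_true_fa(self, small_phantom,
                                                    small_noiseless_dwi):
        _, _, gt = small_phantom
        fa = ichwm.compute_fa_map(small_noiseless_dwi)
        assert np.nanmax(np.abs(fa.data - gt.true_fa_map)) <= 1e-6

    def test_noisy_fa_error_bounded_in_wm(self, small_layout, scheme):
        """σ = 0.02·s0 keeps the mean absolute FA error in white matter below 0.05."""
        spec = ichwm.phantom_spec(small_layout, 3.0, noise_sigma=20.0)
        field, gt = ichwm.generate_tensor_field(spec)
        dwi = ichwm.simulate_dwi(field, scheme, ichwm.s0_map(spec, gt), 20.0, seed=21)
        fa = ichwm.compute_fa_map(dwi)
        err = np.abs(fa.data[gt.wm_mask] - gt.true_fa_map[gt.wm_mask])
        assert np.nanmean(err) < 0.05


class TestEvolveTimepoint:
    def _tc(self, recovery, resolution=0.0, a3=0.4, r3=8.0):
        return ichwm.SubjectTimecourse(3, (3, 14, 30), a3, recovery, r3, resolution)

    def test_zero_recovery_keeps_attenuation(self, small_layout):
        spec = ichwm.phantom_spec(small_layout, 2.0, attenuation=0.4)
        tc = self._tc(recovery=0.0)
        late = ichwm.evolve_timepoint(spec, tc, 30)
        assert late.perilesional_shell.attenuation == pytest.approx(0.4)

    def test_high_recovery_reaches_full_integrity(self, small_layout):
        spec = ichwm.phantom_spec(small_layout, 2.0, attenuation=0.4)
        tc = self._tc(recovery=1.0)
        late = ichwm.evolve_timepoint(spec, tc, 30)
        assert late.perilesional_shell.attenuation == pytest.approx(1.0, abs=1e-6)

    def test_rejects_unknown_day(self, small_layout):
        spec = ichwm.phantom_spec(small_layout, 2.0)
        with pytest.raises(ValueError):
            ichwm.evolve_timepoint(spec, self._tc(0.1), 7)

    def test_radius_never_increases_across_cohort(self):
        design = ichwm.CohortDesign(n_subjects=20, layout=ichwm.PhantomLayout.small(),
                                    hematoma_volume_range_ml=(0.3, 5.0), seed=4,
                                    missingness=tuple([frozenset({3, 14, 30})] * 20))
        from ichwm.cohort import _subject_draws, subject_timecourse
        for draw in _subject_draws(design):
            tc = subject_timecourse(design, draw)
            radii = [tc.radius_at(d) for d in (3, 14, 30)]
            assert radii[0] >= radii[1] >= radii[2]


class TestGenerateCohort:
    def test_record_count_without_missingness(self, scheme):
        design = ichwm.CohortDesign(
            n_subjects=5, layout=ichwm.PhantomLayout.small(),
            hematoma_volume_range_ml=(0.5, 4.0),
            missingness=tuple([frozenset({3, 14, 30})] * 5), seed=2, noise_sigma=30.0)
        recs = ichwm.generate_cohort(design, scheme)
        assert len(recs) == 15
        assert all(r.ground_truth is not None for r in recs)

    def test_default_design_matches_cohort_acquisition_pattern(self):
        """13 subjects acquired 11/10/9 across days 3/14/30, 7 complete."""
        design = ichwm.CohortDesign()
        acquired = design.acquired_days()
        assert len(acquired) == 13
        counts = {d: sum(d in s for s in acquired) for d in (3, 14, 30)}
        assert counts == {3: 11, 14: 10, 30: 9}
        assert sum(len(s) == 3 for s in acquired) == 7

    def test_same_seed_gives_identical_dwi(self, scheme):
        design = ichwm.CohortDesign(
            n_subjects=2, layout=ichwm.PhantomLayout.small(),
            hematoma_volume_range_ml=(1.0, 3.0),
            missingness=(frozenset({3}), frozenset({14})), seed=77, noise_sigma=30.0)
        a = ichwm.generate_cohort(design, scheme)
        b = ichwm.generate_cohort(design, scheme)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id and ra.day == rb.day
            assert np.array_equal(ra.dwi.data, rb.dwi.data)

    def test_rejects_invalid_designs(self):
        with pytest.raises(ValueError):
            ichwm.CohortDesign(n_subjects=0)
        with pytest.raises(ValueError):
            ichwm.CohortDesign(days=(14, 3, 30))
        with pytest.raises(ValueError):
            ichwm.CohortDesign(hematoma_volume_range_ml=(5.0, 1.0))
        with pytest.raises(ValueError):
            ichwm.CohortDesign(n_subjects=2, missingness=(frozenset({3, 7}),
                                                          frozenset({3})))
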