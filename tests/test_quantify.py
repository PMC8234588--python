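"""FA-threshold volumetry, the perilesional deficit, and longitudinal change."""

import dataclasses

import numpy as np
import pytest

import ichwm
from ichwm.quantify import CompartmentError


def _quant(**kw):
    """Hand-built quantification for deficit arithmetic."""
    q = ichwm.SubjectQuantification(
        subject_id=kw.get("subject_id", "S01"), day=kw.get("day", 3),
        sphere_radius_mm=kw.get("radius", 22.0),
        sphere_volume_ml=kw.get("ipsi_vol", 60.0),
        contra_sphere_volume_ml=kw.get("contra_vol", 60.0),
        lesion_volume_ml=kw.get("lesion_vol", 12.0),
        perilesion_volume_ml=kw.get("peri_vol", 48.0),
    )
    q.fa_ml = {
        "ipsilateral_sphere": kw.get("ipsi", 6.0),
        "lesion": kw.get("lesion", 1.0),
        "contralateral_sphere": kw.get("contra", 10.0),
        "perilesion": kw.get("ipsi", 6.0) - kw.get("lesion", 1.0),
    }
    q.fa_pct = {c: 100.0 * v / max(q.sphere_volume_ml, 1e-9)
                for c, v in q.fa_ml.items()}
    return q


class TestSuprathresholdVolume:
    def test_hand_counted_volume(self):
        data = np.full((10, 10, 1), 0.1)
        data.flat[:40] = 0.9
        fa = ichwm.ScalarMap(data, "FA", (1.0, 1.0, 2.3))
        ml, n_nan = ichwm.fa_suprathreshold_volume(fa, np.ones_like(data, bool))
        assert ml == pytest.approx(40 * 0.0023)
        assert n_nan == 0

    def test_all_nan_counts_zero_volume(self):
        fa = ichwm.ScalarMap(np.full((10, 10, 1), np.nan), "FA", (1.0, 1.0, 2.3))
        ml, n_nan = ichwm.fa_suprathreshold_volume(fa, np.ones((10, 10, 1), bool))
        assert ml == 0.0
        assert n_nan == 100

    def test_threshold_sweep_non_increasing(self, symmetric_fa_map):
        mask = np.ones(symmetric_fa_map.data.shape, bool)
        vols = [ichwm.fa_suprathreshold_volume(symmetric_fa_map, mask, t)[0]
                for t in (0.3, 0.5, 0.7)]
        assert vols[0] >= vols[1] >= vols[2]

    def test_grid_mismatch_rejected(self, symmetric_fa_map):
        with pytest.raises(CompartmentError):
            ichwm.fa_suprathreshold_volume(symmetric_fa_map, np.ones((2, 2, 2), bool))

    def test_strict_inequality_at_threshold(self):
        fa = ichwm.ScalarMap(np.full((3, 1, 1), 0.5), "FA", (1.0, 1.0, 1.0))
        ml, _ = ichwm.fa_suprathreshold_volume(fa, np.ones((3, 1, 1), bool), 0.5)
        assert ml == 0.0


class TestQuantifySubjectTimepoint:
    def test_symmetry_without_lesion(self, symmetric_fa_map, small_grid):
        """Left and right sphere percentages agree on a symmetric map."""
        ipsi = ichwm.SphericalROI((41.25, 27.5, 28.75), 11.0)
        contra = ichwm.mirror_sphere(ipsi, small_grid)
        empty = ichwm.LesionMask(np.zeros(small_grid.shape, bool), small_grid.spacing)
        q = ichwm.quantify_subject_timepoint(symmetric_fa_map, ipsi, contra, empty)
        assert q.fa_pct["ipsilateral_sphere"] == pytest.approx(
            q.fa_pct["contralateral_sphere"], abs=0.5)
        assert q.loss_ml == pytest.approx(0.0, abs=0.05)

    def test_contralateral_white_matter_share_near_design(self, scheme):
        """The control sphere holds ≈ 17% white matter (cohort-typical value)."""
        layout = ichwm.PhantomLayout.standard()
        spec = ichwm.phantom_spec(layout, hematoma_volume_ml=5.0)
        field, gt = ichwm.generate_tensor_field(spec)
        dwi = ichwm.simulate_dwi(field, scheme, ichwm.s0_map(spec, gt), 50.0, seed=3)
        fa = ichwm.compute_fa_map(dwi)
        grid = ichwm.Grid(layout.grid_shape, layout.voxel_spacing)
        lesion = ichwm.LesionMask(gt.lesion_mask_true, spec.voxel_spacing)
        ipsi = ichwm.place_ipsilateral_sphere(lesion, grid, (22.0, 25.0))
        contra = ichwm.mirror_sphere(ipsi, grid)
        q = ichwm.quantify_subject_timepoint(fa, ipsi, contra, lesion)
        assert 15.0 <= q.fa_pct["contralateral_sphere"] <= 19.0
        assert q.fa_pct["perilesion"] < q.fa_pct["contralateral_sphere"]

    def test_compartment_additivity(self, small_phantom, small_grid):
        spec, _, gt = small_phantom
        fa = ichwm.ScalarMap(gt.true_fa_map, "FA", spec.voxel_spacing)
        lesion = ichwm.LesionMask(gt.lesion_mask_true, spec.voxel_spacing)
        ipsi = ichwm.place_ipsilateral_sphere(lesion, small_grid, (11.0, 14.0))
        contra = ichwm.mirror_sphere(ipsi, small_grid)
        q = ichwm.quantify_subject_timepoint(fa, ipsi, contra, lesion)
        assert q.fa_ml["lesion"] + q.fa_ml["perilesion"] == pytest.approx(
            q.fa_ml["ipsilateral_sphere"], abs=1e-12)

    def test_lesion_escaping_sphere_rejected(self, symmetric_fa_map, small_grid):
        ipsi = ichwm.SphericalROI((41.25, 27.5, 28.75), 11.0)
        contra = ichwm.mirror_sphere(ipsi, small_grid)
        stray = np.zeros(small_grid.shape, bool)
        stray[41, 27, 12] = True
        stray[50, 5, 2] = True    # far outside the sphere
        lesion = ichwm.LesionMask(stray, small_grid.spacing)
        with pytest.raises(CompartmentError, match="voxel"):
            ichwm.quantify_subject_timepoint(symmetric_fa_map, ipsi, contra, lesion)


class TestPerilesionalDeficit:
    def test_worked_example(self):
        """ipsi 6, lesion 1, perilesion 48 mL, contra 10 of 60 mL → −3 mL (+3 loss)."""
        q = _quant(ipsi=6.0, lesion=1.0, contra=10.0, peri_vol=48.0, contra_vol=60.0)
        d = ichwm.perilesional_deficit(q)
        assert d.deficit_printed_ml == pytest.approx(-3.0)
        assert d.loss_ml == pytest.approx(3.0)
        assert d.measured_ml == pytest.approx(5.0)
        assert d.expected_ml == pytest.approx(8.0)

    def test_zero_contra_volume_rejected(self):
        q = _quant(contra_vol=0.0)
        with pytest.raises(ValueError):
            ichwm.perilesional_deficit(q)

    def test_deeper_attenuation_increases_loss(self, small_layout, small_grid):
        # 0.7 leaves shell FA above the 0.5 cut; 0.35 pushes it below
        losses = []
        for f in (0.7, 0.35):
            spec = ichwm.phantom_spec(small_layout, 2.0, attenuation=f,
                                      shell_thickness_mm=4.0, noise_sigma=0.0)
            _, gt = ichwm.generate_tensor_field(spec)
            fa = ichwm.ScalarMap(gt.true_fa_map, "FA", spec.voxel_spacing)
            lesion = ichwm.LesionMask(gt.lesion_mask_true, spec.voxel_spacing)
            ipsi = ichwm.place_ipsilateral_sphere(lesion, small_grid, (11.0, 14.0))
            contra = ichwm.mirror_sphere(ipsi, small_grid)
            q = ichwm.quantify_subject_timepoint(fa, ipsi, contra, lesion)
            losses.append(q.loss_ml)
        assert losses[1] > losses[0]

    def test_loss_recovers_ground_truth_deficit(self, scheme):
        """Measured loss tracks the ground-truth expected deficit within 15% (median)."""
        layout = ichwm.PhantomLayout.small()
        grid = ichwm.Grid(layout.grid_shape, layout.voxel_spacing)
        rel_errors = []
        rng = np.random.default_rng(8)
        for i in range(6):
            v = float(rng.uniform(1.5, 4.5))
            spec = ichwm.phantom_spec(layout, v, noise_sigma=30.0)
            field, gt = ichwm.generate_tensor_field(spec)
            # ground-truth deficit from the true FA map and true masks
            fa_true = ichwm.ScalarMap(gt.true_fa_map, "FA", spec.voxel_spacing)
            lesion_true = ichwm.LesionMask(gt.lesion_mask_true, spec.voxel_spacing)
            ipsi = ichwm.place_ipsilateral_sphere(lesion_true, grid, (11.0, 14.0))
            contra = ichwm.mirror_sphere(ipsi, grid)
            q_true = ichwm.quantify_subject_timepoint(fa_true, ipsi, contra, lesion_true)
            # measured loss from the fitted (noisy) FA map
            dwi = ichwm.simulate_dwi(field, scheme, ichwm.s0_map(spec, gt), 30.0,
                                     seed=500 + i)
            fa_fit = ichwm.compute_fa_map(dwi)
            q_fit = ichwm.quantify_subject_timepoint(fa_fit, ipsi, contra, lesion_true)
            rel_errors.append(abs(q_fit.loss_ml - q_true.loss_ml)
                              / max(abs(q_true.loss_ml), 1e-9))
        assert np.median(rel_errors) <= 0.15

    def test_percentages_invariant_under_spacing_rescale(self, small_phantom):
        spec, _, gt = small_phantom
        lesion = ichwm.LesionMask(gt.lesion_mask_true, spec.voxel_spacing)
        results = []
        for scale in (1.0, 2.0):
            spacing = tuple(s * scale for s in spec.voxel_spacing)
            grid = ichwm.Grid(spec.grid_shape, spacing)
            fa = ichwm.ScalarMap(gt.true_fa_map, "FA", spacing)
            les = ichwm.LesionMask(gt.lesion_mask_true, spacing)
            ipsi = ichwm.place_ipsilateral_sphere(les, grid, (11.0 * scale, 14.0 * scale))
            contra = ichwm.mirror_sphere(ipsi, grid)
            results.append(ichwm.quantify_subject_timepoint(fa, ipsi, contra, les))
        for c in ichwm.COMPARTMENTS:
            assert results[0].fa_pct[c] == pytest.approx(results[1].fa_pct[c], abs=1e-9)
        assert results[1].fa_ml["contralateral_sphere"] == pytest.approx(
            results[0].fa_ml["contralateral_sphere"] * 8.0)


class TestLongitudinalChange:
    def _pair(self, delta=0.5):
        early = _quant(day=3)
        late = _quant(day=14, ipsi=6.0 + delta)
        return early, late

    def test_identical_quantifications_zero_delta(self):
        early = _quant(day=3)
        late = _quant(day=14)
        ch = ichwm.longitudinal_change(early, late)
        assert all(v == 0.0 for v in ch.delta_ml.values())
        assert not any(ch.declined.values())

    def test_antisymmetry(self):
        early, late = self._pair(0.7)
        fwd = ichwm.longitudinal_change(early, late)
        swapped = dataclasses.replace(late)
        swapped.day = 3
        early2 = dataclasses.replace(early)
        early2.day = 14
        back = ichwm.longitudinal_change(swapped, early2)
        for c in ichwm.COMPARTMENTS:
            assert fwd.delta_ml[c] == pytest.approx(-back.delta_ml[c])

    def test_radius_mismatch_rejected(self):
        early = _quant(day=3)
        late = _quant(day=14, radius=23.0)
        with pytest.raises(ValueError, match="radius"):
            ichwm.longitudinal_change(early, late)

    def test_subject_mismatch_rejected(self):
        early = _quant(day=3)
        late = _quant(day=14, subject_id="S02")
        with pytest.raises(ValueError):
            ichwm.longitudinal_change(early, late)
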