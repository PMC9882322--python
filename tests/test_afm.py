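"""AFM analysis: background, segmentation, skeleton decomposition, contour
lengths, volumes, particle detection, and volume-ratio stoichiometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleoquant import afm, synthetic as syn
from nucleoquant.afm import HeightMap, MoleculeTrace
from nucleoquant.errors import (
    BackgroundEstimationError,
    ParameterError,
    PathError,
)
from conftest import make_rod_mask


def trace_from_mask(mask, molecule_id=0):
    return MoleculeTrace(
        molecule_id=molecule_id, mask=mask, origin=(0, 0),
        boundary=np.zeros((0, 2), dtype=int),
    )


class TestBackground:
    def test_uniform_map(self):
        hm = HeightMap(np.full((64, 64), 0.37))
        assert afm.estimate_background(hm, 0.5) == pytest.approx(0.37)

    def test_ignores_molecule_pixels(self):
        grid = np.zeros((100, 100))
        grid[:10] = 1.5  # 10% molecule pixels
        hm = HeightMap(grid)
        assert afm.estimate_background(hm, 0.5) == 0.0

    def test_median_concentrates_under_noise(self):
        rng = np.random.default_rng(0)
        hm = HeightMap(rng.normal(0.2, 0.1, size=(128, 128)))
        assert abs(afm.estimate_background(hm, 10.0) - 0.2) < 0.02

    def test_too_few_background_pixels(self):
        hm = HeightMap(np.ones((32, 32)))
        with pytest.raises(BackgroundEstimationError):
            afm.estimate_background(hm, 0.5)


class TestSegmentation:
    def test_blank_map_no_molecules(self, flat_map):
        assert afm.segment_molecules(flat_map, 0.0) == []

    def test_two_separate_chains_two_molecules(self):
        wlc = syn.WLCParams(contour_length=200, persistence_length=50, seed=0)
        hm, manifest = syn.simulate_afm_scene(
            n_chains=2, wlc=wlc, particle_mean=0.0, seed=17
        )
        traces = afm.segment_molecules(hm, afm.estimate_background(hm, 0.5))
        assert len(traces) == 2

    def test_crossing_chains_merge_with_branch_points(self):
        # two straight rods crossed as an X form one molecule whose skeleton
        # has at least one junction
        rp = syn.RenderParams(extent=(128, 128), noise_sigma=0.0)
        t = np.linspace(-40.0, 40.0, 81)
        a = np.column_stack([64 + t / math.sqrt(2), 64 + t / math.sqrt(2)])
        b = np.column_stack([64 + t / math.sqrt(2), 64 - t / math.sqrt(2)])
        hm, _ = syn.render_afm_scene([a, b], [], rp, seed=0)
        traces = afm.segment_molecules(hm, 0.0)
        assert len(traces) == 1
        afm.skeletonize_and_decompose(traces[0])
        assert len(traces[0].branch_points) >= 1

    def test_min_area_filters_specks(self):
        grid = np.zeros((64, 64))
        grid[10, 10] = 5.0
        traces = afm.segment_molecules(HeightMap(grid), 0.0, min_area=5)
        assert traces == []


class TestSkeletonDecomposition:
    def test_straight_rod(self):
        trace = trace_from_mask(make_rod_mask(length=60, width=3))
        afm.skeletonize_and_decompose(trace)
        assert len(trace.branch_points) == 0
        assert len(trace.segments) == 1
        assert len(trace.endpoints) == 2

    def test_plus_shape_one_junction_four_segments(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[20, 5:36] = True
        mask[5:36, 20] = True
        trace = trace_from_mask(mask)
        afm.skeletonize_and_decompose(trace)
        assert len(trace.branch_points) == 1
        assert len(trace.segments) == 4
        assert len(trace.endpoints) == 4

    def test_ring_mask_one_closed_segment(self):
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.hypot(yy - 32, xx - 32)
        mask = (r >= 15) & (r <= 19)
        trace = trace_from_mask(mask)
        afm.skeletonize_and_decompose(trace)
        assert trace.endpoints == []
        assert len(trace.segments) == 1
        assert trace.segments[0][0] == trace.segments[0][-1]  # closed

    def test_short_spurs_pruned(self):
        mask = make_rod_mask(length=60, width=3)
        mask[8:10, 40] = True  # 2-px spur off the rod
        trace = trace_from_mask(mask)
        afm.skeletonize_and_decompose(trace, min_branch_length=5)
        assert len(trace.branch_points) == 0
        assert len(trace.segments) == 1

    def test_empty_mask_flagged_degenerate(self):
        trace = trace_from_mask(np.zeros((10, 10), dtype=bool))
        afm.skeletonize_and_decompose(trace)
        assert trace.degenerate

    def test_segments_partition_skeleton_lengths(self, small_scene):
        hm, _ = small_scene
        traces, _, _, _ = afm.analyze_height_map(hm)
        for t in traces:
            assert t.total_contour_length == pytest.approx(sum(t.segment_lengths))


class TestContourLength:
    def test_horizontal_path(self):
        path = np.column_stack([np.zeros(101, dtype=int), np.arange(101)])
        assert afm.contour_length(path, 1.0, 1.0) == pytest.approx(100.0)

    def test_diagonal_path(self):
        path = np.column_stack([np.arange(101), np.arange(101)])
        assert afm.contour_length(path, 1.0, 1.0) == pytest.approx(100 * math.sqrt(2))

    def test_anisotropic_pixels(self):
        path = np.column_stack([np.arange(11), np.zeros(11, dtype=int)])
        assert afm.contour_length(path, 1.0, 2.0) == pytest.approx(20.0)

    def test_non_adjacent_pixels_raise(self):
        with pytest.raises(PathError):
            afm.contour_length(np.array([[0, 0], [0, 2]]), 1.0, 1.0)

    def test_rotation_invariance_of_path_length(self):
        # rotating a pixel path by 90 degrees maps horizontal steps to
        # vertical ones and leaves the weighted length unchanged
        rng = np.random.default_rng(4)
        steps = rng.integers(-1, 2, size=(80, 2))
        steps = steps[np.any(steps != 0, axis=1)]
        path = np.cumsum(np.vstack([[0, 0], steps]), axis=0)
        keep = np.ones(len(path), dtype=bool)
        keep[1:] = np.any(np.diff(path, axis=0) != 0, axis=1)
        path = path[keep]
        rotated = np.column_stack([path[:, 1], -path[:, 0]])
        assert afm.contour_length(rotated, 1.0, 1.0) == pytest.approx(
            afm.contour_length(path, 1.0, 1.0)
        )

    def test_traced_straight_rod_recovers_length(self):
        # rendered 340-nm straight chain traced to within 5%
        rp = syn.RenderParams(extent=(400, 400), noise_sigma=0.0)
        chain = np.column_stack([np.linspace(30.0, 370.0, 341), np.full(341, 200.0)])
        hm, _ = syn.render_afm_scene([chain], [], rp, seed=0)
        traces = afm.segment_molecules(hm, 0.0)
        assert len(traces) == 1
        afm.skeletonize_and_decompose(traces[0])
        assert traces[0].total_contour_length == pytest.approx(340, rel=0.05)


class TestVolume:
    def test_flat_region_zero(self):
        trace = trace_from_mask(make_rod_mask())
        assert afm.molecule_volume(trace, HeightMap(np.zeros(trace.mask.shape)), 0.0) == 0.0

    def test_single_pixel_formula(self):
        grid = np.zeros((5, 5))
        grid[2, 2] = 2.0
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        v = afm.molecule_volume(trace_from_mask(mask), HeightMap(grid), 0.0)
        assert v == pytest.approx(2.0)

    def test_gaussian_bump_analytic_volume(self):
        # amplitude A, width sigma: integral = 2 pi sigma^2 A
        yy, xx = np.mgrid[0:101, 0:101].astype(float)
        sigma, amp = 5.0, 2.0
        grid = amp * np.exp(-((yy - 50) ** 2 + (xx - 50) ** 2) / (2 * sigma**2))
        mask = grid > 1e-6
        v = afm.molecule_volume(trace_from_mask(mask), HeightMap(grid), 0.0)
        assert v == pytest.approx(2 * math.pi * sigma**2 * amp, rel=0.01)

    def test_matches_brute_force_on_random_masks(self):
        # independent per-pixel loop oracle, exact agreement
        rng = np.random.default_rng(3)
        from scipy.ndimage import binary_fill_holes

        for _ in range(50):
            grid = rng.normal(0.5, 0.5, size=(24, 24))
            mask = rng.random((24, 24)) > 0.6
            hm = HeightMap(grid)
            v = afm.molecule_volume(trace_from_mask(mask), hm, 0.1)
            brute = 0.0
            region = binary_fill_holes(mask)
            for r in range(24):
                for c in range(24):
                    if region[r, c]:
                        brute += max(grid[r, c] - 0.1, 0.0)
            assert v == pytest.approx(brute, abs=1e-9)

    def test_additivity_of_disjoint_molecules(self):
        rp = syn.RenderParams(extent=(200, 200), noise_sigma=0.0)
        wlc = syn.WLCParams(contour_length=120, persistence_length=50, seed=0)
        hm, man = syn.simulate_afm_scene(
            n_chains=2, wlc=wlc, rp=None, particle_mean=0.0, seed=33
        )
        traces = afm.segment_molecules(hm, 0.0)
        assert len(traces) == 2
        vols = [afm.molecule_volume(t, hm, 0.0) for t in traces]
        total_mask = np.zeros(hm.shape, dtype=bool)
        for t in traces:
            r0, c0 = t.origin
            total_mask[r0 : r0 + t.mask.shape[0], c0 : c0 + t.mask.shape[1]] |= t.mask
        whole = MoleculeTrace(
            molecule_id=0, mask=total_mask, origin=(0, 0),
            boundary=np.zeros((0, 2), dtype=int),
        )
        assert afm.molecule_volume(whole, hm, 0.0) == pytest.approx(sum(vols), rel=1e-9)


class TestParticleDetection:
    def test_bare_chain_no_particles(self):
        wlc = syn.WLCParams(contour_length=200, persistence_length=50, seed=0)
        hm, _ = syn.simulate_afm_scene(n_chains=1, wlc=wlc, particle_mean=0.0, seed=2)
        traces, particles, _, _ = afm.analyze_height_map(hm)
        assert particles == [[]]

    def _scene_with_particle(self, end_bias):
        rp = syn.RenderParams(extent=(300, 300), noise_sigma=0.0)
        chain = np.column_stack([np.linspace(50.0, 250.0, 201), np.full(201, 150.0)])
        specs = syn.place_particles(chain, 1, end_bias=end_bias, seed=8)
        hm, man = syn.render_afm_scene([chain], specs, rp, seed=0)
        traces, particles, _, _ = afm.analyze_height_map(hm)
        assert len(traces) == 1 and len(particles[0]) == 1
        return man.particles[0], particles[0][0]

    def test_terminal_particle_classified_end(self):
        truth, rec = self._scene_with_particle(end_bias=1.0)
        assert truth["placement_class"] == "end"
        assert rec.placement_class == "end"

    def test_interstitial_particle_classified_interstitial(self):
        truth, rec = self._scene_with_particle(end_bias=0.0)
        assert truth["placement_class"] == "interstitial"
        assert rec.placement_class == "interstitial"


class TestStoichiometry:
    def test_reference_volume_from_mass_and_density(self):
        # 17,970 Da at 1.44 g/cm^3 -> 2.072e-20 cm^3 = 20.7 nm^3
        v = afm.protein_reference_volume(17970, 1.44)
        assert v == pytest.approx(20.7, abs=0.05)

    def test_density_proportionality(self):
        assert afm.protein_reference_volume(10000, 2.88) == pytest.approx(
            afm.protein_reference_volume(10000, 1.44) / 2
        )

    def test_nonpositive_mass_raises(self):
        with pytest.raises(ParameterError):
            afm.protein_reference_volume(0, 1.44)

    def test_study_worked_example(self):
        assert afm.bound_trimer_count(303, 20.7, 2.2) == pytest.approx(6.65, abs=0.005)

    def test_identity_and_zero(self):
        assert afm.bound_trimer_count(20.7 * 2.2, 20.7, 2.2) == pytest.approx(1.0)
        assert afm.bound_trimer_count(0, 20.7, 2.2) == 0.0

    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        vd=st.floats(min_value=1.0, max_value=1000.0),
        vp=st.floats(min_value=1.0, max_value=100.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_common_rescaling(self, scale, vd, vp):
        a = afm.bound_trimer_count(vd, vp, 2.2)
        b = afm.bound_trimer_count(vd * scale, vp * scale, 2.2)
        assert b == pytest.approx(a, rel=1e-9)

    def test_recovery_from_rendered_scenes(self):
        # each binding site carries k trimers (particle volume k * V_p); the
        # volume-difference estimator recovers k
        vp, k_true = 20.7, 3
        bare, bound, counts = [], [], []
        for s in range(8):
            hm0, _ = syn.simulate_afm_scene(n_chains=1, seed=500 + s, particle_mean=0.0)
            _, _, v0, _ = afm.analyze_height_map(hm0)
            bare += v0
            hm1, _ = syn.simulate_afm_scene(
                n_chains=1, seed=700 + s, particle_mean=2.2, particle_volume=k_true * vp
            )
            _, pp, v1, _ = afm.analyze_height_map(hm1)
            for i, plist in enumerate(pp):
                if plist:
                    bound.append(v1[i])
                    counts.append(len(plist))
        v_d = np.mean(bound) - np.mean(bare)
        n_bound = afm.bound_trimer_count(v_d, vp, np.mean(counts))
        assert n_bound == pytest.approx(k_true, rel=0.15)


class TestSummaries:
    def test_empty_scene_empty_tables(self):
        per_molecule, grouped = afm.summarize_scene([], [], [])
        assert per_molecule.empty and grouped.empty

    def test_grouped_counts_match_manifest(self, small_scene):
        hm, manifest = small_scene
        traces, particles, volumes, _ = afm.analyze_height_map(hm)
        per_molecule, grouped = afm.summarize_scene(traces, particles, volumes)
        assert len(per_molecule) == len(manifest.chains)
        assert grouped["n_molecules"].sum() == len(manifest.chains)
        # detected-particle total matches rendered truth on clean scenes
        assert per_molecule["n_particles"].sum() == len(manifest.particles)

    def test_bare_chain_group_mean_near_truth(self):
        lengths = []
        for s in range(10):
            hm, man = syn.simulate_afm_scene(
                n_chains=1, seed=1000 + s, particle_mean=0.0,
                wlc=syn.WLCParams(contour_length=340, persistence_length=50, seed=s),
            )
            traces, particles, volumes, _ = afm.analyze_height_map(hm)
            _, grouped = afm.summarize_scene(traces, particles, volumes)
            row = grouped[grouped["n_particles_bin"] == "0"]
            lengths.append(float(row["contour_length_mean_nm"].iloc[0]))
        assert np.mean(lengths) == pytest.approx(340, rel=0.10)
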