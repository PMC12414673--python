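"""Leaflet assignment, thickness maps and thickness distributions."""

import numpy as np
import pytest

from bilayerscope import synth, thickness
from bilayerscope.model import (
    LEAFLET_LOWER,
    LEAFLET_UPPER,
    ROLE_PHOSPHORUS,
    Trajectory,
)

from conftest import flat_phosphate_frame, make_frame


def sinusoid_frame(n_side=30, box=60.0, base=18.0, amp=2.0):
    """Leaflets at z = ±(base + amp sin(2πx/L)): analytic thickness."""
    xs = (np.arange(n_side) + 0.5) * box / n_side
    X, Y = np.meshgrid(xs, xs)
    wave = base + amp * np.sin(2 * np.pi * X.ravel() / box)
    coords, lids, leaf = [], [], []
    for sign, name in ((1.0, LEAFLET_UPPER), (-1.0, LEAFLET_LOWER)):
        for x, y, w in zip(X.ravel(), Y.ravel(), wave):
            coords.append([x, y, 50.0 + sign * w])
        lids.extend(range(len(lids), len(lids) + X.size))
        leaf.extend([name] * X.size)
    return make_frame(np.array(coords), [box, box, 100.0],
                      [ROLE_PHOSPHORUS] * 2 * X.size, lipid_id=lids,
                      leaflet=leaf)


class TestAssignLeaflets:
    def test_mirrored_fixture_splits_evenly(self, gel_frame):
        _, labels = thickness.assign_leaflets(gel_frame)
        up = np.count_nonzero(labels == LEAFLET_UPPER)
        assert up == labels.size - up

    def test_invariant_under_z_translation(self, fluid_frame):
        lids, ref = thickness.assign_leaflets(fluid_frame)
        moved = fluid_frame.translated([0.0, 0.0, 17.3])
        _, out = thickness.assign_leaflets(moved)
        assert np.array_equal(out, ref)

    def test_interdigitated_fixture_still_two_leaflets(self):
        frame = synth.build_bilayer(
            synth.BilayerSpec.gel(16, seed=2, interdigitated=True))
        _, labels = thickness.assign_leaflets(frame)
        assert set(labels) == {LEAFLET_UPPER, LEAFLET_LOWER}

    def test_one_sided_system_warns(self):
        frame = flat_phosphate_frame()
        keep = frame.coords[:, 2] > 50.0
        one_sided = make_frame(frame.coords[keep], frame.box,
                               frame.roles[keep],
                               lipid_id=frame.lipid_id[keep],
                               leaflet=frame.leaflet[keep])
        with pytest.warns(UserWarning, match="degenerate"):
            thickness.assign_leaflets(one_sided)


class TestThicknessMap:
    @pytest.mark.parametrize("grid", [20, 100])
    def test_flat_planes_exact_at_every_node(self, grid):
        frame = flat_phosphate_frame(sep=42.0)
        tmap = thickness.thickness_map(frame, grid=grid)
        assert np.allclose(tmap.thickness, 42.0, atol=1e-9)

    def test_sinusoidal_leaflets_match_analytic_surface(self):
        frame = sinusoid_frame()
        tmap = thickness.thickness_map(frame, grid=60)
        X = tmap.x[:, None] * np.ones_like(tmap.y)[None, :]
        expected = 36.0 + 4.0 * np.sin(2 * np.pi * X / frame.box[0])
        assert np.allclose(tmap.thickness, expected, atol=0.05)

    def test_equivariant_under_wrapped_inplane_translation(self, gel_frame):
        ref = thickness.thickness_map(gel_frame, grid=40)
        moved = gel_frame.translated([gel_frame.box[0] / 2, 0.0, 0.0],
                                     wrap=True)
        out = thickness.thickness_map(moved, grid=40)
        # the thickness field shifts by exactly half the box: roll nodes
        assert np.allclose(np.roll(out.thickness, -20, axis=0),
                           ref.thickness, atol=0.3)

    def test_mask_matches_point_in_ellipse_oracle(self, barrel_frame):
        tmap = thickness.thickness_map(barrel_frame, grid=60)
        ell = barrel_frame.metadata["ellipse"]
        prot = barrel_frame.select("protein_heavy")
        z0 = barrel_frame.coords[
            barrel_frame.select(ROLE_PHOSPHORUS), 2].mean()
        pz = barrel_frame.coords[prot, 2]
        brute = np.zeros_like(tmap.mask)
        X = tmap.x[:, None] * np.ones_like(tmap.y)[None, :]
        Y = np.ones_like(tmap.x)[:, None] * tmap.y[None, :]
        for half in (pz >= z0, pz < z0):
            com = barrel_frame.coords[prot[half], :2].mean(axis=0)
            brute |= (((X - com[0]) / ell["semi_axis_a"]) ** 2
                      + ((Y - com[1]) / ell["semi_axis_b"]) ** 2) < 1.0
        assert np.array_equal(tmap.mask, brute)
        assert tmap.mask.any()

    def test_layer_annuli_are_disjoint_rings(self, barrel_frame):
        tmap = thickness.thickness_map(barrel_frame, grid=60,
                                       layers=(5.0, 9.5))
        s1, s2 = tmap.layer_masks["shell1"], tmap.layer_masks["shell2"]
        assert not np.any(s1 & s2)
        assert not np.any(s1 & tmap.mask)
        assert s1.sum() > 0 and s2.sum() > 0

    def test_degenerate_phosphorus_set_rejected(self):
        coords = np.array([[x, 10.0, 30.0 + 20.0 * s]
                           for s in (0, 1) for x in (5.0, 10.0, 15.0)])
        frame = make_frame(coords, [60.0, 60.0, 60.0],
                           [ROLE_PHOSPHORUS] * 6,
                           lipid_id=list(range(6)),
                           leaflet=[LEAFLET_LOWER] * 3
                           + [LEAFLET_UPPER] * 3)
        with pytest.raises(Exception):
            thickness.thickness_map(frame, grid=10)


class TestThicknessDistribution:
    def test_flat_fixture_single_mode_zero_variance(self):
        frame = flat_phosphate_frame(sep=38.0)
        dist = thickness.thickness_distribution(frame, grid=40,
                                                window_ns=None)
        assert dist.samples.std() == pytest.approx(0.0, abs=1e-9)
        assert dist.main_mode == pytest.approx(38.0, abs=0.5)
        assert dist.modes.size == 1

    def test_two_region_mixture_is_bimodal(self):
        # left half of the box at 42 Å separation, right half at 30 Å
        n, box = 16, 80.0
        xs = (np.arange(n) + 0.5) * box / n
        X, Y = np.meshgrid(xs, xs)
        half = 21.0 * (X.ravel() < box / 2) + 15.0 * (X.ravel() >= box / 2)
        coords, lids, leaf = [], [], []
        for sign, name in ((1.0, LEAFLET_UPPER), (-1.0, LEAFLET_LOWER)):
            for x, y, h in zip(X.ravel(), Y.ravel(), half):
                coords.append([x, y, 50.0 + sign * h])
            lids.extend(range(len(lids), len(lids) + X.size))
            leaf.extend([name] * X.size)
        frame = make_frame(np.array(coords), [box, box, 100.0],
                           [ROLE_PHOSPHORUS] * 2 * X.size,
                           lipid_id=lids, leaflet=leaf)
        dist = thickness.thickness_distribution(frame, grid=60,
                                                window_ns=None)
        assert dist.modes.size >= 2
        top_two = sorted(dist.modes[:2])
        assert top_two[0] == pytest.approx(30.0, abs=1.0)
        assert top_two[1] == pytest.approx(42.0, abs=1.0)

    def test_gel_mode_exceeds_fluid_mode(self, gel_frame, fluid_frame):
        gel = thickness.thickness_distribution(gel_frame, grid=40,
                                               window_ns=None)
        fluid = thickness.thickness_distribution(fluid_frame, grid=40,
                                                 window_ns=None)
        assert gel.main_mode > fluid.main_mode

    def test_grid_refinement_stable(self, gel_frame):
        coarse = thickness.thickness_distribution(gel_frame, grid=100,
                                                  window_ns=None)
        fine = thickness.thickness_distribution(gel_frame, grid=200,
                                                window_ns=None)
        assert abs(coarse.main_mode - fine.main_mode) <= 0.5

    def test_stride_and_window_select_frames(self):
        traj = synth.build_bilayer(synth.BilayerSpec.gel(
            9, seed=4, n_frames=6, frame_spacing_ns=0.1))
        # window keeps t in [0.1, 0.5] (5 frames); stride takes every 2nd
        dist = thickness.thickness_distribution(
            traj, grid=20, stride_ns=0.2, window_ns=0.4)
        assert dist.n_frames == 3
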