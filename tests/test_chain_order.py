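"""Dihedral classification, gauche fraction, APL, S_CH, running averages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilayerscope import chain_order as co
from bilayerscope import synth
from bilayerscope.errors import SelectionError
from bilayerscope.model import ROLE_CHAIN_CARBON, LEAFLET_UPPER

from conftest import make_frame


def frame_with_chains(chains, box=200.0):
    """One lipid per chain, centered in a large box (no wrapping)."""
    coords, lids, chain_ix, carbon_ix, leaflet = [], [], [], [], []
    for i, chain in enumerate(chains):
        chain = np.asarray(chain) + np.array([box / 2, box / 2, box / 2])
        n = chain.shape[0]
        coords.append(chain)
        lids.extend([i] * n)
        chain_ix.extend([0] * n)
        carbon_ix.extend(range(1, n + 1))
        leaflet.extend([LEAFLET_UPPER] * n)
    coords = np.vstack(coords)
    return make_frame(coords, [box, box, box],
                      [ROLE_CHAIN_CARBON] * len(coords), lipid_id=lids,
                      chain=chain_ix, carbon=carbon_ix, leaflet=leaflet)


class TestClassifyDihedral:
    @pytest.mark.parametrize("angle,label", [
        (60.0, "gauche+"), (180.0, "trans"), (300.0, "gauche-"),
        (0.0, "gauche+"), (119.99, "gauche+"), (120.0, "trans"),
        (239.99, "trans"), (240.0, "gauche-"), (359.99, "gauche-"),
        (-60.0, "gauche-"),       # canonicalized to 300
    ])
    def test_window_boundaries(self, angle, label):
        assert co.classify_dihedral(angle) == label

    def test_non_finite_angle_rejected(self):
        with pytest.raises(ValueError):
            co.classify_dihedral(float("nan"))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 359.999), min_size=1, max_size=50))
    def test_three_windows_partition_the_circle(self, angles):
        labels = [co.classify_dihedral(a) for a in angles]
        counts = {lab: labels.count(lab)
                  for lab in ("gauche+", "trans", "gauche-")}
        assert sum(counts.values()) == len(angles)
        assert counts["gauche+"] + counts["gauche-"] == \
            int(np.count_nonzero(co.is_gauche(angles)))


class TestGaucheFraction:
    def test_all_trans_fixture_is_zero(self, gel_frame):
        assert co.gauche_fraction(gel_frame).f_g == 0.0

    def test_three_of_eleven_gauche(self):
        angles = [60.0, 300.0, 60.0] + [180.0] * 8
        frame = frame_with_chains([synth.chain_from_dihedrals(angles)])
        summary = co.gauche_fraction(frame)
        assert summary.f_g == pytest.approx(3 / 11)
        assert summary.n_dihedrals == 11

    def test_matches_brute_force_per_dihedral_count(self, fluid_frame):
        angles = co.frame_dihedrals(fluid_frame)
        brute = sum(co.classify_dihedral(a) != "trans"
                    for a in angles.ravel()) / angles.size
        assert co.gauche_fraction(fluid_frame).f_g == pytest.approx(
            brute, abs=1e-12)

    def test_invariant_under_rigid_rotation_translation(self):
        rng = np.random.default_rng(3)
        chains = [synth.build_chain(14, 0.4, rng)[0] for _ in range(10)]
        frame = frame_with_chains(chains)
        ref = co.gauche_fraction(frame).f_g
        # random proper rotation + translation
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rot = frame.copy()
        rot.coords = rot.coords @ q.T + np.array([3.0, -7.0, 11.0])
        assert co.gauche_fraction(rot).f_g == pytest.approx(ref, abs=1e-12)

    def test_empty_subset_is_selection_error(self, fluid_frame):
        with pytest.raises(SelectionError):
            co.gauche_fraction(fluid_frame, subset=np.array([99999]))

    def test_replica_aggregation(self):
        reps = [synth.build_bilayer(synth.BilayerSpec.fluid(16, seed=s))
                for s in (1, 2, 3)]
        summary = co.gauche_fraction(reps)
        singles = [co.gauche_fraction(r).f_g for r in reps]
        assert summary.f_g == pytest.approx(np.mean(singles))
        assert summary.sd_replicas == pytest.approx(np.std(singles, ddof=1))


class TestAreaPerLipid:
    def test_direct_arithmetic(self):
        frame = make_frame(
            np.zeros((3, 3)) + 1.0, [60.0, 60.0, 50.0],
            ["glycerol_C"] * 3, lipid_id=[0, 1, 2],
            leaflet=[LEAFLET_UPPER] * 3)
        assert co.area_per_lipid(frame) == pytest.approx(60.0 * 60.0 / 3)

    def test_generator_round_trip(self):
        frame = synth.build_bilayer(
            synth.BilayerSpec(25, area_per_lipid=50.0, seed=1))
        assert co.area_per_lipid(frame) == pytest.approx(50.0)

    def test_protein_carving_raises_apl(self, barrel_frame, fluid_frame):
        frame = synth.build_bilayer(synth.BilayerSpec.fluid(64, seed=14))
        assert co.area_per_lipid(barrel_frame) > co.area_per_lipid(frame)

    def test_empty_leaflet_rejected(self, fluid_frame):
        with pytest.raises(SelectionError):
            co.area_per_lipid(fluid_frame, leaflet="sideways")


class TestNormalizedVolume:
    def test_reference_maps_to_one_and_others_below(self):
        out = co.normalized_volume({"a": 100.0, "b": 80.0, "c": 95.0})
        assert out["a"] == 1.0
        assert out["b"] == pytest.approx(0.8)
        assert all(v <= 1.0 for v in out.values())

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            co.normalized_volume([100.0, -5.0])


class TestSchOrderParameters:
    def test_z_aligned_all_trans_is_minus_half(self):
        # align the zigzag axis (C1->C3 direction) exactly with z: every
        # rebuilt C-H bond is then perpendicular to the normal
        base, _ = synth.build_chain(14, 0.0, seed=0)
        axis = base[2] - base[0]
        chain = base @ synth._rotation_onto_z(axis / np.linalg.norm(axis)).T
        _, S = co.sch_order_parameters(frame_with_chains([chain]))
        assert np.allclose(S, -0.5, atol=1e-9)

    def test_gel_bilayer_is_near_minus_half(self):
        frame = synth.build_bilayer(synth.BilayerSpec.gel(
            16, seed=0, jitter_xy=0.0, jitter_z=0.0))
        _, S = co.sch_order_parameters(frame)
        # chains anchor their end-to-end vector (not the zigzag axis)
        # along the normal, a ~3 degree residual tilt
        assert np.allclose(S, -0.5, atol=0.01)

    def test_isotropic_chains_average_to_zero(self):
        rng = np.random.default_rng(8)
        chains = []
        base, _ = synth.build_chain(14, 0.0, seed=0)
        for _ in range(3000):
            q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            chains.append(base @ q.T)
        _, S = co.sch_order_parameters(frame_with_chains(chains, box=400.0))
        assert np.all(np.abs(S) < 0.05)

    def test_bounded(self, fluid_frame):
        _, S = co.sch_order_parameters(fluid_frame)
        assert np.all(S >= -0.5 - 1e-12) and np.all(S <= 1.0 + 1e-12)

    def test_gel_more_ordered_than_fluid(self, gel_frame, fluid_frame):
        _, Sg = co.sch_order_parameters(gel_frame)
        _, Sf = co.sch_order_parameters(fluid_frame)
        assert np.abs(Sg).mean() > np.abs(Sf).mean()

    def test_too_few_carbons_rejected(self):
        frame = frame_with_chains([np.array([[0, 0, 0], [0, 0, 1.53]])])
        with pytest.raises(SelectionError):
            co.sch_order_parameters(frame)


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        y = np.full(50, 3.7)
        assert np.allclose(co.running_average(y, 100.0, 10.0), y)

    def test_unit_step_midpoint_is_half(self):
        y = np.concatenate([np.zeros(50), np.ones(50)])
        out = co.running_average(y, 11.0, 1.0)
        # the boxcar straddles the step symmetrically around index 49.5
        assert (out[49] + out[50]) / 2 == pytest.approx(0.5, abs=1e-12)
        assert abs(out[49] - 0.5) < 0.06 and abs(out[50] - 0.5) < 0.06

    def test_full_window_gives_global_mean(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=21)
        out = co.running_average(y, 21.0, 1.0)
        assert out[10] == pytest.approx(y.mean())

    def test_subsample_window_rejected(self):
        with pytest.raises(ValueError):
            co.running_average(np.ones(5), 0.5, 1.0)
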