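"""Generator tests: chain growth, bilayer assembly, barrel embedding,
synthetic pressure series."""

import math

import numpy as np
import pytest

from bilayerscope import chain_order, nmr, synth
from bilayerscope.errors import InvalidSpecError, PackingError
from bilayerscope.model import (
    LEAFLET_LOWER,
    LEAFLET_UPPER,
    ROLE_GLYCEROL,
    ROLE_PHOSPHORUS,
)


def measured_dihedrals(coords):
    return chain_order.dihedral_angles(coords[:-3], coords[1:-2],
                                       coords[2:-1], coords[3:])


class TestBuildChain:
    def test_myristoyl_chain_has_eleven_dihedrals(self):
        _, dihedrals = synth.build_chain(14, 0.3, seed=0)
        assert dihedrals.size == 11

    def test_too_short_chain_rejected(self):
        with pytest.raises(InvalidSpecError):
            synth.build_chain(3, 0.0, seed=0)

    def test_all_trans_extent_matches_zigzag_geometry(self):
        coords, dihedrals = synth.build_chain(14, 0.0, seed=5)
        assert np.all(dihedrals == 180.0)
        # 13 bonds x 1.27 Å rise along the chain axis
        expected = 13 * synth.CC_BOND * math.sin(math.radians(55.5))
        assert coords[-1, 2] == pytest.approx(expected, abs=0.15)
        assert coords[-1, 2] == pytest.approx(16.5, abs=0.2)

    def test_all_gauche_chain_stays_in_gauche_windows(self):
        coords, dihedrals = synth.build_chain(14, 1.0, seed=2)
        meas = measured_dihedrals(coords)
        assert np.all(chain_order.is_gauche(dihedrals))
        assert np.all(chain_order.is_gauche(meas))

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.7, 1.0])
    def test_realized_geometry_reproduces_requested_dihedrals(self, p):
        coords, requested = synth.build_chain(14, p, seed=7)
        meas = measured_dihedrals(coords)
        diff = np.abs((meas - requested + 180.0) % 360.0 - 180.0)
        assert np.all(diff < 1e-6)

    def test_chain_from_explicit_dihedrals(self):
        angles = [60.0, 300.0, 180.0, 180.0, 60.0]
        coords = synth.chain_from_dihedrals(angles)
        assert coords.shape == (8, 3)
        assert np.allclose(measured_dihedrals(coords), angles, atol=1e-6)

    def test_seed_determinism(self):
        a, da = synth.build_chain(14, 0.5, seed=42)
        b, db = synth.build_chain(14, 0.5, seed=42)
        c, _ = synth.build_chain(14, 0.5, seed=43)
        assert np.array_equal(a, b) and np.array_equal(da, db)
        assert not np.array_equal(a, c)


class TestBuildBilayer:
    def test_box_area_equals_lipids_times_apl(self):
        frame = synth.build_bilayer(
            synth.BilayerSpec(64, area_per_lipid=60.0, seed=0))
        assert frame.box[0] * frame.box[1] == pytest.approx(64 * 60.0)

    def test_leaflets_mirrored_with_equal_counts(self, fluid_frame):
        lids = fluid_frame.lipid_ids()
        leaf = fluid_frame.lipid_leaflets()
        upper = sum(1 for v in leaf.values() if v == LEAFLET_UPPER)
        lower = sum(1 for v in leaf.values() if v == LEAFLET_LOWER)
        assert upper == lower == lids.size // 2

    def test_gel_phosphate_plane_separation(self):
        # untilted all-trans chains, no jitter: 2 x (chain rise + offset)
        frame = synth.build_bilayer(synth.BilayerSpec.gel(
            16, seed=0, jitter_xy=0.0, jitter_z=0.0))
        p = frame.select(ROLE_PHOSPHORUS)
        z = frame.coords[p, 2]
        mid = z.mean()
        sep = z[z > mid].mean() - z[z < mid].mean()
        assert sep == pytest.approx(2 * (16.5 + 4.6), abs=0.5)

    def test_gel_thicker_than_fluid_at_equal_head_offset(
            self, gel_frame, fluid_frame):
        def sep(frame):
            z = frame.coords[frame.select(ROLE_PHOSPHORUS), 2]
            return z[z > z.mean()].mean() - z[z < z.mean()].mean()
        assert sep(gel_frame) > sep(fluid_frame)

    def test_interdigitation_reduces_separation_by_depth(self):
        base = synth.BilayerSpec.gel(16, seed=3, jitter_z=0.0)
        inter = synth.BilayerSpec.gel(16, seed=3, jitter_z=0.0,
                                      interdigitated=True,
                                      interdigitation_depth=12.0)
        def sep(spec):
            frame = synth.build_bilayer(spec)
            z = frame.coords[frame.select(ROLE_PHOSPHORUS), 2]
            return z[z > z.mean()].mean() - z[z < z.mean()].mean()
        assert sep(base) - sep(inter) == pytest.approx(12.0, abs=0.1)

    def test_all_atoms_inside_periodic_box(self, fluid_frame, gel_frame):
        for frame in (fluid_frame, gel_frame):
            assert np.all(frame.coords >= 0.0)
            assert np.all(frame.coords <= frame.box + 1e-9)

    def test_overpacked_lattice_rejected(self):
        with pytest.raises(PackingError):
            synth.build_bilayer(synth.BilayerSpec(16, area_per_lipid=20.0))

    def test_seed_determinism_and_count_stability(self):
        spec = synth.BilayerSpec.fluid(16, seed=9)
        a = synth.build_bilayer(spec)
        b = synth.build_bilayer(spec)
        c = synth.build_bilayer(synth.BilayerSpec.fluid(16, seed=10))
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)
        assert a.n_atoms == c.n_atoms
        assert a.lipid_ids().size == c.lipid_ids().size

    def test_realized_gauche_fraction_within_binomial_error(self):
        p = 0.5
        traj = synth.build_bilayer(synth.BilayerSpec(
            64, gauche_prob=p, seed=21, n_frames=8))
        summary = chain_order.gauche_fraction(traj, window_ns=None)
        assert summary.n_dihedrals >= 10_000
        se = math.sqrt(p * (1 - p) / summary.n_dihedrals)
        assert abs(summary.f_g - p) < 3 * se


class TestEmbedBarrel:
    def test_default_cross_section_in_barrel_band(self):
        e = synth.EllipseSpec()
        assert 600.0 <= e.area <= 700.0
        assert e.area == pytest.approx(math.pi * 17 * 12)

    def test_no_glycerol_remains_inside_ellipse(self, barrel_frame):
        ell = barrel_frame.metadata["ellipse"]
        cx, cy = ell["center"]
        _, gly = barrel_frame.glycerol_positions()
        q = (((gly[:, 0] - cx) / ell["semi_axis_a"]) ** 2
             + ((gly[:, 1] - cy) / ell["semi_axis_b"]) ** 2)
        assert np.all(q >= 1.0)

    def test_carved_count_matches_point_in_ellipse_oracle(self):
        frame = synth.build_bilayer(synth.BilayerSpec.fluid(64, seed=31))
        ell = synth.EllipseSpec()
        cx, cy = frame.box[0] / 2, frame.box[1] / 2
        _, gly = frame.glycerol_positions()
        inside = (((gly[:, 0] - cx) / ell.semi_axis_a) ** 2
                  + ((gly[:, 1] - cy) / ell.semi_axis_b) ** 2) < 1.0
        carved = synth.embed_barrel(frame, ell, seed=0)
        n_before = frame.lipid_ids().size
        n_after = carved.lipid_ids().size
        assert n_after == n_before - int(inside.sum())
        assert carved.metadata["n_lipids_carved"] == int(inside.sum())

    def test_beta_fraction_of_pseudo_atoms(self, barrel_frame):
        prot = barrel_frame.roles == "protein_heavy"
        assert prot.sum() == 256
        assert barrel_frame.beta[prot].sum() == round(0.75 * 256)

    def test_oversized_ellipse_rejected(self):
        frame = synth.build_bilayer(synth.BilayerSpec.fluid(9, seed=0))
        big = synth.EllipseSpec(semi_axis_a=25.0, semi_axis_b=8.0,
                                area_band=(400.0, 700.0))
        with pytest.raises(InvalidSpecError):
            synth.embed_barrel(frame, big, seed=0)


class TestPressureSeries:
    def test_two_state_population_is_half_at_midpoint(self):
        spec = synth.NmrSynthSpec(
            Pm=600.0, width=100.0, noise_sd=0.0, two_state=True,
            pressures=(1.0, 300.0, 600.0, 900.0, 1200.0, 1500.0))
        _, two = synth.synth_pressure_series(spec)
        p_g, _ = nmr.two_state_populations(two)
        assert p_g[2] == pytest.approx(0.5, abs=1e-12)

    def test_noiseless_series_plateaus_and_monotonicity(self):
        spec = synth.NmrSynthSpec(Pm=1200.0, width=80.0, noise_sd=0.0)
        s = synth.synth_pressure_series(spec)
        assert s.intensity[0] == pytest.approx(spec.plateau_high, abs=1e-3)
        assert np.all(np.diff(s.intensity) <= 1e-12)

    def test_fit_recovers_generator_midpoint(self):
        s = synth.synth_pressure_series(
            synth.NmrSynthSpec(Pm=750.0, width=120.0, noise_sd=0.0))
        fit = nmr.fit_transition(s)
        assert not fit.rejected
        assert fit.Pm == pytest.approx(750.0, abs=1.0)

    def test_missing_ambient_point_rejected(self):
        with pytest.raises(InvalidSpecError):
            synth.NmrSynthSpec(pressures=(100.0, 500.0, 1000.0, 1500.0,
                                          2000.0))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidSpecError):
            synth.NmrSynthSpec(width=0.0)
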