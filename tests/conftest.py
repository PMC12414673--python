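"""Shared fixtures: small synthetic membranes built once per session."""

import numpy as np
import pytest

from bilayerscope import synth
from bilayerscope.model import (
    LEAFLET_LOWER,
    LEAFLET_UPPER,
    ROLE_GLYCEROL,
    ROLE_PHOSPHORUS,
    AtomFrame,
)


@pytest.fixture(scope="session")
def gel_frame():
    """All-trans gel bilayer, 36 lipids per leaflet."""
    return synth.build_bilayer(synth.BilayerSpec.gel(36, seed=11))


@pytest.fixture(scope="session")
def fluid_frame():
    """Disordered fluid bilayer, 36 lipids per leaflet."""
    return synth.build_bilayer(synth.BilayerSpec.fluid(36, seed=12))


@pytest.fixture(scope="session")
def fluid_traj():
    """Three-frame fluid trajectory (independent redraws)."""
    return synth.build_bilayer(
        synth.BilayerSpec.fluid(25, seed=13, n_frames=3))


@pytest.fixture(scope="session")
def barrel_frame():
    """Fluid bilayer with an embedded elliptical β-barrel."""
    frame = synth.build_bilayer(synth.BilayerSpec.fluid(64, seed=14))
    return synth.embed_barrel(frame, synth.EllipseSpec(), seed=14)


def make_frame(coords, box, roles, lipid_id=None, chain=None, carbon=None,
               leaflet=None, beta=None, time=0.0):
    """Assemble an AtomFrame from partial annotations (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return AtomFrame(
        coords=coords,
        box=np.asarray(box, dtype=float),
        roles=np.asarray(roles, dtype=object),
        lipid_id=np.full(n, -1) if lipid_id is None else np.asarray(lipid_id),
        chain=np.full(n, -1) if chain is None else np.asarray(chain),
        carbon=np.full(n, -1) if carbon is None else np.asarray(carbon),
        leaflet=(np.full(n, "", dtype=object) if leaflet is None
                 else np.asarray(leaflet, dtype=object)),
        beta=np.zeros(n, dtype=bool) if beta is None else np.asarray(beta),
        time=time,
    )


def flat_phosphate_frame(sep=42.0, box_xy=60.0, n_side=5):
    """Frame with phosphorus planes at ±sep/2: exact thickness oracle."""
    xs = (np.arange(n_side) + 0.5) * box_xy / n_side
    X, Y = np.meshgrid(xs, xs)
    n = X.size
    coords, lids, leaf = [], [], []
    for sign, name in ((1.0, LEAFLET_UPPER), (-1.0, LEAFLET_LOWER)):
        for x, y in zip(X.ravel(), Y.ravel()):
            coords.append([x, y, 50.0 + sign * sep / 2.0])
        lids.extend(range(len(lids), len(lids) + n))
        leaf.extend([name] * n)
    coords = np.array(coords)
    return make_frame(coords, [box_xy, box_xy, 100.0],
                      [ROLE_PHOSPHORUS] * (2 * n), lipid_id=lids,
                      leaflet=leaf)
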