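"""Acyl-chain conformational statistics.

The primary order metric for the lipid fluid-to-gel transition is the
*gauche fraction*: every acyl-chain C–C–C–C dihedral is classified as
gauche+ (0–120°), trans (120–240°) or gauche− (240–360°), and the
fraction of gauche dihedrals over all chains is reported (a 14-carbon
chain has 11 such dihedrals).  Companion metrics: area per lipid (leaflet
box area / lipid count), box volume normalized to the largest condition,
carbon–hydrogen order parameters S_CH = ⟨(3cos²θ − 1)/2⟩ with θ the C–H
angle to the membrane normal, and 100 ns boxcar running averages of
time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import SelectionError
from .model import (
    ROLE_CHAIN_CARBON,
    AtomFrame,
    Trajectory,
    as_trajectory,
)

GAUCHE_PLUS = "gauche+"
GAUCHE_MINUS = "gauche-"
TRANS = "trans"

#: Default analysis window, ns (the equilibrated tail of a run).
DEFAULT_WINDOW_NS = 300.0


# ----------------------------------------------------------------------
# dihedral geometry and classification
# ----------------------------------------------------------------------

def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Torsion angle(s) of atom quadruples, degrees on [0, 360)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


def classify_dihedral(angle: float) -> str:
    """Classify one dihedral angle (degrees, reduced to [0, 360)).

    gauche+ on [0, 120), trans on [120, 240), gauche− on [240, 360).
    The three windows partition the circle.
    """
    if not np.isfinite(angle):
        raise ValueError("dihedral angle must be finite")
    a = float(np.mod(angle, 360.0))
    if a < 120.0:
        return GAUCHE_PLUS
    if a < 240.0:
        return TRANS
    return GAUCHE_MINUS


def is_gauche(angles) -> np.ndarray:
    """Vectorized gauche test on angles in degrees (any range)."""
    a = np.mod(np.asarray(angles, dtype=float), 360.0)
    return (a < 120.0) | (a >= 240.0)


def _chain_stacks(frame: AtomFrame, subset=None) -> np.ndarray:
    """Stack chain-carbon coordinates as (n_chains, n_carbons, 3).

    Chains are ordered by (lipid_id, chain); carbons by their index along
    the chain.  All chains must have the same carbon count.
    """
    sel = frame.select(ROLE_CHAIN_CARBON)
    if subset is not None:
        subset = np.asarray(subset)
        sel = sel[np.isin(frame.lipid_id[sel], subset)]
    if sel.size == 0:
        raise SelectionError("no chain carbons in selection")
    order = np.lexsort((frame.carbon[sel], frame.chain[sel],
                        frame.lipid_id[sel]))
    sel = sel[order]
    pair = frame.lipid_id[sel].astype(np.int64) * 8 + frame.chain[sel]
    _, counts = np.unique(pair, return_counts=True)
    if np.unique(counts).size != 1:
        raise SelectionError("chains have inconsistent carbon counts")
    n_carbons = int(counts[0])
    stacks = frame.coords[sel].reshape(-1, n_carbons, 3)
    # rebuild chain continuity across periodic boundaries: each carbon is
    # placed at the minimum image relative to its predecessor
    steps = np.diff(stacks, axis=1)
    steps -= frame.box * np.round(steps / frame.box)
    stacks[:, 1:] = stacks[:, :1] + np.cumsum(steps, axis=1)
    return stacks


def frame_dihedrals(frame: AtomFrame, subset=None) -> np.ndarray:
    """All chain dihedrals of one frame as (n_chains, n_carbons-3)."""
    stacks = _chain_stacks(frame, subset)
    if stacks.shape[1] < 4:
        raise SelectionError("chains too short for dihedrals")
    return dihedral_angles(stacks[:, :-3], stacks[:, 1:-2],
                           stacks[:, 2:-1], stacks[:, 3:])


# ----------------------------------------------------------------------
# gauche fraction
# ----------------------------------------------------------------------

@dataclass
class GaucheSummary:
    """Gauche fraction with optional replica spread and shell breakdown."""

    f_g: float
    sd_replicas: float | None = None
    per_shell: Mapping[str, float] | None = None
    window_ns: float | None = None
    n_dihedrals: int = 0


def gauche_fraction(traj, subset=None,
                    window_ns: float | None = DEFAULT_WINDOW_NS
                    ) -> GaucheSummary:
    """Fraction of gauche dihedrals over all chains of a lipid subset.

    ``traj`` may be a frame, a trajectory, or a list of replica
    trajectories; replicas are aggregated as mean ± across-replica
    standard deviation.  The window selects the final ``window_ns`` of
    each replica (``None`` = everything).
    """
    replicas = traj if isinstance(traj, (list, tuple)) else [traj]
    fractions, total = [], 0
    for rep in replicas:
        rep = as_trajectory(rep).last_window(window_ns)
        n_g = n_tot = 0
        for frame in rep:
            ang = frame_dihedrals(frame, subset)
            n_g += int(np.count_nonzero(is_gauche(ang)))
            n_tot += ang.size
        fractions.append(n_g / n_tot)
        total += n_tot
    f = float(np.mean(fractions))
    sd = float(np.std(fractions, ddof=1)) if len(fractions) > 1 else None
    return GaucheSummary(f_g=f, sd_replicas=sd, window_ns=window_ns,
                         n_dihedrals=total)


def gauche_fraction_of_lipids(frame: AtomFrame, lipids) -> float:
    """Single-frame gauche fraction of an explicit lipid set.

    Suitable as the per-shell metric in
    :func:`bilayerscope.proximity.shellwise_metric`.
    """
    ang = frame_dihedrals(frame, subset=lipids)
    return float(np.count_nonzero(is_gauche(ang)) / ang.size)


# ----------------------------------------------------------------------
# area per lipid, volume normalization
# ----------------------------------------------------------------------

def area_per_lipid(frame: AtomFrame, leaflet: str = "upper") -> float:
    """Box xy-area divided by the leaflet's lipid count, Å²."""
    lids = np.unique(frame.lipid_id[(frame.lipid_id >= 0)
                                    & (frame.leaflet == leaflet)])
    if lids.size == 0:
        raise SelectionError(f"no lipids in leaflet {leaflet!r}")
    return float(frame.box[0] * frame.box[1] / lids.size)


def normalized_volume(volumes):
    """Divide per-condition box volumes by the largest one.

    Accepts a mapping (returned as a mapping) or a sequence; the largest
    condition maps to exactly 1.0.
    """
    if isinstance(volumes, Mapping):
        vals = np.array(list(volumes.values()), dtype=float)
    else:
        vals = np.asarray(list(volumes), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one condition")
    if np.any(vals <= 0):
        raise ValueError("volumes must be positive")
    out = vals / vals.max()
    if isinstance(volumes, Mapping):
        return dict(zip(volumes.keys(), out.tolist()))
    return out


# ----------------------------------------------------------------------
# carbon-hydrogen order parameters
# ----------------------------------------------------------------------

_HCH_HALF = np.radians(109.47 / 2.0)  # half the tetrahedral H-C-H angle


def _ch_directions(stacks: np.ndarray) -> np.ndarray:
    """Unit C–H bond vectors for interior carbons of chain stacks.

    Hydrogens are rebuilt at ideal tetrahedral positions from the two
    carbon neighbors (the fixtures are carbon-only).  Returns
    (n_chains, n_carbons-2, 2, 3).
    """
    u = stacks[:, :-2] - stacks[:, 1:-1]
    v = stacks[:, 2:] - stacks[:, 1:-1]
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    b = -(u + v)
    b = b / np.linalg.norm(b, axis=-1, keepdims=True)
    n = np.cross(u, v)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    h1 = np.cos(_HCH_HALF) * b + np.sin(_HCH_HALF) * n
    h2 = np.cos(_HCH_HALF) * b - np.sin(_HCH_HALF) * n
    return np.stack([h1, h2], axis=2)


def sch_order_parameters(traj, subset=None,
                         window_ns: float | None = DEFAULT_WINDOW_NS
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-carbon C–H order parameter S = ⟨(3cos²θ − 1)/2⟩.

    θ is the angle between each (reconstructed) C–H bond and the membrane
    normal (z).  Only interior carbons (2..n−1) carry rebuilt hydrogens.

    Returns
    -------
    carbons : 1-based carbon indices (2..n−1).
    S : order parameter per carbon, in [−0.5, 1.0].
    """
    replicas = traj if isinstance(traj, (list, tuple)) else [traj]
    acc = None
    count = 0
    for rep in replicas:
        rep = as_trajectory(rep).last_window(window_ns)
        for frame in rep:
            stacks = _chain_stacks(frame, subset)
            if stacks.shape[1] < 3:
                raise SelectionError("need at least 3 carbons for S_CH")
            cosz = _ch_directions(stacks)[..., 2]
            s = 0.5 * (3.0 * cosz ** 2 - 1.0)       # (chains, carbons, 2H)
            per_carbon = s.mean(axis=(0, 2))
            acc = per_carbon if acc is None else acc + per_carbon
            count += 1
    S = acc / count
    carbons = np.arange(2, S.size + 2)
    return carbons, S


# ----------------------------------------------------------------------
# running averages
# ----------------------------------------------------------------------

def running_average(values, window_ns: float = 100.0,
                    dt_ns: float = 1.0) -> np.ndarray:
    """Boxcar moving mean of a uniformly sampled time series.

    The boxcar spans ``window_ns`` (``window_ns / dt_ns`` samples,
    rounded); edges use shrinking windows so the output has the same
    length as the input and a constant series is returned unchanged.
    """
    y = np.asarray(values, dtype=float)
    if dt_ns <= 0:
        raise ValueError("dt_ns must be positive")
    if window_ns < dt_ns:
        raise ValueError("window shorter than one sample")
    w = max(1, int(round(window_ns / dt_ns)))
    kernel = np.ones(w)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den
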