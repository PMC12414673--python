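"""Grid-mapped bilayer thickness from interpolated phosphate surfaces.

Each leaflet's phosphorus atoms define a surface: their z positions are
interpolated onto a regular in-plane grid (100 × 100 nodes by default)
by Delaunay-triangulated linear interpolation, with periodic ghost
points in x and y so the surface tiles the box; any node still outside
the triangulation is filled with the nearest value.  The local bilayer
thickness is the separation of the upper and lower surfaces at each
node.  When a protein is embedded, elliptical patches centered on the
upper-half and lower-half protein centers of mass are masked out (with
optional concentric annuli marking the annular lipid shells), and the
pooled node thickness over a trajectory window gives a thickness
distribution whose modes separate fluid (~35 Å), gel (~42 Å) and
interdigitated (~30 Å) states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.signal import find_peaks
from scipy.spatial import QhullError

from .errors import GeometryError, RoleError
from .model import (
    LEAFLET_LOWER,
    LEAFLET_UPPER,
    ROLE_PHOSPHORUS,
    ROLE_PROTEIN,
    AtomFrame,
    as_trajectory,
)

DEFAULT_GRID = 100
#: Default thickness-map sampling: every 0.1 ns over the last 300 ns.
DEFAULT_STRIDE_NS = 0.1
DEFAULT_WINDOW_NS = 300.0


def assign_leaflets(frame: AtomFrame) -> tuple[np.ndarray, np.ndarray]:
    """Label each lipid upper/lower by its phosphorus z position.

    The midplane is the mean phosphorus z; lipids above it are "upper",
    below "lower".  Emits a degenerate-bilayer warning when every lipid
    falls on one side.  Returns (lipid ids, labels), sorted by lipid id.
    """
    p_idx = frame.select(ROLE_PHOSPHORUS)
    if p_idx.size == 0:
        raise RoleError(ROLE_PHOSPHORUS, "leaflet assignment")
    lids = frame.lipid_id[p_idx]
    order = np.argsort(lids)
    lids = lids[order]
    z = frame.coords[p_idx[order], 2]
    mid = float(z.mean())
    labels = np.where(z >= mid, LEAFLET_UPPER, LEAFLET_LOWER).astype(object)
    if np.unique(labels).size < 2:
        warnings.warn("degenerate bilayer: all lipids on one side of the "
                      "midplane", stacklevel=2)
    return lids, labels


@dataclass
class ThicknessMap:
    """Interpolated leaflet surfaces and their separation on a grid."""

    x: np.ndarray                  # (grid,) node x coordinates, Å
    y: np.ndarray                  # (grid,) node y coordinates, Å
    upper_z: np.ndarray            # (grid, grid)
    lower_z: np.ndarray            # (grid, grid)
    mask: np.ndarray               # (grid, grid) bool; True = excluded
    layer_masks: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def thickness(self) -> np.ndarray:
        """upper_z − lower_z with masked nodes as NaN."""
        t = self.upper_z - self.lower_z
        return np.where(self.mask, np.nan, t)

    @property
    def samples(self) -> np.ndarray:
        """Unmasked node thickness values, flattened."""
        t = self.thickness
        return t[~np.isnan(t)]


def _interpolate_surface(xy: np.ndarray, z: np.ndarray, box,
                         gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Linear interpolation of scattered z onto the grid, periodic in xy."""
    if xy.shape[0] < 3:
        raise GeometryError("need at least 3 phosphorus atoms per leaflet")
    # periodic images would fabricate a surface from collinear points;
    # reject the degeneracy on the raw in-plane positions
    centered = xy - xy.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-8:
        raise GeometryError("degenerate (collinear) phosphorus set")
    shifts = [(dx, dy) for dx in (-box[0], 0.0, box[0])
              for dy in (-box[1], 0.0, box[1])]
    pts = np.vstack([xy + np.array(s) for s in shifts])
    zz = np.tile(z, len(shifts))
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    try:
        lin = LinearNDInterpolator(pts, zz)
    except QhullError as exc:
        raise GeometryError(f"degenerate phosphorus set: {exc}") from exc
    out = lin(X, Y)
    bad = np.isnan(out)
    if np.any(bad):
        near = NearestNDInterpolator(pts, zz)
        out[bad] = near(X[bad], Y[bad])
    return out


def _ellipse_mask(X, Y, center, a, b) -> np.ndarray:
    return (((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2) < 1.0


def thickness_map(frame: AtomFrame, grid: int = DEFAULT_GRID,
                  ellipse: tuple[float, float] | None = None,
                  layers: Sequence[float] | None = None) -> ThicknessMap:
    """Map the local bilayer thickness on a grid × grid lattice.

    When the frame carries an embedded protein (or explicit ``ellipse``
    semi-axes are given), elliptical patches centered on the upper- and
    lower-half protein centers of mass are masked; ``layers`` (e.g. the
    shell boundaries (5, 9.5)) add concentric annular masks recorded in
    ``layer_masks`` for shell-resolved thickness statistics.
    """
    lids, leaf = assign_leaflets(frame)
    p_idx = frame.select(ROLE_PHOSPHORUS)
    p_lids = frame.lipid_id[p_idx]
    leaf_of = dict(zip(lids.tolist(), leaf.tolist()))
    gx = (np.arange(grid) + 0.5) * frame.box[0] / grid
    gy = (np.arange(grid) + 0.5) * frame.box[1] / grid
    surfaces = {}
    for name in (LEAFLET_UPPER, LEAFLET_LOWER):
        sel = p_idx[[leaf_of[int(l)] == name for l in p_lids]]
        surfaces[name] = _interpolate_surface(
            frame.coords[sel, :2], frame.coords[sel, 2], frame.box, gx, gy)

    X, Y = np.meshgrid(gx, gy, indexing="ij")
    mask = np.zeros((grid, grid), dtype=bool)
    layer_masks: dict[str, np.ndarray] = {}
    meta_ellipse = frame.metadata.get("ellipse")
    prot = frame.select(ROLE_PROTEIN)
    if (ellipse is not None or meta_ellipse is not None) and prot.size > 0:
        if ellipse is not None:
            a, b = ellipse
        else:
            a, b = meta_ellipse["semi_axis_a"], meta_ellipse["semi_axis_b"]
        z0 = float(frame.coords[p_idx, 2].mean())
        pz = frame.coords[prot, 2]
        centers = []
        for half in (pz >= z0, pz < z0):
            com = frame.coords[prot[half], :2].mean(axis=0) if \
                np.any(half) else frame.coords[prot, :2].mean(axis=0)
            centers.append(com)
        for com in centers:
            mask |= _ellipse_mask(X, Y, com, a, b)
        if layers:
            inner = mask.copy()
            for i, w in enumerate(layers, start=1):
                grown = np.zeros_like(mask)
                for com in centers:
                    grown |= _ellipse_mask(X, Y, com, a + w, b + w)
                layer_masks[f"shell{i}"] = grown & ~inner
                inner = inner | grown
    return ThicknessMap(
        x=gx, y=gy, upper_z=surfaces[LEAFLET_UPPER],
        lower_z=surfaces[LEAFLET_LOWER], mask=mask,
        layer_masks=layer_masks,
        metadata={"grid": grid, "time": frame.time})


@dataclass
class ThicknessDistribution:
    """Pooled node-thickness samples with detected histogram modes."""

    samples: np.ndarray
    bin_edges: np.ndarray
    hist: np.ndarray
    modes: np.ndarray              # bin centers of detected peaks, main first
    n_frames: int
    metadata: dict = field(default_factory=dict)

    @property
    def main_mode(self) -> float:
        return float(self.modes[0])

    @property
    def secondary_mode(self) -> float | None:
        return float(self.modes[1]) if self.modes.size > 1 else None


def detect_modes(samples: np.ndarray, bin_width: float = 0.5,
                 smooth_bins: int = 5, prominence_frac: float = 0.05
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram a sample set and locate its modes.

    The histogram is boxcar-smoothed over ``smooth_bins`` bins and local
    maxima with prominence at least ``prominence_frac`` of the tallest
    peak are reported, tallest first.
    """
    lo = np.floor(samples.min() / bin_width) * bin_width - bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, _ = np.histogram(samples, bins=edges)
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, props = find_peaks(smooth,
                              prominence=prominence_frac * smooth.max())
    if peaks.size == 0:                      # monotone or single-bin mass
        peaks = np.array([int(np.argmax(smooth))])
        order = np.array([0])
    else:
        order = np.argsort(smooth[peaks])[::-1]
    modes = centers[peaks[order]]
    return edges, hist, modes


def thickness_distribution(traj, grid: int = DEFAULT_GRID,
                           stride_ns: float = DEFAULT_STRIDE_NS,
                           window_ns: float | None = DEFAULT_WINDOW_NS,
                           ellipse: tuple[float, float] | None = None,
                           layers: Sequence[float] | None = None,
                           bin_width: float = 0.5) -> ThicknessDistribution:
    """Pooled thickness distribution over a trajectory window.

    Frames are sampled every ``stride_ns`` within the final ``window_ns``
    of the run; each frame contributes its unmasked node thickness
    values.  Mode detection as in :func:`detect_modes`.
    """
    traj = as_trajectory(traj).last_window(window_ns)
    dt = traj.dt
    step = max(1, int(round(stride_ns / dt))) if dt > 0 else 1
    frames = traj.frames[::step]
    samples = []
    for frame in frames:
        tmap = thickness_map(frame, grid=grid, ellipse=ellipse,
                             layers=layers)
        samples.append(tmap.samples)
    pooled = np.concatenate(samples)
    edges, hist, modes = detect_modes(pooled, bin_width=bin_width)
    return ThicknessDistribution(
        samples=pooled, bin_edges=edges, hist=hist, modes=modes,
        n_frames=len(frames),
        metadata={"grid": grid, "stride_ns": stride_ns,
                  "window_ns": window_ns, "bin_width": bin_width})
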