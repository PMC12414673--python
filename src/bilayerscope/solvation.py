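"""Headgroup hydration: radial pair distribution and number integral.

Hydration of the lipid head is quantified by the radial pair
distribution g(r) between the central glycerol carbon and water oxygens,
and its number integral N(r) = 4πρ ∫₀ʳ g(s) s² ds, the expected number
of waters within r of a glycerol carbon (ρ = mean water-oxygen density
over the box).  Distances use the periodic minimum image; the default
binning (delta = 0.1 Å, rmax = 15 Å) matches common trajectory-analysis
practice.

Note on the 4π factor: the number integral here includes it, so N(r) is
a physical coordination number; some tool conventions print the integral
without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .model import (
    ROLE_GLYCEROL,
    ROLE_WATER_O,
    AtomFrame,
    minimum_image,
    as_trajectory,
)


@dataclass
class RDFResult:
    """Binned g(r) with the reference density used to normalize it."""

    bin_edges: np.ndarray          # Å, width delta, spanning (0, rmax]
    g: np.ndarray                  # one value per bin, >= 0
    rho: float                     # mean target density, targets / Å^3
    n_centers: float               # mean center count per frame
    n_frames: int
    metadata: dict = field(default_factory=dict)

    @property
    def r(self) -> np.ndarray:
        """Bin centers, Å."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        e = self.bin_edges
        return 4.0 / 3.0 * np.pi * (e[1:] ** 3 - e[:-1] ** 3)


def _resolve(frame: AtomFrame, sel) -> np.ndarray:
    """Resolve a role name or an index array to atom indices."""
    if isinstance(sel, str):
        idx = frame.select(sel)
        if idx.size == 0:
            frame.require_roles([sel], "radial distribution")
        return idx
    return np.asarray(sel, dtype=int)


def _pair_distances(frame: AtomFrame, centers: np.ndarray,
                    targets: np.ndarray) -> np.ndarray:
    """Minimum-image center-target distances, self-pairs excluded."""
    c = frame.coords[centers]
    t = frame.coords[targets]
    delta = t[None, :, :] - c[:, None, :]
    delta = minimum_image(delta, frame.box)
    d = np.sqrt(np.sum(delta ** 2, axis=-1))
    same = centers[:, None] == targets[None, :]
    if np.any(same):
        d = np.where(same, np.inf, d)
    return d


def radial_distribution(centers, targets, frames, delta: float = 0.1,
                        rmax: float = 15.0) -> RDFResult:
    """Frame-averaged radial pair distribution g(r).

    ``centers`` and ``targets`` are role names (e.g. ``"glycerol_C"``,
    ``"water_O"``) or explicit atom-index arrays; ``frames`` is a frame,
    trajectory, or list of frames.  The histogram of minimum-image
    distances is normalized per bin by the spherical-shell volume and the
    mean target density over the box.
    """
    traj = as_trajectory(frames) if not isinstance(frames, list) \
        else frames
    edges = np.arange(0.0, rmax + delta / 2, delta)
    counts = np.zeros(edges.size - 1)
    n_centers_acc = 0.0
    rho_acc = 0.0
    n_frames = 0
    for frame in traj:
        if rmax > 0.5 * float(frame.box.min()):
            raise GeometryError(
                "rmax exceeds half the smallest box length")
        c_idx = _resolve(frame, centers)
        t_idx = _resolve(frame, targets)
        d = _pair_distances(frame, c_idx, t_idx)
        h, _ = np.histogram(d[np.isfinite(d)], bins=edges)
        counts += h
        n_centers_acc += c_idx.size
        rho_acc += t_idx.size / float(np.prod(frame.box))
        n_frames += 1
    n_centers = n_centers_acc / n_frames
    rho = rho_acc / n_frames
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = counts / (n_frames * n_centers * shell * rho)
    g = np.nan_to_num(g)
    return RDFResult(bin_edges=edges, g=g, rho=rho, n_centers=n_centers,
                     n_frames=n_frames,
                     metadata={"delta": delta, "rmax": rmax, "usepbc": 1})


def number_integral(rdf: RDFResult) -> np.ndarray:
    """Cumulative expected neighbor count N(r) on the bin grid.

    Discretized as N(r_j) = Σ_{i≤j} ρ g_i V_shell,i — the exact discrete
    counterpart of 4πρ ∫₀ʳ g(s) s² ds, so N(rmax) reproduces the mean
    raw neighbor count within rmax.  Non-decreasing by construction.
    """
    return np.cumsum(rdf.rho * rdf.g * rdf.shell_volumes)


def hydration_number(frames, cutoff: float = 4.5) -> float:
    """Mean number of water oxygens within ``cutoff`` Å of each glycerol
    central carbon, averaged over glycerols and frames.

    The default 4.5 Å cutoff is the first-minimum scale of a
    carbon-water g(r).
    """
    traj = as_trajectory(frames) if not isinstance(frames, list) \
        else frames
    total = 0.0
    n = 0
    for frame in traj:
        frame.require_roles([ROLE_GLYCEROL, ROLE_WATER_O],
                            "hydration number")
        g_idx = frame.select(ROLE_GLYCEROL)
        w_idx = frame.select(ROLE_WATER_O)
        d = _pair_distances(frame, g_idx, w_idx)
        total += float(np.count_nonzero(d < cutoff)) / g_idx.size
        n += 1
    return total / n
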