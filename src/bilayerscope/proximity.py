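"""Annular lipid shells around an embedded membrane protein.

Lipids are binned by their minimum distance to the protein's β-sheet
transmembrane surface: for each lipid the reference point is its central
glycerol carbon, for the protein all β-flagged heavy atoms, and the
distance is the 3D minimum over reference atoms with the periodic
minimum image applied in the membrane plane (x, y) only — the protein is
unique along z in an infinite-bilayer geometry.  The first and second
annular shells default to the [0, 5) Å and [5, 9.5) Å distance
intervals, held fixed across thermodynamic conditions; everything beyond
is bulk.  Any lipid-subset metric (e.g. the gauche fraction) can then be
evaluated shell by shell, with membership resolved per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import RoleError
from .model import (
    ROLE_PROTEIN,
    AtomFrame,
    minimum_image,
    as_trajectory,
)

BULK = "bulk"

#: Default window for shell distance distributions, ns.
DEFAULT_SHELL_WINDOW_NS = 500.0


@dataclass(frozen=True)
class ShellModel:
    """Shell boundaries (Å) and histogram bin width for distributions."""

    boundaries: tuple[float, ...] = (5.0, 9.5)
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size == 0 or np.any(b <= 0) or np.any(np.diff(b) <= 0):
            raise ValueError(
                "boundaries must be positive and strictly increasing")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def labels(self) -> tuple[str, ...]:
        """Shell labels, innermost first, then "bulk"."""
        return tuple(f"shell{i + 1}" for i in range(len(self.boundaries))
                     ) + (BULK,)


@dataclass
class ShellAssignment:
    """Per-lipid shell labels and minimum distances for one frame."""

    lipid_ids: np.ndarray
    distances: np.ndarray
    labels: np.ndarray
    model: ShellModel

    def counts(self) -> dict[str, int]:
        """Lipid count per shell (all shells listed, possibly zero)."""
        return {lab: int(np.count_nonzero(self.labels == lab))
                for lab in self.model.labels}

    def lipids_in(self, label: str) -> np.ndarray:
        return self.lipid_ids[self.labels == label]


def protein_lipid_distances(frame: AtomFrame
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-lipid minimum distance to the β-sheet protein surface.

    Returns (lipid ids, distances) aligned and sorted by lipid id.  The
    distance is min over β-flagged protein heavy atoms of the xy-periodic
    minimum-image distance to the lipid's glycerol central carbon.
    """
    beta_idx = np.flatnonzero((frame.roles == ROLE_PROTEIN) & frame.beta)
    if beta_idx.size == 0:
        raise RoleError("protein_heavy (β-flagged)", "shell decomposition")
    lids, gly = frame.glycerol_positions()
    ref = frame.coords[beta_idx]
    delta = ref[None, :, :] - gly[:, None, :]
    delta = minimum_image(delta, frame.box, axes=(0, 1))
    d = np.sqrt(np.sum(delta ** 2, axis=-1)).min(axis=1)
    return lids, d


def shell_assign(distances, model: ShellModel = ShellModel(),
                 lipid_ids=None) -> ShellAssignment:
    """Assign lipids to shells by half-open distance intervals.

    With the default boundaries: [0, 5) → shell1, [5, 9.5) → shell2,
    ≥ 9.5 → bulk.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("distances must be finite and non-negative")
    if lipid_ids is None:
        lipid_ids = np.arange(d.size)
    idx = np.searchsorted(np.asarray(model.boundaries), d, side="right")
    labels = np.array(model.labels, dtype=object)[idx]
    return ShellAssignment(np.asarray(lipid_ids), d, labels, model)


@dataclass
class ShellDistribution:
    """Replica-averaged histogram of lipid-protein minimum distances."""

    bin_edges: np.ndarray
    counts: np.ndarray             # mean over replicas of pooled counts
    per_replica_mass: np.ndarray   # total samples per replica
    model: ShellModel
    window_ns: float | None = None

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode(self) -> float:
        """Distance bin center with the highest count."""
        return float(self.r[int(np.argmax(self.counts))])


def shell_distribution(trajs, model: ShellModel = ShellModel(),
                       window_ns: float | None = DEFAULT_SHELL_WINDOW_NS
                       ) -> ShellDistribution:
    """Pooled distance histogram at ``model.bin_width`` resolution.

    ``trajs`` is a trajectory or a list of replica trajectories; the
    final ``window_ns`` of each replica is pooled and the per-bin counts
    are averaged across replicas.
    """
    replicas = trajs if isinstance(trajs, (list, tuple)) else [trajs]
    pooled: list[np.ndarray] = []
    for rep in replicas:
        rep = as_trajectory(rep).last_window(window_ns)
        ds = [protein_lipid_distances(frame)[1] for frame in rep]
        pooled.append(np.concatenate(ds))
    rmax = max(float(d.max()) for d in pooled)
    n_bins = int(np.ceil(rmax / model.bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 0.5) * model.bin_width,
                      model.bin_width)
    hists = np.array([np.histogram(d, bins=edges)[0] for d in pooled])
    return ShellDistribution(
        bin_edges=edges, counts=hists.mean(axis=0),
        per_replica_mass=np.array([d.size for d in pooled]),
        model=model, window_ns=window_ns)


def shellwise_metric(traj, model: ShellModel,
                     metric: Callable[[AtomFrame, np.ndarray], float],
                     window_ns: float | None = None) -> dict[str, float]:
    """Evaluate a lipid-subset metric shell by shell.

    ``metric(frame, lipid_ids) -> float`` is applied per frame to the
    lipids of each shell (membership resolved in that frame) and
    frame-averaged.  A shell that is empty in every frame is absent from
    the result — not reported as zero.
    """
    traj = as_trajectory(traj).last_window(window_ns)
    sums: dict[str, float] = {}
    hits: dict[str, int] = {}
    for frame in traj:
        lids, d = protein_lipid_distances(frame)
        assignment = shell_assign(d, model, lipid_ids=lids)
        for lab in model.labels:
            members = assignment.lipids_in(lab)
            if members.size == 0:
                continue
            sums[lab] = sums.get(lab, 0.0) + float(metric(frame, members))
            hits[lab] = hits.get(lab, 0) + 1
    return {lab: sums[lab] / hits[lab] for lab in sums}
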