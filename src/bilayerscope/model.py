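"""In-memory data model: labeled coordinate frames and trajectories.

Every analysis in the package consumes :class:`AtomFrame` /
:class:`Trajectory` objects rather than raw files.  An ``AtomFrame`` is a
set of 3D coordinates in an orthorhombic periodic box, annotated with atom
*roles* (which chemical part of the system each atom stands for) and with
per-lipid bookkeeping (lipid id, leaflet, acyl chain index, carbon index
along the chain).  Roles are deliberately supplied as explicit labels —
not inferred from force-field atom names — so the analyses are independent
of any naming dialect.

Units: coordinates and box lengths in Å, times in ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import RoleError, SelectionError

# Atom role labels.  ``chain_carbon`` atoms additionally carry a chain index
# (0/1, the two acyl chains) and a 1-based carbon index along the chain.
ROLE_CHAIN_CARBON = "chain_carbon"
ROLE_GLYCEROL = "glycerol_C"
ROLE_PHOSPHORUS = "phosphorus"
ROLE_NITROGEN = "nitrogen"
ROLE_WATER_O = "water_O"
ROLE_PROTEIN = "protein_heavy"

KNOWN_ROLES = (
    ROLE_CHAIN_CARBON,
    ROLE_GLYCEROL,
    ROLE_PHOSPHORUS,
    ROLE_NITROGEN,
    ROLE_WATER_O,
    ROLE_PROTEIN,
)

LEAFLET_UPPER = "upper"
LEAFLET_LOWER = "lower"


def minimum_image(delta: np.ndarray, box: np.ndarray,
                  axes: Sequence[int] = (0, 1, 2)) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Parameters
    ----------
    delta : (..., 3) displacement vectors in Å.
    box : (3,) orthorhombic box lengths.
    axes : which Cartesian axes are periodic.  Membrane-plane analyses use
        ``(0, 1)`` (periodic in x, y; the bilayer is unique in z).
    """
    delta = np.asarray(delta, dtype=float).copy()
    for ax in axes:
        L = box[ax]
        delta[..., ax] -= L * np.round(delta[..., ax] / L)
    return delta


@dataclass
class AtomFrame:
    """Labeled coordinates of one configuration.

    Attributes
    ----------
    coords : (N, 3) float array, Å.
    box : (3,) float array, orthorhombic box lengths, Å.
    roles : (N,) string array; one of :data:`KNOWN_ROLES` (unknown labels
        are tolerated but flagged in :attr:`metadata`).
    lipid_id : (N,) int array; -1 for non-lipid atoms.
    chain : (N,) int array; acyl chain index 0/1 for chain carbons, else -1.
    carbon : (N,) int array; 1-based carbon index along the chain, else -1.
    leaflet : (N,) string array; "upper"/"lower" for lipid atoms, "" else.
    beta : (N,) bool array; True for protein heavy atoms in β-sheet residues.
    time : frame time in ns.
    """

    coords: np.ndarray
    box: np.ndarray
    roles: np.ndarray
    lipid_id: np.ndarray
    chain: np.ndarray
    carbon: np.ndarray
    leaflet: np.ndarray
    beta: np.ndarray
    time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.lipid_id = np.asarray(self.lipid_id, dtype=int)
        self.chain = np.asarray(self.chain, dtype=int)
        self.carbon = np.asarray(self.carbon, dtype=int)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        self.beta = np.asarray(self.beta, dtype=bool)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        for name in ("roles", "lipid_id", "chain", "carbon", "leaflet", "beta"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match coords")
        unknown = sorted(
            {r for r in self.roles if r not in KNOWN_ROLES})
        if unknown:
            self.metadata.setdefault("unknown_roles", unknown)
        cc = self.roles == ROLE_CHAIN_CARBON
        if np.any(self.lipid_id[cc] < 0):
            raise ValueError("every chain carbon must map to a lipid_id")

    # -- selections -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select(self, role: str) -> np.ndarray:
        """Indices of atoms with the given role."""
        return np.flatnonzero(self.roles == role)

    def has_role(self, role: str) -> bool:
        return bool(np.any(self.roles == role))

    def require_roles(self, roles: Iterable[str], analysis: str = "") -> None:
        missing = [r for r in roles if not self.has_role(r)]
        if missing:
            raise RoleError(missing, analysis)

    def lipid_ids(self) -> np.ndarray:
        """Sorted unique lipid ids present in the frame."""
        ids = np.unique(self.lipid_id[self.lipid_id >= 0])
        return ids

    def lipid_leaflets(self) -> dict[int, str]:
        """Per-lipid leaflet label (from the atom annotation)."""
        out: dict[int, str] = {}
        for lid in self.lipid_ids():
            labels = self.leaflet[self.lipid_id == lid]
            out[int(lid)] = str(labels[0])
        return out

    def glycerol_positions(self, lipids: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
        """(lipid ids, glycerol central-carbon coordinates), aligned."""
        sel = self.select(ROLE_GLYCEROL)
        if sel.size == 0:
            raise RoleError(ROLE_GLYCEROL)
        lids = self.lipid_id[sel]
        order = np.argsort(lids)
        lids, pos = lids[order], self.coords[sel[order]]
        if lipids is not None:
            keep = np.isin(lids, lipids)
            lids, pos = lids[keep], pos[keep]
        return lids, pos

    def chain_carbons(self, lipid: int, chain: int) -> np.ndarray:
        """Coordinates of one acyl chain's carbons, ordered C1..Cn."""
        sel = np.flatnonzero((self.roles == ROLE_CHAIN_CARBON)
                             & (self.lipid_id == lipid)
                             & (self.chain == chain))
        if sel.size == 0:
            raise SelectionError(
                f"lipid {lipid} chain {chain}: no chain carbons")
        order = np.argsort(self.carbon[sel])
        return self.coords[sel[order]]

    # -- transforms -----------------------------------------------------

    def copy(self) -> "AtomFrame":
        return AtomFrame(self.coords.copy(), self.box.copy(),
                         self.roles.copy(), self.lipid_id.copy(),
                         self.chain.copy(), self.carbon.copy(),
                         self.leaflet.copy(), self.beta.copy(),
                         self.time, dict(self.metadata))

    def translated(self, shift: Sequence[float], wrap: bool = False
                   ) -> "AtomFrame":
        out = self.copy()
        out.coords = out.coords + np.asarray(shift, dtype=float)
        if wrap:
            out.wrap()
        return out

    def wrap(self) -> None:
        """Wrap all coordinates into [0, L) per axis, in place."""
        self.coords = np.mod(self.coords, self.box)


class Trajectory:
    """An ordered sequence of frames with strictly increasing times."""

    def __init__(self, frames: Sequence[AtomFrame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].n_atoms
        if any(f.n_atoms != n for f in frames):
            raise ValueError("constant atom count required across frames")
        times = np.array([f.time for f in frames], dtype=float)
        if len(frames) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.frames = frames

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def dt(self) -> float:
        """Frame spacing in ns (median of successive time differences)."""
        t = self.times
        if len(t) < 2:
            return 0.0
        return float(np.median(np.diff(t)))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[AtomFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i])
        return self.frames[i]

    def last_window(self, window_ns: float | None) -> "Trajectory":
        """Sub-trajectory covering the final ``window_ns`` of the run.

        ``None`` (or a window at least as long as the run) returns the
        whole trajectory.
        """
        if window_ns is None:
            return self
        if window_ns <= 0:
            raise ValueError("window must be positive")
        t = self.times
        keep = t >= t[-1] - window_ns - 1e-9
        frames = [f for f, k in zip(self.frames, keep) if k]
        if not frames:
            raise ValueError("empty analysis window")
        return Trajectory(frames)


def as_trajectory(obj: AtomFrame | Trajectory) -> Trajectory:
    """Wrap a single frame as a one-frame trajectory if needed."""
    if isinstance(obj, Trajectory):
        return obj
    return Trajectory([obj])
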