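"""Synthetic bilayer configurations and synthetic barotropic NMR series.

The generator produces *geometric* membrane fixtures with known ground
truth — not physical trajectories.  Lipids are myristoyl-like: two
14-carbon acyl chains grown by internal-coordinate extension (C–C bond
1.53 Å, C–C–C angle 111°), each of the 11 chain dihedrals set to trans
(180°) or gauche (±60°, random sign) independently with a configurable
probability.  Fluid bilayers are emulated with a high gauche probability
and ~60 Å² area per lipid; gel bilayers with all-trans chains and a
smaller area; an interdigitated mode shifts one leaflet inward so the
chains of opposing leaflets interpenetrate.  An elliptical β-barrel of
protein pseudo-atoms (~600–700 Å² cross-section) can be carved into the
bilayer, and a water slab hydrates each headgroup region.

Synthetic NMR pressure series follow a descending logistic between two
plateaus with a known midpoint Pm and width; the two-state mode emits
fluid-state (If) and gel-state (Ig) intensities whose relative population
follows an ascending logistic at the same midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidSpecError, PackingError
from .model import (
    LEAFLET_LOWER,
    LEAFLET_UPPER,
    ROLE_CHAIN_CARBON,
    ROLE_GLYCEROL,
    ROLE_NITROGEN,
    ROLE_PHOSPHORUS,
    ROLE_PROTEIN,
    ROLE_WATER_O,
    AtomFrame,
    Trajectory,
)
from .nmr import PressureSeries, TwoStateSeries

# Standard aliphatic geometry.
CC_BOND = 1.53          # Å
CCC_ANGLE = 111.0       # degrees
TRANS_ANGLE = 180.0
GAUCHE_ANGLE = 60.0     # gauche+ 60°, gauche- 300°

#: Rise per C–C bond along the all-trans chain axis, Å.
TRANS_RISE = CC_BOND * math.sin(math.radians(CCC_ANGLE / 2.0))

#: Number density of liquid water, molecules / Å^3 (0.997 g/cm^3).
WATER_DENSITY = 0.0334

# Default barotropic pressure ramp, bar (ambient first).
DEFAULT_PRESSURES = (1.0, 250.0, 500.0, 750.0, 1000.0, 1250.0,
                     1500.0, 1750.0, 2000.0, 2250.0, 2500.0)


@dataclass(frozen=True)
class EllipseSpec:
    """Elliptical β-barrel cross-section embedded in the membrane plane.

    Defaults give π·a·b ≈ 641 Å², in the 600–700 Å² band typical of a
    small outer-membrane β-barrel's transmembrane cross-section.
    """

    semi_axis_a: float = 17.0
    semi_axis_b: float = 12.0
    n_pseudo_atoms: int = 256
    beta_fraction: float = 0.75
    area_band: tuple[float, float] = (400.0, 900.0)

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise InvalidSpecError("ellipse semi-axes must be positive")
        if not 0.0 <= self.beta_fraction <= 1.0:
            raise InvalidSpecError("beta_fraction must be in [0, 1]")
        lo, hi = self.area_band
        if not lo <= self.area <= hi:
            raise InvalidSpecError(
                f"ellipse area {self.area:.0f} Å² outside band [{lo}, {hi}]")

    @property
    def area(self) -> float:
        return math.pi * self.semi_axis_a * self.semi_axis_b


@dataclass(frozen=True)
class BilayerSpec:
    """Recipe for a synthetic hydrated bilayer.

    Parameters
    ----------
    n_lipids_per_leaflet : lipids per leaflet before any protein carving;
        both leaflets always receive identical counts.  Best chosen as a
        product of two near-equal integers (lattice packing).
    n_carbons_per_chain : carbons per acyl chain (14 = myristoyl;
        11 dihedrals).
    gauche_prob : per-dihedral gauche probability (0 = all-trans gel,
        ~0.28 = fluid).
    area_per_lipid : lattice cell area, Å² (fluid ~60, gel ~50).
    head_offset : phosphorus displacement outward from the first chain
        carbon along the membrane normal, Å.  The default 4.6 Å makes the
        untilted all-trans bilayer's phosphate-plane separation ≈42 Å,
        the gel-phase scale.
    jitter_xy, jitter_z : Gaussian placement noise per lipid, Å.
    tilt_deg : chain tilt from the membrane normal (0 = untilted).
    interdigitated : shift one leaflet inward by ``interdigitation_depth``
        so chains interpenetrate (locally thin, ≈30 Å gel mode).
    n_waters : water oxygens; ``None`` fills both 22.5 Å slabs at liquid
        water density.
    protein : optional elliptical barrel to embed after packing.
    n_frames / frame_spacing_ns : number of independently re-drawn frames
        and their time spacing.
    """

    n_lipids_per_leaflet: int
    n_carbons_per_chain: int = 14
    gauche_prob: float = 0.28
    area_per_lipid: float = 60.0
    head_offset: float = 4.6
    jitter_xy: float = 0.5
    jitter_z: float = 0.3
    tilt_deg: float = 0.0
    chain_spacing: float = 4.8
    interdigitated: bool = False
    interdigitation_depth: float = 12.0
    n_waters: int | None = None
    water_thickness: float = 22.5
    protein: EllipseSpec | None = None
    n_frames: int = 1
    frame_spacing_ns: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet < 1:
            raise InvalidSpecError("need at least one lipid per leaflet")
        if self.n_carbons_per_chain < 4:
            raise InvalidSpecError("chains need at least 4 carbons")
        if not 0.0 <= self.gauche_prob <= 1.0:
            raise InvalidSpecError("gauche_prob must be in [0, 1]")
        if self.area_per_lipid <= 0:
            raise InvalidSpecError("area_per_lipid must be positive")
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")

    # Canonical study conditions: a disordered fluid phase and an
    # all-trans gel phase at their typical areas per lipid.
    @staticmethod
    def fluid(n_lipids_per_leaflet: int = 64, **kw) -> "BilayerSpec":
        kw.setdefault("gauche_prob", 0.28)
        kw.setdefault("area_per_lipid", 60.0)
        return BilayerSpec(n_lipids_per_leaflet, **kw)

    @staticmethod
    def gel(n_lipids_per_leaflet: int = 64, **kw) -> "BilayerSpec":
        kw.setdefault("gauche_prob", 0.0)
        kw.setdefault("area_per_lipid", 50.0)
        return BilayerSpec(n_lipids_per_leaflet, **kw)


@dataclass(frozen=True)
class NmrSynthSpec:
    """Recipe for a synthetic barotropic intensity series.

    ``Pm`` and ``width`` are in bar; intensities in arbitrary units (raw —
    normalization to the ambient point is a downstream operation).
    """

    Pm: float = 600.0
    width: float = 100.0
    plateau_low: float = 0.2
    plateau_high: float = 1.0
    noise_sd: float = 0.02
    pressures: tuple[float, ...] = DEFAULT_PRESSURES
    two_state: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidSpecError("width must be positive")
        p = np.asarray(self.pressures, dtype=float)
        if p.size < 2 or np.any(np.diff(p) <= 0):
            raise InvalidSpecError("pressures must be strictly increasing")
        if not np.isclose(p[0], 1.0):
            raise InvalidSpecError(
                "pressure ramp must include the ambient point (1 bar)")


# ----------------------------------------------------------------------
# chain construction
# ----------------------------------------------------------------------

def _extend_position(p1, p2, p3, bond, angle_deg, dihedral_deg):
    """Place the next atom from internal coordinates (NeRF extension)."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    b1 = p2 - p1
    b2 = p3 - p2
    bc = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = (-math.cos(theta) * bc
         + math.sin(theta) * (math.cos(phi) * m + math.sin(phi) * n))
    return p3 + bond * d


def chain_from_dihedrals(dihedrals) -> np.ndarray:
    """Grow a chain with an explicit dihedral list (degrees).

    ``len(dihedrals) + 3`` carbons are placed with standard aliphatic
    bond geometry, canonically oriented (first carbon at the origin,
    end-to-end vector along +z).
    """
    dihedrals = np.asarray(dihedrals, dtype=float)
    n_carbons = dihedrals.size + 3
    coords = np.zeros((n_carbons, 3))
    coords[1] = (0.0, 0.0, CC_BOND)
    bend = math.radians(180.0 - CCC_ANGLE)
    coords[2] = coords[1] + CC_BOND * np.array(
        [math.sin(bend), 0.0, math.cos(bend)])
    for i in range(3, n_carbons):
        coords[i] = _extend_position(coords[i - 3], coords[i - 2],
                                     coords[i - 1], CC_BOND, CCC_ANGLE,
                                     dihedrals[i - 3])
    coords -= coords[0]
    e2e = coords[-1]
    norm = np.linalg.norm(e2e)
    if norm > 1e-9:
        coords = coords @ _rotation_onto_z(e2e / norm).T
    return coords


def build_chain(n_carbons: int, gauche_prob: float,
                seed: int | np.random.Generator = 0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Grow one acyl chain by internal-coordinate extension.

    Each of the ``n_carbons - 3`` dihedrals is set to trans (180°) with
    probability ``1 - gauche_prob``, otherwise gauche (60° or 300° with
    equal probability).  The returned chain is canonically oriented: the
    first carbon at the origin and the end-to-end vector along +z.

    Returns
    -------
    coords : (n_carbons, 3) positions, Å.
    dihedrals : realized dihedral angles in degrees on [0, 360).
    """
    if n_carbons < 4:
        raise InvalidSpecError("chains need at least 4 carbons")
    if not 0.0 <= gauche_prob <= 1.0:
        raise InvalidSpecError("gauche_prob must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    n_dihedrals = n_carbons - 3
    is_gauche = rng.random(n_dihedrals) < gauche_prob
    signs = rng.random(n_dihedrals) < 0.5
    dihedrals = np.where(
        is_gauche,
        np.where(signs, GAUCHE_ANGLE, 360.0 - GAUCHE_ANGLE),
        TRANS_ANGLE,
    ).astype(float)
    return chain_from_dihedrals(dihedrals), dihedrals


def _rotation_onto_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto +z."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _lattice_dims(n: int) -> tuple[int, int]:
    """Factor n into the most nearly square nx × ny grid."""
    best = (1, n)
    for nx in range(1, int(math.isqrt(n)) + 1):
        if n % nx == 0:
            best = (nx, n // nx)
    return best


# ----------------------------------------------------------------------
# bilayer assembly
# ----------------------------------------------------------------------

def build_bilayer(spec: BilayerSpec):
    """Assemble a hydrated bilayer from a :class:`BilayerSpec`.

    Returns a single :class:`AtomFrame` when ``spec.n_frames == 1``, else
    a :class:`Trajectory` of independently re-drawn frames.  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for i in range(spec.n_frames):
        frame = _build_frame(spec, rng, time=i * spec.frame_spacing_ns)
        if spec.protein is not None:
            frame = embed_barrel(frame, spec.protein, rng)
        frames.append(frame)
    if spec.n_frames == 1:
        return frames[0]
    return Trajectory(frames)


def _build_frame(spec: BilayerSpec, rng: np.random.Generator,
                 time: float = 0.0) -> AtomFrame:
    n = spec.n_lipids_per_leaflet
    cell = math.sqrt(spec.area_per_lipid)
    # a lipid footprint of two chains plus ~1 Å clearance each side
    if spec.chain_spacing + 2.0 > cell:
        raise PackingError(
            f"lipid footprint {spec.chain_spacing + 2.0:.1f} Å exceeds the "
            f"lattice cell side {cell:.2f} Å at "
            f"{spec.area_per_lipid:.1f} Å² per lipid")
    nx, ny = _lattice_dims(n)
    Lx, Ly = nx * cell, ny * cell

    coords, roles, lipid_id, chain_ix, carbon_ix, leaflet = \
        [], [], [], [], [], []
    tilt = math.radians(spec.tilt_deg)

    lid = 0
    for leaf, sign in ((LEAFLET_UPPER, 1.0), (LEAFLET_LOWER, -1.0)):
        for iy in range(ny):
            for ix in range(nx):
                site = np.array([(ix + 0.5) * cell, (iy + 0.5) * cell, 0.0])
                jig = np.array([rng.normal(0.0, spec.jitter_xy),
                                rng.normal(0.0, spec.jitter_xy),
                                rng.normal(0.0, spec.jitter_z)])
                c1_positions = []
                for ic in (0, 1):
                    chain, _ = build_chain(spec.n_carbons_per_chain,
                                           spec.gauche_prob, rng)
                    chain = chain @ _rot_z(rng.uniform(0, 2 * math.pi)).T
                    if tilt:
                        chain = chain @ _rot_y(tilt).T
                    extent = chain[-1, 2]  # Cn z after canonical build
                    if sign > 0:
                        # flip so C1 is at the top, terminal methyl at z=0
                        chain = chain * np.array([1.0, -1.0, -1.0])
                        chain[:, 2] += extent
                    else:
                        chain[:, 2] -= extent
                    offset = np.array(
                        [(ic - 0.5) * spec.chain_spacing, 0.0, 0.0])
                    chain = chain + site + offset + jig
                    for k in range(spec.n_carbons_per_chain):
                        coords.append(chain[k])
                        roles.append(ROLE_CHAIN_CARBON)
                        lipid_id.append(lid)
                        chain_ix.append(ic)
                        carbon_ix.append(k + 1)
                        leaflet.append(leaf)
                    c1_positions.append(chain[0])
                c1_a, c1_b = c1_positions
                glycerol = 0.5 * (c1_a + c1_b) + np.array([0, 0, sign * 1.0])
                phosphorus = c1_a + np.array([0, 0, sign * spec.head_offset])
                nitrogen = phosphorus + np.array([0, 0, sign * 3.5])
                for pos, role in ((glycerol, ROLE_GLYCEROL),
                                  (phosphorus, ROLE_PHOSPHORUS),
                                  (nitrogen, ROLE_NITROGEN)):
                    coords.append(pos)
                    roles.append(role)
                    lipid_id.append(lid)
                    chain_ix.append(-1)
                    carbon_ix.append(-1)
                    leaflet.append(leaf)
                lid += 1

    coords = np.array(coords)
    if spec.interdigitated:
        lower = np.array([lf == LEAFLET_LOWER for lf in leaflet])
        coords[lower, 2] += spec.interdigitation_depth

    # hydrating water slabs: water penetrates to the glycerol level in
    # real bilayers, so each slab starts at its leaflet's mean glycerol z
    roles_arr = np.array(roles, dtype=object)
    leaf_arr = np.array(leaflet, dtype=object)
    gly = roles_arr == ROLE_GLYCEROL
    z_top = float(coords[gly & (leaf_arr == LEAFLET_UPPER), 2].mean())
    z_bot = float(coords[gly & (leaf_arr == LEAFLET_LOWER), 2].mean())
    if spec.n_waters is None:
        per_slab = int(round(WATER_DENSITY * Lx * Ly * spec.water_thickness))
        n_up, n_dn = per_slab, per_slab
    else:
        n_up = spec.n_waters - spec.n_waters // 2
        n_dn = spec.n_waters // 2
    for count, zlo, zhi in ((n_up, z_top, z_top + spec.water_thickness),
                            (n_dn, z_bot - spec.water_thickness, z_bot)):
        if count <= 0:
            continue
        w = np.column_stack([rng.uniform(0, Lx, count),
                             rng.uniform(0, Ly, count),
                             rng.uniform(zlo, zhi, count)])
        coords = np.vstack([coords, w])
        roles.extend([ROLE_WATER_O] * count)
        lipid_id.extend([-1] * count)
        chain_ix.extend([-1] * count)
        carbon_ix.extend([-1] * count)
        leaflet.extend([""] * count)

    Lz = 2.0 * (max(abs(coords[:, 2].max()), abs(coords[:, 2].min())) + 1.0)
    coords[:, 2] += Lz / 2.0  # box spans [0, L) on every axis
    box = np.array([Lx, Ly, Lz])

    frame = AtomFrame(
        coords=coords,
        box=box,
        roles=np.array(roles, dtype=object),
        lipid_id=np.array(lipid_id),
        chain=np.array(chain_ix),
        carbon=np.array(carbon_ix),
        leaflet=np.array(leaflet, dtype=object),
        beta=np.zeros(len(roles), dtype=bool),
        time=time,
        metadata={
            "n_lipids_per_leaflet": n,
            "area_per_lipid": spec.area_per_lipid,
            "lattice": (nx, ny),
            "gauche_prob": spec.gauche_prob,
            "interdigitated": spec.interdigitated,
        },
    )
    frame.wrap()
    return frame


def embed_barrel(frame: AtomFrame, ellipse: EllipseSpec,
                 seed: int | np.random.Generator = 0) -> AtomFrame:
    """Carve an elliptical hole in the bilayer and insert a β-barrel.

    Every lipid whose glycerol central carbon falls inside the ellipse
    (xy test, ellipse centered in the box) is deleted; a barrel of
    ``ellipse.n_pseudo_atoms`` protein pseudo-atoms spanning the bilayer
    is inserted, the transmembrane-most ``beta_fraction`` of them flagged
    as β-sheet.  The ellipse parameters are recorded in frame metadata.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    a, b = ellipse.semi_axis_a, ellipse.semi_axis_b
    Lx, Ly = frame.box[0], frame.box[1]
    if 2 * a > Lx or 2 * b > Ly:
        raise InvalidSpecError("ellipse does not fit inside the box")
    cx, cy = Lx / 2.0, Ly / 2.0

    p_sel = frame.select(ROLE_PHOSPHORUS)
    if p_sel.size == 0:
        raise InvalidSpecError("frame has no phosphorus plane (no midplane)")
    z0 = float(frame.coords[p_sel, 2].mean())
    half_height = float(np.abs(frame.coords[p_sel, 2] - z0).max())

    lids, gly = frame.glycerol_positions()
    inside = (((gly[:, 0] - cx) / a) ** 2
              + ((gly[:, 1] - cy) / b) ** 2) < 1.0
    carved = set(int(x) for x in lids[inside])
    keep = ~np.isin(frame.lipid_id, list(carved)) | (frame.lipid_id < 0)

    # barrel pseudo-atoms: rings on the ellipse perimeter spanning the
    # bilayer, with a small positional jitter
    n = ellipse.n_pseudo_atoms
    n_rings = max(4, int(round(n / 24)))
    per_ring = [n // n_rings + (1 if i < n % n_rings else 0)
                for i in range(n_rings)]
    zs = np.linspace(z0 - half_height, z0 + half_height, n_rings)
    pts = []
    for z, m in zip(zs, per_ring):
        t = np.linspace(0, 2 * math.pi, m, endpoint=False)
        ring = np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t),
                                np.full(m, z)])
        pts.append(ring)
    barrel = np.vstack(pts) + rng.normal(0.0, 0.2, (n, 3))
    # β-sheet flag: the transmembrane-most fraction of atoms
    n_beta = int(round(ellipse.beta_fraction * n))
    order = np.argsort(np.abs(barrel[:, 2] - z0), kind="stable")
    beta = np.zeros(n, dtype=bool)
    beta[order[:n_beta]] = True

    out = AtomFrame(
        coords=np.vstack([frame.coords[keep], barrel]),
        box=frame.box.copy(),
        roles=np.concatenate([frame.roles[keep],
                              np.full(n, ROLE_PROTEIN, dtype=object)]),
        lipid_id=np.concatenate([frame.lipid_id[keep], np.full(n, -1)]),
        chain=np.concatenate([frame.chain[keep], np.full(n, -1)]),
        carbon=np.concatenate([frame.carbon[keep], np.full(n, -1)]),
        leaflet=np.concatenate([frame.leaflet[keep],
                                np.full(n, "", dtype=object)]),
        beta=np.concatenate([frame.beta[keep], beta]),
        time=frame.time,
        metadata=dict(frame.metadata),
    )
    out.metadata["ellipse"] = {
        "semi_axis_a": a, "semi_axis_b": b,
        "center": (cx, cy), "area": ellipse.area,
    }
    out.metadata["n_lipids_carved"] = len(carved)
    out.wrap()
    return out


# ----------------------------------------------------------------------
# synthetic barotropic NMR series
# ----------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def synth_pressure_series(spec: NmrSynthSpec):
    """Emit a synthetic barotropic intensity series.

    The intensity follows a descending logistic between ``plateau_high``
    (ambient) and ``plateau_low`` (high pressure) with midpoint ``Pm``
    and the given width, plus Gaussian noise.  In two-state mode a
    :class:`~bilayerscope.nmr.TwoStateSeries` is returned alongside, with
    the gel-state fraction Ig/(If+Ig) following an ascending logistic at
    the same midpoint.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.asarray(spec.pressures, dtype=float)
    amp = spec.plateau_high - spec.plateau_low
    intensity = (spec.plateau_low
                 + amp * _logistic((spec.Pm - p) / spec.width)
                 + rng.normal(0.0, spec.noise_sd, p.size))
    series = PressureSeries(
        pressures=p, intensity=intensity, peak_id="synthetic",
        metadata={"Pm": spec.Pm, "width": spec.width, "seed": spec.seed},
    )
    if not spec.two_state:
        return series
    p_gel = _logistic((p - spec.Pm) / spec.width)
    total = spec.plateau_high
    i_f = total * (1.0 - p_gel) + rng.normal(0.0, spec.noise_sd, p.size)
    i_g = total * p_gel + rng.normal(0.0, spec.noise_sd, p.size)
    two = TwoStateSeries(pressures=p, intensity_f=i_f, intensity_g=i_g,
                         metadata={"Pm": spec.Pm, "width": spec.width})
    return series, two


def synth_shift_series(pressures, kind: str = "sigmoidal", *,
                       shift0: float = 0.8, slope: float = 4e-5,
                       amplitude: float = 0.05, Pm: float = 600.0,
                       width: float = 100.0, noise_sd: float = 0.002,
                       seed: int = 0) -> np.ndarray:
    """Synthetic chemical-shift-vs-pressure curve (ppm).

    ``kind="linear"`` gives a pure linear drift (the behavior of peaks in
    a bilayer that never gels); ``kind="sigmoidal"`` adds a logistic step
    of the given amplitude at Pm on top of the same linear baseline (the
    inflection that tracks a lipid phase transition).
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(pressures, dtype=float)
    shifts = shift0 + slope * p
    if kind == "sigmoidal":
        shifts = shifts + amplitude * _logistic((p - Pm) / width)
    elif kind != "linear":
        raise InvalidSpecError(f"unknown shift-series kind: {kind!r}")
    return shifts + rng.normal(0.0, noise_sd, p.size)
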