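"""File I/O: structure/trajectory formats, role sidecars, peak tables.

Coordinates travel as PDB (single- or multi-model, box in CRYST1), GRO
(single frame) or multi-frame XYZ, all read and written through
MDAnalysis.  Atom roles are never inferred from atom names: every
trajectory is accompanied by a *role sidecar* CSV (atom index, lipid id,
leaflet, role, chain, carbon, β-flag) and a small JSON metadata file
(box lengths, frame times) covering what the coordinate format itself
cannot carry.  NMR peak tables are plain CSV with one row per
(pressure, peak, state).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

from .errors import FormatError
from .model import AtomFrame, Trajectory, as_trajectory

logger = logging.getLogger("bilayerscope")

_ROLE_NAMES = {  # short atom names for the coordinate formats
    "chain_carbon": "C",
    "glycerol_C": "CG",
    "phosphorus": "P",
    "nitrogen": "N",
    "water_O": "OW",
    "protein_heavy": "PR",
}

SIDECAR_COLUMNS = ["atom_index", "lipid_id", "leaflet", "role", "chain",
                   "carbon", "beta"]


def log_stage(stage: str, **params) -> None:
    """One structured log line per pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s %s", stage, kv)


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------

def _sidecar_frame(frame: AtomFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "atom_index": np.arange(frame.n_atoms),
        "lipid_id": frame.lipid_id,
        "leaflet": frame.leaflet.astype(str),
        "role": frame.roles.astype(str),
        "chain": frame.chain,
        "carbon": frame.carbon,
        "beta": frame.beta.astype(int),
    })


def write_trajectory(traj, prefix, fmt: str = "pdb") -> dict[str, Path]:
    """Write a trajectory (or single frame) plus its sidecars.

    Produces ``<prefix>.<fmt>``, ``<prefix>.roles.csv`` and
    ``<prefix>.meta.json``.  ``fmt`` is one of pdb (multi-model), gro
    (single frame only) or xyz (multi-frame; box lives in the metadata
    sidecar).  Returns the written paths.
    """
    traj = as_trajectory(traj)
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt not in ("pdb", "gro", "xyz"):
        raise FormatError(f"unsupported trajectory format {fmt!r}")
    if fmt == "gro" and traj.n_frames > 1:
        raise FormatError("GRO holds a single frame; use pdb or xyz")

    first = traj[0]
    n = first.n_atoms
    names = [_ROLE_NAMES.get(r, "X") for r in first.roles]
    u = mda.Universe.empty(n, n_residues=1,
                           atom_resindex=np.zeros(n, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", ["SYS"])
    u.add_TopologyAttr("resids", [1])
    coords = np.stack([f.coords for f in traj.frames]).astype(np.float32)
    dims = np.array([[*f.box, 90.0, 90.0, 90.0] for f in traj.frames],
                    dtype=np.float32)
    u.load_new(coords, format=MemoryReader, dimensions=dims)

    coord_path = prefix.with_suffix(f".{fmt}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(coord_path), n,
                        multiframe=traj.n_frames > 1) as w:
            for _ in u.trajectory:
                w.write(u.atoms)

    roles_path = prefix.parent / (prefix.name + ".roles.csv")
    _sidecar_frame(first).to_csv(roles_path, index=False)
    meta_path = prefix.parent / (prefix.name + ".meta.json")
    meta = {
        "format": fmt,
        "n_atoms": n,
        "box": [[float(x) for x in f.box] for f in traj.frames],
        "times_ns": [float(f.time) for f in traj.frames],
        "metadata": _jsonable(first.metadata),
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    log_stage("write_trajectory", path=str(coord_path),
              frames=traj.n_frames, atoms=n)
    return {"coordinates": coord_path, "roles": roles_path,
            "meta": meta_path}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_trajectory(path, role_sidecar=None, meta=None,
                    dt_ns: float | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    ``role_sidecar`` and ``meta`` default to the paths the writer uses.
    Frame times come from the metadata sidecar, or from ``dt_ns`` times
    the frame index when no metadata is available.  Unknown roles in the
    sidecar are tolerated (flagged in frame metadata); an atom-count
    mismatch between sidecar and coordinates is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    stem = path.parent / path.stem
    if role_sidecar is None:
        role_sidecar = stem.parent / (stem.name + ".roles.csv")
    if meta is None:
        candidate = stem.parent / (stem.name + ".meta.json")
        meta = candidate if candidate.exists() else None

    roles_df = pd.read_csv(role_sidecar)
    missing_cols = set(SIDECAR_COLUMNS) - set(roles_df.columns)
    if missing_cols:
        raise FormatError(
            f"role sidecar lacks columns: {sorted(missing_cols)}")

    meta_d = json.loads(Path(meta).read_text()) if meta else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    n = len(u.atoms)
    if len(roles_df) != n:
        raise FormatError(
            f"sidecar atom count {len(roles_df)} does not match "
            f"coordinates ({n} atoms)")

    boxes = meta_d.get("box")
    times = meta_d.get("times_ns")
    frames = []
    for i, ts in enumerate(u.trajectory):
        if boxes is not None:
            box = np.asarray(boxes[i] if isinstance(boxes[0], list)
                             else boxes, dtype=float)
        elif ts.dimensions is not None and ts.dimensions[:3].min() > 0:
            box = np.asarray(ts.dimensions[:3], dtype=float)
        else:
            raise FormatError(
                f"{path.suffix} carries no box; provide a meta sidecar")
        if times is not None:
            t = float(times[i])
        else:
            t = float(i * dt_ns) if dt_ns is not None else float(i)
        frames.append(AtomFrame(
            coords=ts.positions.astype(float),
            box=box,
            roles=roles_df["role"].to_numpy(dtype=object),
            lipid_id=roles_df["lipid_id"].to_numpy(dtype=int),
            chain=roles_df["chain"].to_numpy(dtype=int),
            carbon=roles_df["carbon"].to_numpy(dtype=int),
            leaflet=roles_df["leaflet"].fillna("").to_numpy(dtype=object),
            beta=roles_df["beta"].to_numpy(dtype=bool),
            time=t,
            metadata=dict(meta_d.get("metadata", {})),
        ))
    log_stage("read_trajectory", path=str(path), frames=len(frames))
    return Trajectory(frames)


# ----------------------------------------------------------------------
# NMR peak tables
# ----------------------------------------------------------------------

PEAK_REQUIRED = ["pressure", "peak_id", "intensity"]
PEAK_SHIFT_COLUMNS = ["shift_1H", "shift_13C"]


def read_peak_table(path) -> pd.DataFrame:
    """Read a CSV of (pressure, peak_id, intensity[, shifts, state]).

    Pressures must be numeric and ≥ 1 bar; duplicate
    (pressure, peak_id, state_label) rows are rejected.  When the shift
    columns are absent, the table is intensities-only and
    ``table.attrs["shifts_present"]`` is False.
    """
    df = pd.read_csv(path)
    missing = [c for c in PEAK_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"peak table lacks columns: {missing}")
    try:
        df["pressure"] = pd.to_numeric(df["pressure"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric pressure value: {exc}") from exc
    if (df["pressure"] < 1.0 - 1e-9).any():
        raise FormatError("pressures must be >= 1 bar")
    key = ["pressure", "peak_id"]
    if "state_label" in df.columns:
        key.append("state_label")
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key)].iloc[0]
        raise FormatError(
            f"duplicate peak-table row for {tuple(dup[key])}")
    df.attrs["shifts_present"] = any(
        c in df.columns for c in PEAK_SHIFT_COLUMNS)
    log_stage("read_peak_table", path=str(path), rows=len(df))
    return df


def write_peak_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ----------------------------------------------------------------------
# run manifests
# ----------------------------------------------------------------------

def write_manifest(outdir, config: dict) -> Path:
    """Record the run configuration, seeds and versions beside outputs."""
    import bilayerscope
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _jsonable(config),
        "versions": {
            "bilayerscope": bilayerscope.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "MDAnalysis": mda.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
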