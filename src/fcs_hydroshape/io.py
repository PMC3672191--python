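"""Reading and writing the package's text formats.

* correlation curves — delimited text with header ``lag_s,g[,sigma]``,
  '.' decimal separator (any of comma/tab/whitespace delimiters accepted
  on read, comma written);
* photon traces — two columns ``t_s,counts``; the bin width is recovered
  from the time column;
* trajectories — XYZ (atom count header, comment line carrying the frame
  time in ps, coordinates in nm) or multi-model PDB (via MDAnalysis; the
  PDB format carries no frame times, so times are re-synthesized as
  0,1,2,… ps on read).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import UsageError
from .fcs import CorrelationCurve
from .synthetic import PhotonTrace
from .traj import Trajectory

__all__ = [
    "read_curve",
    "write_curve",
    "read_trace",
    "write_trace",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
]

PathLike = Union[str, Path]


def _read_table(path: PathLike) -> pd.DataFrame:
    """Delimiter-sniffing CSV/TSV reader with exact float round-trip."""
    import csv

    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        delim = csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
    except csv.Error:
        delim = ","
    return pd.read_csv(path, sep=delim, float_precision="round_trip")


def read_curve(path: PathLike) -> CorrelationCurve:
    df = _read_table(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "lag_s" not in cols or "g" not in cols:
        raise UsageError(f"curve file {path} must have header columns lag_s,g[,sigma]")
    sigma = df[cols["sigma"]].to_numpy(float) if "sigma" in cols else None
    return CorrelationCurve(lags_s=df[cols["lag_s"]].to_numpy(float), g=df[cols["g"]].to_numpy(float), sigma=sigma)


def write_curve(curve: CorrelationCurve, path: PathLike) -> None:
    data = {"lag_s": curve.lags_s, "g": curve.g}
    if curve.sigma is not None:
        data["sigma"] = curve.sigma
    pd.DataFrame(data).to_csv(path, index=False)


def read_trace(path: PathLike) -> PhotonTrace:
    df = _read_table(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "t_s" not in cols or "counts" not in cols:
        raise UsageError(f"trace file {path} must have header columns t_s,counts")
    t = df[cols["t_s"]].to_numpy(float)
    if len(t) < 2:
        raise UsageError("trace must contain at least two bins")
    return PhotonTrace(bin_width_s=float(t[1] - t[0]), counts=df[cols["counts"]].to_numpy())


def write_trace(trace: PhotonTrace, path: PathLike) -> None:
    t = np.arange(len(trace.counts)) * trace.bin_width_s
    pd.DataFrame({"t_s": t, "counts": trace.counts}).to_csv(path, index=False)


def write_xyz(traj: Trajectory, path: PathLike) -> None:
    """XYZ with coordinates in nm and the frame time (ps) on the comment line."""
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {float(traj.times_ps[i])!r} ps\n")
            for label, (x, y, z) in zip(traj.atom_labels, traj.coords[i]):
                fh.write(f"{label} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path: PathLike, units: str = "nm") -> Trajectory:
    scale = {"nm": 1.0, "angstrom": 0.1}.get(units)
    if scale is None:
        raise UsageError(f"units must be 'nm' or 'angstrom', got {units!r}")
    times, frames, labels = [], [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    frame_idx = 0
    while i < len(lines) and lines[i].strip():
        n_atoms = int(lines[i].strip())
        comment = lines[i + 1]
        tokens = comment.replace("=", " ").split()
        t = None
        for j, tok in enumerate(tokens):
            if tok == "t" and j + 1 < len(tokens):
                t = float(tokens[j + 1])
                break
        times.append(float(frame_idx) if t is None else t)
        block = lines[i + 2 : i + 2 + n_atoms]
        frame_labels = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords * scale)
        if labels is None:
            labels = frame_labels
        i += 2 + n_atoms
        frame_idx += 1
    if not frames:
        raise UsageError(f"no frames found in {path}")
    return Trajectory(times_ps=np.array(times), coords=np.stack(frames), atom_labels=tuple(labels))


def write_pdb(traj: Trajectory, path: PathLike) -> None:
    """Multi-model PDB (coordinates converted nm → Å). Frame times are not
    representable in the format and are dropped."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        u.add_TopologyAttr("names", list(traj.atom_labels))
        u.add_TopologyAttr("resnames", ["GLY"])
        u.add_TopologyAttr("resids", [1])
        with mda.Writer(str(path), multiframe=True, n_atoms=traj.n_atoms) as writer:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.coords[i] * 10.0
                writer.write(u.atoms)


def read_pdb(path: PathLike) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        labels = tuple(u.atoms.names)
        frames = np.stack([u.atoms.positions.copy() / 10.0 for _ in u.trajectory])
    times = np.arange(len(frames), dtype=float)
    return Trajectory(times_ps=times, coords=frames, atom_labels=labels)


def read_trajectory(path: PathLike, units: str = "nm") -> Trajectory:
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path, units=units)
    if suffix == ".pdb":
        return read_pdb(path)
    raise UsageError(f"unsupported trajectory format {suffix!r}; use .xyz or .pdb")


def write_trajectory(traj: Trajectory, path: PathLike) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        write_xyz(traj, path)
    elif suffix == ".pdb":
        write_pdb(traj, path)
    else:
        raise UsageError(f"unsupported trajectory format {suffix!r}; use .xyz or .pdb")
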