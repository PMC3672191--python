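"""Post-processing statistics for molecular trajectories.

Implements the standard desk analyses applied to molecular-dynamics output:
mean square displacement and the Einstein-relation diffusion constant,
least-squares (Kabsch) superposed RMSD, radius of gyration, the greedy
neighbor-counting conformational clustering of Daura, principal component
analysis of Cα coordinates, and two-dimensional free-energy landscapes from
principal-component projections.

Coordinates are in nm and frame times in ps throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import linregress

from .constants import NM2_PER_PS_TO_UM2_PER_S
from .errors import DomainError, FitError, UsageError

__all__ = [
    "Trajectory",
    "MsdCurve",
    "DiffusionEstimate",
    "ClusterResult",
    "PcaResult",
    "FelGrid",
    "msd",
    "einstein_diffusion",
    "kabsch_rmsd",
    "radius_of_gyration",
    "daura_cluster",
    "pca_ca",
    "free_energy_landscape",
]

Selection = Union[None, str, Sequence[int]]

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped frames of labelled 3D coordinates.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm; ``times_ps`` is
    strictly increasing; ``atom_labels`` enables named selections such as
    "CA" or "backbone".
    """

    times_ps: np.ndarray
    coords: np.ndarray
    atom_labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times_ps, dtype=float)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise DomainError(f"coords must have shape (n_frames, n_atoms, 3), got {coords.shape}")
        if len(times) != coords.shape[0]:
            raise DomainError("times and coords disagree on frame count")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise DomainError("frame times must be strictly increasing")
        labels = tuple(self.atom_labels)
        if len(labels) != coords.shape[1]:
            raise DomainError("atom_labels length must equal atom count")
        object.__setattr__(self, "times_ps", times)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_labels", labels)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, selection: Selection) -> np.ndarray:
        """Resolve a selection (None/"all", "CA", "backbone", or index list)."""
        if selection is None or (isinstance(selection, str) and selection.lower() == "all"):
            idx = np.arange(self.n_atoms)
        elif isinstance(selection, str):
            name = selection.upper()
            if name == "BACKBONE":
                idx = np.array([i for i, lab in enumerate(self.atom_labels) if lab.upper() in _BACKBONE_NAMES], dtype=int)
            else:
                idx = np.array([i for i, lab in enumerate(self.atom_labels) if lab.upper() == name], dtype=int)
        else:
            idx = np.asarray(selection, dtype=int)
        if len(idx) == 0:
            raise UsageError(f"selection {selection!r} matches no atoms")
        return idx

    def frame(self, i: int, selection: Selection = None) -> np.ndarray:
        return self.coords[i][self.atom_indices(selection)]


@dataclass(frozen=True)
class MsdCurve:
    """Mean square displacement versus lag time."""

    lags_ps: np.ndarray
    msd_nm2: np.ndarray


@dataclass(frozen=True)
class DiffusionEstimate:
    """Einstein-relation diffusion constant with ordinary-least-squares SE."""

    D_um2_s: float
    D_se_um2_s: float
    slope_nm2_ps: float
    intercept_nm2: float


@dataclass(frozen=True)
class ClusterResult:
    assignments: np.ndarray  # frame index -> cluster id (0-based, by extraction order)
    centers: Tuple[int, ...]  # representative frame per cluster
    sizes: Tuple[int, ...]

    def __post_init__(self) -> None:
        if int(np.sum(self.sizes)) != len(self.assignments):
            raise DomainError("cluster sizes must sum to frame count")
        for cid, center in enumerate(self.centers):
            if self.assignments[center] != cid:
                raise DomainError("cluster center must belong to its own cluster")


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray  # nm², descending
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    projections: np.ndarray  # (n_frames, n_modes), mean zero per mode
    mean: np.ndarray  # (3N,) mean superposed configuration


@dataclass(frozen=True)
class FelGrid:
    """Free-energy landscape over a 2D projection, in units of kT.

    ``delta_g_kT`` is NaN on unvisited bins; ``occupied`` distinguishes them
    from genuinely high-energy (but visited) bins.  The occupied minimum is
    exactly zero.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    delta_g_kT: np.ndarray
    occupied: np.ndarray


def _uniform_dt(times: np.ndarray) -> float:
    dts = np.diff(times)
    if len(dts) == 0:
        raise UsageError("need at least two frames")
    if not np.allclose(dts, dts[0], rtol=1e-8, atol=0.0):
        raise UsageError("MSD over all time origins requires uniformly spaced frames")
    return float(dts[0])


def _msd_fft_1atom(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of one particle track (n, 3) via the FFT identity
    MSD(k) = S1(k) − 2·S2(k), with S2 the positional autocorrelation."""
    n = len(x)
    norms = np.sum(x**2, axis=1)
    # S2 per dimension via FFT-based autocorrelation
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(f * np.conj(f), n=nfft, axis=0)[:n].sum(axis=1)
    counts = np.arange(n, 0, -1, dtype=float)
    s2 = acf / counts
    # S1 via the standard recursive sum
    sq_sum = 2.0 * np.sum(norms)
    s1 = np.empty(n)
    s1[0] = sq_sum / n
    for k in range(1, n):
        sq_sum -= norms[k - 1] + norms[n - k]
        s1[k] = sq_sum / (n - k)
    return s1 - 2.0 * s2


def msd(traj: Trajectory, selection: Selection = None) -> MsdCurve:
    """Mean square displacement averaged over selected atoms and all time
    origins (sliding window), as a function of lag time."""
    if traj.n_frames < 2:
        raise UsageError("MSD requires at least two frames")
    idx = traj.atom_indices(selection)
    dt = _uniform_dt(traj.times_ps)
    total = np.zeros(traj.n_frames)
    for a in idx:
        total += _msd_fft_1atom(traj.coords[:, a, :])
    values = total / len(idx)
    values[0] = 0.0  # exact by definition; guards FFT rounding
    lags = np.arange(traj.n_frames) * dt
    return MsdCurve(lags_ps=lags, msd_nm2=values)


def einstein_diffusion(curve: MsdCurve, fit_window: Tuple[float, float] = (0.1, 0.5)) -> DiffusionEstimate:
    """Diffusion constant from the Einstein relation MSD = 6·D·Δt.

    An ordinary least-squares line is fitted through the MSD over the lag
    window given as fractions of the maximum lag; D = slope/6, converted to
    µm²/s.
    """
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise UsageError(f"fit_window must satisfy 0 <= lo < hi <= 1, got {fit_window}")
    lag_max = curve.lags_ps[-1]
    mask = (curve.lags_ps >= lo * lag_max) & (curve.lags_ps <= hi * lag_max)
    if int(mask.sum()) < 5:
        raise UsageError(f"fit window contains {int(mask.sum())} points; need >= 5")
    res = linregress(curve.lags_ps[mask], curve.msd_nm2[mask])
    d = res.slope / 6.0 * NM2_PER_PS_TO_UM2_PER_S
    d_se = res.stderr / 6.0 * NM2_PER_PS_TO_UM2_PER_S
    return DiffusionEstimate(D_um2_s=d, D_se_um2_s=d_se, slope_nm2_ps=res.slope, intercept_nm2=res.intercept)


def kabsch_rmsd(frame_a: np.ndarray, frame_b: np.ndarray, superpose: bool = True) -> float:
    """RMSD (nm) between two coordinate sets, optionally after optimal
    least-squares rotation/translation (Kabsch superposition)."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise UsageError(f"frames must share shape (n_atoms, 3), got {a.shape} and {b.shape}")
    if superpose:
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(ac, bc)
        diff = ac - rot.apply(bc)
    else:
        diff = a - b
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def radius_of_gyration(frame: np.ndarray, masses: Optional[np.ndarray] = None) -> float:
    """Radius of gyration (nm): RMS distance of atoms from their centroid.

    Geometric (unweighted) by default; pass per-atom masses for the
    mass-weighted variant.
    """
    x = np.asarray(frame, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or len(x) == 0:
        raise UsageError("frame must be a non-empty (n_atoms, 3) array")
    if masses is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(masses, dtype=float)
        if len(w) != len(x) or np.any(w <= 0):
            raise UsageError("masses must be positive and match the atom count")
    center = np.average(x, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((x - center) ** 2, axis=1), weights=w)))


def pairwise_rmsd_matrix(
    traj: Trajectory,
    selection: Selection = None,
    superpose: bool = True,
    _chunk_rows: int = 64,
) -> np.ndarray:
    """Symmetric matrix of (superposed) RMSDs between all frame pairs.

    Uses the closed-form Kabsch result via batched 3×3 SVDs: for centered
    frames A, B the minimal squared deviation is
    (|A|² + |B|² − 2·(σ1+σ2±σ3))/m with σ the singular values of AᵀB and
    the sign fixed by det to exclude reflections.
    """
    idx = traj.atom_indices(selection)
    frames = np.asarray(traj.coords[:, idx, :], dtype=float)
    n, m, _ = frames.shape
    if not superpose:
        diff = frames[:, None, :, :] - frames[None, :, :, :]
        return np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))
    centered = frames - frames.mean(axis=1, keepdims=True)
    sq = np.sum(centered**2, axis=(1, 2))
    dist = np.zeros((n, n))
    for start in range(0, n, _chunk_rows):
        stop = min(start + _chunk_rows, n)
        # cross-covariances H[i,j] = A_iᵀ A_j for the row block
        h = np.einsum("iak,jal->ijkl", centered[start:stop], centered)
        u, s, vt = np.linalg.svd(h)
        sign = np.sign(np.linalg.det(u @ vt))
        d = s[..., 0] + s[..., 1] + sign * s[..., 2]
        msd_block = (sq[start:stop, None] + sq[None, :] - 2.0 * d) / m
        dist[start:stop] = np.sqrt(np.clip(msd_block, 0.0, None))
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0  # enforce exact symmetry against SVD rounding


def daura_cluster(
    traj: Trajectory,
    cutoff_nm: float = 0.25,
    selection: Selection = None,
    distance_matrix: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Greedy neighbor-counting conformational clustering (Daura algorithm).

    Repeatedly: count, for every unassigned frame, its unassigned neighbors
    within the RMSD cutoff; the frame with the most neighbors (ties broken
    by lowest frame index) becomes a cluster center and is removed together
    with its neighbors.  A precomputed distance matrix may be supplied to
    skip the O(n²) superposed-RMSD computation.
    """
    if cutoff_nm < 0:
        raise DomainError(f"cutoff must be non-negative, got {cutoff_nm}")
    dist = pairwise_rmsd_matrix(traj, selection) if distance_matrix is None else np.asarray(distance_matrix, float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != traj.n_frames:
        raise UsageError("distance matrix shape must be (n_frames, n_frames)")
    neighbors = dist <= cutoff_nm
    np.fill_diagonal(neighbors, True)
    active = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    while active.any():
        counts = np.where(active, (neighbors & active).sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the first maximum -> lowest index wins ties
        members = np.nonzero(neighbors[center] & active)[0]
        assignments[members] = len(centers)
        centers.append(center)
        sizes.append(len(members))
        active[members] = False
    return ClusterResult(assignments=assignments, centers=tuple(centers), sizes=tuple(sizes))


def _superpose_to(reference: np.ndarray, frames: np.ndarray) -> np.ndarray:
    ref_c = reference - reference.mean(axis=0)
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        fc = fr - fr.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, fc)
        out[i] = rot.apply(fc)
    return out


def pca_ca(traj: Trajectory, selection: Selection = "CA", n_superpose_iter: int = 3) -> PcaResult:
    """Principal component analysis of the positional covariance of selected
    atoms (Cα by default) — "essential dynamics".

    Frames are iteratively superposed onto their mean structure, then the
    3N×3N covariance of the flattened coordinates is diagonalized.  All
    selected atoms share one species, so the mass-weighted and geometric
    covariance coincide up to a constant factor.
    """
    if traj.n_frames < 3:
        raise UsageError("PCA requires at least three frames")
    idx = traj.atom_indices(selection)
    frames = traj.coords[:, idx, :].copy()
    reference = frames[0]
    aligned = frames
    for _ in range(max(1, n_superpose_iter)):
        aligned = _superpose_to(reference, frames)
        reference = aligned.mean(axis=0)
    n, m, _ = aligned.shape
    x = aligned.reshape(n, 3 * m)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = xc @ evecs
    return PcaResult(eigenvalues=evals, eigenvectors=evecs, projections=projections, mean=mean)


def free_energy_landscape(
    p1: np.ndarray,
    p2: np.ndarray,
    n_bins: int = 32,
    temperature_K: Optional[float] = None,
) -> FelGrid:
    """Free-energy landscape ΔG = −ln(P/P_max) over two projections.

    ``temperature_K`` is accepted for callers that convert the kT-unit
    surface to absolute energies; the grid itself is stored in kT.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise UsageError("projections must be equal-length 1D arrays")
    if n_bins < 4:
        raise UsageError(f"n_bins must be >= 4, got {n_bins}")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise FitError("degenerate histogram: all projection points identical")
    counts, x_edges, y_edges = np.histogram2d(a, b, bins=n_bins)
    occupied = counts > 0
    delta_g = np.full_like(counts, np.nan)
    p_max = counts.max()
    delta_g[occupied] = -np.log(counts[occupied] / p_max)
    return FelGrid(x_edges=x_edges, y_edges=y_edges, counts=counts, delta_g_kT=delta_g, occupied=occupied)
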