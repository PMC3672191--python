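"""Synthetic data generators: the package's stand-in for the instrument and
for molecular-dynamics engine output.

Three layers of realism are provided for correlation data:

1. :func:`simulate_curve` — the analytic autocorrelation with multiplicative
   Gaussian noise of constant coefficient of variation (curve-level noise;
   full detector noise theory is deliberately out of scope);
2. :func:`simulate_photon_trace` — physical ground truth: point emitters
   performing Brownian motion through a squared-Gaussian (two-photon)
   detection profile in a periodic box, with Poisson photon statistics;
3. :func:`multitau_correlate` — the quasi-logarithmic multi-tau correlator
   that turns a photon-count trace into a correlation curve, as correlator
   hardware does.

:func:`titration_scenario` emulates a pH series of a protein that is
compact near neutral pH and partially unfolded/aggregating at the extremes,
with a minor slow-diffusing (aggregate) species.  :func:`toy_trajectory`
produces trajectories with known diffusion constants or planted cluster
structure for the trajectory-statistics module.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .constants import FL_TO_L, N_AVOGADRO, UM2_PER_S_TO_NM2_PER_PS
from .errors import DomainError, NormalizationError, UsageError
from .fcs import (
    BeamGeometry,
    CorrelationCurve,
    FcsModel,
    PhotonMode,
    Species,
    autocorrelation,
    diffusion_time,
    effective_volume,
)
from .traj import Trajectory

__all__ = [
    "PhotonTrace",
    "EmitterSpecies",
    "TitrationScenario",
    "simulate_curve",
    "simulate_photon_trace",
    "multitau_correlate",
    "titration_scenario",
    "toy_trajectory",
    "default_lag_grid",
]


@dataclass(frozen=True)
class PhotonTrace:
    """Detector stream: photon counts per bin of fixed width."""

    bin_width_s: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not self.bin_width_s > 0:
            raise DomainError(f"bin width must be positive, got {self.bin_width_s}")
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or np.any(counts < 0):
            raise DomainError("counts must be a 1D array of non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def duration_s(self) -> float:
        return self.bin_width_s * len(self.counts)


@dataclass(frozen=True)
class EmitterSpecies:
    """A population of identical point emitters for the Brownian simulator.

    ``brightness_cps`` is the mean detected count rate of one emitter at
    the focus center; ``D_um2_s`` may be zero (immobile emitters).
    """

    D_um2_s: float
    brightness_cps: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.D_um2_s < 0:
            raise DomainError("emitter D must be non-negative")
        if self.brightness_cps < 0:
            raise DomainError("brightness must be non-negative")
        if self.count < 1:
            raise DomainError("emitter count must be >= 1")


@dataclass(frozen=True)
class TitrationScenario:
    """Ground truth and simulated curves for a synthetic pH titration."""

    ph_values: Tuple[float, ...]
    D_profile_um2_s: Tuple[float, ...]
    slow_fraction_profile: Tuple[float, ...]
    slow_D_um2_s: float
    occupancy: float
    curves: Dict[float, CorrelationCurve]


def default_lag_grid(n_lags: int = 64, lag_min_s: float = 1e-6, lag_max_s: float = 1.0) -> np.ndarray:
    """Logarithmically spaced lag grid (s), the shape correlators report."""
    if n_lags < 2 or not 0 < lag_min_s < lag_max_s:
        raise UsageError("invalid lag grid specification")
    return np.geomspace(lag_min_s, lag_max_s, n_lags)


def simulate_curve(
    model: FcsModel,
    beam: BeamGeometry,
    noise_cv: float = 0.0,
    lag_grid: Optional[np.ndarray] = None,
    seed: int = 0,
) -> CorrelationCurve:
    """Analytic autocorrelation with multiplicative Gaussian noise.

    g = G(τ)·(1 + noise_cv·ζ) with ζ i.i.d. standard normal; the sigma field
    is set to the true per-point standard deviation noise_cv·G(τ).
    """
    if noise_cv < 0:
        raise DomainError(f"noise_cv must be non-negative, got {noise_cv}")
    lags = default_lag_grid() if lag_grid is None else np.asarray(lag_grid, dtype=float)
    g_true = autocorrelation(model, beam, lags)
    if noise_cv == 0:
        return CorrelationCurve(lags_s=lags, g=g_true)
    rng = np.random.default_rng(seed)
    zeta = rng.standard_normal(len(lags))
    return CorrelationCurve(lags_s=lags, g=g_true * (1.0 + noise_cv * zeta), sigma=noise_cv * g_true)


def simulate_photon_trace(
    emitters: Sequence[EmitterSpecies],
    beam: BeamGeometry,
    box_um,
    dt_s: float,
    duration_s: float,
    seed: int = 0,
    initial_positions: Optional[Mapping[int, np.ndarray]] = None,
    _chunk_bins: int = 20000,
) -> PhotonTrace:
    """Brownian-dynamics photon trace through a squared-Gaussian focus.

    Emitters take 3D Gaussian steps of per-axis variance 2·D·dt in a
    periodic box centered on the focus; ``box_um`` is a cube side or an
    (Lx, Ly, Lz) triple — an elongated z side keeps the slow axial decay
    well resolved by the box's discrete diffusion modes.  The
    expected count in a bin is Σ brightness·dt·exp(−4r²/ω0² − 4z²/z0²)
    (the square of the Gaussian illumination profile, as appropriate for
    two-photon detection); realized counts are Poisson draws.

    ``initial_positions`` maps an emitter-species index to a (count, 3)
    array of starting positions (µm, focus at the origin); species without
    an entry start uniformly distributed in the box.
    """
    if not dt_s > 0 or not duration_s > 0:
        raise DomainError("dt and duration must be positive")
    box = np.broadcast_to(np.asarray(box_um, dtype=float), (3,)).copy()
    if np.any(box < 10.0 * beam.omega0_um):
        raise UsageError(
            f"every box side must satisfy box >= 10·omega0 = {10 * beam.omega0_um:.3g} µm, got {box_um}"
        )
    mobile = [e for e in emitters if e.D_um2_s > 0]
    if mobile:
        tau_fast = min(diffusion_time(e.D_um2_s, beam) for e in mobile)
        if dt_s > tau_fast / 20.0:
            raise UsageError(
                f"dt = {dt_s:.3g} s violates dt <= tau_D/20 = {tau_fast / 20:.3g} s "
                "for the fastest species"
            )
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration_s / dt_s))
    positions: list[np.ndarray] = []
    for k, em in enumerate(emitters):
        if initial_positions is not None and k in initial_positions:
            pos = np.array(initial_positions[k], dtype=float).reshape(em.count, 3)
        else:
            pos = rng.uniform(-box / 2.0, box / 2.0, size=(em.count, 3))
        positions.append(pos)

    inv_w2 = 4.0 / beam.omega0_um**2
    inv_z2 = 4.0 / beam.z0_um**2
    counts = np.empty(n_bins, dtype=np.int64)
    start = 0
    while start < n_bins:
        nb = min(_chunk_bins, n_bins - start)
        expected = np.zeros(nb)
        for k, em in enumerate(emitters):
            sigma = np.sqrt(2.0 * em.D_um2_s * dt_s)  # µm
            if sigma > 0:
                # single precision is ample for µm-scale Brownian steps and
                # roughly halves the generation cost
                steps = rng.standard_normal(size=(nb, em.count, 3), dtype=np.float32) * np.float32(sigma)
                path = positions[k][None, :, :].astype(np.float32) + np.cumsum(steps, axis=0)
            else:
                path = np.broadcast_to(positions[k], (nb, em.count, 3))
            wrapped = (path + box / 2.0) % box - box / 2.0
            if em.brightness_cps > 0:
                profile = np.exp(
                    -inv_w2 * (wrapped[..., 0] ** 2 + wrapped[..., 1] ** 2)
                    - inv_z2 * wrapped[..., 2] ** 2
                )
                expected += em.brightness_cps * profile.sum(axis=1)
            positions[k] = wrapped[-1].copy()
        counts[start : start + nb] = rng.poisson(expected * dt_s)
        start += nb
    return PhotonTrace(bin_width_s=dt_s, counts=counts)


def _norm_corr(series: np.ndarray, k: int) -> float:
    """Symmetrically normalized fluctuation correlation at integer lag k."""
    left = series[:-k]
    right = series[k:]
    ml = left.mean()
    mr = right.mean()
    return float((left * right).mean() / (ml * mr) - 1.0)


def _multitau_grid(x: np.ndarray, dt: float, m: int) -> Tuple[np.ndarray, np.ndarray]:
    lags: list[float] = []
    g: list[float] = []
    width = dt
    series = x
    for k in range(1, m + 1):
        lags.append(k * width)
        g.append(_norm_corr(series, k))
    while True:
        n2 = (len(series) // 2) * 2
        series = series[0:n2:2] + series[1:n2:2]
        width *= 2.0
        if len(series) < 2 * m:
            break
        for k in range(m // 2 + 1, m + 1):
            lags.append(k * width)
            g.append(_norm_corr(series, k))
    return np.array(lags), np.array(g)


def multitau_correlate(trace: PhotonTrace, m: int = 16, n_segments: int = 1) -> CorrelationCurve:
    """Multi-tau autocorrelation of a photon-count trace.

    The first block evaluates lags 1..m at the native bin width; each later
    block halves the time resolution (summing adjacent bins) and evaluates
    lags m/2+1..m in the coarser units, producing a quasi-logarithmic grid
    reaching at least a quarter of the trace duration.  Normalization is
    symmetric (separate means over the left and right segments), which
    removes the leading finite-length bias.

    With ``n_segments > 1`` per-point standard errors are estimated by
    correlating equal contiguous segments of the trace and taking the
    standard error of the mean across segments; the curve is then truncated
    to the lag range every segment covers.
    """
    if m < 2 or m % 2:
        raise UsageError(f"m must be a positive even integer, got {m}")
    x = trace.counts.astype(float)
    if len(x) < 4 * m:
        raise UsageError(f"trace length {len(x)} is below the minimum 4·m = {4 * m}")
    if x.mean() == 0:
        raise NormalizationError("trace has zero mean intensity; correlation undefined")
    lags, g = _multitau_grid(x, trace.bin_width_s, m)
    if n_segments <= 1:
        return CorrelationCurve(lags_s=lags, g=g)
    seg_len = len(x) // n_segments
    if seg_len < 4 * m:
        raise UsageError(f"{n_segments} segments of {seg_len} bins are too short (need >= {4 * m})")
    seg_g = []
    for i in range(n_segments):
        seg = x[i * seg_len : (i + 1) * seg_len]
        if seg.mean() == 0:
            raise NormalizationError("a trace segment has zero mean intensity")
        seg_g.append(_multitau_grid(seg, trace.bin_width_s, m)[1])
    seg_g = np.vstack(seg_g)
    n_common = seg_g.shape[1]
    sigma = np.std(seg_g, axis=0, ddof=1) / np.sqrt(n_segments)
    sigma = np.maximum(sigma, 1e-12)  # guard exactly-reproducible segments
    return CorrelationCurve(lags_s=lags[:n_common], g=g[:n_common], sigma=sigma)


# pH -> fast-species diffusion coefficient, µm²/s: rises 25->50 over pH 2-4.5,
# plateaus to pH 6, peaks at 84 at neutral pH, declines to ~31 by pH 10.
_PH_KNOTS = np.array([2.0, 4.5, 6.0, 7.0, 10.0, 11.0])
_D_KNOTS = np.array([25.0, 50.0, 50.0, 84.0, 31.0, 31.0])


def titration_D_profile(ph: np.ndarray) -> np.ndarray:
    return np.interp(ph, _PH_KNOTS, _D_KNOTS)


def titration_slow_fraction(ph: np.ndarray) -> np.ndarray:
    """Aggregate fraction: ~0.2% at pH 7 (negligible, below the model-selection
    floor), ~3% at pH 4/10, ~10% at the extremes."""
    return 0.002 + 0.098 * np.clip(np.abs(np.asarray(ph, float) - 7.0) / 4.5, 0.0, 1.0) ** 3


def titration_scenario(
    ph_values: Sequence[float],
    seed: int = 0,
    beam: Optional[BeamGeometry] = None,
    concentration_nM: float = 10.0,
    noise_cv: float = 0.02,
    slow_D_um2_s: float = 15.0,
    n_lags: int = 1024,
) -> TitrationScenario:
    """Simulate a pH titration of correlation curves with known ground truth.

    Defaults mirror the measurement conditions of a two-photon titration of
    a 10 nM labelled protein: a fast (monomer) species whose D follows the
    piecewise-linear pH profile, plus a minor slow (aggregate) species at
    D = 15 µm²/s whose fraction peaks at extreme pH.  The lag grid is the
    dense (1024-point) grid a software correlator produces; resolving a
    few-percent slow component at 2% per-point noise requires that density.
    """
    ph = np.asarray(list(ph_values), dtype=float)
    if np.any((ph < 2.0) | (ph > 11.0)):
        raise UsageError("pH values must lie within [2, 11]")
    if beam is None:
        beam = BeamGeometry(omega0_um=0.4, z0_um=2.0, photon_mode=PhotonMode.TWO_PHOTON)
    occupancy = concentration_nM * 1e-9 * N_AVOGADRO * effective_volume(beam) * FL_TO_L
    d_fast = titration_D_profile(ph)
    f_slow = titration_slow_fraction(ph)
    children = np.random.SeedSequence(seed).spawn(len(ph))
    lag_grid = default_lag_grid(n_lags=n_lags)
    curves: Dict[float, CorrelationCurve] = {}
    for value, d1, f2, child in zip(ph, d_fast, f_slow, children):
        model = FcsModel(
            species=(Species(d1, 1.0 - f2), Species(slow_D_um2_s, f2)),
            occupancy=occupancy,
        )
        curves[float(value)] = simulate_curve(
            model, beam, noise_cv=noise_cv, lag_grid=lag_grid, seed=child
        )
    return TitrationScenario(
        ph_values=tuple(float(v) for v in ph),
        D_profile_um2_s=tuple(d_fast),
        slow_fraction_profile=tuple(f_slow),
        slow_D_um2_s=slow_D_um2_s,
        occupancy=occupancy,
        curves=curves,
    )


def toy_trajectory(
    n_frames: int,
    n_atoms: int,
    mode: str,
    params: Optional[Mapping] = None,
    seed: int = 0,
) -> Trajectory:
    """Toy trajectories with known structure for the statistics module.

    Modes
    -----
    ``static``
        identical frames (a random rigid structure).
    ``diffusive``
        the same rigid structure whose center of mass performs Brownian
        motion with diffusion constant ``D_um2_s`` (default 80) at time step
        ``dt_ps`` (default 1.0).
    ``two-state``
        frames drawn from two reference conformations separated by
        ``separation_nm`` RMSD (default 1.0) with isotropic Gaussian jitter
        ``jitter_nm`` (default 0.01); state counts are exact
        (round(weight·n_frames)), order shuffled by the seed.
    """
    if n_frames < 2:
        raise UsageError(f"n_frames must be >= 2, got {n_frames}")
    if n_atoms < 1:
        raise UsageError(f"n_atoms must be >= 1, got {n_atoms}")
    p = dict(params or {})
    dt_ps = float(p.pop("dt_ps", 1.0))
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=(n_atoms, 3))
    times = np.arange(n_frames) * dt_ps
    labels = tuple(p.pop("labels", ["CA"] * n_atoms))

    if mode == "static":
        coords = np.repeat(base[None, :, :], n_frames, axis=0)
    elif mode == "diffusive":
        d_nm2_ps = float(p.pop("D_um2_s", 80.0)) * UM2_PER_S_TO_NM2_PER_PS
        sigma = np.sqrt(2.0 * d_nm2_ps * dt_ps)
        steps = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
        com = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        coords = base[None, :, :] + com[:, None, :]
    elif mode == "two-state":
        weights = tuple(p.pop("weights", (0.9, 0.1)))
        jitter = float(p.pop("jitter_nm", 0.01))
        separation = float(p.pop("separation_nm", 1.0))
        offset = rng.normal(0.0, 1.0, size=(n_atoms, 3))
        offset *= separation / np.sqrt(np.mean(np.sum(offset**2, axis=1)))
        n_minor = int(round(weights[1] * n_frames))
        states = np.zeros(n_frames, dtype=int)
        states[:n_minor] = 1
        rng.shuffle(states)
        refs = np.stack([base, base + offset])
        coords = refs[states] + rng.normal(0.0, jitter, size=(n_frames, n_atoms, 3))
    else:
        raise UsageError(f"unknown trajectory mode {mode!r}; use static|diffusive|two-state")
    if p:
        raise UsageError(f"unused parameters for mode {mode!r}: {sorted(p)}")
    return Trajectory(times_ps=times, coords=coords, atom_labels=labels)
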