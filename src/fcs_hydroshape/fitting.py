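"""Weighted nonlinear least-squares fitting of FCS correlation curves.

One- and two-species 3D-Gaussian diffusion models are fitted by bounded
trust-region least squares (through lmfit) with a small multi-start over
log-spaced diffusion-coefficient initializations — the two-species objective
is multimodal, and a single start frequently lands in the wrong basin.

Conventions:

* residuals are (g_obs − g_model)/σ; σ = 1 when the curve carries no
  uncertainties, in which case the reduced χ² is only a relative measure;
* fitted species are reported sorted by descending D, so ``D1`` is always
  the faster species and ``F1`` its amplitude fraction;
* a two-species fit is preferred over the nested one-species fit only when
  the reduced χ² improves by more than a configurable relative threshold
  *and* the minor fraction exceeds a floor — mirroring the parsimony rule
  used when analyzing titration data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import lmfit
import numpy as np

from .errors import FitError, UsageError
from .fcs import BeamGeometry, CorrelationCurve, FcsModel, Species, autocorrelation, diffusion_from_time

__all__ = ["FitResult", "ModelSelection", "fit_correlation", "compare_models", "bootstrap_uncertainty"]

_DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "D": (0.1, 1000.0),
    "occupancy": (1e-6, 1e4),
    "fraction": (0.0, 1.0),
}

_MIN_POINTS = {1: 8, 2: 12}


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit to one correlation curve."""

    model: FcsModel
    chi2: float
    chi2_red: float
    param_sd: Mapping[str, float]
    n_points: int
    n_free: int
    converged: bool
    weighted: bool
    curve_fingerprint: str

    @property
    def n_species(self) -> int:
        return len(self.model.species)

    def as_dict(self) -> dict:
        out = {
            "n_species": self.n_species,
            "occupancy": self.model.occupancy,
            "baseline": self.model.baseline,
            "chi2_red": self.chi2_red,
            "converged": self.converged,
        }
        for i, sp in enumerate(self.model.species, start=1):
            out[f"D{i}"] = sp.D_um2_s
            out[f"F{i}"] = sp.fraction
        out["param_sd"] = dict(self.param_sd)
        return out


@dataclass(frozen=True)
class ModelSelection:
    """Verdict of a nested one- vs two-species comparison."""

    n_species: int
    best: FitResult
    chi2_improvement: float
    reason: str


def _model_from_params(params: lmfit.Parameters, n_species: int) -> FcsModel:
    if n_species == 1:
        species = (Species(D_um2_s=params["d1"].value, fraction=1.0),)
    else:
        f1 = params["f1"].value
        species = (
            Species(D_um2_s=params["d1"].value, fraction=f1),
            Species(D_um2_s=params["d2"].value, fraction=1.0 - f1),
        )
    return FcsModel(species=species, occupancy=params["occupancy"].value, baseline=params["baseline"].value)


def _residual(params: lmfit.Parameters, curve: CorrelationCurve, beam: BeamGeometry, n_species: int, weights):
    model = _model_from_params(params, n_species)
    g_model = autocorrelation(model, beam, curve.lags_s)
    return (curve.g - g_model) * weights


def _guess_scales(curve: CorrelationCurve, beam: BeamGeometry) -> Tuple[float, float]:
    """Rough (occupancy, D) from curve amplitude and half-decay lag."""
    g0 = float(np.max(curve.g[: max(3, len(curve) // 8)]))
    occ = 1.0 / max(g0, 1e-6)
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau_half = float(curve.lags_s[below[0]]) if len(below) else float(curve.lags_s[-1])
    d_guess = diffusion_from_time(tau_half, beam)
    lo, hi = _DEFAULT_BOUNDS["D"]
    return occ, float(np.clip(d_guess, lo * 3.0, hi / 3.0))


def _make_params(
    n_species: int,
    occ: float,
    d_values: Tuple[float, ...],
    f1: float,
    baseline: float,
    fit_baseline: bool,
    bounds: Optional[Mapping[str, Tuple[float, float]]],
) -> lmfit.Parameters:
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    params = lmfit.Parameters()
    params.add("occupancy", value=float(np.clip(occ, *b["occupancy"])), min=b["occupancy"][0], max=b["occupancy"][1])
    params.add("baseline", value=baseline, vary=fit_baseline)
    for i, d in enumerate(d_values, start=1):
        params.add(f"d{i}", value=float(np.clip(d, *b["D"])), min=b["D"][0], max=b["D"][1])
    if n_species == 2:
        params.add("f1", value=float(np.clip(f1, *b["fraction"])), min=b["fraction"][0], max=b["fraction"][1])
    return params


def _sorted_result(
    best: lmfit.minimizer.MinimizerResult,
    n_species: int,
    curve: CorrelationCurve,
    weighted: bool,
) -> FitResult:
    params = best.params
    sd = {name: (p.stderr if p.stderr is not None else float("nan")) for name, p in params.items() if p.vary}
    model = _model_from_params(params, n_species)
    if n_species == 2 and model.species[0].D_um2_s < model.species[1].D_um2_s:
        # report the faster species first; swap fractions and stderr labels too
        s1, s2 = model.species
        model = FcsModel(
            species=(Species(s2.D_um2_s, s2.fraction), Species(s1.D_um2_s, s1.fraction)),
            occupancy=model.occupancy,
            baseline=model.baseline,
        )
        sd["d1"], sd["d2"] = sd.get("d2", float("nan")), sd.get("d1", float("nan"))
        if "f1" in sd:
            pass  # sd of f1 equals sd of (1 - f1); label now refers to the faster species
    n_free = best.nvarys
    chi2 = float(best.chisqr)
    dof = best.ndata - n_free
    if dof <= 0:
        raise UsageError("fit requires more points than free parameters")
    return FitResult(
        model=model,
        chi2=chi2,
        chi2_red=chi2 / dof,
        param_sd=sd,
        n_points=best.ndata,
        n_free=n_free,
        converged=bool(best.success),
        weighted=weighted,
        curve_fingerprint=curve.fingerprint(),
    )


def fit_correlation(
    curve: CorrelationCurve,
    n_species: int,
    beam: BeamGeometry,
    init: Optional[FcsModel] = None,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    fit_baseline: bool = False,
    _single_start: bool = False,
) -> FitResult:
    """Fit a one- or two-species diffusion model to a correlation curve.

    Minimizes Σ[(g_obs − g_model)/σ]² with σ = 1 when the curve carries no
    per-point uncertainties.  Returns a flagged (``converged=False``) result
    rather than raising if no start converges.
    """
    if n_species not in (1, 2):
        raise UsageError(f"n_species must be 1 or 2, got {n_species}")
    if len(curve) < _MIN_POINTS[n_species]:
        raise UsageError(
            f"{n_species}-species fit requires >= {_MIN_POINTS[n_species]} points, got {len(curve)}"
        )
    if float(np.ptp(curve.g)) <= 1e-14 * max(1.0, float(np.max(np.abs(curve.g)))):
        raise FitError("degenerate curve: g is constant, nothing to fit")

    weighted = curve.sigma is not None
    weights = 1.0 / curve.sigma if weighted else np.ones_like(curve.g)

    occ0, d0 = _guess_scales(curve, beam)
    starts: list[lmfit.Parameters] = []
    if init is not None:
        d_init = tuple(sp.D_um2_s for sp in init.species)
        if len(d_init) != n_species:
            raise UsageError("init model species count must match n_species")
        f1 = init.species[0].fraction if n_species == 2 else 1.0
        starts.append(_make_params(n_species, init.occupancy, d_init, f1, init.baseline, fit_baseline, bounds))
    if not (init is not None and _single_start):
        if n_species == 1:
            for scale in ((1.0,) if _single_start else (1.0, 0.3, 3.0)):
                starts.append(_make_params(1, occ0, (d0 * scale,), 1.0, 0.0, fit_baseline, bounds))
        else:
            # seed one start from the nested one-species optimum so the
            # two-species fit can never end above it
            base = fit_correlation(curve, 1, beam, bounds=bounds, fit_baseline=fit_baseline, _single_start=True)
            d1 = base.model.species[0].D_um2_s
            seeds = [(d1, d1, 0.5), (d1, d1 / 10.0, 0.97)]
            if not _single_start:
                seeds += [(d1 * 1.5, d1 / 3.0, 0.8), (d0, d0 / 20.0, 0.9)]
            for da, db, f1 in seeds:
                starts.append(_make_params(2, base.model.occupancy, (da, db), f1, 0.0, fit_baseline, bounds))

    best: Optional[lmfit.minimizer.MinimizerResult] = None
    for params in starts:
        try:
            res = lmfit.minimize(
                _residual,
                params,
                args=(curve, beam, n_species, weights),
                method="least_squares",
                nan_policy="raise",
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("all fit starts failed to evaluate")
    return _sorted_result(best, n_species, curve, weighted)


def compare_models(
    fit1: FitResult,
    fit2: FitResult,
    rel_improvement: float = 0.10,
    fraction_floor: float = 0.005,
) -> ModelSelection:
    """Select between nested one- and two-species fits of the same curve.

    The richer model wins only if the reduced χ² improves by more than
    ``rel_improvement`` (relative) *and* its minor amplitude fraction
    exceeds ``fraction_floor`` — otherwise parsimony keeps one species.
    """
    if fit1.n_species != 1 or fit2.n_species != 2:
        raise UsageError("compare_models expects (one-species fit, two-species fit)")
    if fit1.curve_fingerprint != fit2.curve_fingerprint:
        raise UsageError("fits were made on different curves")
    if fit1.chi2_red > 0:
        improvement = (fit1.chi2_red - fit2.chi2_red) / fit1.chi2_red
    else:
        improvement = 0.0
    minor = min(sp.fraction for sp in fit2.model.species)
    if improvement > rel_improvement and minor > fraction_floor:
        return ModelSelection(2, fit2, improvement, f"chi2_red improved {improvement:.1%}, minor fraction {minor:.2%}")
    if improvement <= rel_improvement:
        reason = f"chi2_red improvement {improvement:.1%} below threshold {rel_improvement:.0%}"
    else:
        reason = f"minor fraction {minor:.2%} below floor {fraction_floor:.1%}"
    return ModelSelection(1, fit1, improvement, reason)


def bootstrap_uncertainty(
    curve: CorrelationCurve,
    fit: FitResult,
    beam: BeamGeometry,
    n_boot: int = 500,
    seed: int = 0,
) -> Dict[str, Tuple[float, float]]:
    """Residual-resampling bootstrap confidence intervals (16th/84th percentiles).

    Residuals of the converged fit are resampled with replacement onto the
    fitted curve and each replicate is refitted from the original optimum.
    Deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise UsageError(f"n_boot must be >= 100, got {n_boot}")
    if not fit.converged:
        raise UsageError("bootstrap requires a converged fit")
    rng = np.random.default_rng(seed)
    g_fit = autocorrelation(fit.model, beam, curve.lags_s)
    residuals = curve.g - g_fit
    n = len(curve)
    samples: Dict[str, list] = {}
    for _ in range(n_boot):
        g_star = g_fit + rng.choice(residuals, size=n, replace=True)
        star = CorrelationCurve(lags_s=curve.lags_s, g=g_star, sigma=curve.sigma)
        try:
            refit = fit_correlation(star, fit.n_species, beam, init=fit.model, _single_start=True)
        except FitError:
            continue
        for key, value in refit.as_dict().items():
            if key in ("param_sd", "converged", "n_species"):
                continue
            samples.setdefault(key, []).append(value)
    return {
        key: (float(np.percentile(vals, 16)), float(np.percentile(vals, 84)))
        for key, vals in samples.items()
    }
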