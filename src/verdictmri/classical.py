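"""Conventional least-squares fitting of the ADC, IVIM and three-compartment
models, plus a Monte-Carlo random-walk oracle for the restricted-sphere signal.

The non-linear fits use a deterministic multi-start strategy: the sum of
squared residuals is evaluated on a fixed grid of starting points, and
bound-constrained ``scipy.optimize.least_squares`` refinement is run from the
best few grid points.  This keeps the fit deterministic (same data, same
config, same answer) while handling the multimodal loss surface in the cell
radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import models
from .models import AdcParams, IvimParams, TissueParams
from .scheme import AcquisitionScheme

__all__ = ["FitConfig", "FitResult", "McResult", "fit_nlls", "model_mse", "mc_sphere_oracle"]

# fitting bounds: ADC and tissue diffusivity in (0, 4] um^2/ms; IVIM
# pseudo-diffusivity in [4, 100] um^2/ms; fractions on [0, 1]; radius [0, 15] um
ADC_BOUNDS = (1e-6, 4.0)
IVIM_D_BOUNDS = (1e-6, 4.0)
IVIM_DSTAR_BOUNDS = (4.0, 100.0)
VERDICT_R_BOUNDS = (0.0, models.R_MAX)


@dataclass(frozen=True)
class FitConfig:
    """Multi-start configuration for :func:`fit_nlls`.

    grid_points: starts per free-parameter axis (the simplex grid for the
    fractions is pruned to f_ic + f_ees <= 1).  refine_top: how many of the
    best grid points are polished with least_squares.
    """

    grid_points: int = 5
    refine_top: int = 3
    xtol: float = 1e-12
    ftol: float = 1e-12
    max_nfev: int = 400


@dataclass(frozen=True)
class FitResult:
    model: str
    params: TissueParams | IvimParams | AdcParams
    predicted: np.ndarray
    mse: float
    n_starts: int


@dataclass(frozen=True)
class McResult:
    attenuation: float
    stderr: float
    n_walkers: int
    warnings: tuple[str, ...] = ()


def model_mse(predicted: np.ndarray, signals: np.ndarray) -> float:
    """Mean squared residual between a model prediction and observed signals."""
    predicted = np.asarray(predicted, float)
    signals = np.asarray(signals, float)
    if predicted.shape != signals.shape:
        raise ValueError(
            f"length mismatch: predicted {predicted.shape}, observed {signals.shape}"
        )
    return float(np.mean((predicted - signals) ** 2))


def _verdict_predict(theta: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Forward signal for raw optimiser coordinates (f_ic, f_ees, R).

    If the fractions leave the simplex they are renormalised proportionally,
    keeping the objective continuous; the same convention is used by the
    self-supervised fitter.
    """
    f_ic, f_ees, radius = theta
    s = f_ic + f_ees
    if s > 1.0:
        f_ic, f_ees = f_ic / s, f_ees / s
    p = TissueParams(f_ic=f_ic, f_ees=f_ees, radius=radius)
    return models.model_signal("verdict", p, scheme)


def _ivim_predict(theta: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    f, d_star, d = theta
    b = scheme.b_values * models.B_UNIT
    return f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d)


def _adc_predict(theta: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    return np.exp(-scheme.b_values * models.B_UNIT * theta[0])


_MODEL_TABLE = {
    "verdict": _verdict_predict,
    "ivim": _ivim_predict,
    "adc": _adc_predict,
}


def _start_grid(model: str, cfg: FitConfig) -> np.ndarray:
    g = cfg.grid_points
    if model == "adc":
        return np.linspace(0.2, 3.8, g)[:, None]
    if model == "ivim":
        fs = np.linspace(0.05, 0.95, g)
        dstars = np.linspace(5.0, 90.0, g)
        ds = np.linspace(0.2, 3.8, g)
        return np.array([(f, ds_, d) for f in fs for ds_ in dstars for d in ds])
    if model == "verdict":
        fr = np.linspace(0.05, 0.95, g)
        rs = np.linspace(1.0, 14.0, g)
        pts = [
            (fic, fees, r)
            for fic in fr
            for fees in fr
            if fic + fees <= 1.0
            for r in rs
        ]
        return np.array(pts)
    raise ValueError(f"unknown model {model!r}")


def _bounds(model: str) -> tuple[np.ndarray, np.ndarray]:
    if model == "adc":
        return np.array([ADC_BOUNDS[0]]), np.array([ADC_BOUNDS[1]])
    if model == "ivim":
        return (
            np.array([0.0, IVIM_DSTAR_BOUNDS[0], IVIM_D_BOUNDS[0]]),
            np.array([1.0, IVIM_DSTAR_BOUNDS[1], IVIM_D_BOUNDS[1]]),
        )
    # verdict
    return (
        np.array([0.0, 0.0, VERDICT_R_BOUNDS[0]]),
        np.array([1.0, 1.0, VERDICT_R_BOUNDS[1]]),
    )


def _pack_params(model: str, theta: np.ndarray):
    if model == "adc":
        return AdcParams(adc=float(theta[0]))
    if model == "ivim":
        f, d_star, d = (float(x) for x in theta)
        if d_star <= d:  # degenerate bi-exponential collapsed onto one rate
            d_star = max(d_star, d + 1e-9)
        return IvimParams(f=f, d_star=d_star, d=d)
    f_ic, f_ees, radius = (float(x) for x in theta)
    s = f_ic + f_ees
    if s > 1.0:
        f_ic, f_ees = f_ic / s, f_ees / s
    return TissueParams(f_ic=f_ic, f_ees=f_ees, radius=radius)


def fit_nlls(
    model: str,
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
) -> FitResult:
    """Bound-constrained multi-start least squares for one signal vector.

    ``signals`` holds one normalised value per scheme combo.  The lowest-loss
    start wins; ties break on the lowest start index so the fit is
    reproducible.
    """
    cfg = config or FitConfig()
    name = model.lower()
    if name not in _MODEL_TABLE:
        raise ValueError(f"unknown model {model!r}")
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (scheme.n_combos,):
        raise ValueError(
            f"signals must have one value per combo ({scheme.n_combos}), "
            f"got shape {signals.shape}"
        )
    if not np.all(np.isfinite(signals)) or np.any(signals <= 0):
        raise ValueError("signals must be finite and positive")

    predict = _MODEL_TABLE[name]
    grid = _start_grid(name, cfg)
    lo, hi = _bounds(name)

    sse = np.array(
        [np.sum((predict(theta, scheme) - signals) ** 2) for theta in grid]
    )
    order = np.argsort(sse, kind="stable")[: cfg.refine_top]

    best_theta, best_loss = None, np.inf
    failures: list[str] = []
    for idx in order:
        theta0 = np.clip(grid[idx], lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                lambda th: predict(th, scheme) - signals,
                theta0,
                bounds=(lo, hi),
                xtol=cfg.xtol,
                ftol=cfg.ftol,
                max_nfev=cfg.max_nfev,
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            failures.append(f"start {idx}: {exc}")
            continue
        loss = float(np.sum(res.fun**2))
        if loss < best_loss - 1e-15:
            best_loss, best_theta = loss, res.x
    if best_theta is None:
        raise RuntimeError(f"all starts failed for {name}: {failures}")

    params = _pack_params(name, best_theta)
    predicted = models.model_signal(name, params, scheme)
    return FitResult(
        model=name,
        params=params,
        predicted=predicted,
        mse=model_mse(predicted, signals),
        n_starts=len(grid),
    )


def mc_sphere_oracle(
    radius: float,
    d: float,
    b: float,
    delta: float,
    Delta: float,
    n_walkers: int = 100_000,
    dt: float = 0.02,
    seed: int = 0,
) -> McResult:
    """Random-walk-in-a-sphere estimate of the PGSE attenuation.

    Walkers start uniformly inside an impermeable sphere (radius um), take
    Gaussian steps (diffusivity d um^2/ms, time step dt ms) with radial
    specular reflection at the boundary, and accumulate phase under the two
    rectangular gradient lobes (duration delta, separation Delta, ms).  The
    attenuation estimate is |mean exp(i phase)| with its standard error.

    Independent of the closed-form GPD implementation; used as its oracle.
    """
    if n_walkers < 10_000:
        raise ValueError("n_walkers must be >= 1e4 for a usable estimate")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not delta < Delta:
        raise ValueError("PGSE timing requires delta < Delta")
    warnings: list[str] = []
    step = np.sqrt(2.0 * d * dt)
    if d > 0 and step > 0.35 * radius:
        warnings.append(
            f"step size {step:.3g} um is coarse relative to radius {radius} um"
        )

    rng = np.random.default_rng(seed)
    # gamma*g in 1/(um ms), from b = (gamma g)^2 delta^2 (Delta - delta/3)
    gam_g = np.sqrt(b * models.B_UNIT / (delta**2 * (Delta - delta / 3.0)))

    pos = rng.normal(size=(n_walkers, 3))
    pos *= (radius * rng.random(n_walkers) ** (1.0 / 3.0))[:, None] / np.linalg.norm(
        pos, axis=1
    )[:, None]
    phase = np.zeros(n_walkers)
    n_steps = int(round((Delta + delta) / dt))
    sigma = np.sqrt(2.0 * d * dt)
    for i in range(n_steps):
        t = i * dt
        if t < delta:
            lobe = 1.0
        elif t >= Delta:
            lobe = -1.0
        else:
            lobe = 0.0
        if d > 0:
            pos += rng.normal(size=(n_walkers, 3)) * sigma
            r = np.linalg.norm(pos, axis=1)
            outside = r > radius
            if outside.any():
                pos[outside] *= ((2.0 * radius - r[outside]) / r[outside])[:, None]
        if lobe:
            phase += lobe * gam_g * pos[:, 2] * dt

    cosphi = np.cos(phase)
    est = float(np.abs(np.mean(np.exp(1j * phase))))
    stderr = float(np.std(cosphi, ddof=1) / np.sqrt(n_walkers))
    return McResult(
        attenuation=est, stderr=stderr, n_walkers=n_walkers, warnings=tuple(warnings)
    )
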