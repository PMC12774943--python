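"""Closed-form compartment signals and composite diffusion models.

The three-compartment kidney model decomposes the normalised PGSE signal into

    S = f_VASC * S_VASC(d_VASC, b) + f_IC * S_IC(d_IC, R, b, Delta, delta)
        + f_EES * S_EES(d_EES, b)

with volume fractions summing to one and f_VASC derived as 1 - f_IC - f_EES.
The intracellular compartment is an impermeable sphere of radius R (Gaussian
phase distribution / Murday-Cotts attenuation), the vascular compartment is
randomly-oriented sticks with a high pseudo-diffusivity (spherical mean), and
the extracellular-extravascular space is an isotropic Gaussian ball.  Fixed
diffusivities: d_IC = d_EES = 2 um^2/ms, d_VASC = 50 um^2/ms.

Mono-exponential (ADC) and bi-exponential (IVIM) models are provided as
baselines on the same scheme interface.

Units at the interface: b in s/mm^2, times in ms, diffusivities in um^2/ms,
radii in um.  Internally b is converted with 1 s/mm^2 = 1e-3 ms/um^2 so that
b*d is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, spherical_jn

from .scheme import AcquisitionScheme

__all__ = [
    "TissueParams",
    "AdcParams",
    "IvimParams",
    "ModelConstants",
    "DEFAULT_CONSTANTS",
    "signal_sphere_gpd",
    "signal_astrosticks",
    "signal_ball",
    "model_signal",
    "sphere_attenuation",
]

# b-value unit conversion: 1 s/mm^2 = 1e-3 ms/um^2
B_UNIT = 1.0e-3

D_IC = 2.0  # um^2/ms, fixed intracellular diffusivity
D_EES = 2.0  # um^2/ms, fixed extracellular-extravascular diffusivity
D_VASC = 50.0  # um^2/ms, fixed vascular pseudo-diffusivity
R_MAX = 15.0  # um, upper clamp for cell radius

GAMMA = 2.675e8  # rad s^-1 T^-1, proton gyromagnetic ratio


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants and numerical controls shared by the models."""

    gamma: float = GAMMA  # rad s^-1 T^-1
    n_gpd_roots: int = 40  # Bessel-derivative roots kept in the GPD sum

    def __post_init__(self) -> None:
        if self.n_gpd_roots < 20:
            raise ValueError("n_gpd_roots must be >= 20 for convergence")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class TissueParams:
    """Three-compartment tissue parameters.

    f_ic, f_ees : signal volume fractions in [0, 1]; f_vasc = 1 - f_ic - f_ees.
    radius : cell radius in um, in [0, 15].
    """

    f_ic: float
    f_ees: float
    radius: float
    d_ic: float = D_IC
    d_ees: float = D_EES
    d_vasc: float = D_VASC

    def __post_init__(self) -> None:
        for name, f in (("f_ic", self.f_ic), ("f_ees", self.f_ees)):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if self.f_ic + self.f_ees > 1.0 + 1e-12:
            raise ValueError(
                f"f_ic + f_ees must be <= 1, got {self.f_ic + self.f_ees}"
            )
        if not (0.0 <= self.radius <= R_MAX):
            raise ValueError(f"radius must be in [0, {R_MAX}] um, got {self.radius}")

    @property
    def f_vasc(self) -> float:
        return max(0.0, 1.0 - self.f_ic - self.f_ees)


@dataclass(frozen=True)
class AdcParams:
    """Mono-exponential decay with apparent diffusion coefficient in um^2/ms."""

    adc: float

    def __post_init__(self) -> None:
        if self.adc <= 0:
            raise ValueError(f"adc must be > 0, got {self.adc}")


@dataclass(frozen=True)
class IvimParams:
    """Bi-exponential intravoxel-incoherent-motion parameters.

    f : perfusion fraction in [0, 1]; d_star > d, both in um^2/ms.
    """

    f: float
    d_star: float
    d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f must be in [0, 1], got {self.f}")
        if self.d <= 0 or self.d_star <= 0:
            raise ValueError("diffusivities must be > 0")
        if self.d_star <= self.d:
            raise ValueError(f"d_star must exceed d, got {self.d_star} <= {self.d}")


@lru_cache(maxsize=8)
def _gpd_roots(n: int) -> np.ndarray:
    """First n positive roots of d/dx j1(x) = 0 (j1: spherical Bessel, order 1).

    These are the radial eigenvalues mu_m of restricted diffusion in an
    impermeable sphere; alpha_m = mu_m / R.
    """

    def f(x: float) -> float:
        return spherical_jn(1, x, derivative=True)

    roots: list[float] = []
    # roots are ~pi apart starting near 2.08; scan sign changes on a fine grid
    xs = np.arange(1e-3, (n + 2) * np.pi, 1e-2)
    vals = f(xs)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    for i in sign_change:
        r = brentq(f, xs[i], xs[i + 1], xtol=1e-14)
        if r > 1e-6:
            roots.append(r)
        if len(roots) == n:
            break
    if len(roots) < n:
        raise RuntimeError(f"found only {len(roots)} GPD roots, needed {n}")
    return np.asarray(roots)


def sphere_attenuation(
    radius,
    d: float,
    b,
    delta,
    Delta,
    n_roots: int = DEFAULT_CONSTANTS.n_gpd_roots,
) -> np.ndarray:
    """Vectorised GPD sphere attenuation.

    Broadcasts over `radius` (any shape) against per-measurement arrays
    b / delta / Delta (shape (M,)).  Returns shape radius.shape + (M,).
    Units: radius um, d um^2/ms, b s/mm^2, times ms.
    """
    radius = np.asarray(radius, dtype=float)
    b = np.atleast_1d(np.asarray(b, dtype=float))
    delta = np.broadcast_to(np.asarray(delta, dtype=float), b.shape)
    Delta = np.broadcast_to(np.asarray(Delta, dtype=float), b.shape)
    if np.any(radius < 0):
        raise ValueError("radius must be >= 0")
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if d < 0:
        raise ValueError("diffusivity must be >= 0")
    if np.any(delta >= Delta):
        raise ValueError("PGSE timing requires delta < Delta")

    mu = _gpd_roots(n_roots)  # (n_roots,)
    out_shape = radius.shape + b.shape
    R = radius.reshape(radius.shape + (1, 1))  # (..., 1, 1)
    mu2 = (mu**2).reshape((1,) * radius.ndim + (1, -1))  # (..., 1, n_roots)
    dl = delta.reshape((1,) * radius.ndim + (-1, 1))  # (..., M, 1)
    DL = Delta.reshape((1,) * radius.ndim + (-1, 1))
    b_ms = (b * B_UNIT).reshape((1,) * radius.ndim + (-1, 1))

    # gamma^2 g^2 in (um^2 ms^2)^-1, recovered from b = gamma^2 g^2 delta^2 (Delta - delta/3)
    g2gam2 = b_ms / (dl**2 * (DL - dl / 3.0))

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        lam = d * mu2 / R**2  # 1/ms; inf at R=0 handled below
        num = (
            2.0 * lam * dl
            - 2.0
            + 2.0 * np.exp(-lam * dl)
            + 2.0 * np.exp(-lam * DL)
            - np.exp(-lam * (DL - dl))
            - np.exp(-lam * (DL + dl))
        )
        # sum_m num_m * R^6 / (d^2 mu^6 (mu^2 - 2))
        terms = num * R**6 / (d**2 * mu2**3 * (mu2 - 2.0))
        log_s = np.sum(-2.0 * g2gam2 * terms, axis=-1)  # (..., M)

    log_s = np.where(np.isfinite(log_s), log_s, 0.0)
    # degenerate limits: R=0 (point), d=0 (frozen spins), b=0 -> no attenuation
    zero_b = np.broadcast_to((b == 0.0), out_shape)
    zero_R = np.broadcast_to((radius == 0.0).reshape(radius.shape + (1,)), out_shape)
    s = np.exp(log_s)
    s = np.where(zero_b | zero_R | (d == 0.0), 1.0, s)
    return s


def signal_sphere_gpd(
    radius: float,
    d: float,
    b: float,
    delta: float,
    Delta: float,
    n_roots: int = DEFAULT_CONSTANTS.n_gpd_roots,
) -> float:
    """PGSE attenuation of water restricted in an impermeable sphere.

    Gaussian-phase-distribution (Murday-Cotts) closed form: the log-signal is a
    sum over the radial eigenmodes mu_m (roots of j1'(x) = 0),

        ln S = -2 g^2 gamma^2 sum_m
               [2 d a_m^2 delta - 2 + 2 e^{-d a_m^2 delta} + 2 e^{-d a_m^2 Delta}
                - e^{-d a_m^2 (Delta-delta)} - e^{-d a_m^2 (Delta+delta)}]
               / [d^2 a_m^6 (a_m^2 R^2 - 2)],   a_m = mu_m / R,

    which recovers free Gaussian diffusion exp(-b d) as R grows large and is
    cross-checked against a random-walk Monte-Carlo oracle in the test suite.

    with the gradient amplitude recovered from b = gamma^2 g^2 delta^2 (Delta - delta/3).

    Parameters: radius um, d um^2/ms, b s/mm^2, delta/Delta ms.
    """
    if b == 0:
        return 1.0
    s = sphere_attenuation(np.asarray(radius, float), d, b, delta, Delta, n_roots)
    return float(s.reshape(-1)[0])


def signal_astrosticks(b, d: float) -> np.ndarray | float:
    """Spherical-mean attenuation of randomly-oriented sticks.

    S = sqrt(pi) * erf(sqrt(b d)) / (2 sqrt(b d)); equals the orientation
    average of exp(-b d cos^2 theta).  A series expansion is used for small
    b*d so that b=0 returns exactly 1.  b in s/mm^2, d in um^2/ms.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b must be >= 0")
    if d <= 0:
        raise ValueError("d must be > 0")
    x = b_arr * B_UNIT * d
    small = x < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = np.sqrt(np.where(small, 1.0, x))
        exact = np.sqrt(np.pi) * erf(sx) / (2.0 * sx)
    series = 1.0 - x / 3.0 + x**2 / 10.0
    out = np.where(small, series, exact)
    return out if np.ndim(b) else float(out)


def signal_ball(b, d: float) -> np.ndarray | float:
    """Isotropic Gaussian diffusion: S = exp(-b d).  b s/mm^2, d um^2/ms."""
    b_arr = np.asarray(b, dtype=float)
    out = np.exp(-b_arr * B_UNIT * d)
    return out if np.ndim(b) else float(out)


def _verdict_signal(
    params: TissueParams, scheme: AcquisitionScheme, n_roots: int
) -> np.ndarray:
    s_ic = sphere_attenuation(
        np.asarray(params.radius, float),
        params.d_ic,
        scheme.b_values,
        scheme.deltas,
        scheme.Deltas,
        n_roots,
    ).reshape(-1)
    s_ees = signal_ball(scheme.b_values, params.d_ees)
    s_vasc = signal_astrosticks(scheme.b_values, params.d_vasc)
    return (
        params.f_vasc * s_vasc + params.f_ic * s_ic + params.f_ees * s_ees
    )


def model_signal(
    model: str,
    params: TissueParams | AdcParams | IvimParams,
    scheme: AcquisitionScheme,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Normalised model signal, one value per scheme combo.

    model is one of "verdict", "ivim", "adc" (case-insensitive); params must be
    the matching parameter dataclass.
    """
    name = model.lower()
    b = scheme.b_values
    if name == "verdict":
        if not isinstance(params, TissueParams):
            raise TypeError("verdict model requires TissueParams")
        return _verdict_signal(params, scheme, constants.n_gpd_roots)
    if name == "ivim":
        if not isinstance(params, IvimParams):
            raise TypeError("ivim model requires IvimParams")
        return params.f * np.exp(-b * B_UNIT * params.d_star) + (
            1.0 - params.f
        ) * np.exp(-b * B_UNIT * params.d)
    if name == "adc":
        if not isinstance(params, AdcParams):
            raise TypeError("adc model requires AdcParams")
        return np.exp(-b * B_UNIT * params.adc)
    raise ValueError(f"unknown model {model!r}; expected verdict, ivim or adc")
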