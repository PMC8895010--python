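"""Diffusion coefficients from pulsed-field-gradient NMR and Stokes–Einstein scaling.

In a diffusion-ordered (DOSY) experiment the spin-echo amplitude decays
with gradient strength ``g`` following the Stejskal–Tanner relation

    I(g) = I₀ · exp( −D · γ² g² δ² (Δ − δ/3) )

with gyromagnetic ratio γ, gradient pulse length δ and diffusion delay Δ.
The fitted self-diffusion coefficient maps to a hydrodynamic radius via
Stokes–Einstein, ``D = k_B·T / (6πη·r_H)``, so diffusion coefficients of
species in the same solution scale inversely with their radii — which is
how a dimer's D is obtained from the monomer's without a separate
measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import lmfit
import numpy as np

from .constants import K_B
from .errors import FitFailureError, InvalidArgumentError

logger = logging.getLogger(__name__)

#: ¹H gyromagnetic ratio [rad s⁻¹ T⁻¹], the default DOSY nucleus.
GAMMA_1H = 2.6752218744e8


@dataclass(frozen=True)
class DosyExperiment:
    """One pulsed-field-gradient attenuation series."""

    gradient_strengths: np.ndarray  # [T m⁻¹], nonnegative increasing
    intensities: np.ndarray  # arbitrary units, positive
    gamma: float = GAMMA_1H  # [rad s⁻¹ T⁻¹]
    delta_little: float = 4e-3  # gradient pulse duration δ [s]
    delta_big: float = 0.1  # diffusion delay Δ [s]

    def __post_init__(self):
        g = np.asarray(self.gradient_strengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "gradient_strengths", g)
        object.__setattr__(self, "intensities", i)
        if g.ndim != 1 or i.shape != g.shape:
            raise InvalidArgumentError("gradients and intensities must be 1-D, equal length")
        if not np.all(i > 0):
            raise InvalidArgumentError("intensities must be positive")
        if np.any(g < 0) or not np.all(np.diff(g) > 0):
            raise InvalidArgumentError("gradients must be nonnegative and increasing")
        if self.delta_big <= self.delta_little / 3.0:
            raise InvalidArgumentError("require Δ > δ/3 for a positive diffusion exponent")

    @property
    def b_values(self) -> np.ndarray:
        """Diffusion weighting γ²g²δ²(Δ − δ/3) [s m⁻²] at each gradient."""
        return (self.gamma**2 * self.gradient_strengths**2 * self.delta_little**2
                * (self.delta_big - self.delta_little / 3.0))


@dataclass(frozen=True)
class DosyFit:
    """Fitted Stejskal–Tanner decay."""

    D: float  # [m² s⁻¹]
    D_stderr: float | None
    I0: float
    residuals: np.ndarray
    r_squared: float


@dataclass(frozen=True)
class DiffusionParams:
    """Monomer/dimer transport bundle with Stokes–Einstein consistency.

    ``D·r`` is the same for every species in one solution at one
    temperature (it equals ``k_B·T/6πη``); construction enforces
    ``D1·r1 == D2·r2`` to 1e-9 relative.
    """

    D1: float  # [m² s⁻¹]
    D2: float
    r1: float  # [m]
    r2: float
    T: float = 298.15  # [K]
    eta: float = 5.44e-4  # [Pa s]

    def __post_init__(self):
        for name in ("D1", "D2", "r1", "r2", "T", "eta"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        lhs, rhs = self.D1 * self.r1, self.D2 * self.r2
        if abs(lhs - rhs) > 1e-9 * max(lhs, rhs):
            raise InvalidArgumentError(
                "Stokes–Einstein inconsistency: D1·r1 != D2·r2 "
                f"({lhs:.6e} vs {rhs:.6e})"
            )

    @classmethod
    def from_monomer(cls, D1: float, r1: float, r2: float, T: float = 298.15,
                     eta: float = 5.44e-4) -> "DiffusionParams":
        """Build the bundle from monomer data, deriving D2 by inverse-radius scaling."""
        return cls(D1=D1, D2=scale_diffusion(D1, r1, r2), r1=r1, r2=r2, T=T, eta=eta)


def fit_dosy(experiment: DosyExperiment) -> DosyFit:
    """Fit the single-exponential Stejskal–Tanner decay, returning D and its error.

    A log-linear regression of intensity against the diffusion weighting
    seeds a nonlinear least-squares refinement of (I₀, D); this makes the
    fit exact on noiseless data and robust to the multiplicative noise of
    real attenuation curves.  D is constrained positive; data whose
    best-fit D pins at the bound raise :class:`FitFailureError`.
    """
    if len(experiment.gradient_strengths) < 5:
        raise InvalidArgumentError("need at least 5 gradient points")
    if experiment.gradient_strengths[0] != 0.0:
        raise InvalidArgumentError("attenuation series must include a g = 0 point")
    b = experiment.b_values
    y = experiment.intensities
    # Seed from the log-linear form: ln I = ln I0 − D·b.
    slope, intercept = np.polyfit(b, np.log(y), 1)
    d0 = max(-slope, 1e-16)

    params = lmfit.Parameters()
    params.add("I0", value=float(np.exp(intercept)), min=0.0)
    params.add("D", value=float(d0), min=0.0)

    def residuals(p):
        return p["I0"].value * np.exp(-p["D"].value * b) - y

    result = lmfit.minimize(residuals, params, method="leastsq")
    if not result.success:
        raise FitFailureError("DOSY fit did not converge", best_result=result)
    d = result.params["D"].value
    if d <= 0 or (slope > 0 and d < 1e-15):
        raise FitFailureError("fitted D pinned at zero: gross non-monotone data",
                              best_result=result)
    res = residuals(result.params)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res**2)) / tss if tss > 0 else 1.0
    logger.info("DOSY fit: D=%.4g m² s⁻¹ (R²=%.5f, %d gradients)",
                d, r2, len(b))
    return DosyFit(D=float(d), D_stderr=result.params["D"].stderr,
                   I0=float(result.params["I0"].value), residuals=res, r_squared=r2)


def stokes_einstein_radius(D: float, T: float, eta: float) -> float:
    """Hydrodynamic radius r_H = k_B·T/(6πη·D) [m]."""
    if D <= 0 or T <= 0 or eta <= 0:
        raise InvalidArgumentError("D, T and eta must be positive")
    return K_B * T / (6.0 * np.pi * eta * D)


def stokes_einstein_diffusion(r_H: float, T: float, eta: float) -> float:
    """Diffusion coefficient D = k_B·T/(6πη·r_H) [m² s⁻¹] (inverse of the above)."""
    if r_H <= 0 or T <= 0 or eta <= 0:
        raise InvalidArgumentError("r_H, T and eta must be positive")
    return K_B * T / (6.0 * np.pi * eta * r_H)


def scale_diffusion(D_ref: float, r_ref: float, r_target: float) -> float:
    """Transfer a diffusion coefficient between species: D_target = D_ref·r_ref/r_target."""
    if D_ref <= 0 or r_ref <= 0 or r_target <= 0:
        raise InvalidArgumentError("all arguments must be positive")
    return D_ref * r_ref / r_target
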