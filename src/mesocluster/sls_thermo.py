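"""Static-light-scattering thermodynamics.

A Debye plot records ``Kc/R_θ`` — optical constant × mass concentration
over the Rayleigh ratio — as a function of solute mass concentration ``c``.
For an ideal-to-moderately-nonideal solution this ratio equals the inverse
osmotic compressibility ``(1/RT) ∂Π/∂c`` and expands in the osmotic virial
series::

    Kc/R_θ = 1/Mw + 2·A2·c + 3·A3·c²

with apparent molar mass ``Mw`` and second/third virial coefficients
``A2``/``A3``.  Integrating the per-molecule chemical potential increment
``dμ = dΠ/ρ_N`` (``ρ_N = c·N_A/M`` the solute number density) between two
concentrations gives the excess free energy per molecule::

    Δg(c_L → c_H) = (M·R·T/N_A) ∫ (Kc/R_θ)(c)/c dc
                  = (M·R·T/N_A) [ (1/Mw)·ln(c_H/c_L) + 2A2(c_H−c_L)
                                  + (3/2)A3(c_H²−c_L²) ]

which is the quantity that decides whether inserting one more monomer into
a dense region is thermodynamically costly.

Unit conventions
----------------
Concentrations are held internally in g ml⁻¹; ``Kc/R_θ`` in mol g⁻¹;
``A2`` in mol ml g⁻²; ``A3`` in mol ml² g⁻³; Δg in J per molecule (with a
k_BT-scaled companion).  The optical constant is returned in
mol ml² g⁻² m⁻⁴ · m⁴ bookkeeping, i.e. computed directly from inputs in
(ml g⁻¹, m) without hidden rescaling — only ratios of K enter the fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .constants import GAS_CONSTANT, N_A, K_B
from .errors import DegenerateDataError, InvalidArgumentError, UnderdeterminedFitError

logger = logging.getLogger(__name__)

_MASS_UNITS = {"mg/ml": 1e-3, "g/ml": 1.0}
_SUPPORTED_UNITS = set(_MASS_UNITS) | {"M"}


@dataclass(frozen=True)
class ConcentrationSeries:
    """Paired (concentration, observable) measurements with declared units.

    Parameters
    ----------
    concentration
        Strictly positive, strictly increasing concentrations in ``unit``.
    value
        Observable at each concentration (``Kc/R_θ`` in mol g⁻¹ for SLS,
        chemical shift in ppm for NMR dilution series).
    unit
        One of ``"mg/ml"``, ``"g/ml"`` (mass) or ``"M"`` (molar).
    sigma
        Optional per-point 1-σ uncertainty of ``value``.
    temperature
        Measurement temperature [K].
    label
        Free-text tag (e.g. a carbon assignment for NMR series).
    """

    concentration: np.ndarray
    value: np.ndarray
    unit: str = "mg/ml"
    sigma: np.ndarray | None = None
    temperature: float = 298.15
    label: str = ""

    def __post_init__(self):
        conc = np.asarray(self.concentration, dtype=float)
        val = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "concentration", conc)
        object.__setattr__(self, "value", val)
        if self.unit not in _SUPPORTED_UNITS:
            raise InvalidArgumentError(
                f"unsupported concentration unit {self.unit!r}; "
                f"expected one of {sorted(_SUPPORTED_UNITS)}"
            )
        if conc.ndim != 1 or val.shape != conc.shape:
            raise InvalidArgumentError("concentration and value must be 1-D and equal length")
        if not np.all(conc > 0):
            raise InvalidArgumentError("concentrations must be strictly positive")
        if not np.all(np.diff(conc) > 0):
            raise InvalidArgumentError("concentrations must be strictly increasing")
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            if sig.shape != conc.shape or not np.all(sig > 0):
                raise InvalidArgumentError("sigma must match length and be positive")
            object.__setattr__(self, "sigma", sig)
        if self.temperature <= 0:
            raise InvalidArgumentError("temperature must be positive [K]")

    def __len__(self) -> int:
        return len(self.concentration)

    @property
    def conc_g_per_ml(self) -> np.ndarray:
        """Concentrations converted to g ml⁻¹ (mass units only)."""
        if self.unit not in _MASS_UNITS:
            raise InvalidArgumentError(
                f"cannot convert unit {self.unit!r} to g/ml without a molar mass"
            )
        return self.concentration * _MASS_UNITS[self.unit]

    def to_molar(self, molar_mass: float) -> np.ndarray:
        """Concentrations in mol l⁻¹, given the solute molar mass [g mol⁻¹]."""
        if self.unit == "M":
            return self.concentration.copy()
        # g/ml -> g/l -> mol/l
        return self.conc_g_per_ml * 1e3 / molar_mass


@dataclass(frozen=True)
class VirialFit:
    """Result of fitting the osmotic virial expansion to Debye-plot data."""

    Mw_app: float  # apparent molar mass [g mol⁻¹]
    A2: float  # second virial coefficient [mol ml g⁻²]
    A3: float  # third virial coefficient [mol ml² g⁻³]
    covariance: np.ndarray  # over (Mw_app, A2, A3)
    fit_rss: float
    order: int = 3
    temperature: float = 298.15
    conc_range: tuple[float, float] = (0.0, np.inf)  # fitted range [g ml⁻¹]

    def __post_init__(self):
        if self.Mw_app <= 0:
            raise InvalidArgumentError("apparent molar mass must be positive")
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-12 * (1 + np.abs(cov).max())):
            raise InvalidArgumentError("covariance must be symmetric")
        object.__setattr__(self, "covariance", cov)

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        """``Kc/R_θ`` [mol g⁻¹] predicted at mass concentration ``c`` [g ml⁻¹]."""
        c = np.asarray(c, dtype=float)
        return 1.0 / self.Mw_app + 2.0 * self.A2 * c + 3.0 * self.A3 * c**2

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


@dataclass(frozen=True)
class FreeEnergyCurve:
    """Per-molecule excess free energy Δg(c) relative to a reference concentration."""

    c_grid: np.ndarray  # [g ml⁻¹]
    dg: np.ndarray  # [J per molecule]
    dg_kBT: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference_c: float = 0.0
    temperature: float = 298.15

    def __post_init__(self):
        if not np.all(np.isfinite(self.dg)):
            raise InvalidArgumentError("Δg must be finite on the grid")


def optical_constant(n_solvent: float, dndc: float, wavelength: float) -> float:
    """Optical constant ``K = 4π²·n²·(dn/dc)²/(N_A·λ⁴)`` of a scattering setup.

    Parameters are the solvent refractive index (dimensionless), the
    refractive-index increment in ml g⁻¹ and the vacuum wavelength in m.
    ``K`` scales as ``(dn/dc)²`` and ``λ⁻⁴``; its absolute unit convention
    (mol ml² g⁻² m⁻⁴) cancels in any ``Kc/R_θ`` analysis.
    """
    if n_solvent <= 0 or dndc <= 0 or wavelength <= 0:
        raise InvalidArgumentError("optical_constant arguments must be positive")
    return 4.0 * np.pi**2 * n_solvent**2 * dndc**2 / (N_A * wavelength**4)


def _weighted_lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray, absolute_sigma: bool):
    """Solve min ||sqrt(w)(Xθ − y)||²; return θ, covariance, rss, cond.

    With ``absolute_sigma`` the weights are 1/σ² of known uncertainties and
    (XᵀWX)⁻¹ is the parameter covariance directly; otherwise it is scaled
    by the residual variance, as in unweighted ordinary least squares.
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    cond = np.linalg.cond(Xw)
    if cond > 1e12:
        raise DegenerateDataError(f"singular design matrix (condition number {cond:.3g})")
    theta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDataError("rank-deficient design matrix")
    resid = y - X @ theta
    rss = float(np.sum(w * resid**2))
    dof = max(len(y) - X.shape[1], 1)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    cov = XtX_inv if absolute_sigma else XtX_inv * (rss / dof)
    return theta, cov, rss, cond


def fit_virial(series: ConcentrationSeries, order: int = 3, auto_fallback: bool = True) -> VirialFit:
    """Weighted least-squares fit of the osmotic virial expansion.

    ``order=2`` fits (1/Mw, A2); ``order=3`` additionally fits A3.  With
    ``auto_fallback`` (default) an order-3 request falls back to order 2
    when an F-test cannot distinguish the cubic term from zero at the 5%
    level, which guards against overfitting shallow Debye plots.
    """
    if order not in (2, 3):
        raise InvalidArgumentError("order must be 2 or 3")
    c = series.conc_g_per_ml
    y = series.value
    n = len(c)
    if n < order + 2:
        raise UnderdeterminedFitError(
            f"need at least {order + 2} points for an order-{order} fit, got {n}"
        )
    absolute_sigma = series.sigma is not None
    w = 1.0 / series.sigma**2 if absolute_sigma else np.ones(n)

    def _fit(k: int):
        cols = [np.ones(n), 2.0 * c]
        if k == 3:
            cols.append(3.0 * c**2)
        X = np.column_stack(cols)
        return X, *_weighted_lstsq(X, y, w, absolute_sigma)

    X, theta, cov_lin, rss, cond = _fit(order)
    chosen = order
    if order == 3 and auto_fallback:
        _, theta2, cov2, rss2, _ = _fit(2)
        scale = max(np.sum(w * y**2), 1e-300)
        if rss <= 1e-24 * scale:
            # Numerically exact fit at both orders → keep the simpler model
            # unless the cubic term is genuinely needed.
            significant = rss2 > 1e-20 * scale
        else:
            f_stat = (rss2 - rss) / (rss / (n - 3))
            p = stats.f.sf(max(f_stat, 0.0), 1, n - 3)
            significant = p < 0.05
        if not significant:
            theta, cov_lin, rss, chosen = theta2, cov2, rss2, 2

    inv_mw, a2 = theta[0], theta[1]
    a3 = theta[2] if chosen == 3 else 0.0
    if inv_mw <= 0:
        raise DegenerateDataError("fitted 1/Mw is non-positive; data inconsistent with model")
    mw = 1.0 / inv_mw
    # Delta method: var(Mw) = Mw⁴ var(1/Mw); cross terms scaled by −Mw².
    J = np.zeros((3, len(theta)))
    J[0, 0] = -(mw**2)
    J[1, 1] = 1.0
    if chosen == 3:
        J[2, 2] = 1.0
    cov = J @ cov_lin @ J.T
    cov = 0.5 * (cov + cov.T)

    fit = VirialFit(
        Mw_app=mw, A2=float(a2), A3=float(a3), covariance=cov, fit_rss=rss,
        order=chosen, temperature=series.temperature,
        conc_range=(float(c[0]), float(c[-1])),
    )
    logger.info(
        "virial fit: n=%d order=%d Mw=%.6g±%.2g A2=%.6g±%.2g A3=%.6g cond=%.3g",
        n, chosen, mw, fit.standard_errors[0], a2, fit.standard_errors[1], a3, cond,
    )
    return fit


def osmotic_pressure_derivative(fit: VirialFit, c: float | np.ndarray) -> np.ndarray | float:
    """``∂Π/∂c = RT·(Kc/R_θ)(c)`` with Π in J ml⁻¹ and c in g ml⁻¹.

    Multiply by 10⁶ for Π in Pa per (g ml⁻¹).  Values outside the fitted
    concentration range are extrapolations of the virial series and are
    flagged at WARNING level rather than rejected.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise InvalidArgumentError("concentration must be positive")
    lo, hi = fit.conc_range
    if np.any(c_arr < lo) or np.any(c_arr > hi):
        logger.warning("osmotic_pressure_derivative: extrapolating beyond fitted range")
    out = GAS_CONSTANT * fit.temperature * fit.predict(c_arr)
    return out if np.ndim(c) else float(out)


def free_energy_excess(
    fit: VirialFit,
    c_low: float,
    c_high: float,
    molar_mass: float,
    temperature: float | None = None,
    method: str = "closed_form",
) -> float:
    """Excess free energy per molecule Δg between two mass concentrations [J].

    ``method="closed_form"`` evaluates the analytic integral of the virial
    series; ``method="quad"`` integrates ``(Kc/R_θ)(c)/c`` numerically —
    the two agree to ~1e-10 relative and the quadrature path exists as an
    internal cross-check for user-supplied fits.
    """
    if molar_mass <= 0:
        raise InvalidArgumentError("molar mass must be positive")
    if c_low <= 0:
        raise InvalidArgumentError("c_low must be positive (integral diverges at c=0)")
    if c_low > c_high:
        raise InvalidArgumentError("require c_low <= c_high")
    T = fit.temperature if temperature is None else temperature
    prefactor = molar_mass * GAS_CONSTANT * T / N_A
    if method == "closed_form":
        integral = (
            np.log(c_high / c_low) / fit.Mw_app
            + 2.0 * fit.A2 * (c_high - c_low)
            + 1.5 * fit.A3 * (c_high**2 - c_low**2)
        )
    elif method == "quad":
        integral, _ = quad(lambda cc: fit.predict(cc) / cc, c_low, c_high,
                           epsabs=1e-14, epsrel=1e-12)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return prefactor * integral


def free_energy_curve(
    fit: VirialFit,
    c_grid: np.ndarray,
    reference_c: float,
    molar_mass: float,
    temperature: float | None = None,
) -> FreeEnergyCurve:
    """Δg(c) on a concentration grid relative to ``reference_c`` [g ml⁻¹]."""
    T = fit.temperature if temperature is None else temperature
    c_grid = np.asarray(c_grid, dtype=float)
    dg = np.array([
        free_energy_excess(fit, reference_c, ch, molar_mass, T)
        if ch >= reference_c
        else -free_energy_excess(fit, ch, reference_c, molar_mass, T)
        for ch in c_grid
    ])
    return FreeEnergyCurve(
        c_grid=c_grid, dg=dg, dg_kBT=dg / (K_B * T), reference_c=reference_c, temperature=T
    )
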