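"""Monomer–dimer self-association equilibria and dilution-series fitting.

The association 2M ⇌ D is described by the dimerization constant

    k_D = [D]/[M]²      (no statistical factor; units M⁻¹)

together with the mass balance ``c = [M] + 2[D]`` over total solute
concentration ``c``.  Eliminating [M] gives the closed-form speciation

    [D] = (4·k_D·c + 1 − sqrt(8·k_D·c + 1)) / (8·k_D)

Under fast exchange an NMR resonance reports the population-weighted
average of the monomer and dimer environments, so the observed shift of a
given carbon follows the dimerization isotherm

    δ_obs(c) = δ_M + (δ_D − δ_M) · 2[D]/c

where ``2[D]/c`` is the fraction of molecules (equivalently nuclei) bound
in dimers.  Fitting δ_obs over a dilution series — one shared k_D across
carbons, one (δ_M, δ_D) pair per carbon — yields the dimerization
constant; the convention above must be kept in mind when quoting dimer
populations, since ``2[D]/c`` (molecule fraction) and ``[D]/([M]+[D])``
(species fraction) differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import lmfit
import numpy as np

from .errors import FitFailureError, InvalidArgumentError
from .sls_thermo import ConcentrationSeries

logger = logging.getLogger(__name__)

#: log10 bounds of the default multi-start grid for k_D [M⁻¹].
_KD_START_RANGE = (-3.0, 2.0)
_N_STARTS = 8


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium monomer/dimer concentrations at one total concentration."""

    c_total: float  # [M]
    monomer: float  # [M]
    dimer: float  # [M]

    @property
    def frac_molecules_in_dimers(self) -> float:
        """Fraction of solute molecules bound in dimers, 2[D]/c."""
        return 2.0 * self.dimer / self.c_total if self.c_total > 0 else 0.0

    @property
    def frac_dimer_species(self) -> float:
        """Fraction of solution species that are dimers, [D]/([M]+[D])."""
        tot = self.monomer + self.dimer
        return self.dimer / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class DimerizationFit:
    """Global dimerization-isotherm fit across one or more carbons."""

    k_D: float  # [M⁻¹]
    k_D_stderr: float | None
    per_carbon: list[tuple[str, float, float]]  # (label, δ_M, δ_D) [ppm]
    r_squared: float
    covariance: np.ndarray | None
    flat_model: bool = False  # set when the data carry no association signal

    def __post_init__(self):
        if self.k_D < 0:
            raise InvalidArgumentError("k_D must be nonnegative")
        if self.r_squared > 1 + 1e-12:
            raise InvalidArgumentError("r_squared cannot exceed 1")


def speciate(k_D: float, c_total: float) -> SpeciationResult:
    """Solve the monomer–dimer equilibrium at total concentration ``c_total`` [M]."""
    if k_D < 0 or c_total < 0:
        raise InvalidArgumentError("k_D and c_total must be nonnegative")
    if k_D == 0 or c_total == 0:
        return SpeciationResult(c_total=c_total, monomer=c_total, dimer=0.0)
    s = np.sqrt(8.0 * k_D * c_total + 1.0)
    dimer = (4.0 * k_D * c_total + 1.0 - s) / (8.0 * k_D)
    monomer = c_total - 2.0 * dimer
    return SpeciationResult(c_total=c_total, monomer=monomer, dimer=dimer)


def shift_model(
    k_D: float, delta_M: float, delta_D: float, c_total: float | np.ndarray
) -> float | np.ndarray:
    """Fast-exchange observed shift [ppm] at total concentration [M]."""
    c = np.asarray(c_total, dtype=float)
    if np.any(c < 0):
        raise InvalidArgumentError("c_total must be nonnegative")
    if k_D < 0:
        raise InvalidArgumentError("k_D must be nonnegative")
    with np.errstate(invalid="ignore", divide="ignore"):
        if k_D == 0:
            frac = np.zeros_like(c)
        else:
            s = np.sqrt(8.0 * k_D * c + 1.0)
            dimer = (4.0 * k_D * c + 1.0 - s) / (8.0 * k_D)
            frac = np.where(c > 0, 2.0 * dimer / np.where(c > 0, c, 1.0), 0.0)
    out = delta_M + (delta_D - delta_M) * frac
    return out if np.ndim(c_total) else float(out)


def population_curve(k_D: float, c_grid: np.ndarray) -> dict[str, np.ndarray]:
    """Monomer/dimer population fractions along a concentration grid [M].

    Returns arrays keyed ``frac_molecules_in_dimers`` (2[D]/c) and
    ``frac_dimer_species`` ([D]/([M]+[D])), both monotone nondecreasing
    in concentration.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    if not (np.all(c_grid > 0) and np.all(np.diff(c_grid) > 0)):
        raise InvalidArgumentError("c_grid must be positive and strictly increasing")
    results = [speciate(k_D, c) for c in c_grid]
    return {
        "c_total": c_grid,
        "frac_molecules_in_dimers": np.array([r.frac_molecules_in_dimers for r in results]),
        "frac_dimer_species": np.array([r.frac_dimer_species for r in results]),
    }


def _pooled_r_squared(series_list, residuals) -> float:
    """1 − RSS/TSS with the total sum of squares centred per carbon."""
    rss = float(np.sum(np.concatenate(residuals) ** 2))
    tss = float(sum(np.sum((s.value - s.value.mean()) ** 2) for s in series_list))
    if tss == 0:
        return 1.0 if rss == 0 else -np.inf
    return 1.0 - rss / tss


def fit_dimerization(
    series_list: list[ConcentrationSeries],
    shared_kD: bool = True,
    n_starts: int = _N_STARTS,
) -> DimerizationFit | list[DimerizationFit]:
    """Nonlinear least-squares fit of the dimerization isotherm.

    By default a single k_D is shared across all carbons with per-carbon
    limiting shifts (δ_M, δ_D); with ``shared_kD=False`` each carbon is
    fitted independently (diagnostic mode) and a list is returned.  The
    optimizer is restarted from ``n_starts`` log-spaced k_D values in
    10⁻³–10² M⁻¹ to avoid local minima; the best (lowest-RSS) solution
    wins.

    Raises :class:`FitFailureError` carrying the best iterate if no
    restart converges.  A fit is flagged ``flat_model`` when k_D is
    statistically indistinguishable from zero, which is the expected
    outcome for carbons whose shift does not move with concentration.
    """
    if not series_list:
        raise InvalidArgumentError("need at least one concentration series")
    for s in series_list:
        if s.unit != "M":
            raise InvalidArgumentError("dimerization fitting expects molar ('M') series")
        if len(s) < 4:
            raise InvalidArgumentError("need at least 4 concentrations per carbon")
    if not shared_kD:
        return [fit_dimerization([s], shared_kD=True, n_starts=n_starts) for s in series_list]

    labels = [s.label or f"carbon{i}" for i, s in enumerate(series_list)]

    def residuals(params):
        kd = params["k_D"].value
        out = []
        for lab, s in zip(labels, series_list):
            pred = shift_model(kd, params[f"dM_{lab}"].value, params[f"dD_{lab}"].value,
                               s.concentration)
            res = pred - s.value
            if s.sigma is not None:
                res = res / s.sigma
            out.append(res)
        return np.concatenate(out)

    spans = [s.value[-1] - s.value[0] for s in series_list]
    noise_scale = max((np.median(s.sigma) for s in series_list if s.sigma is not None),
                      default=0.0)
    if noise_scale and max(abs(sp) for sp in spans) < noise_scale:
        logger.warning("fit_dimerization: shift range below noise level; fit ill-conditioned")

    kd_starts = np.logspace(*_KD_START_RANGE, n_starts)
    best = None
    for kd0 in kd_starts:
        params = lmfit.Parameters()
        params.add("k_D", value=kd0, min=0.0)
        for lab, s in zip(labels, series_list):
            # Extrapolate limiting shifts from the series endpoints.
            params.add(f"dM_{lab}", value=float(s.value[0]))
            params.add(f"dD_{lab}", value=float(s.value[-1] + (s.value[-1] - s.value[0])))
        try:
            result = lmfit.minimize(residuals, params, method="leastsq")
        except Exception:  # pragma: no cover - lmfit raises rarely
            continue
        if best is None or result.chisqr < best.chisqr:
            best = result
    if best is None:
        raise FitFailureError("dimerization fit failed from every restart")
    if not best.success:
        raise FitFailureError("dimerization fit did not converge", best_result=best)

    kd = best.params["k_D"].value
    kd_err = best.params["k_D"].stderr
    per_carbon = [
        (lab, best.params[f"dM_{lab}"].value, best.params[f"dD_{lab}"].value) for lab in labels
    ]
    # Unweighted residuals for the pooled R² regardless of sigma weighting.
    raw_res = [
        shift_model(kd, dm, dd, s.concentration) - s.value
        for (lab, dm, dd), s in zip(per_carbon, series_list)
    ]
    r2 = _pooled_r_squared(series_list, raw_res)
    flat = bool(kd_err is not None and kd <= 2.0 * kd_err) or kd < 1e-12
    cov = np.asarray(best.covar) if best.covar is not None else None
    logger.info("dimerization fit: k_D=%.4g±%s M⁻¹, R²=%.5f, %d carbons%s",
                kd, f"{kd_err:.2g}" if kd_err else "?", r2, len(labels),
                " [flat]" if flat else "")
    return DimerizationFit(
        k_D=float(kd), k_D_stderr=kd_err, per_carbon=per_carbon,
        r_squared=r2, covariance=cov, flat_model=flat,
    )
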