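"""Monomer–dimer reaction–diffusion model of a stabilized mesoscale cluster.

Mass-action kinetics for the association 2M ⇌ D read

    dn₁/dt = −2k₁n₁² + 2k₂n₂        dn₂/dt = k₁n₁² − k₂n₂

(number densities n₁, n₂; formation rate k₁, decay rate k₂), which
conserve total molecules n₁ + 2n₂ exactly.  Adding Fickian transport
gives the reaction–diffusion system

    ∂n₁/∂t = D₁∇²n₁ − 2k₁n₁² + 2k₂n₂
    ∂n₂/∂t = D₂∇²n₂ + k₁n₁² − k₂n₂

Far from a cluster the solution sits at bulk chemical equilibrium
(k₁n₁∞² = k₂n₂∞).  Linearizing about that state for a spherically
symmetric cluster — and dropping the monomer→dimer feedback term, which
is smaller by the bulk dimer fraction — the dimer excess δn₂ = n₂ − n₂∞
obeys a screened (Yukawa-type) equation D₂∇²δn₂ = k₂δn₂ with decay
length

    Λ = sqrt(D₂ / k₂)

Its regular solutions are ``sinh(r/Λ)/r`` inside and ``e^{−r/Λ}/r``
outside; identifying Λ with the cluster radius R (the observation that
the dimer halo decays on the cluster's own scale) inverts to the decay
rate k₂ = D₂/R².  The monomer field is slaved to the dimer field by the
steady flux-balance identity D₁δn₁ + 2D₂δn₂ = 0 — the unique bounded
solution with both fields approaching bulk at infinity — so monomers are
depleted wherever dimers are enriched.

The cluster interior is modelled as a region r < R whose local dimer
equilibrium is elevated by a constant plateau (set by ``core_contrast``);
the interior and exterior solutions are matched in value and radial flux
at R.  ``evolve_rd`` integrates the same linearized system in time
(method of lines, finite volumes on a logarithmic grid), so its long-time
limit is exactly the analytic steady profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .constants import N_A
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RDParams:
    """Rate and transport parameters of the monomer–dimer reaction–diffusion model.

    k1 carries number-density units [m³ s⁻¹] (rate = k1·n1²); k2 is first
    order [s⁻¹].  When ``equilibrated`` the bulk densities must satisfy
    detailed balance k1·n1_inf² = k2·n2_inf to 1e-9 relative.
    """

    k1: float  # [m³ s⁻¹]
    k2: float  # [s⁻¹]
    D1: float  # [m² s⁻¹]
    D2: float  # [m² s⁻¹]
    n1_inf: float  # [m⁻³]
    n2_inf: float  # [m⁻³]
    equilibrated: bool = True

    def __post_init__(self):
        for name in ("k1", "k2", "D1", "D2", "n1_inf", "n2_inf"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be nonnegative")
        if self.equilibrated:
            lhs = self.k1 * self.n1_inf**2
            rhs = self.k2 * self.n2_inf
            if abs(lhs - rhs) > 1e-9 * max(lhs, rhs, 1e-300):
                raise InvalidArgumentError(
                    f"bulk not in chemical equilibrium: k1·n1² = {lhs:.6e} "
                    f"but k2·n2 = {rhs:.6e}"
                )

    @classmethod
    def from_solution(
        cls, k_D: float, c_total: float, D1: float, D2: float, k2: float
    ) -> "RDParams":
        """Build equilibrated parameters from solution-phase quantities.

        ``k_D`` [M⁻¹] and total concentration ``c_total`` [M] fix the bulk
        monomer/dimer densities through the speciation closed form; the
        formation rate follows from k1 = k2 · k_D(number-density units).
        """
        from .dimerization import speciate

        sp = speciate(k_D, c_total)
        return cls(
            k1=k2 * kd_to_number_density(k_D),
            k2=k2,
            D1=D1,
            D2=D2,
            n1_inf=molar_to_number_density(sp.monomer),
            n2_inf=molar_to_number_density(sp.dimer),
        )


@dataclass(frozen=True)
class SpatialProfile:
    """Steady-state monomer/dimer density fields around one cluster."""

    r: np.ndarray  # radial grid [m], strictly increasing, > 0
    n1: np.ndarray  # monomer density [m⁻³]
    n2: np.ndarray  # dimer density [m⁻³]
    R_cluster: float  # [m]
    lambda_screen: float  # Λ = sqrt(D2/k2) [m]
    B: float  # exterior matching amplitude [m⁻³]
    core_plateau: float  # interior elevated-equilibrium excess Δ [m⁻³]
    params: RDParams

    def __post_init__(self):
        if np.any(self.n1 < -1e-6 * max(self.params.n1_inf, 1.0)):
            raise InvalidArgumentError("monomer density negative on grid")
        if np.any(self.n2 < -1e-6 * max(self.params.n2_inf, 1.0)):
            raise InvalidArgumentError("dimer density negative on grid")


def reaction_rates(
    n1: float | np.ndarray, n2: float | np.ndarray, k1: float, k2: float
):
    """Pure mass-action rates (dn1/dt, dn2/dt); conserves n1 + 2·n2 exactly."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 0) or np.any(n2 < 0):
        raise InvalidArgumentError("densities must be nonnegative")
    formation = k1 * n1**2
    decay = k2 * n2
    dn1 = -2.0 * formation + 2.0 * decay
    dn2 = formation - decay
    if dn1.ndim == 0:
        return float(dn1), float(dn2)
    return dn1, dn2


def molar_to_number_density(c_molar: float | np.ndarray) -> float | np.ndarray:
    """mol l⁻¹ → m⁻³ (factor N_A·10³)."""
    return np.multiply(c_molar, N_A * 1e3)


def number_density_to_molar(n: float | np.ndarray) -> float | np.ndarray:
    """m⁻³ → mol l⁻¹."""
    return np.divide(n, N_A * 1e3)


def kd_to_number_density(k_D: float) -> float:
    """Convert a dimerization constant [M⁻¹] to the k1/k2 ratio [m³].

    At bulk equilibrium k1·n1² = k2·n2 and k_D = [D]/[M]², so
    k1/k2 = k_D/(N_A·10³).
    """
    if k_D < 0:
        raise InvalidArgumentError("k_D must be nonnegative")
    return k_D / (N_A * 1e3)


def decay_rate_from_radius(D2: float, R_cluster: float) -> float:
    """Dimer decay rate k₂ = D₂/R² from the decay-length ≡ cluster-radius identification."""
    if D2 <= 0 or R_cluster <= 0:
        raise InvalidArgumentError("D2 and R_cluster must be positive")
    return D2 / R_cluster**2


def screening_length(D2: float, k2: float) -> float:
    """Dimer-excess decay length Λ = sqrt(D₂/k₂) [m] (inverse of the above)."""
    if D2 <= 0 or k2 <= 0:
        raise InvalidArgumentError("D2 and k2 must be positive")
    return float(np.sqrt(D2 / k2))


def default_grid(lambda_screen: float, n_nodes: int = 200,
                 r_min_factor: float = 0.1, r_max_factor: float = 50.0) -> np.ndarray:
    """Logarithmic radial grid spanning [0.1, 50]·Λ by default."""
    return np.geomspace(r_min_factor * lambda_screen, r_max_factor * lambda_screen, n_nodes)


def _interior_shape(x: np.ndarray) -> np.ndarray:
    """sinh(x)/x, regular at the origin."""
    return np.where(x < 1e-8, 1.0 + x**2 / 6.0, np.sinh(np.clip(x, None, 700.0)) / x)


def steady_profiles(
    params: RDParams,
    R_cluster: float,
    core_contrast: float,
    r_grid: np.ndarray | None = None,
) -> SpatialProfile:
    """Analytic steady-state fields n₁(r), n₂(r) around a cluster of radius R.

    ``core_contrast`` sets the dimer excess at the cluster centre as a
    multiple of the bulk dimer density: δn₂(0) = core_contrast · n2_inf.
    The interior solution Δ + A·sinh(r/Λ)/(r/Λ) and exterior solution
    B·(R/r)·e^{−(r−R)/Λ} are matched in value and radial derivative at R;
    the monomer field follows from D₁δn₁ + 2D₂δn₂ = 0.  A contrast large
    enough to drive the monomer density negative is clipped (with a
    warning) to the largest admissible value.
    """
    if R_cluster <= 0:
        raise InvalidArgumentError("R_cluster must be positive")
    if core_contrast < 0:
        raise InvalidArgumentError("core_contrast must be nonnegative")
    lam = screening_length(params.D2, params.k2)
    if r_grid is None:
        r_grid = default_grid(lam)
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or np.any(r <= 0) or not np.all(np.diff(r) > 0):
        raise InvalidArgumentError("r_grid must be positive and strictly increasing")
    if not (r[0] < R_cluster < r[-1]):
        raise InvalidArgumentError("r_grid must span the cluster radius")

    chi = core_contrast * params.n2_inf  # requested core excess [m⁻³]
    # Clip so that n1 = n1_inf − 2(D2/D1)·δn2 stays nonnegative at the core.
    chi_max = params.n1_inf * params.D1 / (2.0 * params.D2)
    if chi > chi_max:
        logger.warning(
            "core_contrast clipped from %.3g to %.3g to keep monomer density nonnegative",
            core_contrast, chi_max / params.n2_inf if params.n2_inf > 0 else np.inf,
        )
        chi = chi_max

    x_R = R_cluster / lam
    s_R = float(_interior_shape(np.array([x_R]))[0])
    # d/dr [sinh(r/Λ)/(r/Λ)] at R
    sp_R = (np.cosh(x_R) / x_R - np.sinh(x_R) / x_R**2) / lam
    # d/dr [(R/r)e^{−(r−R)/Λ}] at R
    ep_R = -(1.0 / R_cluster + 1.0 / lam)

    denom = sp_R - ep_R * (s_R - 1.0)
    A = ep_R * chi / denom if chi > 0 else 0.0
    plateau = chi - A
    B = plateau + A * s_R

    inside = r <= R_cluster
    dn2 = np.empty_like(r)
    dn2[inside] = plateau + A * _interior_shape(r[inside] / lam)
    r_out = r[~inside]
    dn2[~inside] = B * (R_cluster / r_out) * np.exp(-(r_out - R_cluster) / lam)
    dn1 = -2.0 * (params.D2 / params.D1) * dn2

    return SpatialProfile(
        r=r, n1=params.n1_inf + dn1, n2=params.n2_inf + dn2,
        R_cluster=R_cluster, lambda_screen=lam, B=float(B),
        core_plateau=float(plateau), params=params,
    )


# ---------------------------------------------------------------------------
# Time-dependent solver (method of lines, finite volumes, spherical symmetry)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RDEvolution:
    """Time series of (n1, n2) fields from :func:`evolve_rd`."""

    t: np.ndarray  # [s]
    r: np.ndarray  # [m]
    n1: np.ndarray  # shape (nt, nr)
    n2: np.ndarray  # shape (nt, nr)
    cell_volumes: np.ndarray  # [m³]

    def total_molecules(self) -> np.ndarray:
        """∫(n1 + 2·n2) dV at each output time."""
        return ((self.n1 + 2.0 * self.n2) * self.cell_volumes).sum(axis=1)


def _finite_volume_geometry(r: np.ndarray):
    """Cell faces, face areas and cell volumes for a node-centred spherical mesh."""
    faces = np.empty(len(r) + 1)
    faces[1:-1] = 0.5 * (r[:-1] + r[1:])
    faces[0] = max(r[0] - (faces[1] - r[0]), 0.0)
    faces[-1] = r[-1] + (r[-1] - faces[-2])
    areas = 4.0 * np.pi * faces**2
    volumes = (4.0 * np.pi / 3.0) * (faces[1:] ** 3 - faces[:-1] ** 3)
    return faces, areas, volumes


def evolve_rd(
    params: RDParams,
    n1_init: np.ndarray,
    n2_init: np.ndarray,
    r_grid: np.ndarray,
    t_end: float,
    R_cluster: float | None = None,
    core_plateau: float = 0.0,
    outer: str = "fixed",
    n_eval: int = 25,
    rtol: float = 1e-8,
    atol_scale: float = 1e-10,
) -> RDEvolution:
    """Integrate the linearized reaction–diffusion system on a radial grid.

    The fields evolve by spherical diffusion plus first-order exchange
    toward the local dimer equilibrium (bulk outside, elevated by
    ``core_plateau`` inside ``R_cluster``); the reaction exchange
    conserves n1 + 2·n2 pointwise.  Boundary conditions: zero flux at the
    inner face always; at the outer face either clamped bulk densities
    (``outer="fixed"``) or zero flux (``outer="closed"``, a closed box
    that conserves total molecules to integrator tolerance).

    Stiffness is handled by the implicit BDF integrator; a step-size
    failure surfaces as a RuntimeError from the integrator.
    """
    r = np.asarray(r_grid, dtype=float)
    n = len(r)
    if outer not in ("fixed", "closed"):
        raise InvalidArgumentError("outer must be 'fixed' or 'closed'")
    faces, areas, volumes = _finite_volume_geometry(r)
    dr = np.diff(r)

    forcing = np.zeros(n)
    if R_cluster is not None and core_plateau != 0.0:
        # Volume fraction of each finite-volume cell inside the cluster, so the
        # sharp core edge is represented to better than cell resolution.
        inner3 = np.clip(faces[:-1], None, R_cluster) ** 3
        outer3 = np.clip(faces[1:], None, R_cluster) ** 3
        frac = np.clip((outer3 - inner3) / (faces[1:] ** 3 - faces[:-1] ** 3), 0.0, 1.0)
        forcing = core_plateau * frac

    n1_bulk = params.n1_inf
    n2_bulk = params.n2_inf
    k2 = params.k2
    D1, D2 = params.D1, params.D2

    def diffusion(dn: np.ndarray, D: float) -> np.ndarray:
        flux = np.zeros(n + 1)  # outward diffusive flux through each face
        flux[1:-1] = -D * areas[1:-1] * (dn[1:] - dn[:-1]) / dr
        if outer == "fixed":
            # Ghost value δn = 0 at the outer face.
            flux[-1] = -D * areas[-1] * (0.0 - dn[-1]) / (faces[-1] - r[-1])
        return -(flux[1:] - flux[:-1]) / volumes

    def rhs(t, y):
        dn1 = y[:n]
        dn2 = y[n:]
        exch = k2 * (dn2 - forcing)  # dimer decay toward local equilibrium
        ddn1 = diffusion(dn1, D1) + 2.0 * exch
        ddn2 = diffusion(dn2, D2) - exch
        return np.concatenate([ddn1, ddn2])

    y0 = np.concatenate([np.asarray(n1_init, float) - n1_bulk,
                         np.asarray(n2_init, float) - n2_bulk])
    scale = max(n1_bulk, n2_bulk, np.abs(y0).max(), 1.0)
    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", t_eval=t_eval,
                    rtol=rtol, atol=atol_scale * scale)
    if not sol.success:  # pragma: no cover - integrator failure path
        raise RuntimeError(f"reaction-diffusion integration failed: {sol.message}")
    dn1_t = sol.y[:n].T
    dn2_t = sol.y[n:].T
    return RDEvolution(t=sol.t, r=r, n1=n1_bulk + dn1_t, n2=n2_bulk + dn2_t,
                       cell_volumes=volumes)
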