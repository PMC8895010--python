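"""End-to-end derived-constant chain.

From the measured inputs — monomer diffusion coefficient, monomer and
dimer hydrodynamic radii, mean cluster diameter, dimerization constant —
the chain derives, in order: the dimer diffusion coefficient (inverse-
radius scaling), the dimer decay rate (k₂ = D₂/R²), the screening
length, the steady cluster radius and its 99% arrival time (radius
evolution equation), and the monomer/dimer speciation at a requested
concentration.  Every value is produced by the corresponding stage
function, so the report is bit-for-bit identical to running the stages
individually.
"""

from __future__ import annotations

from .cluster_dynamics import RadiusModel, integrate_radius, steady_radius
from .config import PipelineConfig
from .dimerization import speciate
from .hydrodynamics import scale_diffusion
from .reaction_diffusion import decay_rate_from_radius, screening_length


def run_derivation_chain(config: PipelineConfig | None = None) -> dict:
    """Derive the full constant cascade from a pipeline configuration."""
    cfg = config or PipelineConfig()
    report: dict = {"inputs": cfg.to_dict()}

    d2 = None
    if "hydrodynamics" in cfg.stages:
        d2 = scale_diffusion(cfg.d1, cfg.r1, cfg.r2)
        report["D2"] = {
            "value": d2, "unit": "m^2 s^-1",
            "provenance": "inverse-radius Stokes-Einstein scaling of d1 by r1/r2",
        }

    k2 = None
    if "reaction_diffusion" in cfg.stages:
        if d2 is None:
            d2 = scale_diffusion(cfg.d1, cfg.r1, cfg.r2)
        radius = cfg.cluster_diameter / 2.0
        k2 = decay_rate_from_radius(d2, radius)
        report["k2"] = {
            "value": k2, "unit": "s^-1",
            "provenance": "k2 = D2/R^2 with R = cluster_diameter/2",
        }
        report["lambda_screen"] = {
            "value": screening_length(d2, k2), "unit": "m",
            "provenance": "dimer-excess decay length sqrt(D2/k2)",
        }

    if "cluster_dynamics" in cfg.stages:
        if d2 is None:
            d2 = scale_diffusion(cfg.d1, cfg.r1, cfg.r2)
        if k2 is None:
            k2 = decay_rate_from_radius(d2, cfg.cluster_diameter / 2.0)
        model = RadiusModel(D2=d2, k2=k2, drive=cfg.drive, shrink=cfg.shrink)
        traj = integrate_radius(cfg.r0, model, cfg.t_end)
        report["R_steady"] = {
            "value": steady_radius(model), "unit": "m",
            "provenance": "fixed point sqrt(3*drive*D2/(shrink*k2)) of the radius equation",
        }
        report["t_99"] = {
            "value": traj.t_99, "unit": "s",
            "provenance": f"trajectory from r0 = {cfg.r0} m to 99% of R_steady",
        }

    if "speciation" in cfg.stages:
        sp = speciate(cfg.k_D, cfg.speciation_conc)
        report["speciation"] = {
            "c_total_M": sp.c_total,
            "monomer_M": sp.monomer,
            "dimer_M": sp.dimer,
            "frac_molecules_in_dimers": sp.frac_molecules_in_dimers,
            "frac_dimer_species": sp.frac_dimer_species,
            "provenance": f"monomer-dimer equilibrium at k_D = {cfg.k_D} M^-1",
        }
    return report
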