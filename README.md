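# mesocluster

Quantitative modelling of mesoscale solute-rich clusters in small-molecule
solutions: why they form, why they stop growing, and how every constant in
that story is measured or derived.

Concentrated solutions of small organic molecules — the reference system
here is 2-cyano-4'-methylbiphenyl (OTBN) in methanol — can host stable,
liquid-like clusters tens of nanometres across that act as
crystal-nucleation precursors.  A cluster made of monomers alone would
dissolve: static light scattering shows the excess free energy per
molecule Δg rises with concentration, so chemical-potential-driven
("uphill") diffusion empties any monomer-rich domain.  Clusters persist
because a second species, the π-stacked dimer, is enriched inside them
and continuously converts back to monomers, balancing diffusive influx
against reaction-limited loss.

The package implements that mechanism as a chain of five testable stages,
each usable on its own:

1. **`sls_thermo`** — osmotic-virial fit of Debye plots,
   `Kc/R_θ = 1/Mw + 2A₂c + 3A₃c²`, and the per-molecule excess free
   energy `Δg = (M·RT/N_A)∫(Kc/R_θ)/c·dc`.
2. **`dimerization`** — closed-form monomer–dimer speciation for
   `k_D = [D]/[M]²`, and nonlinear fitting of the fast-exchange isotherm
   `δ(c) = δ_M + (δ_D−δ_M)·2[D]/c` to ¹³C dilution series (shared k_D
   across carbons).
3. **`hydrodynamics`** — diffusion coefficients from Stejskal–Tanner
   DOSY attenuation, Stokes–Einstein `D = k_BT/(6πη r_H)`, and
   inverse-radius scaling `D₂ = D₁·r₁/r₂` between species.
4. **`reaction_diffusion`** — mass-action kinetics
   `dn₂/dt = k₁n₁² − k₂n₂`, the screened steady-state dimer halo with
   decay length `Λ = √(D₂/k₂)` (whence `k₂ = D₂/R²` from the observed
   cluster radius), analytic steady profiles n₁(r), n₂(r) and a
   finite-volume time-dependent solver.
5. **`cluster_dynamics`** — the radius equation
   `dR/dt = (D₂/R)σ_d − (k₂/3)χR` with its stable fixed point
   `R* = √(3σ_d D₂/(χk₂))`.

A seeded `synthetic_data` module generates datasets with exactly the
statistical structure each fitter assumes, so the full pipeline is
testable without instrument data.  See `docs/methods.md` for models,
assumptions, defaults and limitations.

## Worked example

```python
import mesocluster as mc

report = mc.run_derivation_chain()
for key in ("D2", "k2", "lambda_screen", "R_steady", "t_99"):
    print(f"{key:14s} {report[key]['value']:.6g} {report[key]['unit']}")

sp = report["speciation"]
print(f"speciation at {sp['c_total_M']} M: monomer {sp['monomer_M']:.5f} M, "
      f"dimer {sp['dimer_M']:.5f} M, molecules in dimers "
      f"{100 * sp['frac_molecules_in_dimers']:.1f}%")

series = mc.gen_nmr_shifts(mc.GeneratorConfig(seed=1))   # synthetic ¹³C dilution data
fit = mc.fit_dimerization(series)
print(f"k_D = {fit.k_D:.3f} M^-1 (R^2 = {fit.r_squared:.4f})")
```

prints

```
D2             3.2e-11 m^2 s^-1
k2             125000 s^-1
lambda_screen  1.6e-08 m
R_steady       1.6e-08 m
t_99           4.7619e-05 s
speciation at 0.5 M: monomer 0.29727 M, dimer 0.10136 M, molecules in dimers 40.5%
k_D = 1.146 M^-1 (R^2 = 0.9989)
```

Reading the chain: the dimer diffusion coefficient D₂ = 3.2×10⁻¹¹ m² s⁻¹
follows from the measured monomer value (4×10⁻¹¹ m² s⁻¹) and the
monomer/dimer hydrodynamic radii (3.72/4.65 Å); combined with the
observed 32 nm mean cluster diameter it gives the dimer decay rate
k₂ = D₂/(16 nm)² = 125 000 s⁻¹.  The dimer-halo decay length Λ and the
steady cluster radius R* then both come out at 16 nm, and a 1 nm seed
cluster grows monotonically to 99% of R* in ~5×10⁻⁵ s — stabilization
well inside a millisecond.  At 0.5 M roughly 40% of molecules are bound
in dimers (note this is the 2[D]/c convention; [D]/([M]+[D]) is also
exposed and differs).  The last line refits the dimerization constant
from noisy synthetic shift data, recovering the generating value
1.147 M⁻¹.

The same stages are available as a CLI:

```bash
mesocluster simulate nmr --seed 1 --out shifts.csv
mesocluster fit-dimerization --input shifts.csv --out dimer.json
mesocluster derive-chain --out chain.json
mesocluster rd-profile --contrast 10 --conc 0.01 --out profile.csv
mesocluster radius-dynamics --r0 1e-9 --out traj.csv
```

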