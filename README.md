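# bexfes

Free-energy landscapes of intrinsically disordered peptides from
bias-exchange metadynamics, and the biophysics used to test them against
experiment.

Intrinsically disordered proteins such as the amyloid-β 40-mer have no
folded native state; their behaviour is governed by a free-energy
landscape over collective variables (CVs) with a broad disordered global
minimum and many partially structured states a few kJ/mol above it.  A
striking consequence is *inverted* thermal behaviour: raising the
temperature populates higher free-energy, more structured and more
compact states.  This package provides, as a tested and reusable library:

- **Microstate free-energy reconstruction** (`bexfes.fes`): hypercube
  binning of post-equilibration CV frames and self-consistent
  weighted-histogram (WHAM) estimation from the replicas'
  one-dimensional bias potentials,

      F_α = −kT · ln[ Σ_k n_kα / Σ_k N_k e^{(f_k − V_k(s_α))/kT} ],
      f_k = −kT · ln Σ_α e^{−(F_α + V_k(s_α))/kT},

  with block-analysis errors and consistency-driven bin refinement.
- **Structural CVs and observables** (`bexfes.structure`): rational
  switching functions, side-chain coordination number, α/β segment
  counts by template RMSD, χ1 similarity, dihedral secondary-structure
  assignment, Shrake–Rupley SASA, radius of gyration.
- **Ensemble analysis** (`bexfes.ensemble`): Boltzmann averages
  ⟨O⟩ = Σ_α O_α e^{−F_α/kT}/Σ_α e^{−F_α/kT} and free-energy slices
  (6 kJ/mol bands) with per-residue secondary-structure populations and
  ΔSASA profiles against the global minimum.
- **Two-state thermodynamics** (`bexfes.thermo`): restraint-filtered
  enthalpy estimation and the constant-ΔCp Gibbs–Helmholtz model
  ΔG(T) = ΔH − TΔS + ΔCp[(T − T_ref) − T ln(T/T_ref)], whose structured
  population ratio peaks at T* = T_ref − ΔH/ΔCp.
- **Experimental layer** (`bexfes.biophys`): empirical hydrodynamic
  radii (folded / unfolded / pre-molten globule), SEC apparent-mass
  conversion, compaction index, Stejskal–Tanner PFG-NMR diffusion fits
  with internal standards and Stokes–Einstein, CD mean residue
  ellipticity, peptide masses.
- **Synthetic data with ground truth** (`bexfes.synthetic`): multi-well
  CV landscapes, a Metropolis bias-exchange sampler following the
  0.30 kJ/mol / 5 ps / 20 ps metadynamics schedule, toy peptides with
  prescribed H/E/C content, diffusion decays and restrained energy
  traces — so every estimator is validated against a known answer.

## Worked example

Reconstruct a two-well landscape (basins 12 and 7 kJ/mol deep, so the
true basin difference is 5 kJ/mol) from two bias-exchange replicas:

```python
import numpy as np
from bexfes import *
from bexfes.synthetic import ToyLandscape

spec = ToyLandscape(cv_names=["cv1", "cv2"],
                    wells=[([0.8, 0.8], 12.0, [0.25, 0.25]),
                           ([2.2, 2.2], 7.0, [0.25, 0.25])],
                    domain=[(0.0, 3.0), (0.0, 3.0)])
land = make_landscape(spec, seed=1)
sched = MetadSchedule(gaussian_height=0.30, gaussian_width_per_cv=[0.2, 0.2],
                      deposition_stride=5, exchange_stride=20, t_eq=30000)
runs = sample_biased_replicas(land, sched, n_replicas=2, n_steps=150000, seed=1)

bspec = BinningSpec(["cv1", "cv2"], {"cv1": 0.2, "cv2": 0.2},
                    {"cv1": (0.0, 3.0), "cv2": (0.0, 3.0)}, t_eq=30000)
occ = assign_microstates(runs, bspec)
fes = reconstruct_fes(occ, runs, bspec, kT=spec.kT)

centers = np.column_stack([occ.microstates["center_cv1"],
                           occ.microstates["center_cv2"]])
f_true = land.F(centers); f_true -= f_true.min()
err = np.median(np.abs(fes.F - f_true)[f_true < 40])
print(f"{len(occ.microstates)} microstates from {len(occ.frames)} frames")
print(f"WHAM converged in {fes.n_iter} iterations (residual {fes.residual:.1e})")
print(f"median |F_est - F_true| below 40 kJ/mol: {err:.2f} kJ/mol")
```

prints

```
158 microstates from 240000 frames
WHAM converged in 9 iterations (residual 4.5e-05)
median |F_est - F_true| below 40 kJ/mol: 0.59 kJ/mol
```

i.e. the landscape is recovered well within the 2–3 kJ/mol precision
expected of the method, and the estimated basin difference (5.03 kJ/mol
here) matches the constructed 5 kJ/mol.

On the experimental side, the two-state model with the structured states'
parameters (ΔG = 8 and 10 kJ/mol, ΔH = −60 and −28 kJ/mol at 350 K,
ΔCp = −1.98 kJ/mol·K in the ordering direction):

```python
from bexfes.thermo import EXAMPLE_STATES, t_max_structured
for name, model in EXAMPLE_STATES.items():
    t_star, _ = t_max_structured(model)
    print(name, round(t_star, 1), "K")
# C2 319.7 K
# C3 335.9 K
```

places the population maxima of the β-rich and helix-rich states between
320 and 340 K — the temperature window where a disordered peptide
becomes most structured, and hence most compact, before entropy takes
over again.

A CLI mirrors the library:

```sh
bexfes hydro predict --nres 41 --state F --basis length   # Rh = 13.9 Å
bexfes thermo tmax --dg 8 --dh -60                        # T* = 319.7 K
bexfes synth replicas --seed 1 --out runs/
bexfes run --config config.yaml
```

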