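# Methods

## Scope and model

`bexfes` reconstructs the free-energy landscape of a small disordered
peptide from bias-exchange metadynamics data and implements the
surrounding analysis used to connect that landscape to experiment:
Boltzmann ensemble observables sliced by free energy, a two-state
Gibbs–Helmholtz model of temperature-induced structuring, and the
hydrodynamic/spectroscopic calculations (empirical hydrodynamic radii,
compaction index, PFG-NMR diffusion, circular-dichroism mean residue
ellipticity).  Atomistic molecular dynamics itself is out of scope;
synthetic generators with known ground truth stand in for trajectories
and spectrometer output so every stage can be validated quantitatively.

Units are fixed package-wide: coordinates in Å, switching-function radii
in nm (converted explicitly), energies in kJ/mol, temperatures in K.
Residues are numbered 1..n as in PDB files.

## Free-energy reconstruction

Post-equilibration frames from all replicas are assigned to hypercube
microstates in a chosen CV subspace (`fes.assign_microstates`).  Frames
with time ≤ t_eq are discarded; frames outside the binning ranges are
dropped and counted.  Default bin widths are naturally taken equal to the
metadynamics Gaussian width of each CV (0.2 / 0.1 / 0.2 / 10 for the
helix, parallel-β, antiparallel-β and coordination CVs of the original
setup).

Microstate free energies solve the multi-histogram (WHAM) equations

    F_α = −kT · ln[ Σ_k n_kα / Σ_k N_k · exp((f_k − V_kα)/kT) ]
    f_k = −kT · ln Σ_α exp(−(F_α + V_kα)/kT)

with n_kα the occupancy of microstate α in replica k, N_k = Σ_α n_kα and
V_kα the replica's one-dimensional bias interpolated at the microstate
center along its biased CV.  Iteration stops when max|ΔF_α| < 1e-4 kJ/mol
(default), after shifting min F = 0 each sweep; non-convergence raises an
error carrying the residual.  kT defaults to 2.9 kJ/mol (350 K).  All
exponentials are evaluated through log-sum-exp.  Two exact limits anchor
the implementation: with one replica and zero bias, WHAM reduces to the
histogram estimator −kT ln n_α + const; with one replica and any static
bias it reduces to the closed-form reweighting −kT ln n_α − V(s_α) +
const.  Both are enforced by tests to numerical precision, together with
gauge invariance under a constant bias offset.

When a replica is biased along a CV that is not part of the binning
subspace, V_kα falls back to the mean bias over the microstate's member
frames — the bias is then not constant within a microstate and the center
evaluation has no meaning.

Errors (`fes.estimate_errors`) come from block analysis: the
post-equilibration span is cut into 4 equal time windows, F_α is
re-estimated per block with the same biases, per-block gauge freedom is
removed by aligning block means over the microstates present in all
blocks, and the error is std/√n_blocks.  Microstates absent from any
block are reported as unavailable (NaN), never as zero.

Hypercube consistency (`fes.refine_bins`): a microstate whose members
spread beyond a threshold standard deviation in any CV outside the
binning subset is split in half along its widest binned axis (width
measured in units of the original bin width), recursively down to 1/8 of
the original width.  Frame counts are conserved by construction.

## Synthetic bias-exchange generator

The generator emulates the statistical structure of bias-exchange
metadynamics, not its dynamics.  The ground-truth landscape is a sum of
Gaussian basins, F(s) = −kT ln Σ_w exp(depth_w/kT − ½|s−c_w|²/σ_w²),
normalized to min F = 0; exact marginals come from dense trapezoid
quadrature.  Sampling is a Metropolis random walk in CV space on
F(s) + V_k(s_k): any ergodic sampler of the biased density validates the
reconstruction.  Step sizes are tuned to 30–50% acceptance during the
equilibration span only, so detailed balance holds for all analysed
frames.  One sampler step plays the role of 1 ps, keeping the familiar
schedule numbers: Gaussians of height 0.30 kJ/mol every 5 steps, bias
exchanges every 20 steps.  Exchanges swap the configurations of a random
adjacent replica pair with the standard Metropolis criterion on the two
one-dimensional biases.  Optional "loose upper boundaries" are
half-harmonic walls with spring constant 500 kJ/mol per CV-unit²
(positions configurable; the original work does not state them).

Deposition stops at t_eq.  This realizes the premise under which the
reconstruction is valid — the bias potentials are stationary for every
frame entering the analysis — and makes the accumulated grid identical to
the post-equilibration time-averaged bias.  With deposition continuing
past t_eq the WHAM premise is violated and recovery degrades measurably
(median errors of several kJ/mol on the two-well benchmark).  Bias grids
extend 5σ beyond the CV domain so no deposited mass is clipped, which
keeps the bookkeeping identity (deposited mass = height × n_deposits ×
σ√2π) exact.

Benchmark sizes: the bundled two-well 2-CV landscape (depths 12 and
7 kJ/mol, well width 0.25, domain [0,3]²) sampled by 2 replicas for
150,000 steps with t_eq = 30,000 reconstructs free energies below
40 kJ/mol with a median absolute error under 2 kJ/mol and basin
free-energy differences within ±1 kJ/mol, at about ten seconds of
compute; these sizes are the package's validation conditions.

Toy peptides are built from ideal backbone geometry by internal
coordinates (NeRF): helix (φ,ψ) = (−57°,−47°), strand (−139°,135°), coil
drawn uniformly from the broad β/PPII basin (φ∈[−150°,−60°],
ψ∈[90°,180°]) with a 20% α-basin admixture.  Atoms are N, CA, C, O and CB
(non-Gly).  Coil builds are resampled up to 50 times when atoms of
residues ≥ 2 apart come within 1.5 Å.  These fixtures exercise the CV and
SASA code; they do not emulate side-chain packing, hydrogen-bond energies
or real disordered-state statistics, so passing tests demonstrate
correctness of the estimators, not realism of the ensembles.

## Collective variables and structural observables

The rational switching function s(r) = (1−x^n)/(1−x^m), x = (r−d0)/r0,
uses the printed parameter pairs: (n=4, m=8, r0=0.1 nm) for the helix
count, (n=6, m=12, r0=0.1 nm) for the β counts, (n=4, m=8, r0=0.4 nm) for
the side-chain coordination number.  n is the numerator exponent (m > n).
The value at x = 1 is the continuous limit n/m.

Segment counts sum switching(RMSD) over 6-residue windows (helix) or
pairs of 3-residue segments with sequence separation ≥ 2, capped at 30
(β modes); RMSD is over backbone N, CA, C, O, CB after optimal
superposition (Kabsch, via scipy).  The ideal templates are built
internally from ideal dihedrals; the β pair templates place two ideal
strands 4.8 Å apart, the antiparallel partner rotated 180°.  The original
CV software inherits its templates unprinted; these internal templates
reproduce the required behaviour (near-zero RMSD on ideal fixtures,
discrimination between classes).

Secondary structure is assigned from dihedral boxes — H: φ∈[−100°,−30°],
ψ∈[−67°,−7°] in runs ≥ 4; E: φ∈[−180°,−90°], ψ∈[90°,180°] in runs ≥ 2;
PPII: φ∈[−90°,−55°], ψ∈[120°,180°] when not strand; C otherwise — with
chain breaks (CA–CA > 4.5 Å) splitting runs and terminal residues coil.
A backbone H-bond criterion does not alter labels (paired and unpaired
extended runs both count as strand), so the assignment is purely
dihedral; this is a stated approximation to the unnamed assignment tool
behind the original per-residue populations.

SASA uses Shrake–Rupley quadrature with a deterministic Fibonacci-spiral
point set (960 points/atom by default; doubling changes totals < 0.5% on
fixtures), Bondi van der Waals radii, probe 1.4 Å, unknown elements
falling back to 1.8 Å with a warning.  The implementation agrees with an
independent library implementation (biotite) to a fraction of a percent
on test fixtures.  The side-chain similarity CV uses χ1 (N–CA–CB–γ);
residues without a γ heavy atom are skipped and logged.

## Ensemble observables

⟨O⟩ = Σ_α O_α e^{−F_α/kT} / Σ_α e^{−F_α/kT}, with O_α the arithmetic mean
over member frames and weights computed with a max shift.  Slices are
half-open bands [i·w, (i+1)·w) of width 6 kJ/mol by default.  Within a
slice, summaries weight microstates by Boltzmann factors renormalized
inside the slice; uniform weighting is available as an option since the
original figures do not state the choice.  ΔSASA profiles are referenced
to the single microstate at F = 0.

## Two-state thermodynamics

Enthalpies of restrained runs are means of the total force-field energy
(restraint term included) over frames whose restraint energy does not
exceed 2.9 kJ/mol, with block-averaged (5 blocks) standard errors.

The Gibbs–Helmholtz model with constant ΔCp,

    ΔG(T) = ΔH(T_ref) − T·ΔS(T_ref) + ΔCp[(T − T_ref) − T ln(T/T_ref)],

stores differences in the structuring direction (structured −
unstructured).  ΔS(T_ref) is derived as (ΔH − ΔG)/T_ref, so ΔG(T_ref)
reproduces the input exactly.  The literature ΔCp = 1.98 kJ/(mol·K) is
quoted for unfolding; the model therefore carries dCp = −1.98 by default —
only this sign yields a structured-population maximum below T_ref.  The
log population ratio −ΔG/(RT) is stationary where ΔH(T) = 0, giving the
closed form T* = T_ref − ΔH(T_ref)/ΔCp, cross-checked against a grid
search on [250, 400] K; R·T (not a fixed kT) is used in the ratio.  With
the bundled example states (ΔG = 8 and 10 kJ/mol, ΔH = −60 and −28 kJ/mol
at 350 K) the maxima fall at 319.7 K and 335.9 K.  The mixture radius of
gyration weights per-state Rg values by populations ∝ e^{−G/RT} with the
unstructured state at G = 0.

## Hydrodynamic and spectroscopic layer

Empirical Rh relations live in one editable constants table:
mass basis log10 Rh = a + b log10 M with (−0.204, 0.357) folded,
(−0.649, 0.521) urea-unfolded, (−0.21, 0.392) pre-molten globule; length
basis Rh = 4.75·N^0.29 (folded) and 2.21·N^0.57 (unfolded).  The SEC
conversion applies the folded mass relation to the apparent mass (a
folded globule of that mass elutes identically).  The compaction index
CI = (Rh_U − Rh)/(Rh_U − Rh_F) is affine and deliberately unclamped;
values outside [0, 1] are flagged.  With the reference endpoints
Rh_U = 18.0 Å, Rh_F = 12.4 Å, the 5 °C radius of 16.9 Å gives CI = 0.20,
not the printed 0.21 — a documented rounding discrepancy in the source
table, not fitted away.

Diffusion decays follow Stejskal–Tanner, I = I0 exp(−Dγ²g²δ²(Δ−δ/3)); a
linearized ln-fit initializes a nonlinear least-squares fit.  Stokes–
Einstein converts D to Rh with k_B T/(6πηD); water viscosity comes from a
standard 0–100 °C table with linear interpolation, though the internal-
standard route (Rh = Rh_ref·D_ref/D_sample) cancels T and η and is the
one the experiments rely on.  Mean residue ellipticity uses
MRW = m/(n_res − 1) (mass per peptide bond, the standard CD convention).
Peptide masses are sums of average residue masses plus one water,
cross-checked against Biopython.

## Known limitations

- The sampler explores CV space directly; kinetic quantities and
  anything depending on atomistic detail are out of reach by design.
- The WHAM treatment assumes the bias static over the analysed frames;
  data with substantial post-equilibration bias drift will show larger
  errors than the benchmark suggests.
- The dihedral-box secondary-structure rule approximates H-bond-based
  assignments; PPII populations in particular are convention-dependent.
- β-pair templates are idealized (no shear between parallel strands);
  absolute β counts are comparable within this package, not across CV
  implementations.
- The empirical Rh coefficient sets are literature calibrations for
  generic polypeptides; they carry their published scatter (≈10–20%)
  even though they are evaluated here deterministically.
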