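# Methods

## Scope and model

felbind implements the analysis layer of an absolute binding free energy
(ABFE) workflow by double decoupling.  The ligand is decoupled twice —
from solution and from the restrained complex — and the standard binding
free energy is assembled as

    ΔG°_binding = −ΔG_prot(elec+vdw+restr) + ΔG_solv(elec+vdw) + ΔG_restr_on(solv).

Both decoupling legs are defined as the free energy of turning the
interactions **off**; with that convention the equation applies with the
signs as written, and making the complex leg costlier makes binding more
favourable.  Leg uncertainties combine in quadrature.  Everything
upstream (force fields, soft-core potentials, the MD integrator) is out
of scope: the package consumes per-window Hamiltonian-difference samples
and collective-variable series as text.

Internal units are fixed: kcal/mol, nm, radians, Kelvin
(R = 1.98720×10⁻³ kcal/mol/K).  Readers convert at the boundary
(1 kcal = 4.184 kJ; PDB Å → nm); energy files default to kJ/mol, the
GROMACS convention.

## BAR estimation

For one window pair the shift constant C is the root of the monotone
self-consistency condition (sum form)

    Σ_j f(β(ΔU_fwd − C)) = Σ_k f(β(ΔU_rev + C)),   f(x) = 1/(1+e^x),

with ΔU_fwd = H_k − H_j sampled in ensemble j and ΔU_rev = H_j − H_k
sampled in k, and ΔG = C + kT ln(N_j/N_k).  The reported C is rebased so
that ΔG = kT ln(N_k/N_j) + C; at equal sample counts (the normal case —
every window is simulated for the same length) all conventions coincide
and the condition reduces to equality of the two Fermi-average means.
The sum-form/ΔG pairing was validated against the analytic ground truth
of the Gaussian work generator at strongly unequal sample counts, which
pins the sign of the ln(N/N) term unambiguously.

Numerics: the Fermi function is evaluated through a stable logistic
(`expit`), exponential averages through log-sum-exp, and the root is
bracketed by the two one-sided exponential-averaging estimates (BAR
always lies between them) and solved by Brent's method to 10⁻⁸ kcal/mol,
200-iteration budget.  No automatic decorrelation is applied; a stride
flag subsamples if desired.  Errors are bootstrap (frames resampled with
replacement per direction per window, default 200 replicates, seeded);
the per-leg and cycle-combined errors are reported separately since
either convention is found in published tables.

## Boresch restraint term

Six-point restraint: one distance r₀, two angles θA₀/θB₀, three
dihedrals, harmonic with U = K/2 (x−x₀)².  Closed (stiff-limit) form:

    ΔG_restr = RT ln[ 8π² V⁰ √(K_r K_θA K_θB K_φA K_φB K_φC)
                      / ( r₀² sinθA₀ sinθB₀ (2πRT)³ ) ]

with V⁰ = 1.6605 nm³ (1 M).  Defaults for the stock setup: K_r = 1000
kcal/mol/nm², all five angular constants 10 kcal/mol/rad².

`boresch_numeric` evaluates the same ratio of configurational integrals
by separable 1-D trapezoid quadrature over the exact curvilinear measure
(r²dr, sinθ dθ, dφ), grid spanning 8 thermal widths clipped to physical
ranges, with a refinement check that warns when halving the spacing moves
the result by > 0.01 kcal/mol.  The quadrature agrees with adaptive
`scipy.integrate.quad` to ~10⁻¹³.

A point worth knowing: at angular constants of 10 kcal/mol/rad² the
stiff-limit formula is **not** exact.  The thermal width σ_θ = √(RT/K) ≈
0.24 rad is wide enough that ⟨sinθ⟩ = e^(−σ²/2)·sinθ₀ deviates from
sinθ₀; the two polar angles contribute +RT σ_θ² ≈ +0.035 kcal/mol and the
r² Jacobian −0.004, so quadrature sits 0.031 kcal/mol above the closed
form (7.4646 vs 7.4334 for the stock restraint at 298 K).  The tests
freeze both values; for genuinely stiff restraints (K ≳ 500) the two
routes agree to < 0.002.  For very soft angular constants (~0.01) the
stiff limit is meaningless and the routes diverge by > 1 kcal/mol.

## Collective variables

Rg is mass-weighted: √(Σmᵢ|rᵢ−r_com|²/Σmᵢ).  RMSD is the minimum over
rigid motions via Kabsch SVD with determinant sign correction (proper
rotations only; mirrored inputs are never "fixed" by a reflection).  The
fit is mass-weighted and the deviation unweighted by default — the
dominant trajectory-tool convention — with flags to change either.  Both
CVs are computed on whatever atom set is supplied; selection is input
preparation, not analysis.  The RMSD reference is the first frame of the
apo production run, per the first-frame convention.

## Free energy landscape and correction

The FEL is the raw 2-D histogram of the apo (Rg, RMSD) series converted
to relative Gibbs energies, G = −kT ln(count/max_count): the most
populated bin is 0, occupied bins are ≥ 0, empty bins carry no value
(never 0).  Defaults: 100×100 bins over the sample range padded by one
bin width; no kernel smoothing.  **The zero point matters**: the
correction is defined relative to the apo global minimum, so a different
normalisation would shift every correction by a constant.  This
convention is adopted deliberately and flagged here.

Correction protocol: conformations are extracted from the tail of the
end-state window (`tail_conformations`: n = 5 evenly strided frames from
the last 100 ps), looked up on the FEL, and averaged; the SEM
(sample SD/√n) is the reported uncertainty, combined in quadrature with
the alchemical error.  Lookups in empty or out-of-grid bins fall back to
the nearest occupied bin by bin-index distance with a logged warning
(policy `error` raises instead).

For validation, the inter-basin gap of a synthetic landscape is measured
with `basin_gap`: −kT ln of the ratio of counts summed over matched
(2·2+1)² bin blocks centred on the two known minima.  Reading single
minimum bins instead suffers extreme-value bias (the deepest bin is the
maximum of many Poisson counts) and bin-alignment noise; matched blocks
of ≈ ±1σ make the estimate a direct population ratio with ln-noise below
2% at the validation sample size (10⁵ points, 60×60 bins).

## Synthetic generators (what they do and do not emulate)

* `gaussian_work_windows`: forward work N(ΔG + σ²/2kT, σ), reverse work
  N(−ΔG + σ²/2kT, σ).  This pair satisfies the Crooks fluctuation
  theorem P_F(W)/P_R(−W) = e^((W−ΔG)/kT) identically, so the implied
  state pair has exact free energy difference ΔG — a closed-form oracle
  for BAR.  Defaults σ = 1 kcal/mol, n = 10⁴ per direction.
* `two_basin_cv`: two isotropic 2-D Gaussians at (1.10, 0.15) and
  (1.30, 0.45) nm with σ = 0.02 nm and populations 0.8/0.2 — Rg/RMSD
  scales realistic for a small helical domain, basins separated far
  beyond the 3σ identifiability limit (a warning fires below it).  Exact
  gap: −kT ln(p₂/p₁).
* `toy_structures`: reference under random proper rotations +
  translations, plus optional per-atom displacement of fixed magnitude d
  in random directions; superposed RMSD → d at large N.

All generators take explicit seeds and never touch global random state.
They emulate equilibrium sample statistics only: no autocorrelation, no
anharmonicity, no water or force-field structure.  Passing tests
therefore demonstrate estimator correctness on clean equilibrium input,
not robustness to correlated or poorly converged MD data.

## Benchmark tables

Two bundled CSVs hold the published benchmark values: 5 MDMX complexes
(IC50, ΔG_calculated, ΔG_experimental) and 14 MDM2 complexes (IC50/Ki,
ΔG_calculated, ΔG_correction, ΔG_experimental).  IC50 and Ki are both
converted as Kd surrogates, ΔG = RT ln(c/1 M) at 298 K.  Metric
reproduction uses the tables' rounded inputs, so metric checks carry
±0.01–0.02 absolute tolerance.  Two caveats surfaced by direct
enumeration: the corrected-column entries for WK298 and 3TJ2 differ from
ΔG_calculated + ΔG_correction by small rounding slips (the package
always uses the exact sum), and the number of corrected predictions
within 2 kcal/mol of experiment enumerates to 9/14, not the sometimes
quoted 11/14.  The corrected Pearson computed from rounded table values
is 0.435.

## Problem sizes in validation

The validation suite and `scripts/acceptance.py` use n = 10⁴ samples per
BAR window (6 replicates per grid point for bias), 10⁵ points for the
landscape gap, and 20 independent end-to-end cycles of 10 windows at
n = 2000 — sizes at which the stochastic error of each check is several
times smaller than its tolerance.  The whole acceptance run completes in
seconds.

## Known limitations

* No MBAR/multi-state estimation and no automatic equilibration or
  decorrelation detection.
* The FEL correction inherits the landscape's zero-point convention and
  its histogram resolution; corrections read from sparsely sampled
  landscapes are only as good as the apo sampling.
* The stiff-limit Boresch form carries the O(RT σ_θ²) Jacobian error
  quantified above; use the quadrature for soft restraints.
* Binary trajectory formats are not read; conversion to the text dialects
  is expected upstream.
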