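# felbind

Analysis toolkit for **absolute binding free energy (ABFE) calculations on
flexible protein–ligand systems**, with a free-energy-landscape (FEL)
correction for receptors whose apo state is undersampled.

Alchemical double-decoupling gives the standard binding free energy from
three legs of a non-physical thermodynamic cycle:

```
ΔG°_binding = −ΔG_prot(elec+vdw+restr) + ΔG_solv(elec+vdw) + ΔG_restr_on(solv)
```

where the two decoupling legs come from per-λ-window Hamiltonian-difference
samples via the Bennett acceptance ratio (BAR), and the last term is the
analytic standard-state cost of the six-point (Boresch-style) restraint.
For a highly flexible receptor such as MDM2, the apo protein stays
kinetically trapped near the holo conformation on the simulation
timescale, so the raw estimate systematically overbinds.  The correction
implemented here maps the end-state conformations of the decoupling run
onto a 2-D free energy landscape of the apo protein over
(radius of gyration, RMSD),

```
G(bin) = −kT ln( count(bin) / max_count ),
ΔG_correction = ⟨ G(Rg_i, RMSD_i) ⟩ over extracted end-state conformations,
ΔG_corrected  = ΔG_calculated + ΔG_correction,
```

i.e. the free-energy cost of the trapped apo state relative to the apo
global minimum is paid back to the estimate.

The package covers everything downstream of the MD engine: BAR pair/chain
estimation with bootstrap errors, the Boresch closed form plus a
quadrature oracle, λ-schedule handling and cycle assembly, mass-weighted
Rg and Kabsch RMSD collective variables, FEL construction/lookup/
correction, IC50/Ki → ΔG conversion, and benchmark metrics
(MAE/RMSE/Pearson/Spearman).  Bundled datasets hold the two published
benchmark tables: 5 MDMX complexes and 14 MDM2 complexes with
experimental affinities.  Synthetic generators with exact ground truth
(Crooks-consistent Gaussian work, two-basin CV mixtures, rigid-motion toy
structures) validate every estimator without any MD data.

## Worked example

Evaluate the flexible-receptor benchmark before and after the landscape
correction:

```
$ felbind evaluate --dataset src/felbind/data/mdm2_benchmark.csv
n        = 14
MAE      = 3.077 kcal/mol
RMSE     = 3.808 kcal/mol
Pearson  = 0.389
Spearman = 0.314
within 2 kcal/mol: 7/14

$ felbind evaluate --dataset src/felbind/data/mdm2_benchmark.csv --corrected
n        = 14
MAE      = 1.953 kcal/mol
RMSE     = 2.838 kcal/mol
Pearson  = 0.435
Spearman = 0.345
within 2 kcal/mol: 9/14
```

The raw alchemical estimates overbind MDM2 by 3.1 kcal/mol on average;
adding the apo-landscape correction (≈ 1.0–1.7 kcal/mol per complex)
cuts the mean absolute error to 1.95 kcal/mol and improves both rank
correlations.

The same from Python, for a single complex:

```python
import felbind as fb

recs = fb.load_mdm2()
r = recs[0]                                   # 6GGN, IC50 = 0.08 nM
dg, err = fb.apply_correction(r.dg_calculated, r.dg_correction)
print(dg)                                     # -16.01
print(fb.dg_from_affinity(0.08, "nM"))        # -13.7677...
```

A full synthetic ABFE cycle with known answer:

```python
import numpy as np
import felbind as fb
from felbind.synthetic import gaussian_work_windows

prot = fb.bar_chain(gaussian_work_windows([1.5, 2.0, 1.0], n=10_000, seed=1))
solv = fb.bar_chain(gaussian_work_windows([1.0, 1.5], n=10_000, seed=2))
rest = fb.BoreschRestraint(r0=0.3, thetaA0=np.pi/2, thetaB0=np.pi/2,
                           k_r=1000, k_thetaA=10, k_thetaB=10,
                           k_phiA=10, k_phiB=10, k_phiC=10)
dg, _ = fb.assemble_binding_dg(
    fb.CycleLegs(prot.dg, solv.dg, fb.boresch_dg(rest)))
# designed: -(1.5+2.0+1.0) + (1.0+1.5) + 7.4334 = 5.4334; dg ≈ 5.43
```

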