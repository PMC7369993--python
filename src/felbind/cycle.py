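"""Thermodynamic-cycle assembly for absolute binding free energies.

The non-physical cycle decouples the ligand twice: from solution
(electrostatics first, then van der Waals) and from the restrained complex
(restraints switched on over a bonded-λ leg, then elec + vdW off).  The
standard binding free energy combines the two decoupling legs with the
analytic restraint term:

    dG_binding = -dG_prot(elec+vdw+restr) + dG_solv(elec+vdw) + dG_restr_on(solv)

Both decoupling legs are reported as the free energy of turning the
interactions OFF, so the equation applies with the signs as written.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LambdaSchedule",
    "CycleLegs",
    "COULOMB_LAMBDAS",
    "VDW_LAMBDAS",
    "BONDED_LAMBDAS",
    "default_schedules",
    "assemble_binding_dg",
    "validate_schedule",
]

# Coulomb switched off in uniform steps of 0.25; vdW on a non-uniform grid
# refined near full coupling; restraints grown on a bonded-λ leg (complex only).
COULOMB_LAMBDAS = (0.0, 0.25, 0.5, 0.75, 1.0)
VDW_LAMBDAS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.65,
               0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0)
BONDED_LAMBDAS = (0.01, 0.025, 0.05, 0.075, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0)


@dataclass
class LambdaSchedule:
    """Per-interaction λ window lists for one leg of the cycle."""

    coulomb: tuple[float, ...] = ()
    vdw: tuple[float, ...] = ()
    bonded: tuple[float, ...] = ()

    @property
    def n_windows(self) -> int:
        return len(self.coulomb) + len(self.vdw) + len(self.bonded)


@dataclass
class CycleLegs:
    """Free energies of the three legs, kcal/mol (decoupling = OFF direction)."""

    dg_prot_decouple: float
    dg_solv_decouple: float
    dg_restr_on_solv: float
    stderr_prot: float | None = None
    stderr_solv: float | None = None


def default_schedules() -> tuple[LambdaSchedule, LambdaSchedule]:
    """(solution, complex) schedules: 5 + 15 = 20 and 5 + 15 + 10 = 30 windows."""
    solution = LambdaSchedule(coulomb=COULOMB_LAMBDAS, vdw=VDW_LAMBDAS)
    complex_ = LambdaSchedule(coulomb=COULOMB_LAMBDAS, vdw=VDW_LAMBDAS,
                              bonded=BONDED_LAMBDAS)
    return solution, complex_


def assemble_binding_dg(legs: CycleLegs) -> tuple[float, float | None]:
    """Standard binding free energy and quadrature-combined uncertainty."""
    dg = -legs.dg_prot_decouple + legs.dg_solv_decouple + legs.dg_restr_on_solv
    errs = [e for e in (legs.stderr_prot, legs.stderr_solv) if e is not None]
    stderr = float(np.sqrt(sum(e * e for e in errs))) if errs else None
    return float(dg), stderr


@dataclass
class ScheduleReport:
    valid: bool
    n_windows: int
    issues: list[str] = field(default_factory=list)


def validate_schedule(s: LambdaSchedule) -> ScheduleReport:
    """Flag non-monotone, duplicated or out-of-range λ values per leg."""
    issues: list[str] = []
    for name, lams in (("coulomb", s.coulomb), ("vdw", s.vdw), ("bonded", s.bonded)):
        arr = np.asarray(lams, dtype=float)
        if arr.size == 0:
            continue
        if np.any((arr < 0) | (arr > 1)):
            issues.append(f"{name}: λ outside [0, 1]")
        if np.any(np.diff(arr) == 0):
            issues.append(f"{name}: duplicated λ value")
        elif np.any(np.diff(arr) < 0):
            issues.append(f"{name}: non-monotone λ sequence")
        if arr.size and arr[-1] != 1.0:
            issues.append(f"{name}: schedule does not end at λ = 1")
    return ScheduleReport(valid=not issues, n_windows=s.n_windows, issues=issues)
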