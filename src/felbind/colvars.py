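"""Collective variables: mass-weighted radius of gyration and Kabsch RMSD.

Both CVs are computed on whatever atom set the caller provides; selection
(backbone, residue range, ...) belongs to input preparation, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "Structure",
    "CVSample",
    "radius_of_gyration",
    "kabsch_rotation",
    "kabsch_rmsd",
    "cv_timeseries",
]


@dataclass
class Structure:
    """Coordinates (N x 3, nm) and per-atom masses (amu)."""

    coords: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(f"coords must be N x 3, got {self.coords.shape}")
        if self.coords.shape[0] == 0:
            raise ValidationError("structure has zero atoms")
        if self.masses.shape[0] != self.coords.shape[0]:
            raise ValidationError("masses and coords disagree on atom count")
        if np.any(self.masses <= 0):
            raise ValidationError("all masses must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def center_of_mass(self) -> np.ndarray:
        return np.average(self.coords, axis=0, weights=self.masses)


@dataclass(frozen=True)
class CVSample:
    """One point of the (Rg, RMSD) collective-variable time series."""

    time: float  # ps
    rg: float    # nm
    rmsd: float  # nm

    def __post_init__(self) -> None:
        if self.rg < 0 or self.rmsd < 0:
            raise ValidationError("rg and rmsd must be non-negative")


def radius_of_gyration(s: Structure) -> float:
    """Mass-weighted radius of gyration, nm.

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i ).
    """
    d = s.coords - s.center_of_mass()
    return float(np.sqrt(np.average(np.einsum("ij,ij->i", d, d), weights=s.masses)))


def kabsch_rotation(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Optimal proper rotation (3x3) aligning centred mobile onto centred reference.

    SVD of the weighted covariance; the smallest singular direction is
    sign-flipped when the raw optimum is a reflection, so det(U) = +1 always.
    """
    cov = (weights[:, None] * mobile).T @ reference
    v, _, wt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(v @ wt))
    flip = np.diag([1.0, 1.0, d])
    return v @ flip @ wt


def kabsch_rmsd(
    mobile: Structure,
    reference: Structure,
    fit_weights: str = "mass",
    rmsd_weights: str = "uniform",
) -> float:
    """Minimum RMSD (nm) over rigid rotations and translations.

    The superposition fit is mass-weighted by default and the deviation is
    unweighted, mirroring the common trajectory-tool convention; both can
    be switched to ``"mass"`` or ``"uniform"`` independently.
    """
    if mobile.n_atoms != reference.n_atoms:
        raise ValidationError(
            f"atom count mismatch: {mobile.n_atoms} vs {reference.n_atoms}"
        )

    def _w(kind: str, s: Structure) -> np.ndarray:
        if kind == "mass":
            return s.masses / s.masses.sum()
        if kind == "uniform":
            return np.full(s.n_atoms, 1.0 / s.n_atoms)
        raise ValidationError(f"unknown weighting {kind!r}")

    wf = _w(fit_weights, mobile)
    x = mobile.coords - np.average(mobile.coords, axis=0, weights=wf)
    y = reference.coords - np.average(reference.coords, axis=0, weights=wf)
    rot = kabsch_rotation(x, y, wf)
    diff = x @ rot - y
    wd = _w(rmsd_weights, mobile)
    msd = float(np.sum(wd * np.einsum("ij,ij->i", diff, diff)))
    return float(np.sqrt(max(msd, 0.0)))


def cv_timeseries(
    frames: list[Structure],
    reference: Structure,
    dt: float = 10.0,
    t0: float = 0.0,
    fit_weights: str = "mass",
    rmsd_weights: str = "uniform",
) -> list[CVSample]:
    """Rg and RMSD-to-reference for every frame, time-stamped every ``dt`` ps."""
    out: list[CVSample] = []
    for i, frame in enumerate(frames):
        if frame.n_atoms != reference.n_atoms:
            raise ValidationError(
                f"frame {i} has {frame.n_atoms} atoms, reference has "
                f"{reference.n_atoms}"
            )
        out.append(
            CVSample(
                time=t0 + i * dt,
                rg=radius_of_gyration(frame),
                rmsd=kabsch_rmsd(frame, reference, fit_weights, rmsd_weights),
            )
        )
    return out
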