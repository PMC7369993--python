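"""Ground-truth data generators for validating the estimators.

Three generators stand in for the MD outputs the analysis normally
consumes, each with an exactly known answer:

* ``gaussian_work_windows`` — per-window Hamiltonian-difference samples
  drawn from a Crooks-fluctuation-theorem-consistent pair of Gaussians.
  If forward work is N(dG + s^2/(2 kT), s) and reverse work is
  N(-dG + s^2/(2 kT), s), the Crooks relation
  P_F(W) / P_R(-W) = exp((W - dG)/kT) holds identically, so the exact
  free-energy difference of the implied state pair is dG by construction.
* ``two_basin_cv`` — a two-component 2-D Gaussian mixture in (Rg, RMSD)
  whose inter-basin free-energy gap is exactly -kT ln(p2/p1).
* ``toy_structures`` — a reference structure under known rigid motions
  plus controlled per-atom noise with analytically known RMSD.

All generators take explicit integer seeds; none touch global state.
They emulate equilibrium sample statistics only — no autocorrelation,
force fields or water.
"""

from __future__ import annotations

import warnings

import numpy as np

from .bar import WindowSamples
from .colvars import CVSample, Structure
from .errors import ValidationError
from .units import kT as _kT

__all__ = [
    "gaussian_work_windows",
    "two_basin_cv",
    "toy_structures",
    "random_rotation",
]


def gaussian_work_windows(
    dg_true: list[float] | float,
    sigma: float = 1.0,
    n: int = 10_000,
    temperature: float = 298.0,
    seed: int = 0,
) -> list[WindowSamples]:
    """Crooks-consistent Gaussian work samples, one window per dG value.

    Window boundaries are spread evenly over λ in [0, 1].  The exact
    free-energy difference of window i is ``dg_true[i]``; the chain total
    is their sum.
    """
    dgs = np.atleast_1d(np.asarray(dg_true, dtype=float))
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if n < 1:
        raise ValidationError("n must be >= 1")
    kT = _kT(temperature)
    rng = np.random.default_rng(seed)
    lams = np.linspace(0.0, 1.0, len(dgs) + 1)
    shift = sigma**2 / (2.0 * kT)
    windows = []
    for i, dg in enumerate(dgs):
        windows.append(
            WindowSamples(
                lambda_j=lams[i],
                lambda_k=lams[i + 1],
                du_forward=rng.normal(dg + shift, sigma, n),
                du_reverse=rng.normal(-dg + shift, sigma, n),
                temperature=temperature,
            )
        )
    return windows


def two_basin_cv(
    centers=((1.10, 0.15), (1.30, 0.45)),
    sigmas=(0.02, 0.02),
    populations=(0.8, 0.2),
    n: int = 100_000,
    dt: float = 10.0,
    seed: int = 0,
) -> list[CVSample]:
    """Mixture of two isotropic 2-D Gaussians in (Rg, RMSD), nm.

    Exact inter-basin free-energy gap: -kT ln(p2 / p1).  Basins closer
    than 3 combined sigma trigger a warning because the gap is then no
    longer identifiable from histogram minima.
    """
    p = np.asarray(populations, dtype=float)
    if p.shape != (2,) or np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
        raise ValidationError("populations must be two positive numbers summing to 1")
    c = np.asarray(centers, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    sep = np.linalg.norm(c[0] - c[1])
    if sep < 3.0 * (s[0] + s[1]):
        warnings.warn(
            "basins closer than 3 sigma: free-energy gap not identifiable "
            "from histogram minima", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    which = rng.random(n) < p[1]
    pts = np.where(which[:, None],
                   rng.normal(c[1], s[1], (n, 2)),
                   rng.normal(c[0], s[0], (n, 2)))
    pts = np.abs(pts)  # Rg and RMSD are non-negative by definition
    return [CVSample(time=i * dt, rg=float(x), rmsd=float(y))
            for i, (x, y) in enumerate(pts)]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def toy_structures(
    n_atoms: int = 100,
    n_frames: int = 5,
    displacement: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, list[Structure], list[float]]:
    """Reference structure plus frames under known rigid motion and noise.

    Each frame is the reference rotated and translated at random, with
    every atom additionally displaced by exactly ``displacement`` nm along
    an independent random direction.  Because the displacements are
    isotropic and independent of the rigid motion, the minimum RMSD after
    superposition approaches ``displacement`` for large N; the returned
    ``known_rmsd`` carries that construction value per frame.
    """
    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, 0.5, (n_atoms, 3))
    masses = rng.uniform(1.0, 16.0, n_atoms)
    reference = Structure(coords=coords, masses=masses)
    frames, known = [], []
    for _ in range(n_frames):
        rot = random_rotation(rng)
        trans = rng.normal(0.0, 1.0, 3)
        moved = coords @ rot.T + trans
        if displacement > 0:
            dirs = rng.normal(size=(n_atoms, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            moved = moved + displacement * dirs
        frames.append(Structure(coords=moved, masses=masses.copy()))
        known.append(float(displacement))
    return reference, frames, known
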