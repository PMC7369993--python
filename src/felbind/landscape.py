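"""2-D free energy landscape over (Rg, RMSD) and the end-state correction term.

The landscape is the raw population histogram of an apo-state
collective-variable series converted to relative Gibbs energies,

    G(bin) = -kT ln( count(bin) / max_count ),

so the most populated bin sits at G = 0 and every occupied bin carries a
non-negative value; unoccupied bins carry no value at all.  The correction
term for one complex is the mean landscape value at the (Rg, RMSD)
positions of conformations extracted from the end of the decoupling run:
if those conformations sit in the global apo basin the correction is zero,
and if the protein stayed trapped in a higher-lying state the correction
is the positive free-energy cost of that trapping, which is then added to
the raw alchemical estimate:

    dG_corrected = dG_calculated + dG_correction.

The zero point of the landscape (global minimum) matters: the correction
is defined relative to the minimum-free-energy apo state, so a different
normalisation convention would shift every correction by a constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .colvars import CVSample
from .errors import EmptyInputError, OutOfLandscapeError, ValidationError

__all__ = [
    "FELGrid",
    "CorrectionResult",
    "build_fel",
    "basin_gap",
    "lookup",
    "correction_term",
    "apply_correction",
    "tail_conformations",
]

logger = logging.getLogger(__name__)


@dataclass
class FELGrid:
    """Binned free-energy surface; ``g`` is NaN on unoccupied bins."""

    rg_edges: np.ndarray
    rmsd_edges: np.ndarray
    g: np.ndarray          # (n_rg, n_rmsd), kcal/mol, NaN where empty
    kT: float
    n_samples: int
    counts: np.ndarray = field(repr=False, default=None)

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.g)


def build_fel(
    samples: list[CVSample] | np.ndarray,
    n_bins: tuple[int, int] = (100, 100),
    kT: float = 0.5922,
    pad_bins: int = 1,
) -> FELGrid:
    """Histogram a CV series into a relative Gibbs free-energy surface.

    ``samples`` may be CVSample objects or an (n, 2) array of (rg, rmsd).
    The grid spans the sample range padded by ``pad_bins`` bin widths on
    each side.  Bins with zero counts are flagged (NaN), never zero.
    """
    pts = _as_points(samples)
    if pts.shape[0] == 0:
        raise EmptyInputError("no CV samples")
    if kT <= 0:
        raise ValidationError("kT must be positive")
    nx, ny = n_bins
    if nx < 2 or ny < 2:
        raise ValidationError("need at least 2 bins per axis")

    edges = []
    for axis, n in ((0, nx), (1, ny)):
        lo, hi = pts[:, axis].min(), pts[:, axis].max()
        if hi == lo:  # degenerate axis: give the single value a finite bin
            hi = lo + 1e-9
        width = (hi - lo) / n
        edges.append(np.linspace(lo - pad_bins * width, hi + pad_bins * width,
                                 n + 2 * pad_bins + 1))
    counts, rg_edges, rmsd_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=edges
    )
    g = np.full_like(counts, np.nan)
    occ = counts > 0
    g[occ] = -kT * np.log(counts[occ] / counts.max())
    return FELGrid(rg_edges=rg_edges, rmsd_edges=rmsd_edges, g=g, kT=kT,
                   n_samples=pts.shape[0], counts=counts)


def _as_points(samples) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        return np.atleast_2d(samples.astype(float))
    return np.array([[s.rg, s.rmsd] for s in samples], dtype=float)


def _bin_index(edges: np.ndarray, x: float) -> int:
    """Bin of x, clipped into range; -1 when x lies outside the grid."""
    if x < edges[0] or x > edges[-1]:
        return -1
    return int(min(np.searchsorted(edges, x, side="right") - 1, len(edges) - 2))


def lookup(fel: FELGrid, cv: CVSample, policy: str = "nearest_occupied") -> float:
    """Free energy (kcal/mol) of the bin containing a CV point.

    Empty or out-of-grid bins are resolved per ``policy``: the nearest
    occupied bin by Euclidean bin-index distance (with a logged warning),
    or an :class:`OutOfLandscapeError`.
    """
    if policy not in ("nearest_occupied", "error"):
        raise ValidationError(f"unknown lookup policy {policy!r}")
    i = _bin_index(fel.rg_edges, cv.rg)
    j = _bin_index(fel.rmsd_edges, cv.rmsd)
    if i >= 0 and j >= 0 and not math.isnan(fel.g[i, j]):
        return float(fel.g[i, j])
    if policy == "error":
        raise OutOfLandscapeError(
            f"CV point (rg={cv.rg}, rmsd={cv.rmsd}) falls in an empty or "
            f"out-of-grid bin"
        )
    # clip out-of-grid points onto the edge bins before the nearest search
    ic = i if i >= 0 else int(np.clip(
        np.searchsorted(fel.rg_edges, cv.rg) - 1, 0, fel.g.shape[0] - 1))
    jc = j if j >= 0 else int(np.clip(
        np.searchsorted(fel.rmsd_edges, cv.rmsd) - 1, 0, fel.g.shape[1] - 1))
    occ = np.argwhere(fel.occupied)
    if occ.shape[0] == 0:
        raise EmptyInputError("landscape has no occupied bins")
    d2 = (occ[:, 0] - ic) ** 2 + (occ[:, 1] - jc) ** 2
    bi, bj = occ[np.argmin(d2)]
    logger.warning(
        "CV point (rg=%.4f, rmsd=%.4f) in empty/outside bin (%d, %d); "
        "using nearest occupied bin (%d, %d)", cv.rg, cv.rmsd, ic, jc, bi, bj,
    )
    return float(fel.g[bi, bj])


def basin_gap(
    fel: FELGrid, minimum_a: CVSample, minimum_b: CVSample, halfwidth: int = 2
) -> float:
    """Free-energy gap (kcal/mol) between two basin minima, b relative to a.

    Counts are summed over a (2*halfwidth+1)^2 bin block centred on each
    minimum and the gap is -kT ln of the ratio.  Matched blocks make the
    estimate insensitive to how either minimum aligns with the bin grid
    and to the single-bin extreme-value bias of reading off raw minima of
    g; for basins of equal shape the block-count ratio estimates the
    population ratio of the two minima directly.
    """
    if fel.counts is None:
        raise ValidationError("landscape carries no counts")

    def _block(cv: CVSample) -> float:
        i = _bin_index(fel.rg_edges, cv.rg)
        j = _bin_index(fel.rmsd_edges, cv.rmsd)
        if i < 0 or j < 0:
            raise OutOfLandscapeError(
                f"basin minimum (rg={cv.rg}, rmsd={cv.rmsd}) outside the grid"
            )
        total = fel.counts[max(i - halfwidth, 0):i + halfwidth + 1,
                           max(j - halfwidth, 0):j + halfwidth + 1].sum()
        if total == 0:
            raise EmptyInputError("no samples near the stated basin minimum")
        return float(total)

    return float(-fel.kT * np.log(_block(minimum_b) / _block(minimum_a)))


@dataclass
class CorrectionResult:
    """Mean landscape free energy of the end-state conformations."""

    mean: float
    sem: float
    per_conformation: list[float]


def correction_term(
    fel: FELGrid, confs: list[CVSample], policy: str = "nearest_occupied"
) -> CorrectionResult:
    """Average landscape value over extracted conformations, with SEM."""
    if not confs:
        raise EmptyInputError("no conformations given")
    vals = [lookup(fel, c, policy=policy) for c in confs]
    n = len(vals)
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return CorrectionResult(mean=mean, sem=sem, per_conformation=vals)


def apply_correction(
    dg_calculated: float,
    corr: CorrectionResult | float,
    dg_stderr: float | None = None,
) -> tuple[float, float | None]:
    """dG_corrected = dG_calculated + correction mean.

    Returns ``(dg_corrected, stderr)``; the uncertainty combines the
    alchemical stderr and the correction SEM in quadrature when both are
    available.
    """
    if isinstance(corr, CorrectionResult):
        mean, sem = corr.mean, corr.sem
    else:
        mean, sem = float(corr), None
    dg = dg_calculated + mean
    if dg_stderr is None and sem is None:
        return dg, None
    parts = [x for x in (dg_stderr, sem) if x is not None]
    return dg, float(np.sqrt(sum(x * x for x in parts)))


def tail_conformations(
    samples: list[CVSample], n: int = 5, window: float = 100.0
) -> list[CVSample]:
    """Evenly strided selection of ``n`` samples from the last ``window`` ps.

    Mirrors the extraction protocol for end-state conformations: take the
    tail of the per-window CV series and pick ``n`` evenly spaced frames.
    """
    if not samples:
        raise EmptyInputError("no samples")
    t_end = samples[-1].time
    tail = [s for s in samples if s.time >= t_end - window]
    if len(tail) <= n:
        return tail
    idx = np.linspace(0, len(tail) - 1, n).round().astype(int)
    return [tail[i] for i in idx]
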