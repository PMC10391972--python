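"""Dual-isotope probabilistic assignment to origin.

For each individual feather with measured (δ²H_f, δ¹³C_f), every raster
cell x of the feather isoscapes is a candidate molt origin with bivariate
normal likelihood

    f(y | μ(x), Σ) = (2π)^{-1} |Σ|^{-1/2} exp(-½ (y-μ(x))ᵀ Σ⁻¹ (y-μ(x)))

where μ(x) = (μ_H(x), μ_C(x)) comes from the isoscape means and
Σ = [[σ_H², ρσ_Hσ_C], [ρσ_Hσ_C, σ_C²]].  The two isoscapes are governed by
different bioclimatic processes and are treated as independent by default
(ρ = 0).  Likelihoods are normalized to sum to one over the valid
(range-constrained) cells, giving a spatially explicit probability surface
of origin.

A surface is then binarized with a 2:1 odds-ratio rule: the smallest set of
highest-probability cells whose cumulative probability reaches the odds
level (default 2/3 ≈ 66.7%) is coded 1 ("potential origin"), everything
else 0.  Binary surfaces are summed across individuals of a population to
map where that population's members could plausibly have molted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .feathers import FeatherRecord
from .isoscape import Isoscape
from .raster import RasterGrid

__all__ = [
    "CovarianceSpec",
    "AssignmentSurface",
    "ODDS_LEVEL",
    "mvn_density_surface",
    "binarize_odds",
    "stack_binaries",
    "assign_population",
]

#: Default odds-ratio level: 2:1 odds, i.e. ≥ 66.7% cumulative probability.
ODDS_LEVEL = 2.0 / 3.0


@dataclass(frozen=True)
class CovarianceSpec:
    """Assignment covariance: per-isotope SDs (‰) and their correlation."""

    sd_h: float
    sd_c: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sd_h > 0 and self.sd_c > 0):
            raise ValueError("sd_h and sd_c must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1 for a positive-definite covariance")

    @property
    def matrix(self) -> np.ndarray:
        off = self.rho * self.sd_h * self.sd_c
        return np.array([[self.sd_h**2, off], [off, self.sd_c**2]])


@dataclass
class AssignmentSurface:
    """One individual's normalized origin-probability surface.

    ``prob`` sums to 1 over valid cells; ``binary`` (if set) is 0/1 on the
    same geometry, nonzero only on valid cells.
    """

    prob: RasterGrid
    individual_id: str
    binary: RasterGrid | None = None

    def __post_init__(self) -> None:
        p = self.prob.values[self.prob.mask]
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-9:
            raise ValueError("probability surface must sum to 1 over valid cells")


def mvn_density_surface(
    record: FeatherRecord,
    h_iso: Isoscape,
    c_iso: Isoscape,
    cov: CovarianceSpec | None = None,
) -> AssignmentSurface:
    """Evaluate the bivariate-normal origin likelihood for one individual.

    If ``cov`` is None, the SDs attached to the isoscapes are used with
    ρ = 0; a scalar ``CovarianceSpec`` overrides both.  The result is
    normalized over the shared valid cells.
    """
    if record.d2h_f is None or record.d13c_f is None:
        raise ValueError(f"record {record.id!r} must have both d2h_f and d13c_f")
    h_iso.mean.require_same_geometry(c_iso.mean)

    mask = h_iso.mean.mask & c_iso.mean.mask
    if not mask.any():
        raise ValueError("no valid cells shared by the two isoscapes")

    if cov is not None:
        sd_h = np.full(mask.shape, cov.sd_h)
        sd_c = np.full(mask.shape, cov.sd_c)
        rho = cov.rho
    else:
        sd_h = h_iso.sd_array()
        sd_c = c_iso.sd_array()
        rho = 0.0

    dh = (record.d2h_f - h_iso.mean.values[mask]) / sd_h[mask]
    dc = (record.d13c_f - c_iso.mean.values[mask]) / sd_c[mask]
    one_m_r2 = 1.0 - rho**2
    # standard bivariate normal density via the standardized quadratic form
    quad = (dh**2 - 2.0 * rho * dh * dc + dc**2) / one_m_r2
    log_norm = -np.log(2.0 * np.pi * sd_h[mask] * sd_c[mask] * np.sqrt(one_m_r2))
    logdens = log_norm - 0.5 * quad
    # normalize in a numerically safe way (subtract max before exp)
    dens = np.exp(logdens - logdens.max())
    dens /= dens.sum()

    values = np.zeros(mask.shape)
    values[mask] = dens
    prob = RasterGrid(
        values=values, mask=mask,
        origin_x=h_iso.mean.origin_x, origin_y=h_iso.mean.origin_y,
        cell_size=h_iso.mean.cell_size,
    )
    return AssignmentSurface(prob=prob, individual_id=record.id)


def binarize_odds(surface: AssignmentSurface, level: float = ODDS_LEVEL) -> AssignmentSurface:
    """Binarize a surface at an odds level: the minimal top-probability set.

    Valid cells are ranked by descending probability (ties broken by
    row-major cell index, so results are reproducible) and included until
    the cumulative probability first reaches ``level``; those cells become
    1, all other valid cells 0.  The returned surface shares ``prob`` and
    carries the binary grid.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"odds level must be in (0, 1), got {level}")
    prob = surface.prob
    flat_idx = np.flatnonzero(prob.mask.ravel())
    p = prob.values.ravel()[flat_idx]
    order = np.lexsort((flat_idx, -p))  # descending p, then ascending index
    csum = np.cumsum(p[order])
    # first position where cumulative mass reaches the level
    n_keep = int(np.searchsorted(csum, level - 1e-12)) + 1
    n_keep = min(n_keep, len(order))
    keep = flat_idx[order[:n_keep]]
    binary_values = np.zeros(prob.shape)
    binary_values.ravel()[keep] = 1.0
    binary = prob.copy_with(values=binary_values)
    return AssignmentSurface(prob=prob, individual_id=surface.individual_id, binary=binary)


def stack_binaries(surfaces: Sequence[AssignmentSurface]) -> RasterGrid:
    """Sum binary origin surfaces into a per-cell count raster."""
    if len(surfaces) == 0:
        raise ValueError("stack_binaries requires at least one surface")
    first = surfaces[0]
    if first.binary is None:
        raise ValueError("surfaces must be binarized before stacking")
    total = np.zeros(first.binary.shape)
    for s in surfaces:
        if s.binary is None:
            raise ValueError(f"surface {s.individual_id!r} has no binary grid")
        first.binary.require_same_geometry(s.binary)
        total += np.nan_to_num(s.binary.values, nan=0.0)
    mask = first.binary.mask.copy()
    for s in surfaces[1:]:
        mask |= s.binary.mask
    return first.binary.copy_with(values=total, mask=mask)


def assign_population(
    records: Iterable[FeatherRecord],
    h_iso: Isoscape,
    c_iso: Isoscape,
    cov: CovarianceSpec | None = None,
    level: float = ODDS_LEVEL,
) -> tuple[dict[str, AssignmentSurface], dict[str, RasterGrid]]:
    """Assign every record and stack binaries per population.

    Returns ``(surfaces, stacks)``: surfaces keyed by individual id (each
    binarized at ``level``), stacks keyed by population label.  Records are
    expected to be outlier-filtered and population-grouped already.
    """
    surfaces: dict[str, AssignmentSurface] = {}
    by_pop: dict[str, list[AssignmentSurface]] = {}
    for rec in records:
        surf = binarize_odds(mvn_density_surface(rec, h_iso, c_iso, cov), level)
        surfaces[rec.id] = surf
        by_pop.setdefault(rec.population, []).append(surf)
    stacks = {pop: stack_binaries(surfs) for pop, surfs in by_pop.items()}
    return surfaces, stacks
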