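"""The optical core: Kd490 -> KdPAR -> seabed irradiance -> percent PAR.

The broadband diffuse attenuation coefficient for PAR is derived from the
490 nm satellite product by the empirical polynomial

    KdPAR = a + b * Kd490 - c / Kd490        [m^-1]

with default coefficients a=0.0665, b=0.874, c=0.00121.  Surface PAR (a
daily photon dose, mol photons m^-2 day^-1) is then attenuated to the
seabed with Beer's law, Ez = E0 * exp(-KdPAR * z), and expressed as a
percentage of the surface value.  Inverting Beer's law gives the depth of
any target isolume, z = ln(E0 / E) / KdPAR.

The polynomial is negative for very clear water (Kd490 below the positive
root of b*k^2 + a*k - c = 0, about 0.01517 m^-1 with the defaults); such
cells are physically meaningless under this parameterization and are
masked invalid by default (``invalid_policy="mask"``) rather than clamped,
with the count logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .grid import GeoGrid, require_aligned

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OpticalParams:
    """Coefficients of the KdPAR polynomial and the zone's light floor.

    ``e_min`` is the minimum daily photon dose taken to sustain net
    photosynthesis (the zone's lower isolume).  ``invalid_policy`` decides
    what happens where the polynomial would yield KdPAR <= 0: ``"mask"``
    turns the cell to nodata, ``"clamp"`` pins KdPAR to ``clamp_floor``.
    """

    a: float = 0.0665
    b: float = 0.874
    c: float = 0.00121
    e_min: float = 0.0001
    invalid_policy: str = "mask"
    clamp_floor: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.e_min) <= 0:
            raise ValueError("optical parameters must all be positive")
        if self.invalid_policy not in ("mask", "clamp"):
            raise ValueError("invalid_policy must be 'mask' or 'clamp'")

    @property
    def kd490_floor(self) -> float:
        """Kd490 below which the polynomial gives non-positive KdPAR.

        The positive root of b*k**2 + a*k - c = 0 (~0.01517 m^-1 for the
        default coefficients).
        """
        return (-self.a + math.sqrt(self.a**2 + 4 * self.b * self.c)) / (2 * self.b)


def kdpar_from_kd490(kd490, params: OpticalParams = OpticalParams()):
    """Broadband attenuation KdPAR (m^-1) from the 490 nm coefficient.

    Scalar or array input.  Values at or below ``params.kd490_floor`` map to
    NaN under the default mask policy (or to ``clamp_floor`` when clamping);
    non-positive Kd490 is rejected outright.
    """
    k = np.asarray(kd490, dtype=np.float64)
    finite = np.isfinite(k)
    if np.any(finite & (k <= 0)):
        raise ValueError("kd490 must be strictly positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        kdpar = params.a + params.b * k - params.c / k
    bad = finite & (kdpar <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        if params.invalid_policy == "mask":
            kdpar = np.where(bad, np.nan, kdpar)
            logger.info("kdpar_from_kd490: %d cell(s) below the Kd490 floor masked", n_bad)
        else:
            kdpar = np.where(bad, params.clamp_floor, kdpar)
            logger.info("kdpar_from_kd490: %d cell(s) clamped to %.2g", n_bad, params.clamp_floor)
    return kdpar if kdpar.ndim else float(kdpar)


def seabed_irradiance(e0, kdpar, depth):
    """Beer's law: irradiance surviving to depth z, E0 * exp(-KdPAR * z)."""
    e0 = np.asarray(e0, dtype=np.float64)
    kdpar = np.asarray(kdpar, dtype=np.float64)
    depth = np.asarray(depth, dtype=np.float64)
    if np.any(np.isfinite(depth) & (depth < 0)):
        raise ValueError("depth must be non-negative (positive down)")
    ez = e0 * np.exp(-kdpar * depth)
    return ez if ez.ndim else float(ez)


def percent_surface_par(ez, e0):
    """Seabed irradiance as percent of surface PAR, 100 * Ez / E0."""
    ez = np.asarray(ez, dtype=np.float64)
    e0 = np.asarray(e0, dtype=np.float64)
    if np.any(np.isfinite(e0) & (e0 <= 0)):
        raise ValueError("surface PAR must be strictly positive")
    pct = 100.0 * ez / e0
    return pct if pct.ndim else float(pct)


def isolume_depth(e0, kdpar, e_target):
    """Depth of the isolume where irradiance equals ``e_target``.

    ln(E0/E)/KdPAR; where the target exceeds the surface value the isolume
    is notionally above the surface and the depth is reported as 0.
    """
    e0 = np.asarray(e0, dtype=np.float64)
    kdpar = np.asarray(kdpar, dtype=np.float64)
    e_target = np.asarray(e_target, dtype=np.float64)
    if np.any(np.isfinite(e_target) & (e_target <= 0)):
        raise ValueError("target irradiance must be strictly positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.log(e0 / e_target) / kdpar
    above = np.isfinite(z) & (z < 0)
    if np.any(above):
        logger.info("isolume_depth: %d point(s) with target above surface PAR -> depth 0",
                    int(above.sum()))
        z = np.where(above, 0.0, z)
    return z if z.ndim else float(z)


def light_fields(
    kd490: GeoGrid,
    par0: GeoGrid,
    depth: GeoGrid,
    params: OpticalParams = OpticalParams(),
) -> tuple[GeoGrid, GeoGrid, GeoGrid]:
    """Element-wise optics over aligned grids.

    Returns the (kdpar, ez, percent_par) grids.  Nodata is absorbing: a cell
    missing in any input is missing in every output.
    """
    require_aligned(kd490, par0, depth)
    invalid = ~(kd490.valid & par0.valid & depth.valid)
    kd = np.where(invalid, np.nan, kd490.values)
    kdpar_v = kdpar_from_kd490(np.where(np.isfinite(kd), kd, np.nan), params)
    ez_v = seabed_irradiance(
        np.where(invalid, np.nan, par0.values), kdpar_v,
        np.where(invalid, np.nan, depth.values),
    )
    pct_v = percent_surface_par(ez_v, np.where(invalid, np.nan, par0.values))
    # keep outputs mutually consistent: a cell lost to the Kd floor is lost everywhere
    lost = ~np.isfinite(kdpar_v)
    ez_v = np.where(lost, np.nan, ez_v)
    pct_v = np.where(lost, np.nan, pct_v)
    return (
        kd490.like(kdpar_v, role="kdpar"),
        kd490.like(ez_v, role="ez"),
        kd490.like(pct_v, role="percent_par"),
    )
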