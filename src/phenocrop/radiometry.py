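"""Radiometric correction and vegetation index computation.

Converts raw Landsat-style digital numbers (DN) to top-of-atmosphere (TOA)
reflectance, applies image-based dark-object subtraction (DOS) atmospheric
correction with Rayleigh transmittance terms (the "DOS3" variant), and
computes NDVI.  Scenes delivered as surface reflectance (e.g. from a
LEDAPS-style processing chain) bypass correction entirely.

Per band, with gain g and bias b (radiance per DN), earth–sun distance d
(AU), solar zenith theta_z, view zenith theta_v and exo-atmospheric solar
irradiance E_sun:

    radiance        L   = g * DN + b
    TOA reflectance rho = pi * L * d^2 / (E_sun * cos(theta_z))

DOS3 estimates the additive path radiance L_p from the dark-object radiance
L_dark (a low quantile of the positive radiances, assumed to image targets
of ~1 % reflectance):

    tau_r  = 0.008569 * lambda^-4 * (1 + 0.0113 * lambda^-2 + 0.00013 * lambda^-4)
    T_v    = exp(-tau_r / cos(theta_v));  T_z = exp(-tau_r / cos(theta_z))
    L_p    = L_dark - 0.01 * (E_sun * cos(theta_z) * T_z) * T_v / (pi * d^2)
    rho    = pi * (L - L_p) * d^2 / (T_v * E_sun * cos(theta_z) * T_z)

Downwelling diffuse irradiance is taken as zero (Rayleigh-only), the common
simplification of the method.  Corrected reflectance is clipped to [0, 1];
the number of clipped cells is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid

log = logging.getLogger(__name__)

__all__ = [
    "BandCalibration",
    "CalibrationMeta",
    "dn_to_toa",
    "dos_correct",
    "ndvi",
    "compare_corrections",
    "rayleigh_optical_thickness",
]

NDVI_NODATA = -9999.0


@dataclass
class BandCalibration:
    """Per-band calibration: radiance = gain * DN + bias."""

    gain: float
    bias: float
    e_sun: float          # exo-atmospheric solar irradiance, W m-2 um-1
    wavelength_um: float  # band effective wavelength, micrometers

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("calibration gain must be positive")


@dataclass
class CalibrationMeta:
    """Scene-level calibration and geometry metadata."""

    bands: dict[str, BandCalibration]
    solar_zenith_deg: float
    view_zenith_deg: float = 0.0
    earth_sun_distance_au: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.solar_zenith_deg < 90:
            raise ValueError("solar zenith must be in [0, 90) degrees")
        if not self.earth_sun_distance_au > 0:
            raise ValueError("earth-sun distance must be positive")

    def band(self, role: str) -> BandCalibration:
        try:
            return self.bands[role]
        except KeyError:
            raise KeyError(f"no calibration (gain/bias) for band {role!r}") from None

    @property
    def cos_solar_zenith(self) -> float:
        return math.cos(math.radians(self.solar_zenith_deg))

    @property
    def cos_view_zenith(self) -> float:
        return math.cos(math.radians(self.view_zenith_deg))


def rayleigh_optical_thickness(wavelength_um: float) -> float:
    """Rayleigh optical thickness tau_r at the given wavelength (um)."""
    lam = wavelength_um
    return 0.008569 * lam ** -4 * (1 + 0.0113 * lam ** -2 + 0.00013 * lam ** -4)


def _radiance(dn: RasterGrid, cal: BandCalibration) -> np.ndarray:
    return cal.gain * dn.values.astype(float) + cal.bias


def _clip_reflectance(rho: np.ndarray, valid: np.ndarray, label: str) -> np.ndarray:
    neg = int(np.sum((rho < 0) & valid))
    over = int(np.sum((rho > 1) & valid))
    if neg or over:
        log.info("%s: clipped %d negative and %d >1 reflectance cells", label, neg, over)
    return np.clip(rho, 0.0, 1.0)


def dn_to_toa(stack, meta: CalibrationMeta, clip: bool = True):
    """Convert a digital-number band stack to TOA reflectance.

    Returns a new stack with ``value_kind = "toa_reflectance"``.
    """
    from .io_pipeline import BandStack  # local import to avoid a cycle

    if stack.value_kind != "digital_number":
        raise ValueError(f"dn_to_toa expects digital_number input, got {stack.value_kind}")
    mu = meta.cos_solar_zenith
    d2 = meta.earth_sun_distance_au ** 2
    out_bands = {}
    for role, dn in stack.bands.items():
        cal = meta.band(role)
        L = _radiance(dn, cal)
        rho = math.pi * L * d2 / (cal.e_sun * mu)
        valid = dn.mask
        if clip:
            rho = _clip_reflectance(rho, valid, f"dn_to_toa[{role}]")
        rho = np.where(valid, rho, dn.nodata)
        out_bands[role] = dn.like(rho)
    return stack.with_bands(out_bands, value_kind="toa_reflectance",
                            provenance="toa")


def dos_correct(stack, meta: CalibrationMeta, dark_fraction: float = 0.01):
    """Dark-object subtraction (DOS3) from digital numbers to surface reflectance.

    The dark-object radiance per band is the ``dark_fraction`` quantile of
    the positive in-scene radiances; the dark targets are assumed to have
    1 % surface reflectance, and Rayleigh transmittances account for the
    two-way path.  Negative corrected reflectances are clipped to 0.
    """
    if stack.value_kind != "digital_number":
        raise ValueError(f"dos_correct expects digital_number input, got {stack.value_kind}")
    if not 0 < dark_fraction <= 0.05:
        raise ValueError("dark_fraction must be in (0, 0.05]")
    mu_z = meta.cos_solar_zenith
    mu_v = meta.cos_view_zenith
    d2 = meta.earth_sun_distance_au ** 2
    out_bands = {}
    for role, dn in stack.bands.items():
        cal = meta.band(role)
        L = _radiance(dn, cal)
        valid = dn.mask
        positive = L[valid & (L > 0)]
        if positive.size == 0:
            raise ValueError(f"band {role!r} has no positive radiance; cannot "
                             "select a dark object")
        tau = rayleigh_optical_thickness(cal.wavelength_um)
        t_v = math.exp(-tau / mu_v)
        t_z = math.exp(-tau / mu_z)
        direct = cal.e_sun * mu_z * t_z          # ground-reaching direct irradiance
        l_dark = float(np.quantile(positive, dark_fraction))
        l_path = l_dark - 0.01 * direct * t_v / (math.pi * d2)
        rho = math.pi * (L - l_path) * d2 / (t_v * direct)
        rho = _clip_reflectance(rho, valid, f"dos_correct[{role}]")
        rho = np.where(valid, rho, dn.nodata)
        out_bands[role] = dn.like(rho)
    return stack.with_bands(out_bands, value_kind="surface_reflectance",
                            provenance="dos_corrected")


def ndvi(stack) -> RasterGrid:
    """NDVI = (NIR - Red) / (NIR + Red) from a reflectance stack.

    Cells where either band is nodata, or where NIR + Red == 0, are nodata
    in the result.  Cells flagged in the stack's quality mask (cloud, snow,
    haze) are also nodata so that downstream composites skip them.
    """
    for role in ("red", "nir"):
        if role not in stack.bands:
            raise ValueError(f"ndvi requires a {role!r} band")
    if stack.value_kind == "digital_number":
        raise ValueError("ndvi expects reflectance input; correct DN scenes first")
    red = stack.bands["red"]
    nir = stack.bands["nir"]
    red.require_same_geometry(nir, "band")
    r = red.values.astype(float)
    n = nir.values.astype(float)
    denom = n + r
    valid = red.mask & nir.mask & (denom != 0)
    if stack.quality is not None:
        valid &= stack.quality.values == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(valid, (n - r) / np.where(denom == 0, 1.0, denom), NDVI_NODATA)
    return red.like(out, nodata=NDVI_NODATA)


def compare_corrections(a, b) -> float:
    """Mean absolute NDVI difference between two reflectance stacks.

    Used to quantify agreement between alternative atmospheric corrections
    of the same acquisition (e.g. DOS vs an externally processed product).
    """
    ndvi_a = ndvi(a)
    ndvi_b = ndvi(b)
    ndvi_a.require_same_geometry(ndvi_b, "NDVI grid")
    valid = ndvi_a.mask & ndvi_b.mask
    if not valid.any():
        raise ValueError("no jointly valid cells to compare")
    return float(np.mean(np.abs(ndvi_a.values[valid] - ndvi_b.values[valid])))
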