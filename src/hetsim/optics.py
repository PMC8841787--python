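"""Diffraction-limit calculators and numerical PSF/OTF construction.

All lengths are in nanometres and all spatial frequencies in cycles/nm.
The imaging model is 2D, scalar and incoherent: the pupil is a clear disk
of radius NA/lambda in frequency space, the intensity PSF is the squared
modulus of its transform and the OTF is the (normalized) autocorrelation
of the pupil.  DFT arrays use the standard corner-origin layout; use
``numpy.fft.fftshift`` for centred display.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "ResolutionLimits",
    "TransferFunction",
    "abbe_limits",
    "combined_resolution",
    "detection_na_from_sim_resolution",
    "sim_resolution_factor",
    "evanescent_decay_length",
    "make_transfer_function",
    "xz_support_extents",
    "arc_autocorrelation_support",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters shared by the simulator and the calculators.

    Exactly one of ``semiaperture`` (the half-angle alpha, radians) or
    ``na`` (n*sin(alpha), dimensionless) must be given; the other is
    derived.  ``pixel_nm`` is the detector-plane sampling.
    """

    lambda_ill: float
    lambda_em: float
    n_sample: float = 1.33
    semiaperture: float | None = None
    na: float | None = None
    pixel_nm: float = 20.0

    def __post_init__(self) -> None:
        if self.lambda_ill <= 0 or self.lambda_em <= 0:
            raise ValueError("wavelengths must be positive")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if (self.semiaperture is None) == (self.na is None):
            raise ValueError("give exactly one of semiaperture or na")
        if self.semiaperture is not None:
            if not 0.0 < self.semiaperture <= math.pi / 2:
                raise ValueError("semiaperture must lie in (0, pi/2]")
            object.__setattr__(
                self, "na", self.n_sample * math.sin(self.semiaperture)
            )
        else:
            if self.na <= 0:
                raise ValueError("na must be positive")
            if self.na > self.n_sample:
                raise ValueError(
                    f"na={self.na} exceeds n_sample={self.n_sample}: "
                    "n*sin(alpha) cannot exceed n"
                )
            object.__setattr__(
                self, "semiaperture", math.asin(self.na / self.n_sample)
            )

    def wavelength(self, which: str) -> float:
        if which == "illumination":
            return self.lambda_ill
        if which == "emission":
            return self.lambda_em
        raise ValueError("which must be 'illumination' or 'emission'")


@dataclass(frozen=True)
class ResolutionLimits:
    """Closed-form Abbe-type limits, nm (see :func:`abbe_limits`)."""

    d_headon: float
    d_oblique: float
    d_lateral: float
    d_axial: float
    d_farfield: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "d_headon_nm": self.d_headon,
                "d_oblique_nm": self.d_oblique,
                "d_lateral_nm": self.d_lateral,
                "d_axial_nm": self.d_axial,
                "d_farfield_nm": self.d_farfield,
            }
        )


@dataclass
class TransferFunction:
    """Sampled OTF/PSF pair on matched frequency/space grids.

    ``otf`` is normalized so otf[0, 0] == 1 and vanishes (to numerical
    tolerance) beyond ``k_cutoff`` = 2*NA/lambda.  ``psf`` is non-negative
    and sums to 1.
    """

    otf: np.ndarray
    psf: np.ndarray
    k_cutoff: float
    grid_shape: tuple[int, int]
    freq_step: tuple[float, float]
    pixel_nm: float = field(default=0.0)


def abbe_limits(config: OpticalConfig, which_wavelength: str = "emission") -> ResolutionLimits:
    """All five closed-form diffraction limits for one wavelength.

    d_headon   = lambda0 / (n sin a)     transmission grating, head-on
    d_oblique  = lambda0 / (2 n sin a)   oblique illumination (half of head-on)
    d_lateral  = lambda0 / (2 n sin a)   fluorescence, in-plane
    d_axial    = lambda0 / (n (1 - cos a))
    d_farfield = lambda0 / (2 n)         no lens at all, far-field bound
    """
    lam = config.wavelength(which_wavelength)
    n = config.n_sample
    a = config.semiaperture
    nsin = n * math.sin(a)
    ncos = n * (1.0 - math.cos(a))
    return ResolutionLimits(
        d_headon=lam / nsin,
        d_oblique=lam / (2.0 * nsin),
        d_lateral=lam / (2.0 * nsin),
        d_axial=math.inf if ncos == 0.0 else lam / ncos,
        d_farfield=lam / (2.0 * n),
    )


def combined_resolution(
    na_ill: float, lambda_ill: float, na_det: float, lambda_em: float
) -> float:
    """SIM resolution from separate illumination/detection apertures, nm.

    d = (2 na_ill/lambda_ill + 2 na_det/lambda_em)^-1 — the harmonic
    combination of the illumination-pattern and emission diffraction
    limits.
    """
    for name, v in (
        ("na_ill", na_ill),
        ("lambda_ill", lambda_ill),
        ("na_det", na_det),
        ("lambda_em", lambda_em),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return 1.0 / (2.0 * na_ill / lambda_ill + 2.0 * na_det / lambda_em)


def detection_na_from_sim_resolution(
    d_sim: float, na_ill: float, lambda_ill: float, lambda_em: float
) -> float:
    """Effective detection NA implied by a claimed SIM resolution.

    Inverts :func:`combined_resolution` for the detection aperture:
    na_det = (1/d - 2 na_ill/lambda_ill) * lambda_em / 2.  Useful for
    checking a reported resolution against the sample's refractive index.
    """
    if d_sim <= 0:
        raise ValueError("d_sim must be positive")
    inv = 1.0 / d_sim - 2.0 * na_ill / lambda_ill
    if inv <= 0:
        raise ValueError(
            "claimed resolution is achievable by the illumination alone"
        )
    return inv * lambda_em / 2.0


def sim_resolution_factor(beta: float) -> float:
    """Resolution gain of sinusoidal SIM over emission-only wide-field.

    ``beta`` is the Stokes-shift factor lambda_em/lambda_ill; the gain is
    beta + 1 (equal wavelengths give the familiar factor of two).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    return beta + 1.0


def evanescent_decay_length(
    n1: float, n2: float, alpha_inc: float, lambda0: float
) -> float:
    """1/e decay length of a TIRF evanescent field, nm.

    l = lambda0 / (4 pi sqrt(n1^2 sin^2 a - n2^2)) for incidence beyond
    the critical angle arcsin(n2/n1).  The minus sign under the root is
    required for a decaying field; it diverges at the critical angle.
    """
    if n1 <= n2:
        raise ValueError("need n1 > n2 for total internal reflection")
    s = n1 * math.sin(alpha_inc)
    if s <= n2:
        raise ValueError(
            "no evanescent field: incidence below the critical angle "
            f"(n1 sin a = {s:.4f} <= n2 = {n2})"
        )
    return lambda0 / (4.0 * math.pi * math.sqrt(s * s - n2 * n2))


def disk_otf_closed_form(rho: np.ndarray) -> np.ndarray:
    """Autocorrelation of a clear disk pupil vs. normalized frequency.

    otf(rho) = (2/pi)(arccos rho - rho sqrt(1-rho^2)) for rho <= 1, else 0.
    """
    rho = np.asarray(rho, dtype=float)
    r = np.clip(rho, 0.0, 1.0)
    out = (2.0 / np.pi) * (np.arccos(r) - r * np.sqrt(1.0 - r * r))
    return np.where(rho <= 1.0, out, 0.0)


def _freq_grids(grid_shape: tuple[int, int], pixel_nm: float):
    ky = np.fft.fftfreq(grid_shape[0], d=pixel_nm)
    kx = np.fft.fftfreq(grid_shape[1], d=pixel_nm)
    return np.meshgrid(ky, kx, indexing="ij")


def _antialiased_disk(
    kyy: np.ndarray, kxx: np.ndarray, radius: float, bin_width: float, ss: int = 8
) -> np.ndarray:
    """Disk indicator with area-weighted (supersampled) edge pixels."""
    kr = np.hypot(kyy, kxx)
    disk = (kr <= radius).astype(float)
    edge = np.abs(kr - radius) <= bin_width
    if ss > 1 and np.any(edge):
        offs = (np.arange(ss) + 0.5) / ss - 0.5
        oy, ox = np.meshgrid(offs * bin_width, offs * bin_width, indexing="ij")
        ey, ex = kyy[edge], kxx[edge]
        sub = (
            np.hypot(ey[:, None] + oy.ravel()[None, :],
                     ex[:, None] + ox.ravel()[None, :]) <= radius
        )
        disk[edge] = sub.mean(axis=1)
    return disk


def make_transfer_function(
    config: OpticalConfig,
    grid_shape: tuple[int, int] | int,
    which_wavelength: str = "emission",
) -> TransferFunction:
    """Numerical PSF and OTF from a clear-disk pupil.

    The pupil is a disk of radius NA/lambda in frequency space, rasterized
    with an anti-aliased edge; the intensity PSF is |FT(pupil)|^2 and the
    OTF is its transform, normalized to 1 at zero frequency, so the OTF is
    the pupil autocorrelation with support radius k_cutoff = 2 NA/lambda.

    The grid must satisfy pixel_nm <= lambda/(8 NA), i.e. be at least
    twice oversampled relative to the SIM-reconstruction Nyquist rate.
    """
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape, grid_shape)
    lam = config.wavelength(which_wavelength)
    na = config.na
    max_pixel = lam / (8.0 * na)
    if config.pixel_nm > max_pixel:
        raise ValueError(
            f"grid under-sampled: pixel_nm={config.pixel_nm:.3f} nm but the "
            f"SIM-oversampled model needs pixel_nm <= {max_pixel:.3f} nm"
        )
    kyy, kxx = _freq_grids(grid_shape, config.pixel_nm)
    dk = 1.0 / (grid_shape[0] * config.pixel_nm)
    pupil = _antialiased_disk(kyy, kxx, na / lam, dk)
    amp = np.fft.ifft2(pupil)
    psf = np.abs(amp) ** 2
    psf /= psf.sum()
    otf = np.fft.fft2(psf)
    otf /= otf[0, 0]
    return TransferFunction(
        otf=otf,
        psf=psf,
        k_cutoff=2.0 * na / lam,
        grid_shape=grid_shape,
        freq_step=(
            1.0 / (grid_shape[0] * config.pixel_nm),
            1.0 / (grid_shape[1] * config.pixel_nm),
        ),
        pixel_nm=config.pixel_nm,
    )


def arc_autocorrelation_support(
    n: float,
    lambda0: float,
    alpha: float,
    grid: int = 512,
    threshold: float = 1e-6,
) -> tuple[float, float]:
    """Support extents of the autocorrelated x-z pupil arc, cycles/nm.

    The detectable wavevectors of a point emitter form (in the x-z
    cross-section) an arc of radius n/lambda0 and half-angle ``alpha``
    about the optical axis.  The intensity transfer function is its
    autocorrelation; this rasterizes the arc, autocorrelates it with FFTs
    and measures the maximum |k_lateral| and |k_axial| of the support,
    which equal 2 n sin(a)/lambda0 and n (1 - cos a)/lambda0.

    ``alpha`` may exceed pi/2 here (up to pi: the full sphere), which the
    physical :class:`OpticalConfig` forbids.
    """
    if not 0.0 < alpha <= math.pi:
        raise ValueError("alpha must lie in (0, pi]")
    R = n / lambda0
    extent = 2.4 * R
    k = np.linspace(-extent, extent, grid)
    dk = k[1] - k[0]
    kx, kz = np.meshgrid(k, k, indexing="ij")
    kr = np.hypot(kx, kz)
    # one-bin-wide antialiased annulus, restricted to the cap angle
    radial = np.clip(1.0 - np.abs(kr - R) / dk, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(kr > 0, kz / np.maximum(kr, 1e-300), 1.0), -1, 1))
    arc = radial * (theta <= alpha + dk / R)
    F = np.fft.fft2(arc)
    ac = np.abs(np.fft.ifft2(np.abs(F) ** 2))
    ac = np.fft.fftshift(ac)
    mask = ac > threshold * ac.max()
    lag = np.fft.fftshift(np.fft.fftfreq(grid)) * grid * dk
    lx, lz = np.meshgrid(lag, lag, indexing="ij")
    return float(np.abs(lx[mask]).max()), float(np.abs(lz[mask]).max())


def xz_support_extents(
    config: OpticalConfig, which_wavelength: str = "emission", grid: int = 512
) -> tuple[float, float]:
    """(k_lateral, k_axial) support of the x-z transfer function, cycles/nm."""
    lam = config.wavelength(which_wavelength)
    return arc_autocorrelation_support(
        config.n_sample, lam, config.semiaperture, grid=grid
    )


def limits_record(config: OpticalConfig, which_wavelength: str = "emission") -> dict:
    """JSON-friendly record: inputs echoed plus the five limits, nm units."""
    lim = abbe_limits(config, which_wavelength)
    return {
        "lambda_nm": config.wavelength(which_wavelength),
        "n_sample": config.n_sample,
        "semiaperture_rad": config.semiaperture,
        "na": config.na,
        "d_headon_nm": lim.d_headon,
        "d_oblique_nm": lim.d_oblique,
        "d_lateral_nm": lim.d_lateral,
        "d_axial_nm": lim.d_axial,
        "d_farfield_nm": lim.d_farfield,
    }
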