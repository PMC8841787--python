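"""Fluorophore response models and harmonic analysis.

A non-uniform illumination pattern I(x) acting on a fluorophore with a
nonlinear response produces an *effective* excitation with extra spatial
harmonics, each of which shifts another copy of the sample spectrum into
the detection passband.  This module provides the pointwise response maps
(linear, integer power, continuous-wave saturation, pulsed saturation),
the exact harmonic strengths of polynomial responses, and a numerical
harmonic analyzer.

Irradiance is dimensionless: multiples of the saturation irradiance
1/(sigma*tau), i.e. photons per absorption cross-section per lifetime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "ResponseModel",
    "HarmonicSpectrum",
    "apply_response",
    "polynomial_harmonic_strength",
    "harmonic_spectrum",
    "extension_factor",
]

KINDS = ("linear", "power", "cw_saturation", "pulsed_saturation")


@dataclass(frozen=True)
class ResponseModel:
    """Pointwise map from illumination irradiance to effective excitation.

    kind='linear'             I_eff = I
    kind='power'              I_eff = I**exponent       (exponent = N >= 1)
    kind='cw_saturation'      I_eff = I / (I + 1/tau)
    kind='pulsed_saturation'  I_eff = 1 - exp(-(I*sigma + 1/tau)*t_pulse)
    """

    kind: str = "linear"
    exponent: int = 1
    tau: float | None = None
    sigma: float | None = None
    t_pulse: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown response kind {self.kind!r}")
        if self.kind == "power" and self.exponent < 1:
            raise ValueError("power response needs exponent >= 1")
        if self.kind == "cw_saturation" and (self.tau is None or self.tau <= 0):
            raise ValueError("cw_saturation needs tau > 0")
        if self.kind == "pulsed_saturation":
            for name in ("tau", "sigma", "t_pulse"):
                v = getattr(self, name)
                if v is None or v <= 0:
                    raise ValueError(f"pulsed_saturation needs {name} > 0")


@dataclass
class HarmonicSpectrum:
    """Harmonic orders n >= 0 and their strengths s_n (s_0 == 1)."""

    orders: list[int]
    strengths: list[float]

    def to_rows(self) -> list[tuple[int, float]]:
        return list(zip(self.orders, self.strengths))


def apply_response(model: ResponseModel, irradiance: np.ndarray) -> np.ndarray:
    """Apply the response map pointwise; monotone non-decreasing in I."""
    I = np.asarray(irradiance, dtype=float)
    if np.min(I) < 0:
        raise ValueError("irradiance must be non-negative")
    if model.kind == "linear":
        return I.copy()
    if model.kind == "power":
        return I**model.exponent
    if model.kind == "cw_saturation":
        return I / (I + 1.0 / model.tau)
    # pulsed saturation: fraction excited by one pulse, proportionality 1
    return 1.0 - np.exp(-(I * model.sigma + 1.0 / model.tau) * model.t_pulse)


def polynomial_harmonic_strength(N: int, n: int) -> float:
    """Strength of harmonic n for the response I_eff = (1 + cos u)**N.

    s_n = (N!)^2 / ((N+n)! (N-n)!), exact; s_0 = 1 and s_n = 0 for n > N
    (no such harmonic).  These are row 2N of Pascal's triangle divided by
    its central element.
    """
    if N < 1 or n < 0:
        raise ValueError("need N >= 1 and n >= 0")
    if n > N:
        return 0.0
    s = Fraction(math.factorial(N) ** 2, math.factorial(N + n) * math.factorial(N - n))
    return float(s)


def harmonic_spectrum(
    model: ResponseModel,
    n_periods: int = 8,
    grid: int = 4096,
    mean_irradiance: float = 1.0,
    n_harmonics: int | None = None,
) -> HarmonicSpectrum:
    """Numerical harmonic strengths of the effective excitation pattern.

    Applies the response to a unit-contrast sinusoid
    I = mean_irradiance * (1 + cos u) sampled with a whole number of
    periods on the grid (so the discrete spectrum is leakage-free) and
    reads the normalized peak magnitudes at multiples of the pattern
    frequency.
    """
    if grid % n_periods != 0:
        raise ValueError(
            "grid must hold a whole number of pattern periods "
            "(spectral leakage would corrupt the harmonic peaks)"
        )
    u = 2.0 * np.pi * n_periods * np.arange(grid) / grid
    I = mean_irradiance * (1.0 + np.cos(u))
    eff = apply_response(model, I)
    spec = np.abs(np.fft.rfft(eff))
    if n_harmonics is None:
        n_harmonics = grid // (2 * n_periods)
    dc = spec[0]
    if dc == 0:
        raise ValueError("effective excitation has zero mean")
    # s_n is the complex-exponential peak magnitude relative to DC, which
    # for a real signal is exactly the rfft bin ratio
    orders = list(range(n_harmonics + 1))
    strengths = [float(spec[n * n_periods] / dc) for n in orders]
    return HarmonicSpectrum(orders=orders, strengths=strengths)


def extension_factor(n_harmonics: int) -> int:
    """Resolution-extension factor for a pattern at the detection cutoff.

    With n usable harmonics the highest recoverable sample frequency is
    (n + 1) times the wide-field cutoff: 1 harmonic doubles resolution,
    a quadratic response (2 harmonics) triples it, a cubic quadruples it.
    """
    if n_harmonics < 0:
        raise ValueError("n_harmonics must be >= 0")
    return n_harmonics + 1
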