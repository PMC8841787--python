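"""Illumination-pattern generators.

Sinusoidal two/three-beam fringes, multifocal spot lattices, scanned
bitmap projections and focal-plane patterns computed from back-focal-plane
amplitudes.  Frames are relative irradiance (dimensionless, >= 0) on
periodic grids; coordinates are in nm with x along axis 1 and y along
axis 0; pattern frequencies are in cycles/nm.

Phase convention: a sinusoid frame is 1 + c*cos(2*pi*p.x + phi) with the
frequency vector p rotated by ``orientation``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .optics import TransferFunction

__all__ = [
    "IlluminationStack",
    "PhaseSet",
    "sinusoidal_stack",
    "multibeam_stack",
    "check_phase_conditions",
    "multifocal_stack",
    "bitmap_stack",
    "pattern_from_bfp",
    "spatial_grids",
    "snap_frequency",
    "raster_offsets",
]


@dataclass
class PhaseSet:
    """Pattern phases (radians, stored modulo 2*pi) and the harmonic
    orders whose phase sums must cancel for a clean reconstruction."""

    phases: list[float]
    orders_required: list[int] = field(default_factory=lambda: [1, 2])

    def __post_init__(self) -> None:
        if len(self.phases) == 0:
            raise ValueError("PhaseSet needs at least one phase")
        self.phases = [float(p) % (2.0 * np.pi) for p in self.phases]

    @classmethod
    def equal_steps(cls, m: int, orders_required: list[int] | None = None) -> "PhaseSet":
        """m phases in equal 2*pi/m steps (cancel all orders 1..m-1)."""
        phases = [2.0 * np.pi * i / m for i in range(m)]
        if orders_required is None:
            orders_required = list(range(1, m))
        return cls(phases=phases, orders_required=orders_required)


@dataclass
class IlluminationStack:
    """Per-exposure illumination fields plus the pattern metadata needed
    to build a matching local oscillator."""

    frames: list[np.ndarray]
    kind: str
    pixel_nm: float
    p: tuple[float, float] | None = None
    phases: list[float] | None = None
    orientation: float = 0.0
    contrast: float = 1.0
    scan_offsets: list[tuple[float, float]] | None = None
    pitch_nm: float | None = None

    def __post_init__(self) -> None:
        for f in self.frames:
            if np.min(f) < -1e-9:
                raise ValueError("illumination frames must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def spatial_grids(shape: tuple[int, int], pixel_nm: float):
    """(Y, X) coordinate arrays in nm, corner origin, periodic wrap."""
    y = np.arange(shape[0]) * pixel_nm
    x = np.arange(shape[1]) * pixel_nm
    return np.meshgrid(y, x, indexing="ij")


def snap_frequency(
    p: tuple[float, float], shape: tuple[int, int], pixel_nm: float
) -> tuple[float, float]:
    """Snap a frequency vector to the nearest DFT grid frequency.

    Guarantees a whole number of periods across the (periodic) grid so
    spectra are leakage-free and circular convolutions are consistent.
    """
    cy = round(p[0] * shape[0] * pixel_nm)
    cx = round(p[1] * shape[1] * pixel_nm)
    return (cy / (shape[0] * pixel_nm), cx / (shape[1] * pixel_nm))


def _p_vector(p_mag: float, orientation: float) -> tuple[float, float]:
    # orientation 0 -> fringes vary along x (axis 1)
    return (p_mag * np.sin(orientation), p_mag * np.cos(orientation))


def _check_realizable(p_mag, config, tirf_override):
    if config is None:
        return
    k_max = 2.0 * config.na / config.lambda_ill
    if p_mag > k_max * (1 + 1e-12) and not tirf_override:
        raise ValueError(
            f"pattern frequency {p_mag:.3g} cycles/nm exceeds the "
            f"illumination diffraction cutoff {k_max:.3g}; pass "
            "tirf_override=True for an evanescent (TIRF) pattern"
        )


def sinusoidal_stack(
    p_mag: float,
    orientation: float,
    phases: PhaseSet,
    shape: tuple[int, int],
    pixel_nm: float,
    contrast: float = 1.0,
    config=None,
    tirf_override: bool = False,
    snap: bool = True,
) -> IlluminationStack:
    """Two-beam interference fringes: I_m = 1 + c*cos(2 pi p.x + phi_m)."""
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    _check_realizable(p_mag, config, tirf_override)
    pv = _p_vector(p_mag, orientation)
    if snap:
        pv = snap_frequency(pv, shape, pixel_nm)
    Y, X = spatial_grids(shape, pixel_nm)
    u0 = 2.0 * np.pi * (pv[0] * Y + pv[1] * X)
    frames = [1.0 + contrast * np.cos(u0 + phi) for phi in phases.phases]
    return IlluminationStack(
        frames=frames,
        kind="sinusoid",
        pixel_nm=pixel_nm,
        p=pv,
        phases=list(phases.phases),
        orientation=orientation,
        contrast=contrast,
    )


def multibeam_stack(
    n_beams: int,
    p_mag: float,
    orientation: float,
    phases: PhaseSet,
    shape: tuple[int, int],
    pixel_nm: float,
    config=None,
    tirf_override: bool = False,
    snap: bool = True,
) -> IlluminationStack:
    """Coherent 2- or 3-beam fringes.

    Three beams of equal amplitude give I = |1 + 2 cos(u)|^2
    = 3 + 4 cos(u) + 2 cos(2u): five spectral peaks at {0, +-p, +-2p}
    with amplitudes 3:2:2:1:1.  Two beams reduce to the plain sinusoid.
    """
    if n_beams == 2:
        stack = sinusoidal_stack(
            p_mag, orientation, phases, shape, pixel_nm,
            contrast=1.0, config=config, tirf_override=tirf_override, snap=snap,
        )
        stack.kind = "multibeam"
        return stack
    if n_beams != 3:
        raise ValueError("n_beams must be 2 or 3")
    _check_realizable(p_mag, config, tirf_override)
    pv = _p_vector(p_mag, orientation)
    if snap:
        pv = snap_frequency(pv, shape, pixel_nm)
    Y, X = spatial_grids(shape, pixel_nm)
    u0 = 2.0 * np.pi * (pv[0] * Y + pv[1] * X)
    frames = [
        3.0 + 4.0 * np.cos(u0 + phi) + 2.0 * np.cos(2.0 * (u0 + phi))
        for phi in phases.phases
    ]
    # interference minimum is exactly 0; clip the few -1e-16 excursions
    frames = [np.clip(f, 0.0, None) for f in frames]
    return IlluminationStack(
        frames=frames,
        kind="multibeam",
        pixel_nm=pixel_nm,
        p=pv,
        phases=list(phases.phases),
        orientation=orientation,
        contrast=1.0,
    )


def check_phase_conditions(
    phases: PhaseSet, tol: float = 1e-9
) -> dict[int, dict]:
    """Report |sum_m exp(i q phi_m)| for each required order q.

    The reconstruction's unwanted cross terms cancel only when these sums
    vanish; e.g. three equal 2*pi/3 steps cancel orders 1 and 2, while two
    phases {0, pi} cancel order 1 but leave order 2 at magnitude 2.
    """
    report = {}
    phi = np.asarray(phases.phases)
    for q in phases.orders_required:
        mag = float(np.abs(np.exp(1j * q * phi).sum()))
        report[q] = {"magnitude": mag, "pass": mag <= tol}
    return report


def raster_offsets(pitch_nm: float, n_steps: int) -> list[tuple[float, float]]:
    """n_steps x n_steps raster covering one unit cell of a square lattice."""
    step = pitch_nm / n_steps
    return [
        (i * step, j * step) for i in range(n_steps) for j in range(n_steps)
    ]


def _splat_delta(frame: np.ndarray, y: float, x: float, value: float = 1.0):
    """Bilinear deposition of a delta at fractional pixel (y, x), wrapped."""
    ny, nx = frame.shape
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            frame[(y0 + dy) % ny, (x0 + dx) % nx] += value * wy * wx


def multifocal_stack(
    pitch_nm: float,
    scan_offsets: list[tuple[float, float]],
    excitation_tf: TransferFunction,
    shape: tuple[int, int],
    pixel_nm: float,
) -> IlluminationStack:
    """Scanned square lattice of diffraction-limited excitation spots.

    Each frame is a lattice of excitation-PSF spots displaced by one scan
    offset (dy, dx in nm); summing over a full raster gives a spatially
    uniform dose up to the lattice ripple.  A pitch larger than the grid
    degenerates to a single scanned spot (ISM).
    """
    ny, nx = shape
    span_y, span_x = ny * pixel_nm, nx * pixel_nm
    n_y = max(1, round(span_y / pitch_nm))
    n_x = max(1, round(span_x / pitch_nm))
    pitch_y, pitch_x = span_y / n_y, span_x / n_x
    otf = excitation_tf.otf
    frames = []
    for (dy, dx) in scan_offsets:
        comb = np.zeros(shape)
        for i in range(n_y):
            for j in range(n_x):
                _splat_delta(
                    comb, (i * pitch_y + dy) / pixel_nm, (j * pitch_x + dx) / pixel_nm
                )
        frame = np.fft.ifft2(np.fft.fft2(comb) * otf).real
        frames.append(np.clip(frame, 0.0, None))
    stack = IlluminationStack(
        frames=frames,
        kind="multifocal",
        pixel_nm=pixel_nm,
        scan_offsets=list(scan_offsets),
        pitch_nm=pitch_nm,
    )
    total = np.sum(frames, axis=0)
    mean = total.mean()
    if mean > 0 and (total.max() - total.min()) / mean > 0.25:
        warnings.warn(
            "scan offsets do not cover the lattice unit cell: total "
            "illumination dose is non-uniform",
            stacklevel=2,
        )
    return stack


def bitmap_stack(
    bitmap: np.ndarray,
    scan_offsets: list[tuple[float, float]],
    excitation_tf: TransferFunction,
    pixel_nm: float,
) -> IlluminationStack:
    """Scanned diffraction-limited projection of an arbitrary bitmap.

    Each frame is the bitmap circularly shifted by a scan offset (nm,
    sub-pixel via the Fourier shift theorem) and convolved with the
    excitation PSF, so its spectrum never exceeds the excitation cutoff.
    A delta bitmap reduces to a scanned single spot (ISM).
    """
    bitmap = np.asarray(bitmap, dtype=float)
    if bitmap.min() < 0:
        raise ValueError("bitmap must be non-negative")
    ny, nx = bitmap.shape
    ky = np.fft.fftfreq(ny, d=pixel_nm)
    kx = np.fft.fftfreq(nx, d=pixel_nm)
    kyy, kxx = np.meshgrid(ky, kx, indexing="ij")
    B = np.fft.fft2(bitmap)
    frames = []
    for (dy, dx) in scan_offsets:
        ramp = np.exp(-2j * np.pi * (kyy * dy + kxx * dx))
        frame = np.fft.ifft2(B * ramp * excitation_tf.otf).real
        frames.append(np.clip(frame, 0.0, None))
    return IlluminationStack(
        frames=frames,
        kind="bitmap",
        pixel_nm=pixel_nm,
        scan_offsets=list(scan_offsets),
    )


def pattern_from_bfp(bfp_amplitude: np.ndarray) -> np.ndarray:
    """Focal-plane irradiance from a back-focal-plane amplitude.

    Scalar model: the focal field is the Fourier transform of the BFP
    amplitude (given in centred layout), and the irradiance is its squared
    modulus, scaled so total energy equals sum(|bfp|^2) (Parseval).
    """
    bfp = np.asarray(bfp_amplitude, dtype=complex)
    field_ = np.fft.ifft2(np.fft.ifftshift(bfp))
    irr = np.abs(field_) ** 2
    n = bfp.size
    return irr * n  # ifft2 carries 1/n^2; one factor n restores Parseval
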