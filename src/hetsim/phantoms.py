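"""Synthetic ground-truth samples and resolution measurement.

All phantoms live on periodic grids (the forward model's convolutions
are circular) and are reproducible from a seed.  The ``periodic`` kind
is synthesized directly in the Fourier domain with the axis-aligned
frequencies zeroed, so its spectrum shows none of the 'cross' artefact
that windowing a non-periodic image produces — convenient when reading
spectral-extension effects off reconstruction spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import SampleImage

__all__ = [
    "PhantomSpec",
    "generate",
    "measure_fwhm",
    "render_text_bitmap",
    "spectral_extension_db",
]


@dataclass
class PhantomSpec:
    """Recipe for one synthetic sample.

    kind: 'periodic' (broadband random field, spectrum clear of the DFT
    axes), 'beads' (separated Gaussian spots), 'spokes' (Siemens-star
    resolution target) or 'bitmap_text' (rendered text).
    """

    kind: str
    grid_shape: tuple[int, int] = (256, 256)
    pixel_nm: float = 20.0
    seed: int = 0
    # kind-specific knobs
    n_beads: int = 40
    bead_radius_nm: float = 40.0
    min_separation_nm: float = 200.0
    n_spokes: int = 24
    text: str = "SIM"
    spectral_index: float = 1.0  # envelope k^-index for 'periodic'

    def __post_init__(self) -> None:
        if self.kind not in ("periodic", "beads", "spokes", "bitmap_text"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if min(self.grid_shape) < 8:
            raise ValueError("degenerate grid")


def generate(spec: PhantomSpec) -> SampleImage:
    """Deterministic (seeded) phantom of the requested kind, >= 0."""
    rng = np.random.default_rng(spec.seed)
    builders = {
        "periodic": _periodic,
        "beads": _beads,
        "spokes": _spokes,
        "bitmap_text": _bitmap_text,
    }
    img = builders[spec.kind](spec, rng)
    img = np.clip(img, 0.0, None)
    return SampleImage(density=img, pixel_nm=spec.pixel_nm)


def _periodic(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    ny, nx = spec.grid_shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    kr = np.hypot(ky, kx)
    envelope = 1.0 / (0.02 + kr) ** spec.spectral_index
    phase = rng.uniform(0, 2 * np.pi, size=(ny, nx))
    amp = rng.rayleigh(1.0, size=(ny, nx))
    F = amp * envelope * np.exp(1j * phase)
    F[0, :] = 0.0  # keep the DFT axes dark: no cross in the spectrum
    F[:, 0] = 0.0
    img = np.fft.ifft2(F).real
    img -= img.min()  # shifts only the DC bin
    if img.max() > 0:
        img /= img.max()
    return img


def _beads(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    ny, nx = spec.grid_shape
    span = np.array([ny, nx]) * spec.pixel_nm
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.n_beads and attempts < 200 * spec.n_beads:
        attempts += 1
        c = rng.uniform(0, 1, size=2) * span
        ok = True
        for prev in centers:
            d = np.abs(c - prev)
            d = np.minimum(d, span - d)  # torus metric
            if np.hypot(*d) < spec.min_separation_nm:
                ok = False
                break
        if ok:
            centers.append(c)
    deltas = np.zeros((ny, nx))
    for cy, cx in centers:
        _bilinear(deltas, cy / spec.pixel_nm, cx / spec.pixel_nm)
    # exact periodic Gaussian blur in the frequency domain
    sigma = spec.bead_radius_nm / spec.pixel_nm
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    G = np.exp(-2.0 * (np.pi * sigma) ** 2 * (ky**2 + kx**2))
    return np.fft.ifft2(np.fft.fft2(deltas) * G).real


def _bilinear(arr, y, x):
    ny, nx = arr.shape
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            arr[(y0 + dy) % ny, (x0 + dx) % nx] += wy * wx


def _spokes(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    ny, nx = spec.grid_shape
    y = np.arange(ny) - ny / 2
    x = np.arange(nx) - nx / 2
    Y, X = np.meshgrid(y, x, indexing="ij")
    theta = np.arctan2(Y, X)
    r = np.hypot(Y, X)
    star = 0.5 * (1.0 + np.cos(spec.n_spokes * theta))
    rmax = min(ny, nx) / 2 - 2
    return star * (r < rmax) * (r > 2)


def render_text_bitmap(
    text: str, shape: tuple[int, int], fill_fraction: float = 0.6
) -> np.ndarray:
    """Binary bitmap of ``text`` rasterized to span ``fill_fraction`` of
    the grid width, centred; uses Pillow's built-in bitmap font."""
    from PIL import Image, ImageDraw, ImageFont

    font = ImageFont.load_default()
    tiny = Image.new("L", (4 * len(text) * 8, 32), 0)
    d = ImageDraw.Draw(tiny)
    d.text((2, 2), text, fill=255, font=font)
    arr = np.array(tiny)
    ys, xs = np.nonzero(arr)
    if len(ys) == 0:
        raise ValueError("text rendered empty")
    crop = arr[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    target_w = max(1, int(shape[1] * fill_fraction))
    target_h = max(1, int(crop.shape[0] * target_w / crop.shape[1]))
    target_h = min(target_h, shape[0])
    im = Image.fromarray(crop).resize((target_w, target_h), Image.NEAREST)
    out = np.zeros(shape)
    oy = (shape[0] - target_h) // 2
    ox = (shape[1] - target_w) // 2
    out[oy : oy + target_h, ox : ox + target_w] = np.array(im) / 255.0
    return (out > 0.5).astype(float)


def _bitmap_text(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    return render_text_bitmap(spec.text, spec.grid_shape)


def measure_fwhm(
    image: np.ndarray,
    peak: tuple[int, int] | None = None,
    pixel_nm: float = 1.0,
) -> float:
    """Full width at half maximum of a single peak, nm.

    Rolls the peak to the grid centre, takes 1D profiles through it along
    both axes, locates the half-maximum crossings by linear interpolation
    and returns the mean of the two widths.
    """
    image = np.asarray(image, dtype=float)
    if peak is None:
        peak = np.unravel_index(np.argmax(image), image.shape)
    if image[peak] <= 0:
        raise ValueError("no positive peak found")
    ny, nx = image.shape
    centred = np.roll(image, (ny // 2 - peak[0], nx // 2 - peak[1]), axis=(0, 1))
    widths = []
    for profile in (centred[:, nx // 2], centred[ny // 2, :]):
        widths.append(_fwhm_1d(profile) * pixel_nm)
    return float(np.mean(widths))


def spectral_extension_db(
    image: np.ndarray,
    reference: np.ndarray,
    pixel_nm: float,
    k_min: float,
    k_max: float,
    direction: tuple[float, float] | None = None,
    half_angle: float = np.pi / 6,
) -> float:
    """Median spectral energy of ``image`` over ``reference`` in an
    annulus k_min < |k| < k_max (cycles/nm), in dB.

    For a single fringe orientation the extended information lies along
    the pattern direction only, so pass ``direction`` (the frequency
    vector) to restrict the annulus to a +-``half_angle`` double sector
    about that axis.  Positive dB: the image carries energy there that
    the reference does not.
    """
    ny, nx = image.shape
    ky = np.fft.fftfreq(ny, d=pixel_nm)
    kx = np.fft.fftfreq(nx, d=pixel_nm)
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    kr = np.hypot(KY, KX)
    region = (kr > k_min) & (kr < k_max)
    if direction is not None:
        axis = np.arctan2(direction[0], direction[1])
        ang = np.arctan2(KY, KX) - axis
        ang = np.abs((ang + np.pi / 2) % np.pi - np.pi / 2)  # fold +-k
        region &= ang <= half_angle
    a = np.median(np.abs(np.fft.fft2(image))[region])
    b = np.median(np.abs(np.fft.fft2(reference))[region])
    return float(20.0 * np.log10(a / b))


def _fwhm_1d(profile: np.ndarray, c: int | None = None) -> float:
    # c: index of the peak to measure (default: the profile centre, where
    # measure_fwhm rolled it); a global argmax could land on a different
    # peak of a lattice
    if c is None:
        c = len(profile) // 2
    half = profile[c] / 2.0
    # walk outwards to the first crossing on each side, interpolate
    right = None
    for i in range(c, len(profile) - 1):
        if profile[i + 1] < half <= profile[i]:
            right = i + (profile[i] - half) / (profile[i] - profile[i + 1])
            break
    left = None
    for i in range(c, 0, -1):
        if profile[i - 1] < half <= profile[i]:
            left = i - (profile[i] - half) / (profile[i] - profile[i - 1])
            break
    if left is None or right is None:
        raise ValueError("half-maximum crossing not found in the window")
    return right - left
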