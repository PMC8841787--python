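"""Forward model: simulate raw SIM/ISM camera frames.

Each frame is D_m = (R(I_m) * S) conv H — the fluorophore density S
weighted by the (response-mapped) illumination and blurred by the
detection PSF — with optional Poisson photon noise and Gaussian read
noise.  Convolutions are circular (periodic boundary), matching the
periodic phantoms; pad aperiodic samples before calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import TransferFunction
from .patterns import IlluminationStack
from .response import ResponseModel, apply_response

__all__ = ["SampleImage", "AcquisitionStack", "widefield", "acquire", "moire_preview"]


@dataclass
class SampleImage:
    """Fluorophore density S(x) >= 0 on a periodic grid."""

    density: np.ndarray
    pixel_nm: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if not np.all(np.isfinite(self.density)):
            raise ValueError("sample density must be finite")
        if self.density.min() < 0:
            raise ValueError("sample density must be non-negative")


@dataclass
class AcquisitionStack:
    """Raw camera frames aligned 1:1 with an illumination stack."""

    frames: list[np.ndarray]
    illumination_meta: dict
    photons_per_frame: float | None = None
    noise: str = "none"
    read_noise_sd: float = 0.0
    seed: int | None = None
    pixel_nm: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _convolve(img: np.ndarray, tf: TransferFunction) -> np.ndarray:
    return np.fft.ifft2(np.fft.fft2(img) * tf.otf).real


def widefield(sample: SampleImage, tf: TransferFunction) -> np.ndarray:
    """Uniform-illumination image: S convolved with the detection PSF."""
    if sample.density.shape != tf.otf.shape:
        raise ValueError(
            f"grid mismatch: sample {sample.density.shape} vs OTF {tf.otf.shape}"
        )
    return _convolve(sample.density, tf)


def illumination_meta(illum: IlluminationStack) -> dict:
    return {
        "kind": illum.kind,
        "p": list(illum.p) if illum.p is not None else None,
        "phases": illum.phases,
        "orientation": illum.orientation,
        "contrast": illum.contrast,
        "scan_offsets": (
            [list(o) for o in illum.scan_offsets] if illum.scan_offsets else None
        ),
        "pitch_nm": illum.pitch_nm,
        "pixel_nm": illum.pixel_nm,
    }


def acquire(
    sample: SampleImage,
    illum: IlluminationStack,
    tf: TransferFunction,
    response: ResponseModel | None = None,
    noise: str = "none",
    photons_per_frame: float = 1e6,
    read_noise_sd: float = 0.0,
    seed: int | None = None,
) -> AcquisitionStack:
    """Simulate one acquisition: frame_m = (R(I_m) * S) conv H.

    With noise='poisson' frames are rescaled so the *mean* frame total is
    ``photons_per_frame`` and Poisson-sampled; 'poisson+gaussian' adds
    zero-mean read noise of ``read_noise_sd`` photons.  Noise default is
    off so simulations are deterministic.
    """
    if response is None:
        response = ResponseModel(kind="linear")
    if noise not in ("none", "poisson", "poisson+gaussian"):
        raise ValueError(f"unknown noise kind {noise!r}")
    if sample.density.shape != tf.otf.shape:
        raise ValueError("sample grid does not match the transfer function")
    frames = []
    for I in illum.frames:
        if I.shape != sample.density.shape:
            raise ValueError("illumination grid does not match the sample")
        eff = apply_response(response, I)
        frames.append(_convolve(eff * sample.density, tf))
    if noise != "none":
        mean_total = float(np.mean([f.sum() for f in frames]))
        if mean_total <= 0:
            raise ValueError("cannot scale an all-zero acquisition to photons")
        scale = photons_per_frame / mean_total
        rng = np.random.default_rng(seed)
        noisy = []
        for f in frames:
            lam = np.clip(f * scale, 0.0, None)
            g = rng.poisson(lam).astype(float)
            if noise == "poisson+gaussian":
                g = g + rng.normal(0.0, read_noise_sd, size=g.shape)
            noisy.append(g)
        frames = noisy
    return AcquisitionStack(
        frames=frames,
        illumination_meta=illumination_meta(illum),
        photons_per_frame=photons_per_frame if noise != "none" else None,
        noise=noise,
        read_noise_sd=read_noise_sd,
        seed=seed,
        pixel_nm=sample.pixel_nm,
    )


def moire_preview(sample: SampleImage, illum_frame: np.ndarray) -> np.ndarray:
    """Pre-convolution product I_m * S: the raw Moire beat pattern.

    Multiplying the sample by a fine fringe creates low-frequency beats
    (the difference frequencies) — the mechanism that folds sample detail
    from beyond the passband into the detectable band.
    """
    return illum_frame * sample.density
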