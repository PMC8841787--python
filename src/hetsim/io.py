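"""Stack file formats: multi-page float32 TIFF + JSON metadata sidecar.

A stack on disk is ``name.tif`` (frames, phase-major then orientation
then scan-offset order) and ``name.json`` (schema version, optical
config, pattern metadata, noise settings, seed; units declared in field
names).  Round trips are bit-exact for float32 frames.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .forward import AcquisitionStack

__all__ = ["SCHEMA_VERSION", "write_stack", "read_stack", "sidecar_path"]

SCHEMA_VERSION = "1"


def sidecar_path(tif_path: str | Path) -> Path:
    return Path(tif_path).with_suffix(".json")


def _pattern_metadata(meta: dict, pixel_nm: float) -> dict:
    out = dict(meta)
    p = meta.get("p")
    if p is not None and (p[0] or p[1]):
        mag = float(np.hypot(*p))
        out["p_cycles_per_um"] = [1e3 * p[0], 1e3 * p[1]]
        out["pixels_per_period"] = 1.0 / (mag * pixel_nm)
    return out


def write_stack(
    stack: AcquisitionStack,
    path: str | Path,
    optics: dict | None = None,
    extra: dict | None = None,
) -> Path:
    """Write frames to multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    frames = np.stack([np.asarray(f, dtype=np.float32) for f in stack.frames])
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_frames": int(frames.shape[0]),
        "frame_order": "phase-major, then orientation, then scan-offset",
        "pixel_nm": stack.pixel_nm,
        "pattern": _pattern_metadata(stack.illumination_meta, stack.pixel_nm),
        "noise": stack.noise,
        "photons_per_frame": stack.photons_per_frame,
        "read_noise_sd_photons": stack.read_noise_sd,
        "seed": stack.seed,
        "optics": optics,
    }
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> tuple[AcquisitionStack, dict]:
    """Read a TIFF + sidecar pair back into an AcquisitionStack.

    Raises on a missing sidecar, an unknown schema version or a frame
    count that disagrees with the metadata.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {side}")
    meta = json.loads(side.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unknown stack schema version {version!r} (supported: {SCHEMA_VERSION})"
        )
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"frame-count mismatch: TIFF holds {frames.shape[0]} frames, "
            f"sidecar declares {meta['n_frames']}"
        )
    stack = AcquisitionStack(
        frames=[frames[i] for i in range(frames.shape[0])],
        illumination_meta=meta.get("pattern", {}),
        photons_per_frame=meta.get("photons_per_frame"),
        noise=meta.get("noise", "none"),
        read_noise_sd=meta.get("read_noise_sd_photons", 0.0),
        seed=meta.get("seed"),
        pixel_nm=meta.get("pixel_nm", 0.0),
    )
    return stack, meta
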