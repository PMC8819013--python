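"""Shared on-disk formats: TIFF stacks, ring masks, provenance records.

Movies travel as multi-page TIFF with a JSON sidecar carrying the exposure
(and anything else that does not fit in TIFF tags). Maps are 32-bit float
TIFF with NaN as the absent-value sentinel. Tables are plain comma-separated
UTF-8 CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import FormatError
from .geometry import DetectorGeometry, RingSelection

SIDE_CAR_SUFFIX = ".json"


@dataclass
class DiffractionMovie:
    """A time series of detector frames (photon counts) plus exposure."""

    frames: np.ndarray  # (n_frames, n_rows, n_cols)
    exposure_s: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"movie must be a 3-D stack, got shape {self.frames.shape}"
            )
        if not self.exposure_s > 0:
            raise FormatError(f"exposure must be positive, got {self.exposure_s}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + SIDE_CAR_SUFFIX)


def write_movie(movie: DiffractionMovie, path, dtype=None) -> None:
    """Write a movie as multi-page TIFF plus a JSON exposure sidecar.

    ``dtype`` defaults to the movie's own dtype. Saturation on integer
    narrowing is flagged in the sidecar rather than silently wrapped.
    """
    path = Path(path)
    data = movie.frames
    saturated = False
    if dtype is not None:
        dtype = np.dtype(dtype)
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            saturated = bool((data > info.max).any() or (data < info.min).any())
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "exposure_s": movie.exposure_s,
        "n_frames": movie.n_frames,
        "shape": list(movie.frame_shape),
        "dtype": str(data.dtype),
        "saturated": saturated,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_movie(path, exposure_s: float | None = None) -> DiffractionMovie:
    """Read a multi-page TIFF movie; exposure comes from the sidecar unless
    given explicitly. Ragged page shapes raise a :class:`FormatError` naming
    the offending page."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = [p.shape for p in tif.pages]
            for i, s in enumerate(shapes[1:], start=1):
                if s != shapes[0]:
                    raise FormatError(
                        f"page {i} of {path} has shape {s}, expected {shapes[0]}"
                    )
            frames = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # unreadable container
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if exposure_s is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            exposure_s = json.loads(sidecar.read_text())["exposure_s"]
        else:
            raise FormatError(
                f"no exposure given and no sidecar {sidecar} found for {path}"
            )
    return DiffractionMovie(frames=frames, exposure_s=float(exposure_s))


def write_map(image: np.ndarray, path) -> None:
    """Write a per-pixel float map (NaN = absent) as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def read_map(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_ring(ring: RingSelection, mask_path, sidecar_path) -> None:
    """Export a ring selection: boolean-mask TIFF + JSON sidecar."""
    tifffile.imwrite(Path(mask_path), ring.mask.astype(np.uint8))
    meta = {
        "two_theta_center": ring.two_theta_center,
        "phi_theta": ring.phi_theta,
        "hkl": list(ring.hkl) if ring.hkl is not None else None,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def read_ring(mask_path, sidecar_path) -> RingSelection:
    mask = tifffile.imread(Path(mask_path)).astype(bool)
    meta = json.loads(Path(sidecar_path).read_text())
    hkl = tuple(meta["hkl"]) if meta.get("hkl") is not None else None
    return RingSelection(
        two_theta_center=float(meta["two_theta_center"]),
        phi_theta=float(meta["phi_theta"]),
        mask=mask,
        hkl=hkl,
    )


def write_provenance(path, config: dict, seed: int | None) -> None:
    """Machine-readable record sufficient to re-run a stage bit-identically."""
    import blinktrack

    record = {
        "config": config,
        "seed": seed,
        "package": "blinktrack",
        "package_version": blinktrack.__version__,
        "numpy_version": np.__version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))


def read_provenance(path) -> dict:
    return json.loads(Path(path).read_text())


def load_geometry(path) -> DetectorGeometry:
    return DetectorGeometry.from_yaml(path)
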