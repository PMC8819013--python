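"""Diffraction geometry for a flat detector at normal incidence.

Conventions (fixed here, used everywhere else in the package):

* pixel ``(0, 0)`` is the top-left corner of the detector; ``row`` increases
  downward, ``col`` increases to the right; continuous coordinates refer to
  pixel centres;
* the azimuth ``chi`` is measured from the +col axis, ``chi = atan2(row -
  center_row, col - center_col)``, with range ``(-pi, pi]``; the beam-centre
  pixel maps to ``chi = 0`` by convention;
* the scattering angle uses the flat-detector small-obliquity model
  ``two_theta = arctan(r / distance)`` — no tilt or parallax corrections;
* all angles are radians, energies keV, lengths mm (detector) or Å
  (wavelengths, lattice constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .exceptions import (
    EmptySelectionError,
    InvalidInputError,
    NoDiffractionError,
    OutOfGeometryError,
)

#: h*c in keV·Å — energy/wavelength conversion constant.
HC_KEV_ANGSTROM = 12.3984

#: Gold fcc lattice constant in Å (standard reference value).
GOLD_LATTICE_ANGSTROM = 4.0782


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in Å for a photon energy in keV."""
    if not energy_kev > 0:
        raise InvalidInputError(f"energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def bragg_two_theta(
    wavelength: float,
    lattice_constant: float,
    hkl: tuple[int, int, int],
) -> float:
    """Scattering angle 2θ (rad) of a cubic reflection ``hkl``.

    Raises
    ------
    NoDiffractionError
        If ``wavelength > 2 d``, i.e. the reflection cannot be excited.
    """
    if not wavelength > 0:
        raise InvalidInputError(f"wavelength must be positive, got {wavelength}")
    if not lattice_constant > 0:
        raise InvalidInputError(
            f"lattice constant must be positive, got {lattice_constant}"
        )
    h, k, l = hkl
    if h == 0 and k == 0 and l == 0:
        raise InvalidInputError("hkl must not be (0, 0, 0)")
    d = lattice_constant / np.sqrt(h * h + k * k + l * l)
    s = wavelength / (2.0 * d)
    if s > 1.0:
        raise NoDiffractionError(
            f"reflection {hkl} unreachable: wavelength {wavelength} Å exceeds 2d = {2 * d:.4f} Å"
        )
    return 2.0 * float(np.arcsin(s))


def scherrer_size(
    beta: float,
    theta: float,
    wavelength: float,
    shape_factor: float = 0.9,
) -> float:
    """Scherrer crystallite size (Å) from peak broadening.

    Parameters
    ----------
    beta : FWHM of the peak in radians.
    theta : Bragg half-angle in radians.
    wavelength : in Å.
    shape_factor : dimensionless Scherrer constant, 0.9 by default.
    """
    if not beta > 0:
        raise InvalidInputError(f"beta must be positive, got {beta}")
    if not 0 <= theta < np.pi / 2:
        raise InvalidInputError(f"theta must lie in [0, pi/2), got {theta}")
    return shape_factor * wavelength / (beta * np.cos(theta))


@dataclass(frozen=True)
class DetectorGeometry:
    """Detector and beam description mapping pixels to (2θ, χ)."""

    energy_kev: float
    distance_mm: float
    pixel_pitch_mm: float
    beam_center: tuple[float, float]  # (row, col), continuous pixel units
    n_rows: int
    n_cols: int
    bandwidth: float = 0.0  # fractional ΔE/E

    def __post_init__(self):
        if not self.energy_kev > 0:
            raise InvalidInputError(f"energy must be positive, got {self.energy_kev}")
        if not self.distance_mm > 0:
            raise InvalidInputError(f"distance must be positive, got {self.distance_mm}")
        if not self.pixel_pitch_mm > 0:
            raise InvalidInputError(
                f"pixel pitch must be positive, got {self.pixel_pitch_mm}"
            )
        if self.bandwidth < 0:
            raise InvalidInputError(f"bandwidth must be >= 0, got {self.bandwidth}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidInputError("detector must have at least one pixel")

    @property
    def wavelength(self) -> float:
        """Beam wavelength in Å at the (peak) energy."""
        return wavelength_from_energy(self.energy_kev)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_yaml(cls, path) -> "DetectorGeometry":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "DetectorGeometry":
        shape = cfg["shape"]
        return cls(
            energy_kev=float(cfg["energy_keV"]),
            distance_mm=float(cfg["distance_mm"]),
            pixel_pitch_mm=float(cfg["pixel_pitch_mm"]),
            beam_center=(float(cfg["beam_center"][0]), float(cfg["beam_center"][1])),
            n_rows=int(shape[0]),
            n_cols=int(shape[1]),
            bandwidth=float(cfg.get("bandwidth", 0.0)),
        )

    def to_dict(self) -> dict:
        return {
            "energy_keV": self.energy_kev,
            "distance_mm": self.distance_mm,
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "beam_center": list(self.beam_center),
            "shape": [self.n_rows, self.n_cols],
            "bandwidth": self.bandwidth,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


def pixel_to_angles(pixel, geom: DetectorGeometry):
    """Map continuous pixel coordinates to ``(two_theta, chi)`` in radians.

    ``pixel`` is ``(row, col)``; both may be scalars or arrays.
    """
    row = np.asarray(pixel[0], dtype=float)
    col = np.asarray(pixel[1], dtype=float)
    drow = row - geom.beam_center[0]
    dcol = col - geom.beam_center[1]
    r_mm = geom.pixel_pitch_mm * np.hypot(drow, dcol)
    two_theta = np.arctan(r_mm / geom.distance_mm)
    chi = np.arctan2(drow, dcol)  # atan2(0, 0) == 0: on-axis convention
    if two_theta.ndim == 0:
        return float(two_theta), float(chi)
    return two_theta, chi


def angles_to_pixel(two_theta, chi, geom: DetectorGeometry):
    """Inverse of :func:`pixel_to_angles`; returns continuous ``(row, col)``."""
    two_theta = np.asarray(two_theta, dtype=float)
    chi = np.asarray(chi, dtype=float)
    if np.any(two_theta < 0) or np.any(two_theta >= np.pi / 2):
        raise OutOfGeometryError(
            "two_theta must lie in [0, pi/2) for a flat normal-incidence detector"
        )
    r_px = geom.distance_mm * np.tan(two_theta) / geom.pixel_pitch_mm
    row = geom.beam_center[0] + r_px * np.sin(chi)
    col = geom.beam_center[1] + r_px * np.cos(chi)
    if row.ndim == 0:
        return float(row), float(col)
    return row, col


@dataclass
class RingSelection:
    """A 2θ annulus of detector pixels with its angular width ``phi_theta``.

    ``phi_theta`` is the FULL width of the 2θ band; it doubles as the angular
    excursion used when converting decay constants to rotational diffusion
    coefficients.
    """

    two_theta_center: float
    phi_theta: float
    mask: np.ndarray  # boolean, detector shape
    hkl: tuple[int, int, int] | None = None
    two_theta_map: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.phi_theta > 0:
            raise InvalidInputError(f"phi_theta must be positive, got {self.phi_theta}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def pixels(self) -> set[tuple[int, int]]:
        """Masked pixels as a set of ``(row, col)`` tuples."""
        rows, cols = np.nonzero(self.mask)
        return set(zip(rows.tolist(), cols.tolist()))


def ring_mask(
    geom: DetectorGeometry,
    two_theta_center: float,
    phi_theta: float,
    hkl: tuple[int, int, int] | None = None,
) -> RingSelection:
    """Select every pixel whose centre 2θ lies within the closed band
    ``[two_theta_center - phi_theta/2, two_theta_center + phi_theta/2]``.
    """
    if not phi_theta > 0:
        raise InvalidInputError(f"phi_theta must be positive, got {phi_theta}")
    rows, cols = np.meshgrid(
        np.arange(geom.n_rows, dtype=float),
        np.arange(geom.n_cols, dtype=float),
        indexing="ij",
    )
    two_theta, _ = pixel_to_angles((rows, cols), geom)
    half = phi_theta / 2.0
    mask = np.abs(two_theta - two_theta_center) <= half
    if not mask.any():
        raise EmptySelectionError(
            f"no pixel falls in the 2θ band {two_theta_center} ± {half} rad"
        )
    return RingSelection(
        two_theta_center=two_theta_center,
        phi_theta=phi_theta,
        mask=mask,
        hkl=hkl,
        two_theta_map=two_theta,
    )
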