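"""Synthetic diffraction-movie generator.

Nanocrystal orientations undergo small-angle rotational Brownian motion in
two detector-aligned coordinates: ``theta_tilt`` (deviation of the lattice
normal from the exact Bragg orientation, moving the diffracted beam radially)
and ``chi_azimuth`` (azimuth of the diffraction spot). Both receive
independent Gaussian increments of variance ``2 * d_rot * dt`` per step —
the small-angle 2-D approximation to rotational diffusion, valid for the
milliradian-scale excursions of interest; full SO(3) dynamics are a
documented non-goal.

A tilt of the lattice planes by ``delta`` rotates the diffracted beam by
``2 * delta``, so spots are rendered at
``two_theta = two_theta_center + 2 * theta_tilt``.

Rocking curves are Gaussian in ``theta_tilt``. A broadband ("pink") beam
widens the effective rocking curve by ``w_bw = tan(theta_B) * dE/E`` (the
differentiated Bragg law), which keeps spots persistently visible so they
can be tracked rather than blink.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError
from .geometry import DetectorGeometry, RingSelection
from .io import DiffractionMovie

#: radial projection: d(two_theta) / d(theta_tilt) for a tilted reflection
TILT_TO_TWO_THETA = 2.0

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class BeamModel:
    """Beam/crystal reflectivity model.

    ``rocking_width`` is the Gaussian sigma of the reflectivity versus
    ``theta_tilt``. Broadband mode additionally needs ``bandwidth`` (dE/E)
    and ``bragg_theta`` (the Bragg half-angle used to convert bandwidth to
    angular acceptance).
    """

    mode: str  # "monochromatic" | "broadband"
    rocking_width: float = 1e-3
    bandwidth: float = 0.0
    bragg_theta: float | None = None

    def __post_init__(self):
        if self.mode not in ("monochromatic", "broadband"):
            raise InvalidInputError(f"unknown beam mode {self.mode!r}")
        if not self.rocking_width > 0:
            raise InvalidInputError(
                f"rocking width must be positive, got {self.rocking_width}"
            )
        if self.mode == "broadband":
            if not self.bandwidth > 0:
                raise InvalidInputError("broadband mode requires bandwidth > 0")
            if self.bragg_theta is None:
                raise InvalidInputError("broadband mode requires bragg_theta")

    @property
    def effective_width(self) -> float:
        """Sigma of the effective rocking curve (rad)."""
        if self.mode == "monochromatic":
            return self.rocking_width
        w_bw = np.tan(self.bragg_theta) * self.bandwidth
        return float(np.hypot(self.rocking_width, w_bw))


def rocking_intensity(theta_tilt, beam: BeamModel):
    """Relative reflectivity in [0, 1] at tilt ``theta_tilt`` (rad)."""
    theta_tilt = np.asarray(theta_tilt, dtype=float)
    w = beam.effective_width
    out = np.exp(-(theta_tilt**2) / (2.0 * w * w))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CrystalEnsemble:
    """Static description of the simulated nanocrystal population."""

    n_crystals: int
    d_rot: float  # rad^2/s
    radius_nm: float = 70.0  # paper-scale crystals are 60-80 nm

    def __post_init__(self):
        if self.d_rot < 0:
            raise InvalidInputError(f"d_rot must be >= 0, got {self.d_rot}")
        if not self.radius_nm > 0:
            raise InvalidInputError(f"radius must be positive, got {self.radius_nm}")
        if self.n_crystals < 1:
            raise InvalidInputError("need at least one crystal")


@dataclass
class GroundTruth:
    """Everything the simulator knows: the recovery oracle for the analyses.

    ``theta_paths``/``chi_paths`` have shape ``(n_steps + 1, n_crystals)``
    and include the initial state. ``spot_tracks`` (``(n_frames, n_crystals,
    2)`` sub-pixel ``(row, col)``) and the exposure-averaged orientations are
    filled in by the renderers.
    """

    theta_paths: np.ndarray
    chi_paths: np.ndarray
    d_rot_true: float
    dt: float
    seed: int
    spot_tracks: np.ndarray | None = None
    frame_theta: np.ndarray | None = None  # (n_frames, n_crystals)
    frame_chi: np.ndarray | None = None

    @property
    def n_crystals(self) -> int:
        return self.theta_paths.shape[1]

    @property
    def n_steps(self) -> int:
        return self.theta_paths.shape[0] - 1

    def to_csv(self, path) -> None:
        """One row per crystal per time point.

        When the truth has been rendered, rows are per movie frame with
        detector positions; otherwise per dynamics step with positions empty.
        """
        if self.frame_theta is not None:
            n_frames, n_crystals = self.frame_theta.shape
            frame_idx, crystal_idx = np.meshgrid(
                np.arange(n_frames), np.arange(n_crystals), indexing="ij"
            )
            if self.spot_tracks is not None:
                row_px = self.spot_tracks[..., 0].ravel()
                col_px = self.spot_tracks[..., 1].ravel()
            else:
                row_px = np.full(frame_idx.size, np.nan)
                col_px = np.full(frame_idx.size, np.nan)
            df = pd.DataFrame(
                {
                    "crystal_id": crystal_idx.ravel(),
                    "frame": frame_idx.ravel(),
                    "theta_tilt_rad": self.frame_theta.ravel(),
                    "chi_rad": self.frame_chi.ravel(),
                    "row_px": row_px,
                    "col_px": col_px,
                }
            )
        else:
            n_steps_p1, n_crystals = self.theta_paths.shape
            step_idx, crystal_idx = np.meshgrid(
                np.arange(n_steps_p1), np.arange(n_crystals), indexing="ij"
            )
            df = pd.DataFrame(
                {
                    "crystal_id": crystal_idx.ravel(),
                    "frame": step_idx.ravel(),
                    "theta_tilt_rad": self.theta_paths.ravel(),
                    "chi_rad": self.chi_paths.ravel(),
                    "row_px": np.nan,
                    "col_px": np.nan,
                }
            )
        df.to_csv(path, index=False)


def simulate_orientations(
    n_crystals: int,
    d_rot: float,
    dt: float,
    n_steps: int,
    seed: int,
    theta_init_halfwidth: float = 3e-3,
    chi_init: np.ndarray | None = None,
) -> GroundTruth:
    """Rotational-Brownian orientation paths for ``n_crystals`` crystals.

    Initial ``theta_tilt`` is uniform in ``[-theta_init_halfwidth,
    +theta_init_halfwidth]`` (the capture window around the exact Bragg
    orientation); initial ``chi`` is uniform in ``(-pi, pi]`` unless given.
    Identical ``(parameters, seed)`` yield bit-identical paths.
    """
    if d_rot < 0:
        raise InvalidInputError(f"d_rot must be >= 0, got {d_rot}")
    if not dt > 0:
        raise InvalidInputError(f"dt must be positive, got {dt}")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-theta_init_halfwidth, theta_init_halfwidth, n_crystals)
    if chi_init is None:
        chi0 = rng.uniform(-np.pi, np.pi, n_crystals)
    else:
        chi0 = np.asarray(chi_init, dtype=float)
        if chi0.shape != (n_crystals,):
            raise InvalidInputError("chi_init must have one azimuth per crystal")
    sigma = np.sqrt(2.0 * d_rot * dt)
    steps = rng.normal(0.0, 1.0, size=(n_steps, n_crystals, 2)) * sigma
    theta_paths = np.empty((n_steps + 1, n_crystals))
    chi_paths = np.empty((n_steps + 1, n_crystals))
    theta_paths[0] = theta0
    chi_paths[0] = chi0
    np.cumsum(steps[:, :, 0], axis=0, out=theta_paths[1:])
    theta_paths[1:] += theta0
    np.cumsum(steps[:, :, 1], axis=0, out=chi_paths[1:])
    chi_paths[1:] += chi0
    return GroundTruth(
        theta_paths=theta_paths,
        chi_paths=chi_paths,
        d_rot_true=d_rot,
        dt=dt,
        seed=seed,
    )


def stokes_einstein_debye(
    temperature_k: float, viscosity_pa_s: float, radius_m: float
) -> float:
    """Rotational diffusion coefficient (rad^2/s) of a sphere.

    Advisory helper for picking physically plausible ``d_rot`` values; the
    analyses never use it.
    """
    if temperature_k <= 0 or viscosity_pa_s <= 0 or radius_m <= 0:
        raise InvalidInputError("temperature, viscosity and radius must be positive")
    return BOLTZMANN_J_PER_K * temperature_k / (
        8.0 * np.pi * viscosity_pa_s * radius_m**3
    )


# --------------------------------------------------------------- rendering

PSF_SIGMA_PX = 1.0
PSF_TRUNC_SIGMA = 3.0


def _deposit_spots(frame, rows, cols, amounts, psf_sigma=PSF_SIGMA_PX):
    """Add Gaussian point-spread stamps (normalised to unit sum before edge
    clipping) at continuous positions; photons falling off-detector are lost."""
    n_rows, n_cols = frame.shape
    radius = int(np.ceil(PSF_TRUNC_SIGMA * psf_sigma))
    offsets = np.arange(-radius, radius + 1)
    off_r, off_c = np.meshgrid(offsets, offsets, indexing="ij")
    off_r = off_r.ravel()
    off_c = off_c.ravel()

    base_r = np.rint(rows).astype(int)
    base_c = np.rint(cols).astype(int)
    pr = base_r[:, None] + off_r[None, :]
    pc = base_c[:, None] + off_c[None, :]
    dr = pr - rows[:, None]
    dc = pc - cols[:, None]
    d2 = dr * dr + dc * dc
    w = np.exp(-d2 / (2.0 * psf_sigma * psf_sigma))
    w[d2 > (PSF_TRUNC_SIGMA * psf_sigma) ** 2] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    w *= amounts[:, None]

    inb = (pr >= 0) & (pr < n_rows) & (pc >= 0) & (pc < n_cols)
    np.add.at(frame, (pr[inb], pc[inb]), w[inb])


def _frame_averages(truth: GroundTruth, n_frames: int, substeps: int):
    """Exposure-averaged (theta, chi, reflectivity-weighting states) per frame."""
    # states 1..n_steps are grouped in blocks of `substeps` per exposure
    theta = truth.theta_paths[1:].reshape(n_frames, substeps, truth.n_crystals)
    chi = truth.chi_paths[1:].reshape(n_frames, substeps, truth.n_crystals)
    return theta, chi


def _wrap_angle(theta, period):
    """Map angles onto ``[-period/2, period/2)``."""
    return (theta + period / 2.0) % period - period / 2.0


def _render(
    truth: GroundTruth,
    geom: DetectorGeometry,
    two_theta_center: float,
    beam: BeamModel,
    photons_per_crystal: float,
    background: float,
    exposure: float,
    poisson: bool,
    seed: int,
    substeps: int,
    theta_period: float | None = None,
    tilt_projection: float = TILT_TO_TWO_THETA,
):
    if not exposure > 0:
        raise InvalidInputError(f"exposure must be positive, got {exposure}")
    if substeps < 1 or truth.n_steps % substeps != 0:
        raise ConfigurationError(
            f"n_steps ({truth.n_steps}) must be a positive multiple of substeps ({substeps})"
        )
    if not np.isclose(truth.dt * substeps, exposure, rtol=1e-9):
        raise ConfigurationError(
            f"truth dt*substeps = {truth.dt * substeps} does not match exposure {exposure}"
        )
    n_frames = truth.n_steps // substeps
    theta_blocks, chi_blocks = _frame_averages(truth, n_frames, substeps)
    theta_mean = theta_blocks.mean(axis=1)
    chi_mean = chi_blocks.mean(axis=1)
    if theta_period is not None:
        # periodic tilt: restores the recurrence of real orientational motion
        # that the unwrapped small-angle approximation loses at large d_rot;
        # paths in the ground truth stay unwrapped.
        theta_blocks = _wrap_angle(theta_blocks, theta_period)
        theta_mean = _wrap_angle(theta_mean, theta_period)
    # time-averaged reflectivity within each exposure
    weights = rocking_intensity(theta_blocks, beam).mean(axis=1)  # (n_frames, n)

    two_theta = two_theta_center + tilt_projection * theta_mean
    # crystals that have wandered outside the forward-scattering half-space
    # carry negligible reflectivity; drop them instead of failing the mapping
    valid = (two_theta >= 0) & (two_theta < np.pi / 2)
    rows = np.full_like(two_theta, np.nan)
    cols = np.full_like(two_theta, np.nan)
    r_px = geom.distance_mm * np.tan(two_theta[valid]) / geom.pixel_pitch_mm
    rows[valid] = geom.beam_center[0] + r_px * np.sin(chi_mean[valid])
    cols[valid] = geom.beam_center[1] + r_px * np.cos(chi_mean[valid])

    frames = np.full(
        (n_frames, geom.n_rows, geom.n_cols), float(background), dtype=float
    )
    amounts = photons_per_crystal * weights
    for f in range(n_frames):
        v = valid[f]
        if v.any():
            _deposit_spots(frames[f], rows[f][v], cols[f][v], amounts[f][v])
    if poisson:
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(float)
    tracks = np.stack([rows, cols], axis=-1)  # (n_frames, n_crystals, 2)
    return frames, tracks, theta_mean, chi_mean


def render_dxb_movie(
    truth: GroundTruth,
    geom: DetectorGeometry,
    ring: RingSelection,
    beam: BeamModel,
    photons_per_crystal: float = 500.0,
    background: float = 0.5,
    exposure: float = 0.2,
    poisson: bool = True,
    seed: int = 0,
    substeps: int = 10,
    theta_period: float | None = None,
    tilt_projection: float = TILT_TO_TWO_THETA,
) -> DiffractionMovie:
    """Render a monochromatic blinking movie onto the ring's detector.

    Each crystal deposits ``photons_per_crystal`` times its exposure-averaged
    reflectivity into a Gaussian point-spread footprint centred at its
    instantaneous ring position; a uniform background is added, then
    (optionally) every pixel is Poisson-resampled.

    ``tilt_projection`` scales the radial spot displacement per unit tilt
    (physical value 2; 0 renders pure intensity blinking at a fixed ring
    position, the regime of real measurements where angular excursions are
    far below one pixel).
    """
    if beam.mode != "monochromatic":
        raise ConfigurationError("DXB rendering requires a monochromatic beam")
    if ring.mask.shape != geom.shape:
        raise ConfigurationError(
            f"ring mask shape {ring.mask.shape} does not match detector {geom.shape}"
        )
    frames, tracks, theta_mean, chi_mean = _render(
        truth,
        geom,
        ring.two_theta_center,
        beam,
        photons_per_crystal,
        background,
        exposure,
        poisson,
        seed,
        substeps,
        theta_period=theta_period,
        tilt_projection=tilt_projection,
    )
    truth.frame_theta = theta_mean
    truth.frame_chi = chi_mean
    truth.spot_tracks = tracks
    return DiffractionMovie(frames=frames, exposure_s=exposure)


def render_dxt_movie(
    truth: GroundTruth,
    geom: DetectorGeometry,
    beam: BeamModel,
    two_theta_center: float,
    photons_per_crystal: float = 2000.0,
    background: float = 0.0,
    exposure: float = 0.01,
    poisson: bool = False,
    seed: int = 0,
    substeps: int = 1,
) -> tuple[DiffractionMovie, GroundTruth]:
    """Render a broadband movie with persistent, moving diffraction spots.

    Returns the movie and the ground truth augmented with exact sub-pixel
    ``spot_tracks`` per frame.
    """
    if beam.mode != "broadband":
        raise ConfigurationError("DXT rendering requires a broadband beam")
    frames, tracks, theta_mean, chi_mean = _render(
        truth,
        geom,
        two_theta_center,
        beam,
        photons_per_crystal,
        background,
        exposure,
        poisson,
        seed,
        substeps,
    )
    new_truth = dataclasses.replace(
        truth, spot_tracks=tracks, frame_theta=theta_mean, frame_chi=chi_mean
    )
    return DiffractionMovie(frames=frames, exposure_s=exposure), new_truth
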