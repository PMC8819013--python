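"""Spot tracking: detection, greedy nearest-neighbour linking, angular
tracks, displacement histograms and Gaussian peak statistics.

The linker is a deliberate re-implementation of the standard single-particle
contract: frame-to-frame assignment among candidate pairs within
``max_disp``, conflicts resolved by distance rank, gaps bridged up to
``memory`` frames. It is sufficient for sparse bright spots and documented
as replaceable by a global-optimisation tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .exceptions import (
    EmptySampleError,
    InvalidInputError,
    InvalidTrajectoryError,
)
from .geometry import DetectorGeometry, pixel_to_angles
from .io import DiffractionMovie


@dataclass
class Spot:
    """A single detection: sub-pixel position and integrated intensity."""

    frame: int
    row: float
    col: float
    intensity: float


@dataclass
class SpotTrajectory:
    """A linked sequence of detections (gaps up to the linker's memory)."""

    frames: list[int] = field(default_factory=list)
    rows: list[float] = field(default_factory=list)
    cols: list[float] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)

    @property
    def duration(self) -> int:
        """Number of frames in which the spot was observed."""
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.rows, self.cols])

    def append(self, spot: Spot) -> None:
        self.frames.append(spot.frame)
        self.rows.append(spot.row)
        self.cols.append(spot.col)
        self.intensities.append(spot.intensity)


@dataclass
class AngularTrack:
    """Per-frame (theta, chi) of one trajectory; chi is unwrapped so that
    displacements across the ±pi seam stay continuous."""

    frames: np.ndarray
    theta: np.ndarray  # Bragg half-angle, rad
    chi: np.ndarray  # unwrapped azimuth, rad


@dataclass
class AngularDisplacementStats:
    """Histogram + Gaussian fit of pooled angular displacements."""

    direction: str  # "theta" | "chi"
    displacements: np.ndarray
    bin_edges: np.ndarray
    densities: np.ndarray
    mu: float
    sigma: float
    peak: float  # equals mu for the symmetric Gaussian model
    n_samples: int
    degenerate: bool = False


# ------------------------------------------------------------- detection

def mad_threshold(image: np.ndarray, k: float = 5.0) -> float:
    """Default detection threshold: median + k * MAD of the frame."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med + k * mad


def detect_spots(
    image: np.ndarray,
    threshold: float,
    min_separation: float = 5.0,
    centroid_halfwidth: int = 3,
    frame: int = 0,
) -> list[Spot]:
    """Local maxima above ``threshold`` refined to sub-pixel by an
    intensity-weighted centroid over a ``(2k+1)**2`` window; maxima closer
    than ``min_separation`` are merged keeping the brighter."""
    if not threshold > 0:
        raise InvalidInputError(f"threshold must be positive, got {threshold}")
    image = np.asarray(image, dtype=float)
    local_max = ndimage.maximum_filter(image, size=3, mode="constant") == image
    cand = np.nonzero(local_max & (image > threshold))
    if len(cand[0]) == 0:
        return []
    peaks = np.column_stack(cand).astype(float)
    heights = image[cand]
    order = np.argsort(heights)[::-1]
    kept: list[int] = []
    for i in order:
        p = peaks[i]
        if all(np.hypot(*(p - peaks[j])) >= min_separation for j in kept):
            kept.append(i)

    k = centroid_halfwidth
    spots = []
    n_rows, n_cols = image.shape
    for i in kept:
        r0, c0 = int(peaks[i][0]), int(peaks[i][1])
        rlo, rhi = max(r0 - k, 0), min(r0 + k + 1, n_rows)
        clo, chi_ = max(c0 - k, 0), min(c0 + k + 1, n_cols)
        window = image[rlo:rhi, clo:chi_]
        total = window.sum()
        if total <= 0:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi_]
        row = float((rr * window).sum() / total)
        col = float((cc * window).sum() / total)
        spots.append(Spot(frame=frame, row=row, col=col, intensity=float(total)))
    return spots


# --------------------------------------------------------------- linking

def link_trajectories(
    spots_per_frame: list[list[Spot]],
    max_disp: float,
    memory: int = 0,
) -> list[SpotTrajectory]:
    """Greedy nearest-neighbour linking with distance-rank conflict
    resolution; unmatched spots may bridge up to ``memory`` missing frames,
    otherwise they start new trajectories."""
    if not max_disp > 0:
        raise InvalidInputError(f"max_disp must be positive, got {max_disp}")
    if memory < 0:
        raise InvalidInputError(f"memory must be >= 0, got {memory}")

    done: list[SpotTrajectory] = []
    active: list[SpotTrajectory] = []
    for frame_idx, spots in enumerate(spots_per_frame):
        # retire trajectories whose gap exceeded the memory limit
        still = []
        for traj in active:
            if frame_idx - traj.frames[-1] > memory + 1:
                done.append(traj)
            else:
                still.append(traj)
        active = still

        pairs = []
        for ti, traj in enumerate(active):
            last = np.array([traj.rows[-1], traj.cols[-1]])
            for si, spot in enumerate(spots):
                d = float(np.hypot(spot.row - last[0], spot.col - last[1]))
                if d <= max_disp:
                    pairs.append((d, ti, si))
        pairs.sort(key=lambda t: t[0])
        used_t: set[int] = set()
        used_s: set[int] = set()
        for d, ti, si in pairs:
            if ti in used_t or si in used_s:
                continue
            active[ti].append(spots[si])
            used_t.add(ti)
            used_s.add(si)
        for si, spot in enumerate(spots):
            if si not in used_s:
                traj = SpotTrajectory()
                traj.append(spot)
                active.append(traj)
    return done + active


def track_movie(
    movie: DiffractionMovie,
    threshold: float | None = None,
    min_separation: float = 5.0,
    max_disp: float = 3.0,
    memory: int = 0,
    centroid_halfwidth: int = 3,
) -> list[SpotTrajectory]:
    """Detect-and-link convenience wrapper over a whole movie."""
    spots_per_frame = []
    for f in range(movie.n_frames):
        img = movie.frames[f]
        thr = mad_threshold(img) if threshold is None else threshold
        thr = max(thr, np.finfo(float).tiny)
        spots_per_frame.append(
            detect_spots(
                img,
                thr,
                min_separation=min_separation,
                centroid_halfwidth=centroid_halfwidth,
                frame=f,
            )
        )
    return link_trajectories(spots_per_frame, max_disp=max_disp, memory=memory)


# ----------------------------------------------------------- angular view

def trajectory_to_angles(
    traj: SpotTrajectory, geom: DetectorGeometry
) -> AngularTrack:
    """Per-frame (theta, chi): theta is the Bragg half-angle (2theta / 2),
    chi the detector azimuth unwrapped across the ±pi seam."""
    rows = np.asarray(traj.rows, dtype=float)
    cols = np.asarray(traj.cols, dtype=float)
    if (
        (rows < -0.5).any()
        or (rows > geom.n_rows - 0.5).any()
        or (cols < -0.5).any()
        or (cols > geom.n_cols - 0.5).any()
    ):
        raise InvalidTrajectoryError("trajectory leaves the detector bounds")
    two_theta, chi = pixel_to_angles((rows, cols), geom)
    return AngularTrack(
        frames=np.asarray(traj.frames, dtype=int),
        theta=np.asarray(two_theta) / 2.0,
        chi=np.unwrap(np.atleast_1d(chi)),
    )


def angular_displacements(
    tracks: AngularTrack | list[AngularTrack],
    lag: int = 1,
    mode: str = "signed",
    direction: str = "theta",
    frame_time: float = 1.0,
) -> np.ndarray:
    """Pooled per-step displacement samples at a fixed lag.

    ``signed`` returns raw differences (rad); ``speed`` returns
    ``|diff| / (lag * frame_time)`` (rad/s). Pairs spanning linker gaps are
    skipped.
    """
    if mode not in ("signed", "speed"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    if direction not in ("theta", "chi"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    if lag < 1:
        raise InvalidInputError(f"lag must be >= 1, got {lag}")
    if isinstance(tracks, AngularTrack):
        tracks = [tracks]
    samples = []
    for track in tracks:
        values = getattr(track, direction)
        frames = track.frames
        if len(values) <= lag:
            continue
        gapless = frames[lag:] - frames[:-lag] == lag
        diffs = (values[lag:] - values[:-lag])[gapless]
        samples.append(diffs)
    if not samples:
        raise EmptySampleError(f"no track long enough for lag {lag}")
    out = np.concatenate(samples)
    if mode == "speed":
        out = np.abs(out) / (lag * frame_time)
    return out


# -------------------------------------------------------- peak statistics

def _freedman_diaconis_bins(samples: np.ndarray) -> int:
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 10
    width = 2.0 * iqr / len(samples) ** (1.0 / 3.0)
    n = int(np.ceil((samples.max() - samples.min()) / width))
    return max(n, 4)


def fit_gaussian_peak(
    samples: np.ndarray,
    n_bins: int | None = None,
    direction: str = "theta",
) -> AngularDisplacementStats:
    """Density-normalised histogram with a least-squares Gaussian fit; the
    reported peak is the fitted mean. Requires at least 50 samples."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 50:
        raise InvalidInputError(f"need >= 50 samples, got {len(samples)}")
    std = samples.std()
    if std == 0:
        return AngularDisplacementStats(
            direction=direction,
            displacements=samples,
            bin_edges=np.array([samples[0], samples[0]]),
            densities=np.array([]),
            mu=float(samples[0]),
            sigma=0.0,
            peak=float(samples[0]),
            n_samples=len(samples),
            degenerate=True,
        )
    if n_bins is None:
        n_bins = _freedman_diaconis_bins(samples)
    densities, edges = np.histogram(samples, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    p0 = [densities.max(), float(samples.mean()), float(std)]
    lo, hi = float(samples.min()), float(samples.max())
    mu, sigma = p0[1], p0[2]
    try:
        popt, _ = curve_fit(
            gauss,
            centers,
            densities,
            p0=p0,
            bounds=([0.0, lo, 1e-12 * std], [np.inf, hi, np.inf]),
            maxfev=10000,
        )
        # keep the fit only if it beats the plain moment estimate and is not
        # degenerate (a Gaussian far wider than the data carries no peak)
        improves = np.sum((gauss(centers, *popt) - densities) ** 2) <= np.sum(
            (gauss(centers, *p0) - densities) ** 2
        )
        if improves and abs(popt[2]) <= (hi - lo):
            mu, sigma = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:
        pass
    return AngularDisplacementStats(
        direction=direction,
        displacements=samples,
        bin_edges=edges,
        densities=densities,
        mu=mu,
        sigma=sigma,
        peak=mu,
        n_samples=len(samples),
    )


def compare_conditions(
    stats_by_condition: dict[object, tuple[AngularDisplacementStats, AngularDisplacementStats]],
) -> pd.DataFrame:
    """Tidy peak-vs-condition table from per-condition (theta, chi) stats."""
    if not stats_by_condition:
        raise InvalidInputError("need at least one condition")
    rows = []
    for cond, (st, sc) in stats_by_condition.items():
        rows.append(
            {
                "condition": cond,
                "E_theta": st.peak,
                "E_chi": sc.peak,
                "sigma_theta": st.sigma,
                "sigma_chi": sc.sigma,
                "n_samples": st.n_samples,
            }
        )
    return pd.DataFrame(rows)


def trajectories_to_csv(
    trajectories: list[SpotTrajectory], geom: DetectorGeometry, path
) -> None:
    """Export linked trajectories with their angular tracks."""
    records = []
    for tid, traj in enumerate(trajectories):
        track = trajectory_to_angles(traj, geom)
        for i in range(traj.duration):
            records.append(
                {
                    "trajectory_id": tid,
                    "frame": traj.frames[i],
                    "row_px": traj.rows[i],
                    "col_px": traj.cols[i],
                    "theta_rad": track.theta[i],
                    "chi_rad": track.chi[i],
                    "intensity": traj.intensities[i],
                }
            )
    pd.DataFrame.from_records(
        records,
        columns=[
            "trajectory_id", "frame", "row_px", "col_px",
            "theta_rad", "chi_rad", "intensity",
        ],
    ).to_csv(path, index=False)
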