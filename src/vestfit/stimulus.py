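"""Translation-stimulus geometry and temporal basis profiles.

The stimulus protocol translates the animal along directions sampled on a
sphere while following a Gaussian velocity profile in time.  Directions are
parameterized by azimuth (0-360 deg, measured in the horizontal plane;
forward = 90, backward = 270, leftward = 0, rightward = 180) and elevation
(-90 to +90 deg; +90 is the downward pole under this lab's convention, -90
upward).  The default protocol samples 26 directions: 8 azimuths x 3
elevations (0, +/-45) plus the two poles.

Temporal tuning is expressed through four basis profiles derived from the
Gaussian velocity trajectory: position (its integral), velocity (the
Gaussian itself), acceleration (its first derivative, biphasic) and jerk
(its second derivative, triphasic).  Each profile is normalized so that its
peak-to-trough range over the trial window equals 1; model weights therefore
carry units of spikes/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "Direction",
    "DirectionGrid",
    "MotionStimulus",
    "TemporalProfiles",
    "make_direction_grid",
    "direction_to_unit_vector",
    "angular_difference",
    "temporal_profiles",
    "kinematic_scaling",
]


@dataclass(frozen=True)
class Direction:
    """A 3D motion direction in spherical coordinates (degrees).

    Azimuth is canonicalized to [0, 360); at the poles (|elevation| = 90)
    azimuth is degenerate and canonicalized to 0 so each pole is a unique
    point.
    """

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation {self.elevation} outside [-90, 90]")
        az = float(self.azimuth) % 360.0
        if abs(self.elevation) == 90.0:
            az = 0.0
        object.__setattr__(self, "azimuth", az)
        object.__setattr__(self, "elevation", float(self.elevation))

    def unit_vector(self) -> np.ndarray:
        return direction_to_unit_vector(self)


@dataclass(frozen=True)
class DirectionGrid:
    """An ordered set of stimulus directions."""

    directions: tuple[Direction, ...]

    def __len__(self) -> int:
        return len(self.directions)

    def __iter__(self):
        return iter(self.directions)

    def __getitem__(self, i: int) -> Direction:
        return self.directions[i]

    def unit_vectors(self) -> np.ndarray:
        """(n, 3) array of Cartesian unit vectors."""
        return np.array([direction_to_unit_vector(d) for d in self.directions])

    def neighbor_pairs(self, separation: float = 45.0, tol: float = 1e-6) -> list[tuple[int, int]]:
        """Index pairs of directions exactly `separation` degrees apart in 3D."""
        pairs = []
        for i in range(len(self.directions)):
            for j in range(i + 1, len(self.directions)):
                if abs(angular_difference(self.directions[i], self.directions[j]) - separation) < tol:
                    pairs.append((i, j))
        return pairs

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "azimuth_deg": [d.azimuth for d in self.directions],
                "elevation_deg": [d.elevation for d in self.directions],
            }
        )

    @classmethod
    def from_dataframe(cls, df) -> "DirectionGrid":
        return cls(
            tuple(
                Direction(a, e)
                for a, e in zip(df["azimuth_deg"], df["elevation_deg"])
            )
        )


def make_direction_grid() -> DirectionGrid:
    """The canonical 26-direction sphere sampling.

    All combinations of azimuth in {0, 45, ..., 315} with elevation in
    {-45, 0, 45}, plus the two poles (elevation -90 and +90).
    """
    dirs = [
        Direction(az, el)
        for el in (-45.0, 0.0, 45.0)
        for az in np.arange(0.0, 360.0, 45.0)
    ]
    dirs.append(Direction(0.0, -90.0))
    dirs.append(Direction(0.0, 90.0))
    return DirectionGrid(tuple(dirs))


def direction_to_unit_vector(d: Direction) -> np.ndarray:
    """Cartesian unit vector [cos(az)cos(el), sin(az)cos(el), sin(el)]."""
    az = np.deg2rad(d.azimuth)
    el = np.deg2rad(d.elevation)
    return np.array(
        [np.cos(az) * np.cos(el), np.sin(az) * np.cos(el), np.sin(el)]
    )


def angular_difference(d1: Direction, d2: Direction) -> float:
    """Angle in degrees ([0, 180]) between two directions in 3D."""
    c = float(np.dot(direction_to_unit_vector(d1), direction_to_unit_vector(d2)))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class MotionStimulus:
    """Kinematics of a single translation trial.

    The velocity profile is a Gaussian of width `sigma` centered at
    `peak_velocity_time`, scaled so the net displacement equals
    `displacement`.  `time_step` sets the evaluation grid (bin centers over
    [0, trial_duration]), which matches the PSTH binning by default.
    """

    sigma: float = 0.2
    peak_velocity_time: float = 1.0
    displacement: float = 0.13
    trial_duration: float = 2.0
    time_step: float = 0.025

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.displacement < 0:
            raise ValueError("displacement must be non-negative")
        if self.time_step <= 0 or self.time_step > self.trial_duration:
            raise ValueError("invalid time_step")

    @property
    def n_bins(self) -> int:
        return int(round(self.trial_duration / self.time_step))

    @property
    def time_grid(self) -> np.ndarray:
        """Bin-center times over the trial window."""
        return (np.arange(self.n_bins) + 0.5) * self.time_step

    def with_time_step(self, time_step: float) -> "MotionStimulus":
        return MotionStimulus(
            sigma=self.sigma,
            peak_velocity_time=self.peak_velocity_time,
            displacement=self.displacement,
            trial_duration=self.trial_duration,
            time_step=time_step,
        )


@dataclass(frozen=True)
class TemporalProfiles:
    """Peak-to-trough-normalized temporal basis profiles over a time grid."""

    time: np.ndarray
    fp: np.ndarray
    fv: np.ndarray
    fa: np.ndarray
    fj: np.ndarray

    def by_kind(self, kind: str) -> np.ndarray:
        return {"position": self.fp, "velocity": self.fv,
                "acceleration": self.fa, "jerk": self.fj}[kind]


def _peak_to_trough_normalize(x: np.ndarray) -> np.ndarray:
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return np.zeros_like(x)
    return x / rng


def temporal_profiles(stim: MotionStimulus, tau0: float = 0.0) -> TemporalProfiles:
    """Evaluate the four temporal basis profiles delayed by `tau0`.

    With u = t - peak_velocity_time - tau0 and Gaussian G(u) = exp(-u^2/2s^2):
    fv = G, fa = (-u/s^2) G (the derivative of fv), fj = ((u^2-s^2)/s^4) G
    (the second derivative), and fp the cumulative integral of G.  Each is
    then normalized so max - min = 1 over the realized trial window.
    """
    if stim.time_step > 0.025 + 1e-12:
        raise ValueError("time grid resolution must be <= 25 ms")
    t = stim.time_grid
    s = stim.sigma
    center = stim.peak_velocity_time + tau0
    if center - 2 * s < t[0] or center + 2 * s > t[-1]:
        warnings.warn(
            "trial window covers less than +/-2 sigma around the profile "
            "center; normalization uses the available window",
            stacklevel=2,
        )
    u = t - center
    g = np.exp(-(u**2) / (2 * s**2))
    fv = g
    fa = (-u / s**2) * g
    fj = ((u**2 - s**2) / s**4) * g
    fp = 0.5 * (1.0 + erf(u / (s * np.sqrt(2.0))))
    return TemporalProfiles(
        time=t,
        fp=_peak_to_trough_normalize(fp),
        fv=_peak_to_trough_normalize(fv),
        fa=_peak_to_trough_normalize(fa),
        fj=_peak_to_trough_normalize(fj),
    )


def kinematic_scaling(stim: MotionStimulus) -> tuple[float, float]:
    """(peak velocity m/s, peak acceleration m/s^2) of the ideal Gaussian.

    Peak velocity = displacement / (sigma * sqrt(2*pi)); peak acceleration
    occurs one sigma from the center, = peak velocity * exp(-1/2) / sigma.
    """
    v_peak = stim.displacement / (stim.sigma * np.sqrt(2 * np.pi))
    a_peak = v_peak * np.exp(-0.5) / stim.sigma
    return float(v_peak), float(a_peak)
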