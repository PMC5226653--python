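"""Population-level derived statistics.

Summaries computed across a fitted population: response modulation
amplitudes, the offset/cosine decomposition of spatial tuning, ternary
coordinates of normalized component weights, distributions of angles between
component preferred directions with their chance (H1) and perfectly aligned
(H2) reference distributions, a resampling-based 3D Rayleigh uniformity
test, the position ratio of four-component fits, and bootstrap confidence
intervals of medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .model import ModelParams, predict_firing_rate, spatial_nonlinearity
from .stimulus import (
    Direction,
    MotionStimulus,
    angular_difference,
    direction_to_unit_vector,
    temporal_profiles,
)

__all__ = [
    "AngleDistribution",
    "peak_to_trough_modulation",
    "component_modulation",
    "offset_cosine_decomposition",
    "pd_angle_distribution",
    "h1_null",
    "h2_null",
    "ks_test_vs_null",
    "rayleigh_uniformity",
    "position_ratio",
    "bootstrap_median_ci",
    "ternary_coordinates",
]

_PAIR_LETTERS = {"P": "p", "V": "v", "A": "a", "J": "j"}


def _sph_grid(step_deg: float) -> np.ndarray:
    az = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    el = np.deg2rad(np.arange(-90.0, 90.0 + 1e-9, step_deg))
    AZ, EL = np.meshgrid(az, el)
    return np.column_stack(
        [
            (np.cos(AZ) * np.cos(EL)).ravel(),
            (np.sin(AZ) * np.cos(EL)).ravel(),
            np.sin(EL).ravel(),
        ]
    )


def _response(
    params: ModelParams,
    U: np.ndarray,
    stim: MotionStimulus,
    kinds: tuple[str, ...] | None = None,
    with_baseline: bool = True,
    rectify: bool = True,
) -> np.ndarray:
    """Model response over arbitrary unit vectors, shape (n_dirs, n_bins)."""
    profiles = temporal_profiles(stim, params.delay)
    rate = np.full((U.shape[0], len(stim.time_grid)),
                   params.baseline if with_baseline else 0.0)
    for c in params.components:
        if kinds is not None and c.kind not in kinds:
            continue
        g = np.clip(U @ direction_to_unit_vector(c.tuning.pd), -1.0, 1.0)
        y = spatial_nonlinearity(g, c.tuning.offset)
        rate += c.weight * np.outer(y, profiles.by_kind(c.kind))
    if rectify:
        np.maximum(rate, 0.0, out=rate)
    return rate


def _max_ptt(
    params: ModelParams,
    stim: MotionStimulus,
    kinds: tuple[str, ...] | None,
    with_baseline: bool,
    rectify: bool,
    grid_step: float = 3.0,
    refine: bool = True,
) -> float:
    """Max over directions of the temporal peak-to-trough of the response.

    Searched on a dense azimuth x elevation grid, then refined with a local
    simplex optimization over (azimuth, elevation).
    """
    U = _sph_grid(grid_step)
    resp = _response(params, U, stim, kinds, with_baseline, rectify)
    ptt = resp.max(axis=1) - resp.min(axis=1)
    i = int(np.argmax(ptt))
    best = float(ptt[i])
    if not refine:
        return best
    az0 = float(np.rad2deg(np.arctan2(U[i, 1], U[i, 0])))
    el0 = float(np.rad2deg(np.arcsin(np.clip(U[i, 2], -1, 1))))

    def neg_ptt(x):
        az, el = x
        el = float(np.clip(el, -90.0, 90.0))
        u = direction_to_unit_vector(Direction(az % 360.0, el))[None, :]
        r = _response(params, u, stim, kinds, with_baseline, rectify)
        return -(r.max() - r.min())

    res = minimize(neg_ptt, [az0, el0], method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-9})
    return max(best, float(-res.fun))


def peak_to_trough_modulation(
    params: ModelParams, stim: MotionStimulus | None = None, refine: bool = True
) -> float:
    """Largest temporal peak-to-trough of the rectified fitted response
    over all motion directions (spikes/s)."""
    stim = stim or MotionStimulus()
    return _max_ptt(params, stim, kinds=None, with_baseline=True,
                    rectify=True, refine=refine)


def component_modulation(
    params: ModelParams,
    kind: str,
    stim: MotionStimulus | None = None,
    refine: bool = True,
) -> float:
    """Largest peak-to-trough of a single fitted component (no baseline,
    no rectification) over all motion directions (spikes/s)."""
    stim = stim or MotionStimulus()
    return _max_ptt(params, stim, kinds=(kind,), with_baseline=False,
                    rectify=False, refine=refine)


def position_ratio(
    params: ModelParams, stim: MotionStimulus | None = None
) -> float:
    """Position-component modulation over total modulation, in [0, 1].

    Requires a fit that includes a position component.  Equals 1 only when
    the non-position weights vanish.
    """
    if "position" not in params.spec.components:
        raise ValueError("position ratio requires a fit with a position component")
    stim = stim or MotionStimulus()
    total = peak_to_trough_modulation(params, stim)
    if total <= 0:
        raise ValueError("total modulation is zero; position ratio undefined")
    pos = component_modulation(params, "position", stim)
    return float(np.clip(pos / total, 0.0, 1.0))


def offset_cosine_decomposition(
    weights: dict[str, float], offsets: dict[str, float]
) -> dict[str, tuple[float, float]]:
    """Split each component's weighted tuning into cosine and offset parts.

    Returns per component (w * (1 - |o|), w * o): abscissa and ordinate of
    the cosine-vs-offset scatter.  Pass normalized weights to reproduce the
    population summary convention.
    """
    return {
        k: (w * (1.0 - abs(offsets[k])), w * offsets[k])
        for k, w in weights.items()
    }


@dataclass(frozen=True)
class AngleDistribution:
    """Angles between the preferred directions of one component pair."""

    pair: str
    angles: np.ndarray
    neuron_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.size and (a.min() < 0 or a.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")
        object.__setattr__(self, "angles", a)


def pd_angle_distribution(pop: pd.DataFrame, pair: str) -> AngleDistribution:
    """Angular PD differences for a component pair across a population table.

    `pair` is e.g. "V-A".  Only neurons whose BIC-best model contains both
    components are included (single-component best fits never are).
    The table needs columns best_model, pd_<x>_az, pd_<x>_el.
    """
    a, b = pair.upper().split("-")
    la, lb = _PAIR_LETTERS[a], _PAIR_LETTERS[b]
    angles, ids = [], []
    for _, row in pop.iterrows():
        best = str(row["best_model"]).upper()
        if a not in best or b not in best:
            continue
        d1 = Direction(row[f"pd_{la}_az"], row[f"pd_{la}_el"])
        d2 = Direction(row[f"pd_{lb}_az"], row[f"pd_{lb}_el"])
        angles.append(angular_difference(d1, d2))
        ids.append(str(row.get("neuron_id", len(ids))))
    return AngleDistribution(pair=f"{a}-{b}", angles=np.array(angles),
                             neuron_ids=tuple(ids))


def h1_null(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Angles (deg) between independent area-uniform direction pairs.

    The chance distribution for unrelated preferred directions: density
    proportional to sin(angle)/2, CDF (1 - cos(angle))/2, median 90 deg.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    return np.rad2deg(np.arccos(rng.uniform(-1.0, 1.0, size=n)))


def h2_null(n: int) -> np.ndarray:
    """Degenerate perfectly-aligned reference: all angles zero."""
    return np.zeros(n)


def ks_test_vs_null(angles: np.ndarray, null: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov p-value of angles against a null sample."""
    angles = np.asarray(angles, float)
    null = np.asarray(null, float)
    if angles.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    if angles.size < 5:
        import warnings

        warnings.warn("fewer than 5 angles: KS test is underpowered", stacklevel=2)
    return float(stats.ks_2samp(angles, null).pvalue)


def rayleigh_uniformity(
    pds: list[Direction],
    n_resamples: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """3D Rayleigh test of PD uniformity on the sphere.

    R is the norm of the mean PD unit vector; the p-value is the fraction
    of R values from `n_resamples` area-uniform populations of the same
    size that reach or exceed the observed R.
    """
    if len(pds) < 5:
        raise ValueError("need at least 5 directions")
    rng = rng if rng is not None else np.random.default_rng(0)
    V = np.array([direction_to_unit_vector(d) for d in pds])
    R = float(np.linalg.norm(V.mean(axis=0)))
    n = len(pds)
    z = rng.uniform(-1.0, 1.0, size=(n_resamples, n))
    phi = rng.uniform(0.0, 2 * np.pi, size=(n_resamples, n))
    s = np.sqrt(1.0 - z**2)
    sim = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1)  # (m, n, 3)
    R_sim = np.linalg.norm(sim.mean(axis=1), axis=1)
    p = float(np.mean(R_sim >= R))
    return R, p


def bootstrap_median_ci(
    values,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile-bootstrap confidence interval of the median."""
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    rng = rng if rng is not None else np.random.default_rng(0)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return float(np.median(values)), float(lo), float(hi)


#: ternary corner layout: first weight at the origin corner, second at (1, 0),
#: third at the apex.
_TERNARY_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def ternary_coordinates(w) -> np.ndarray:
    """Barycentric embedding of three normalized weights in the plane.

    `w` is a length-3 sequence summing to 1 (e.g. normalized velocity,
    acceleration, jerk weights); returns (x, y) in the unit equilateral
    triangle.
    """
    w = np.asarray(w, float)
    if w.shape != (3,):
        raise ValueError("expected exactly three weights")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return w @ _TERNARY_CORNERS
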