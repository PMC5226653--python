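"""PSTH construction and response-screening criteria.

Spike trains are binned at 25 ms per trial, averaged across repetitions per
direction, and smoothed with a Gaussian kernel (sigma = 100 ms) to form the
direction x time firing-rate matrix the models are fitted to.  Raw
(unsmoothed) per-trial binned rates are retained for the two inclusion
criteria:

* temporal response modulation — for each direction, the per-trial firing
  rates at the PSTH peak (trough) bin are compared against pooled
  baseline-window rates with a Wilcoxon rank-sum test; the cell passes if
  two neighboring directions (45 deg apart in 3D) are both significant.
* space-time structure — a two-way ANOVA (direction x time bin, with
  interaction) on the single-trial binned rates; the cell passes if both
  main effects and the interaction are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .stimulus import DirectionGrid, make_direction_grid

__all__ = [
    "SpikeTrainSet",
    "PSTHMatrix",
    "ScreeningResult",
    "build_psth",
    "temporal_modulation_test",
    "spacetime_anova",
    "screen",
]


@dataclass(frozen=True)
class SpikeTrainSet:
    """Trial-resolved spike times keyed by (direction index, repetition)."""

    trains: dict[tuple[int, int], np.ndarray]
    grid: DirectionGrid
    n_reps: int
    trial_duration: float = 2.0

    def __post_init__(self) -> None:
        for (d, r), t in self.trains.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.trial_duration):
                raise ValueError(
                    f"spike time outside [0, {self.trial_duration}] s for "
                    f"direction {d}, repetition {r}"
                )
            if np.any(np.diff(t) < 0):
                t = np.sort(t)
            self.trains[(d, r)] = t

    def spikes(self, direction: int, rep: int) -> np.ndarray:
        return self.trains[(direction, rep)]

    @property
    def n_spikes(self) -> int:
        return sum(len(t) for t in self.trains.values())

    def to_dataframe(self, neuron_id: str = "n0"):
        import pandas as pd

        rows = []
        for (d, r), t in sorted(self.trains.items()):
            for s in t:
                rows.append((neuron_id, d, r, s))
        return pd.DataFrame(
            rows, columns=["neuron_id", "direction_index", "repetition", "spike_time_s"]
        )


@dataclass(frozen=True)
class PSTHMatrix:
    """Direction x time firing-rate matrix with trial-level provenance.

    `rates` is the smoothed trial-averaged PSTH (spikes/s); `per_trial_rates`
    holds the raw binned single-trial rates, shape (n_dir, n_reps, n_bins).
    """

    rates: np.ndarray
    grid: DirectionGrid
    bin_width: float = 0.025
    smoothing_sigma: float = 0.1
    per_trial_rates: np.ndarray | None = None
    baseline_window: tuple[float, float] = (0.0, 0.25)

    def __post_init__(self) -> None:
        if np.any(self.rates < -1e-9):
            raise ValueError("firing rates must be non-negative")

    @property
    def n_directions(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def trial_duration(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def time_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def baseline_bins(self) -> np.ndarray:
        t = self.time_centers
        lo, hi = self.baseline_window
        return np.flatnonzero((t >= lo) & (t <= hi))


def build_psth(
    spikes: SpikeTrainSet,
    bin_width: float = 0.025,
    smoothing_sigma: float = 0.1,
    baseline_window: tuple[float, float] = (0.0, 0.25),
) -> PSTHMatrix:
    """Bin, trial-average and Gaussian-smooth a spike-train set.

    Every (direction, repetition) cell of the protocol must be present
    (empty trains are fine); a missing cell raises.
    """
    n_dir = len(spikes.grid)
    n_bins = int(round(spikes.trial_duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    per_trial = np.empty((n_dir, spikes.n_reps, n_bins))
    for d in range(n_dir):
        for r in range(spikes.n_reps):
            if (d, r) not in spikes.trains:
                raise ValueError(f"missing spike train for direction {d}, rep {r}")
            counts, _ = np.histogram(spikes.trains[(d, r)], bins=edges)
            per_trial[d, r] = counts / bin_width
    mean_rates = per_trial.mean(axis=1)
    smoothed = gaussian_filter1d(
        mean_rates, sigma=smoothing_sigma / bin_width, axis=1, mode="nearest"
    )
    return PSTHMatrix(
        rates=smoothed,
        grid=spikes.grid,
        bin_width=bin_width,
        smoothing_sigma=smoothing_sigma,
        per_trial_rates=per_trial,
        baseline_window=baseline_window,
    )


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the two inclusion criteria."""

    passes_temporal: bool
    passes_spacetime: bool
    peak_p: np.ndarray | None = None
    trough_p: np.ndarray | None = None
    anova_p: dict | None = None

    @property
    def included(self) -> bool:
        return self.passes_temporal and self.passes_spacetime


def _ranksum_p(sample: np.ndarray, baseline: np.ndarray, alternative: str) -> float:
    if np.ptp(np.concatenate([sample, baseline])) == 0:
        return 1.0
    return float(
        stats.mannwhitneyu(sample, baseline, alternative=alternative).pvalue
    )


def temporal_modulation_test(psth: PSTHMatrix, alpha: float = 0.01) -> ScreeningResult:
    """Peak/trough firing vs baseline, per direction, with 45-deg conjunction.

    For each direction, the per-trial smoothed firing rate at the PSTH peak
    (trough) bin is compared against the per-trial mean baseline-window
    rates with a one-sided rank-sum test.  The peak (trough) bin for each
    trial is located on the smoothed average of the *other* trials
    (leave-one-out), which removes the selection bias a shared argmax would
    otherwise induce under the null.  The cell passes if some pair of
    directions 45 deg apart is significant for the peak, or some pair for
    the trough.
    """
    if psth.per_trial_rates is None:
        raise ValueError("per-trial rates required for screening")
    n_reps = psth.per_trial_rates.shape[1]
    if n_reps < 5:
        raise ValueError("temporal modulation test requires >= 5 repetitions")
    smoothed_trials = gaussian_filter1d(
        psth.per_trial_rates, sigma=psth.smoothing_sigma / psth.bin_width,
        axis=-1, mode="nearest",
    )
    base_bins = psth.baseline_bins
    n_dir = psth.n_directions
    peak_p = np.ones(n_dir)
    trough_p = np.ones(n_dir)
    for d in range(n_dir):
        trials = smoothed_trials[d]  # (reps, bins)
        baseline = psth.per_trial_rates[d][:, base_bins].mean(axis=1)
        peak_vals = np.empty(n_reps)
        trough_vals = np.empty(n_reps)
        for r in range(n_reps):
            others = trials[np.arange(n_reps) != r].mean(axis=0)
            peak_vals[r] = trials[r, int(np.argmax(others))]
            trough_vals[r] = trials[r, int(np.argmin(others))]
        peak_p[d] = _ranksum_p(peak_vals, baseline, "greater")
        trough_p[d] = _ranksum_p(trough_vals, baseline, "less")
    pairs = psth.grid.neighbor_pairs(45.0)
    sig_peak = peak_p < alpha
    sig_trough = trough_p < alpha
    passes = any(sig_peak[i] and sig_peak[j] for i, j in pairs) or any(
        sig_trough[i] and sig_trough[j] for i, j in pairs
    )
    return ScreeningResult(
        passes_temporal=bool(passes),
        passes_spacetime=False,
        peak_p=peak_p,
        trough_p=trough_p,
    )


def spacetime_anova(
    psth: PSTHMatrix, alpha: float = 0.001, use_smoothed: bool = False
) -> ScreeningResult:
    """Balanced two-way ANOVA (direction x time, with interaction).

    Computed from the closed-form sums of squares of the balanced design on
    the single-trial binned rates.  The cell passes if the direction and
    time main effects and their interaction are all significant.  Raw
    (unsmoothed) bins are the default; `use_smoothed` runs the ANOVA on
    kernel-smoothed per-trial rates instead, which raises sensitivity at
    the cost of correlated residuals (an anticonservative convention some
    analyses adopt).
    """
    if psth.per_trial_rates is None:
        raise ValueError("per-trial rates required for screening")
    y = psth.per_trial_rates  # (a, n, b)
    if use_smoothed:
        y = gaussian_filter1d(
            y, sigma=psth.smoothing_sigma / psth.bin_width, axis=-1, mode="nearest"
        )
    a, n, b = y.shape
    if n < 2:
        raise ValueError("ANOVA requires >= 2 repetitions")
    grand = y.mean()
    cell = y.mean(axis=1)  # (a, b)
    row = cell.mean(axis=1)  # (a,)
    col = cell.mean(axis=0)  # (b,)
    ss_a = n * b * np.sum((row - grand) ** 2)
    ss_b = n * a * np.sum((col - grand) ** 2)
    ss_ab = n * np.sum((cell - row[:, None] - col[None, :] + grand) ** 2)
    ss_e = np.sum((y - cell[:, None, :]) ** 2)
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)
    mse = ss_e / df_e
    if mse == 0:
        # degenerate noiseless data: effects are significant iff nonzero
        p = {
            "space": 0.0 if ss_a > 0 else 1.0,
            "time": 0.0 if ss_b > 0 else 1.0,
            "interaction": 0.0 if ss_ab > 0 else 1.0,
        }
    else:
        p = {
            "space": float(stats.f.sf(ss_a / df_a / mse, df_a, df_e)),
            "time": float(stats.f.sf(ss_b / df_b / mse, df_b, df_e)),
            "interaction": float(stats.f.sf(ss_ab / df_ab / mse, df_ab, df_e)),
        }
    passes = all(v < alpha for v in p.values())
    return ScreeningResult(passes_temporal=False, passes_spacetime=passes, anova_p=p)


def screen(
    psth: PSTHMatrix,
    alpha_temporal: float = 0.01,
    alpha_anova: float = 0.001,
    anova_use_smoothed: bool = False,
) -> ScreeningResult:
    """Apply both inclusion criteria and combine the results."""
    t = temporal_modulation_test(psth, alpha_temporal)
    s = spacetime_anova(psth, alpha_anova, use_smoothed=anova_use_smoothed)
    return ScreeningResult(
        passes_temporal=t.passes_temporal,
        passes_spacetime=s.passes_spacetime,
        peak_p=t.peak_p,
        trough_p=t.trough_p,
        anova_p=s.anova_p,
    )
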