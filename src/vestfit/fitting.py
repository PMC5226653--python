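"""Model fitting, goodness of fit, and BIC-based model selection.

`SpatioTemporalTuningModel` is a statsmodels-style model object built from a
`PSTHMatrix`.  `fit(spec)` minimizes the residual sum of squares between the
rectified model prediction and the smoothed direction x time PSTH by bounded
nonlinear least squares, and returns a `TuningFitResults`.  `fit_family()`
fits the canonical family (V, A, J, VA, VJ, AJ, VAJ plus the separable VAJ
variant and, on request, PVAJ), selects the best member by BIC, and derives
the partial-R2 and separability summaries.

The objective is multimodal in the preferred directions, so each fit is
multi-started.  The key device is a linear profiling initializer: for a
fixed delay tau0 and before rectification, the model is linear in the
per-component vectors w = W (1 - |o|) * pd_unit_vector and scalars
b = W * o, plus the baseline — so an ordinary least-squares solve yields
near-optimal starting values for every spatial parameter at once.  Starts
from warm embeddings of nested submodel solutions guarantee that R2 never
decreases along nested model chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import (
    CANONICAL_SPECS,
    PVAJ,
    SEPARABLE_VAJ,
    Component,
    ModelParams,
    ModelSpec,
    SpatialTuning,
    count_free_parameters,
    predict_firing_rate,
    spatial_nonlinearity,
)
from .psth import PSTHMatrix
from .stimulus import (
    Direction,
    MotionStimulus,
    angular_difference,
    direction_to_unit_vector,
    temporal_profiles,
)

__all__ = [
    "FitBounds",
    "SpatioTemporalTuningModel",
    "TuningFitResults",
    "ModelFamilyResults",
    "bic",
    "effective_n",
    "partial_r2",
    "separability_index",
    "normalized_weights",
    "select_best_model",
]


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the optimizer (units: spikes/s, seconds)."""

    weight: tuple[float, float] = (0.0, 500.0)
    baseline: tuple[float, float] = (0.0, 300.0)
    offset: tuple[float, float] = (-1.0, 1.0)
    delay: tuple[float, float] = (-0.1, 0.3)
    elevation: tuple[float, float] = (-90.0, 90.0)
    azimuth: tuple[float, float] = (-360.0, 720.0)


def bic(rss: float, n_effective: int, p: int) -> float:
    """Bayesian Information Criterion, n log(RSS/n) + p log(n) (natural log).

    A perfect fit (RSS = 0) returns -inf.
    """
    if n_effective <= 0 or p < 1:
        raise ValueError("need n > 0 and p >= 1")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        return float("-inf")
    return float(n_effective * np.log(rss / n_effective) + p * np.log(n_effective))


def effective_n(psth: PSTHMatrix) -> int:
    """Effective number of independent data points for BIC.

    Gaussian smoothing with kernel sigma leaves roughly one independent
    sample per 2*sigma of time, so each profile contributes
    round(duration / (2 sigma)) points; 26 x 10 = 260 for the default
    protocol.
    """
    per_profile = int(round(psth.trial_duration / (2.0 * psth.smoothing_sigma)))
    return psth.n_directions * per_profile


def normalized_weights(params: ModelParams) -> dict[str, float]:
    """Component weights divided by their sum (sums to 1)."""
    w = params.weights
    total = sum(w.values())
    if total <= 0:
        raise ValueError("cannot normalize all-zero weights")
    return {k: v / total for k, v in w.items()}


# ---------------------------------------------------------------------------
# parameter vector packing


def _pack(params: ModelParams) -> np.ndarray:
    x = [params.delay, params.baseline]
    if params.spec.separable:
        t = params.components[0].tuning
        x += [t.pd.azimuth, t.pd.elevation, t.offset]
        x += [c.weight for c in params.components]
    else:
        for c in params.components:
            x += [c.weight, c.tuning.pd.azimuth, c.tuning.pd.elevation, c.tuning.offset]
    return np.array(x, dtype=float)


def _unpack(x: np.ndarray, spec: ModelSpec) -> ModelParams:
    delay, baseline = float(x[0]), max(float(x[1]), 0.0)
    comps = []
    if spec.separable:
        tuning = SpatialTuning(
            pd=Direction(float(x[2]), float(np.clip(x[3], -90, 90))),
            offset=float(np.clip(x[4], -1, 1)),
        )
        for i, kind in enumerate(spec.components):
            comps.append(Component(kind, max(float(x[5 + i]), 0.0), tuning))
    else:
        for i, kind in enumerate(spec.components):
            w, az, el, o = x[2 + 4 * i : 6 + 4 * i]
            comps.append(
                Component(
                    kind,
                    max(float(w), 0.0),
                    SpatialTuning(
                        pd=Direction(float(az), float(np.clip(el, -90, 90))),
                        offset=float(np.clip(o, -1, 1)),
                    ),
                )
            )
    return ModelParams(spec=spec, components=tuple(comps), delay=delay, baseline=baseline)


def _bounds_for(spec: ModelSpec, b: FitBounds) -> tuple[np.ndarray, np.ndarray]:
    lo = [b.delay[0], b.baseline[0]]
    hi = [b.delay[1], b.baseline[1]]
    if spec.separable:
        lo += [b.azimuth[0], b.elevation[0], b.offset[0]]
        hi += [b.azimuth[1], b.elevation[1], b.offset[1]]
        lo += [b.weight[0]] * len(spec.components)
        hi += [b.weight[1]] * len(spec.components)
    else:
        for _ in spec.components:
            lo += [b.weight[0], b.azimuth[0], b.elevation[0], b.offset[0]]
            hi += [b.weight[1], b.azimuth[1], b.elevation[1], b.offset[1]]
    return np.array(lo), np.array(hi)


def _embed(sub: ModelParams, spec: ModelSpec) -> ModelParams:
    """Embed a submodel solution into a supermodel (new weights zero)."""
    by_kind = {c.kind: c for c in sub.components}
    if spec.separable:
        # shared tuning from the submodel's dominant component
        dom = max(sub.components, key=lambda c: c.weight)
        comps = tuple(
            Component(k, by_kind[k].weight if k in by_kind else 0.0, dom.tuning)
            for k in spec.components
        )
    else:
        comps = tuple(
            by_kind.get(k)
            or Component(k, 0.0, SpatialTuning(Direction(0.0, 0.0), 0.0))
            for k in spec.components
        )
    return ModelParams(spec=spec, components=comps, delay=sub.delay, baseline=sub.baseline)


# ---------------------------------------------------------------------------
# model


class SpatioTemporalTuningModel:
    """Spatio-temporal tuning model of one neuron's direction x time PSTH.

    Parameters
    ----------
    psth : PSTHMatrix
        Smoothed trial-averaged firing-rate matrix (directions x time bins).
    stimulus : MotionStimulus, optional
        Trial kinematics; defaults to the standard protocol evaluated on
        the PSTH's own time bins.
    bounds : FitBounds, optional
        Optimizer box constraints.
    """

    def __init__(
        self,
        psth: PSTHMatrix,
        stimulus: MotionStimulus | None = None,
        bounds: FitBounds | None = None,
    ):
        self.psth = psth
        if stimulus is None:
            stimulus = MotionStimulus(
                trial_duration=psth.trial_duration, time_step=psth.bin_width
            )
        if len(stimulus.time_grid) != psth.n_bins:
            raise ValueError("stimulus time grid does not match PSTH bins")
        self.stimulus = stimulus
        self.bounds = bounds or FitBounds()
        self._data = psth.rates
        self._flat = self._data.ravel()
        self._U = psth.grid.unit_vectors()
        grand = self._flat.mean()
        self._tss = float(np.sum((self._flat - grand) ** 2))
        if self._tss == 0:
            raise ValueError("flat PSTH: variance is zero, R2 undefined")

    @classmethod
    def from_spike_trains(cls, spikes, stimulus=None, **psth_kwargs):
        from .psth import build_psth

        return cls(build_psth(spikes, **psth_kwargs), stimulus=stimulus)

    # -- prediction --------------------------------------------------------

    def predict(self, params: ModelParams, rectify: bool = True) -> np.ndarray:
        return predict_firing_rate(params, self.psth.grid, self.stimulus, rectify)

    def _residuals(self, x: np.ndarray, spec: ModelSpec) -> np.ndarray:
        profiles = temporal_profiles(self.stimulus, float(x[0]))
        rate = np.full_like(self._data, float(x[1]))
        if spec.separable:
            az, el, o = x[2], np.clip(x[3], -90, 90), np.clip(x[4], -1, 1)
            u = _sph_unit(az, el)
            y = spatial_nonlinearity(np.clip(self._U @ u, -1, 1), float(o))
            for i, kind in enumerate(spec.components):
                rate += x[5 + i] * np.outer(y, profiles.by_kind(kind))
        else:
            for i, kind in enumerate(spec.components):
                w, az, el, o = x[2 + 4 * i : 6 + 4 * i]
                u = _sph_unit(az, np.clip(el, -90, 90))
                y = spatial_nonlinearity(
                    np.clip(self._U @ u, -1, 1), float(np.clip(o, -1, 1))
                )
                rate += w * np.outer(y, profiles.by_kind(kind))
        np.maximum(rate, 0.0, out=rate)
        return rate.ravel() - self._flat

    def _cost(self, x: np.ndarray, spec: ModelSpec) -> float:
        r = self._residuals(x, spec)
        return float(r @ r)

    # -- initialization ----------------------------------------------------

    def _linear_init(self, spec: ModelSpec, tau0: float) -> np.ndarray:
        """Profile all spatial parameters linearly at fixed delay."""
        profiles = temporal_profiles(self.stimulus, tau0)
        k = len(spec.components)
        n_dir, n_bins = self._data.shape
        cols = []
        for kind in spec.components:
            f = profiles.by_kind(kind)
            for ax in range(3):
                cols.append(np.outer(self._U[:, ax], f).ravel())
            cols.append(np.outer(np.ones(n_dir), f).ravel())
        cols.append(np.ones(n_dir * n_bins))
        A = np.column_stack(cols)
        sol, *_ = np.linalg.lstsq(A, self._flat, rcond=None)
        b = self.bounds
        x = [tau0, float(np.clip(sol[-1], *b.baseline))]
        per_comp = []
        for i, kind in enumerate(spec.components):
            wvec = sol[4 * i : 4 * i + 3]
            off_term = float(sol[4 * i + 3])
            m = float(np.linalg.norm(wvec))
            W = m + abs(off_term)
            if W <= 1e-12:
                per_comp.append((0.0, 0.0, 0.0, 0.0))
                continue
            o = off_term / W
            if m > 1e-12:
                az = float(np.rad2deg(np.arctan2(wvec[1], wvec[0]))) % 360.0
                el = float(np.rad2deg(np.arcsin(np.clip(wvec[2] / m, -1, 1))))
            else:
                az, el = 0.0, 0.0
            per_comp.append(
                (
                    float(np.clip(W, *b.weight)),
                    az,
                    el,
                    float(np.clip(o, *b.offset)),
                )
            )
        if spec.separable:
            # shared tuning: weight-averaged direction of component vectors
            vecs = []
            for i, (W, az, el, o) in enumerate(per_comp):
                m = W * (1 - abs(o))
                vecs.append(m * _sph_unit(az, el))
            vsum = np.sum(vecs, axis=0)
            if np.linalg.norm(vsum) > 1e-12:
                az = float(np.rad2deg(np.arctan2(vsum[1], vsum[0]))) % 360.0
                el = float(
                    np.rad2deg(np.arcsin(np.clip(vsum[2] / np.linalg.norm(vsum), -1, 1)))
                )
            else:
                az, el = 0.0, 0.0
            o_shared = float(
                np.clip(
                    np.average(
                        [c[3] for c in per_comp],
                        weights=[max(c[0], 1e-9) for c in per_comp],
                    ),
                    *b.offset,
                )
            )
            x += [az, el, o_shared] + [c[0] for c in per_comp]
        else:
            for W, az, el, o in per_comp:
                x += [W, az, el, o]
        return np.array(x, dtype=float)

    def _random_start(self, spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
        b = self.bounds
        scale = max(self._flat.max() - self._flat.min(), 1.0)
        x = [rng.uniform(0.0, 0.15), float(np.clip(self._flat.mean(), *b.baseline))]

        def tuning():
            return [
                rng.uniform(0, 360),
                float(np.rad2deg(np.arcsin(rng.uniform(-1, 1)))),
                rng.uniform(-0.5, 0.5),
            ]

        if spec.separable:
            x += tuning()
            x += list(rng.uniform(0.1, 1.0, len(spec.components)) * scale)
        else:
            for _ in spec.components:
                x += [rng.uniform(0.1, 1.0) * scale, *tuning()]
        lo, hi = _bounds_for(spec, b)
        return np.clip(np.array(x), lo, hi)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        spec: ModelSpec | str = "VAJ",
        *,
        warm_starts: tuple[ModelParams, ...] = (),
        delay_grid: tuple[float, ...] = (0.0, 0.05, 0.1),
        n_random_starts: int = 1,
        n_polish: int = 2,
        seed: int = 0,
        max_nfev: int | None = None,
        xtol: float = 1e-8,
    ) -> "TuningFitResults":
        """Fit one model spec by multi-start bounded least squares.

        Candidate starts come from the linear profiling initializer on a
        small delay grid, from embeddings of any `warm_starts` (nested
        submodel solutions), and from seeded random draws.  The `n_polish`
        best candidates (by initial cost) are refined with a trust-region
        least-squares solver; the returned solution is the best over all
        polished and unpolished candidates, so a warm start can never be
        degraded.
        """
        if isinstance(spec, str):
            spec = ModelSpec.from_string(spec)
        rng = np.random.default_rng(seed)
        lo, hi = _bounds_for(spec, self.bounds)
        starts: list[np.ndarray] = []
        for tau0 in delay_grid:
            starts.append(np.clip(self._linear_init(spec, tau0), lo, hi))
        for ws in warm_starts:
            starts.append(np.clip(_pack(_embed(ws, spec)), lo, hi))
        for _ in range(n_random_starts):
            starts.append(self._random_start(spec, rng))
        costs = [self._cost(x, spec) for x in starts]
        order = np.argsort(costs)
        best_x, best_cost = starts[order[0]], costs[order[0]]
        converged = False
        for idx in order[:n_polish]:
            res = least_squares(
                self._residuals,
                starts[idx],
                args=(spec,),
                bounds=(lo, hi),
                method="trf",
                xtol=xtol,
                max_nfev=max_nfev,
            )
            cost = float(2.0 * res.cost)
            if cost < best_cost:
                best_x, best_cost = res.x, cost
                converged = res.status > 0
        params = _unpack(best_x, spec)
        rss = best_cost
        n_eff = effective_n(self.psth)
        p = count_free_parameters(spec)
        return TuningFitResults(
            model=self,
            spec=spec,
            params=params,
            rss=rss,
            r2=1.0 - rss / self._tss,
            bic=bic(rss, n_eff, p),
            n_effective=n_eff,
            p=p,
            converged=converged,
        )

    def fit_family(
        self,
        include_pvaj: bool = False,
        seed: int = 0,
        **fit_kwargs,
    ) -> "ModelFamilyResults":
        """Fit the canonical model family and derive the comparison summary.

        Supermodels are warm-started from their fitted submodels, which
        enforces R2 monotonicity along nested chains.
        """
        fits: dict[str, TuningFitResults] = {}

        def do(name: str, warm: tuple[str, ...] = ()):
            spec = ModelSpec.from_string(name)
            ws = tuple(fits[w].params for w in warm)
            fits[name] = self.fit(spec, warm_starts=ws, seed=seed, **fit_kwargs)

        do("V")
        do("A")
        do("J")
        do("VA", ("V", "A"))
        do("VJ", ("V", "J"))
        do("AJ", ("A", "J"))
        do("SepVAJ", ("V", "A", "J"))
        do("VAJ", ("VA", "VJ", "AJ", "SepVAJ"))
        if include_pvaj:
            do("PVAJ", ("VAJ",))
        return ModelFamilyResults(model=self, fits=fits)


def _sph_unit(az_deg: float, el_deg: float) -> np.ndarray:
    az = np.deg2rad(az_deg)
    el = np.deg2rad(el_deg)
    return np.array([np.cos(az) * np.cos(el), np.sin(az) * np.cos(el), np.sin(el)])


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class TuningFitResults:
    """Fit of one model spec: parameters, goodness of fit, information score."""

    model: SpatioTemporalTuningModel
    spec: ModelSpec
    params: ModelParams
    rss: float
    r2: float
    bic: float
    n_effective: int
    p: int
    converged: bool

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.psth.rates - self.fittedvalues

    def normalized_weights(self) -> dict[str, float]:
        return normalized_weights(self.params)

    def summary(self) -> str:
        lines = [
            f"Spatio-temporal tuning fit: {self.spec.name} model",
            f"  R2 = {self.r2:.4f}   RSS = {self.rss:.2f}   "
            f"BIC = {self.bic:.2f} (n = {self.n_effective}, p = {self.p})",
            f"  delay tau0 = {self.params.delay * 1e3:.1f} ms   "
            f"baseline FR0 = {self.params.baseline:.1f} spikes/s",
        ]
        for c in self.params.components:
            lines.append(
                f"  {c.kind:<12s} W = {c.weight:7.2f} spikes/s   "
                f"PD = ({c.tuning.pd.azimuth:6.1f}, {c.tuning.pd.elevation:6.1f}) deg"
                f"   offset = {c.tuning.offset:+.3f}"
            )
        return "\n".join(lines)


def partial_r2(fits: dict[str, "TuningFitResults"]) -> dict[str, float]:
    """Partial coefficient of determination of each VAJ component.

    partial R2 of A given V and J is (R2_VAJ - R2_VJ) / (1 - R2_VJ), etc.
    Slightly negative numerators from optimizer noise are clipped at 0.
    """
    out = {}
    full = fits["VAJ"].r2
    for comp, reduced in (("velocity", "AJ"), ("acceleration", "VJ"), ("jerk", "VA")):
        r2_red = fits[reduced].r2
        if r2_red >= 1.0:
            raise ValueError(f"reduced model {reduced} has R2 = 1; partial undefined")
        out[comp] = max(0.0, (full - r2_red) / (1.0 - r2_red))
    return out


def separability_index(fits: dict[str, "TuningFitResults"]) -> float:
    """R2 of the shared-tuning VAJ model over R2 of the full VAJ model.

    1 means spatial and temporal tuning factorize exactly.
    """
    if fits["VAJ"].r2 <= 0:
        raise ValueError("R2 of the VAJ model is not positive; SepI undefined")
    return fits["SepVAJ"].r2 / fits["VAJ"].r2


def select_best_model(fits: dict[str, "TuningFitResults"]) -> ModelSpec:
    """Lowest-BIC spec among the canonical seven; ties favor fewer parameters."""
    names = [s.name for s in CANONICAL_SPECS]
    best = min(names, key=lambda n: (fits[n].bic, fits[n].p))
    return fits[best].spec


@dataclass(frozen=True)
class ModelFamilyResults:
    """Fits of the whole model family for one neuron, plus derived summaries."""

    model: SpatioTemporalTuningModel
    fits: dict[str, TuningFitResults]

    @property
    def best_spec(self) -> ModelSpec:
        return select_best_model(self.fits)

    @property
    def best(self) -> TuningFitResults:
        return self.fits[self.best_spec.name]

    def partial_r2(self) -> dict[str, float]:
        return partial_r2(self.fits)

    def separability_index(self) -> float:
        return separability_index(self.fits)

    def to_row(self, neuron_id: str = "n0") -> dict:
        vaj = self.fits["VAJ"]
        row: dict = {"neuron_id": neuron_id, "best_model": self.best_spec.name}
        row["r2_vaj"] = vaj.r2
        for name, fr in self.fits.items():
            row[f"bic_{name.lower()}"] = fr.bic
        nw = vaj.normalized_weights()
        for kind, letter in (("velocity", "v"), ("acceleration", "a"), ("jerk", "j")):
            c = vaj.params.component(kind)
            row[f"w_{letter}"] = nw[kind]
            row[f"o_{letter}"] = c.tuning.offset
            row[f"pd_{letter}_az"] = c.tuning.pd.azimuth
            row[f"pd_{letter}_el"] = c.tuning.pd.elevation
        row["tau0"] = vaj.params.delay
        row["fr0"] = vaj.params.baseline
        row["sep_index"] = self.separability_index()
        for kind, letter in (("velocity", "v"), ("acceleration", "a"), ("jerk", "j")):
            row[f"partial_r2_{letter}"] = self.partial_r2()[kind]
        return row

    def summary(self) -> str:
        lines = ["Model family comparison (sorted by BIC)"]
        lines.append(f"{'model':>8s} {'p':>3s} {'R2':>8s} {'BIC':>10s}")
        for name, fr in sorted(self.fits.items(), key=lambda kv: kv[1].bic):
            lines.append(f"{name:>8s} {fr.p:>3d} {fr.r2:>8.4f} {fr.bic:>10.2f}")
        lines.append(f"best model by BIC: {self.best_spec.name}")
        pr = self.partial_r2()
        lines.append(
            "partial R2: V = {velocity:.3f}, A = {acceleration:.3f}, "
            "J = {jerk:.3f}".format(**pr)
        )
        lines.append(f"separability index: {self.separability_index():.3f}")
        return "\n".join(lines)
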