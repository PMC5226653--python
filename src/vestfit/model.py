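"""Parametric spatio-temporal response-model family.

A neuron's firing rate over direction and time is modeled as a sum of
components, one per kinematic variable (position, velocity, acceleration,
jerk).  Each component contributes

    W * y(g(dir)) * f(t - tau0)

where g is cosine directional tuning (the dot product between the stimulus
direction and the component's preferred direction), y(x) = o + (1 - |o|) x
maps the cosine through an offset nonlinearity (o -> 1 means
omnidirectional), f is the component's peak-to-trough-normalized temporal
basis profile, W >= 0 is the response amplitude in spikes/s, and tau0 is a
single response delay shared across components.  A non-negative baseline
FR0 is added and the total is rectified at zero (a neuron cannot fire at a
negative rate; the model is silent where the sum is negative).

Weights are constrained non-negative: the sign degeneracy (W, pd) vs
(-W, antipodal pd) is resolved by expressing reversals through the
preferred direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .stimulus import (
    Direction,
    DirectionGrid,
    MotionStimulus,
    direction_to_unit_vector,
    temporal_profiles,
)

__all__ = [
    "COMPONENT_KINDS",
    "CANONICAL_SPECS",
    "SpatialTuning",
    "Component",
    "ModelSpec",
    "ModelParams",
    "cosine_tuning",
    "spatial_nonlinearity",
    "predict_firing_rate",
    "count_free_parameters",
]

COMPONENT_KINDS = ("position", "velocity", "acceleration", "jerk")
_KIND_LETTER = {"position": "P", "velocity": "V", "acceleration": "A", "jerk": "J"}
_LETTER_KIND = {v: k for k, v in _KIND_LETTER.items()}


@dataclass(frozen=True)
class SpatialTuning:
    """Preferred direction plus offset of the cosine-plus-offset tuning."""

    pd: Direction
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.offset <= 1.0:
            raise ValueError(f"offset {self.offset} outside [-1, 1]")

    def evaluate(self, stim_dir: Direction) -> float:
        return spatial_nonlinearity(cosine_tuning(stim_dir, self.pd), self.offset)


@dataclass(frozen=True)
class Component:
    kind: str
    weight: float
    tuning: SpatialTuning

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("component weight must be non-negative")


@dataclass(frozen=True)
class ModelSpec:
    """Which components are active, and whether tuning is shared.

    `separable=True` constrains all components to one shared SpatialTuning
    (one preferred direction and one offset).
    """

    components: tuple[str, ...]
    separable: bool = False

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("spec needs at least one component")
        seen = []
        for k in self.components:
            if k not in COMPONENT_KINDS:
                raise ValueError(f"unknown component kind {k!r}")
            if k in seen:
                raise ValueError(f"duplicate component {k!r}")
            seen.append(k)
        # canonical ordering P, V, A, J
        ordered = tuple(k for k in COMPONENT_KINDS if k in self.components)
        object.__setattr__(self, "components", ordered)
        if self.separable and len(ordered) < 2:
            raise ValueError("separable requires at least two components")

    @classmethod
    def from_string(cls, name: str) -> "ModelSpec":
        """Parse names like 'A', 'VA', 'VAJ', 'SepVAJ', 'PVAJ'."""
        name = name.strip()
        separable = False
        if name.lower().startswith("sep"):
            separable = True
            name = name[3:].lstrip("-_ ")
        try:
            kinds = tuple(_LETTER_KIND[c] for c in name.upper())
        except KeyError as e:
            raise ValueError(f"cannot parse model spec {name!r}") from e
        return cls(kinds, separable=separable)

    @property
    def name(self) -> str:
        letters = "".join(_KIND_LETTER[k] for k in self.components)
        return ("Sep" + letters) if self.separable else letters

    @property
    def n_parameters(self) -> int:
        return count_free_parameters(self)

    def __str__(self) -> str:
        return self.name


#: The model family fitted by default: the three single-component models,
#: the three pairs, and the full velocity+acceleration+jerk model.
CANONICAL_SPECS = tuple(
    ModelSpec.from_string(s) for s in ("V", "A", "J", "VA", "VJ", "AJ", "VAJ")
)
SEPARABLE_VAJ = ModelSpec.from_string("SepVAJ")
PVAJ = ModelSpec.from_string("PVAJ")


def count_free_parameters(spec: ModelSpec) -> int:
    """Free-parameter count: delay + baseline + per-component scalars.

    Non-separable: 2 + 4k (weight, preferred azimuth/elevation, offset per
    component).  Separable: 2 + k weights + 3 shared tuning scalars.
    """
    k = len(spec.components)
    if spec.separable:
        return 2 + k + 3
    return 2 + 4 * k


@dataclass(frozen=True)
class ModelParams:
    """A fully specified member of the model family."""

    spec: ModelSpec
    components: tuple[Component, ...]
    delay: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        kinds = tuple(c.kind for c in self.components)
        if kinds != self.spec.components:
            raise ValueError(
                f"components {kinds} do not match spec {self.spec.components}"
            )
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.spec.separable:
            t0 = self.components[0].tuning
            for c in self.components[1:]:
                if c.tuning != t0:
                    raise ValueError("separable spec requires identical tunings")

    def component(self, kind: str) -> Component:
        for c in self.components:
            if c.kind == kind:
                return c
        raise KeyError(kind)

    @property
    def weights(self) -> dict[str, float]:
        return {c.kind: c.weight for c in self.components}

    def to_dict(self) -> dict:
        d = {"spec": self.spec.name, "delay_s": self.delay,
             "baseline_spikes_per_s": self.baseline}
        for c in self.components:
            p = _KIND_LETTER[c.kind].lower()
            d[f"w_{p}_spikes_per_s"] = c.weight
            d[f"pd_{p}_azimuth_deg"] = c.tuning.pd.azimuth
            d[f"pd_{p}_elevation_deg"] = c.tuning.pd.elevation
            d[f"o_{p}"] = c.tuning.offset
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        spec = ModelSpec.from_string(d["spec"])
        comps = []
        for kind in spec.components:
            p = _KIND_LETTER[kind].lower()
            comps.append(
                Component(
                    kind=kind,
                    weight=float(d[f"w_{p}_spikes_per_s"]),
                    tuning=SpatialTuning(
                        pd=Direction(
                            float(d[f"pd_{p}_azimuth_deg"]),
                            float(d[f"pd_{p}_elevation_deg"]),
                        ),
                        offset=float(d[f"o_{p}"]),
                    ),
                )
            )
        return cls(
            spec=spec,
            components=tuple(comps),
            delay=float(d["delay_s"]),
            baseline=float(d["baseline_spikes_per_s"]),
        )


def cosine_tuning(stim_dir: Direction, pd: Direction) -> float:
    """Cosine of the 3D angle between stimulus direction and PD.

    Equals 1 at the preferred direction, -1 at the anti-preferred direction
    and 0 in any orthogonal direction.
    """
    c = float(
        np.dot(direction_to_unit_vector(stim_dir), direction_to_unit_vector(pd))
    )
    return float(np.clip(c, -1.0, 1.0))


def spatial_nonlinearity(x, offset: float):
    """Offset nonlinearity y(x) = o + (1 - |o|) x.

    Keeps |y| <= 1 on x in [-1, 1] and reaches |y| = 1 at one endpoint.
    offset=0 is pure cosine tuning; |offset|=1 is omnidirectional.
    """
    if not -1.0 <= offset <= 1.0:
        raise ValueError(f"offset {offset} outside [-1, 1]")
    return offset + (1.0 - abs(offset)) * np.asarray(x)


def predict_firing_rate(
    params: ModelParams,
    grid: DirectionGrid,
    stim: MotionStimulus,
    rectify: bool = True,
) -> np.ndarray:
    """Predicted firing rate, shape (n_directions, n_time_bins), spikes/s.

    Sum over active components of weight x offset-nonlinear cosine tuning x
    delayed temporal profile, plus baseline, rectified at zero.
    """
    profiles = temporal_profiles(stim, params.delay)
    U = grid.unit_vectors()  # (n_dir, 3)
    rate = np.full((len(grid), len(stim.time_grid)), params.baseline, dtype=float)
    for c in params.components:
        g = np.clip(U @ direction_to_unit_vector(c.tuning.pd), -1.0, 1.0)
        y = spatial_nonlinearity(g, c.tuning.offset)
        rate += c.weight * np.outer(y, profiles.by_kind(c.kind))
    if rectify:
        np.maximum(rate, 0.0, out=rate)
    return rate
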