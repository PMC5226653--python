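"""File formats, configuration, and the end-to-end pipeline.

Tables are plain delimited text (CSV).  Spike tables have columns
neuron_id, direction_index, repetition, spike_time_s; direction indices
refer to the canonical 26-direction grid.  Model parameters round-trip
through a flat key-value text document with explicit units.  A RunConfig
captures every setting (stimulus, screening alphas, generator ranges, fit
options, seed) and serializes to YAML; result tables carry its hash so
outputs from different configurations cannot be mixed silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import SpatioTemporalTuningModel
from .model import ModelParams
from .psth import SpikeTrainSet, build_psth, screen
from .simulate import GeneratorConfig, generate_population
from .stimulus import DirectionGrid, MotionStimulus, make_direction_grid

__all__ = [
    "RunConfig",
    "read_spike_table",
    "write_spike_table",
    "read_params",
    "write_params",
    "run_pipeline",
]

logger = logging.getLogger("vestfit")

_SPIKE_COLUMNS = ["neuron_id", "direction_index", "repetition", "spike_time_s"]


def write_spike_table(path, neurons: dict[str, SpikeTrainSet]) -> None:
    """Write one or more neurons' spike trains to a delimited table."""
    frames = [s.to_dataframe(nid) for nid, s in neurons.items()]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_SPIKE_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_spike_table(
    path,
    grid: DirectionGrid | None = None,
    trial_duration: float = 2.0,
) -> dict[str, SpikeTrainSet]:
    """Parse a spike table into per-neuron SpikeTrainSets.

    Every (direction, repetition) pair observed for a neuron defines the
    protocol; repetitions must form a complete 0..n_reps-1 range per
    direction.  Malformed rows raise with their line number.
    """
    grid = grid or make_direction_grid()
    df = pd.read_csv(path)
    missing = [c for c in _SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    n_dir = len(grid)
    out: dict[str, SpikeTrainSet] = {}
    for nid, g in df.groupby("neuron_id", sort=True):
        for line_offset, (idx, row) in enumerate(g.iterrows()):
            line = idx + 2  # header + 1-based
            d = int(row["direction_index"])
            if not 0 <= d < n_dir:
                raise ValueError(
                    f"{path}:{line}: direction index {d} outside 0..{n_dir - 1}"
                )
            t = float(row["spike_time_s"])
            if not 0.0 <= t <= trial_duration:
                raise ValueError(
                    f"{path}:{line}: spike time {t} s outside the "
                    f"[0, {trial_duration}] s trial window"
                )
        n_reps = int(g["repetition"].max()) + 1
        trains = {
            (d, r): np.array([], dtype=float)
            for d in range(n_dir)
            for r in range(n_reps)
        }
        for (d, r), gg in g.groupby(["direction_index", "repetition"]):
            trains[(int(d), int(r))] = np.sort(gg["spike_time_s"].to_numpy(float))
        out[str(nid)] = SpikeTrainSet(
            trains=trains, grid=grid, n_reps=n_reps, trial_duration=trial_duration
        )
    return out


def write_params(path, params: ModelParams) -> None:
    """Flat key = value text document; floats written with full precision."""
    lines = []
    for k, v in params.to_dict().items():
        lines.append(f"{k} = {v!r}" if not isinstance(v, str) else f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> ModelParams:
    d = {}
    for raw in Path(path).read_text().splitlines():
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        k, _, v = raw.partition("=")
        k, v = k.strip(), v.strip()
        d[k] = v if k == "spec" else float(v)
    return ModelParams.from_dict(d)


@dataclass(frozen=True)
class RunConfig:
    """Every knob of the simulate -> screen -> fit -> summarize pipeline."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    stimulus: MotionStimulus = field(default_factory=MotionStimulus)
    alpha_temporal: float = 0.01
    alpha_anova: float = 0.001
    include_pvaj: bool = False
    fit_seed: int = 0
    n_polish: int = 2

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["generator"]["specs"] = [s.name for s in self.generator.specs]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        from .model import ModelSpec

        d = yaml.safe_load(text)
        gen = d.pop("generator")
        gen["specs"] = tuple(ModelSpec.from_string(s) for s in gen["specs"])
        for k in ("weight_range", "offset_range", "baseline_range", "delay_range"):
            gen[k] = tuple(gen[k])
        stim = d.pop("stimulus")
        return cls(
            generator=GeneratorConfig(**gen),
            stimulus=MotionStimulus(**stim),
            **d,
        )

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Simulate a population, screen, fit the model family, and summarize.

    Writes truth, screening and per-neuron fit-summary tables plus a
    manifest (config hash, seeds, timings, package version) under
    `out_dir` and returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    (out / "config.yaml").write_text(config.to_yaml())

    logger.info("simulating %d neurons (seed %d)", config.generator.n_neurons,
                config.generator.seed)
    neurons, truth = generate_population(config.generator, stim=config.stimulus)
    truth.insert(0, "config_hash", config.hash)
    truth.to_csv(out / "truth.csv", index=False)
    write_spike_table(out / "spikes.csv", {n.neuron_id: n.spikes for n in neurons})
    t_sim = time.time()

    screen_rows, fit_rows = [], []
    for n in neurons:
        psth = build_psth(n.spikes)
        sr = screen(psth, config.alpha_temporal, config.alpha_anova)
        screen_rows.append(
            {
                "config_hash": config.hash,
                "neuron_id": n.neuron_id,
                "passes_temporal": sr.passes_temporal,
                "passes_spacetime": sr.passes_spacetime,
                "included": sr.included,
            }
        )
        model = SpatioTemporalTuningModel(psth, stimulus=config.stimulus)
        fam = model.fit_family(
            include_pvaj=config.include_pvaj,
            seed=config.fit_seed,
            n_polish=config.n_polish,
        )
        row = fam.to_row(n.neuron_id)
        row["config_hash"] = config.hash
        fit_rows.append(row)
        logger.info("fit %s: best=%s r2_vaj=%.3f", n.neuron_id,
                    row["best_model"], row["r2_vaj"])
    cols_s = ["config_hash", "neuron_id", "passes_temporal", "passes_spacetime",
              "included"]
    pd.DataFrame(screen_rows, columns=cols_s).to_csv(
        out / "screening.csv", index=False
    )
    if fit_rows:
        fit_df = pd.DataFrame(fit_rows)
        fit_df = fit_df[["config_hash"] + [c for c in fit_df.columns
                                           if c != "config_hash"]]
    else:
        fit_df = pd.DataFrame(columns=["config_hash", "neuron_id", "best_model"])
    fit_df.to_csv(out / "summary.csv", index=False)

    manifest = {
        "config_hash": config.hash,
        "n_neurons": config.generator.n_neurons,
        "generator_seed": config.generator.seed,
        "fit_seed": config.fit_seed,
        "n_included": int(sum(r["included"] for r in screen_rows)),
        "timing_s": {
            "simulate": round(t_sim - t0, 3),
            "fit": round(time.time() - t_sim, 3),
        },
        "outputs": ["config.yaml", "truth.csv", "spikes.csv", "screening.csv",
                    "summary.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
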