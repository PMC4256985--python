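"""Trial orchestration and the four preset experiments.

One training step presents one noisy stimulus and runs two sweeps:

1. *feedforward* sweep: layer 2 -> layer 3 -> winner-take-all, then
   winner-gated adaptation with the unmodulated layer-2 activity;
2. the winner's projective field predicts the input; the rectified
   prediction error (residual template) multiplicatively amplifies the
   stimulus drive;
3. *feedback* sweep: layer 2 -> layer 3 -> winner-take-all on the
   amplified activity, then winner-gated adaptation with the modulated
   layer-2 activity.

The feedforward winner consolidates the overall category; when the
residual is large enough, the feedback sweep hands the winner-take-all
to a previously unused cell, recruiting a subcategory representation.
With the feedback gain at zero the two sweeps coincide exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from . import stimuli as stim
from .model_core import (
    ModelParams,
    ModelState,
    SweepResult,
    init_state,
    layer2_response,
    layer3_response,
    residual_template,
    wta,
)
from .plasticity import LearningEvent, apply_learning

__all__ = [
    "TrainingConfig",
    "StepRecord",
    "TrainingTrace",
    "run_step",
    "probe_step",
    "run_experiment",
    "preset",
    "EXPERIMENT_IDS",
]

EXPERIMENT_IDS = (1, 2, 3, 4)


@dataclasses.dataclass
class TrainingConfig:
    """Everything needed to re-run an experiment bit-identically."""

    categories: tuple[str, ...]  # subset of ("A", "B")
    schedule: Literal["blocked", "random"]
    block_size: int
    m_cells: int
    n_steps: int
    seed: int
    params: ModelParams = dataclasses.field(default_factory=ModelParams)
    noise_sigma: float = 0.05
    image_size: tuple[int, int] = stim.DEFAULT_SIZE
    snapshot_every: int = 0  # 0 disables weight snapshots
    experiment_id: int | None = None

    def validate(self) -> None:
        self.params.validate()
        if self.m_cells < 1:
            raise ValueError("m_cells must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if not self.categories or any(c not in ("A", "B") for c in self.categories):
            raise ValueError(f"categories must be drawn from ('A', 'B'), got {self.categories!r}")

    def stimulus_sets(self) -> tuple[stim.StimulusSet, ...]:
        return tuple(stim.category_set(c, self.image_size) for c in self.categories)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        d["params"] = ModelParams(**d.get("params", {}))
        d["categories"] = tuple(d["categories"])
        d["image_size"] = tuple(d["image_size"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class StepRecord:
    """Winners and layer-3 activities of both sweeps of one step."""

    step: int
    category_label: str
    variation_label: int
    ff_winner: int
    fb_winner: int
    g_v_ff: np.ndarray
    g_v_fb: np.ndarray
    events: tuple[LearningEvent, LearningEvent]


@dataclasses.dataclass
class TrainingTrace:
    """Per-step records plus the final state of one experiment run."""

    config: TrainingConfig
    records: list[StepRecord]
    final_state: ModelState
    snapshots: list[tuple[int, np.ndarray, np.ndarray]]  # (step, w_in, w_out)

    def __len__(self) -> int:
        return len(self.records)

    def winners(self, sweep: str = "feedback") -> np.ndarray:
        attr = "fb_winner" if sweep == "feedback" else "ff_winner"
        return np.array([getattr(r, attr) for r in self.records], dtype=int)

    def recruitment_steps(self) -> dict[int, int]:
        """First step at which each recruited cell was selected."""
        first: dict[int, int] = {}
        for rec in self.records:
            for ev in rec.events:
                if ev.first_use and ev.winner not in first:
                    first[ev.winner] = ev.step
        return first

    def to_frame(self):
        """Per-step winners and labels as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "step": [r.step for r in self.records],
                "category": [r.category_label for r in self.records],
                "variant": [r.variation_label for r in self.records],
                "ff_winner": [r.ff_winner for r in self.records],
                "fb_winner": [r.fb_winner for r in self.records],
                "g_v_ff_max": [float(r.g_v_ff.max()) for r in self.records],
                "g_v_fb_max": [float(r.g_v_fb.max()) for r in self.records],
            }
        )


def run_step(
    state: ModelState, s: np.ndarray, params: ModelParams, step: int = 0, labels: tuple[str, int] = ("?", 0)
) -> tuple[ModelState, StepRecord]:
    """Run one full trial (feedforward sweep, adapt, feedback sweep, adapt)."""
    g_u0 = layer2_response(s, None, params)
    v0, g_v0 = layer3_response(g_u0, state.w_in, params)
    k0 = wta(g_v0)
    ff = SweepResult(g_u=g_u0, v_raw=v0, g_v=g_v0, winner=k0)
    state, ev0 = apply_learning(state, ff, params, step=step, sweep_kind="feedforward")

    res = residual_template(g_u0, state.w_out[k0, :])
    g_u1 = layer2_response(s, res, params)
    v1, g_v1 = layer3_response(g_u1, state.w_in, params)
    k1 = wta(g_v1)
    fb = SweepResult(g_u=g_u1, v_raw=v1, g_v=g_v1, winner=k1, res_templ=res)
    state, ev1 = apply_learning(state, fb, params, step=step, sweep_kind="feedback")

    record = StepRecord(
        step=step,
        category_label=labels[0],
        variation_label=labels[1],
        ff_winner=k0,
        fb_winner=k1,
        g_v_ff=g_v0.copy(),
        g_v_fb=g_v1.copy(),
        events=(ev0, ev1),
    )
    return state, record


def probe_step(
    state: ModelState, s: np.ndarray, params: ModelParams
) -> tuple[SweepResult, SweepResult]:
    """Run both sweeps on a stimulus without any weight adaptation."""
    g_u0 = layer2_response(s, None, params)
    v0, g_v0 = layer3_response(g_u0, state.w_in, params)
    k0 = wta(g_v0)
    res = residual_template(g_u0, state.w_out[k0, :])
    g_u1 = layer2_response(s, res, params)
    v1, g_v1 = layer3_response(g_u1, state.w_in, params)
    k1 = wta(g_v1)
    return (
        SweepResult(g_u=g_u0, v_raw=v0, g_v=g_v0, winner=k0),
        SweepResult(g_u=g_u1, v_raw=v1, g_v=g_v1, winner=k1, res_templ=res),
    )


def run_experiment(config: TrainingConfig) -> TrainingTrace:
    """Run a seeded training loop over the configured stimulus stream."""
    config.validate()
    sets = config.stimulus_sets()
    n_inputs = int(np.prod(config.image_size))
    ss = np.random.SeedSequence([int(config.seed), 0xC0]).spawn(2)
    state = init_state(n_inputs, config.m_cells, config.params, np.random.default_rng(ss[0]))
    records: list[StepRecord] = []
    snapshots: list[tuple[int, np.ndarray, np.ndarray]] = []
    if config.n_steps > 0:
        stream = stim.build_stream(
            sets,
            schedule=config.schedule,
            block_size=config.block_size,
            n_steps=config.n_steps,
            seed=int(np.random.default_rng(ss[1]).integers(0, 2**31 - 1)),
            noise_sigma=config.noise_sigma,
        )
        for step, pres in enumerate(stream.presentations()):
            s = pres.image.flatten()
            state, rec = run_step(
                state, s, config.params, step=step, labels=(pres.category_label, pres.variation_label)
            )
            records.append(rec)
            if config.snapshot_every and (step + 1) % config.snapshot_every == 0:
                snapshots.append((step, state.w_in.copy(), state.w_out.copy()))
    return TrainingTrace(config=config, records=records, final_state=state, snapshots=snapshots)


def preset(experiment_id: int, seed: int = 0, n_steps: int | None = None) -> TrainingConfig:
    """The four printed experiment configurations.

    1. category B, blocked epochs of 4 x 100 sorted presentations, M = 6,
       slowed-down learning (eta = 2**-5, mu_log = 800, init N(0.5, 0.1));
    2. category A, random order, M = 6, default parameters;
    3. experiment 2 with the feedback gain disabled (lambda = 0);
    4. categories A and B, M = 12, 1000 steps, experiment-1 parameters.
    """
    if experiment_id not in EXPERIMENT_IDS:
        raise ValueError(f"experiment_id must be in 1..4, got {experiment_id!r}")
    slow = ModelParams(eta_in=2.0**-5, eta_out=2.0**-5, mu_log=800.0, init_mu=0.5)
    if experiment_id == 1:
        cfg = TrainingConfig(
            categories=("B",),
            schedule="blocked",
            block_size=100,
            m_cells=6,
            n_steps=n_steps if n_steps is not None else 800,
            seed=seed,
            params=slow,
        )
    elif experiment_id == 2:
        cfg = TrainingConfig(
            categories=("A",),
            schedule="random",
            block_size=100,
            m_cells=6,
            n_steps=n_steps if n_steps is not None else 400,
            seed=seed,
            params=ModelParams(),
        )
    elif experiment_id == 3:
        cfg = TrainingConfig(
            categories=("A",),
            schedule="random",
            block_size=100,
            m_cells=6,
            n_steps=n_steps if n_steps is not None else 400,
            seed=seed,
            params=ModelParams(lam=0.0),
        )
    else:
        cfg = TrainingConfig(
            categories=("A", "B"),
            schedule="blocked",
            block_size=100,
            m_cells=12,
            n_steps=n_steps if n_steps is not None else 1000,
            seed=seed,
            params=slow,
        )
    cfg.experiment_id = experiment_id
    return cfg
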