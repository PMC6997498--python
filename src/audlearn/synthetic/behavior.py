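"""Staged go/no-go behavior logs.

Each stage presents one target/non-target tone pair; targets are played at
70% probability.  Lick decisions are Bernoulli with stage-specific hit and
false-alarm probabilities, so a log's true sensitivity is known exactly and
every behavioral statistic can be validated against it.  Optional catch
trials (default 6% when enabled) carry unreinforced probe frequencies for
psychometric-curve extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ..grids import tone_train_duration_s


class StageSpec(BaseModel):
    """One training stage: a tone pair and the true lick probabilities."""

    target_khz: float = Field(10.0, gt=0)
    nontarget_khz: float = Field(gt=0)
    n_trials: int = Field(400, ge=1)
    p_hit: float = Field(ge=0, le=1)
    p_fa: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "StageSpec":
        if self.target_khz == self.nontarget_khz:
            raise ValueError("target and non-target tones must differ")
        return self


def default_training_stages() -> list[StageSpec]:
    """The staged curriculum: separations of 49, 26, 14 and 6 %/octave.

    Lick probabilities are calibrated so that stage d' is near the reported
    group means for the easy-to-hard progression (≈2.4, 1.9, 1.4, ≈0.5).
    """
    return [
        StageSpec(nontarget_khz=7.1, n_trials=400, p_hit=0.92, p_fa=0.12),
        StageSpec(nontarget_khz=8.333, n_trials=400, p_hit=0.88, p_fa=0.18),
        StageSpec(nontarget_khz=9.07, n_trials=400, p_hit=0.85, p_fa=0.30),
        StageSpec(nontarget_khz=9.6, n_trials=400, p_hit=0.72, p_fa=0.53),
    ]


@dataclass
class BehaviorLog:
    """Time-ordered go/no-go trial records.

    ``trials`` columns: mouse_id, timestamp_s, stage_id, stimulus_kind
    (target|nontarget|catch), stimulus_khz, licked, outcome
    (hit|miss|fa|cr|catch), lick_times_ms (semicolon-joined string).
    """

    trials: pd.DataFrame

    OUTCOME = {("target", True): "hit", ("target", False): "miss",
               ("nontarget", True): "fa", ("nontarget", False): "cr"}

    def __post_init__(self) -> None:
        df = self.trials
        required = {"mouse_id", "timestamp_s", "stage_id", "stimulus_kind",
                    "stimulus_khz", "licked", "outcome", "lick_times_ms"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"behavior log missing columns: {sorted(missing)}")
        noncatch = df[df.stimulus_kind != "catch"]
        expected = [
            self.OUTCOME[(k, bool(l))]
            for k, l in zip(noncatch.stimulus_kind, noncatch.licked)
        ]
        if list(noncatch.outcome) != expected:
            raise ValueError("outcomes inconsistent with (stimulus_kind, licked)")
        if (df[df.stimulus_kind == "catch"].outcome != "catch").any():
            raise ValueError("catch trials must carry outcome 'catch'")

    @property
    def stages(self) -> list:
        return list(dict.fromkeys(self.trials.stage_id))

    def stage(self, stage_id) -> pd.DataFrame:
        return self.trials[self.trials.stage_id == stage_id]


def _lick_times(rng: np.random.Generator, window_ms: float) -> str:
    """A small lick train: first lick 150–600 ms, then ~6 Hz within window."""
    t = rng.uniform(150.0, 600.0)
    times = [t]
    while True:
        t += rng.exponential(1000.0 / 6.0)
        if t > window_ms:
            break
        times.append(t)
    return ";".join(f"{x:.1f}" for x in times)


def generate_behavior_log(
    stages: list[StageSpec],
    mouse_id: str = "m000",
    seed: int = 0,
    p_target: float = 0.70,
    catch_rate: float = 0.0,
    catch_freqs_khz: tuple[float, ...] | None = None,
    catch_boundary_khz: float | None = None,
    catch_slope_per_octave: float = 6.0,
    inter_trial_s: float = 8.0,
) -> BehaviorLog:
    """Simulate a staged training log.

    Catch-trial licks follow a logistic in log2 frequency centered on
    ``catch_boundary_khz`` (default: geometric mean of each stage's tone
    pair), falling from the stage hit probability to its false-alarm
    probability — the ground truth the psychometric fit should recover.
    """
    if not stages:
        raise ValueError("at least one stage is required")
    if not (0 <= catch_rate < 1):
        raise ValueError("catch_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    trial_s = tone_train_duration_s()
    rows = []
    t = 0.0
    for si, stage in enumerate(stages):
        for _ in range(stage.n_trials):
            t += trial_s + inter_trial_s
            is_catch = catch_rate > 0 and rng.random() < catch_rate
            if is_catch:
                freqs = catch_freqs_khz or (7.1, 7.7, 8.3, 9.0, 9.7, 10.0)
                f = float(rng.choice(freqs))
                boundary = catch_boundary_khz or float(
                    np.sqrt(stage.target_khz * stage.nontarget_khz)
                )
                sign = 1.0 if stage.target_khz > stage.nontarget_khz else -1.0
                x = sign * catch_slope_per_octave * np.log2(f / boundary)
                p_lick = stage.p_fa + (stage.p_hit - stage.p_fa) / (1 + np.exp(-x))
                kind, outcome = "catch", "catch"
            else:
                is_target = rng.random() < p_target
                kind = "target" if is_target else "nontarget"
                f = stage.target_khz if is_target else stage.nontarget_khz
                p_lick = stage.p_hit if is_target else stage.p_fa
            licked = bool(rng.random() < p_lick)
            if kind != "catch":
                outcome = BehaviorLog.OUTCOME[(kind, licked)]
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "timestamp_s": round(t, 3),
                    "stage_id": f"stage_{si}",
                    "stimulus_kind": kind,
                    "stimulus_khz": f,
                    "licked": licked,
                    "outcome": outcome,
                    "lick_times_ms": _lick_times(rng, 3000.0) if licked else "",
                }
            )
    return BehaviorLog(trials=pd.DataFrame(rows))
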