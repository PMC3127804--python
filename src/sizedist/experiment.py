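"""Synthetic experiment: trial schedule generation and observer simulation.

Reproduces the interception task's design — 4 days of 4 blocks of 80 trials,
ball diameter uniform on [14, 42] mm, crossing distance uniform on
[300, 640] mm, haptic and no-haptic trials interleaved in equal proportions
within each block — and simulates responses from a ground-truth observer so
the whole fitting pipeline can be exercised without any recorded data.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .observer import (
    HAPTIC,
    NO_HAPTIC,
    ResponseRecord,
    SceneStimulus,
    simulate_responses,
)


class ConfigurationError(ValueError):
    """Invalid experiment configuration."""


class ScheduleConfig(BaseModel):
    """Design of the trial schedule (defaults mirror the original study)."""

    model_config = ConfigDict(frozen=True)

    n_days: int = Field(default=4, ge=1)
    blocks_per_day: int = Field(default=4, ge=1)
    trials_per_block: int = Field(default=80, ge=2)
    distance_range_mm: tuple[float, float] = (300.0, 640.0)
    diameter_range_mm: tuple[float, float] = (14.0, 42.0)
    speed_range_mm_s: tuple[float, float] = (250.0, 375.0)
    angle_range_deg: tuple[float, float] = (-8.5, 8.5)
    training_days_excluded: int = Field(default=1, ge=0)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ScheduleConfig":
        for name in ("distance_range_mm", "diameter_range_mm", "speed_range_mm_s"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        if self.trials_per_block % 2 != 0:
            raise ConfigurationError(
                "trials_per_block must be even for an exact haptic/no-haptic split"
            )
        return self

    @property
    def n_trials(self) -> int:
        return self.n_days * self.blocks_per_day * self.trials_per_block


class GroundTruth(BaseModel):
    """The observer that generated a synthetic dataset."""

    model_config = ConfigDict(frozen=True)

    model_id: int
    theta: dict[str, float]


def generate_schedule(config: ScheduleConfig, rng: np.random.Generator) -> list[SceneStimulus]:
    """Draw the full trial schedule.

    Distances and diameters are uniform in mm over their ranges (stored as
    natural logs); each block gets exactly half haptic and half no-haptic
    trials in random order.
    """
    stimuli: list[SceneStimulus] = []
    half = config.trials_per_block // 2
    trial_index = 0
    for day in range(1, config.n_days + 1):
        for block in range(1, config.blocks_per_day + 1):
            conditions = np.array([HAPTIC] * half + [NO_HAPTIC] * half, dtype=object)
            rng.shuffle(conditions)
            dist = rng.uniform(*config.distance_range_mm, size=config.trials_per_block)
            diam = rng.uniform(*config.diameter_range_mm, size=config.trials_per_block)
            speed = rng.uniform(*config.speed_range_mm_s, size=config.trials_per_block)
            angle = rng.uniform(*config.angle_range_deg, size=config.trials_per_block)
            for i in range(config.trials_per_block):
                stimuli.append(
                    SceneStimulus(
                        d_true=math.log(dist[i]),
                        s_true=math.log(diam[i]),
                        condition=conditions[i],
                        day=day,
                        block=block,
                        trial_index=trial_index,
                        speed_mm_s=float(speed[i]),
                        angle_deg=float(angle[i]),
                    )
                )
                trial_index += 1
    return stimuli


def apply_training_exclusion(records: Sequence, config: ScheduleConfig) -> list:
    """Drop training-day items (day <= ``training_days_excluded``), keeping order.

    Works on both stimuli and response records.
    """
    def day_of(item):
        return item.stimulus.day if isinstance(item, ResponseRecord) else item.day

    return [it for it in records if day_of(it) > config.training_days_excluded]


def stimulus_log_stats(stimuli: Sequence[SceneStimulus]) -> dict[str, float]:
    """Sample mean/SD of log-distance and log-size over a schedule.

    These are the quantities fitted prior parameters are compared against.
    """
    if len(stimuli) == 0:
        raise ConfigurationError("stimuli must be non-empty")
    stims = [it.stimulus if isinstance(it, ResponseRecord) else it for it in stimuli]
    d = np.array([st.d_true for st in stims])
    s = np.array([st.s_true for st in stims])
    ddof = 1 if len(stimuli) > 1 else 0
    return {
        "mean_log_distance": float(d.mean()),
        "sd_log_distance": float(d.std(ddof=ddof)),
        "mean_log_size": float(s.mean()),
        "sd_log_size": float(s.std(ddof=ddof)),
    }


def mean_log_uniform(a: float, b: float) -> float:
    """E[ln X] for X ~ Uniform(a, b): (b ln b - b - a ln a + a) / (b - a)."""
    if a == b:
        return math.log(a)
    return (b * math.log(b) - b - a * math.log(a) + a) / (b - a)


def sd_log_uniform(a: float, b: float) -> float:
    """SD[ln X] for X ~ Uniform(a, b) (closed form via the ln^2 antiderivative)."""
    if a == b:
        return 0.0

    def f2(x: float) -> float:  # antiderivative of ln^2
        lx = math.log(x)
        return x * (lx * lx - 2.0 * lx + 2.0)

    second = (f2(b) - f2(a)) / (b - a)
    return math.sqrt(second - mean_log_uniform(a, b) ** 2)


def reference_theta(model, config: Optional[ScheduleConfig] = None) -> dict[str, float]:
    """A plausible ground-truth parameter set for simulation studies.

    Sensory/motor SDs use round benchmark values (image 0.1, true haptic
    0.08 assumed as 0.2 when misestimated, motor 0.02, K = 4); the prior
    parameters match the analytic log-domain statistics of the schedule's
    uniform stimulus ranges, mirroring how fitted priors track the stimuli.
    """
    from .mcmc import active_parameters

    config = config or ScheduleConfig()
    full = {
        "sigma_phi_true": 0.1,
        "sigma_phi": 0.1 if model.image_knowledge_accurate else 0.15,
        "sigma_h_true": 0.08,
        "sigma_h": 0.08 if model.haptic_knowledge_accurate else 0.2,
        "mu_d": mean_log_uniform(*config.distance_range_mm),
        "sigma_d": sd_log_uniform(*config.distance_range_mm),
        "mu_s": mean_log_uniform(*config.diameter_range_mm),
        "sigma_s": sd_log_uniform(*config.diameter_range_mm),
        "sigma_m": 0.02,
        "K": 4.0,
    }
    return {name: full[name] for name in active_parameters(model)}


#: accuracy-feedback collision window of the interception task, in mm
FEEDBACK_WINDOW_MM = 32.0

RECORD_COLUMNS = [
    "day",
    "block",
    "trial",
    "condition",
    "distance_mm",
    "diameter_mm",
    "speed_mm_s",
    "angle_deg",
    "judged_mm",
]


def records_to_frame(records: Sequence[ResponseRecord], feedback: bool = False) -> pd.DataFrame:
    """Tabulate response records in the mm-domain CSV schema.

    With ``feedback=True`` adds a ``feedback_hit`` column marking judgments
    within the 32-mm collision window (recorded only; observers never see it).
    """
    rows = []
    for rec in records:
        st = rec.stimulus
        row = {
            "day": st.day,
            "block": st.block,
            "trial": st.trial_index,
            "condition": st.condition,
            "distance_mm": math.exp(st.d_true),
            "diameter_mm": math.exp(st.s_true),
            "speed_mm_s": st.speed_mm_s,
            "angle_deg": st.angle_deg,
            "judged_mm": math.exp(rec.r),
        }
        if feedback:
            row["feedback_hit"] = abs(row["judged_mm"] - row["distance_mm"]) <= FEEDBACK_WINDOW_MM
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ResponseRecord]:
    """Inverse of :func:`records_to_frame`: mm columns back to log records."""
    records = []
    for row in df.itertuples(index=False):
        st = SceneStimulus(
            d_true=math.log(row.distance_mm),
            s_true=math.log(row.diameter_mm),
            condition=str(row.condition),
            day=int(row.day),
            block=int(row.block),
            trial_index=int(row.trial),
            speed_mm_s=None if pd.isna(row.speed_mm_s) else float(row.speed_mm_s),
            angle_deg=None if pd.isna(row.angle_deg) else float(row.angle_deg),
        )
        records.append(ResponseRecord(stimulus=st, r=math.log(row.judged_mm)))
    return records


def frame_to_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract fitting arrays ``(d_true, s_true, is_haptic, r)`` in log-mm."""
    d = np.log(df["distance_mm"].to_numpy(dtype=float))
    s = np.log(df["diameter_mm"].to_numpy(dtype=float))
    hap = (df["condition"] == HAPTIC).to_numpy()
    r = np.log(df["judged_mm"].to_numpy(dtype=float))
    return d, s, hap, r


def simulate_experiment(
    config: ScheduleConfig,
    truth: GroundTruth | Mapping,
    rng: np.random.Generator,
    feedback: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full synthetic run: schedule -> observer responses -> table + manifest.

    The manifest records everything needed to reproduce the dataset exactly
    (model id, theta, schedule config, seed). Training-day trials are kept in
    the table, flagged by their ``day`` column, so day-based re-analyses are
    filters rather than regenerations.
    """
    from .compare import get_model  # local import: compare sits above observer

    if not isinstance(truth, GroundTruth):
        truth = GroundTruth(**dict(truth))
    model = get_model(truth.model_id)
    stimuli = generate_schedule(config, rng)
    records = simulate_responses(stimuli, truth.theta, model, rng)
    df = records_to_frame(records, feedback=feedback)
    manifest = {
        "model_id": truth.model_id,
        "theta": dict(truth.theta),
        "seed": config.seed,
        "config": config.model_dump(),
    }
    return df, manifest
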