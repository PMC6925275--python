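"""Reward Go/No-Go task: stimuli, controllability conditions, contingencies,
trial-sequence generation, outcome sampling, and trial CSV I/O.

The task presents three interleaved stimuli per session: a Go stimulus
(pressing is rewarded 75% of the time), a No-Go stimulus (withholding is
rewarded 75% of the time), and a Decoy whose reward schedule operationalizes
controllability — action-independent 50% under Low Control (LC) versus 80%
for Go under High Control (HC). Experiment 1 assigns one condition per
session (120 trials, 40 per stimulus); Experiment 2 runs both conditions in
two 120-trial blocks whose order is randomized per participant.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pavarb._rng import substream


class ConfigError(ValueError):
    """Raised for invalid task configuration inputs."""


class TrialParseError(ValueError):
    """Raised when a trial CSV row violates the schema."""


class Stimulus(str, enum.Enum):
    GO_WIN = "go_win"
    NOGO_WIN = "nogo_win"
    DECOY_LC = "decoy_lc"
    DECOY_HC = "decoy_hc"


class Action(str, enum.Enum):
    GO = "go"
    NOGO = "nogo"


class OptimalAction(str, enum.Enum):
    GO = "go"
    NOGO = "nogo"
    UNDEFINED = "undefined"


class Condition(str, enum.Enum):
    LC = "lc"
    HC = "hc"


class Experiment(str, enum.Enum):
    EXP1 = "exp1"
    EXP2 = "exp2"


@dataclass(frozen=True)
class StimulusSpec:
    """Reward contingency for one stimulus: P(reward) for each action."""

    stimulus: Stimulus
    p_reward_go: float
    p_reward_nogo: float

    def __post_init__(self) -> None:
        for p in (self.p_reward_go, self.p_reward_nogo):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"reward probability {p} outside [0, 1]")

    @property
    def optimal_action(self) -> OptimalAction:
        # Undefined iff both actions are rewarded at the same rate (LC decoy).
        if self.p_reward_go == self.p_reward_nogo:
            return OptimalAction.UNDEFINED
        if self.p_reward_go > self.p_reward_nogo:
            return OptimalAction.GO
        return OptimalAction.NOGO


#: Default contingencies. Values for the non-described action on each
#: stimulus are complementary (Go-family task convention) and exposed here
#: so alternative schedules can be configured.
DEFAULT_CONTINGENCIES: dict[Stimulus, StimulusSpec] = {
    Stimulus.GO_WIN: StimulusSpec(Stimulus.GO_WIN, 0.75, 0.25),
    Stimulus.NOGO_WIN: StimulusSpec(Stimulus.NOGO_WIN, 0.25, 0.75),
    Stimulus.DECOY_LC: StimulusSpec(Stimulus.DECOY_LC, 0.50, 0.50),
    Stimulus.DECOY_HC: StimulusSpec(Stimulus.DECOY_HC, 0.80, 0.20),
}

_DECOY_FOR_CONDITION = {Condition.LC: Stimulus.DECOY_LC, Condition.HC: Stimulus.DECOY_HC}


def stimuli_for_condition(condition: Condition) -> tuple[Stimulus, Stimulus, Stimulus]:
    """The three stimuli shown in a session (or block) of one condition."""
    return (Stimulus.GO_WIN, Stimulus.NOGO_WIN, _DECOY_FOR_CONDITION[condition])


@dataclass(frozen=True)
class TaskConfig:
    """Full description of one participant's session."""

    experiment: Experiment
    block_order: tuple[Condition, ...]
    trials_per_stimulus: int = 40
    rng_seed: int = 0
    contingencies: dict[Stimulus, StimulusSpec] = field(
        default_factory=lambda: dict(DEFAULT_CONTINGENCIES)
    )

    def __post_init__(self) -> None:
        if self.trials_per_stimulus < 1:
            raise ConfigError("trials_per_stimulus must be positive")
        if self.experiment is Experiment.EXP1 and len(self.block_order) != 1:
            raise ConfigError("EXP1 has exactly one block")
        if self.experiment is Experiment.EXP2 and sorted(self.block_order) != sorted(
            (Condition.LC, Condition.HC)
        ):
            raise ConfigError("EXP2 has two blocks, one per condition")

    @property
    def n_blocks(self) -> int:
        return len(self.block_order)

    @property
    def trials_per_block(self) -> int:
        return 3 * self.trials_per_stimulus

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def block_stimuli(self, block_index: int) -> tuple[Stimulus, Stimulus, Stimulus]:
        return stimuli_for_condition(self.block_order[block_index])

    def spec_for(self, stimulus: Stimulus) -> StimulusSpec:
        return self.contingencies[stimulus]

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment.value,
            "block_order": [c.value for c in self.block_order],
            "trials_per_stimulus": self.trials_per_stimulus,
            "rng_seed": self.rng_seed,
            "contingencies": {
                s.value: {"p_reward_go": spec.p_reward_go, "p_reward_nogo": spec.p_reward_nogo}
                for s, spec in self.contingencies.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        contingencies = {
            Stimulus(name): StimulusSpec(Stimulus(name), v["p_reward_go"], v["p_reward_nogo"])
            for name, v in d.get("contingencies", {}).items()
        } or dict(DEFAULT_CONTINGENCIES)
        return cls(
            experiment=Experiment(d["experiment"]),
            block_order=tuple(Condition(c) for c in d["block_order"]),
            trials_per_stimulus=int(d.get("trials_per_stimulus", 40)),
            rng_seed=int(d.get("rng_seed", 0)),
            contingencies=contingencies,
        )


def build_task_config(
    experiment: Experiment | str,
    condition: Condition | str | None = None,
    seed: int = 0,
    trials_per_stimulus: int = 40,
    contingencies: dict[Stimulus, StimulusSpec] | None = None,
) -> TaskConfig:
    """Build a session configuration.

    EXP1 requires ``condition`` (the single decoy condition). EXP2 ignores
    it: both conditions are generated as separate blocks whose order is
    randomized by ``seed``.
    """
    try:
        experiment = Experiment(experiment)
    except ValueError as exc:
        raise ConfigError(f"unknown experiment {experiment!r}") from exc

    if experiment is Experiment.EXP1:
        if condition is None:
            raise ConfigError("EXP1 requires a condition (lc or hc)")
        try:
            condition = Condition(condition)
        except ValueError as exc:
            raise ConfigError(f"unknown condition {condition!r}") from exc
        block_order: tuple[Condition, ...] = (condition,)
    else:
        order = [Condition.LC, Condition.HC]
        rng = substream(seed, "block_order")
        rng.shuffle(order)
        block_order = tuple(order)

    return TaskConfig(
        experiment=experiment,
        block_order=block_order,
        trials_per_stimulus=trials_per_stimulus,
        rng_seed=seed,
        contingencies=dict(contingencies or DEFAULT_CONTINGENCIES),
    )


def sample_trial_sequence(config: TaskConfig) -> list[tuple[Stimulus, int]]:
    """Sample the ordered stimulus sequence for one session.

    Within each block, every stimulus of that block appears exactly
    ``trials_per_stimulus`` times, in a seeded uniform shuffle.
    """
    sequence: list[tuple[Stimulus, int]] = []
    for b in range(config.n_blocks):
        rng = substream(config.rng_seed, "sequence", b)
        block = [s for s in config.block_stimuli(b) for _ in range(config.trials_per_stimulus)]
        rng.shuffle(block)
        sequence.extend((s, b) for s in block)
    return sequence


def sample_outcome(spec: StimulusSpec, action: Action, rng: np.random.Generator) -> int:
    """Bernoulli reward draw for taking ``action`` on ``spec``'s stimulus."""
    p = spec.p_reward_go if action is Action.GO else spec.p_reward_nogo
    return int(rng.random() < p)


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial of the task."""

    participant_id: str
    experiment: Experiment
    condition: Condition
    block_index: int
    trial_index: int
    stimulus: Stimulus
    action: Action
    reward: int
    optimal_action: OptimalAction

    def __post_init__(self) -> None:
        if self.reward not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.reward!r}")


CSV_HEADER = [
    "participant_id",
    "experiment",
    "condition",
    "block",
    "trial",
    "stimulus",
    "action",
    "reward",
    "optimal_action",
]


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trial records to the documented CSV schema (UTF-8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.participant_id,
                    rec.experiment.value,
                    rec.condition.value,
                    rec.block_index,
                    rec.trial_index,
                    rec.stimulus.value,
                    rec.action.value,
                    rec.reward,
                    rec.optimal_action.value,
                ]
            )


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read trial records from CSV, validating schema and invariants."""
    path = Path(path)
    records: list[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrialParseError(f"{path}: empty file without header")
        missing = set(CSV_HEADER) - set(reader.fieldnames)
        if missing:
            raise TrialParseError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                reward = int(row["reward"])
                if reward not in (0, 1):
                    raise ValueError(f"non-binary reward {row['reward']!r}")
                records.append(
                    TrialRecord(
                        participant_id=row["participant_id"],
                        experiment=Experiment(row["experiment"]),
                        condition=Condition(row["condition"]),
                        block_index=int(row["block"]),
                        trial_index=int(row["trial"]),
                        stimulus=Stimulus(row["stimulus"]),
                        action=Action(row["action"]),
                        reward=reward,
                        optimal_action=OptimalAction(row["optimal_action"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise TrialParseError(f"{path}, row {i}: {exc}") from exc
    return records


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame in the CSV column layout."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "experiment": [r.experiment.value for r in records],
            "condition": [r.condition.value for r in records],
            "block": [r.block_index for r in records],
            "trial": [r.trial_index for r in records],
            "stimulus": [r.stimulus.value for r in records],
            "action": [r.action.value for r in records],
            "reward": [r.reward for r in records],
            "optimal_action": [r.optimal_action.value for r in records],
        }
    )


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame`."""
    return [
        TrialRecord(
            participant_id=str(row.participant_id),
            experiment=Experiment(row.experiment),
            condition=Condition(row.condition),
            block_index=int(row.block),
            trial_index=int(row.trial),
            stimulus=Stimulus(row.stimulus),
            action=Action(row.action),
            reward=int(row.reward),
            optimal_action=OptimalAction(row.optimal_action),
        )
        for row in df.itertuples(index=False)
    ]
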