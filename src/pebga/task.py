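"""Probabilistic instrumental learning task: structure and trial schedules.

The task interleaves reward pairs (outcomes +1 EUR / 0) and punishment pairs
(0 / -1 EUR) of abstract cues. Within each pair the two cues carry reciprocal
outcome contingencies (by default 0.75 / 0.25 for the better cue's good
outcome). Each pair is shown a fixed number of times per session; a default
session is 4 pairs x 24 presentations = 96 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REWARD = "reward"
PUNISHMENT = "punishment"

#: canonical column order of a behavioral session table
SESSION_COLUMNS = [
    "trial",
    "pair_id",
    "condition",
    "cue_left",
    "cue_right",
    "chosen_side",
    "chosen_cue",
    "correct",
    "outcome",
    "rt_ms",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the learning task.

    Cue index 0 of each pair is, by convention, the "better" cue: in the
    reward condition it yields +1 EUR with probability ``contingency``; in the
    punishment condition it yields -1 EUR with probability
    ``1 - contingency``. Cue 1 carries the reciprocal contingency.
    """

    n_pairs_per_condition: int = 2
    presentations_per_pair: int = 24
    reward_outcomes: tuple[float, float] = (1.0, 0.0)
    punishment_outcomes: tuple[float, float] = (-1.0, 0.0)
    contingency: float = 0.75
    n_sessions: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.contingency < 1.0:
            raise ValueError(f"contingency must lie in (0, 1), got {self.contingency}")
        if self.n_pairs_per_condition < 1 or self.presentations_per_pair < 1:
            raise ValueError("pair and presentation counts must be positive")

    @property
    def n_pairs(self) -> int:
        return 2 * self.n_pairs_per_condition

    @property
    def trials_per_session(self) -> int:
        return self.n_pairs * self.presentations_per_pair

    def pair_condition(self, pair_id: int) -> str:
        """Condition of a pair; pairs alternate reward/punishment by id."""
        return REWARD if pair_id % 2 == 0 else PUNISHMENT

    def good_outcome(self, condition: str) -> float:
        """The non-zero outcome a cue's contingency refers to."""
        return self.reward_outcomes[0] if condition == REWARD else self.punishment_outcomes[0]

    def cue_nonzero_prob(self, condition: str, cue: int) -> float:
        """Probability that the given cue delivers its non-zero outcome.

        For reward pairs the better cue (0) delivers +1 most often; for
        punishment pairs the better cue delivers -1 least often.
        """
        p_good = self.contingency if cue == 0 else 1.0 - self.contingency
        if condition == REWARD:
            return p_good
        return 1.0 - p_good


def build_session_schedule(config: TaskConfig, rng: np.random.Generator | int) -> pd.DataFrame:
    """Draw one session's trial schedule with latent outcomes for both cues.

    Returns a DataFrame with one row per trial: ``trial`` (1-based),
    ``pair_id``, ``condition``, ``side_of_cue0`` (counterbalanced screen
    position of the better cue) and the latent outcome each cue *would*
    deliver if chosen (``outcome_cue0``, ``outcome_cue1``). Drawing both
    counterfactual outcomes up front makes agent simulation and replay
    deterministic given the schedule.
    """
    rng = np.random.default_rng(rng)
    pair_ids = np.repeat(np.arange(config.n_pairs), config.presentations_per_pair)
    rng.shuffle(pair_ids)

    n = len(pair_ids)
    conditions = np.array([config.pair_condition(p) for p in pair_ids])
    out0 = np.empty(n)
    out1 = np.empty(n)
    for i, (pid, cond) in enumerate(zip(pair_ids, conditions)):
        nonzero = config.good_outcome(cond)
        out0[i] = nonzero if rng.random() < config.cue_nonzero_prob(cond, 0) else 0.0
        out1[i] = nonzero if rng.random() < config.cue_nonzero_prob(cond, 1) else 0.0
    side0 = rng.permuted(
        np.where(np.arange(n) % 2 == 0, "left", "right")
    )
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "pair_id": pair_ids,
            "condition": conditions,
            "side_of_cue0": side0,
            "outcome_cue0": out0,
            "outcome_cue1": out1,
        }
    )


@dataclass
class SessionTiming:
    """Event timing used when a session is rendered as a continuous recording.

    The chosen cue is highlighted for 250 ms and the outcome appears 1 s
    later, so outcome onset trails the choice by 1.25 s. ``iti`` paces trials
    far enough apart that every outcome-locked epoch (-3 to +3 s) has full
    support without overlapping its neighbours.
    """

    pre_task: float = 5.0
    cue_to_choice_extra: float = 0.0
    choice_to_outcome: float = 1.25
    iti: float = 4.0
    post_task: float = 5.0

    def event_times(self, rts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cue and outcome onset times (s) for a vector of reaction times."""
        n = len(rts)
        cue = np.empty(n)
        outcome = np.empty(n)
        t = self.pre_task
        for i in range(n):
            cue[i] = t
            outcome[i] = t + rts[i] + self.choice_to_outcome
            t = outcome[i] + self.iti
        return cue, outcome


def write_session_tsv(session: pd.DataFrame, path) -> None:
    """Write one behavioral session as a BIDS-events-like TSV."""
    session.to_csv(path, sep="\t", index=False)


def read_session_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session TSV missing columns: {sorted(missing)}")
    return df
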