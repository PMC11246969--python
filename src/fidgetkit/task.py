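"""Flanker session structure: trial events and the task schedule."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRIAL_TYPES = ("congruent", "incongruent", "neutral")
RESPONSES = ("left", "right", "none")


@dataclass(frozen=True)
class TrialEvent:
    """One trial of a Flanker session.

    ``rt_ms`` is ``None`` exactly when the trial is an omission
    (``response == "none"``).
    """

    trial_index: int
    trial_type: str
    onset_ms: float
    response: str = "none"
    correct: bool = False
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if (self.response == "none") != (self.rt_ms is None):
            raise ValueError(
                "omission contract violated: response 'none' iff rt_ms is None"
            )
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")

    @property
    def omitted(self) -> bool:
        return self.response == "none"


@dataclass(frozen=True)
class TaskSchedule:
    """Trial timing of a Flanker session.

    Default: 40 trials per type (120 total), 1000 ms stimulus followed by
    a 1000 ms inter-trial interval, trial order a seeded permutation.
    """

    n_per_type: int = 40
    types: tuple[str, ...] = TRIAL_TYPES
    stimulus_ms: float = 1000.0
    iti_ms: float = 1000.0
    seed: int = 0
    trial_types: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_per_type < 1:
            raise ValueError("n_per_type must be >= 1")
        if self.stimulus_ms <= 0 or self.iti_ms < 0:
            raise ValueError("stimulus_ms must be > 0 and iti_ms >= 0")
        labels = np.repeat(np.asarray(self.types, dtype=object), self.n_per_type)
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(labels.size)
        object.__setattr__(self, "trial_types", tuple(labels[order]))

    @property
    def n_trials(self) -> int:
        return self.n_per_type * len(self.types)

    @property
    def trial_ms(self) -> float:
        return self.stimulus_ms + self.iti_ms

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.trial_ms / 1000.0

    def onsets_ms(self) -> np.ndarray:
        """Strictly increasing trial onsets, spaced stimulus + ITI apart."""
        return np.arange(self.n_trials) * self.trial_ms

    def events(self) -> list[TrialEvent]:
        """Schedule skeleton as unanswered trial events."""
        return [
            TrialEvent(trial_index=i, trial_type=t, onset_ms=float(o))
            for i, (t, o) in enumerate(zip(self.trial_types, self.onsets_ms()))
        ]
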