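"""Trial schedule of the live action paradigm.

Three conditions — motor execution (ME), observation (MO), imagery (MI) —
15 trials each, in randomized order with no condition occurring more than
three times in a row. A trial lasts about 5 s and is followed by a 20 s
recovery so the hemodynamic response can return to baseline. ME/MO trials
are anchored to a ``start_action`` marker, MI trials to ``end_speak``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONDITIONS = ("ME", "MO", "MI")
TRIAL_DURATION_S = 5.0
RECOVERY_S = 20.0
N_TRIALS_PER_CONDITION = 15


@dataclass(frozen=True)
class Trial:
    condition: str
    onset: float  # s from recording start; the anchor marker time
    duration: float

    @property
    def marker(self) -> str:
        return "start_action" if self.condition in ("ME", "MO") else "end_speak"


@dataclass(frozen=True)
class EventSchedule:
    trials: tuple[Trial, ...]
    lead_in: float = 10.0

    def __len__(self) -> int:
        return len(self.trials)

    def by_condition(self, condition: str) -> list[Trial]:
        return [t for t in self.trials if t.condition == condition]

    @property
    def end_time(self) -> float:
        last = self.trials[-1]
        return last.onset + last.duration + RECOVERY_S

    def to_dicts(self) -> list[dict]:
        return [
            {
                "condition": t.condition,
                "onset": t.onset,
                "duration": t.duration,
                "marker": t.marker,
            }
            for t in self.trials
        ]

    @staticmethod
    def from_dicts(rows: list[dict], lead_in: float = 10.0) -> "EventSchedule":
        return EventSchedule(
            trials=tuple(
                Trial(r["condition"], float(r["onset"]), float(r["duration"]))
                for r in rows
            ),
            lead_in=lead_in,
        )


def _condition_order(rng: np.random.Generator, max_run: int = 3) -> list[str]:
    """Random order of 15+15+15 condition labels, longest run <= max_run."""
    while True:
        order = list(np.repeat(CONDITIONS, N_TRIALS_PER_CONDITION))
        rng.shuffle(order)
        run, ok = 1, True
        for a, b in zip(order, order[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return order


def generate_schedule(
    seed: int,
    trial_duration: float = TRIAL_DURATION_S,
    duration_jitter: float = 0.5,
    recovery: float = RECOVERY_S,
    lead_in: float = 10.0,
) -> EventSchedule:
    """Generate the 45-trial schedule (15 per condition).

    Trial durations are jittered uniformly by ``+/- duration_jitter`` around
    the nominal 5 s; each trial is followed by the fixed recovery period, so
    every inter-onset interval is at least
    ``trial_duration - duration_jitter + recovery`` (24.5 s by default).
    """
    rng = np.random.default_rng(seed)
    order = _condition_order(rng)
    t = float(lead_in)
    trials = []
    for cond in order:
        dur = trial_duration + rng.uniform(-duration_jitter, duration_jitter)
        trials.append(Trial(cond, round(t, 3), round(dur, 3)))
        t += dur + recovery
    return EventSchedule(trials=tuple(trials), lead_in=lead_in)


__all__ = [
    "CONDITIONS",
    "Trial",
    "EventSchedule",
    "generate_schedule",
    "TRIAL_DURATION_S",
    "RECOVERY_S",
    "N_TRIALS_PER_CONDITION",
]
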