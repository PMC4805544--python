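"""Sensory-preconditioning task structure.

The task has three phases run in order:

1. *Preconditioning* — two sessions in which two pairs of auditory cues
   (A->B and C->D) are presented sequentially with no gap, six pairs each
   per session, in a blocked design, without any reward.
2. *Conditioning* — six sessions in which cue B is paired with reward
   (deliveries 1, 4 and 7 s into its 10-s presentation) and cue D is
   presented unrewarded, six trials each per session in 3-trial blocks.
3. *Probe* — a single session with three rewarded B reminders and three
   D trials interleaved, followed by six unrewarded presentations each of
   A and C.

Cue A is therefore never contemporaneous with reward in any trial, which
is the structural fact that makes responding to A at probe diagnostic of
inferred rather than cached value.

Times inside a trial are seconds from trial start; every trial carries a
pre-cue window (standing in for the tail of the long inter-trial
interval) that downstream analyses use as the firing-rate baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DatasetValidationError

CUES = ("A", "B", "C", "D")
PHASES = ("preconditioning", "conditioning", "probe")

EVENT_COLUMNS = [
    "session_id",
    "phase",
    "trial",
    "cue_id",
    "cue_on",
    "cue_off",
    "reward_times",
    "trial_duration",
]


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of the three-phase task.

    ``iti_range`` (seconds) is retained for completeness and can be
    compressed by ``iti_scale`` when simulating wall-clock timelines;
    the per-trial analyses only require that ``pre_cue_window`` covers
    the baseline window, so the ITI itself never enters the statistics.
    """

    cue_duration: float = 10.0
    reward_times_in_b: tuple[float, ...] = (1.0, 4.0, 7.0)
    n_preconditioning_sessions: int = 2
    pairs_per_session: int = 6
    n_conditioning_sessions: int = 6
    conditioning_trials_per_cue: int = 6
    conditioning_block: int = 3
    probe_reminder_trials: int = 3
    probe_test_trials: int = 6
    iti_range: tuple[float, float] = (180.0, 360.0)
    iti_scale: float = 1.0
    pre_cue_window: float = 2.0
    post_cue_window: float = 3.0

    def __post_init__(self):
        if self.cue_duration <= 0:
            raise ConfigError("cue_duration must be positive")
        for rt in self.reward_times_in_b:
            if not (0 <= rt < self.cue_duration):
                raise ConfigError(
                    f"reward offset {rt} s falls outside the {self.cue_duration} s cue"
                )
        if self.iti_scale <= 0:
            raise ConfigError("iti_scale must be positive")
        if self.pre_cue_window <= 0 or self.post_cue_window < 0:
            raise ConfigError("trial padding windows must be non-negative (pre > 0)")
        for name in (
            "n_preconditioning_sessions",
            "pairs_per_session",
            "n_conditioning_sessions",
            "conditioning_trials_per_cue",
            "conditioning_block",
            "probe_reminder_trials",
            "probe_test_trials",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    # -- session bookkeeping -------------------------------------------------
    @property
    def n_sessions(self) -> int:
        return self.n_preconditioning_sessions + self.n_conditioning_sessions + 1

    @property
    def conditioning_sessions(self) -> tuple[int, ...]:
        first = self.n_preconditioning_sessions + 1
        return tuple(range(first, first + self.n_conditioning_sessions))

    @property
    def probe_session(self) -> int:
        return self.n_sessions

    def phase_of(self, session_id: int) -> str:
        if 1 <= session_id <= self.n_preconditioning_sessions:
            return "preconditioning"
        if session_id in self.conditioning_sessions:
            return "conditioning"
        if session_id == self.probe_session:
            return "probe"
        raise ConfigError(f"session_id {session_id} outside the task ({self.n_sessions} sessions)")

    def conditioning_index(self, session_id: int) -> int:
        """1-based position of a session within the conditioning phase."""
        if self.phase_of(session_id) != "conditioning":
            raise ConfigError(f"session {session_id} is not a conditioning session")
        return session_id - self.n_preconditioning_sessions

    def scaled_iti_range(self) -> tuple[float, float]:
        lo, hi = self.iti_range
        return (lo * self.iti_scale, hi * self.iti_scale)


def trial_table(spec: TaskSpec) -> pd.DataFrame:
    """Deterministic trial/event schedule for the whole task.

    One row per cue presentation; sequential-pair trials in
    preconditioning contribute two rows sharing a trial index.
    ``reward_times`` are absolute within-trial times (seconds).
    """
    pre, post, cd = spec.pre_cue_window, spec.post_cue_window, spec.cue_duration
    rows: list[tuple] = []

    # Phase 1: sequential pairs, blocked, block order alternating across days.
    for s in range(1, spec.n_preconditioning_sessions + 1):
        pairs = [("A", "B"), ("C", "D")]
        if s % 2 == 0:
            pairs = pairs[::-1]
        trial = 0
        dur = pre + 2 * cd + post
        for c1, c2 in pairs:
            for _ in range(spec.pairs_per_session):
                trial += 1
                rows.append((s, "preconditioning", trial, c1, pre, pre + cd, [], dur))
                rows.append((s, "preconditioning", trial, c2, pre + cd, pre + 2 * cd, [], dur))

    # Phase 2: B rewarded / D unrewarded in alternating blocks.
    dur = pre + cd + post
    rewards = [pre + rt for rt in spec.reward_times_in_b]
    for k, s in enumerate(spec.conditioning_sessions):
        order = ["B", "D"] if k % 2 == 0 else ["D", "B"]
        seq: list[str] = []
        left = {c: spec.conditioning_trials_per_cue for c in order}
        turn = 0
        while any(left.values()):
            cue = order[turn % 2]
            take = min(spec.conditioning_block, left[cue])
            seq.extend([cue] * take)
            left[cue] -= take
            turn += 1
        for t, cue in enumerate(seq, start=1):
            rw = list(rewards) if cue == "B" else []
            rows.append((s, "conditioning", t, cue, pre, pre + cd, rw, dur))

    # Phase 3: interleaved reminders, then interleaved unrewarded A/C tests.
    s = spec.probe_session
    t = 0
    for _ in range(spec.probe_reminder_trials):
        for cue in ("B", "D"):
            t += 1
            rw = list(rewards) if cue == "B" else []
            rows.append((s, "probe", t, cue, pre, pre + cd, rw, dur))
    for _ in range(spec.probe_test_trials):
        for cue in ("A", "C"):
            t += 1
            rows.append((s, "probe", t, cue, pre, pre + cd, [], dur))

    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def check_structure(events: pd.DataFrame, spec: TaskSpec | None = None) -> None:
    """Assert the structural guarantees of the design on an event table.

    Raises :class:`DatasetValidationError` if cue A ever shares a trial
    with a reward delivery, if A precedes B outside preconditioning, or
    if any cue presentation deviates from the nominal cue duration.
    """
    cd = spec.cue_duration if spec is not None else None
    for i, row in events.reset_index(drop=True).iterrows():
        if cd is not None and abs((row.cue_off - row.cue_on) - cd) > 1e-9:
            raise DatasetValidationError(
                f"cue duration {row.cue_off - row.cue_on} != {cd}", file="events", row=int(i)
            )
        if row.cue_id == "A" and len(row.reward_times) > 0:
            raise DatasetValidationError("cue A carries reward events", file="events", row=int(i))

    for (sess, trial), grp in events.groupby(["session_id", "trial"], sort=False):
        cues = set(grp.cue_id)
        if "A" in cues:
            n_rewards = int(grp.reward_times.map(len).sum())
            if n_rewards:
                raise DatasetValidationError(
                    f"trial ({sess}, {trial}) contains cue A and {n_rewards} reward(s)",
                    file="events",
                )
            if "B" in cues and grp.phase.iloc[0] != "preconditioning":
                raise DatasetValidationError(
                    f"A precedes B outside preconditioning in trial ({sess}, {trial})",
                    file="events",
                )


def draw_itis(spec: TaskSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inter-trial intervals (s), uniform on the scaled range."""
    lo, hi = spec.scaled_iti_range()
    return rng.uniform(lo, hi, size=n)
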