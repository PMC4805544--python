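"""Model-free and model-based value learners on the identical task.

Both agents see the same deterministic trial sequence, discretized at
1 s per step with a complete-serial-compound state representation (one
state per cue per second, e.g. ``B3`` is the fourth second of cue B).
Reward magnitude is 1 per delivery, arriving on the transition into the
state whose second contains the delivery (rewards 1, 4, 7 s into B land
entering ``B1``, ``B4``, ``B7``).  The inter-trial interval is a single
background state with value fixed at zero, so cue onsets are
unpredictable and the onset prediction error reduces to
``gamma * V(first cue state)``.

* The **model-free** agent is tabular TD(0) over cached values:
  ``V(s) += alpha * (r + gamma * V(s') - V(s))``.  Because cue A is
  never followed by reward within its own trials and is absent during
  conditioning, every state on A's chain keeps exactly zero value, so
  A's probe-onset prediction error is exactly zero — the analytic
  signature that cached-value errors cannot express inferred value.
* The **model-based** agent learns incremental one-step transition
  estimates in every phase (including A->B during preconditioning) and
  per-state reward estimates, and evaluates a cue at probe by value
  iteration over its learned model.  Because it chains A->B->reward, its
  probe-onset signal for A is positive whenever T(A->B) and the learned
  value of B are.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .task import TaskSpec, trial_table

ITI = "ITI"


@dataclass(frozen=True)
class AgentConfig:
    """Learning-rate / discount configuration (step = 1 s)."""

    alpha: float = 0.1
    gamma: float = 0.95
    model_based: bool = False
    step: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigError("alpha must lie in [0, 1]")
        if not (0.0 < self.gamma <= 1.0):
            raise ConfigError("gamma must lie in (0, 1]")
        if self.step <= 0:
            raise ConfigError("step must be positive")


@dataclass
class Episode:
    phase: str
    session_id: int
    trial: int
    states: list[str]     # cue states, in order (background not included)
    rewards: list[float]  # rewards[k] received entering seq[k+1]; len = len(states) + 1

    @property
    def sequence(self) -> list[str]:
        return [ITI] + self.states + [ITI]


def build_episodes(spec: TaskSpec, step: float = 1.0) -> list[Episode]:
    """Deterministic episode list for the whole task (phases in order)."""
    n_steps = spec.cue_duration / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigError("step must divide the cue duration")
    n_steps = round(n_steps)
    episodes = []
    events = trial_table(spec)
    for (sess, trial), grp in events.groupby(["session_id", "trial"], sort=True):
        grp = grp.sort_values("cue_on")
        states: list[str] = []
        reward_steps: dict[int, float] = {}
        offset = 0
        for row in grp.itertuples():
            states.extend(f"{row.cue_id}{i}" for i in range(n_steps))
            for rt in row.reward_times:
                k = int(np.floor((rt - row.cue_on) / step + 1e-9)) + offset
                reward_steps[k] = reward_steps.get(k, 0.0) + 1.0
            offset += n_steps
        rewards = [reward_steps.get(k, 0.0) for k in range(1, len(states) + 1)]
        rewards = [0.0] + rewards  # transition into the first cue state carries no reward
        # rewards[k] is received entering sequence[k+1]; the final entry is
        # the transition into ITI after the last cue state.
        episodes.append(Episode(phase=grp.phase.iloc[0], session_id=int(sess),
                                trial=int(trial), states=states, rewards=rewards))
    return episodes


@dataclass
class AgentTrace:
    """Learning trace plus probe-onset signals.

    ``trace`` has one row per state transition with the pre-update
    values used to form each prediction error, so the Bellman identity
    ``delta == r + gamma * v_next - v_state`` is checkable exactly.
    ``probe_onset`` has one row per cue with the onset signal at that
    cue's first probe presentation.
    """

    config: AgentConfig
    values: dict[str, float]
    trace: pd.DataFrame
    probe_onset: pd.DataFrame
    transitions: dict = field(default_factory=dict)


def run_model_free(spec: TaskSpec, config: AgentConfig) -> AgentTrace:
    """Tabular TD(0) over the three phases in order."""
    a, g = config.alpha, config.gamma
    V: dict[str, float] = defaultdict(float)
    rows = []
    onset: dict[str, float] = {}
    for ep in build_episodes(spec, config.step):
        seq = ep.sequence
        for k in range(len(seq) - 1):
            s, s2 = seq[k], seq[k + 1]
            r = ep.rewards[k]
            vs = 0.0 if s == ITI else V[s]
            vs2 = 0.0 if s2 == ITI else V[s2]
            delta = r + g * vs2 - vs
            rows.append((ep.phase, ep.session_id, ep.trial, k, s, s2, r, vs, vs2, delta))
            if s != ITI:
                V[s] = vs + a * delta
            if k == 0 and ep.phase == "probe":
                cue = s2[0]
                if cue not in onset:
                    onset[cue] = delta
    trace = pd.DataFrame(rows, columns=["phase", "session_id", "trial", "step", "state",
                                        "next_state", "reward", "v_state", "v_next", "delta"])
    probe = pd.DataFrame(sorted(onset.items()), columns=["cue_id", "onset_signal"])
    return AgentTrace(config=config, values=dict(V), trace=trace, probe_onset=probe)


def _value_iteration(T: dict, R: dict, gamma: float, states, tol: float = 1e-12,
                     max_iter: int = 10_000) -> dict[str, float]:
    """Evaluate V(s) = sum_s' T(s,s') * (R(s') + gamma * V(s')); V(ITI) = 0."""
    states = sorted(states)  # fixed sweep order keeps results bit-reproducible
    V = {s: 0.0 for s in states}
    for _ in range(max_iter):
        worst = 0.0
        for s in states:
            total = 0.0
            for s2, p in T.get(s, {}).items():
                r = R.get(s2, 0.0)
                v2 = 0.0 if s2 == ITI else V.get(s2, 0.0)
                total += p * (r + gamma * v2)
            worst = max(worst, abs(total - V[s]))
            V[s] = total
        if worst < tol:
            break
    return V


def run_model_based(spec: TaskSpec, config: AgentConfig) -> AgentTrace:
    """Transition/reward learning plus value iteration at probe.

    Transition estimates update incrementally on every within-trial
    transition (the unpredictable background -> cue onset is not
    modeled); reward estimates update toward the reward received on
    entering each state.  The probe-onset signal for a cue is the
    inferred value of its first state minus the prior expectation of
    zero, evaluated from the model as learned at that trial.
    """
    a, g = config.alpha, config.gamma
    T: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    R: dict[str, float] = defaultdict(float)
    rows = []
    onset: dict[str, float] = {}
    for ep in build_episodes(spec, config.step):
        seq = ep.sequence
        if ep.phase == "probe":
            cue = ep.states[0][0]
            if cue not in onset:
                states = set(T.keys()) | {s2 for d in T.values() for s2 in d}
                states.discard(ITI)
                V = _value_iteration({s: dict(d) for s, d in T.items()}, dict(R), g, states)
                onset[cue] = V.get(ep.states[0], 0.0)
        for k in range(len(seq) - 1):
            s, s2 = seq[k], seq[k + 1]
            r = ep.rewards[k]
            if s != ITI:
                d = T[s]
                for key in list(d):
                    d[key] *= (1.0 - a)
                d[s2] = d.get(s2, 0.0) + a  # completes T(s,.) <- (1-a) T(s,.) + a 1[s'=s2]
            if s2 != ITI:
                R[s2] = R[s2] + a * (r - R[s2])
            rows.append((ep.phase, ep.session_id, ep.trial, k, s, s2, r))
    trace = pd.DataFrame(rows, columns=["phase", "session_id", "trial", "step",
                                        "state", "next_state", "reward"])
    probe = pd.DataFrame(sorted(onset.items()), columns=["cue_id", "onset_signal"])
    states = set(T.keys())
    Vfinal = _value_iteration({s: dict(d) for s, d in T.items()}, dict(R), g, states)
    return AgentTrace(config=config, values=Vfinal, trace=trace, probe_onset=probe,
                      transitions={s: dict(d) for s, d in T.items()})


def compare_agents(spec: TaskSpec, mf_config: AgentConfig | None = None,
                   mb_config: AgentConfig | None = None) -> pd.DataFrame:
    """Probe-onset signals per cue for both agents, with the key contrasts.

    The model-free row has an A−C contrast of exactly zero (neither cue
    chain ever carries cached value); the model-based row's A−C contrast
    is positive.  Both agents acquire B value, so B−D is positive in
    both rows.
    """
    mf_config = mf_config or AgentConfig(alpha=0.1, gamma=0.95, model_based=False)
    mb_config = mb_config or AgentConfig(alpha=0.1, gamma=0.95, model_based=True)
    mf = run_model_free(spec, mf_config)
    mb = run_model_based(spec, mb_config)
    rows = []
    for name, tr in (("model_free", mf), ("model_based", mb)):
        sig = dict(zip(tr.probe_onset.cue_id, tr.probe_onset.onset_signal))
        rows.append({
            "agent": name,
            **{f"onset_{c}": sig.get(c, np.nan) for c in "ABCD"},
            "contrast_A_minus_C": sig.get("A", np.nan) - sig.get("C", np.nan),
            "contrast_B_minus_D": sig.get("B", np.nan) - sig.get("D", np.nan),
        })
    return pd.DataFrame(rows)
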