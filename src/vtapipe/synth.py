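"""Synthetic VTA populations and behavior with the structure the analysis assumes.

The generator emulates three response archetypes observed among VTA units
during appetitive conditioning:

* ``phasic`` — putative dopaminergic: transient excitation at cue onset and
  at each reward delivery.  Across conditioning the transient "mass"
  migrates from the reward deliveries to cue onset (the classic
  prediction-error trajectory), linearly in session index by default.
  At probe, onset-transient amplitudes carry per-neuron coding strengths:
  a B-versus-D strength (cached value) and an A-versus-C strength
  (inferred value), drawn as a correlated bivariate normal pair so the
  population-level coupling between the two codes is a controlled
  parameter ``rho``.  A small sustained component during cue A (scaled by
  the same inferred-value strength) emulates elevated firing throughout a
  cue whose reward lies beyond its offset.
* ``sustained_excited`` — putative GABAergic: tonic elevation over the
  full cue.
* ``sustained_inhibited`` — tonic suppression over the full cue.

Spike trains are inhomogeneous Poisson, sampled by thinning against the
(piecewise) rate template of each neuron-trial; rates are rectified at
zero after summing components.  Firing-rate magnitudes are free
parameters of the generator (no population magnitudes are available to
copy); the defaults — a few-Hz dopaminergic baseline with phasic bursts
peaking tens of Hz above it, and wide across-neuron heterogeneity in
burst amplitude — are chosen to be typical of midbrain recordings.

Behavior is a per-trial food-cup occupancy fraction (percent of cue time
with the head in the cup), Beta-distributed around phase-dependent means:
flat and low in preconditioning, ramping for B across conditioning, and
transferring to A (above C) at probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, UnknownArchetypeError, UnknownCueError
from .task import CUES, EVENT_COLUMNS, TaskSpec, trial_table

ARCHETYPES = ("phasic", "sustained_excited", "sustained_inhibited")

#: Per-archetype defaults for :class:`ArchetypeParams` (rates in Hz).
ARCHETYPE_DEFAULTS: dict[str, dict] = {
    "phasic": dict(baseline_rate=6.0, phasic_gain=45.0, phasic_latency=0.05,
                   phasic_decay=0.2, sustained_gain=0.0, a_sustained_gain=1.0),
    "sustained_excited": dict(baseline_rate=15.0, phasic_gain=0.0, sustained_gain=8.0),
    "sustained_inhibited": dict(baseline_rate=12.0, phasic_gain=0.0, sustained_gain=-7.0),
}


@dataclass(frozen=True)
class ArchetypeParams:
    """Rate-template parameters for a single simulated neuron.

    ``b_minus_d`` and ``a_minus_c`` are this neuron's coding strengths:
    multiplicative boosts (relative to the generalization level shared by
    all cues) of the onset transient to B and to A respectively.

    ``onset_weight_floor`` / ``reward_weight_floor`` bound the linear
    learning trajectory: the cue-onset transient weight rises from the
    floor to 1 across conditioning while the reward weight falls from 1
    to its floor, so reward dominates in session 1 and onset in the final
    session by construction.  ``trajectory_slope`` scales the excursion
    around the mid-trajectory point (0 freezes the weights: the ablation
    used for null calibrations).
    """

    archetype: str
    baseline_rate: float = 6.0
    phasic_gain: float = 0.0
    phasic_latency: float = 0.05
    phasic_decay: float = 0.2
    sustained_gain: float = 0.0
    a_sustained_gain: float = 0.0
    generalization: float = 0.5
    b_minus_d: float = 0.0
    a_minus_c: float = 0.0
    onset_weight_floor: float = 0.2
    reward_weight_floor: float = 0.2
    trajectory_slope: float = 1.0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise UnknownArchetypeError(f"unknown archetype {self.archetype!r}")
        if self.baseline_rate < 0:
            raise ConfigError("baseline_rate must be non-negative")
        if self.phasic_decay <= 0:
            raise ConfigError("phasic_decay must be positive")
        if not (0 <= self.onset_weight_floor <= 1 and 0 <= self.reward_weight_floor <= 1):
            raise ConfigError("trajectory weight floors must lie in [0, 1]")


def learning_weights(params: ArchetypeParams, spec: TaskSpec, session_id: int) -> tuple[float, float]:
    """(onset_weight, reward_weight) for a session.

    Linear in conditioning-session index; preconditioning sits at the
    start of the trajectory and probe at its end.
    """
    phase = spec.phase_of(session_id)
    if phase == "preconditioning":
        frac = 0.0
    elif phase == "conditioning":
        n = spec.n_conditioning_sessions
        idx = spec.conditioning_index(session_id)
        frac = 0.0 if n == 1 else (idx - 1) / (n - 1)
    else:
        frac = 1.0
    frac = 0.5 + params.trajectory_slope * (frac - 0.5)
    w_on = params.onset_weight_floor + (1.0 - params.onset_weight_floor) * frac
    w_rew = 1.0 - (1.0 - params.reward_weight_floor) * frac
    return w_on, w_rew


def _cue_component(params: ArchetypeParams, cue_id: str, session_id: int,
                   spec: TaskSpec, onset: float, reward_times: list[float]):
    """Rate modulation (Hz, may be negative) of one cue presentation.

    Returns ``(fn, max_extra)`` where ``fn`` maps trial times to the
    modulation and ``max_extra`` bounds its positive part (for thinning).
    """
    if cue_id not in CUES:
        raise UnknownCueError(f"unknown cue {cue_id!r}")
    phase = spec.phase_of(session_id)
    w_on, w_rew = learning_weights(params, spec, session_id)

    transients: list[tuple[float, float]] = []
    sustained = 0.0
    if params.archetype == "phasic":
        coding = {"B": params.b_minus_d, "A": params.a_minus_c}.get(cue_id, 0.0)
        amp_on = params.phasic_gain * w_on * (params.generalization + coding)
        transients.append((onset, amp_on))
        for rt in reward_times:
            transients.append((rt, params.phasic_gain * w_rew))
        if cue_id == "A" and phase == "probe":
            sustained = params.a_sustained_gain * params.a_minus_c
    else:
        sustained = params.sustained_gain

    lat, dec, cd = params.phasic_latency, params.phasic_decay, spec.cue_duration

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        m = np.zeros_like(t)
        for e, a in transients:
            u = t - e - lat
            with np.errstate(over="ignore"):
                m += np.where(u >= 0, a * np.exp(-np.clip(u, 0, None) / dec), 0.0)
        if sustained:
            m += sustained * ((t >= onset) & (t < onset + cd))
        return m

    max_extra = sum(max(a, 0.0) for _, a in transients) + max(sustained, 0.0)
    return fn, max_extra


def rate_template(params: ArchetypeParams, cue_id: str, session_id: int, spec: TaskSpec):
    """Firing-rate function (Hz) over a single-cue trial.

    The cue starts at ``spec.pre_cue_window``; rewards are included for
    cue B in any phase after preconditioning.  The returned callable is
    vectorized over trial time and rectified at zero.
    """
    onset = spec.pre_cue_window
    rewards: list[float] = []
    if cue_id == "B" and spec.phase_of(session_id) != "preconditioning":
        rewards = [onset + rt for rt in spec.reward_times_in_b]
    fn, _ = _cue_component(params, cue_id, session_id, spec, onset, rewards)

    def rate(t):
        t = np.asarray(t, float)
        return np.maximum(params.baseline_rate + fn(t), 0.0)

    return rate


@dataclass(frozen=True)
class PopulationSpec:
    """Composition and coding statistics of a simulated population.

    Default archetype counts mirror a ~100-unit probe-session yield
    (52 phasic, 39 sustained-excited, 11 sustained-inhibited).  Coding
    strengths (b_minus_d, a_minus_c) are bivariate normal with
    correlation ``rho``; ``rho = 0`` gives the null population used for
    calibration tests.
    """

    n_phasic: int = 52
    n_sustained_excited: int = 39
    n_sustained_inhibited: int = 11
    seed: int = 0
    rho: float = 0.6
    coding_mean: tuple[float, float] = (0.5, 0.5)
    coding_sd: tuple[float, float] = (0.8, 0.8)
    trajectory_slope: float = 1.0
    wide_fraction_phasic: float = 0.08
    archetype_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (-1.0 <= self.rho <= 1.0):
            raise ConfigError("rho must lie in [-1, 1]")
        for n in (self.n_phasic, self.n_sustained_excited, self.n_sustained_inhibited):
            if n < 0:
                raise ConfigError("archetype counts must be non-negative")
        if self.n_total == 0:
            raise ConfigError("population is empty")
        if any(sd < 0 for sd in self.coding_sd):
            raise ConfigError("coding_sd must be non-negative")
        if not (0 <= self.wide_fraction_phasic <= 1):
            raise ConfigError("wide_fraction_phasic must lie in [0, 1]")
        for key in self.archetype_overrides:
            if key not in ARCHETYPES:
                raise UnknownArchetypeError(f"override for unknown archetype {key!r}")

    @property
    def n_total(self) -> int:
        return self.n_phasic + self.n_sustained_excited + self.n_sustained_inhibited

    @property
    def counts(self) -> dict[str, int]:
        return {
            "phasic": self.n_phasic,
            "sustained_excited": self.n_sustained_excited,
            "sustained_inhibited": self.n_sustained_inhibited,
        }


def draw_population(pop: PopulationSpec):
    """Draw per-neuron parameters, ground truth, and waveform features.

    Returns ``(params_list, truth, waveforms)`` where ``truth`` records
    neuron_id, archetype, coding strengths, and the wide-waveform flag.
    Deterministic in ``pop.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(pop.seed), 0]))
    n = pop.n_total
    s1, s2 = pop.coding_sd
    cov = [[s1 ** 2, pop.rho * s1 * s2], [pop.rho * s1 * s2, s2 ** 2]]
    coding = rng.multivariate_normal(pop.coding_mean, cov, size=n)

    params_list: list[ArchetypeParams] = []
    truth_rows, wf_rows = [], []
    nid = 0
    for arch in ARCHETYPES:
        base = dict(ARCHETYPE_DEFAULTS[arch])
        base.update(pop.archetype_overrides.get(arch, {}))
        for _ in range(pop.counts[arch]):
            p = ArchetypeParams(
                archetype=arch,
                b_minus_d=float(coding[nid, 0]),
                a_minus_c=float(coding[nid, 1]),
                trajectory_slope=pop.trajectory_slope,
                **base,
            )
            params_list.append(p)

            wide = bool(arch == "phasic" and rng.random() < pop.wide_fraction_phasic)
            if wide:
                hw = rng.normal(560.0, 30.0)
                max_pos = rng.uniform(0.2, 0.6)
            else:
                hw = max(rng.normal(260.0, 40.0), 50.0)
                max_pos = rng.uniform(-0.2, 0.2)
            min_neg = -rng.uniform(0.8, 1.5)
            wf_rows.append((nid, hw, max_pos, min_neg))
            truth_rows.append((nid, arch, p.b_minus_d, p.a_minus_c, wide))
            nid += 1

    truth = pd.DataFrame(
        truth_rows, columns=["neuron_id", "archetype", "b_minus_d", "a_minus_c", "wide_waveform"]
    )
    waveforms = pd.DataFrame(
        wf_rows,
        columns=["neuron_id", "negative_half_width", "max_positive_deflection",
                 "min_negative_deflection"],
    )
    return params_list, truth, waveforms


def sample_inhomogeneous_poisson(rate, duration: float, lam_max: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """One realization of an inhomogeneous Poisson process by thinning.

    ``rate`` maps times in [0, duration) to intensities bounded by
    ``lam_max``; returns sorted event times.
    """
    if lam_max <= 0:
        raise ConfigError("lam_max must be positive")
    n_cand = rng.poisson(lam_max * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n_cand))
    keep = rng.uniform(0.0, lam_max, size=n_cand) < rate(times)
    return times[keep]


@dataclass
class SimulationResult:
    spikes: pd.DataFrame
    events: pd.DataFrame
    waveforms: pd.DataFrame
    truth: pd.DataFrame


def _trial_rate(params: ArchetypeParams, rows: pd.DataFrame, spec: TaskSpec):
    comps, lam = [], params.baseline_rate
    for row in rows.itertuples():
        fn, extra = _cue_component(params, row.cue_id, int(row.session_id), spec,
                                   float(row.cue_on), list(row.reward_times))
        comps.append(fn)
        lam += extra

    def rate(t):
        t = np.asarray(t, float)
        r = np.full(t.shape, params.baseline_rate)
        for fn in comps:
            r = r + fn(t)
        return np.maximum(r, 0.0)

    return rate, lam


def simulate_population(pop: PopulationSpec, spec: TaskSpec,
                        phases: tuple[str, ...] | None = None) -> SimulationResult:
    """Inhomogeneous-Poisson spike trains for a whole population.

    Spikes are drawn per neuron-trial by thinning a homogeneous Poisson
    process at the rate template's upper bound.  ``phases`` restricts
    simulation to a subset of task phases (the events table is filtered
    accordingly).  Identical ``(pop, spec, phases)`` with the same seed
    reproduce byte-identical output.
    """
    events = trial_table(spec)
    if phases is not None:
        events = events[events.phase.isin(phases)].reset_index(drop=True)
        if events.empty:
            raise ConfigError(f"no trials in phases {phases!r}")
    params_list, truth, waveforms = draw_population(pop)

    rng = np.random.default_rng(np.random.SeedSequence([int(pop.seed), 1]))
    # Trials sharing a session and cue layout share one rate template per
    # neuron; cache on that structure to avoid rebuilding closures.
    trial_groups = []
    for (sess, trial), grp in events.groupby(["session_id", "trial"], sort=True):
        struct = (int(sess), tuple(
            (row.cue_id, float(row.cue_on), tuple(row.reward_times))
            for row in grp.itertuples()))
        trial_groups.append((int(sess), int(trial), grp.phase.iloc[0],
                             float(grp.trial_duration.iloc[0]), struct, grp))

    nid_out, sess_out, phase_out, trial_out, time_out = [], [], [], [], []
    for nid, params in enumerate(params_list):
        cache: dict = {}
        for sess, trial, phase, T, struct, grp in trial_groups:
            if struct not in cache:
                cache[struct] = _trial_rate(params, grp, spec)
            rate, lam = cache[struct]
            if lam <= 0:
                raise ConfigError(
                    f"non-positive maximal rate for neuron {nid} in trial ({sess}, {trial})"
                )
            st = sample_inhomogeneous_poisson(rate, T, lam, rng)
            if st.size:
                nid_out.append(np.full(st.size, nid))
                sess_out.append(np.full(st.size, sess))
                trial_out.append(np.full(st.size, trial))
                phase_out.append(np.full(st.size, phase, dtype=object))
                time_out.append(st)

    if nid_out:
        spikes = pd.DataFrame({
            "neuron_id": np.concatenate(nid_out).astype(np.int64),
            "session_id": np.concatenate(sess_out).astype(np.int64),
            "phase": np.concatenate(phase_out),
            "trial": np.concatenate(trial_out).astype(np.int64),
            "spike_time": np.concatenate(time_out),
        })
    else:
        spikes = pd.DataFrame({
            "neuron_id": pd.Series(dtype=np.int64),
            "session_id": pd.Series(dtype=np.int64),
            "phase": pd.Series(dtype=object),
            "trial": pd.Series(dtype=np.int64),
            "spike_time": pd.Series(dtype=float),
        })
    return SimulationResult(spikes=spikes, events=events[EVENT_COLUMNS],
                            waveforms=waveforms, truth=truth)


# ---------------------------------------------------------------------------
# Behavior


@dataclass(frozen=True)
class BehaviorParams:
    """Food-cup occupancy model.

    Means are occupancy probabilities in [0, 1]: a common low base rate
    for all cues, a ceiling that B approaches linearly across
    conditioning, and a probe-test level for A reached in proportion to
    ``transfer`` (0 disables preconditioning transfer entirely).
    ``concentration`` is the Beta concentration of trial-to-trial noise.
    """

    base_occupancy: float = 0.05
    max_b_occupancy: float = 0.65
    probe_a_occupancy: float = 0.30
    transfer: float = 1.0
    concentration: float = 8.0

    def __post_init__(self):
        for name in ("base_occupancy", "max_b_occupancy", "probe_a_occupancy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.transfer <= 1.0):
            raise ConfigError("transfer must lie in [0, 1]")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")


def expected_occupancy(params: BehaviorParams, spec: TaskSpec,
                       phase: str, cue_id: str, session_id: int) -> float:
    """Mean occupancy probability for a cue presentation."""
    if cue_id not in CUES:
        raise UnknownCueError(f"unknown cue {cue_id!r}")
    p0 = params.base_occupancy
    if phase == "preconditioning":
        return p0
    if phase == "conditioning":
        if cue_id == "B":
            idx = spec.conditioning_index(session_id)
            return p0 + (params.max_b_occupancy - p0) * idx / spec.n_conditioning_sessions
        return p0
    # probe
    if cue_id == "B":
        return params.max_b_occupancy
    if cue_id == "A":
        return p0 + params.transfer * (params.probe_a_occupancy - p0)
    return p0


def simulate_behavior(spec: TaskSpec, params: BehaviorParams, seed: int) -> pd.DataFrame:
    """Per-trial occupancy fractions (percent of cue time) for one subject."""
    events = trial_table(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    k = params.concentration
    rows = []
    for row in events.itertuples():
        p = expected_occupancy(params, spec, row.phase, row.cue_id, int(row.session_id))
        if p <= 0.0:
            x = 0.0
        elif p >= 1.0:
            x = 1.0
        else:
            x = rng.beta(p * k, (1.0 - p) * k)
        rows.append((row.session_id, row.phase, row.trial, row.cue_id, 100.0 * x))
    return pd.DataFrame(
        rows, columns=["session_id", "phase", "trial", "cue_id", "occupancy_fraction"]
    )


def simulate_cohort(spec: TaskSpec, params: BehaviorParams, seed: int, n_rats: int) -> pd.DataFrame:
    """Stacked behavior tables for several subjects (adds a ``rat`` column).

    The extra column is analysis-side only; the on-disk behavior schema
    stays per-subject.
    """
    frames = []
    for r in range(n_rats):
        df = simulate_behavior(spec, params, seed * 100_003 + r)
        df.insert(0, "rat", r)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def null_population(pop: PopulationSpec) -> PopulationSpec:
    """Copy of a population spec with uncorrelated coding strengths."""
    return replace(pop, rho=0.0)
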