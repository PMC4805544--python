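"""Error-signal and behavioral statistics on labeled populations.

Core quantities:

* the per-neuron, per-session difference between cue-onset and
  reward-evoked auROC (first 500 ms of each period) for the reward cue,
  and its correlation with session index across conditioning — the
  "peak migration" signature of a temporal-difference error signal;
* per-neuron probe-test contrasts between cue pairs (B−D for cached
  value, A−C for inferred value) over the first second of the cue
  response, in baseline-subtracted firing rate (Hz) by default or as
  auROC window means, with paired t tests;
* the across-neuron Pearson correlation between the cached-value and
  inferred-value contrasts;
* the same contrasts over the sustained window (final 9 s of the cue);
* food-cup occupancy summaries and factorial ANOVAs per task phase.

All inferential statistics are standard (scipy / statsmodels); no
multiple-comparison correction is applied, and alpha defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .auroc import AnalysisConfig, _select_events, _spike_index, auroc_matrix, bin_counts
from .errors import (
    BehaviorDesignError,
    ConfigError,
    MissingRewardError,
    SampleSizeError,
    ZeroVarianceError,
)


# ---------------------------------------------------------------------------
# Peak migration (conditioning)


def onset_reward_difference(spikes: pd.DataFrame, events: pd.DataFrame,
                            config: AnalysisConfig, *, sessions=None,
                            neurons=None) -> pd.DataFrame:
    """Per neuron-session difference: onset auROC minus reward auROC.

    Both terms are means over the first ``config.onset_window`` (500 ms)
    of their period for cue B; the reward period is anchored at the
    first reward delivery within the cue.  Returns columns neuron_id,
    session_id, session_index (1-based within the supplied sessions,
    ordered), and diff.
    """
    if sessions is None:
        sessions = sorted(events.loc[events.phase == "conditioning", "session_id"].unique())
    sessions = list(sessions)
    if not sessions:
        raise ConfigError("no sessions supplied")
    frames = []
    for si, sess in enumerate(sorted(sessions), start=1):
        ev = _select_events(events, "B", [sess])
        rel_rewards = [
            [rt - row.cue_on for rt in row.reward_times] for row in ev.itertuples()
        ]
        if any(len(r) == 0 for r in rel_rewards):
            raise MissingRewardError(f"session {sess} has unrewarded B trials")
        first = rel_rewards[0][0]
        if any(abs(r[0] - first) > 1e-9 for r in rel_rewards):
            raise MissingRewardError(f"session {sess}: first-reward latency varies across trials")
        win = (0.0, first + config.onset_window)
        m = auroc_matrix(spikes, events, "B", config, sessions=[sess],
                         neurons=neurons, window=win)
        onset = m.window_mean((0.0, config.onset_window))
        reward = m.window_mean((first, first + config.onset_window))
        frames.append(pd.DataFrame({
            "neuron_id": m.neuron_ids,
            "session_id": sess,
            "session_index": si,
            "diff": onset - reward,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class CorrelationResult:
    r: float
    n: int
    df: int
    p: float


def migration_correlation(diffs: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of onset-minus-reward difference with session index."""
    x = diffs["session_index"].to_numpy(float)
    y = diffs["diff"].to_numpy(float)
    if len(x) < 3:
        raise SampleSizeError("need at least 3 neuron-session points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), df=len(x) - 2, p=float(p))


# ---------------------------------------------------------------------------
# Probe contrasts


@dataclass
class ContrastResult:
    cue_pos: str
    cue_neg: str
    window: tuple[float, float]
    measure: str
    per_neuron: pd.DataFrame   # neuron_id, pos, neg, diff
    mean_diff: float
    t: float
    df: int
    p: float


def _paired_t(diffs: np.ndarray) -> tuple[float, int, float]:
    n = diffs.size
    if n < 2:
        raise SampleSizeError("paired t test needs at least 2 units")
    sd = diffs.std(ddof=1)
    if sd == 0:
        if diffs.mean() == 0:
            return 0.0, n - 1, 1.0
        raise ZeroVarianceError("all per-neuron differences identical and non-zero")
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(t), n - 1, float(p)


def _rate_responses(spikes, events, config, cue_id, window, sessions, neurons, index):
    """Per-neuron mean baseline-subtracted firing rate (Hz) in a cue window."""
    ev = _select_events(events, cue_id, sessions)
    span = window[1] - window[0]
    bspan = config.baseline_window[1] - config.baseline_window[0]
    out = np.empty(len(neurons))
    for i, nid in enumerate(neurons):
        aligned = [
            np.asarray(index.get((nid, row.session_id, row.trial), np.empty(0)), float)
            - row.cue_on
            for row in ev.itertuples()
        ]
        resp = bin_counts(aligned, window, config.bin_width).sum(axis=1) / span
        base = bin_counts(aligned, config.baseline_window, config.bin_width).sum(axis=1) / bspan
        out[i] = float(np.mean(resp - base))
    return out


def cue_contrast(spikes: pd.DataFrame, events: pd.DataFrame, config: AnalysisConfig,
                 cue_pos: str, cue_neg: str, *, window: tuple[float, float] | None = None,
                 sessions=None, neurons=None, measure: str = "rate") -> ContrastResult:
    """Per-neuron response difference between two cues plus a paired t test.

    ``measure="rate"`` (default) uses baseline-subtracted trial firing
    rates; ``measure="auroc"`` uses window means of each cue's auROC
    trace.  ``window`` defaults to the first ``cue_response_window``
    second(s) of the cue.
    """
    if measure not in ("rate", "auroc"):
        raise ConfigError(f"unknown measure {measure!r}")
    window = window if window is not None else (0.0, config.cue_response_window)
    if sessions is None:
        sessions = sorted(events.loc[events.phase == "probe", "session_id"].unique())
    if neurons is None:
        neurons = np.sort(spikes.neuron_id.unique())
    neurons = np.asarray(neurons)
    if neurons.size < 2:
        raise SampleSizeError("contrast needs at least 2 neurons")

    if measure == "rate":
        index = _spike_index(spikes[spikes.neuron_id.isin(neurons)])
        pos = _rate_responses(spikes, events, config, cue_pos, window, sessions, neurons, index)
        neg = _rate_responses(spikes, events, config, cue_neg, window, sessions, neurons, index)
    else:
        mp = auroc_matrix(spikes, events, cue_pos, config, sessions=sessions,
                          neurons=neurons, window=None)
        mn = auroc_matrix(spikes, events, cue_neg, config, sessions=sessions,
                          neurons=neurons, window=None)
        pos = mp.window_mean(window)
        neg = mn.window_mean(window)

    diffs = pos - neg
    t, dof, p = _paired_t(diffs)
    per = pd.DataFrame({"neuron_id": neurons, "pos": pos, "neg": neg, "diff": diffs})
    return ContrastResult(cue_pos=cue_pos, cue_neg=cue_neg, window=tuple(window),
                          measure=measure, per_neuron=per, mean_diff=float(diffs.mean()),
                          t=t, df=dof, p=p)


def phasic_contrast(spikes, events, config, cue_pos, cue_neg, **kw) -> ContrastResult:
    """First-second cue contrast (cached or inferred value signal)."""
    kw.setdefault("window", (0.0, config.cue_response_window))
    return cue_contrast(spikes, events, config, cue_pos, cue_neg, **kw)


def sustained_contrast(spikes, events, config, cue_pos, cue_neg, **kw) -> ContrastResult:
    """Cue contrast over the sustained window (final 9 s of the cue)."""
    kw.setdefault("window", config.sustained_window)
    return cue_contrast(spikes, events, config, cue_pos, cue_neg, **kw)


def inferred_vs_cached_correlation(cached: ContrastResult,
                                   inferred: ContrastResult) -> CorrelationResult:
    """Across-neuron Pearson r between B−D and A−C contrasts (df = n − 2)."""
    merged = cached.per_neuron.merge(inferred.per_neuron, on="neuron_id",
                                     suffixes=("_cached", "_inferred"))
    x = merged["diff_cached"].to_numpy(float)
    y = merged["diff_inferred"].to_numpy(float)
    if len(x) < 3:
        raise SampleSizeError("correlation needs at least 3 shared neurons")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("correlation undefined: a contrast has zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=len(x), df=len(x) - 2, p=float(p))


# ---------------------------------------------------------------------------
# Behavior


@dataclass
class BehaviorStats:
    phase: str
    means: pd.DataFrame     # per cue (× time factor) occupancy means
    anova: pd.DataFrame     # effect, F, df_num, df_den, p
    degenerate: bool


def behavior_stats(behavior: pd.DataFrame, phase: str, alpha: float = 0.05) -> BehaviorStats:
    """Occupancy means and factorial F tests for one task phase.

    Preconditioning: one-way ANOVA across the four cues.  Conditioning:
    cue × session with interaction.  Probe: cue × presentation-order
    (additive when a single subject leaves no residual df for the
    interaction).  Reporting plumbing over standard linear models.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = behavior[behavior.phase == phase].copy()
    if sub.empty:
        raise ConfigError(f"no behavior rows for phase {phase!r}")
    if sub.cue_id.nunique() < 2:
        raise ConfigError("behavior ANOVA needs at least 2 cues")

    if phase == "probe":
        sub = sub[sub.cue_id.isin(["A", "C"])].copy()
        if sub.empty or sub.cue_id.nunique() < 2:
            raise ConfigError("probe ANOVA needs both test cues A and C")
        sub["slot"] = sub.groupby(["cue_id"] + (["rat"] if "rat" in sub else []))[
            "trial"].rank(method="first").astype(int)
        time_factor = "slot"
    elif phase == "conditioning":
        time_factor = "session_id"
    else:
        time_factor = None

    if time_factor is not None:
        cells = sub.groupby(["cue_id", time_factor], observed=True).size()
        full = pd.MultiIndex.from_product(
            [sorted(sub.cue_id.unique()), sorted(sub[time_factor].unique())])
        empty = [c for c in full if c not in cells.index]
        if empty:
            raise BehaviorDesignError(f"empty design cells: {empty}", cells=empty)
        means = sub.groupby(["cue_id", time_factor], observed=True)[
            "occupancy_fraction"].mean().reset_index()
    else:
        means = sub.groupby("cue_id")["occupancy_fraction"].mean().reset_index()

    degenerate = False
    if np.ptp(sub.occupancy_fraction.to_numpy()) == 0:
        degenerate = True
        anova = pd.DataFrame(columns=["effect", "F", "df_num", "df_den", "p"])
        return BehaviorStats(phase=phase, means=means, anova=anova, degenerate=True)

    if time_factor is None:
        formula = "occupancy_fraction ~ C(cue_id)"
    else:
        n_cells = sub.groupby(["cue_id", time_factor], observed=True).ngroups
        interaction_ok = len(sub) > n_cells
        op = "*" if interaction_ok else "+"
        formula = f"occupancy_fraction ~ C(cue_id) {op} C({time_factor})"

    model = smf.ols(formula, data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = float(table.loc["Residual", "df"])
    rows = []
    for eff in table.index:
        if eff == "Residual":
            continue
        rows.append({
            "effect": eff.replace("C(", "").replace(")", ""),
            "F": float(table.loc[eff, "F"]),
            "df_num": float(table.loc[eff, "df"]),
            "df_den": df_den,
            "p": float(table.loc[eff, "PR(>F)"]),
        })
    anova = pd.DataFrame(rows)
    if df_den <= 0 or anova["F"].isna().any():
        degenerate = True
    return BehaviorStats(phase=phase, means=means, anova=anova, degenerate=degenerate)
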