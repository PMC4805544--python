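"""Baseline-referenced ROC normalization of firing rates.

Each neuron's response is expressed, bin by bin, as the area under an
ROC curve that discriminates the distribution of spike counts in a
post-onset test bin (pooled across trials of a cue at a fixed latency)
from the distribution of baseline-bin counts (pooled across all baseline
bins of all trials of that cue).  The statistic lives in [0, 1]:
0.5 means no change from baseline, above 0.5 excitation, below 0.5
inhibition.

Procedure for one bin: jointly min–max normalize the pooled test and
baseline counts to [0, 1]; slide a discrimination threshold from 0 to 1
in steps of ``threshold_step`` (0.01 by default); at each threshold the
hit rate is the fraction of test bins strictly above it and the
false-alarm rate the fraction of baseline bins strictly above it; close
the curve with (0, 0) and (1, 1) and integrate trapezoidally.  When the
two count multisets induce identical curves the area is the diagonal's,
exactly 0.5, and is returned as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyCountsError, NoTrialsError, WindowError


@dataclass(frozen=True)
class AnalysisConfig:
    """Bin widths, windows (seconds, cue-onset-aligned) and alpha level.

    Defaults: 100-ms bins, threshold step 0.01, baseline the 1 s
    immediately preceding cue onset, 500-ms onset/reward comparison
    windows, 1-s cue-response window, sustained window the final 9 s of
    the 10-s cue, alpha 0.05.
    """

    bin_width: float = 0.1
    threshold_step: float = 0.01
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    onset_window: float = 0.5
    cue_response_window: float = 1.0
    sustained_window: tuple[float, float] = (1.0, 10.0)
    matrix_window: tuple[float, float] = (0.0, 10.0)
    alpha: float = 0.05

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if not (0 < self.threshold_step <= 1):
            raise ConfigError("threshold_step must lie in (0, 1]")
        if abs(round(1.0 / self.threshold_step) * self.threshold_step - 1.0) > 1e-9:
            raise ConfigError("threshold_step must divide 1 evenly")
        for name in ("baseline_window", "sustained_window", "matrix_window"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ConfigError(f"{name} is empty")
            self._check_divisible(hi - lo, name)
        self._check_divisible(self.onset_window, "onset_window")
        self._check_divisible(self.cue_response_window, "cue_response_window")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")

    def _check_divisible(self, span: float, name: str) -> None:
        n = span / self.bin_width
        if abs(n - round(n)) > 1e-6 or round(n) < 1:
            raise ConfigError(f"bin_width must divide {name} (span {span})")


def bin_counts(spike_times_per_trial, window: tuple[float, float],
               bin_width: float) -> np.ndarray:
    """Per-trial, per-bin spike counts on a half-open uniform grid.

    ``spike_times_per_trial`` is a sequence of per-trial spike-time
    arrays already aligned to the window's reference (e.g. cue onset).
    Bins are half-open ``[left, right)``: a spike exactly on a boundary
    belongs to the later bin.
    """
    w0, w1 = window
    nb = round((w1 - w0) / bin_width)
    if nb < 1 or abs(nb * bin_width - (w1 - w0)) > 1e-9:
        raise WindowError(f"bin_width {bin_width} does not tile window {window}")
    out = np.zeros((len(spike_times_per_trial), nb), dtype=np.int64)
    for i, st in enumerate(spike_times_per_trial):
        st = np.asarray(st, float)
        st = st[(st >= w0) & (st < w1)]
        if st.size:
            idx = np.floor((st - w0) / bin_width).astype(np.int64)
            np.clip(idx, 0, nb - 1, out=idx)
            np.add.at(out[i], idx, 1)
    return out


def _thresholds(threshold_step: float) -> np.ndarray:
    n = round(1.0 / threshold_step)
    return np.arange(n + 1) / n


def auroc_bin(test_counts, baseline_counts, threshold_step: float = 0.01) -> float:
    """ROC area for one test-bin count multiset against baseline counts.

    Exactly 0.5 when the induced hit and false-alarm curves coincide
    (in particular for identical multisets, or when all pooled counts
    are equal).
    """
    t = np.asarray(test_counts, float).ravel()
    b = np.asarray(baseline_counts, float).ravel()
    if t.size == 0 or b.size == 0:
        raise EmptyCountsError("test and baseline count collections must be non-empty")
    mn = min(t.min(), b.min())
    mx = max(t.max(), b.max())
    if mx == mn:
        return 0.5
    tn = (t - mn) / (mx - mn)
    bn = (b - mn) / (mx - mn)
    thr = _thresholds(threshold_step)
    hits = (tn[None, :] > thr[:, None]).mean(axis=1)
    fas = (bn[None, :] > thr[:, None]).mean(axis=1)
    if np.array_equal(hits, fas):
        return 0.5
    # Threshold descending gives monotone non-decreasing (FA, hit) points.
    x = np.concatenate(([0.0], fas[::-1], [1.0]))
    y = np.concatenate(([0.0], hits[::-1], [1.0]))
    return float(np.trapezoid(y, x))


@dataclass
class AUROCMatrix:
    """Neuron × time-bin matrix of auROC values in [0, 1]."""

    values: np.ndarray
    neuron_ids: np.ndarray
    bin_centers: np.ndarray
    cue_id: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{c:.3f}" for c in self.bin_centers])
        df.insert(0, "neuron_id", self.neuron_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cue_id: str = "") -> "AUROCMatrix":
        nid = df["neuron_id"].to_numpy()
        cols = [c for c in df.columns if c != "neuron_id"]
        return cls(values=df[cols].to_numpy(float), neuron_ids=nid,
                   bin_centers=np.array([float(c) for c in cols]), cue_id=cue_id)

    def window_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Per-neuron mean auROC over bins whose centers fall in [lo, hi)."""
        lo, hi = window
        mask = (self.bin_centers >= lo) & (self.bin_centers < hi)
        if not mask.any():
            raise WindowError(f"no bins inside window {window}")
        return self.values[:, mask].mean(axis=1)


def _spike_index(spikes: pd.DataFrame) -> dict:
    """dict[(neuron, session, trial)] -> sorted spike-time array."""
    out: dict = {}
    for key, grp in spikes.groupby(["neuron_id", "session_id", "trial"], sort=False):
        out[key] = grp.spike_time.to_numpy()
    return out


def _select_events(events: pd.DataFrame, cue_id: str, sessions=None) -> pd.DataFrame:
    ev = events[events.cue_id == cue_id]
    if sessions is not None:
        ev = ev[ev.session_id.isin(list(sessions))]
    if ev.empty:
        raise NoTrialsError(f"no trials for cue {cue_id!r} in sessions {sessions!r}")
    return ev.reset_index(drop=True)


def aligned_spike_trains(spikes: pd.DataFrame, events: pd.DataFrame, neuron_id: int,
                         cue_id: str, sessions=None, index: dict | None = None) -> list[np.ndarray]:
    """Per-trial spike times re-aligned to cue onset for one neuron."""
    ev = _select_events(events, cue_id, sessions)
    if index is None:
        sub = spikes[spikes.neuron_id == neuron_id]
        index = _spike_index(sub)
    out = []
    for row in ev.itertuples():
        st = index.get((neuron_id, row.session_id, row.trial), np.empty(0))
        out.append(np.asarray(st, float) - row.cue_on)
    return out


def _check_window_span(ev: pd.DataFrame, window: tuple[float, float]) -> None:
    lo = (ev.cue_on + window[0]).min()
    hi = (ev.cue_on + window[1] - ev.trial_duration).max()
    if lo < -1e-9 or hi > 1e-9:
        raise WindowError(f"window {window} falls outside the recorded trial span")


def auroc_matrix(spikes: pd.DataFrame, events: pd.DataFrame, cue_id: str,
                 config: AnalysisConfig, *, sessions=None, neurons=None,
                 window: tuple[float, float] | None = None) -> AUROCMatrix:
    """auROC trace for every neuron, test bins pooled across trials of a cue.

    For each post-onset latency bin, the test counts are that bin's
    counts on every trial of ``cue_id``; the baseline counts are pooled
    over all baseline-window bins of all those trials.
    """
    window = window if window is not None else config.matrix_window
    ev = _select_events(events, cue_id, sessions)
    _check_window_span(ev, window)
    _check_window_span(ev, config.baseline_window)

    if neurons is None:
        neurons = np.sort(spikes.neuron_id.unique())
    neurons = np.asarray(neurons)
    pool = spikes[spikes.neuron_id.isin(neurons)]
    index = _spike_index(pool)

    nb = round((window[1] - window[0]) / config.bin_width)
    values = np.empty((len(neurons), nb))
    for i, nid in enumerate(neurons):
        aligned = [
            np.asarray(index.get((nid, row.session_id, row.trial), np.empty(0)), float)
            - row.cue_on
            for row in ev.itertuples()
        ]
        test = bin_counts(aligned, window, config.bin_width)
        base = bin_counts(aligned, config.baseline_window, config.bin_width).ravel()
        for j in range(nb):
            values[i, j] = auroc_bin(test[:, j], base, config.threshold_step)

    centers = window[0] + (np.arange(nb) + 0.5) * config.bin_width
    return AUROCMatrix(values=values, neuron_ids=neurons, bin_centers=centers, cue_id=cue_id)
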