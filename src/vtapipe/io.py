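"""Plain-text dataset container and validation.

A dataset is four CSV files in one directory:

* ``spikes.csv``    — neuron_id, session_id, phase, trial, spike_time
* ``events.csv``    — session_id, phase, trial, cue_id, cue_on, cue_off,
  reward_times (semicolon-joined seconds, empty if none), trial_duration
* ``waveforms.csv`` — neuron_id, negative_half_width (µs),
  max_positive_deflection, min_negative_deflection (signed, arbitrary V)
* ``behavior.csv``  — session_id, phase, trial, cue_id, occupancy_fraction (%)

All times are seconds from trial start; trial windows are half-open
``[0, trial_duration)``.  ``read_dataset`` validates every invariant and
cross-reference and raises :class:`DatasetValidationError` naming the
file and 0-based data row of the first violation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DatasetValidationError
from .task import CUES

SPIKES_COLUMNS = ["neuron_id", "session_id", "phase", "trial", "spike_time"]
EVENTS_COLUMNS = ["session_id", "phase", "trial", "cue_id", "cue_on", "cue_off",
                  "reward_times", "trial_duration"]
WAVEFORMS_COLUMNS = ["neuron_id", "negative_half_width", "max_positive_deflection",
                     "min_negative_deflection"]
BEHAVIOR_COLUMNS = ["session_id", "phase", "trial", "cue_id", "occupancy_fraction"]

_FILES = {
    "spikes": ("spikes.csv", SPIKES_COLUMNS),
    "events": ("events.csv", EVENTS_COLUMNS),
    "waveforms": ("waveforms.csv", WAVEFORMS_COLUMNS),
    "behavior": ("behavior.csv", BEHAVIOR_COLUMNS),
}


@dataclass
class Dataset:
    """In-memory bundle of the four tables (pandas DataFrames)."""

    spikes: pd.DataFrame
    events: pd.DataFrame
    waveforms: pd.DataFrame
    behavior: pd.DataFrame

    @classmethod
    def empty(cls) -> "Dataset":
        return cls(
            spikes=pd.DataFrame(columns=SPIKES_COLUMNS),
            events=pd.DataFrame(columns=EVENTS_COLUMNS),
            waveforms=pd.DataFrame(columns=WAVEFORMS_COLUMNS),
            behavior=pd.DataFrame(columns=BEHAVIOR_COLUMNS),
        )

    def validate(self) -> "Dataset":
        validate_dataset(self)
        return self


def _serialize_rewards(rt) -> str:
    return ";".join(repr(float(x)) for x in rt)


def _parse_rewards(s) -> list[float]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return []
    return [float(x) for x in str(s).split(";")]


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write the four CSVs; stable column order, bit-stable under fixed input."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    events = ds.events.copy()
    if len(events):
        events["reward_times"] = events["reward_times"].map(_serialize_rewards)
    for name, (fname, cols) in _FILES.items():
        df = events if name == "events" else getattr(ds, name)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DatasetValidationError(f"missing column(s) {missing}", file=fname)
        df[cols].to_csv(path / fname, index=False, lineterminator="\n")


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a dataset directory."""
    path = Path(path)
    frames = {}
    dtypes = {
        "neuron_id": np.int64, "session_id": np.int64, "trial": np.int64,
        "phase": str, "cue_id": str,
    }
    for name, (fname, cols) in _FILES.items():
        fp = path / fname
        if not fp.exists():
            raise DatasetValidationError("file not found", file=fname)
        df = pd.read_csv(fp, dtype={c: dtypes[c] for c in cols if c in dtypes},
                         keep_default_na=False if name == "events" else True)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise DatasetValidationError(f"missing column(s) {missing}", file=fname)
        frames[name] = df[cols]
    events = frames["events"]
    events = events.assign(reward_times=events["reward_times"].map(_parse_rewards))
    ds = Dataset(spikes=frames["spikes"], events=events,
                 waveforms=frames["waveforms"], behavior=frames["behavior"])
    validate_dataset(ds)
    return ds


def _first_bad(mask: pd.Series) -> int:
    return int(np.flatnonzero(np.asarray(mask))[0])


def validate_dataset(ds: Dataset) -> None:
    """Check all per-table invariants and cross-references."""
    ev = ds.events.reset_index(drop=True)
    if len(ev):
        bad = ~ev.cue_id.isin(CUES)
        if bad.any():
            raise DatasetValidationError(
                f"invalid cue_id {ev.cue_id[bad].iloc[0]!r}", file="events.csv",
                row=_first_bad(bad))
        bad = ~(ev.cue_off > ev.cue_on)
        if bad.any():
            raise DatasetValidationError("cue_off must exceed cue_on", file="events.csv",
                                         row=_first_bad(bad))
        durs = (ev.cue_off - ev.cue_on).to_numpy()
        if np.ptp(durs) > 1e-9:
            bad = np.abs(durs - durs[0]) > 1e-9
            raise DatasetValidationError(
                "cue presentations have unequal durations", file="events.csv",
                row=int(np.flatnonzero(bad)[0]))
        for i, row in ev.iterrows():
            rts = row.reward_times
            if rts and row.cue_id != "B":
                raise DatasetValidationError(
                    f"reward on cue {row.cue_id!r}", file="events.csv", row=int(i))
            if rts and row.phase == "preconditioning":
                raise DatasetValidationError(
                    "reward during preconditioning", file="events.csv", row=int(i))
            for rt in rts:
                if not (row.cue_on <= rt < row.cue_off):
                    raise DatasetValidationError(
                        f"reward at {rt} s outside cue window", file="events.csv", row=int(i))
            if not (0 <= row.cue_on and row.cue_off <= row.trial_duration):
                raise DatasetValidationError(
                    "cue window outside trial span", file="events.csv", row=int(i))

    sp = ds.spikes.reset_index(drop=True)
    if len(sp):
        bad = sp.spike_time < 0
        if bad.any():
            raise DatasetValidationError("negative spike_time", file="spikes.csv",
                                         row=_first_bad(bad))
        if len(ev) == 0:
            raise DatasetValidationError("spikes present but events table is empty",
                                         file="spikes.csv", row=0)
        durations = ev.groupby(["session_id", "trial"]).trial_duration.max()
        key = pd.MultiIndex.from_frame(sp[["session_id", "trial"]])
        known = key.isin(durations.index)
        if not known.all():
            row = _first_bad(~pd.Series(known))
            raise DatasetValidationError(
                f"spike references unknown trial {tuple(sp.loc[row, ['session_id', 'trial']])}",
                file="spikes.csv", row=row)
        dur = durations.loc[key].to_numpy()
        bad = sp.spike_time.to_numpy() >= dur
        if bad.any():
            raise DatasetValidationError("spike_time beyond trial duration",
                                         file="spikes.csv", row=_first_bad(pd.Series(bad)))

    wf = ds.waveforms.reset_index(drop=True)
    if len(wf):
        bad = ~(wf.negative_half_width > 0)
        if bad.any():
            raise DatasetValidationError("negative_half_width must be positive",
                                         file="waveforms.csv", row=_first_bad(bad))

    bh = ds.behavior.reset_index(drop=True)
    if len(bh):
        bad = ~bh.occupancy_fraction.between(0.0, 100.0)
        if bad.any():
            raise DatasetValidationError("occupancy_fraction outside [0, 100]",
                                         file="behavior.csv", row=_first_bad(bad))


def dataset_equal(a: Dataset, b: Dataset) -> bool:
    """Content equality of two bundles (ignoring pandas index labels)."""
    for f in fields(Dataset):
        x = getattr(a, f.name).reset_index(drop=True)
        y = getattr(b, f.name).reset_index(drop=True)
        if f.name == "events":
            if list(x.columns) != list(y.columns) or len(x) != len(y):
                return False
            rx = x.reward_times.map(tuple)
            ry = y.reward_times.map(tuple)
            if not rx.equals(ry):
                return False
            x = x.drop(columns="reward_times")
            y = y.drop(columns="reward_times")
        try:
            pd.testing.assert_frame_equal(x, y, check_dtype=False)
        except AssertionError:
            return False
    return True
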