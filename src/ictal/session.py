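"""Session data model, bundle IO, and epoch derivation.

A *session* is one head-fixed recording: continuous signals (LFP, MUA,
photometry, wheel encoder), event series (sounds, licks), and a seizure or
sham annotation.  All times are seconds on a single session clock starting
at recording onset; every interval in the package is half-open ``[start,
end)`` and sample selection is by sample-time membership.

Analysis epochs follow the study design: a 60 s baseline immediately before
electrical stimulation, an ictal period from the end of the 2 s stimulus
train to the latest per-channel seizure end, a fixed 30 s early-postictal
period, and a 60 s late-postictal period.  Seizures shorter than 5 s are
excluded from analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousSignal",
    "EventSeries",
    "SeizureAnnotation",
    "EpochSet",
    "Session",
    "load_session",
    "write_session",
    "derive_epochs",
    "slice_signal",
    "IctalError",
    "ValidationError",
    "IntegrityError",
    "LoadError",
    "ExcludedSeizure",
    "CoverageError",
    "EmptySliceError",
]

FORMAT_VERSION = 1

BASELINE_S = 60.0
EARLY_POSTICTAL_S = 30.0
LATE_POSTICTAL_S = 60.0
MIN_ICTAL_S = 5.0

# Numerical slack, in samples, when mapping interval edges to sample indices.
_EDGE_EPS = 1e-9


class IctalError(Exception):
    """Base class for package errors."""


class ValidationError(IctalError):
    """Invalid in-memory data (ordering, NaN/Inf, inconsistent fields)."""


class IntegrityError(IctalError):
    """Bundle contents disagree with their metadata declaration."""


class LoadError(IctalError):
    """A declared bundle file is missing or unreadable."""


class ExcludedSeizure(IctalError):
    """Seizure does not meet the 5 s minimum ictal duration."""


class CoverageError(IctalError):
    """Requested epoch extends outside the recorded span."""


class EmptySliceError(IctalError):
    """A signal slice contains no samples."""


@dataclass(frozen=True)
class ContinuousSignal:
    """A uniformly sampled trace.  Sample ``i`` occurs at ``t0_s + i/rate_hz``."""

    name: str
    samples: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate_hz <= 0:
            raise ValidationError(f"signal {self.name!r}: rate_hz must be > 0")
        if samples.ndim != 1 or samples.size == 0:
            raise ValidationError(f"signal {self.name!r}: samples must be a non-empty 1-d array")
        if not np.all(np.isfinite(samples)):
            raise ValidationError(f"signal {self.name!r}: NaN/Inf samples are not allowed")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def end_s(self) -> float:
        """Time just past the last sample (start of the first missing sample)."""
        return self.t0_s + self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz


@dataclass(frozen=True)
class EventSeries:
    """Named point events (e.g. ``sound``, ``lick``) at strictly increasing times."""

    name: str
    times_s: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=np.float64)
        object.__setattr__(self, "times_s", times)
        if times.ndim != 1:
            raise ValidationError(f"events {self.name!r}: times must be 1-d")
        if not np.all(np.isfinite(times)):
            raise ValidationError(f"events {self.name!r}: NaN/Inf times are not allowed")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError(f"events {self.name!r}: times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class SeizureAnnotation:
    """Stimulation bounds plus per-channel seizure end times (or sham duration).

    ``end_ipsi_s`` / ``end_contra_s`` mark the end of epileptiform activity on
    each hippocampal channel; the analysis ictal period runs to the latest one.
    Sham stimulations carry ``sham_duration_s`` instead (matched to a seizure's
    ictal duration in the study design).
    """

    stim_on_s: float
    stim_off_s: float
    end_ipsi_s: float | None = None
    end_contra_s: float | None = None
    is_sham: bool = False
    sham_duration_s: float | None = None

    def __post_init__(self) -> None:
        if not self.stim_off_s > self.stim_on_s:
            raise ValidationError("annotation: stim_off_s must be > stim_on_s")
        for label, end in (("end_ipsi_s", self.end_ipsi_s), ("end_contra_s", self.end_contra_s)):
            if end is not None and end < self.stim_off_s:
                raise ValidationError(f"annotation: {label} must be >= stim_off_s")
        if self.is_sham != (self.sham_duration_s is not None):
            raise ValidationError("annotation: sham_duration_s present iff is_sham")
        if self.sham_duration_s is not None and self.sham_duration_s <= 0:
            raise ValidationError("annotation: sham_duration_s must be > 0")

    def to_dict(self) -> dict:
        return {
            "stim_on_s": self.stim_on_s,
            "stim_off_s": self.stim_off_s,
            "end_ipsi_s": self.end_ipsi_s,
            "end_contra_s": self.end_contra_s,
            "is_sham": self.is_sham,
            "sham_duration_s": self.sham_duration_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SeizureAnnotation":
        return cls(
            stim_on_s=float(d["stim_on_s"]),
            stim_off_s=float(d["stim_off_s"]),
            end_ipsi_s=None if d.get("end_ipsi_s") is None else float(d["end_ipsi_s"]),
            end_contra_s=None if d.get("end_contra_s") is None else float(d["end_contra_s"]),
            is_sham=bool(d.get("is_sham", False)),
            sham_duration_s=None
            if d.get("sham_duration_s") is None
            else float(d["sham_duration_s"]),
        )


Interval = tuple[float, float]


@dataclass(frozen=True)
class EpochSet:
    """The four analysis intervals, each half-open ``[start, end)`` in seconds."""

    baseline: Interval
    ictal: Interval
    early_postictal: Interval
    late_postictal: Interval

    def __post_init__(self) -> None:
        for name, (a, b) in self.items():
            if not b > a:
                raise ValidationError(f"epoch {name}: end must be > start")
        if not math.isclose(self.baseline[1] - self.baseline[0], BASELINE_S):
            raise ValidationError("baseline epoch must last 60 s")
        if not math.isclose(
            self.early_postictal[1] - self.early_postictal[0], EARLY_POSTICTAL_S
        ):
            raise ValidationError("early postictal epoch must last 30 s")
        if not math.isclose(self.late_postictal[1] - self.late_postictal[0], LATE_POSTICTAL_S):
            raise ValidationError("late postictal epoch must last 60 s")
        if self.ictal[1] - self.ictal[0] < MIN_ICTAL_S - 1e-12:
            raise ExcludedSeizure(
                f"ictal period of {self.ictal[1] - self.ictal[0]:.3f} s "
                "did not reach the 5 s minimum"
            )
        seq = [self.baseline, self.ictal, self.early_postictal, self.late_postictal]
        for (a0, b0), (a1, b1) in zip(seq, seq[1:]):
            if a1 < b0 - 1e-12:
                raise ValidationError("epochs must be ordered and non-overlapping")

    def items(self) -> Iterator[tuple[str, Interval]]:
        yield "baseline", self.baseline
        yield "ictal", self.ictal
        yield "early_postictal", self.early_postictal
        yield "late_postictal", self.late_postictal

    def __getitem__(self, name: str) -> Interval:
        return dict(self.items())[name]

    @property
    def ictal_duration_s(self) -> float:
        return self.ictal[1] - self.ictal[0]

    def label_for(self, t: float) -> str:
        """Epoch label for a time point; 'other' outside all four intervals."""
        for name, (a, b) in self.items():
            if a <= t < b:
                return name
        return "other"


@dataclass
class Session:
    """One recording: signals + events + seizure/sham annotation + metadata."""

    session_id: str
    signals: dict[str, ContinuousSignal]
    events: dict[str, EventSeries]
    annotation: SeizureAnnotation
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, sig in self.signals.items():
            if sig.name != name:
                raise ValidationError(f"signal key {name!r} != signal.name {sig.name!r}")
        for name, ev in self.events.items():
            if ev.name != name:
                raise ValidationError(f"event key {name!r} != series.name {ev.name!r}")

    @property
    def start_s(self) -> float:
        return min(sig.t0_s for sig in self.signals.values()) if self.signals else 0.0

    @property
    def end_s(self) -> float:
        return max(sig.end_s for sig in self.signals.values()) if self.signals else 0.0

    def epochs(self) -> EpochSet:
        return derive_epochs(self.annotation, session_start_s=self.start_s)


def derive_epochs(
    annotation: SeizureAnnotation, session_start_s: float | None = None
) -> EpochSet:
    """Derive the four analysis epochs from a seizure/sham annotation.

    Baseline is the 60 s before stimulation onset; the ictal period starts at
    stimulation offset (the 2 s train itself is artifact) and ends at the
    latest per-channel seizure end (or after the matched sham duration).
    Raises :class:`ExcludedSeizure` when the ictal period is under 5 s and
    :class:`CoverageError` when the baseline would precede ``session_start_s``.
    """
    a = annotation
    if a.is_sham:
        ictal_end = a.stim_off_s + float(a.sham_duration_s)
    else:
        ends = [e for e in (a.end_ipsi_s, a.end_contra_s) if e is not None]
        if not ends:
            raise ValidationError("non-sham annotation needs at least one seizure end time")
        ictal_end = max(ends)
    baseline = (a.stim_on_s - BASELINE_S, a.stim_on_s)
    if session_start_s is not None and baseline[0] < session_start_s - 1e-9:
        raise CoverageError(
            f"baseline start {baseline[0]:.3f} s precedes session start {session_start_s:.3f} s"
        )
    ictal = (a.stim_off_s, ictal_end)
    if ictal[1] - ictal[0] < MIN_ICTAL_S - 1e-12:
        raise ExcludedSeizure(
            f"ictal period of {ictal[1] - ictal[0]:.3f} s did not reach the 5 s minimum"
        )
    early = (ictal_end, ictal_end + EARLY_POSTICTAL_S)
    late = (early[1], early[1] + LATE_POSTICTAL_S)
    return EpochSet(baseline=baseline, ictal=ictal, early_postictal=early, late_postictal=late)


def _index_range(signal: ContinuousSignal, interval: Interval) -> tuple[int, int]:
    start, end = interval
    i0 = int(math.ceil((start - signal.t0_s) * signal.rate_hz - _EDGE_EPS))
    i1 = int(math.ceil((end - signal.t0_s) * signal.rate_hz - _EDGE_EPS))
    return max(i0, 0), min(i1, signal.n_samples)


def slice_signal(signal: ContinuousSignal, interval: Interval) -> ContinuousSignal:
    """Samples with time in the half-open ``[start, end)`` window.

    Concatenating slices over a partition of the span reconstructs the
    original sample sequence exactly (no boundary double counting).
    """
    i0, i1 = _index_range(signal, interval)
    if i1 <= i0:
        raise EmptySliceError(
            f"interval [{interval[0]}, {interval[1]}) selects no samples of {signal.name!r}"
        )
    return ContinuousSignal(
        name=signal.name,
        samples=signal.samples[i0:i1],
        rate_hz=signal.rate_hz,
        t0_s=signal.t0_s + i0 / signal.rate_hz,
        units=signal.units,
    )


# ---------------------------------------------------------------------------
# Bundle IO.
#
# Layout: <bundle>/meta.json, one single-column CSV per signal, events.csv
# with header "name,time_s".  Floats are written with repr() so load/write
# round-trips are byte identical.
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def write_session(session: Session, bundle_path: str | Path) -> None:
    """Write a session bundle (meta.json + per-signal CSVs + events.csv)."""
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)

    signal_entries = []
    for name in sorted(session.signals):
        sig = session.signals[name]
        fname = f"{name}.csv"
        with open(bundle / fname, "w", newline="\n") as f:
            f.write("value\n")
            if sig.n_samples:
                f.write("\n".join(map(_fmt, sig.samples.tolist())))
                f.write("\n")
        signal_entries.append(
            {
                "name": name,
                "rate_hz": sig.rate_hz,
                "t0_s": sig.t0_s,
                "units": sig.units,
                "n_samples": sig.n_samples,
                "file": fname,
            }
        )

    with open(bundle / "events.csv", "w", newline="\n") as f:
        f.write("name,time_s\n")
        for name in sorted(session.events):
            for t in session.events[name].times_s.tolist():
                f.write(f"{name},{_fmt(t)}\n")

    meta = {
        "format_version": FORMAT_VERSION,
        "session_id": session.session_id,
        "meta": session.meta,
        "signals": signal_entries,
        "events": sorted(session.events),
        "annotation": session.annotation.to_dict(),
    }
    with open(bundle / "meta.json", "w", newline="\n") as f:
        json.dump(meta, f, indent=2, sort_keys=True)
        f.write("\n")


def load_session(bundle_path: str | Path) -> Session:
    """Load a session bundle written by :func:`write_session`."""
    bundle = Path(bundle_path)
    meta_path = bundle / "meta.json"
    if not meta_path.exists():
        raise LoadError(f"missing file: {meta_path}")
    with open(meta_path) as f:
        meta = json.load(f)

    signals: dict[str, ContinuousSignal] = {}
    for entry in meta["signals"]:
        path = bundle / entry["file"]
        if not path.exists():
            raise LoadError(f"missing file: {path}")
        col = pd.read_csv(path, dtype=np.float64, float_precision="round_trip")
        if list(col.columns) != ["value"]:
            raise IntegrityError(f"{path}: expected single column 'value'")
        values = col["value"].to_numpy()
        if values.size != int(entry["n_samples"]):
            raise IntegrityError(
                f"{path}: {values.size} samples, meta declares {entry['n_samples']}"
            )
        signals[entry["name"]] = ContinuousSignal(
            name=entry["name"],
            samples=values,
            rate_hz=float(entry["rate_hz"]),
            t0_s=float(entry["t0_s"]),
            units=entry["units"],
        )

    events_path = bundle / "events.csv"
    if not events_path.exists():
        raise LoadError(f"missing file: {events_path}")
    table = pd.read_csv(
        events_path, dtype={"name": str, "time_s": np.float64}, float_precision="round_trip"
    )
    events: dict[str, EventSeries] = {}
    for name in meta["events"]:
        times = table.loc[table["name"] == name, "time_s"].to_numpy()
        events[name] = EventSeries(name=name, times_s=times)

    return Session(
        session_id=meta["session_id"],
        signals=signals,
        events=events,
        annotation=SeizureAnnotation.from_dict(meta["annotation"]),
        meta=meta.get("meta", {}),
    )
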