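"""Core seizure-diary data types and CSV I/O.

A *diary* is the expert-annotated list of electrographic seizures of one
animal: onset times, durations and (optionally) a behavioural semiology
label.  All downstream analyses — natural history, circadian profiling,
clustering statistics and count prediction — operate on these diaries, so
this module fixes the time-coordinate conventions once:

* times are stored in **seconds** relative to a per-animal reference epoch,
  either the moment of the epileptogenic insult (``"injection"``) or the
  onset of the first spontaneous seizure (``"first_seizure"``);
* wall-clock hour of day is recovered via ``clock_offset_h``, the hour of
  day at the epoch, so an event's clock hour is independent of which epoch
  the diary is expressed in;
* events shorter than 10 s are not seizures under the inclusion criterion
  used for electrographic review and are rejected by the strict loader.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEMIOLOGY_CLASSES: tuple[str, ...] = (
    "non_motor",
    "unilateral_motor",
    "bilateral_motor",
    "gtcs",
    "unknown",
)

#: minimum electrographic duration for an event to count as a seizure
MIN_DURATION_S: float = 10.0

EPOCHS = ("injection", "first_seizure")

DAY_S = 86400.0
HOUR_S = 3600.0


class DiaryValidationError(ValueError):
    """Raised when a diary or cohort violates a structural invariant."""


class DiaryParseError(ValueError):
    """Raised on malformed input rows; carries the offending row number."""


@dataclass(frozen=True)
class SeizureEvent:
    """One ictal event.

    Parameters
    ----------
    onset_s
        Seconds since the owning diary's reference epoch (may be negative
        only for diaries rebased to ``first_seizure`` whose recording began
        earlier; individual events never precede the recording window).
    duration_s
        Electrographic duration in seconds (positive).
    semiology
        Behavioural class, one of :data:`SEMIOLOGY_CLASSES`, or ``None``
        when no video review is available.
    """

    onset_s: float
    duration_s: float
    semiology: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.onset_s):
            raise DiaryValidationError(f"non-finite onset {self.onset_s!r}")
        if not (self.duration_s > 0):
            raise DiaryValidationError(
                f"duration must be positive, got {self.duration_s!r}"
            )
        if self.semiology is not None and self.semiology not in SEMIOLOGY_CLASSES:
            raise DiaryValidationError(
                f"unknown semiology {self.semiology!r}; "
                f"expected one of {SEMIOLOGY_CLASSES}"
            )

    @property
    def onset_days(self) -> float:
        return self.onset_s / DAY_S

    @property
    def onset_hours(self) -> float:
        return self.onset_s / HOUR_S


@dataclass
class AnimalDiary:
    """Ordered seizure events of one animal plus recording metadata.

    ``clock_offset_h`` is the wall-clock hour of day at the diary's epoch
    (t = 0); together with an event's ``onset_s`` it determines the event's
    clock hour regardless of epoch choice.  ``injection_s`` records the
    injection instant in the *current* coordinate system (0 when
    ``epoch == "injection"``) so that epochs can be rebased in both
    directions without losing the latency information.
    """

    animal_id: str
    strain: str = "SD"
    events: list[SeizureEvent] = field(default_factory=list)
    epoch: str = "injection"
    recording_start_s: float = 0.0
    recording_end_s: float = 30 * DAY_S
    lights_on_clock_h: float = 7.0
    lights_off_clock_h: float = 19.0
    clock_offset_h: float = 0.0
    injection_s: float | None = None

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise DiaryValidationError(f"unknown epoch {self.epoch!r}")
        if self.epoch == "injection" and self.injection_s is None:
            self.injection_s = 0.0
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if not (self.recording_end_s - self.recording_start_s > 0):
            raise DiaryValidationError(
                f"{self.animal_id}: empty or inverted recording window"
            )
        onsets = np.array([e.onset_s for e in self.events])
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise DiaryValidationError(
                    f"{self.animal_id}: events not strictly sorted by onset"
                )
            if onsets[0] < self.recording_start_s or onsets[-1] > self.recording_end_s:
                raise DiaryValidationError(
                    f"{self.animal_id}: event outside recording window"
                )

    # -- convenience -----------------------------------------------------

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([e.duration_s for e in self.events], dtype=float)

    @property
    def recording_days(self) -> float:
        return (self.recording_end_s - self.recording_start_s) / DAY_S

    def __iter__(self) -> Iterator[SeizureEvent]:
        return iter(self.events)


@dataclass
class LoadReport:
    """Outcome of a cohort load: what was kept, dropped, or flagged."""

    n_rows: int = 0
    n_kept: int = 0
    dropped_rows: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_rows)

    def summary(self) -> str:
        return f"{self.n_kept} events kept, {self.n_dropped} dropped"


@dataclass
class Cohort:
    """A labelled collection of animal diaries with unique animal ids."""

    diaries: list[AnimalDiary] = field(default_factory=list)
    label: str = ""
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        ids = [d.animal_id for d in self.diaries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DiaryValidationError(f"duplicate animal_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.diaries)

    def __iter__(self) -> Iterator[AnimalDiary]:
        return iter(self.diaries)

    def get(self, animal_id: str) -> AnimalDiary:
        for d in self.diaries:
            if d.animal_id == animal_id:
                return d
        raise KeyError(animal_id)

    def seizing(self, min_events: int = 1) -> "Cohort":
        """Sub-cohort of diaries with at least ``min_events`` events.

        Seizure-free animals stay in the full cohort (they enter the
        induction-rate denominator) but are excluded, with a log note, from
        analyses that need events.
        """
        kept, skipped = [], []
        for d in self.diaries:
            (kept if d.n_events >= min_events else skipped).append(d)
        if skipped:
            logger.info(
                "excluding %d diaries with < %d events: %s",
                len(skipped), min_events, [d.animal_id for d in skipped],
            )
        return Cohort(diaries=kept, label=self.label)

    @property
    def n_events(self) -> int:
        return sum(d.n_events for d in self.diaries)


# ---------------------------------------------------------------------------
# epoch handling and clock arithmetic
# ---------------------------------------------------------------------------

def rebase_epoch(diary: AnimalDiary, epoch: str) -> AnimalDiary:
    """Return a copy of ``diary`` expressed relative to a different epoch.

    Rebasing to ``first_seizure`` places t = 0 at the first event's onset;
    rebasing back to ``injection`` requires the injection instant to be
    known (``injection_s``).  The wall-clock hour of every event is
    preserved, and rebasing to the current epoch is the identity.
    """
    if epoch not in EPOCHS:
        raise DiaryValidationError(f"unknown epoch {epoch!r}")
    if epoch == diary.epoch:
        return replace(diary)
    if epoch == "first_seizure":
        if diary.n_events == 0:
            raise DiaryValidationError(
                f"{diary.animal_id}: cannot rebase a seizure-free diary "
                "to the first_seizure epoch"
            )
        shift = diary.events[0].onset_s
    else:  # -> injection
        if diary.injection_s is None:
            raise DiaryValidationError(
                f"{diary.animal_id}: injection time unknown; cannot rebase"
            )
        shift = diary.injection_s
    new_events = [replace(e, onset_s=e.onset_s - shift) for e in diary.events]
    return AnimalDiary(
        animal_id=diary.animal_id,
        strain=diary.strain,
        events=new_events,
        epoch=epoch,
        recording_start_s=diary.recording_start_s - shift,
        recording_end_s=diary.recording_end_s - shift,
        lights_on_clock_h=diary.lights_on_clock_h,
        lights_off_clock_h=diary.lights_off_clock_h,
        clock_offset_h=(diary.clock_offset_h + shift / HOUR_S) % 24.0,
        injection_s=None if diary.injection_s is None
        else diary.injection_s - shift,
    )


def clock_hour(diary: AnimalDiary, event: SeizureEvent | float) -> float:
    """Wall-clock hour of day in [0, 24) of an event (or raw onset_s)."""
    onset_s = event.onset_s if isinstance(event, SeizureEvent) else float(event)
    return (diary.clock_offset_h + onset_s / HOUR_S) % 24.0


def clock_hours(diary: AnimalDiary) -> np.ndarray:
    """Vectorised :func:`clock_hour` over all events of a diary."""
    return (diary.clock_offset_h + diary.onsets_s / HOUR_S) % 24.0


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "animal_id", "strain", "epoch", "recording_start_s", "recording_end_s",
    "clock_offset_h", "lights_on_clock_h", "lights_off_clock_h",
]


def load_cohort(
    events_path: str | Path,
    meta_path: str | Path | None = None,
    *,
    strict: bool = True,
    label: str = "",
) -> Cohort:
    """Read a cohort from an events CSV plus a per-animal metadata CSV.

    Events columns: ``animal_id, onset_s`` (or ``onset_iso``),
    ``duration_s``, optional ``semiology``.  Metadata columns:
    ``animal_id, strain, epoch, recording_start_s, recording_end_s,
    clock_offset_h, lights_on_clock_h, lights_off_clock_h`` and optionally
    ``injection_s`` and (for the ISO dialect) ``epoch_iso``.

    Under ``strict=True`` events shorter than 10 s are dropped and listed
    in the attached :class:`LoadReport`; under ``strict=False`` they are
    kept with a warning.  Unsorted rows are sorted; animals present in the
    metadata but without events become seizure-free diaries.
    """
    events_path = Path(events_path)
    if meta_path is None:
        meta_path = events_path.with_name(
            events_path.name.replace("events", "meta")
        )
        if meta_path == events_path or not Path(meta_path).exists():
            raise FileNotFoundError(
                f"no metadata table found alongside {events_path}; "
                "pass meta_path explicitly"
            )
    meta = pd.read_csv(meta_path, dtype={"animal_id": str},
                       float_precision="round_trip")
    missing = [c for c in ("animal_id", "recording_start_s", "recording_end_s")
               if c not in meta.columns]
    if missing:
        raise DiaryParseError(f"metadata missing columns {missing}")
    if meta["animal_id"].duplicated().any():
        dupes = meta.loc[meta["animal_id"].duplicated(), "animal_id"].tolist()
        raise DiaryValidationError(f"duplicate animal_id in metadata: {dupes}")

    ev = pd.read_csv(events_path, dtype={"animal_id": str},
                     float_precision="round_trip")
    report = LoadReport(n_rows=len(ev))

    if "onset_iso" in ev.columns and "onset_s" not in ev.columns:
        if "epoch_iso" not in meta.columns:
            raise DiaryParseError(
                "onset_iso dialect requires an epoch_iso metadata column"
            )
        ref = meta.set_index("animal_id")["epoch_iso"].map(pd.Timestamp)
        try:
            ts = pd.to_datetime(ev["onset_iso"])
        except (ValueError, TypeError) as exc:
            raise DiaryParseError(f"bad onset_iso value: {exc}") from exc
        ev = ev.assign(
            onset_s=(ts - ev["animal_id"].map(ref)).dt.total_seconds()
        )
    for col in ("onset_s", "duration_s"):
        if col not in ev.columns:
            raise DiaryParseError(f"events file missing column {col!r}")
        bad = ev.index[pd.to_numeric(ev[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 0-based index -> 1-based file row
            raise DiaryParseError(
                f"malformed {col!r} in events file row {bad[0] + 2}"
            )
        ev[col] = pd.to_numeric(ev[col])

    diaries = []
    meta = meta.fillna(np.nan)
    for _, m in meta.iterrows():
        rows = ev[ev["animal_id"] == m["animal_id"]].sort_values("onset_s")
        events = []
        for idx, r in rows.iterrows():
            if r["duration_s"] < MIN_DURATION_S:
                if strict:
                    report.dropped_rows.append(
                        (int(idx) + 2,
                         f"duration {r['duration_s']:g} s < {MIN_DURATION_S:g} s")
                    )
                    continue
                report.warnings.append(
                    f"row {int(idx) + 2}: kept sub-threshold duration "
                    f"{r['duration_s']:g} s (permissive mode)"
                )
            semi = r.get("semiology")
            if isinstance(semi, float) and np.isnan(semi):
                semi = None
            events.append(
                SeizureEvent(
                    onset_s=float(r["onset_s"]),
                    duration_s=float(r["duration_s"]),
                    semiology=semi if semi else None,
                )
            )
        inj = m.get("injection_s")
        diaries.append(
            AnimalDiary(
                animal_id=str(m["animal_id"]),
                strain=str(m.get("strain", "SD")),
                events=events,
                epoch=str(m.get("epoch", "injection")),
                recording_start_s=float(m["recording_start_s"]),
                recording_end_s=float(m["recording_end_s"]),
                lights_on_clock_h=float(m.get("lights_on_clock_h", 7.0)),
                lights_off_clock_h=float(m.get("lights_off_clock_h", 19.0)),
                clock_offset_h=float(m.get("clock_offset_h", 0.0)),
                injection_s=None if inj is None or pd.isna(inj) else float(inj),
            )
        )
    unknown = set(ev["animal_id"]) - set(meta["animal_id"])
    if unknown:
        raise DiaryValidationError(
            f"events reference animals absent from metadata: {sorted(unknown)}"
        )
    report.n_kept = sum(d.n_events for d in diaries)
    if report.n_dropped:
        msg = f"{report.n_dropped} dropped (< {MIN_DURATION_S:g} s)"
        logger.info("load report: %s", msg)
        warnings.warn(msg, stacklevel=2)
    return Cohort(diaries=diaries, label=label, load_report=report)


def write_cohort(
    cohort: Cohort,
    events_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write a cohort back to the two-CSV on-disk form (round-trip safe)."""
    ev_rows = [
        {
            "animal_id": d.animal_id,
            "onset_s": repr(float(e.onset_s)),
            "duration_s": repr(float(e.duration_s)),
            "semiology": e.semiology if e.semiology else "",
        }
        for d in cohort.diaries
        for e in d.events
    ]
    pd.DataFrame(
        ev_rows, columns=["animal_id", "onset_s", "duration_s", "semiology"]
    ).to_csv(events_path, index=False)
    meta_rows = [
        {
            "animal_id": d.animal_id,
            "strain": d.strain,
            "epoch": d.epoch,
            "recording_start_s": repr(float(d.recording_start_s)),
            "recording_end_s": repr(float(d.recording_end_s)),
            "clock_offset_h": repr(float(d.clock_offset_h)),
            "lights_on_clock_h": repr(float(d.lights_on_clock_h)),
            "lights_off_clock_h": repr(float(d.lights_off_clock_h)),
            "injection_s": "" if d.injection_s is None
            else repr(float(d.injection_s)),
        }
        for d in cohort.diaries
    ]
    pd.DataFrame(meta_rows, columns=_META_COLUMNS + ["injection_s"]).to_csv(
        meta_path, index=False
    )
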