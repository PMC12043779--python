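"""Shared data model and tidy-log I/O for home-cage operant experiments.

The interchange currency between the trial engine, the cohort simulator and
the analysis suite is the :class:`Event`: one time-stamped record per RFID
read, nose-poke, reward delivery or cue onset.  Time is a single monotonic
experiment clock in seconds (millisecond precision or better); the mapping
to wall-clock time is carried once in the log header (experiment start time
plus the lights-on hour of the housing light cycle), never per event.

Two on-disk dialects are supported and round-trip losslessly:

* CSV — one event per row, fixed column order ``t,kind,rfid_tag,port,
  liquid,volume_ul``, '.' decimal separator, UTF-8.  The header carries a
  single ``#homecage-log`` comment line with the wall-clock anchor.
* JSON lines — identical field names, one object per line, with a leading
  ``{"kind": "header", ...}`` record.

Floats are serialized with ``repr`` so identical inputs produce identical
bytes and every value survives a write/read cycle exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import OrderingError, SchemaError, UnknownTagError, ValidationError

EVENT_KINDS = ("rfid_read", "poke", "reward", "cue_on", "trial_start", "trial_end")
PORTS = ("left", "right", "none")
LIQUIDS = ("water", "fentanyl", "none")
GROUPS = ("control", "experimental")
TERMINATIONS = ("gap_timeout", "no_first_poke", "displaced")

EVENT_COLUMNS = ("t", "kind", "rfid_tag", "port", "liquid", "volume_ul")
ROSTER_COLUMNS = ("rfid_tag", "mouse_label", "group", "cage_id")

#: sort priority for events sharing a timestamp: a poke precedes the reward
#: it triggers, which precedes its cue.
_KIND_ORDER = {k: i for i, k in enumerate(
    ("rfid_read", "trial_start", "poke", "reward", "cue_on", "trial_end"))}


def event_sort_key(ev: "Event") -> tuple:
    return (ev.t, _KIND_ORDER[ev.kind], ev.rfid_tag, ev.port)


@dataclass(frozen=True, slots=True)
class MouseIdentity:
    """One roster entry: an RFID tag bound to a named mouse in a cage."""

    rfid_tag: str
    mouse_label: str
    group: str
    cage_id: str

    def __post_init__(self):
        if not self.rfid_tag:
            raise ValidationError("rfid_tag must be non-empty")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass(frozen=True, slots=True)
class Event:
    """Atomic time-stamped record.

    ``rfid_tag`` is empty only for system events; reward events carry a
    positive ``volume_ul`` and a liquid; poke events carry a port.
    """

    t: float
    kind: str
    rfid_tag: str = ""
    port: str = "none"
    liquid: str = "none"
    volume_ul: float = 0.0

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.t < 0:
            raise ValidationError(f"negative timestamp {self.t!r}")
        if self.port not in PORTS:
            raise ValidationError(f"unknown port {self.port!r}")
        if self.liquid not in LIQUIDS:
            raise ValidationError(f"unknown liquid {self.liquid!r}")
        if self.kind == "reward":
            if self.volume_ul <= 0:
                raise ValidationError("reward event requires volume_ul > 0")
            if self.liquid == "none":
                raise ValidationError("reward event requires a liquid")
        elif self.volume_ul != 0:
            raise ValidationError(f"{self.kind} event must carry volume_ul == 0")
        if self.kind == "poke" and self.port == "none":
            raise ValidationError("poke event requires a port")


@dataclass(frozen=True, slots=True)
class LogHeader:
    """Wall-clock anchor of the experiment clock.

    ``t == 0`` corresponds to ``experiment_start`` (ISO-8601); by convention
    the simulator starts the clock at lights-on of day 1 so circadian phase
    is a pure function of ``t``.
    """

    experiment_start: str = "2024-01-01T07:00:00"
    lights_on_hour: int = 7


@dataclass(frozen=True)
class Trial:
    """One RFID-initiated visit: its pokes, rewards and termination reason."""

    mouse: MouseIdentity
    t_start: float
    t_end: float
    pokes: tuple[tuple[float, str], ...]
    rewards: tuple[tuple[float, str, float], ...]
    termination: str

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValidationError("t_end must not precede t_start")
        if self.termination not in TERMINATIONS:
            raise ValidationError(f"unknown termination {self.termination!r}")
        for t, _port in self.pokes:
            if not (self.t_start <= t <= self.t_end):
                raise ValidationError("poke outside trial window")
        for t, _liq, vol in self.rewards:
            if not (self.t_start <= t <= self.t_end):
                raise ValidationError("reward outside trial window")
            if vol <= 0:
                raise ValidationError("reward volume must be positive")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_pokes(self) -> int:
        return len(self.pokes)

    @property
    def n_rewards(self) -> int:
        return len(self.rewards)

    def rewards_of(self, liquid: str) -> int:
        return sum(1 for _t, liq, _v in self.rewards if liq == liquid)

    def volume_of(self, liquid: str) -> float:
        return sum(v for _t, liq, v in self.rewards if liq == liquid)

    def pokes_at(self, port: str) -> int:
        return sum(1 for _t, p in self.pokes if p == port)


@dataclass(frozen=True)
class TrialLedger:
    """Time-ordered trials; within one cage trials never overlap.

    The drinking zone physically admits a single mouse, so overlapping
    trials in a cage indicate a corrupted or mis-segmented log and are
    rejected at construction.
    """

    trials: tuple[Trial, ...]

    def __post_init__(self):
        ordered = tuple(sorted(self.trials, key=lambda tr: (tr.t_start, tr.t_end)))
        object.__setattr__(self, "trials", ordered)
        last_end: dict[str, float] = {}
        for tr in ordered:
            cage = tr.mouse.cage_id
            if cage in last_end and tr.t_start < last_end[cage]:
                raise ValidationError(
                    f"overlapping trials in cage {cage!r} at t={tr.t_start}")
            last_end[cage] = tr.t_end

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def mice(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for tr in self.trials:
            seen.setdefault(tr.mouse.rfid_tag, None)
        return tuple(seen)

    def for_mouse(self, rfid_tag: str) -> tuple[Trial, ...]:
        return tuple(tr for tr in self.trials if tr.mouse.rfid_tag == rfid_tag)


# ---------------------------------------------------------------------------
# serialization helpers

def _fmt(x: float) -> str:
    return repr(float(x))


def _check_sorted(events: Iterable[Event]) -> list[Event]:
    events = list(events)
    for i in range(1, len(events)):
        if events[i].t < events[i - 1].t:
            raise OrderingError(
                f"timestamps decrease at position {i}", line=i)
    return events


def write_event_log(events: Iterable[Event], path: str | Path,
                    header: LogHeader | None = None) -> Path:
    """Write a tidy event log (CSV, or JSON lines for ``.jsonl`` paths).

    Output is deterministic: identical input yields identical bytes.
    """
    path = Path(path)
    events = _check_sorted(events)
    header = header or LogHeader()
    if path.suffix == ".jsonl":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(json.dumps({
                "kind": "header",
                "experiment_start": header.experiment_start,
                "lights_on_hour": header.lights_on_hour,
            }, separators=(",", ":")) + "\n")
            for ev in events:
                fh.write(json.dumps({
                    "t": ev.t, "kind": ev.kind, "rfid_tag": ev.rfid_tag,
                    "port": ev.port, "liquid": ev.liquid,
                    "volume_ul": ev.volume_ul,
                }, separators=(",", ":")) + "\n")
        return path
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#homecage-log v1 experiment_start={header.experiment_start} "
                 f"lights_on_hour={header.lights_on_hour}\n")
        fh.write(",".join(EVENT_COLUMNS) + "\n")
        for ev in events:
            fh.write(f"{_fmt(ev.t)},{ev.kind},{ev.rfid_tag},{ev.port},"
                     f"{ev.liquid},{_fmt(ev.volume_ul)}\n")
    return path


def read_log_header(path: str | Path) -> LogHeader:
    """Parse the wall-clock anchor from a log's header line."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if path.suffix == ".jsonl":
        try:
            rec = json.loads(first)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: malformed header line") from exc
        if rec.get("kind") != "header":
            return LogHeader()
        return LogHeader(experiment_start=rec["experiment_start"],
                         lights_on_hour=int(rec["lights_on_hour"]))
    if first.startswith("#homecage-log"):
        fields = dict(tok.split("=", 1) for tok in first.split()[2:])
        return LogHeader(experiment_start=fields["experiment_start"],
                         lights_on_hour=int(fields["lights_on_hour"]))
    return LogHeader()


def read_event_log(path: str | Path) -> list[Event]:
    """Read a tidy event log; events come back sorted by ``t``.

    Malformed rows raise :class:`SchemaError` naming the offending line;
    a timestamp stepping backwards raises :class:`OrderingError` naming the
    first offending line.
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        return _read_jsonl(path)
    events: list[Event] = []
    with open(path, encoding="utf-8") as fh:
        lineno = 0
        header_seen = False
        prev_t = None
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if not header_seen:
                if tuple(parts) != EVENT_COLUMNS:
                    raise SchemaError(
                        f"{path}: line {lineno}: expected columns "
                        f"{','.join(EVENT_COLUMNS)}, got {line!r}")
                header_seen = True
                continue
            if len(parts) != len(EVENT_COLUMNS):
                raise SchemaError(
                    f"{path}: line {lineno}: expected {len(EVENT_COLUMNS)} "
                    f"fields, got {len(parts)}")
            try:
                ev = Event(t=float(parts[0]), kind=parts[1], rfid_tag=parts[2],
                           port=parts[3], liquid=parts[4],
                           volume_ul=float(parts[5]))
            except (ValueError, ValidationError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
            if prev_t is not None and ev.t < prev_t:
                raise OrderingError(
                    f"{path}: line {lineno}: timestamp {ev.t} precedes {prev_t}",
                    line=lineno)
            prev_t = ev.t
            events.append(ev)
        if not header_seen:
            raise SchemaError(f"{path}: missing header row")
    return events


def _read_jsonl(path: Path) -> list[Event]:
    events: list[Event] = []
    prev_t = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}: line {lineno}: bad JSON") from exc
            if rec.get("kind") == "header":
                continue
            try:
                ev = Event(t=float(rec["t"]), kind=rec["kind"],
                           rfid_tag=rec.get("rfid_tag", ""),
                           port=rec.get("port", "none"),
                           liquid=rec.get("liquid", "none"),
                           volume_ul=float(rec.get("volume_ul", 0.0)))
            except (KeyError, ValueError, ValidationError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
            if prev_t is not None and ev.t < prev_t:
                raise OrderingError(
                    f"{path}: line {lineno}: timestamp {ev.t} precedes {prev_t}",
                    line=lineno)
            prev_t = ev.t
            events.append(ev)
    return events


def merge_events(*streams: Iterable[Event]) -> list[Event]:
    """Merge event streams into one time-sorted log (stable tie order)."""
    out: list[Event] = []
    for s in streams:
        out.extend(s)
    out.sort(key=event_sort_key)
    return out


# ---------------------------------------------------------------------------
# roster

def write_roster(roster: Iterable[MouseIdentity], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(ROSTER_COLUMNS) + "\n")
        for m in roster:
            fh.write(f"{m.rfid_tag},{m.mouse_label},{m.group},{m.cage_id}\n")
    return path


def read_roster(path: str | Path) -> dict[str, MouseIdentity]:
    """Read a roster CSV into a tag-keyed mapping; duplicate tags are errors."""
    path = Path(path)
    roster: dict[str, MouseIdentity] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if tuple(header.split(",")) != ROSTER_COLUMNS:
            raise SchemaError(f"{path}: expected columns {','.join(ROSTER_COLUMNS)}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(ROSTER_COLUMNS):
                raise SchemaError(f"{path}: line {lineno}: wrong field count")
            try:
                m = MouseIdentity(*parts)
            except ValidationError as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
            if m.rfid_tag in roster:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate rfid_tag {m.rfid_tag!r}")
            roster[m.rfid_tag] = m
    return roster


def resolve_tag(roster: Mapping[str, MouseIdentity], tag: str) -> MouseIdentity:
    try:
        return roster[tag]
    except KeyError:
        raise UnknownTagError(f"rfid_tag {tag!r} not in roster") from None


# ---------------------------------------------------------------------------
# trial ledger

def write_trial_ledger(ledger: TrialLedger, path: str | Path) -> Path:
    """Write a ledger as JSON lines, one trial per line (lossless)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for tr in ledger:
            fh.write(json.dumps({
                "rfid_tag": tr.mouse.rfid_tag,
                "mouse_label": tr.mouse.mouse_label,
                "group": tr.mouse.group,
                "cage_id": tr.mouse.cage_id,
                "t_start": tr.t_start,
                "t_end": tr.t_end,
                "termination": tr.termination,
                "pokes": [[t, p] for t, p in tr.pokes],
                "rewards": [[t, liq, v] for t, liq, v in tr.rewards],
            }, separators=(",", ":")) + "\n")
    return path


def read_trial_ledger(path: str | Path) -> TrialLedger:
    path = Path(path)
    trials: list[Trial] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                tr = Trial(
                    mouse=MouseIdentity(rec["rfid_tag"], rec["mouse_label"],
                                        rec["group"], rec["cage_id"]),
                    t_start=float(rec["t_start"]),
                    t_end=float(rec["t_end"]),
                    pokes=tuple((float(t), p) for t, p in rec["pokes"]),
                    rewards=tuple((float(t), liq, float(v))
                                  for t, liq, v in rec["rewards"]),
                    termination=rec["termination"],
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
            trials.append(tr)
    return TrialLedger(trials=tuple(trials))
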