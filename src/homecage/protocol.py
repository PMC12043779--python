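"""Multi-day protocol staging and per-day contingency resolution.

The default staging mirrors a standard oral self-administration choice
protocol: two days of single-port water habituation (side flipped on day
2), two days of single-port fentanyl habituation at 0.1 mg/ml with a
500-ms reward cue (side flipped on day 4), then a two-port choice phase in
which the liquid/side assignment swaps daily to prevent side bias while
the fixed-ratio requirement escalates — FR1 for four days, FR3 for four
days, then FR5 with the fentanyl concentration raised to 0.15 mg/ml,
open-ended.  Drop size is 10 µl throughout.

Days are 1-based calendar days whose boundary sits at lights-on, so a full
dark phase is never split across days.  Protocols serialize to a
human-editable TOML file and re-parse to an identical configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .engine import (ContingencyResolver, LiquidSchedule, PRState,
                     ReplayResult, ScheduleSettings, replay)
from .errors import ProtocolError, UnknownTagError
from .events import Event, MouseIdentity

SECONDS_PER_DAY = 86400.0
_MIRROR = {"left": "right", "right": "left"}
SWAP_POLICIES = ("none", "flip_day2", "daily_swap")


@dataclass(frozen=True)
class StageSpec:
    """One protocol stage: a day range with its ports, liquids and settings."""

    name: str
    day_start: int
    day_end: int | None  # inclusive; None = open-ended (last stage only)
    liquid_assignment: Mapping[str, str]  # port -> liquid at stage start
    settings: ScheduleSettings
    swap_policy: str = "none"
    cue_enabled: bool = False

    def __post_init__(self):
        if self.swap_policy not in SWAP_POLICIES:
            raise ProtocolError(f"unknown swap_policy {self.swap_policy!r}")
        if self.day_end is not None and self.day_end < self.day_start:
            raise ProtocolError(f"stage {self.name!r}: empty day range")
        object.__setattr__(self, "liquid_assignment", dict(self.liquid_assignment))

    @property
    def active_ports(self) -> tuple[str, ...]:
        return tuple(sorted(self.liquid_assignment))

    def contains(self, day: int) -> bool:
        return day >= self.day_start and (self.day_end is None or day <= self.day_end)

    def port_map_on(self, day: int) -> dict[str, str]:
        """Port→liquid map for a given day, applying the swap policy."""
        if not self.contains(day):
            raise ProtocolError(f"day {day} outside stage {self.name!r}")
        offset = day - self.day_start
        flip = ((self.swap_policy == "flip_day2" and offset >= 1)
                or (self.swap_policy == "daily_swap" and offset % 2 == 1))
        if not flip:
            return dict(self.liquid_assignment)
        return {_MIRROR[p]: liq for p, liq in self.liquid_assignment.items()}


@dataclass(frozen=True)
class ProtocolConfig:
    """An ordered set of stages plus the wall-clock anchor and overrides.

    Stage day ranges must partition the experiment days starting at day 1;
    only the final stage may be open-ended.  ``overrides`` maps an RFID tag
    to a full ScheduleSettings that replaces the stage default for that
    mouse — the hook for individually tailored contingencies.
    """

    stages: tuple[StageSpec, ...]
    lights_on_hour: int = 7
    experiment_start: str = "2024-01-01T07:00:00"
    quinine_habituation: bool = True
    overrides: Mapping[str, ScheduleSettings] = field(default_factory=dict)

    def __post_init__(self):
        if not self.stages:
            raise ProtocolError("protocol requires at least one stage")
        expected = 1
        for i, st in enumerate(self.stages):
            if st.day_start != expected:
                raise ProtocolError(
                    f"stage {st.name!r} starts on day {st.day_start}, "
                    f"expected {expected}")
            if st.day_end is None:
                if i != len(self.stages) - 1:
                    raise ProtocolError("only the final stage may be open-ended")
            else:
                expected = st.day_end + 1
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "overrides", dict(self.overrides))

    def stage_for(self, day: int) -> StageSpec:
        if day < 1:
            raise ProtocolError(f"day must be >= 1, got {day}")
        for st in self.stages:
            if st.contains(day):
                return st
        raise ProtocolError(f"day {day} beyond the protocol span")

    def resolve(self, day: int, rfid_tag: str) -> tuple[dict[str, str], ScheduleSettings]:
        """Active port→liquid map and settings for (day, mouse)."""
        st = self.stage_for(day)
        settings = self.overrides.get(rfid_tag, st.settings)
        return st.port_map_on(day), settings

    @property
    def span_days(self) -> int | None:
        last = self.stages[-1]
        return last.day_end


def resolve(day: int, rfid_tag: str,
            protocol: ProtocolConfig) -> tuple[dict[str, str], ScheduleSettings]:
    return protocol.resolve(day, rfid_tag)


def day_of(t: float) -> int:
    """Calendar day of an experiment-clock instant (day 1 starts at t=0,
    which the log header anchors at lights-on)."""
    return int(t // SECONDS_PER_DAY) + 1


# ---------------------------------------------------------------------------
# default staging

def _water(ratio: int = 1) -> LiquidSchedule:
    return LiquidSchedule(ratio=ratio)


def _fentanyl(ratio: int = 1, concentration: float = 0.1,
              cue: bool = True) -> LiquidSchedule:
    return LiquidSchedule(ratio=ratio, concentration_mg_per_ml=concentration,
                          cue_duration_ms=500.0 if cue else 0.0)


def default_protocol(lights_on_hour: int = 7,
                     experiment_start: str = "2024-01-01T07:00:00") -> ProtocolConfig:
    """The standard FR staging: habituation, then choice with FR escalation."""
    stages = (
        StageSpec(name="water_habituation", day_start=1, day_end=2,
                  liquid_assignment={"left": "water"},
                  settings=ScheduleSettings(liquids={"water": _water(1)}),
                  swap_policy="flip_day2"),
        StageSpec(name="fentanyl_habituation", day_start=3, day_end=4,
                  liquid_assignment={"left": "fentanyl"},
                  settings=ScheduleSettings(
                      liquids={"fentanyl": _fentanyl(1, 0.1)}),
                  swap_policy="flip_day2", cue_enabled=True),
        StageSpec(name="choice_fr1", day_start=5, day_end=8,
                  liquid_assignment={"left": "fentanyl", "right": "water"},
                  settings=ScheduleSettings(
                      liquids={"water": _water(1), "fentanyl": _fentanyl(1, 0.1)}),
                  swap_policy="daily_swap", cue_enabled=True),
        StageSpec(name="choice_fr3", day_start=9, day_end=12,
                  liquid_assignment={"left": "fentanyl", "right": "water"},
                  settings=ScheduleSettings(
                      liquids={"water": _water(3), "fentanyl": _fentanyl(3, 0.1)}),
                  swap_policy="daily_swap", cue_enabled=True),
        StageSpec(name="choice_fr5", day_start=13, day_end=None,
                  liquid_assignment={"left": "fentanyl", "right": "water"},
                  settings=ScheduleSettings(
                      liquids={"water": _water(5), "fentanyl": _fentanyl(5, 0.15)}),
                  swap_policy="daily_swap", cue_enabled=True),
    )
    return ProtocolConfig(stages=stages, lights_on_hour=lights_on_hour,
                          experiment_start=experiment_start)


def choice_protocol(ratio: int = 5, n_days: int | None = None,
                    concentration: float = 0.15,
                    lights_on_hour: int = 7) -> ProtocolConfig:
    """A single-stage two-port choice protocol at a fixed FR, used for
    focused comparisons that do not need the full habituation staging."""
    stage = StageSpec(
        name=f"choice_fr{ratio}", day_start=1, day_end=n_days,
        liquid_assignment={"left": "fentanyl", "right": "water"},
        settings=ScheduleSettings(liquids={
            "water": _water(ratio),
            "fentanyl": _fentanyl(ratio, concentration)}),
        swap_policy="daily_swap", cue_enabled=True)
    return ProtocolConfig(stages=(stage,), lights_on_hour=lights_on_hour,
                          quinine_habituation=False)


def pr_protocol(concentration: float = 0.1,
                lights_on_hour: int = 7) -> ProtocolConfig:
    """Single-session progressive-ratio protocol: both liquids start at a
    requirement of 1 which increments per same-liquid reward, per mouse."""
    stage = StageSpec(
        name="progressive_ratio", day_start=1, day_end=None,
        liquid_assignment={"left": "fentanyl", "right": "water"},
        settings=ScheduleSettings(liquids={
            "water": LiquidSchedule(ratio=1, schedule_kind="progressive"),
            "fentanyl": LiquidSchedule(ratio=1, schedule_kind="progressive",
                                       concentration_mg_per_ml=concentration,
                                       cue_duration_ms=500.0)}),
        swap_policy="none", cue_enabled=True)
    return ProtocolConfig(stages=(stage,), lights_on_hour=lights_on_hour,
                          quinine_habituation=False)


# ---------------------------------------------------------------------------
# reporting

def quinine_habituation_note(protocol: ProtocolConfig) -> str | None:
    """Pre-experiment checklist entry for bitterness habituation, if enabled:
    the home-cage water is replaced with quinine-adulterated water so the
    reference liquid matches the drug solution's intrinsic bitterness."""
    if not protocol.quinine_habituation:
        return None
    return ("Pre-experiment habituation: replace home-cage drinking water "
            "with quinine-adulterated water (0.1 mg/ml) for 2 days before "
            "cage entry, matching the bitterness of the fentanyl solution.")


def protocol_report(protocol: ProtocolConfig) -> str:
    """Human-readable summary of the staging; regeneration is idempotent."""
    lines = ["Protocol report", "==============="]
    note = quinine_habituation_note(protocol)
    if note is not None:
        lines.append(note)
    lines.append(f"Lights on at hour {protocol.lights_on_hour}; experiment "
                 f"clock starts {protocol.experiment_start}.")
    for st in protocol.stages:
        end = "open-ended" if st.day_end is None else f"day {st.day_end}"
        ports = ", ".join(f"{p}={liq}" for p, liq in
                          sorted(st.liquid_assignment.items()))
        scheds = "; ".join(
            f"{liq}: {s.schedule_kind} ratio {s.ratio}, "
            f"{s.drop_volume_ul:g} ul/drop"
            + (f", {s.concentration_mg_per_ml:g} mg/ml" if
               s.concentration_mg_per_ml else "")
            + (", cue" if s.cue_duration_ms else "")
            for liq, s in sorted(st.settings.liquids.items()))
        lines.append(f"- {st.name}: day {st.day_start} to {end}; ports {ports}; "
                     f"swap {st.swap_policy}; {scheds}")
    for tag in sorted(protocol.overrides):
        lines.append(f"- override for {tag}: custom schedule settings")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# TOML serialization

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        if any(c in v for c in '"\\\n'):
            raise ProtocolError(f"cannot serialize string {v!r}")
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ProtocolError(f"cannot serialize {type(v).__name__}")


def _emit_schedule(lines: list[str], prefix: str, liq: str, s: LiquidSchedule):
    lines.append(f"[{prefix}.schedule.{liq}]")
    lines.append(f"ratio = {s.ratio}")
    lines.append(f"drop_volume_ul = {_toml_value(s.drop_volume_ul)}")
    lines.append(f"concentration_mg_per_ml = {_toml_value(s.concentration_mg_per_ml)}")
    lines.append(f"cue_duration_ms = {_toml_value(s.cue_duration_ms)}")
    lines.append(f'schedule_kind = "{s.schedule_kind}"')
    lines.append("")


def write_protocol(protocol: ProtocolConfig, path: str | Path) -> Path:
    """Serialize a protocol to a declarative TOML file."""
    path = Path(path)
    lines = ["[protocol]",
             f"lights_on_hour = {protocol.lights_on_hour}",
             f'experiment_start = "{protocol.experiment_start}"',
             f"quinine_habituation = {_toml_value(protocol.quinine_habituation)}",
             ""]
    for st in protocol.stages:
        lines.append("[[stage]]")
        lines.append(f'name = "{st.name}"')
        lines.append(f"day_start = {st.day_start}")
        if st.day_end is not None:
            lines.append(f"day_end = {st.day_end}")
        lines.append(f'swap_policy = "{st.swap_policy}"')
        lines.append(f"cue_enabled = {_toml_value(st.cue_enabled)}")
        lines.append(f"inter_poke_timeout_s = {_toml_value(st.settings.inter_poke_timeout_s)}")
        lines.append(f"first_poke_window_s = {_toml_value(st.settings.first_poke_window_s)}")
        lines.append("")
        lines.append("[stage.liquid_assignment]")
        for port, liq in sorted(st.liquid_assignment.items()):
            lines.append(f'{port} = "{liq}"')
        lines.append("")
        for liq, s in sorted(st.settings.liquids.items()):
            _emit_schedule(lines, "stage", liq, s)
    for tag in sorted(protocol.overrides):
        settings = protocol.overrides[tag]
        lines.append(f'[override."{tag}"]')
        lines.append(f"inter_poke_timeout_s = {_toml_value(settings.inter_poke_timeout_s)}")
        lines.append(f"first_poke_window_s = {_toml_value(settings.first_poke_window_s)}")
        lines.append("")
        for liq, s in sorted(settings.liquids.items()):
            _emit_schedule(lines, f'override."{tag}"', liq, s)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines).rstrip("\n") + "\n")
    return path


def _settings_from_tables(tbl: Mapping) -> ScheduleSettings:
    liquids = {}
    for liq, s in tbl.get("schedule", {}).items():
        liquids[liq] = LiquidSchedule(
            ratio=int(s["ratio"]),
            drop_volume_ul=float(s["drop_volume_ul"]),
            concentration_mg_per_ml=float(s["concentration_mg_per_ml"]),
            cue_duration_ms=float(s["cue_duration_ms"]),
            schedule_kind=s["schedule_kind"])
    return ScheduleSettings(
        liquids=liquids,
        inter_poke_timeout_s=float(tbl.get("inter_poke_timeout_s", 3.0)),
        first_poke_window_s=float(tbl.get("first_poke_window_s", 3.0)))


def read_protocol(path: str | Path) -> ProtocolConfig:
    import tomllib
    path = Path(path)
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ProtocolError(f"{path}: {exc}") from exc
    head = data.get("protocol", {})
    stages = []
    for st in data.get("stage", []):
        stages.append(StageSpec(
            name=st["name"], day_start=int(st["day_start"]),
            day_end=int(st["day_end"]) if "day_end" in st else None,
            liquid_assignment=st["liquid_assignment"],
            settings=_settings_from_tables(st),
            swap_policy=st.get("swap_policy", "none"),
            cue_enabled=bool(st.get("cue_enabled", False))))
    overrides = {tag: _settings_from_tables(tbl)
                 for tag, tbl in data.get("override", {}).items()}
    return ProtocolConfig(
        stages=tuple(stages),
        lights_on_hour=int(head.get("lights_on_hour", 7)),
        experiment_start=head.get("experiment_start", "2024-01-01T07:00:00"),
        quinine_habituation=bool(head.get("quinine_habituation", True)),
        overrides=overrides)


# ---------------------------------------------------------------------------
# protocol-aware replay

def replay_protocol(events: Iterable[Event],
                    protocol: ProtocolConfig,
                    roster: Mapping[str, MouseIdentity],
                    pr_state: PRState | None = None) -> ReplayResult:
    """Replay a multi-day log, resolving each trial's contingency from the
    calendar day (lights-on boundary) on which it opens."""
    if (any(s.schedule_kind == "progressive"
            for st in protocol.stages for s in st.settings.liquids.values())
            and pr_state is None):
        pr_state = PRState.fresh(roster)

    def resolver(t: float, tag: str):
        return protocol.resolve(day_of(t), tag)

    return replay(events, roster, resolver, pr_state=pr_state)
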