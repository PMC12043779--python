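"""Trial state machine for RFID-gated fixed- and progressive-ratio schedules.

A trial opens when the RFID antenna over the entry tube identifies a mouse.
The mouse then has a first-poke window (default 3 s) to poke at an active
port; thereafter every inter-poke gap must stay strictly below the
inter-poke timeout (default 3 s) or the trial ends and a fresh RFID read
(exit and re-entry) is required.  Rewards are earned by accumulating
consecutive same-port pokes: under FR *n* every *n*-th valid poke at a port
delivers one drop of that port's liquid; under a progressive-ratio schedule
the requirement for a (mouse, liquid) pair starts at 1 and increments by
one after each reward of that liquid, individually per mouse.

Boundary and tie-break semantics, chosen once and applied everywhere:

* a poke qualifies iff its gap is strictly less than the timeout; a gap of
  exactly the timeout ends the trial;
* a poke at the other port does not end the trial — it starts a fresh
  streak of 1 at the new port, discarding the old port's progress;
* a reward resets its port's streak to 0, so FR *n* pays on pokes
  *n*, 2*n*, 3*n*, …;
* a repeated RFID read of the mouse already in the zone is ignored; a read
  of a different mouse closes the open trial (``displaced``) and opens a
  new one, keeping the engine total over arbitrary logs even though the
  tube physically admits one mouse.

``replay_log`` is a pure function of its inputs: replaying the same event
stream yields a byte-identical ledger and reward/cue stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import OrderingError, ProtocolError, UnknownTagError, ValidationError
from .events import (Event, MouseIdentity, Trial, TrialLedger, event_sort_key,
                     resolve_tag)

Contingency = tuple[Mapping[str, str], "ScheduleSettings"]
ContingencyResolver = Callable[[float, str], Contingency]


@dataclass(frozen=True)
class LiquidSchedule:
    """Reinforcement parameters for one liquid.

    ``ratio`` is the FR value, or the starting requirement under a
    progressive schedule.  ``cue_duration_ms > 0`` pairs each reward of
    this liquid with a port-light cue.
    """

    ratio: int = 1
    drop_volume_ul: float = 10.0
    concentration_mg_per_ml: float = 0.0
    cue_duration_ms: float = 0.0
    schedule_kind: str = "fixed"

    def __post_init__(self):
        if self.ratio < 1:
            raise ValidationError("ratio must be >= 1")
        if self.drop_volume_ul <= 0:
            raise ValidationError("drop_volume_ul must be positive")
        if self.schedule_kind not in ("fixed", "progressive"):
            raise ValidationError(f"unknown schedule_kind {self.schedule_kind!r}")


@dataclass(frozen=True)
class ScheduleSettings:
    """Per-mouse reinforcement settings: one LiquidSchedule per liquid plus
    the two 3-s windows (kept separately configurable)."""

    liquids: Mapping[str, LiquidSchedule]
    inter_poke_timeout_s: float = 3.0
    first_poke_window_s: float = 3.0

    def __post_init__(self):
        if self.inter_poke_timeout_s <= 0 or self.first_poke_window_s <= 0:
            raise ValidationError("timeouts must be positive")
        object.__setattr__(self, "liquids", dict(self.liquids))


class PRState:
    """Persistent per-(mouse, liquid) progressive-ratio requirement.

    Initialized to 1 for every registered pair; increments by exactly one
    per same-liquid reward and never resets within a session.
    """

    def __init__(self, requirements: Mapping[tuple[str, str], int] | None = None):
        self._req: dict[tuple[str, str], int] = dict(requirements or {})
        for key, v in self._req.items():
            if v < 1:
                raise ValidationError(f"PR requirement for {key} must be >= 1")

    @classmethod
    def fresh(cls, tags: Iterable[str],
              liquids: Sequence[str] = ("water", "fentanyl")) -> "PRState":
        return cls({(tag, liq): 1 for tag in tags for liq in liquids})

    def requirement(self, rfid_tag: str, liquid: str) -> int:
        try:
            return self._req[(rfid_tag, liquid)]
        except KeyError:
            raise UnknownTagError(
                f"no PR state for mouse {rfid_tag!r}, liquid {liquid!r}") from None

    def register_reward(self, rfid_tag: str, liquid: str) -> None:
        self.requirement(rfid_tag, liquid)  # raise on unknown key
        self._req[(rfid_tag, liquid)] += 1

    def as_dict(self) -> dict[tuple[str, str], int]:
        return dict(self._req)

    def copy(self) -> "PRState":
        return PRState(self._req)


def pr_next_requirement(pr_state: PRState, rfid_tag: str, liquid: str) -> int:
    """Current requirement for the next reward of ``liquid``; no side effect."""
    return pr_state.requirement(rfid_tag, liquid)


def pr_register_reward(pr_state: PRState, rfid_tag: str, liquid: str) -> PRState:
    """Increment exactly the (mouse, liquid) entry by one (in place)."""
    pr_state.register_reward(rfid_tag, liquid)
    return pr_state


@dataclass
class TrialContext:
    """Mutable state of one open trial."""

    mouse: MouseIdentity
    t_start: float
    t_last_event: float
    port_map: Mapping[str, str]
    settings: ScheduleSettings
    streak_port: str = "none"
    streak_count: int = 0
    pokes: list[tuple[float, str]] = field(default_factory=list)
    rewards: list[tuple[float, str, float]] = field(default_factory=list)


def check_timeout(ctx: TrialContext, t_now: float,
                  settings: ScheduleSettings | None = None) -> float | None:
    """Return the trial's end time if it has timed out by ``t_now``.

    The applicable window is the first-poke window while the trial has no
    pokes and the inter-poke timeout afterwards; a gap equal to the window
    ends the trial (only strictly shorter gaps qualify a poke).
    """
    settings = settings or ctx.settings
    window = (settings.first_poke_window_s if not ctx.pokes
              else settings.inter_poke_timeout_s)
    end = ctx.t_last_event + window
    return end if t_now >= end else None


def process_poke(ctx: TrialContext, poke: Event,
                 settings: ScheduleSettings | None = None,
                 pr_state: PRState | None = None) -> list[Event]:
    """Apply one qualifying poke to an open trial; return emitted events.

    The caller has already enforced the timeout.  A same-port poke extends
    the streak; a cross-port poke starts a fresh streak of 1 at the new
    port.  On reaching the active requirement the port's liquid is
    delivered (with its cue when configured) and the streak resets to 0.
    """
    settings = settings or ctx.settings
    tag = ctx.mouse.rfid_tag
    if poke.port == ctx.streak_port:
        ctx.streak_count += 1
    else:
        ctx.streak_port = poke.port
        ctx.streak_count = 1
    ctx.pokes.append((poke.t, poke.port))
    ctx.t_last_event = poke.t

    emitted: list[Event] = []
    liquid = ctx.port_map.get(poke.port)
    if liquid is not None:
        try:
            sched = settings.liquids[liquid]
        except KeyError:
            raise ProtocolError(
                f"no schedule for liquid {liquid!r} (mouse {tag!r})") from None
        if sched.schedule_kind == "progressive":
            if pr_state is None:
                raise ProtocolError("progressive schedule requires a PRState")
            requirement = pr_state.requirement(tag, liquid)
        else:
            requirement = sched.ratio
        if ctx.streak_count >= requirement:
            ctx.rewards.append((poke.t, liquid, sched.drop_volume_ul))
            emitted.append(Event(t=poke.t, kind="reward", rfid_tag=tag,
                                 port=poke.port, liquid=liquid,
                                 volume_ul=sched.drop_volume_ul))
            if sched.cue_duration_ms > 0:
                emitted.append(Event(t=poke.t, kind="cue_on", rfid_tag=tag,
                                     port=poke.port, liquid=liquid))
            ctx.streak_count = 0
            if sched.schedule_kind == "progressive":
                pr_state.register_reward(tag, liquid)
    return emitted


@dataclass(frozen=True)
class ReplayResult:
    """Outcome of replaying an event stream through the engine."""

    ledger: TrialLedger
    emitted: tuple[Event, ...]
    pr_state: PRState | None
    orphans: tuple[Event, ...]

    @property
    def rewards(self) -> tuple[Event, ...]:
        return tuple(ev for ev in self.emitted if ev.kind == "reward")


def _close(ctx: TrialContext, t_end: float, termination: str) -> Trial:
    return Trial(mouse=ctx.mouse, t_start=ctx.t_start,
                 t_end=max(t_end, ctx.t_start),
                 pokes=tuple(ctx.pokes), rewards=tuple(ctx.rewards),
                 termination=termination)


def _timeout_termination(ctx: TrialContext) -> str:
    return "gap_timeout" if ctx.pokes else "no_first_poke"


def replay(events: Iterable[Event],
           roster: Mapping[str, MouseIdentity],
           resolve_contingency: ContingencyResolver,
           pr_state: PRState | None = None) -> ReplayResult:
    """Core replay loop with a per-trial contingency resolver.

    ``resolve_contingency(t, tag)`` is evaluated once when a trial opens,
    which lets a multi-day protocol assign each trial the port/liquid map
    and settings of its calendar day.  Reward, cue and trial bookkeeping
    events present in the input are ignored and regenerated.
    """
    open_trials: dict[str, TrialContext] = {}
    trials: list[Trial] = []
    emitted: list[Event] = []
    orphans: list[Event] = []
    prev_t: float | None = None

    needs_pr = pr_state is not None
    local_pr = pr_state

    def ensure_pr() -> PRState:
        nonlocal local_pr
        if local_pr is None:
            local_pr = PRState.fresh(roster)
        return local_pr

    for ev in events:
        if prev_t is not None and ev.t < prev_t:
            raise OrderingError(f"event stream not time-sorted at t={ev.t}")
        prev_t = ev.t
        if ev.kind not in ("rfid_read", "poke"):
            continue
        mouse = resolve_tag(roster, ev.rfid_tag)
        cage = mouse.cage_id
        ctx = open_trials.get(cage)
        if ctx is not None:
            end = check_timeout(ctx, ev.t)
            if end is not None:
                trials.append(_close(ctx, end, _timeout_termination(ctx)))
                open_trials.pop(cage)
                ctx = None
        if ev.kind == "rfid_read":
            if ctx is None:
                port_map, settings = resolve_contingency(ev.t, ev.rfid_tag)
                open_trials[cage] = TrialContext(
                    mouse=mouse, t_start=ev.t, t_last_event=ev.t,
                    port_map=dict(port_map), settings=settings)
            elif ctx.mouse.rfid_tag != ev.rfid_tag:
                # physically rare: another mouse displaced the occupant
                trials.append(_close(ctx, ev.t, "displaced"))
                port_map, settings = resolve_contingency(ev.t, ev.rfid_tag)
                open_trials[cage] = TrialContext(
                    mouse=mouse, t_start=ev.t, t_last_event=ev.t,
                    port_map=dict(port_map), settings=settings)
            # repeated read of the occupant: ignored
        else:  # poke
            if ctx is None or ctx.mouse.rfid_tag != ev.rfid_tag:
                orphans.append(ev)
                continue
            uses_pr = any(s.schedule_kind == "progressive"
                          for s in ctx.settings.liquids.values())
            emitted.extend(process_poke(
                ctx, ev, pr_state=ensure_pr() if uses_pr else local_pr))
            needs_pr = needs_pr or uses_pr

    for cage in sorted(open_trials):
        ctx = open_trials[cage]
        end = ctx.t_last_event + (ctx.settings.first_poke_window_s if not ctx.pokes
                                  else ctx.settings.inter_poke_timeout_s)
        trials.append(_close(ctx, end, _timeout_termination(ctx)))

    return ReplayResult(ledger=TrialLedger(trials=tuple(trials)),
                        emitted=tuple(sorted(emitted, key=event_sort_key)),
                        pr_state=local_pr if needs_pr else None,
                        orphans=tuple(orphans))


def replay_log(events: Iterable[Event],
               port_map: Mapping[str, str],
               settings_per_mouse: Mapping[str, ScheduleSettings],
               roster: Mapping[str, MouseIdentity],
               pr_state: PRState | None = None) -> ReplayResult:
    """Replay an event stream under a single fixed contingency.

    ``port_map`` maps active ports to their liquids; ``settings_per_mouse``
    supplies each mouse's reinforcement parameters.  Pokes with no open
    trial for their mouse are counted as orphans, never rewarded.
    """
    def resolver(_t: float, tag: str) -> Contingency:
        try:
            settings = settings_per_mouse[tag]
        except KeyError:
            raise UnknownTagError(f"no settings for mouse {tag!r}") from None
        return port_map, settings

    return replay(events, roster, resolver, pr_state=pr_state)
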