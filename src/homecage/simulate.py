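"""Agent-based generator of group-housed cohort event logs.

Each simulated mouse is a small generative model of visit behavior:

* visits arrive from a piecewise-homogeneous Poisson process with a 12-h
  square-wave rate (lights-on at ``t = 0``): the light-phase rate is
  ``base_visit_rate`` visits/hour and the dark-phase rate is
  ``base_visit_rate * dark_light_rate_ratio`` — mice are nocturnal;
* after a visit the agent may immediately re-enter (probability
  ``intra_bout_revisit_rate`` per visit, short exponential gap), which
  produces the heavily clustered inter-trial-interval distribution seen in
  this kind of assay;
* within a visit the agent targets a geometric number of rewards (bout
  size) at its chosen port, picking the fentanyl port with an escalating
  daily probability;
* poke timing is a truncated normal strictly below the engine's 3-s
  timeout, and ``entrainment_fidelity`` is the probability that the poke
  sequence stops exactly on a reward multiple of the active ratio — a
  non-entrained visit undershoots, overshoots, or disengages early.

The simulator only fabricates RFID reads and pokes; every reward and cue
event in its output is produced by running that stream through the trial
engine, so stripping rewards/cues from a simulated log and replaying it
regenerates them exactly.

The ``inhibited`` phenotype models an experimental manipulation that
enlarges drug bouts without touching water intake: it raises the fentanyl
bout-continuation probability and lowers fentanyl-port entrainment
fidelity, leaving all water parameters unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .engine import PRState, ScheduleSettings
from .errors import ConfigError
from .events import Event, MouseIdentity, event_sort_key, merge_events
from .protocol import (SECONDS_PER_DAY, ProtocolConfig, pr_protocol,
                       replay_protocol)

_HALF_DAY = SECONDS_PER_DAY / 2.0
#: margin kept free at the end of each day so a visit never straddles the
#: lights-on day boundary (contingencies can change there)
_DAY_EDGE_MARGIN = 30.0
#: minimum idle gap enforced between successive occupants of the drinking zone
_OCCUPANCY_GAP = 0.05
_MAX_CHAIN = 30


@dataclass(frozen=True)
class AgentProfile:
    """Generative behavioral parameters of one simulated mouse.

    Rates are per hour; probabilities in [0, 1]; times in seconds.  Bout
    sizes are geometric with the given continuation probability (mean
    ``1/(1-p)`` rewards per rewarded visit).  Escalation is a linear
    per-day increment on the fentanyl choice probability and on the
    fentanyl bout-continuation probability, clipped to valid ranges.
    """

    base_visit_rate: float = 1.5          # light-phase visits/hour
    dark_light_rate_ratio: float = 3.0
    bout_continuation_water: float = 0.35
    bout_continuation_fentanyl: float = 0.45
    fentanyl_choice_prob: float = 0.55
    choice_escalation_per_day: float = 0.02
    bout_escalation_per_day: float = 0.01
    poke_interval_mean_s: float = 1.0
    poke_interval_jitter_s: float = 0.35
    entrainment_fidelity: float = 0.85        # fentanyl port
    entrainment_fidelity_water: float = 0.85  # water port
    intra_bout_revisit_rate: float = 0.6      # P(immediate re-entry)
    p_zero_poke_visit: float = 0.05
    pr_cap_fentanyl: int = 8                  # PR motivation caps
    pr_cap_water: int = 3
    phenotype: str = "control"

    def __post_init__(self):
        for name in ("bout_continuation_water", "bout_continuation_fentanyl",
                     "fentanyl_choice_prob", "entrainment_fidelity",
                     "entrainment_fidelity_water", "intra_bout_revisit_rate",
                     "p_zero_poke_visit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.base_visit_rate < 0 or self.dark_light_rate_ratio < 0:
            raise ConfigError("rates must be non-negative")
        if self.base_visit_rate * max(1.0, self.dark_light_rate_ratio) > 60.0:
            raise ConfigError("visit rate exceeds the physical density of "
                              "single-occupancy entries (> 60 visits/hour)")
        if self.phenotype not in ("control", "inhibited"):
            raise ConfigError(f"unknown phenotype {self.phenotype!r}")

    def choice_prob_on(self, day: int) -> float:
        return float(np.clip(self.fentanyl_choice_prob
                             + self.choice_escalation_per_day * (day - 1),
                             0.0, 0.98))

    def bout_continuation_on(self, day: int, liquid: str,
                             multiplier: float = 1.0) -> float:
        if liquid == "fentanyl":
            c = self.bout_continuation_fentanyl \
                + self.bout_escalation_per_day * (day - 1)
        else:
            c = self.bout_continuation_water
        if multiplier != 1.0:
            # scale the mean bout size 1/(1-c) by the cage multiplier
            c = 1.0 - (1.0 - c) / multiplier
        return float(np.clip(c, 0.0, 0.93))

    def fidelity(self, liquid: str) -> float:
        return (self.entrainment_fidelity if liquid == "fentanyl"
                else self.entrainment_fidelity_water)


def make_inhibited(profile: AgentProfile) -> AgentProfile:
    """Derive the inhibited phenotype: larger fentanyl bouts and reduced
    fentanyl-port entrainment; every water parameter is left unchanged."""
    return replace(
        profile,
        bout_continuation_fentanyl=min(0.9, profile.bout_continuation_fentanyl + 0.3),
        entrainment_fidelity=max(0.1, profile.entrainment_fidelity - 0.5),
        phenotype="inhibited")


@dataclass(frozen=True)
class CageConfig:
    """2–5 co-housed agents plus cage-level effect multipliers.

    ``visit_rate_multiplier`` scales every member's visit rate and
    ``bout_multiplier`` scales mean bout size (hence trial length),
    modelling the cage-specific behavioral profiles that make within-cage
    controls necessary.
    """

    cage_id: str
    members: tuple[tuple[MouseIdentity, AgentProfile], ...]
    visit_rate_multiplier: float = 1.0
    bout_multiplier: float = 1.0

    def __post_init__(self):
        if not 2 <= len(self.members) <= 5:
            raise ConfigError("a cage houses 2-5 mice")
        tags = [m.rfid_tag for m, _p in self.members]
        if len(set(tags)) != len(tags):
            raise ConfigError("duplicate rfid_tag within cage")
        for m, _p in self.members:
            if m.cage_id != self.cage_id:
                raise ConfigError(f"mouse {m.rfid_tag} assigned to cage "
                                  f"{m.cage_id!r}, expected {self.cage_id!r}")

    @property
    def roster(self) -> dict[str, MouseIdentity]:
        return {m.rfid_tag: m for m, _p in self.members}


def cohort_roster(cages: Iterable[CageConfig]) -> dict[str, MouseIdentity]:
    roster: dict[str, MouseIdentity] = {}
    for cage in cages:
        for tag, mouse in cage.roster.items():
            if tag in roster:
                raise ConfigError(f"duplicate rfid_tag {tag!r} across cages")
            roster[tag] = mouse
    return roster


def default_cohort(n_cages: int = 4, mice_per_cage: int = 4,
                   inhibited_per_cage: int = 0,
                   heterogeneous: bool = True,
                   profile: AgentProfile | None = None) -> list[CageConfig]:
    """Build a cohort of replicate cages.

    With ``heterogeneous=True`` (the default study conditions) members get
    a deterministic spread of visit rates and bout sizes — busy mice with
    short visits through infrequent visitors with long ones — and cages get
    distinct rate multipliers, reproducing individual and cage-specific
    behavioral profiles.  The last ``inhibited_per_cage`` members of each
    cage carry the inhibited phenotype and the ``experimental`` group
    label, co-housed with their controls.
    """
    if not 0 <= inhibited_per_cage <= mice_per_cage:
        raise ConfigError("inhibited_per_cage out of range")
    base = profile or AgentProfile()
    rate_spread = (0.5, 0.9, 1.3, 1.8, 1.0)
    bout_spread = (0.25, 0.08, -0.05, -0.15, 0.0)
    cage_mult = (0.8, 1.0, 1.2, 1.5)
    cages = []
    for i in range(n_cages):
        members = []
        for j in range(mice_per_cage):
            if heterogeneous:
                p = replace(
                    base,
                    base_visit_rate=base.base_visit_rate * rate_spread[j % 5],
                    bout_continuation_water=float(np.clip(
                        base.bout_continuation_water + bout_spread[j % 5], 0, 0.93)),
                    bout_continuation_fentanyl=float(np.clip(
                        base.bout_continuation_fentanyl + bout_spread[j % 5], 0, 0.93)))
            else:
                p = base
            inhibited = j >= mice_per_cage - inhibited_per_cage
            if inhibited:
                p = make_inhibited(p)
            tag = f"TAG{i:02d}{j:02d}"
            members.append((MouseIdentity(
                rfid_tag=tag, mouse_label=f"m{i}{j}",
                group="experimental" if inhibited else "control",
                cage_id=f"cage{i}"), p))
        cages.append(CageConfig(
            cage_id=f"cage{i}", members=tuple(members),
            visit_rate_multiplier=cage_mult[i % 4] if heterogeneous else 1.0))
    return cages


# ---------------------------------------------------------------------------
# randomness: one root seed, one independent substream per agent

def _tag_hash(rfid_tag: str) -> int:
    return int.from_bytes(hashlib.sha256(rfid_tag.encode()).digest()[:4], "big")


def agent_rng(seed: int, rfid_tag: str) -> np.random.Generator:
    """Deterministic per-agent substream: adding an agent to a cage never
    perturbs the draws of the others."""
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _tag_hash(rfid_tag)])))


# ---------------------------------------------------------------------------
# visit construction

@dataclass
class _Block:
    """One visit's raw events plus its would-be trial end time."""
    start: float
    events: list[Event]
    trial_end: float

    def shift(self, dt: float) -> "_Block":
        if dt == 0:
            return self
        return _Block(start=self.start + dt,
                      events=[replace(ev, t=ev.t + dt) for ev in self.events],
                      trial_end=self.trial_end + dt)


def _poke_times(t0: float, n: int, profile: AgentProfile,
                rng: np.random.Generator, timeout: float, window: float) -> np.ndarray:
    lo, hi = 0.15, min(timeout, window) - 0.2
    gaps = np.clip(rng.normal(profile.poke_interval_mean_s,
                              profile.poke_interval_jitter_s, size=n), lo, hi)
    return t0 + np.cumsum(gaps)


def _poke_total(R: int, n: int, fidelity: float,
                rng: np.random.Generator) -> int:
    """Total pokes emitted for a bout target of R rewards at ratio n."""
    if n == 1:
        return R
    if rng.random() < fidelity:
        return R * n
    u = rng.random()
    extra = int(rng.integers(1, n))
    if u < 0.4:
        return max(1, (R - 1) * n + extra)  # undershoot the final reward
    if u < 0.8:
        return R * n + extra                # overshoot past the last reward
    return extra                            # early disengage, no reward


def _visit_block(t0: float, mouse: MouseIdentity, profile: AgentProfile,
                 port_map: Mapping[str, str], settings: ScheduleSettings,
                 day: int, bout_multiplier: float,
                 rng: np.random.Generator) -> _Block:
    events = [Event(t=t0, kind="rfid_read", rfid_tag=mouse.rfid_tag)]
    window = settings.first_poke_window_s
    timeout = settings.inter_poke_timeout_s
    if rng.random() < profile.p_zero_poke_visit:
        return _Block(start=t0, events=events, trial_end=t0 + window)
    liquids = {liq: port for port, liq in port_map.items()}
    if "fentanyl" in liquids and "water" in liquids:
        liquid = ("fentanyl" if rng.random() < profile.choice_prob_on(day)
                  else "water")
    else:
        liquid = next(iter(liquids))
    port = liquids[liquid]
    sched = settings.liquids[liquid]
    if sched.schedule_kind != "fixed":
        raise ConfigError("simulate() drives fixed-ratio stages; use "
                          "simulate_pr_session for progressive schedules")
    c = profile.bout_continuation_on(day, liquid, bout_multiplier)
    R = int(rng.geometric(1.0 - c))
    total = _poke_total(R, sched.ratio, profile.fidelity(liquid), rng)
    times = _poke_times(t0, total, profile, rng, timeout, window)
    events.extend(Event(t=float(t), kind="poke", rfid_tag=mouse.rfid_tag,
                        port=port) for t in times)
    return _Block(start=t0, events=events,
                  trial_end=float(times[-1]) + timeout)


def _agent_day_blocks(mouse: MouseIdentity, profile: AgentProfile,
                      cage: CageConfig, day: int,
                      port_map: Mapping[str, str], settings: ScheduleSettings,
                      rng: np.random.Generator) -> list[_Block]:
    day0 = (day - 1) * SECONDS_PER_DAY
    day_end = day0 + SECONDS_PER_DAY - _DAY_EDGE_MARGIN
    lam_light = profile.base_visit_rate * cage.visit_rate_multiplier / 3600.0
    lam_dark = lam_light * profile.dark_light_rate_ratio
    starts = []
    for lam, lo in ((lam_light, 0.0), (lam_dark, _HALF_DAY)):
        n = rng.poisson(lam * _HALF_DAY)
        starts.extend(day0 + lo + np.sort(rng.uniform(0.0, _HALF_DAY, size=n)))
    blocks: list[_Block] = []
    for t0 in starts:
        chain = 0
        t = float(t0)
        while t < day_end - 60.0 and chain < _MAX_CHAIN:
            blk = _visit_block(t, mouse, profile, port_map, settings, day,
                               cage.bout_multiplier, rng)
            if blk.trial_end > day_end:
                break
            blocks.append(blk)
            chain += 1
            if rng.random() >= profile.intra_bout_revisit_rate:
                break
            t = blk.trial_end + 0.2 + float(rng.exponential(4.0))
    return blocks


def _enforce_occupancy(blocks: list[_Block], day_end: float | None = None
                       ) -> list[Event]:
    """Serialize visits through the single-occupancy drinking zone.

    Blocks are taken in start order; a visit that would begin while the
    zone is busy waits just past the previous trial's end, emulating the
    queue at the entry tube.
    """
    blocks.sort(key=lambda b: (b.start, b.events[0].rfid_tag))
    out: list[Event] = []
    busy_until = -np.inf
    for blk in blocks:
        s = max(blk.start, busy_until + _OCCUPANCY_GAP)
        blk = blk.shift(s - blk.start)
        if day_end is not None and blk.trial_end > day_end:
            continue  # queueing pushed the visit past the day edge: drop it
        busy_until = blk.trial_end
        out.extend(blk.events)
    return out


# ---------------------------------------------------------------------------
# public entry points

def simulate(cage: CageConfig, protocol: ProtocolConfig, n_days: int,
             seed: int) -> list[Event]:
    """Simulate one cage for ``n_days`` under an FR protocol.

    Returns the full merged event log (RFID reads and pokes as generated;
    rewards and cues emitted by the trial engine).  Reproducible given the
    seed.
    """
    if n_days <= 0:
        raise ConfigError("n_days must be positive")
    rngs = {m.rfid_tag: agent_rng(seed, m.rfid_tag) for m, _p in cage.members}
    raw: list[Event] = []
    for day in range(1, n_days + 1):
        blocks: list[_Block] = []
        for mouse, profile in cage.members:
            port_map, settings = protocol.resolve(day, mouse.rfid_tag)
            blocks.extend(_agent_day_blocks(
                mouse, profile, cage, day, port_map, settings,
                rngs[mouse.rfid_tag]))
        day_end = day * SECONDS_PER_DAY - 1.0
        raw.extend(_enforce_occupancy(blocks, day_end=day_end))
    raw.sort(key=event_sort_key)
    result = replay_protocol(raw, protocol, cage.roster)
    return merge_events(raw, result.emitted)


def simulate_cohort(cages: Sequence[CageConfig], protocol: ProtocolConfig,
                    n_days: int, seed: int) -> list[Event]:
    """Simulate independent replicate cages and merge their logs."""
    cohort_roster(cages)  # tag-uniqueness check
    return merge_events(*(simulate(cage, protocol, n_days, seed)
                          for cage in cages))


def simulate_pr_session(cage: CageConfig, seed: int,
                        session_length_s: float = 4 * 3600.0,
                        protocol: ProtocolConfig | None = None) -> list[Event]:
    """Simulate one progressive-ratio session under a deterministic
    motivation-cap model.

    Each agent keeps visiting as long as some liquid's current requirement
    is within its per-liquid cap; at each such visit it completes the
    requirement exactly (so the engine increments it) and it stops earning
    a liquid once the requirement would exceed the cap.  The breakpoint
    recovered by analysis therefore equals the configured cap.
    """
    protocol = protocol or pr_protocol()
    stage = protocol.stages[0]
    port_map = stage.port_map_on(1)
    settings = stage.settings
    liquids = {liq: port for port, liq in port_map.items()}
    blocks: list[_Block] = []
    for mouse, profile in cage.members:
        rng = agent_rng(seed, mouse.rfid_tag)
        caps = {"fentanyl": profile.pr_cap_fentanyl,
                "water": profile.pr_cap_water}
        req = {"fentanyl": 1, "water": 1}
        t = 10.0 + float(rng.exponential(30.0))
        while t < session_length_s:
            attainable = [liq for liq in ("fentanyl", "water")
                          if req[liq] <= caps[liq]]
            if not attainable:
                break
            liquid = attainable[int(rng.integers(len(attainable)))]
            n = req[liquid]
            events = [Event(t=t, kind="rfid_read", rfid_tag=mouse.rfid_tag)]
            times = _poke_times(t, n, profile, rng,
                                settings.inter_poke_timeout_s,
                                settings.first_poke_window_s)
            events.extend(Event(t=float(pt), kind="poke",
                                rfid_tag=mouse.rfid_tag, port=liquids[liquid])
                          for pt in times)
            end = float(times[-1]) + settings.inter_poke_timeout_s
            blocks.append(_Block(start=t, events=events, trial_end=end))
            req[liquid] += 1
            t = end + 5.0 + float(rng.exponential(30.0))
    raw = _enforce_occupancy(blocks)
    raw.sort(key=event_sort_key)
    result = replay_protocol(raw, protocol, cage.roster,
                             pr_state=PRState.fresh(cage.roster))
    return merge_events(raw, result.emitted)
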