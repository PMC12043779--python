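import pytest

from homecage.engine import LiquidSchedule, ScheduleSettings
from homecage.events import Event, MouseIdentity


@pytest.fixture
def roster():
    """Two mice in one cage plus one in a second cage."""
    mice = [
        MouseIdentity("TAGA", "m1", "control", "cageX"),
        MouseIdentity("TAGB", "m2", "experimental", "cageX"),
        MouseIdentity("TAGC", "m3", "control", "cageY"),
    ]
    return {m.rfid_tag: m for m in mice}


def fr_settings(ratio: int, cue: bool = False) -> ScheduleSettings:
    return ScheduleSettings(liquids={
        "water": LiquidSchedule(ratio=ratio),
        "fentanyl": LiquidSchedule(ratio=ratio, concentration_mg_per_ml=0.1,
                                   cue_duration_ms=500.0 if cue else 0.0),
    })


def pr_settings() -> ScheduleSettings:
    return ScheduleSettings(liquids={
        "water": LiquidSchedule(ratio=1, schedule_kind="progressive"),
        "fentanyl": LiquidSchedule(ratio=1, schedule_kind="progressive",
                                   concentration_mg_per_ml=0.1),
    })


PORT_MAP = {"left": "fentanyl", "right": "water"}


def read(t, tag="TAGA"):
    return Event(t=t, kind="rfid_read", rfid_tag=tag)


def poke(t, port="left", tag="TAGA"):
    return Event(t=t, kind="poke", rfid_tag=tag, port=port)
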