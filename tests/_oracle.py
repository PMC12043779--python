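"""Independent brute-force reward scanner used to cross-check the engine.

Deliberately structured differently from the engine: phase 1 segments the
raw stream into visits with a simple per-cage walk; phase 2 re-derives
rewards per visit from scratch with a streak counter over the poke list.
Fixed-ratio only.
"""

from collections import defaultdict

import numpy as np

from homecage.events import Event, MouseIdentity


def oracle_rewards(events, port_map, ratios, roster,
                   timeout=3.0, window=3.0):
    """Return [(t, tag, liquid), ...] rewards the schedule should emit."""
    visits = []
    current = {}

    def flush(cage):
        v = current.pop(cage, None)
        if v is not None:
            visits.append(v)

    for ev in events:
        if ev.kind not in ("rfid_read", "poke"):
            continue
        cage = roster[ev.rfid_tag].cage_id
        v = current.get(cage)
        if v is not None:
            limit = v["last_t"] + (timeout if v["pokes"] else window)
            if ev.t >= limit:
                flush(cage)
                v = None
        if ev.kind == "rfid_read":
            if v is None:
                current[cage] = {"tag": ev.rfid_tag, "last_t": ev.t, "pokes": []}
            elif v["tag"] != ev.rfid_tag:
                flush(cage)
                current[cage] = {"tag": ev.rfid_tag, "last_t": ev.t, "pokes": []}
        else:
            if v is not None and v["tag"] == ev.rfid_tag:
                v["pokes"].append((ev.t, ev.port))
                v["last_t"] = ev.t
    for cage in list(current):
        flush(cage)

    rewards = []
    for v in visits:
        port, count = None, 0
        for t, p in v["pokes"]:
            if p == port:
                count += 1
            else:
                port, count = p, 1
            liq = port_map.get(p)
            if liq is not None and count == ratios[liq]:
                rewards.append((t, v["tag"], liq))
                count = 0
    rewards.sort()
    return rewards


def fuzz_stream(rng: np.random.Generator):
    """A random rfid/poke stream with gaps straddling the 3-s boundary."""
    mice = [MouseIdentity("F1", "f1", "control", "cage1"),
            MouseIdentity("F2", "f2", "control", "cage1"),
            MouseIdentity("F3", "f3", "experimental", "cage2")]
    roster = {m.rfid_tag: m for m in mice}
    tags = list(roster)
    gaps = np.array([0.1, 0.5, 1.0, 2.0, 2.9, 2.999, 3.0, 3.001, 3.5, 8.0])
    t = float(rng.uniform(0, 5))
    events = []
    for _ in range(int(rng.integers(5, 45))):
        t += float(gaps[rng.integers(len(gaps))])
        tag = tags[rng.integers(len(tags))]
        if rng.random() < 0.35:
            events.append(Event(t=t, kind="rfid_read", rfid_tag=tag))
        else:
            port = "left" if rng.random() < 0.5 else "right"
            events.append(Event(t=t, kind="poke", rfid_tag=tag, port=port))
    return events, roster
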