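"""Behavioral readouts computed from a trial ledger.

Every metric is a pure function of (ledger, protocol): daily intake and
escalation slopes, circadian visit/consumption profiles, inter-trial
interval distributions, bout-size CDFs, reward efficiency, pokes-per-trial
histograms with an entrainment score, visit-count/trial-length profiles
with an exponential-decay fit, progressive-ratio breakpoints, and
two-group comparisons (two-sample KS on poke distributions, paired test on
breakpoints, Bonferroni across FR stages).

Conventions: "daily" metrics use the lights-on day boundary, so a full
dark phase is never split.  A visit is any RFID-initiated trial, including
zero-poke entries; they count in visit totals and in the denominator of
reward efficiency.  Fentanyl mass is reward volume times the concentration
of the stage active on the reward's day.  Fentanyl preference is the
fentanyl fraction of total consumed volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import PRState
from .errors import FitError, InsufficientDataError, MetricError
from .events import Event, TrialLedger
from .protocol import SECONDS_PER_DAY, ProtocolConfig, day_of


def trials_frame(ledger: TrialLedger) -> pd.DataFrame:
    """Tidy per-trial table: one row per visit with counts and volumes."""
    rows = []
    for tr in ledger:
        rows.append({
            "rfid_tag": tr.mouse.rfid_tag,
            "mouse_label": tr.mouse.mouse_label,
            "group": tr.mouse.group,
            "cage_id": tr.mouse.cage_id,
            "t_start": tr.t_start,
            "t_end": tr.t_end,
            "duration_s": tr.duration,
            "day": day_of(tr.t_start),
            "n_pokes": tr.n_pokes,
            "n_rewards": tr.n_rewards,
            "rewards_fentanyl": tr.rewards_of("fentanyl"),
            "rewards_water": tr.rewards_of("water"),
            "fentanyl_ul": tr.volume_of("fentanyl"),
            "water_ul": tr.volume_of("water"),
            "termination": tr.termination,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# daily intake and escalation

def daily_intake(ledger: TrialLedger, protocol: ProtocolConfig,
                 n_days: int | None = None) -> pd.DataFrame:
    """Per mouse-day intake and visit statistics.

    Days with no trials yield explicit zero-intake rows.  Fentanyl mass in
    mg uses the concentration of the stage active on each day.
    """
    df = trials_frame(ledger)
    if df.empty:
        raise MetricError("empty ledger")
    mice = sorted(ledger.mice)
    groups = {tr.mouse.rfid_tag: tr.mouse.group for tr in ledger}
    if n_days is None:
        n_days = int(df["day"].max())
    rows = []
    for tag in mice:
        sub = df[df["rfid_tag"] == tag]
        for day in range(1, n_days + 1):
            d = sub[sub["day"] == day]
            _pm, settings = protocol.resolve(day, tag)
            fent = settings.liquids.get("fentanyl")
            conc = fent.concentration_mg_per_ml if fent is not None else 0.0
            fent_ul = float(d["fentanyl_ul"].sum())
            n_visits = int(len(d))
            rewarded = int((d["n_rewards"] > 0).sum())
            rows.append({
                "rfid_tag": tag,
                "group": groups[tag],
                "day": day,
                "fentanyl_ul": fent_ul,
                "fentanyl_mg": fent_ul * conc / 1000.0,
                "water_ul": float(d["water_ul"].sum()),
                "visit_count": n_visits,
                "mean_trial_length_s": (float(d["duration_s"].mean())
                                        if n_visits else float("nan")),
                "reward_efficiency": (rewarded / n_visits
                                      if n_visits else float("nan")),
                "rewards_per_visit": d["n_rewards"].tolist(),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SlopeResult:
    slope: float            # mg/day
    intercept: float
    stderr: float
    ci_low: float
    ci_high: float
    n_days: int


def escalation_slope(daily: pd.DataFrame, rfid_tag: str,
                     day_range: tuple[int, int] | None = None) -> SlopeResult:
    """Per-mouse ordinary-least-squares slope of daily fentanyl mass.

    ``day_range`` (inclusive) restricts the fit, e.g. to the choice phase.
    Requires at least 3 days.
    """
    sub = daily[daily["rfid_tag"] == rfid_tag]
    if day_range is not None:
        sub = sub[(sub["day"] >= day_range[0]) & (sub["day"] <= day_range[1])]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"escalation slope needs >= 3 days, got {len(sub)}")
    x = sub["day"].to_numpy(dtype=float)
    y = sub["fentanyl_mg"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return SlopeResult(0.0, float(y[0]), 0.0, 0.0, 0.0, len(sub))
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(sub) - 2)
    return SlopeResult(slope=float(res.slope), intercept=float(res.intercept),
                       stderr=float(res.stderr),
                       ci_low=float(res.slope - tcrit * res.stderr),
                       ci_high=float(res.slope + tcrit * res.stderr),
                       n_days=len(sub))


def fentanyl_preference(daily: pd.DataFrame) -> pd.DataFrame:
    """Daily fentanyl volume fraction of total consumed volume per mouse."""
    out = daily[["rfid_tag", "day", "fentanyl_ul", "water_ul"]].copy()
    total = out["fentanyl_ul"] + out["water_ul"]
    out["preference"] = np.where(total > 0, out["fentanyl_ul"] / total,
                                 float("nan"))
    return out


# ---------------------------------------------------------------------------
# circadian profile

def hourly_profile(ledger: TrialLedger, lights_on_hour: int = 7
                   ) -> tuple[pd.DataFrame, dict]:
    """24-bin hour-of-day visit and consumption profile plus phase totals.

    The experiment clock starts at lights-on (log-header convention), so
    hours 0-11 of each day are the light phase and 12-23 the dark phase;
    ``hour`` reports the wall-clock hour.  Returns (per-mouse profile,
    summary) where the summary carries pooled light/dark visit totals and
    the dark-phase visit share.
    """
    df = trials_frame(ledger)
    if df.empty:
        raise MetricError("empty ledger")
    n_days = max(1, int(df["day"].max()))
    df = df.assign(hour_rel=((df["t_start"] % SECONDS_PER_DAY) // 3600).astype(int))
    df["hour"] = (df["hour_rel"] + lights_on_hour) % 24
    df["phase"] = np.where(df["hour_rel"] < 12, "light", "dark")
    grid = pd.MultiIndex.from_product(
        [sorted(ledger.mice), range(24)], names=["rfid_tag", "hour_rel"])
    prof = (df.groupby(["rfid_tag", "hour_rel"])
              .agg(visits=("t_start", "size"),
                   fentanyl_ul=("fentanyl_ul", "sum"),
                   water_ul=("water_ul", "sum"))
              .reindex(grid, fill_value=0)
              .reset_index())
    prof["hour"] = (prof["hour_rel"] + lights_on_hour) % 24
    prof["phase"] = np.where(prof["hour_rel"] < 12, "light", "dark")
    prof["visits_per_day"] = prof["visits"] / n_days
    dark = int(df[df["phase"] == "dark"].shape[0])
    total = int(df.shape[0])
    summary = {
        "n_days": n_days,
        "light_visits": total - dark,
        "dark_visits": dark,
        "dark_visit_share": dark / total if total else float("nan"),
        "dark_fentanyl_ul": float(df.loc[df["phase"] == "dark", "fentanyl_ul"].sum()),
        "light_fentanyl_ul": float(df.loc[df["phase"] == "light", "fentanyl_ul"].sum()),
    }
    return prof, summary


# ---------------------------------------------------------------------------
# inter-trial intervals

@dataclass(frozen=True)
class ITIResult:
    itis: np.ndarray          # seconds, strictly positive
    bin_edges: np.ndarray     # logarithmic bins
    counts: np.ndarray
    median: float


def iti_distribution(ledger: TrialLedger, rfid_tag: str | None = None,
                     n_bins: int = 30) -> ITIResult:
    """Per-mouse inter-trial intervals (next start minus current end),
    log-binned; with ``rfid_tag=None`` all mice are pooled (the intervals
    are still computed within mouse)."""
    tags = [rfid_tag] if rfid_tag is not None else list(ledger.mice)
    itis: list[float] = []
    for tag in tags:
        trs = ledger.for_mouse(tag)
        for a, b in zip(trs, trs[1:]):
            gap = b.t_start - a.t_end
            if gap > 0:
                itis.append(gap)
    arr = np.asarray(itis, dtype=float)
    if arr.size == 0:
        return ITIResult(itis=arr, bin_edges=np.array([]),
                         counts=np.array([]), median=float("nan"))
    lo = max(arr.min() * 0.9, 1e-3)
    hi = arr.max() * 1.1
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    counts, edges = np.histogram(arr, bins=edges)
    return ITIResult(itis=arr, bin_edges=edges, counts=counts,
                     median=float(np.median(arr)))


# ---------------------------------------------------------------------------
# bout microstructure

def bout_size_cdf(ledger: TrialLedger, liquid: str,
                  group: str | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative distribution of consumption by bout size.

    A bout is the rewards of ``liquid`` obtained within one visit; the CDF
    value at x is the fraction of all rewards of that liquid consumed in
    bouts of size <= x.  Monotone, terminal value 1.  Returns (sizes,
    cumulative fraction); both empty if the liquid never rewarded.
    """
    sizes = bout_sizes(ledger, liquid, group=group)
    if sizes.size == 0:
        return np.array([], dtype=int), np.array([])
    xs = np.unique(sizes)
    weights = np.array([(sizes[sizes == x]).sum() for x in xs], dtype=float)
    cdf = np.cumsum(weights) / sizes.sum()
    return xs, cdf


def bout_sizes(ledger: TrialLedger, liquid: str,
               group: str | None = None) -> np.ndarray:
    """Rewards-per-visit of one liquid over all rewarded visits."""
    out = []
    for tr in ledger:
        if group is not None and tr.mouse.group != group:
            continue
        k = tr.rewards_of(liquid)
        if k > 0:
            out.append(k)
    return np.asarray(out, dtype=int)


def reward_efficiency(ledger: TrialLedger, rfid_tag: str, day: int) -> float:
    """Probability that a visit on ``day`` yielded at least one reward.

    Zero-poke visits count in the denominator.  Returns NaN (flagged
    missing) for a day without visits.
    """
    trs = [tr for tr in ledger.for_mouse(rfid_tag) if day_of(tr.t_start) == day]
    if not trs:
        return float("nan")
    return sum(1 for tr in trs if tr.n_rewards > 0) / len(trs)


def pokes_per_trial_distribution(ledger: TrialLedger, liquid: str, fr: int,
                                 protocol: ProtocolConfig
                                 ) -> tuple[pd.Series, float]:
    """Histogram of pokes per trial at the port serving ``liquid`` under a
    given FR, plus the entrainment score.

    Because the liquid/side assignment swaps daily, the relevant port is
    resolved per trial day.  Trials are kept when the day's schedule for
    the liquid runs at the requested ratio and the trial has at least one
    poke at that port.  The entrainment score is the fraction of those
    trials whose poke count is an exact positive multiple of the ratio —
    1.0 for a perfectly schedule-entrained animal, and trivially 1.0 at
    FR1.
    """
    counts = poke_counts(ledger, liquid, fr, protocol)
    if counts.size == 0:
        return pd.Series(dtype=float), float("nan")
    hist = pd.Series(counts).value_counts().sort_index()
    prob = hist / hist.sum()
    score = float(np.mean(counts % fr == 0))
    return prob, score


def poke_counts(ledger: TrialLedger, liquid: str, fr: int,
                protocol: ProtocolConfig,
                group: str | None = None) -> np.ndarray:
    """Pokes per trial at the liquid's port for trials run at ratio ``fr``."""
    out = []
    for tr in ledger:
        if group is not None and tr.mouse.group != group:
            continue
        day = day_of(tr.t_start)
        port_map, settings = protocol.resolve(day, tr.mouse.rfid_tag)
        sched = settings.liquids.get(liquid)
        if sched is None or sched.ratio != fr:
            continue
        ports = [p for p, liq in port_map.items() if liq == liquid]
        if not ports:
            continue
        c = tr.pokes_at(ports[0])
        if c > 0:
            out.append(c)
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# visit-count / trial-length profile

@dataclass(frozen=True)
class DecayFit:
    a: float
    b: float
    c: float
    r_squared: float


def visit_profile_fit(points: pd.DataFrame, offset: bool = False) -> DecayFit:
    """Fit mean trial length as a decaying exponential of daily visit count.

    ``points`` needs columns ``visit_count`` and ``mean_trial_length_s``
    (one row per mouse-day, as produced by :func:`daily_intake`).  The
    model is ``duration = a * exp(-b * count)`` with ``a, b >= 0``, plus an
    optional offset ``c``.  Reports R-squared on the fitted scale; for
    degenerate constant data (zero variance) R-squared is defined as 0.
    """
    pts = points[["visit_count", "mean_trial_length_s"]].dropna()
    if len(pts) < 5:
        raise InsufficientDataError("decay fit needs >= 5 points")
    x = pts["visit_count"].to_numpy(dtype=float)
    y = pts["mean_trial_length_s"].to_numpy(dtype=float)

    if offset:
        def model(x, a, b, c):
            return a * np.exp(-b * x) + c
        p0 = [max(y.max() - y.min(), 1e-6), 1.0 / max(x.mean(), 1.0), y.min()]
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
    else:
        def model(x, a, b):
            return a * np.exp(-b * x)
        p0 = [max(y.max(), 1e-6), 1.0 / max(x.mean(), 1.0)]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    try:
        popt, _pcov = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds,
                                         maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"decay fit did not converge: {exc}; n={len(pts)}, "
                       f"x range [{x.min()}, {x.max()}], "
                       f"y range [{y.min()}, {y.max()}]") from exc
    resid = y - model(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    a, b = float(popt[0]), float(popt[1])
    c = float(popt[2]) if offset else 0.0
    return DecayFit(a=a, b=b, c=c, r_squared=r2)


# ---------------------------------------------------------------------------
# progressive ratio

@dataclass(frozen=True)
class BreakpointResult:
    table: pd.DataFrame       # per-mouse breakpoint_water / breakpoint_fentanyl
    t_statistic: float        # paired t, fentanyl vs water
    p_value: float


def pr_breakpoint(ledger: TrialLedger,
                  pr_state: PRState | None = None) -> BreakpointResult:
    """Per-(mouse, liquid) breakpoint: the highest requirement completed.

    Under a progressive schedule starting at 1 with unit increments per
    same-liquid reward, the breakpoint equals the number of rewards of
    that liquid; 0 if never rewarded.  When the session's final
    :class:`PRState` is supplied, the ledger is cross-checked against it —
    a mismatch means the ledger was not produced under progressive-ratio
    bookkeeping and is rejected.  The paired comparison is a paired t-test
    of fentanyl vs water breakpoints across mice.
    """
    rows = []
    for tag in sorted(ledger.mice):
        trs = ledger.for_mouse(tag)
        counts = {"water": 0, "fentanyl": 0}
        for tr in trs:
            for liq in counts:
                counts[liq] += tr.rewards_of(liq)
        if pr_state is not None:
            for liq, k in counts.items():
                expected = pr_state.requirement(tag, liq)
                if expected != k + 1:
                    raise MetricError(
                        f"ledger is not a progressive-ratio session: mouse "
                        f"{tag!r} has {k} {liq} rewards but final "
                        f"requirement {expected}")
        rows.append({"rfid_tag": tag,
                     "breakpoint_water": counts["water"],
                     "breakpoint_fentanyl": counts["fentanyl"]})
    table = pd.DataFrame(rows)
    diff = (table["breakpoint_fentanyl"] - table["breakpoint_water"]).to_numpy(float)
    if len(table) < 2 or not diff.any():
        tstat, p = float("nan"), float("nan")
    elif np.ptp(diff) == 0:
        # constant paired difference: the t statistic degenerates
        tstat, p = float(np.sign(diff[0]) * np.inf), 0.0
    else:
        res = stats.ttest_rel(table["breakpoint_fentanyl"],
                              table["breakpoint_water"])
        tstat, p = float(res.statistic), float(res.pvalue)
    return BreakpointResult(table=table, t_statistic=tstat, p_value=p)


# ---------------------------------------------------------------------------
# group comparison

def group_compare(control: Sequence[float], experimental: Sequence[float],
                  paired: bool = False) -> tuple[float, float]:
    """Two-group test: two-sample KS (unpaired) or paired t-test.

    Returns (statistic, p-value); groups need at least 2 observations.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(experimental, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MetricError("each group needs >= 2 observations")
    if paired:
        if a.size != b.size:
            raise MetricError("paired comparison requires equal sizes")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_poke_distributions(ledger: TrialLedger, protocol: ProtocolConfig,
                               liquid: str = "fentanyl",
                               fr_values: Sequence[int] = (1, 3, 5)
                               ) -> pd.DataFrame:
    """KS comparison of control vs experimental pokes-per-trial counts at
    the liquid's port, one row per FR stage, Bonferroni-corrected across
    the stages tested."""
    rows = []
    for fr in fr_values:
        a = poke_counts(ledger, liquid, fr, protocol, group="control")
        b = poke_counts(ledger, liquid, fr, protocol, group="experimental")
        if a.size < 2 or b.size < 2:
            raise MetricError(f"FR{fr}: a group has < 2 trials")
        stat, p = group_compare(a, b)
        rows.append({"fr": fr, "ks_statistic": stat, "p_value": p,
                     "n_control": a.size, "n_experimental": b.size})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


# ---------------------------------------------------------------------------
# conservation checks

def total_reward_volume(ledger: TrialLedger, liquid: str) -> float:
    return float(sum(tr.volume_of(liquid) for tr in ledger))


def reward_event_volume(events: Iterable[Event], liquid: str) -> float:
    return float(sum(ev.volume_ul for ev in events
                     if ev.kind == "reward" and ev.liquid == liquid))
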