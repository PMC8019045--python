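"""Male dispersal timing and its association consequences.

A dispersal event is dated by a last-seen-origin / first-seen-destination
range; its month is the calendar month containing the most days of that
range (ties to the earlier month). Monthly male-transfer counts are
correlated with ecological series by Spearman rank correlation with
Monte-Carlo permutation p-values (robust to the many tied zero-count
months), Bonferroni-corrected over the ecological predictors.

Whether units keep associating after males transfer between them is tested
per event and post-dispersal month (offsets 1-3): the dispersal dyad's AI
in the offset month is compared against the baseline AIs each involved
unit had with its other associates during the transfer month, using an
exact one-sample Wilcoxon signed-rank test (one-sided: dyad higher).
"""

from __future__ import annotations

import datetime as dt
import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import days_in_month, month_add, month_of, month_range, parse_month
from .association import dyad_counts, simple_ai, unit_presence
from .io import DispersalEvent, ScanRecord

log = logging.getLogger("multisoc")

__all__ = [
    "assign_dispersal_month",
    "monthly_transfer_counts",
    "spearman_mc",
    "bonferroni",
    "post_dispersal_dyad_ai",
    "baseline_ais",
    "wilcoxon_one_sample",
    "post_dispersal_analysis",
    "PostDispersalComparison",
]


def assign_dispersal_month(event: DispersalEvent) -> str:
    """Month with the most potential dispersal days in the event's date
    range (inclusive); ties break toward the earlier month."""
    start, end = event.last_seen_origin, event.first_seen_destination
    counts: dict[str, int] = {}
    for m in month_range(month_of(start), month_of(end)):
        y, mo = parse_month(m)
        first = dt.date(y, mo, 1)
        last = dt.date(y, mo, days_in_month(y, mo))
        lo, hi = max(first, start), min(last, end)
        counts[m] = (hi - lo).days + 1
    best = max(counts.values())
    return min(m for m, c in counts.items() if c == best)


def monthly_transfer_counts(
    events: Sequence[DispersalEvent], span: tuple[str, str]
) -> dict:
    """Per-month count of dispersing males over an inclusive (first, last)
    year-month span, zero-filled; each male in a parallel transfer counts;
    females are excluded."""
    counts = {m: 0 for m in month_range(*span)}
    for e in events:
        if e.sex != "male":
            continue
        m = e.assigned_month or assign_dispersal_month(e)
        if m in counts:
            counts[m] += 1
        else:
            log.warning("dispersal of %s in %s falls outside span", e.individual_id, m)
    return counts


def spearman_mc(
    x: Sequence[float],
    y: Sequence[float],
    n_mc: int = 10_000,
    seed=None,
) -> tuple[float, float]:
    """Spearman rho (mid-ranks) with a Monte-Carlo two-sided p-value.

    p is the add-one fraction of random permutations of y whose |rho|
    reaches |rho_obs| — robust when ties make the asymptotic null poor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("series must have equal length >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a series; rho undefined")
    rho_obs = float(stats.spearmanr(x, y).statistic)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def rho_of(ry_perm):
        return float(np.corrcoef(rx, ry_perm)[0, 1])

    k = 0
    tol = 1e-12
    for _ in range(n_mc):
        if abs(rho_of(rng.permutation(ry))) >= abs(rho_obs) - tol:
            k += 1
    return rho_obs, (k + 1) / (n_mc + 1)


def bonferroni(alpha: float = 0.05, m: int = 3) -> float:
    """Bonferroni-corrected alpha, rounded to 3 decimals for display
    (0.05 over 3 comparisons displays as 0.017)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(alpha / m, 3)


def _month_bounds(month: str) -> tuple[dt.date, dt.date]:
    y, m = parse_month(month)
    return dt.date(y, m, 1), dt.date(y, m, days_in_month(y, m))


def _month_scans(scans: Sequence[ScanRecord], month: str) -> list[ScanRecord]:
    lo, hi = _month_bounds(month)
    return [s for s in scans if lo <= s.date <= hi]


def post_dispersal_dyad_ai(
    event: DispersalEvent, scans: Sequence[ScanRecord], month_offset: int
) -> float:
    """Simple AI of the dispersal dyad restricted to the calendar month
    ``assigned_month + offset``; NaN when that month has no scans."""
    if month_offset < 1:
        raise ValueError("month_offset must be >= 1")
    month = month_add(event.assigned_month or assign_dispersal_month(event), month_offset)
    mscans = _month_scans(scans, month)
    if not mscans:
        return float("nan")
    return simple_ai(dyad_counts(mscans, event.from_unit, event.to_unit))


def baseline_ais(
    event: DispersalEvent,
    scans: Sequence[ScanRecord],
    eval_month: str | None = None,
) -> list[float]:
    """Baseline AIs for an event: for each of the origin and destination
    units, the AI (in ``eval_month``, default the transfer month) with
    every third unit that unit associated with (AI > 0) during the
    transfer month. The dispersal dyad itself is excluded; the pooled list
    is returned (empty when neither unit had other associates)."""
    transfer_month = event.assigned_month or assign_dispersal_month(event)
    tscans = _month_scans(scans, transfer_month)
    if not tscans:
        return []
    eval_scans = tscans if eval_month is None else _month_scans(scans, eval_month)
    roster = set()
    for s in tscans:
        roster |= unit_presence(s)
    out: list[float] = []
    pair = {event.from_unit, event.to_unit}
    for member in (event.from_unit, event.to_unit):
        for other in sorted(roster - pair):
            ai_transfer = simple_ai(dyad_counts(tscans, member, other))
            if not (np.isfinite(ai_transfer) and ai_transfer > 0):
                continue
            if eval_scans:
                ai_eval = simple_ai(dyad_counts(eval_scans, member, other))
                if np.isfinite(ai_eval):
                    out.append(ai_eval)
    return out


def wilcoxon_one_sample(
    baseline: Sequence[float], dyad_ai: float, exact_max_n: int = 15
) -> float:
    """One-sided one-sample Wilcoxon signed-rank p for H1: the baselines
    sit *below* the dyad value (the dyad associates more than baseline).

    Differences d_i = dyad_ai - baseline_i; zeros dropped; |d| mid-ranked.
    Exact enumeration of all sign assignments up to ``exact_max_n``
    non-zero differences, tie-corrected normal approximation (with
    continuity correction) above.
    """
    d = dyad_ai - np.asarray(baseline, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        count = 0
        total = 2**n
        for signs in itertools.product((0, 1), repeat=n):
            w = float(sum(r for s, r in zip(signs, ranks) if s))
            if w >= w_obs - 1e-12:
                count += 1
        return count / total
    mu = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(tie_counts**3 - tie_counts) / 48
    z = (w_obs - mu - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


@dataclass(frozen=True)
class PostDispersalComparison:
    event_id: str
    from_unit: str
    to_unit: str
    month_offset: int  # 1..3
    dyad_ai: float
    baseline_ais: tuple
    p_value: float
    significant: bool | None  # None when the comparison could not run


def post_dispersal_analysis(
    events: Sequence[DispersalEvent],
    scans: Sequence[ScanRecord],
    alpha: float = 0.05,
    max_offset: int = 3,
) -> list[PostDispersalComparison]:
    """Dyad-vs-baseline comparisons for each event and offset month 1..3.

    Parallel transfers (same origin, destination, and assigned month) are
    collapsed to one dyadic event. Offsets past the data, empty control
    sets, and too-few non-zero differences yield a comparison flagged with
    ``significant=None``.
    """
    dyadic: dict[tuple, DispersalEvent] = {}
    for e in events:
        month = e.assigned_month or assign_dispersal_month(e)
        key = (e.from_unit, e.to_unit, month)
        if key not in dyadic:
            dyadic[key] = DispersalEvent(
                individual_id=e.individual_id,
                sex=e.sex,
                from_unit=e.from_unit,
                to_unit=e.to_unit,
                last_seen_origin=e.last_seen_origin,
                first_seen_destination=e.first_seen_destination,
                assigned_month=month,
            )
    out = []
    for (origin, dest, month), event in sorted(dyadic.items()):
        event_id = f"{origin}->{dest}@{month}"
        for offset in range(1, max_offset + 1):
            dyad_ai = post_dispersal_dyad_ai(event, scans, offset)
            controls = baseline_ais(event, scans, eval_month=month_add(month, offset))
            if not np.isfinite(dyad_ai) or not controls:
                out.append(
                    PostDispersalComparison(
                        event_id, origin, dest, offset, dyad_ai, tuple(controls),
                        float("nan"), None,
                    )
                )
                continue
            try:
                p = wilcoxon_one_sample(controls, dyad_ai)
            except ValueError:
                out.append(
                    PostDispersalComparison(
                        event_id, origin, dest, offset, dyad_ai, tuple(controls),
                        float("nan"), None,
                    )
                )
                continue
            out.append(
                PostDispersalComparison(
                    event_id, origin, dest, offset, dyad_ai, tuple(controls),
                    p, bool(p < alpha),
                )
            )
    return out
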