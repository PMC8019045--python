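"""Small shared helpers: year-month arithmetic and seeding."""

from __future__ import annotations

import datetime as dt
import zlib

import numpy as np

__all__ = [
    "month_of",
    "month_str",
    "parse_month",
    "month_add",
    "month_range",
    "days_in_month",
    "spawn_rng",
]


def month_of(date: dt.date) -> str:
    """Year-month label (``YYYY-MM``) of a calendar date."""
    return f"{date.year:04d}-{date.month:02d}"


def month_str(year: int, month: int) -> str:
    return f"{year:04d}-{month:02d}"


def parse_month(text: str) -> tuple[int, int]:
    """Parse ``YYYY-MM`` into (year, month); raises ValueError when malformed."""
    parts = text.strip().split("-")
    if len(parts) != 2:
        raise ValueError(f"malformed year-month {text!r}")
    year, month = int(parts[0]), int(parts[1])
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range in {text!r}")
    return year, month


def month_add(month: str, k: int) -> str:
    """Shift a ``YYYY-MM`` label by ``k`` calendar months."""
    y, m = parse_month(month)
    idx = y * 12 + (m - 1) + k
    return month_str(idx // 12, idx % 12 + 1)


def month_range(start: str, end: str) -> list[str]:
    """Inclusive list of ``YYYY-MM`` labels from start to end."""
    ys, ms = parse_month(start)
    ye, me = parse_month(end)
    i0, i1 = ys * 12 + ms - 1, ye * 12 + me - 1
    if i1 < i0:
        raise ValueError("end month precedes start month")
    return [month_str(i // 12, i % 12 + 1) for i in range(i0, i1 + 1)]


def days_in_month(year: int, month: int) -> int:
    nxt = dt.date(year + (month == 12), month % 12 + 1, 1)
    return (nxt - dt.date(year, month, 1)).days


def spawn_rng(seed, stream: str) -> np.random.Generator:
    """Derive an independent generator for a named stage from one run seed.

    The stream label is folded into the seed sequence so stages draw from
    non-overlapping streams while staying reproducible from a single integer.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    entropy = [zlib.crc32(stream.encode()) % (2**31)] if stream else []
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *entropy]))
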