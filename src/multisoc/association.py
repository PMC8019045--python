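"""Dyadic simple association indices (AI) from scan samples.

The simple association index of a dyad is the fraction of scans containing
both members among scans containing at least one member:

    AI(A, B) = N_AB / (N_AB + N_A-only + N_B-only)

so that AI = 1 means the two units were always together when either was seen
and AI = 0 means they were never together. The simple (rather than
half-weight) index is appropriate when every unit in association with the
focal can be positively identified. A raw-sum variant
``N_AB / (N_A + N_B)`` is available for sensitivity analysis.

A dyad never sighted at all (union count 0) has no data; its AI is flagged
undefined (NaN) and treated as 0 when building trees and networks but
excluded from coefficient-of-variation computations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ScanRecord

__all__ = [
    "DyadCounts",
    "AssociationMatrix",
    "unit_presence",
    "dyad_counts",
    "simple_ai",
    "association_matrix",
]


@dataclass(frozen=True)
class DyadCounts:
    """Scan counts for one dyad: joint sightings and one-member-only
    sightings; the union is their sum."""

    n_joint: int
    n_a_only: int
    n_b_only: int

    def __post_init__(self):
        if min(self.n_joint, self.n_a_only, self.n_b_only) < 0:
            raise ValueError("dyad counts must be non-negative")

    @property
    def n_union(self) -> int:
        return self.n_joint + self.n_a_only + self.n_b_only


def unit_presence(scan: ScanRecord) -> frozenset:
    """Units present in a scan: the focal plus its associates."""
    return frozenset({scan.focal_unit}) | scan.associates


def dyad_counts(scans: Iterable[ScanRecord], a: str, b: str) -> DyadCounts:
    """Count joint and single sightings of a dyad over scans.

    A scan contributes only when at least one member is present.
    """
    if a == b:
        raise ValueError("dyad members must differ")
    n_joint = n_a = n_b = 0
    for scan in scans:
        present = unit_presence(scan)
        in_a, in_b = a in present, b in present
        if in_a and in_b:
            n_joint += 1
        elif in_a:
            n_a += 1
        elif in_b:
            n_b += 1
    return DyadCounts(n_joint, n_a, n_b)


def simple_ai(counts: DyadCounts, denominator: str = "union") -> float:
    """Simple association index; NaN flags an undefined (never-sighted) dyad.

    ``denominator="union"`` (default) divides by scans containing either
    member; ``"sum"`` divides by N_A + N_B (counting joint scans twice),
    provided for sensitivity analysis.
    """
    if denominator == "union":
        denom = counts.n_union
    elif denominator == "sum":
        denom = 2 * counts.n_joint + counts.n_a_only + counts.n_b_only
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return float("nan")
    return counts.n_joint / denom


class AssociationMatrix:
    """Symmetric unit x unit matrix of simple association indices with the
    dyad-count provenance retained.

    The diagonal is NaN (a unit has no association index with itself), and
    undefined dyads are NaN in ``ai``.
    """

    def __init__(
        self,
        units: Sequence[str],
        ai: np.ndarray,
        joint: np.ndarray,
        totals: np.ndarray,
        period: tuple[dt.date, dt.date] | None = None,
    ):
        self.units = list(units)
        self.ai = ai
        self.joint = joint  # N_AB per dyad
        self.totals = totals  # N_i: scans containing unit i
        self.period = period
        self._index = {u: k for k, u in enumerate(self.units)}
        if ai.shape != (len(self.units),) * 2:
            raise ValueError("matrix shape does not match roster")
        off = ~np.eye(len(self.units), dtype=bool)
        vals = ai[off]
        vals = vals[np.isfinite(vals)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("association indices must lie in [0, 1]")
        if not np.allclose(np.where(np.isnan(ai), -1.0, ai), np.where(np.isnan(ai.T), -1.0, ai.T)):
            raise ValueError("association matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.units)

    def value(self, a: str, b: str) -> float:
        return float(self.ai[self._index[a], self._index[b]])

    def counts(self, a: str, b: str) -> DyadCounts:
        i, j = self._index[a], self._index[b]
        nj = int(self.joint[i, j])
        return DyadCounts(nj, int(self.totals[i]) - nj, int(self.totals[j]) - nj)

    def defined_mask(self) -> np.ndarray:
        """Boolean matrix: True for off-diagonal dyads with at least one
        sighting of either member."""
        mask = np.isfinite(self.ai)
        np.fill_diagonal(mask, False)
        return mask

    def dyad_values(self) -> np.ndarray:
        """Defined dyadic AIs, each dyad once (upper triangle)."""
        iu = np.triu_indices(len(self.units), k=1)
        vals = self.ai[iu]
        return vals[np.isfinite(vals)]

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """AI matrix with undefined dyads and the diagonal replaced by
        ``fill`` — the form consumed by clustering and network construction."""
        out = self.ai.copy()
        out[~np.isfinite(out)] = fill
        np.fill_diagonal(out, fill)
        return out

    def relabelled(self, order: Sequence[str]) -> "AssociationMatrix":
        idx = np.array([self._index[u] for u in order])
        return AssociationMatrix(
            list(order),
            self.ai[np.ix_(idx, idx)],
            self.joint[np.ix_(idx, idx)],
            self.totals[idx],
            self.period,
        )

    # -- export ------------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.units):
            for j in range(i + 1, len(self.units)):
                b = self.units[j]
                c = self.counts(a, b)
                rows.append(
                    (a, b, c.n_joint, c.n_a_only, c.n_b_only, self.ai[i, j])
                )
        return pd.DataFrame(
            rows, columns=["unit_a", "unit_b", "n_joint", "n_a_only", "n_b_only", "ai"]
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ai, index=self.units, columns=self.units)


def association_matrix(
    scans: Sequence[ScanRecord],
    units: Sequence[str] | None = None,
    period: tuple[dt.date, dt.date] | None = None,
    strict: bool = False,
    denominator: str = "union",
) -> AssociationMatrix:
    """Build the full dyadic AI matrix from scans.

    Parameters
    ----------
    scans : scan records; when ``period=(first, last)`` is given, only scans
        dated inside the inclusive interval are used.
    units : roster; defaults to every unit sighted. In strict mode a sighted
        unit missing from a supplied roster raises.
    """
    if period is not None:
        scans = [s for s in scans if period[0] <= s.date <= period[1]]
    seen: set[str] = set()
    for s in scans:
        seen |= unit_presence(s)
    if units is None:
        units = sorted(seen)
    else:
        units = list(units)
        extra = seen - set(units)
        if extra and strict:
            raise ValueError(f"units sighted but absent from roster: {sorted(extra)}")
    if len(units) < 2:
        raise ValueError("need at least 2 units for an association matrix")

    index = {u: k for k, u in enumerate(units)}
    presence = np.zeros((len(scans), len(units)), dtype=np.int64)
    for r, s in enumerate(scans):
        for u in unit_presence(s):
            if u in index:
                presence[r, index[u]] = 1
    joint = presence.T @ presence
    totals = np.diag(joint).copy()
    if denominator == "union":
        denom = totals[:, None] + totals[None, :] - joint
    elif denominator == "sum":
        denom = totals[:, None] + totals[None, :]
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(denom > 0, joint / np.maximum(denom, 1), np.nan)
    ai = ai.astype(float)
    ai[denom == 0] = np.nan
    np.fill_diagonal(ai, np.nan)
    np.fill_diagonal(joint, 0)
    return AssociationMatrix(units, ai, joint, totals, period)
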