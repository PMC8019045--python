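"""Time-aggregated social networks on a sliding window.

Scans are aggregated into weighted undirected networks over consecutive
windows (31 days wide, shifted by 31 days by default, so windows tile the
study span without overlap). Edge weights are the simple association
indices computed from the window's scans. Node metrics (degree, strength),
network metrics (edge density, global clustering coefficient), cosine
similarity between networks, bootstrap uncertainty, and a signal-to-noise
window-size selector are provided.

Edge presence means AI > 0 (no threshold) for degree, density and the
clustering coefficient; strength sums raw AI weights. An optional weight
threshold is available on each metric for sensitivity analysis.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from ._util import spawn_rng
from .association import AssociationMatrix, association_matrix
from .io import ScanRecord

log = logging.getLogger("multisoc")

__all__ = [
    "NetworkSnapshot",
    "NetworkSeries",
    "window_networks",
    "node_degree",
    "node_strength",
    "edge_density",
    "clustering_coefficient",
    "cosine_similarity",
    "stability_series",
    "bootstrap_ci",
    "select_window_size",
]


class NetworkSnapshot:
    """Weighted undirected association network for one half-open window."""

    def __init__(
        self,
        window: tuple[dt.date, dt.date],
        matrix: AssociationMatrix,
        scans: Sequence[ScanRecord] = (),
    ):
        self.window = window
        self.matrix = matrix
        self.units = matrix.units
        self.scans = list(scans)

    def __repr__(self):
        return f"NetworkSnapshot({self.window[0]}..{self.window[1]}, n={len(self.units)})"

    def edges(self, threshold: float = 0.0) -> dict:
        """Dyad -> AI weight for dyads with AI above the threshold."""
        out = {}
        ai = self.matrix.ai
        for i, a in enumerate(self.units):
            for j in range(i + 1, len(self.units)):
                w = ai[i, j]
                if np.isfinite(w) and w > threshold:
                    out[(a, self.units[j])] = float(w)
        return out

    def graph(self, threshold: float = 0.0) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.units)
        for (a, b), w in self.edges(threshold).items():
            g.add_edge(a, b, weight=w)
        return g

    def to_edge_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (self.window[0], a, b, w)
                for (a, b), w in sorted(self.edges().items())
            ],
            columns=["window_start", "unit_a", "unit_b", "ai"],
        )


@dataclass
class NetworkSeries:
    snapshots: list
    window_days: int
    shift_days: int

    def __iter__(self):
        return iter(self.snapshots)

    def __len__(self):
        return len(self.snapshots)

    def __getitem__(self, k):
        return self.snapshots[k]


def window_networks(
    scans: Sequence[ScanRecord],
    units: Sequence[str] | None = None,
    window_days: int = 31,
    shift_days: int = 31,
    span: tuple[dt.date, dt.date] | None = None,
) -> NetworkSeries:
    """Build the sliding-window network series.

    ``span`` is the inclusive (first, last) study interval, defaulting to
    the scan date range. Only complete windows are emitted: window k covers
    [start + k*shift, start + k*shift + window_days) and its last day must
    not pass the span end. A 31/31 configuration over a 624-day study span
    yields 20 windows.
    """
    scans = sorted(scans, key=lambda s: (s.date, s.time, s.focal_unit))
    if span is None:
        if not scans:
            raise ValueError("cannot infer span from an empty scan set")
        span = (scans[0].date, scans[-1].date)
    if not scans:
        warnings.warn("empty scan set: snapshots will be empty")
    if units is None:
        roster = set()
        for s in scans:
            roster |= {s.focal_unit} | s.associates
        units = sorted(roster)
    first, last = span
    total_days = (last - first).days + 1
    if total_days < window_days:
        raise ValueError("span shorter than one window")
    snapshots = []
    k = 0
    while True:
        start = first + dt.timedelta(days=k * shift_days)
        end = start + dt.timedelta(days=window_days)
        if (end - dt.timedelta(days=1)) > last:
            break
        wscans = [s for s in scans if start <= s.date < end]
        matrix = association_matrix(wscans, units=units) if wscans else _empty_matrix(units)
        snapshots.append(NetworkSnapshot((start, end), matrix, wscans))
        k += 1
    return NetworkSeries(snapshots, window_days, shift_days)


def _empty_matrix(units: Sequence[str]) -> AssociationMatrix:
    n = len(units)
    ai = np.full((n, n), np.nan)
    return AssociationMatrix(list(units), ai, np.zeros((n, n), dtype=np.int64), np.zeros(n, dtype=np.int64))


def node_degree(snapshot: NetworkSnapshot, unit: str, threshold: float = 0.0) -> int:
    """Number of units the given unit associated with (AI > threshold)."""
    if unit not in snapshot.matrix._index:
        raise KeyError(unit)
    i = snapshot.matrix._index[unit]
    row = snapshot.matrix.ai[i]
    return int(np.sum(np.isfinite(row) & (row > threshold)))


def node_strength(snapshot: NetworkSnapshot, unit: str) -> float:
    """Sum of the unit's edge weights (total association rate)."""
    if unit not in snapshot.matrix._index:
        raise KeyError(unit)
    i = snapshot.matrix._index[unit]
    row = snapshot.matrix.ai[i]
    return float(np.nansum(row))


def edge_density(snapshot: NetworkSnapshot, threshold: float = 0.0) -> float:
    """Realized dyads (AI > threshold) over all possible dyads."""
    n = len(snapshot.units)
    if n < 2:
        raise ValueError("need at least 2 units for edge density")
    return len(snapshot.edges(threshold)) / (n * (n - 1) / 2)


def clustering_coefficient(snapshot: NetworkSnapshot, threshold: float = 0.0, weighted: bool = False) -> float:
    """Global clustering coefficient (transitivity) of the binarized graph:
    3 x triangles / connected triples. NaN when no connected triples exist.

    ``weighted=True`` returns instead the mean of networkx's weighted
    (geometric-mean) local clustering over nodes.
    """
    if len(snapshot.units) < 3:
        raise ValueError("need at least 3 units for a clustering coefficient")
    g = snapshot.graph(threshold)
    if weighted:
        return float(np.mean(list(nx.clustering(g, weight="weight").values())))
    triples = sum(d * (d - 1) / 2 for _, d in g.degree())
    if triples == 0:
        return float("nan")
    return float(nx.transitivity(g))


def cosine_similarity(net1: NetworkSnapshot, net2: NetworkSnapshot) -> float:
    """Cosine similarity of two networks' edge-weight vectors over the
    union of their dyads: 1 means identical association structure, 0 means
    no shared associations (or an empty network)."""
    e1, e2 = net1.edges(), net2.edges()
    if not e1 or not e2:
        return 0.0
    dyads = sorted(set(e1) | set(e2))
    v1 = np.array([e1.get(d, 0.0) for d in dyads])
    v2 = np.array([e2.get(d, 0.0) for d in dyads])
    val = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    # weights are non-negative so the value lies in [0, 1]; rounding at
    # 1e-12 removes float noise (identical networks give exactly 1.0)
    return float(np.clip(round(val, 12), 0.0, 1.0))


def stability_series(series: NetworkSeries, mode: str = "lag1") -> list[float]:
    """Cosine-similarity stability across the window series.

    ``lag1``: each window vs the previous one (first window NaN).
    ``to_first``: each window vs window 1 (first window = 1.0).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 snapshots for a stability series")
    snaps = series.snapshots
    if mode == "lag1":
        return [float("nan")] + [
            cosine_similarity(a, b) for a, b in zip(snaps, snaps[1:])
        ]
    if mode == "to_first":
        return [1.0] + [cosine_similarity(snaps[0], b) for b in snaps[1:]]
    raise ValueError("mode must be 'lag1' or 'to_first'")


def _hdi(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sample."""
    x = np.sort(samples)
    n = x.size
    k = max(int(np.ceil(level * n)), 1)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def bootstrap_ci(
    scans: Sequence[ScanRecord],
    statistic: Callable[[NetworkSnapshot], float],
    n_boot: int = 100,
    level: float = 0.95,
    seed=None,
    units: Sequence[str] | None = None,
    window: tuple[dt.date, dt.date] | None = None,
) -> tuple[float, float]:
    """Bootstrap the scans of one window and return the 95% highest-density
    interval of the statistic over replicates.

    Scans are resampled with replacement (same count), the snapshot is
    rebuilt, and the statistic recomputed. Raises when the statistic is
    undefined in more than half of the replicates.
    """
    scans = list(scans)
    if len(scans) < 2:
        raise ValueError("need at least 2 scans to bootstrap")
    if units is None:
        roster = set()
        for s in scans:
            roster |= {s.focal_unit} | s.associates
        units = sorted(roster)
    if window is None:
        window = (scans[0].date, scans[-1].date)
    rng = spawn_rng(seed if seed is not None else 0, "bootstrap")
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(len(scans), size=len(scans))
        resampled = [scans[i] for i in idx]
        snap = NetworkSnapshot(window, association_matrix(resampled, units=units), resampled)
        try:
            v = statistic(snap)
        except ValueError:
            v = float("nan")
        vals.append(v)
    vals = np.asarray(vals, dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < n_boot / 2:
        raise ValueError("statistic undefined in more than half the bootstrap replicates")
    return _hdi(vals[ok], level)


def select_window_size(
    scans: Sequence[ScanRecord],
    candidate_days: Sequence[int],
    n_boot: int = 50,
    seed=None,
    units: Sequence[str] | None = None,
    criterion: str = "signal_noise",
) -> tuple[int, "object"]:
    """Choose the window size maximizing variability in edge density.

    For each candidate size, ``signal`` is the variance of edge density
    across that candidate's windows and ``noise`` is the mean bootstrap
    variance of density within windows; the chosen candidate maximizes
    signal/noise (``criterion="variance"`` maximizes the raw signal). Ties
    break toward the smallest candidate. Returns the chosen size and a
    diagnostics table.
    """
    import pandas as pd

    candidates = sorted(set(int(c) for c in candidate_days))
    if not candidates:
        raise ValueError("need at least one candidate window size")
    scans = sorted(scans, key=lambda s: (s.date, s.time, s.focal_unit))
    if not scans:
        raise ValueError("no scans supplied")
    span = (scans[0].date, scans[-1].date)
    span_days = (span[1] - span[0]).days + 1
    rows = []
    for cand in candidates:
        if cand > span_days:
            raise ValueError(f"candidate window {cand} d exceeds the {span_days} d span")
        series = window_networks(scans, units=units, window_days=cand, shift_days=cand, span=span)
        dens = np.array(
            [edge_density(s) if s.scans else np.nan for s in series], dtype=float
        )
        ok = np.isfinite(dens)
        signal = float(np.var(dens[ok])) if ok.sum() >= 2 else float("nan")
        noises = []
        for snap in series:
            if len(snap.scans) < 2:
                continue
            rng = spawn_rng(seed if seed is not None else 0, f"wsel-{cand}-{snap.window[0]}")
            reps = []
            for _ in range(n_boot):
                idx = rng.integers(len(snap.scans), size=len(snap.scans))
                resampled = [snap.scans[i] for i in idx]
                m = association_matrix(resampled, units=snap.units)
                reps.append(edge_density(NetworkSnapshot(snap.window, m)))
            noises.append(float(np.var(reps)))
        noise = float(np.mean(noises)) if noises else float("nan")
        ratio = signal / noise if noise and np.isfinite(noise) and noise > 0 else float("nan")
        rows.append((cand, len(series), signal, noise, ratio))
    table = pd.DataFrame(
        rows, columns=["window_days", "n_windows", "signal", "noise", "signal_noise"]
    )
    score_col = "signal_noise" if criterion == "signal_noise" else "signal"
    scores = table[score_col].to_numpy()
    if np.all(~np.isfinite(scores)):
        chosen = candidates[0]
    else:
        best = np.nanmax(scores)
        chosen = int(table.loc[scores >= best - 1e-12, "window_days"].min())
    return chosen, table
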