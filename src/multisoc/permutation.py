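"""Permutation tests for preferred/avoided association.

Two randomization schemes are provided, matching the two ways such tests
are run in practice:

``data_stream``
    Sequential swaps on the observed scans (Bejder-style): two scans are
    chosen, one associate from each is exchanged provided neither already
    occurs in the other scan, and after every ``swaps_per_sample`` accepted
    swaps the current state is emitted as one permuted dataset. Swaps
    preserve the number of scans, each scan's group size, and every unit's
    total sighting count, so the null keeps the sampling structure and
    gregariousness of the data while destroying consistent dyadic
    preference. Focal units are never swapped out of their own follows.
    Swaps are unconstrained across days by default: under a
    one-focal-unit-per-day design all of a day's scans share the focal, so
    a within-day restriction (``constraint="day"``, provided for designs
    that sample several groups per day) can only shuffle associates of a
    single focal and leaves dyadic preference essentially intact.

``node_label``
    Joint permutation of unit labels over the association matrix. The
    default test statistic — the coefficient of variation (CV) of dyadic
    AIs — depends only on the multiset of dyad values and is therefore
    *invariant* under relabelling: with the CV the node-label scheme
    returns p = 1 by construction. It is useful with label-dependent
    statistics (e.g. the within-clan mean AI given a candidate partition),
    which can be passed via ``statistic``.

A high observed CV relative to the permuted distribution indicates
preferred/avoided companionships; the test is right-tailed with the
add-one estimator p = (k + 1) / (n + 1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from ._util import spawn_rng
from .association import AssociationMatrix, association_matrix, unit_presence
from .io import ScanRecord

log = logging.getLogger("multisoc")

__all__ = [
    "PermutationResult",
    "NullDensityBand",
    "cv_statistic",
    "data_stream_permute",
    "preferred_association_test",
    "null_density_band",
    "within_partition_statistic",
]


@dataclass(frozen=True)
class PermutationResult:
    cv_obs: float
    cv_rand_mean: float
    p_value: float
    n_permutations: int
    scheme: str
    seed: int | None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class NullDensityBand:
    """Per-window 95% interval of edge density under data-stream
    permutation — the density range expected from chance encounters."""

    windows: list  # (start, end) per window
    lower: list
    upper: list
    n_permutations: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "window_start": [w[0] for w in self.windows],
                "window_end": [w[1] for w in self.windows],
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def cv_statistic(matrix: AssociationMatrix, ddof: int = 0) -> float:
    """Coefficient of variation (SD/mean) of the defined dyadic AIs.

    Population SD by default (``ddof=0``); each dyad counted once.
    Undefined dyads are excluded rather than treated as zeros.
    """
    vals = matrix.dyad_values()
    if vals.size < 3:
        raise ValueError("need at least 3 defined dyads for a CV")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean AI is zero; CV undefined")
    return float(vals.std(ddof=ddof) / mean)


def within_partition_statistic(partition) -> Callable[[AssociationMatrix], float]:
    """Label-dependent statistic factory: mean within-clan AI minus mean
    between-clan AI under a candidate partition (for the node_label scheme)."""

    def stat(matrix: AssociationMatrix) -> float:
        labels = np.array([partition.assignment[u] for u in matrix.units])
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(matrix.units), k=1)
        vals = matrix.ai[iu]
        same = same[iu]
        ok = np.isfinite(vals)
        within = vals[ok & same]
        between = vals[ok & ~same]
        if within.size == 0 or between.size == 0:
            raise ValueError("partition has no within- or no between-clan dyads")
        return float(within.mean() - between.mean())

    return stat


# ---------------------------------------------------------------------------
# data-stream swap engine


class _SwapEngine:
    """Mutable permuted state of a scan dataset with incrementally
    maintained co-occurrence counts.

    Invariants preserved by every accepted swap: number of scans, each
    scan's presence-set size, each unit's total sighting count.
    """

    def __init__(
        self,
        scans: Sequence[ScanRecord],
        units: Sequence[str] | None = None,
        constraint: str = "none",
    ):
        if constraint not in ("day", "none"):
            raise ValueError("constraint must be 'day' or 'none'")
        self.scans = list(scans)
        roster = set()
        for s in self.scans:
            roster |= unit_presence(s)
        self.units = sorted(roster) if units is None else list(units)
        self.index = {u: k for k, u in enumerate(self.units)}
        self.n = len(self.units)
        self.constraint = constraint

        self.focal = [self.index[s.focal_unit] for s in self.scans]
        self.assoc = [sorted(self.index[a] for a in s.associates) for s in self.scans]
        self.present = [set(a) | {f} for a, f in zip(self.assoc, self.focal)]

        # joint co-occurrence counts as plain nested lists: the swap loop
        # updates a handful of scalar cells per accepted swap and python
        # list indexing beats numpy scalar indexing there
        self.joint = [[0] * self.n for _ in range(self.n)]
        for p in self.present:
            mem = sorted(p)
            for i_pos, i in enumerate(mem):
                for j in mem[i_pos + 1 :]:
                    self.joint[i][j] += 1
                    self.joint[j][i] += 1
        self.totals = [sum(1 for p in self.present if i in p) for i in range(self.n)]
        self._pairs = [(i, j) for i in range(self.n) for j in range(i + 1, self.n)]
        self.swappable = [r for r, a in enumerate(self.assoc) if a]
        if constraint == "day":
            days: dict = {}
            for r, s in enumerate(self.scans):
                if self.assoc[r]:
                    days.setdefault(s.date, []).append(r)
            self.pools = [idx for idx in days.values() if len(idx) >= 2]
        else:
            self.pools = [self.swappable] if len(self.swappable) >= 2 else []

        self._buf: list = []
        self._ptr = 0

    def can_swap(self) -> bool:
        return bool(self.pools)

    def _uniforms(self, rng: np.random.Generator, k: int) -> np.ndarray:
        # block-buffered uniforms: one generator call serves thousands of
        # swap attempts, which dominates the chain's runtime otherwise
        if self._ptr + k > len(self._buf):
            self._buf = rng.random(65536).tolist()
            self._ptr = 0
        out = self._buf[self._ptr : self._ptr + k]
        self._ptr += k
        return out

    def try_swap(self, rng: np.random.Generator) -> bool:
        """Attempt one random swap; returns True when accepted."""
        if not self.pools:
            return False
        u = self._uniforms(rng, 5)
        pools = self.pools
        pool = pools[int(u[0] * len(pools))] if len(pools) > 1 else pools[0]
        np_pool = len(pool)
        r = pool[int(u[1] * np_pool)]
        s = pool[int(u[2] * np_pool)]
        if r == s:
            return False
        ar = self.assoc[r]
        as_ = self.assoc[s]
        a = ar[int(u[3] * len(ar))]
        b = as_[int(u[4] * len(as_))]
        if a == b or a in self.present[s] or b in self.present[r]:
            return False
        self._exchange(r, a, b)
        self._exchange(s, b, a)
        return True

    def _exchange(self, r: int, out_unit: int, in_unit: int) -> None:
        """Replace associate ``out_unit`` with ``in_unit`` in scan r."""
        joint = self.joint
        j_out, j_in = joint[out_unit], joint[in_unit]
        self.present[r].discard(out_unit)
        for m in self.present[r]:
            j_out[m] -= 1
            joint[m][out_unit] -= 1
            j_in[m] += 1
            joint[m][in_unit] += 1
        self.present[r].add(in_unit)
        a = self.assoc[r]
        a[a.index(out_unit)] = in_unit

    def materialize(self) -> list[ScanRecord]:
        return [
            ScanRecord(
                date=s.date,
                time=s.time,
                focal_unit=s.focal_unit,
                associates=frozenset(self.units[i] for i in self.assoc[r]),
            )
            for r, s in enumerate(self.scans)
        ]

    # -- statistics straight from the maintained counts --------------------

    def cv(self, ddof: int = 0) -> float:
        joint, totals = self.joint, self.totals
        vals = []
        for i, j in self._pairs:
            nj = joint[i][j]
            union = totals[i] + totals[j] - nj
            if union > 0:
                vals.append(nj / union)
        if len(vals) < 3:
            raise ValueError("need at least 3 defined dyads for a CV")
        n = len(vals)
        mean = sum(vals) / n
        if mean <= 0:
            raise ValueError("mean AI is zero; CV undefined")
        var = sum((v - mean) ** 2 for v in vals) / (n - ddof)
        return var**0.5 / mean

    def edge_density(self) -> float:
        joint = self.joint
        hits = sum(1 for i, j in self._pairs if joint[i][j] > 0)
        return hits / len(self._pairs)

    def run(
        self,
        rng: np.random.Generator,
        n_accepted: int,
        max_attempts_per_swap: int = 10_000,
    ) -> bool:
        """Advance the chain by ``n_accepted`` swaps; False when the chain
        cannot mix (no legal swap found within the attempt budget)."""
        done = 0
        attempts = 0
        while done < n_accepted:
            if self.try_swap(rng):
                done += 1
                attempts = 0
            else:
                attempts += 1
                if attempts >= max_attempts_per_swap:
                    return False
        return True


def data_stream_permute(
    scans: Sequence[ScanRecord],
    n_permutations: int,
    swaps_per_sample: int = 100,
    constraint: str = "none",
    seed=None,
    burn_in: int = 1000,
    units: Sequence[str] | None = None,
) -> Iterator[list[ScanRecord]]:
    """Yield data-stream permuted scan sets.

    The chain starts from the observed data, performs ``burn_in`` accepted
    swaps, then emits one permuted dataset every ``swaps_per_sample``
    accepted swaps. With ``constraint="day"`` swaps only exchange
    associates between scans of the same calendar day.
    """
    rng = spawn_rng(seed if seed is not None else 0, "data_stream")
    engine = _SwapEngine(scans, units=units, constraint=constraint)
    if not engine.can_swap():
        warnings.warn("no legal data-stream swap exists; zero mixing")
        return
    if not engine.run(rng, burn_in):
        warnings.warn("data-stream chain stalled during burn-in; zero mixing")
        return
    for _ in range(n_permutations):
        if not engine.run(rng, swaps_per_sample):
            warnings.warn("data-stream chain stalled; permutation skipped")
            return
        yield engine.materialize()


def _permuted_matrix(matrix: AssociationMatrix, perm: np.ndarray) -> AssociationMatrix:
    """Node-label permutation: shuffle which unit sits on which row/column
    while keeping the roster order fixed."""
    return AssociationMatrix(
        matrix.units,
        matrix.ai[np.ix_(perm, perm)],
        matrix.joint[np.ix_(perm, perm)],
        matrix.totals[perm],
        matrix.period,
    )


def preferred_association_test(
    data,
    scheme: str = "data_stream",
    n_permutations: int = 10_000,
    seed=None,
    statistic: Callable[[AssociationMatrix], float] | None = None,
    swaps_per_sample: int = 100,
    burn_in: int = 1000,
    constraint: str = "none",
    units: Sequence[str] | None = None,
) -> PermutationResult:
    """Permutation test for preferred/avoided association.

    ``data`` is a scan sequence for the data_stream scheme or an
    :class:`AssociationMatrix` for the node_label scheme. The statistic
    defaults to the CV of dyadic AIs; the right-tailed p-value uses the
    add-one estimator (k + 1) / (n + 1).
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-value will be unstable")
    seed_out = None if seed is None or isinstance(seed, np.random.Generator) else int(seed)

    if scheme == "data_stream":
        scans = list(data)
        obs_matrix = association_matrix(scans, units=units)
        stat = statistic if statistic is not None else cv_statistic
        use_engine_cv = statistic is None
        cv_obs = stat(obs_matrix)
        rng = spawn_rng(seed if seed is not None else 0, "data_stream")
        engine = _SwapEngine(scans, units=units, constraint=constraint)
        if not engine.can_swap() or not engine.run(rng, burn_in):
            warnings.warn("no legal data-stream swap exists; zero mixing, p = 1")
            return PermutationResult(cv_obs, cv_obs, 1.0, 0, scheme, seed_out)
        perm_stats = np.empty(n_permutations)
        done = 0
        for k in range(n_permutations):
            if not engine.run(rng, swaps_per_sample):
                warnings.warn("data-stream chain stalled; remaining permutations skipped")
                break
            if use_engine_cv:
                perm_stats[k] = engine.cv()
            else:
                perm_stats[k] = stat(association_matrix(engine.materialize(), units=engine.units))
            done += 1
        perm_stats = perm_stats[:done]
    elif scheme == "node_label":
        matrix = data
        if not isinstance(matrix, AssociationMatrix):
            raise TypeError("node_label scheme operates on an AssociationMatrix")
        stat = statistic if statistic is not None else cv_statistic
        cv_obs = stat(matrix)
        rng = spawn_rng(seed if seed is not None else 0, "node_label")
        perm_stats = np.empty(n_permutations)
        for k in range(n_permutations):
            perm = rng.permutation(len(matrix))
            perm_stats[k] = stat(_permuted_matrix(matrix, perm))
        done = n_permutations
    else:
        raise ValueError("scheme must be 'data_stream' or 'node_label'")

    if done == 0:
        return PermutationResult(cv_obs, cv_obs, 1.0, 0, scheme, seed_out)
    tol = 1e-12  # ties with the observed value count as >=
    k_ge = int(np.sum(perm_stats >= cv_obs - tol))
    p = (k_ge + 1) / (done + 1)
    return PermutationResult(
        float(cv_obs), float(perm_stats.mean()), float(p), done, scheme, seed_out
    )


def null_density_band(
    scans: Sequence[ScanRecord],
    windows: Iterable[tuple],
    n_permutations: int = 1000,
    seed=None,
    units: Sequence[str] | None = None,
    swaps_per_sample: int = 100,
    burn_in: int = 1000,
    constraint: str = "none",
    level: float = 0.95,
) -> NullDensityBand:
    """Per-window percentile interval of edge density under data-stream
    permutation — the chance-encounter band plotted behind observed density.

    ``windows`` is an iterable of half-open (start, end) date pairs (e.g.
    from :func:`multisoc.temporal.window_networks` snapshots). Windows with
    fewer than 2 scans get an undefined (NaN) band.
    """
    windows = list(windows)
    if units is None:
        roster = set()
        for s in scans:
            roster |= unit_presence(s)
        units = sorted(roster)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    lowers, uppers = [], []
    for start, end in windows:
        wscans = [s for s in scans if start <= s.date < end]
        if len(wscans) < 2:
            lowers.append(float("nan"))
            uppers.append(float("nan"))
            continue
        rng = spawn_rng(seed if seed is not None else 0, f"band-{start}")
        engine = _SwapEngine(wscans, units=units, constraint=constraint)
        if not engine.can_swap() or not engine.run(rng, burn_in):
            d = engine.edge_density()
            lowers.append(d)
            uppers.append(d)
            continue
        dens = np.empty(n_permutations)
        done = 0
        for k in range(n_permutations):
            if not engine.run(rng, swaps_per_sample):
                break
            dens[k] = engine.edge_density()
            done += 1
        if done == 0:
            d = engine.edge_density()
            lowers.append(d)
            uppers.append(d)
            continue
        lowers.append(float(np.percentile(dens[:done], lo_q)))
        uppers.append(float(np.percentile(dens[:done], hi_q)))
    return NullDensityBand(windows, lowers, uppers, n_permutations)
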