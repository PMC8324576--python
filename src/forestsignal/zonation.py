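"""Stratigraphically constrained incremental sum-of-squares zonation (CONISS).

Pollen zones are found by agglomerative clustering in which only
stratigraphically adjacent clusters may merge; at each step the merge that
least increases the total within-cluster sum of squares (squared Euclidean
dispersion about the cluster mean) is chosen.  The number of significant
zones is assessed by comparing each successive dispersion reduction with its
broken-stick expectation, the conventional null for ordered dispersion
curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ValidationError

__all__ = [
    "ZonationResult",
    "coniss",
    "n_zones_broken_stick",
    "total_within_ss",
]


def total_within_ss(x: np.ndarray) -> float:
    """Within-cluster sum of squares of one cluster about its mean."""
    x = np.asarray(x, dtype=float)
    return float(np.sum((x - x.mean(axis=0)) ** 2))


@dataclass(frozen=True)
class ZonationResult:
    """The full constrained merge tree plus the significant zoning.

    ``merge_sequence`` lists (cluster_a, cluster_b, dispersion_increase) in
    merge order; original samples are clusters 0..n-1 and each merge creates
    cluster n, n+1, ...  ``total_dispersion_curve[m]`` is the total
    within-cluster dispersion after m merges (i.e. with n - m clusters), so
    it is non-decreasing in m.  ``zone_boundaries`` are the ages midway
    between the samples flanking each significant break.
    """

    ages: tuple[float, ...]
    merge_sequence: tuple[tuple[int, int, float], ...]
    total_dispersion_curve: tuple[float, ...]
    n_zones: int
    zone_boundaries: tuple[float, ...]
    boundary_positions: tuple[int, ...]  # break after sample index i (depth order)

    @property
    def n_samples(self) -> int:
        return len(self.ages)

    def dispersion_at(self, n_clusters: int) -> float:
        """Total within-cluster dispersion when cut at ``n_clusters``."""
        n = self.n_samples
        if not 1 <= n_clusters <= n:
            raise ValidationError(f"n_clusters must be in [1, {n}]")
        return self.total_dispersion_curve[n - n_clusters]

    def breaks_at(self, n_clusters: int) -> tuple[int, ...]:
        """Positions of the breaks (after sample i) when cut at ``n_clusters``."""
        n = self.n_samples
        # replay merges until n_clusters remain, tracking segment ends
        ends = set(range(n))  # "break after sample i" for each segment end
        segments = {i: (i, i) for i in range(n)}  # cluster id -> (start, end)
        next_id = n
        for a, b, _ in self.merge_sequence[: n - n_clusters]:
            sa, ea = segments.pop(a)
            sb, eb = segments.pop(b)
            lo, hi = min(sa, sb), max(ea, eb)
            ends.discard(min(ea, eb))
            segments[next_id] = (lo, hi)
            next_id += 1
        return tuple(sorted(e for e in ends if e < n - 1))


def coniss(samples: np.ndarray, ages) -> ZonationResult:
    """Constrained incremental sum-of-squares clustering of ordered samples.

    ``samples`` is an (n, d) array of per-sample composition vectors ordered
    by depth; ``ages`` are the matching calendar ages.  Ties between
    candidate merges are broken toward the shallowest (youngest) pair, which
    makes the tree deterministic.  The significant zone count (broken-stick
    rule, see :func:`n_zones_broken_stick`) and the corresponding boundary
    ages are filled in on the returned result.
    """
    x = np.asarray(samples, dtype=float)
    ages = tuple(float(a) for a in ages)
    if x.ndim != 2:
        raise ValidationError("samples must be a 2-D array (n_samples, n_groups)")
    n = x.shape[0]
    if n < 2:
        raise ValidationError("coniss needs at least 2 samples")
    if len(ages) != n:
        raise ValidationError("ages length must match sample count")
    if not np.all(np.isfinite(x)):
        raise ValidationError("composition vectors must be finite (drop flagged samples)")

    # each active cluster: contiguous [start, end], with sufficient statistics
    class _Seg:
        __slots__ = ("cid", "start", "end", "m", "s", "ss")

        def __init__(self, cid, start, end, m, s, ss):
            self.cid, self.start, self.end = cid, start, end
            self.m, self.s, self.ss = m, s, ss

        @property
        def wss(self):
            return self.ss - float(self.s @ self.s) / self.m

    segs = [
        _Seg(i, i, i, 1, x[i].copy(), float(x[i] @ x[i])) for i in range(n)
    ]
    merges: list[tuple[int, int, float]] = []
    curve = [0.0]
    total = 0.0
    next_id = n

    def merge_cost(a: _Seg, b: _Seg) -> float:
        m = a.m + b.m
        s = a.s + b.s
        wss = (a.ss + b.ss) - float(s @ s) / m
        return wss - a.wss - b.wss

    while len(segs) > 1:
        costs = [merge_cost(segs[i], segs[i + 1]) for i in range(len(segs) - 1)]
        # youngest (shallowest) adjacent pair wins ties: argmin takes the first
        i = int(np.argmin(costs))
        a, b = segs[i], segs[i + 1]
        cost = max(costs[i], 0.0)
        merged = _Seg(
            next_id, a.start, b.end, a.m + b.m, a.s + b.s, a.ss + b.ss
        )
        segs[i : i + 2] = [merged]
        merges.append((a.cid, b.cid, cost))
        total += cost
        curve.append(total)
        next_id += 1

    result = ZonationResult(
        ages=ages,
        merge_sequence=tuple(merges),
        total_dispersion_curve=tuple(curve),
        n_zones=1,
        zone_boundaries=(),
        boundary_positions=(),
    )
    k = n_zones_broken_stick(result)
    positions = result.breaks_at(k)
    boundaries = tuple((ages[i] + ages[i + 1]) / 2.0 for i in positions)
    return ZonationResult(
        ages=ages,
        merge_sequence=result.merge_sequence,
        total_dispersion_curve=result.total_dispersion_curve,
        n_zones=k,
        zone_boundaries=boundaries,
        boundary_positions=positions,
    )


def n_zones_broken_stick(result: ZonationResult) -> int:
    """Significant zone count from the broken-stick null.

    Splitting n samples admits n - 1 successive dispersion reductions
    (``dispersion at k-1 clusters minus dispersion at k``).  Under the null
    these behave like the ordered pieces of a stick of length TSS broken
    into n - 1 parts, whose expected j-th largest piece is
    (TSS / (n-1)) * sum_{i=j}^{n-1} 1/i.  The zone count is the largest k
    such that every reduction for 2..k clusters exceeds its expectation
    (minimum 1).
    """
    n = result.n_samples
    tss = result.dispersion_at(1)
    if n < 3 or tss <= 0.0:
        return 1
    npieces = n - 1
    expected = [
        (tss / npieces) * float(np.sum(1.0 / np.arange(j, npieces + 1)))
        for j in range(1, npieces + 1)
    ]
    k = 1
    for j in range(2, n + 1):
        observed = result.dispersion_at(j - 1) - result.dispersion_at(j)
        if observed > expected[j - 2]:
            k = j
        else:
            break
    return k
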