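"""Connectivity matrices and test-retest reliability statistics.

Connection strengths (fiber counts or summed pruned weights) between pairs of
parcellation regions are compared across two scan visits of a cohort. For each
connection the normalized split ``|c1 - c2| / (c1 + c2)`` is averaged within
participants (V_w: same participant, two visits) and between participants
(V_b: ordered pairs, visit 1 of one against visit 2 of another). Reliability
is the ratio ``phi = V_b / (V_b + V_w)``: phi > 0.5 means a connection
distinguishes people better than it fluctuates across visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Connectome

__all__ = [
    "ConnectivityMatrix",
    "ReliabilityResult",
    "connectivity_matrix",
    "feature_vector",
    "feature_index_map",
    "top_percentile_filter",
    "within_variability",
    "between_variability",
    "reliability_summary",
    "simulate_retest_cohort",
]


@dataclass
class ConnectivityMatrix:
    """One symmetric region-by-region matrix per hemisphere.

    Region labels 1..R belong to the left hemisphere, R+1..2R to the right.
    Inter-hemispheric streamlines are excluded and counted.
    """

    left: np.ndarray  # (R, R) symmetric, non-negative
    right: np.ndarray  # (R, R)
    n_interhemispheric: int = 0

    def __post_init__(self) -> None:
        for m in (self.left, self.right):
            if m.shape[0] != m.shape[1]:
                raise ValueError("hemisphere matrices must be square")
            if not np.allclose(m, m.T):
                raise ValueError("hemisphere matrices must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.left.shape[0]


def connectivity_matrix(
    c: Connectome,
    values: str | np.ndarray = "count",
    labels: np.ndarray | None = None,
    r_per_hemisphere: int = 34,
) -> ConnectivityMatrix:
    """Accumulate streamlines into per-hemisphere region matrices.

    ``values`` is either "count" (entry = number of fibers joining the two
    regions) or a per-streamline weight vector (entry = summed weights).
    Endpoint labels come from ``labels`` or from the connectome itself.
    """
    if labels is None:
        labels = c.labels
    if labels is None:
        raise ValueError("endpoint region labels are required")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(c), 2):
        raise ValueError("labels must be (n_streamlines, 2)")
    R = int(r_per_hemisphere)
    if labels.size and (labels.min() < 1 or labels.max() > 2 * R):
        raise ValueError("endpoint label out of range 1..2R")
    if isinstance(values, str):
        if values != "count":
            raise ValueError("values must be 'count' or a weight vector")
        vals = np.ones(len(c))
    else:
        vals = np.asarray(values, dtype=float)
        if vals.shape != (len(c),):
            raise ValueError("weight vector must have one entry per streamline")

    left = np.zeros((R, R))
    right = np.zeros((R, R))
    n_inter = 0
    for (a, b), v in zip(labels, vals):
        hemi_a, hemi_b = (a - 1) // R, (b - 1) // R
        if hemi_a != hemi_b:
            n_inter += 1
            continue
        m = left if hemi_a == 0 else right
        i, j = (a - 1) % R, (b - 1) % R
        m[i, j] += v
        if i != j:
            m[j, i] += v
    return ConnectivityMatrix(left, right, n_inter)


def feature_index_map(r_per_hemisphere: int) -> list:
    """Feature position -> (hemisphere, i, j) for the vectorization below."""
    out = []
    for hemi in (0, 1):
        for i in range(r_per_hemisphere):
            for j in range(i + 1, r_per_hemisphere):
                out.append((hemi, i, j))
    return out


def feature_vector(m: ConnectivityMatrix) -> np.ndarray:
    """Intra-hemispheric, off-diagonal, unordered-pair features.

    Concatenates the strict upper triangle of the left then the right
    hemisphere matrix, row-major; length 2 * R(R-1)/2 (1,122 for R = 34).
    """
    iu = np.triu_indices(m.n_regions, k=1)
    return np.concatenate([m.left[iu], m.right[iu]])


def top_percentile_filter(values: np.ndarray, percentile: float = 50.0) -> np.ndarray:
    """Indices of the connections in the top percentile of a summary value.

    Keeps the top ``floor(n * (100 - percentile) / 100)`` connections ranked by
    value (ties broken toward the lower index); for the default 50th
    percentile that is floor(n/2) connections (561 of 1,122).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("no connections to filter")
    n_keep = int(np.floor(n * (100.0 - percentile) / 100.0))
    order = np.lexsort((np.arange(n), -values))  # by value desc, then index asc
    return np.sort(order[:n_keep])


def _normalized_split(a: np.ndarray, b: np.ndarray) -> tuple:
    """|a - b| / (a + b) with both-zero pairs flagged undefined."""
    denom = a + b
    defined = denom > 0
    out = np.zeros_like(denom, dtype=float)
    out[defined] = np.abs(a - b)[defined] / denom[defined]
    return out, defined


def within_variability(c1: np.ndarray, c2: np.ndarray) -> tuple:
    """Average within-participant variability per connection.

    ``c1``/``c2`` hold visit-1/visit-2 connection values, shape
    (participants, connections). Both-zero participant-connection pairs are
    excluded from the average; returns (V_w, n_excluded) per connection, with
    NaN where every participant is undefined.
    """
    c1 = np.atleast_2d(np.asarray(c1, dtype=float))
    c2 = np.atleast_2d(np.asarray(c2, dtype=float))
    if c1.shape != c2.shape:
        raise ValueError("visit arrays must be aligned")
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("connection values must be non-negative")
    v, defined = _normalized_split(c1, c2)
    counts = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        vw = np.where(counts > 0, v.sum(axis=0) / np.maximum(counts, 1), np.nan)
    return vw, (c1.shape[0] - counts)


def between_variability(c1: np.ndarray, c2: np.ndarray) -> tuple:
    """Average between-participant variability per connection.

    Averages the normalized split over all *ordered* participant pairs (l, m),
    l != m, pairing participant l's visit 1 with participant m's visit 2.
    Returns (V_b, n_excluded_pairs) per connection.
    """
    c1 = np.atleast_2d(np.asarray(c1, dtype=float))
    c2 = np.atleast_2d(np.asarray(c2, dtype=float))
    if c1.shape != c2.shape:
        raise ValueError("visit arrays must be aligned")
    P = c1.shape[0]
    if P < 2:
        raise ValueError("between-participant variability needs >= 2 participants")
    a = c1[:, None, :]  # participant l, visit 1
    b = c2[None, :, :]  # participant m, visit 2
    denom = a + b
    off = ~np.eye(P, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.abs(a - b) / denom
    defined = (denom > 0) & off[:, :, None]
    counts = defined.sum(axis=(0, 1))
    sums = np.where(defined, np.nan_to_num(v), 0.0).sum(axis=(0, 1))
    vb = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return vb, (P * (P - 1) - counts)


@dataclass
class ReliabilityResult:
    phi: np.ndarray  # V_b / (V_b + V_w), NaN where undefined
    delta_vw: np.ndarray  # pruned - unpruned
    delta_vb: np.ndarray
    quadrant: np.ndarray  # "high" | "low" | "neither" per connection
    n_high: int
    n_low: int
    p_binomial: float  # one-sided, high vs low, p = 0.5

    @property
    def mean_phi(self) -> float:
        return float(np.nanmean(self.phi))


def reliability_summary(
    vb: np.ndarray,
    vw: np.ndarray,
    vb_unpruned: np.ndarray | None = None,
    vw_unpruned: np.ndarray | None = None,
) -> ReliabilityResult:
    """Reliability ratio, variability changes and quadrant proportions.

    ``phi = V_b / (V_b + V_w)`` per connection. When unpruned baselines are
    given, each connection is placed on the (delta V_w, delta V_b) plane:
    "high"-reliability connections moved toward lower within- and higher
    between-participant variability (delta V_w < 0 < delta V_b, strictly),
    "low" the opposite; boundary cases count as neither. A one-sided binomial
    test asks whether high-reliability connections outnumber low ones.
    """
    vb = np.asarray(vb, dtype=float)
    vw = np.asarray(vw, dtype=float)
    if vb.shape != vw.shape:
        raise ValueError("V_b and V_w must be aligned")
    total = vb + vw
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(total > 0, vb / total, np.nan)

    if vb_unpruned is None or vw_unpruned is None:
        nanv = np.full_like(vb, np.nan)
        return ReliabilityResult(
            phi, nanv, nanv.copy(), np.full(vb.shape, "neither", dtype=object),
            0, 0, float("nan"),
        )
    dvw = vw - np.asarray(vw_unpruned, dtype=float)
    dvb = vb - np.asarray(vb_unpruned, dtype=float)
    quadrant = np.full(vb.shape, "neither", dtype=object)
    quadrant[(dvb > 0) & (dvw < 0)] = "high"
    quadrant[(dvb < 0) & (dvw > 0)] = "low"
    n_high = int(np.sum(quadrant == "high"))
    n_low = int(np.sum(quadrant == "low"))
    if n_high + n_low > 0:
        p = stats.binomtest(n_high, n_high + n_low, 0.5, alternative="greater").pvalue
    else:
        p = float("nan")
    return ReliabilityResult(phi, dvw, dvb, quadrant, n_high, n_low, float(p))


def simulate_retest_cohort(
    n_participants: int = 5,
    n_connections: int = 50,
    between_sd: float = 0.5,
    within_sd: float = 0.05,
    seed: int = 0,
) -> tuple:
    """Two-visit synthetic connection-strength tables.

    Each connection has a lognormal base strength. Each participant scales it
    by a stable (trait) lognormal effect of spread ``between_sd``, and the two
    visits straddle that trait value by a per-participant, per-connection
    session-state excursion of spread ``within_sd`` (visit 1 at ``+d``, visit
    2 at ``-d`` on the log scale), so ``within_sd`` directly sets the planted
    within-participant visit-to-visit variability while leaving each visit's
    marginal distribution symmetric. Returns (visit1, visit2), shape
    (participants, connections). With between_sd >> within_sd connections are
    reliable (phi > 0.5); reversed spreads give phi < 0.5; within_sd = 0 makes
    the visits identical (V_w = 0, phi = 1).
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=2.0, sigma=0.5, size=n_connections)
    trait = rng.normal(0.0, between_sd, size=(n_participants, 1))
    state = rng.normal(0.0, within_sd, size=(n_participants, n_connections))
    visit1 = base[None, :] * np.exp(trait + state)
    visit2 = base[None, :] * np.exp(trait - state)
    return visit1, visit2
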