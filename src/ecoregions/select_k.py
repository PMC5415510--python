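"""Choose the number of regions against a random-clustering null.

The within-region sum of squares (SSW) decreases monotonically in k even
for purely random labels — for uniform random partitions its expectation
is TotalSS·(n−k)/(n−1), exactly linear in k — so an elbow on the SSW curve
alone is not evidence of structure.  Instead, the SSW-vs-k curve of
spatially constrained spectral clustering is compared with the mean SSW
curve of random clusterings through the ratio of slopes

    Δslope(k) = Slope_SSC(k) / Slope_random(k),

where each slope is the per-unit-k finite difference of its SSW curve over
a grid interval (attributed to the interval midpoint, where a finite
difference estimates the derivative).  While constrained clustering is
still discovering real regional structure, each added region removes far
more SSW than a random partition would and the ratio is far from 1; once
the structure is exhausted the constrained curve declines like the null
and the ratio settles near 1.  Because the empirical ratio fluctuates, it
is averaged over windows [k − w/2, k + w/2]; the chosen k is the first
window center (scanning k upward) at which |window average − 1| attains a
local minimum, windows whose average equals 1 exactly being excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterConfig, cluster_regions
from .evaluate import within_between_ss
from .io import AdjacencyGraph
from .preprocess import FeatureEmbedding

log = logging.getLogger(__name__)


def default_k_grid() -> list[int]:
    """Step 5 over 5–600, step 10 over 610–800, step 50 over 850–1000."""
    return (list(range(5, 601, 5)) + list(range(610, 801, 10))
            + list(range(850, 1001, 50)))


@dataclass
class KSelectionConfig:
    delta: int
    k_grid: list[int] = field(default_factory=default_k_grid)
    n_random: int = 200
    window_halfwidth: int = 10   # w/2; window spans [k - w/2, k + w/2]
    restarts_per_k: int = 10
    seed: int = 0
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        g = list(self.k_grid)
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ValueError("k_grid must be strictly increasing")
        if g[0] < 2:
            raise ValueError("k_grid must start at k >= 2")
        if self.n_random < 2:
            raise ValueError("n_random must be >= 2")
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")


@dataclass
class KSelectionCurve:
    """SSW-vs-k curves plus the derived slope-ratio statistics.

    ``slope_ssc`` / ``slope_random`` are per-interval finite differences
    (ΔSSW/Δk); ``slope_ratio`` their ratio, located at ``interval_mid``
    (NaN where the null slope is zero).  ``window_avg`` is the ratio
    averaged over the window centered at each grid point (NaN = no usable
    ratio in the window).
    """

    k: np.ndarray
    ssw_ssc: np.ndarray
    ssw_random_mean: np.ndarray
    slope_ssc: np.ndarray | None = None
    slope_random: np.ndarray | None = None
    slope_ratio: np.ndarray | None = None
    interval_mid: np.ndarray | None = None
    window_avg: np.ndarray | None = None
    chosen_k: int | None = None
    chosen_window: tuple[float, float] | None = None

    def to_frame(self):
        import pandas as pd

        cols = {"k": self.k, "ssw_ssc": self.ssw_ssc,
                "ssw_random_mean": self.ssw_random_mean}
        if self.window_avg is not None:
            cols["window_avg"] = self.window_avg
        return pd.DataFrame(cols)


def ssw_vs_k_curves(embedding: FeatureEmbedding, graph: AdjacencyGraph,
                    config: KSelectionConfig,
                    space: np.ndarray | None = None) -> KSelectionCurve:
    """SSW(k) for constrained spectral clustering and for the random null.

    For each k on the grid one SSC regionalization (with ``config.delta``)
    is scored, together with the mean SSW of ``n_random`` independent
    random clusterings.  Both SSWs are computed in ``space`` (default: the
    embedding scores).  All seeds derive from ``config.seed``.
    """
    if space is None:
        space = embedding.scores
    n = space.shape[0]
    root = np.random.SeedSequence(config.seed)
    grid = [k for k in config.k_grid if k < n]
    skipped = [k for k in config.k_grid if k >= n]
    if skipped:
        warnings.warn(f"skipping grid k >= n: {skipped}", stacklevel=2)

    ssw_ssc = np.empty(len(grid))
    ssw_rand = np.empty(len(grid))
    for i, (k, ss) in enumerate(zip(grid, root.spawn(len(grid)))):
        k_seeds = ss.generate_state(1 + config.n_random) % (2**31 - 1)
        reg = cluster_regions(
            embedding, graph,
            ClusterConfig(k=k, method="SSC", delta=config.delta,
                          restarts=config.restarts_per_k, seed=int(k_seeds[0]),
                          bandwidth=config.bandwidth),
        )
        ssw_ssc[i], _, _ = within_between_ss(space, reg.label)
        acc = 0.0
        for s in k_seeds[1:]:
            rnd = cluster_regions(None, None,
                                  ClusterConfig(k=k, method="RANDOM", seed=int(s)),
                                  unit_ids=list(embedding.unit_id))
            w, _, _ = within_between_ss(space, rnd.label)
            acc += w
        ssw_rand[i] = acc / config.n_random
    return KSelectionCurve(k=np.array(grid), ssw_ssc=ssw_ssc, ssw_random_mean=ssw_rand)


def select_optimal_k(curve: KSelectionCurve, config: KSelectionConfig) -> KSelectionCurve:
    """Complete the curve: slopes, slope ratios, window averages, chosen k.

    The slope ratio over each grid interval (ΔSSW_SSC / ΔSSW_random, sited
    at the interval midpoint) is averaged over the window
    [k − w/2, k + w/2] around every grid point k.  Ratios with a zero null
    slope are excluded (logged); windows averaging exactly 1 carry no
    information and are excluded too.  Scanning centers in increasing k,
    the chosen k is the first local minimum of |window average − 1| —
    the first window at which the constrained curve has come closest to
    declining like the random null.
    """
    k = np.asarray(curve.k, dtype=float)
    if k.size < 5:
        raise ValueError("need at least 5 grid points to select k")
    slope_ssc = np.diff(curve.ssw_ssc) / np.diff(k)
    slope_rand = np.diff(curve.ssw_random_mean) / np.diff(k)
    mid = (k[:-1] + k[1:]) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(slope_rand != 0, slope_ssc / slope_rand, np.nan)
    for j in np.flatnonzero(slope_rand == 0):
        log.info("null slope zero on interval (%g, %g); ratio excluded",
                 k[j], k[j + 1])

    w2 = config.window_halfwidth
    m = k.size
    window_avg = np.full(m, np.nan)
    for j in range(m):
        in_win = (mid >= k[j] - w2) & (mid <= k[j] + w2) & ~np.isnan(ratio)
        if in_win.any():
            window_avg[j] = ratio[in_win].mean()

    dist = np.abs(window_avg - 1.0)
    dist[np.isnan(window_avg) | (window_avg == 1.0)] = np.inf
    if not np.isfinite(dist).any():
        raise ValueError(
            "no informative window: SSW curves indistinguishable from random")

    # first local minimum, with a relative tolerance so flat stretches of the
    # distance curve (equal up to round-off) do not register as upturns
    rtol = 1e-9
    j_star = None
    running_min = np.inf
    for j in range(m):
        if np.isfinite(dist[j]):
            nxt = dist[j + 1] if j + 1 < m else np.inf
            at_min = dist[j] <= running_min * (1 + rtol) + 1e-12
            upturn = nxt > dist[j] * (1 + rtol) + 1e-12
            if at_min and upturn:
                j_star = j
                break
            running_min = min(running_min, dist[j])
    if j_star is None:  # monotone decrease: closest approach is the last center
        j_star = int(np.nanargmin(dist))

    return KSelectionCurve(
        k=curve.k, ssw_ssc=curve.ssw_ssc, ssw_random_mean=curve.ssw_random_mean,
        slope_ssc=slope_ssc, slope_random=slope_rand, slope_ratio=ratio,
        interval_mid=mid, window_avg=window_avg, chosen_k=int(k[j_star]),
        chosen_window=(float(k[j_star] - w2), float(k[j_star] + w2)),
    )


def choose_k(embedding: FeatureEmbedding, graph: AdjacencyGraph,
             config: KSelectionConfig, space: np.ndarray | None = None) -> KSelectionCurve:
    """Convenience: compute the curves then select the optimal window."""
    return select_optimal_k(ssw_vs_k_curves(embedding, graph, config, space=space), config)
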