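"""Dependent multidimensional DTW with open endpoints and a Sakoe-Chiba band.

This is the similarity engine of the package: every pair of motifs is
compared, feature by feature, with a dynamic-time-warping variant designed
for segmented melodic phrases:

* **dependent** — for a 3-D kinematic series all three axes share one
  warping path and the local cost is the Euclidean norm of the frame
  difference (for 1-D sonic series this reduces to ``|a_i - b_j|``);
* **open-ended** — the path may start and end within a margin of
  ``open_frac * L`` frames of each series' extremes (``L`` = length of the
  longer series), absorbing small segmentation-point jitter;
* **banded** — a slope-corrected Sakoe-Chiba corridor of half-width
  ``ceil(band_frac * L)`` excludes alignments of temporally distant frames.

The admissible path set is: monotone paths with steps (1,0), (0,1), (1,1),
every cell inside the band, the first cell ``(i, j)`` with
``i <= m and j <= m`` and the last cell with ``i >= n_a-1-m and
j >= n_b-1-m`` where ``m = ceil(open_frac * L)``.  The distance is the
minimum total path cost, optionally divided by the number of cells of the
(shortest) optimal path.  The band test is symmetric in the two series,
``L * |i/n_a - j/n_b| <= width``, so ``d(a, b) == d(b, a)`` holds also for
unequal lengths.

Relaxing ``open_frac`` enlarges the admissible path set, so the
un-normalized distance is non-increasing in ``open_frac``; likewise for
``band_frac``.  With ``open_frac = 0`` and ``band_frac = 1`` the distance
equals textbook fixed-endpoint DTW.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DtwParams",
    "dtw_distance",
    "build_distance_table",
    "SONIC_FEATURES",
    "KINEMATIC_FEATURES",
    "FEATURE_COLUMNS",
    "PAIR_COLUMNS",
]

SONIC_FEATURES = ("f0", "delta_f0", "loudness", "spectral_centroid")
KINEMATIC_FEATURES = (
    "hand_pos",
    "head_pos",
    "hand_vel",
    "head_vel",
    "hand_acc",
    "head_acc",
)
FEATURE_COLUMNS = SONIC_FEATURES + KINEMATIC_FEATURES
PAIR_COLUMNS = ("motif_i", "motif_j", "performer_i", "performer_j", "same_performer")


@dataclass(frozen=True)
class DtwParams:
    """Alignment parameters.

    band_frac
        Sakoe-Chiba half-width as a fraction of the longer series length.
    open_frac
        Endpoint margin as a fraction of the longer series length.
    normalize_by_path
        Divide the optimal total cost by the optimal path's cell count.
    """

    band_frac: float = 0.1
    open_frac: float = 0.1
    local_metric: str = "euclidean"
    normalize_by_path: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.band_frac <= 1.0:
            raise ValueError(f"band_frac must be in (0, 1], got {self.band_frac}")
        if not 0.0 <= self.open_frac < 0.5:
            raise ValueError(f"open_frac must be in [0, 0.5), got {self.open_frac}")
        if self.local_metric != "euclidean":
            raise ValueError(f"unsupported local metric: {self.local_metric!r}")


@njit(cache=True)
def _dtw_band(a, b, band_w, margin, normalize):  # pragma: no cover - jitted
    na, nb = a.shape[0], b.shape[0]
    d = a.shape[1]
    INF = np.inf
    # cost and path-length (cells) per lattice cell; band stored row-wise
    cost = np.full((na, nb), INF)
    plen = np.zeros((na, nb), dtype=np.int64)
    L = max(na, nb)
    for i in range(na):
        # symmetric slope-corrected band: L * |i/na - j/nb| <= band_w.
        # Conservative index range, then the exact same float test the
        # enumeration oracle uses, so boundary cells agree bit-for-bit.
        lo = int(math.floor((i / na - band_w / L) * nb)) - 1
        hi = int(math.ceil((i / na + band_w / L) * nb)) + 1
        if lo < 0:
            lo = 0
        if hi > nb - 1:
            hi = nb - 1
        for j in range(lo, hi + 1):
            if L * abs(i / na - j / nb) > band_w:
                continue
            loc = 0.0
            for k in range(d):
                diff = a[i, k] - b[j, k]
                loc += diff * diff
            loc = math.sqrt(loc)
            # lexicographic (cost, path length) minimum over predecessors
            best = INF
            blen = 0
            if i > 0 and j > 0 and cost[i - 1, j - 1] < INF:
                c = cost[i - 1, j - 1]
                if c < best or (c == best and plen[i - 1, j - 1] < blen):
                    best = c
                    blen = plen[i - 1, j - 1]
            if i > 0 and cost[i - 1, j] < INF:
                c = cost[i - 1, j]
                if c < best or (c == best and plen[i - 1, j] < blen):
                    best = c
                    blen = plen[i - 1, j]
            if j > 0 and cost[i, j - 1] < INF:
                c = cost[i, j - 1]
                if c < best or (c == best and plen[i, j - 1] < blen):
                    best = c
                    blen = plen[i, j - 1]
            if i <= margin and j <= margin:
                # fresh path start: zero accumulated cost, zero cells
                if best > 0.0 or blen > 0:
                    best = 0.0
                    blen = 0
            if best == INF:
                continue
            cost[i, j] = best + loc
            plen[i, j] = blen + 1
    # admissible end cells
    res = INF
    rlen = 1
    for i in range(na - 1 - margin, na):
        if i < 0:
            continue
        for j in range(nb - 1 - margin, nb):
            if j < 0:
                continue
            c = cost[i, j]
            if c < res or (c == res and plen[i, j] < rlen):
                res = c
                rlen = plen[i, j]
    if res == INF:
        return -1.0
    if normalize:
        return res / rlen
    return res


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"series must be 1-D or 2-D, got shape {x.shape}")
    return np.ascontiguousarray(x)


def dtw_distance(a: np.ndarray, b: np.ndarray, params: DtwParams | None = None) -> float:
    """Open-ended banded dependent DTW distance between two series.

    Parameters
    ----------
    a, b
        Arrays of shape ``(n,)`` or ``(n, d)``; both series must share ``d``.
    params
        Alignment parameters; defaults reproduce the 0.1L margins.
    """
    params = params or DtwParams()
    a2, b2 = _as_2d(a), _as_2d(b)
    if a2.shape[0] == 0 or b2.shape[0] == 0:
        raise ValueError("DTW requires nonempty series")
    if a2.shape[1] != b2.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: {a2.shape[1]} vs {b2.shape[1]}"
        )
    if not (np.all(np.isfinite(a2)) and np.all(np.isfinite(b2))):
        raise ValueError("series contain non-finite values")
    L = max(a2.shape[0], b2.shape[0])
    band_w = math.ceil(params.band_frac * L)
    margin = math.ceil(params.open_frac * L)
    res = _dtw_band(a2, b2, band_w, margin, params.normalize_by_path)
    if res < 0:
        raise ValueError(
            f"no admissible warping path for lengths {a2.shape[0]}, {b2.shape[0]} "
            f"(band={band_w}, margin={margin})"
        )
    return float(res)


def dtw_distance_bruteforce(
    a: np.ndarray, b: np.ndarray, params: DtwParams | None = None
) -> float:
    """Exhaustive path-enumeration DTW, tractable only for short series.

    Enumerates every admissible monotone warping path under the same band,
    margin and step rules as :func:`dtw_distance` and returns the minimum
    total cost (divided by the shortest optimal path's length when
    normalizing).  Used as an independent oracle in the test suite and the
    acceptance run; it shares no code with the dynamic program.
    """
    params = params or DtwParams()
    a2, b2 = _as_2d(a), _as_2d(b)
    na, nb = a2.shape[0], b2.shape[0]
    L = max(na, nb)
    band_w = math.ceil(params.band_frac * L)
    margin = math.ceil(params.open_frac * L)

    def in_band(i: int, j: int) -> bool:
        return L * abs(i / na - j / nb) <= band_w

    local = np.linalg.norm(a2[:, None, :] - b2[None, :, :], axis=2)
    best_cost = math.inf
    best_len = 0
    steps = ((1, 1), (1, 0), (0, 1))
    stack: list[tuple[int, int, float, int]] = []
    for si in range(min(margin, na - 1) + 1):
        for sj in range(min(margin, nb - 1) + 1):
            if in_band(si, sj):
                stack.append((si, sj, local[si, sj], 1))
    while stack:
        i, j, c, ln = stack.pop()
        if c > best_cost:
            continue
        if i >= na - 1 - margin and j >= nb - 1 - margin:
            if c < best_cost or (c == best_cost and ln < best_len):
                best_cost = c
                best_len = ln
            # a path may also continue past an admissible end cell
        for di, dj in steps:
            ni, nj = i + di, j + dj
            if ni < na and nj < nb and in_band(ni, nj):
                stack.append((ni, nj, c + local[ni, nj], ln + 1))
    if not math.isfinite(best_cost):
        raise ValueError("no admissible warping path")
    if params.normalize_by_path:
        return best_cost / best_len
    return best_cost


def pair_metadata(motif_table: pd.DataFrame, excluded: set | None = None) -> pd.DataFrame:
    """Unordered-pair skeleton of the distance table (no distances yet).

    One row per pair (i < j in table order) of non-excluded motifs, with
    performer metadata; ``build_distance_table`` fills its distance columns.
    """
    excluded = excluded or set()
    ids = [m for m in motif_table["motif_id"] if m not in excluded]
    if len(ids) < 2:
        raise ValueError("need at least 2 motifs to build a distance table")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate motif ids")
    performer = dict(zip(motif_table["motif_id"], motif_table["performer_id"]))
    mi, mj = zip(*itertools.combinations(ids, 2))
    pi = [performer[m] for m in mi]
    pj = [performer[m] for m in mj]
    return pd.DataFrame(
        {
            "motif_i": mi,
            "motif_j": mj,
            "performer_i": pi,
            "performer_j": pj,
            "same_performer": [a == b for a, b in zip(pi, pj)],
        }
    )


def build_distance_table(
    sonic: dict,
    kinematic: dict,
    motif_table: pd.DataFrame,
    params: DtwParams | None = None,
    excluded: set | None = None,
) -> pd.DataFrame:
    """All-pairs 10-feature DTW distance table.

    Parameters
    ----------
    sonic, kinematic
        Mappings ``motif_id -> SonicFeatures`` / ``motif_id -> KinematicFeatures``
        (any objects exposing the feature-series attributes named in
        ``SONIC_FEATURES`` / ``KINEMATIC_FEATURES``).
    motif_table
        DataFrame with at least ``motif_id`` and ``performer_id`` columns;
        its row order fixes motif ordering.
    excluded
        Motif ids to drop before pairing (e.g. motifs whose pitch track
        kept an uninterpolatable gap).

    Returns
    -------
    DataFrame with one row per unordered motif pair (i < j in table order),
    pair metadata and the 10 DTW distance columns.
    """
    params = params or DtwParams()
    table = pair_metadata(motif_table, excluded)
    ids = sorted(set(table["motif_i"]) | set(table["motif_j"]))
    for m in ids:
        if m not in sonic or m not in kinematic:
            raise ValueError(f"motif {m!r} lacks feature series")

    series: dict[str, dict] = {}
    for feat in SONIC_FEATURES:
        series[feat] = {m: _as_2d(getattr(sonic[m], feat)) for m in ids}
    for feat in KINEMATIC_FEATURES:
        series[feat] = {m: _as_2d(getattr(kinematic[m], feat)) for m in ids}

    for feat in FEATURE_COLUMNS:
        s = series[feat]
        table[feat] = [
            dtw_distance(s[mi], s[mj], params)
            for mi, mj in zip(table["motif_i"], table["motif_j"])
        ]
    return table[list(PAIR_COLUMNS) + list(FEATURE_COLUMNS)]
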