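"""Conventional phenotypic distances and distance-matrix assembly.

Correlation distance (1 − Pearson r) is the field's traditional metric for
motion-index traces; Euclidean and dynamic-time-warping distances are the
other baselines.  DTW is provided both as an exact O(nm) dynamic program
and as the banded multiresolution approximation (coarsen, solve, project,
refine within a radius-constrained window) popularized as FastDTW; the
exact form is the oracle for the approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "correlation_distance",
    "euclidean_distance",
    "dtw_distance",
    "dtw_exact",
    "pairwise_distance_matrix",
    "cross_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Labeled (possibly rectangular) matrix of non-negative distances."""

    values: np.ndarray
    ids: list[str]
    metric: str = ""
    column_ids: list[str] | None = None   # set for rectangular query x library
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        col_ids = self.column_ids if self.column_ids is not None else self.ids
        if self.values.shape != (len(self.ids), len(col_ids)):
            raise ValueError("distance matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")

    @property
    def is_square(self) -> bool:
        return self.column_ids is None


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − Pearson correlation; a zero-variance member yields distance 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("correlation distance needs length >= 2")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        warnings.warn("zero-variance trace in correlation distance; returning 1.0")
        return 1.0
    r = float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))
    return 1.0 - r


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def dtw_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Full dynamic-programming DTW with the standard step pattern and
    absolute-difference local cost."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW needs non-empty traces")
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    cost = np.abs(a[:, None] - b[None, :])
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(D[n, m])


def _dtw_windowed(a: np.ndarray, b: np.ndarray, window: list[tuple[int, int]]) -> float:
    D: dict[tuple[int, int], float] = {(0, 0): 0.0}
    for i, j in window:
        D[(i + 1, j + 1)] = np.inf
    for i, j in window:
        c = abs(a[i] - b[j])
        D[(i + 1, j + 1)] = c + min(D.get((i, j + 1), np.inf),
                                    D.get((i + 1, j), np.inf),
                                    D.get((i, j), np.inf))
    return float(D[(a.size, b.size)])


def _expand_window(path: list[tuple[int, int]], n: int, m: int, radius: int):
    cells = set()
    for i, j in path:
        for di in range(-radius, radius + 1):
            for dj in range(-radius, radius + 1):
                cells.add((i + di, j + dj))
    window = set()
    for i, j in cells:   # project each low-res cell onto the 2x2 block above
        for a_ in (2 * i, 2 * i + 1):
            for b_ in (2 * j, 2 * j + 1):
                if 0 <= a_ < n and 0 <= b_ < m:
                    window.add((a_, b_))
    return sorted(window)


def _dtw_path(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = abs(a[i - 1] - b[j - 1]) + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        step = int(np.argmin([D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]]))
        if step == 0:
            i, j = i - 1, j - 1
        elif step == 1:
            i -= 1
        else:
            j -= 1
    return path[::-1]


def _fastdtw(a: np.ndarray, b: np.ndarray, radius: int) -> tuple[float, list[tuple[int, int]]]:
    min_size = radius + 2
    if a.size <= min_size or b.size <= min_size:
        return dtw_exact(a, b), _dtw_path(a, b)
    half_a = (a[: a.size // 2 * 2].reshape(-1, 2)).mean(axis=1)
    half_b = (b[: b.size // 2 * 2].reshape(-1, 2)).mean(axis=1)
    _, coarse_path = _fastdtw(half_a, half_b, radius)
    window = _expand_window(coarse_path, a.size, b.size, radius)
    cost = _dtw_windowed(a, b, window)
    # recover a path inside the window for the next refinement level up
    path = _windowed_path(a, b, window)
    return cost, path


def _windowed_path(a, b, window) -> list[tuple[int, int]]:
    D: dict[tuple[int, int], float] = {(0, 0): 0.0}
    order = window
    for i, j in order:
        c = abs(a[i] - b[j])
        D[(i + 1, j + 1)] = c + min(D.get((i, j + 1), np.inf),
                                    D.get((i + 1, j), np.inf),
                                    D.get((i, j), np.inf))
    path = []
    i, j = a.size, b.size
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        options = [(D.get((i - 1, j - 1), np.inf), (i - 1, j - 1)),
                   (D.get((i - 1, j), np.inf), (i - 1, j)),
                   (D.get((i, j - 1), np.inf), (i, j - 1))]
        _, (i, j) = min(options, key=lambda t: t[0])
    return path[::-1]


def dtw_distance(a: np.ndarray, b: np.ndarray, radius: int = 1) -> float:
    """Banded multiresolution DTW; ``radius=None`` or a radius covering the
    full plane reproduces :func:`dtw_exact`."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW needs non-empty traces")
    if radius is None or radius >= max(a.size, b.size):
        return dtw_exact(a, b)
    cost, _ = _fastdtw(a, b, int(radius))
    return cost


def pairwise_distance_matrix(data: np.ndarray, metric, ids: list[str],
                             metric_name: str = "") -> DistanceMatrix:
    """Symmetric all-by-all matrix; the metric is called once per unordered pair."""
    data = np.asarray(data)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 entities")
    if len(ids) != n:
        raise ValueError("ids length does not match data")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(metric(data[i], data[j]))
            if not np.isfinite(d) or d < 0:
                raise ValueError(f"metric returned invalid distance {d} for pair ({i}, {j})")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values=values, ids=list(ids),
                          metric=metric_name or getattr(metric, "__name__", "custom"))


def cross_distance_matrix(queries: np.ndarray, library: np.ndarray, metric,
                          query_ids: list[str], library_ids: list[str],
                          metric_name: str = "") -> DistanceMatrix:
    """Rectangular query x library distance matrix."""
    queries = np.asarray(queries)
    library = np.asarray(library)
    values = np.zeros((queries.shape[0], library.shape[0]))
    for i in range(queries.shape[0]):
        for j in range(library.shape[0]):
            d = float(metric(queries[i], library[j]))
            if not np.isfinite(d) or d < 0:
                raise ValueError(f"metric returned invalid distance {d} for pair ({i}, {j})")
            values[i, j] = d
    return DistanceMatrix(values=values, ids=list(query_ids),
                          column_ids=list(library_ids),
                          metric=metric_name or getattr(metric, "__name__", "custom"))
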