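"""Per-window features of the beat-to-beat AC amplitude series.

Eight features summarise each stressor-phase window of the AC series
``X = {x_1..x_N}`` (N is typically 60-140 beats):

* ``mean`` and ``sd`` — location and spread (population form, divisor N);
* ``katz``, ``petrosian``, ``higuchi`` — fractal dimensions of the short
  waveform, measuring curve-length and sign-change complexity;
* ``sampen`` — sample entropy at the conventional (m=2, r=0.15*sd) point,
  which on short windows is frequently undefined (no template matches);
* ``total_sampen`` and ``avg_sampen`` — sum and mean of the sample-entropy
  profile SampEn(r) evaluated over the data-driven set of distinct template
  distances, which stays defined where single-r SampEn fails.

Undefined entropy values are returned as ``None`` and propagate as missing
cells; they are never silently replaced by a number.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_M = 2
DEFAULT_R_FRAC = 0.15
DEFAULT_K_MAX = 8
# Amplitude resolution used to quantize template distances before building
# the data-driven tolerance grid. Emulates the finite measurement
# resolution of real AC series; without it every pairwise distance of a
# continuous-valued series is distinct and the profile size q carries no
# information about signal regularity.
DEFAULT_R_RESOLUTION = 0.001
# Grid cap for very long windows (uniform subsampling above this size).
MAX_PROFILE_POINTS = 1000


@dataclass
class EntropyProfile:
    """SampEn evaluated over the data-driven tolerance grid."""

    r_grid: np.ndarray
    sampen_values: np.ndarray

    @property
    def q(self) -> int:
        return len(self.r_grid)


@dataclass
class FeatureVector:
    mean: float
    sd: float
    katz: float | None
    petrosian: float | None
    higuchi: float | None
    sampen: float | None
    total_sampen: float | None
    avg_sampen: float | None
    q: int | None

    FIELDS = ("mean", "sd", "katz", "petrosian", "higuchi", "sampen",
              "total_sampen", "avg_sampen")

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.FIELDS}
        d["q"] = self.q
        return d


def _as_window(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("empty window")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    return x


def mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation (divisor N)."""
    x = _as_window(values)
    mu = float(np.mean(x))
    return mu, float(np.sqrt(np.mean((x - mu) ** 2)))


def katz_fd(values) -> float:
    """Katz fractal dimension of the planar curve (i, x_i), unit abscissa.

    ``log(S/M) / log(d/M)`` with S the total and M the mean Euclidean
    distance between successive points, and d the largest distance from the
    first point to any other.
    """
    x = _as_window(values)
    n = len(x)
    if n < 3:
        raise ValueError("Katz needs at least 3 points")
    steps = np.sqrt(1.0 + np.diff(x) ** 2)
    s = float(np.sum(steps))
    m = s / (n - 1)
    i = np.arange(1, n, dtype=float)
    d = float(np.max(np.sqrt(i ** 2 + (x[1:] - x[0]) ** 2)))
    if m == 0 or d == m:
        raise ValueError("degenerate curve: d == M or M == 0")
    return math.log(s / m) / math.log(d / m)


def petrosian_fd(values) -> float:
    """Petrosian fractal dimension from the mean-threshold binary sequence."""
    x = _as_window(values)
    n = len(x)
    if n < 2:
        raise ValueError("Petrosian needs at least 2 points")
    binary = x > np.mean(x)
    n_delta = int(np.count_nonzero(binary[1:] != binary[:-1]))
    log_n = math.log10(n)
    return log_n / (log_n + math.log10(n / (n + 0.4 * n_delta)))


def higuchi_fd(values, k_max: int = DEFAULT_K_MAX) -> float:
    """Higuchi fractal dimension: least-squares slope of log<L(k)> on log(1/k).

    L_m(k) is the normalized length of the decimated curve starting at
    offset m with stride k; <L(k)> averages over the k offsets.
    """
    x = _as_window(values)
    n = len(x)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 2 * k_max:
        raise ValueError(f"window of {n} too short for k_max={k_max}")
    ks = np.arange(1, k_max + 1)
    avg_lengths = np.empty(len(ks))
    for j, k in enumerate(ks):
        lengths = []
        for m in range(1, k + 1):
            idx = np.arange(m - 1, n, k)  # x(m), x(m+k), ... 1-based
            n_seg = len(idx) - 1
            if n_seg < 1:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            lengths.append(dist * (n - 1) / (n_seg * k * k))
        avg_lengths[j] = np.mean(lengths)
    if np.any(avg_lengths <= 0):
        raise ValueError("degenerate curve lengths (constant window)")
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(avg_lengths), 1)
    return float(slope)


def _pair_distances(x: np.ndarray, length: int, count: int) -> np.ndarray:
    """Condensed upper-triangle Chebyshev distances between the first
    ``count`` templates of the given ``length``.

    Both the m- and (m+1)-dimensional embeddings use N-m templates, so the
    conditional-probability ratio compares like with like.
    """
    t = np.lib.stride_tricks.sliding_window_view(x, length)[:count]
    iu, ju = np.triu_indices(len(t), k=1)
    return np.max(np.abs(t[iu] - t[ju]), axis=1)


def sampen(values, m: int = DEFAULT_M, r: float | None = None,
           r_frac: float = DEFAULT_R_FRAC) -> float | None:
    """Sample entropy ln(B/A): B, A are the m- and (m+1)-template match
    counts at tolerance r (Chebyshev distance, self-matches excluded).

    ``r`` defaults to ``r_frac * sd(window)``. Returns ``None`` (undefined)
    when either count is zero.
    """
    x = _as_window(values)
    if len(x) < m + 2:
        raise ValueError(f"window of {len(x)} too short for m={m}")
    if r is None:
        _, sd = mean_sd(x)
        if sd == 0:
            raise ValueError("constant window: tolerance r = r_frac * sd degenerates")
        r = r_frac * sd
    count = len(x) - m
    b = int(np.count_nonzero(_pair_distances(x, m, count) <= r))
    a = int(np.count_nonzero(_pair_distances(x, m + 1, count) <= r))
    if a == 0 or b == 0:
        return None
    return float(np.log(b / a))


def sampen_profile(values, m: int = DEFAULT_M,
                   r_resolution: float = DEFAULT_R_RESOLUTION,
                   max_points: int = MAX_PROFILE_POINTS) -> EntropyProfile:
    """SampEn(r) over the data-driven tolerance grid.

    The grid is the set of distinct positive m-template Chebyshev distances
    after quantization to ``r_resolution`` — the tolerances at which the
    match counts actually change. Grid points where SampEn is undefined
    (zero match count at dimension m+1) are excluded; a constant window has
    no positive distances and raises.
    """
    x = _as_window(values)
    if len(x) < m + 2:
        raise ValueError(f"window of {len(x)} too short for m={m}")
    count = len(x) - m
    dm = np.round(_pair_distances(x, m, count) / r_resolution) * r_resolution
    dm1 = np.round(_pair_distances(x, m + 1, count) / r_resolution) * r_resolution
    grid = np.unique(dm)
    grid = grid[grid > 0]
    if len(grid) == 0:
        raise ValueError("constant window: no positive template distances")
    dm_sorted = np.sort(dm)
    dm1_sorted = np.sort(dm1)
    b = np.searchsorted(dm_sorted, grid, side="right")
    a = np.searchsorted(dm1_sorted, grid, side="right")
    defined = (a > 0) & (b > 0)
    grid, a, b = grid[defined], a[defined], b[defined]
    if len(grid) == 0:
        raise ValueError("sample entropy undefined at every tolerance")
    if len(grid) > max_points:
        keep = np.unique(np.round(np.linspace(0, len(grid) - 1, max_points)).astype(int))
        grid, a, b = grid[keep], a[keep], b[keep]
    return EntropyProfile(r_grid=grid, sampen_values=np.log(b / a))


def total_sampen(profile: EntropyProfile) -> float:
    """Sum of SampEn(r) along the profile."""
    if profile.q < 1:
        raise ValueError("empty profile")
    return float(np.sum(profile.sampen_values))


def avg_sampen(profile: EntropyProfile) -> float:
    """Mean of SampEn(r) along the profile."""
    if profile.q < 1:
        raise ValueError("empty profile")
    return float(np.mean(profile.sampen_values))


def compute_features(values, m: int = DEFAULT_M, r_frac: float = DEFAULT_R_FRAC,
                     k_max: int = DEFAULT_K_MAX,
                     r_resolution: float = DEFAULT_R_RESOLUTION) -> FeatureVector:
    """All eight features for one window; features whose preconditions fail
    on this window come back as ``None`` rather than raising."""
    x = _as_window(values)
    mu, sd = mean_sd(x)

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError:
            return None

    katz = _try(katz_fd, x)
    petrosian = _try(petrosian_fd, x)
    higuchi = _try(higuchi_fd, x, k_max)
    sentropy = _try(sampen, x, m, None, r_frac)
    profile = _try(sampen_profile, x, m, r_resolution)
    if profile is None:
        total = avg = q = None
    else:
        total, avg, q = total_sampen(profile), avg_sampen(profile), profile.q
    return FeatureVector(mean=mu, sd=sd, katz=katz, petrosian=petrosian,
                         higuchi=higuchi, sampen=sentropy, total_sampen=total,
                         avg_sampen=avg, q=q)
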