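"""Coarse-graining, sample entropy, and multiscale entropy.

Sample entropy (SampEn) of a series y of length L is

    SampEn(m, r) = -ln( A / B )

where B counts pairs of m-point templates whose Chebyshev (max-coordinate)
distance is strictly below the tolerance r, A counts the same pairs at
dimension m + 1, self-matches are excluded, and both counts run over the
templates i = 1..L-m that can be extended to m + 1 points — the standard
conditional-probability convention, under which A/B is the probability that
two sequences matching for m points also match for the next one.

Multiscale entropy (MSE) evaluates SampEn on coarse-grained versions of the
signal: at scale factor tau, non-overlapping blocks of tau consecutive samples
are replaced by their mean and the remainder is discarded.

Conventions adopted throughout this package:

* The similarity factor r is in SD units: the series is z-scored once at
  scale 1 (population SD) and NOT re-normalized per scale, preserving the
  cross-scale "complexity loss" interpretation.
* Matches are strict (d < r); self-matches are excluded.
* An undefined entropy (zero match count at either dimension, or a
  zero-variance input) is marked NaN, never +/-inf; MSECurve carries an
  explicit undefined mask and tables a defined flag.

Series-length guidance: roughly 10^m - 20^m points are needed for a stable
estimate; a UserWarning (not an error) is emitted when a coarse series is
shorter than 10*m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io import StudyDataset, zscore_series

__all__ = [
    "EntropyParams",
    "CoarseSeries",
    "MatchStatistics",
    "MSECurve",
    "coarse_grain",
    "sample_entropy",
    "sample_entropy_profile",
    "match_statistics",
    "mse_curve",
    "entropy_table",
    "cohort_entropy_tensor",
]


@dataclass(frozen=True)
class EntropyParams:
    """The (m, r, tau) triple: embedding dimension, similarity factor (SD
    units), scale factor."""

    m: int
    r: float
    tau: int

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"tau must be a positive integer, got {self.tau}")


@dataclass
class CoarseSeries:
    """A coarse-grained series: block means of tau consecutive points."""

    y: np.ndarray
    tau: int
    L: int


@dataclass
class MatchStatistics:
    """Template-match bookkeeping behind one SampEn value.

    C_m and C_m1 are the average match fractions at dimensions m and m+1 over
    the n_templates = L - m templates that extend to m+1; matches are
    unordered pairs, so fractions are counts / (n_templates choose 2).
    """

    B: int
    A: int
    C_m: float
    C_m1: float
    n_templates_m: int
    n_templates_m1: int


@dataclass
class MSECurve:
    """SampEn values indexed by scale factor tau = 1..tau_max."""

    values: np.ndarray  # values[k] is the entropy at tau = k + 1
    m: int
    r: float
    undefined_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined_mask is None:
            self.undefined_mask = np.isnan(self.values)
        self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool)

    @property
    def tau_values(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)

    def value_at(self, tau: int) -> float:
        return float(self.values[tau - 1])


def coarse_grain(x: np.ndarray, tau: int) -> CoarseSeries:
    """Coarse-grain a series at scale factor tau.

    y[j] is the mean of the j-th non-overlapping block of tau consecutive
    points; the trailing N mod tau points are discarded, so the coarse length
    is L = floor(N / tau).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("coarse_grain expects a 1-D series")
    if int(tau) != tau or tau < 1:
        raise ValueError(f"tau must be a positive integer, got {tau}")
    tau = int(tau)
    if tau > x.size:
        raise ValueError(f"tau = {tau} exceeds series length {x.size}")
    L = x.size // tau
    y = x[: L * tau].reshape(L, tau).mean(axis=1)
    return CoarseSeries(y=y, tau=tau, L=L)


@njit(cache=True, inline="always")
def _r_bin(r_grid: np.ndarray, d: float) -> int:
    """Index of the first r in the sorted grid with r > d (strict match d < r).

    Descending linear scan: most pair distances exceed the largest tolerance,
    so the common case exits after one comparison.
    """
    k = r_grid.shape[0]
    while k > 0 and r_grid[k - 1] > d:
        k -= 1
    return k


@njit(cache=True)
def _match_histograms(y: np.ndarray, m: int, r_grid: np.ndarray):
    """Histogram pair distances at dimensions m and m+1 against a sorted r grid.

    Returns (hist_B, hist_A) of length len(r_grid) + 1; the cumulative sum of
    hist up to index k is the number of unordered template pairs with
    Chebyshev distance strictly below r_grid[k].  Templates run over
    i = 1..L-m (those extendable to m+1); self-matches are excluded by i < j.
    """
    L = y.shape[0]
    nt = L - m
    nr = r_grid.shape[0]
    hist_b = np.zeros(nr + 1, dtype=np.int64)
    hist_a = np.zeros(nr + 1, dtype=np.int64)
    if m == 1:  # dominant case: skip the k-loop entirely
        for i in range(nt - 1):
            yi = y[i]
            yi1 = y[i + 1]
            for j in range(i + 1, nt):
                d = abs(yi - y[j])
                hist_b[_r_bin(r_grid, d)] += 1
                t = abs(yi1 - y[j + 1])
                if t > d:
                    d = t
                hist_a[_r_bin(r_grid, d)] += 1
    else:
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    t = abs(y[i + k] - y[j + k])
                    if t > d:
                        d = t
                hist_b[_r_bin(r_grid, d)] += 1
                t = abs(y[i + m] - y[j + m])
                if t > d:
                    d = t
                hist_a[_r_bin(r_grid, d)] += 1
    return hist_b, hist_a


@njit(cache=True, inline="always")
def _bisect_left(a: np.ndarray, x: float) -> int:
    lo = 0
    hi = a.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if a[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True, inline="always")
def _bisect_right(a: np.ndarray, x: float) -> int:
    lo = 0
    hi = a.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if a[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True, inline="always")
def _fenwick_add(tree: np.ndarray, i: int, delta: int) -> None:
    i += 1
    n = tree.shape[0] - 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True, inline="always")
def _fenwick_prefix(tree: np.ndarray, i: int) -> int:
    # sum of positions 0..i inclusive (i = -1 -> 0)
    s = 0
    i += 1
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


@njit(cache=True)
def _match_counts_m1_sorted(y: np.ndarray, r: float):
    """Exact (B, A) pair-match counts for m = 1 in O(L log L).

    Same counting convention as the quadratic kernel: templates i = 1..L-1,
    strict Chebyshev matches, self-matches excluded.  B is a two-pointer
    count over the sorted first coordinates; A adds a sliding window over the
    first coordinate with a Fenwick tree over the ranks of the second, i.e.
    2-D orthogonal range counting.
    """
    L = y.shape[0]
    nt = L - 1
    u = y[:nt]
    v = y[1:L]
    order = np.argsort(u)
    us = u[order]
    vs = v[order]

    B = 0
    lo = 0
    for p in range(nt):
        while us[p] - us[lo] >= r:
            lo += 1
        B += p - lo

    uv = np.unique(v)
    ranks = np.empty(nt, dtype=np.int64)
    for p in range(nt):
        ranks[p] = _bisect_left(uv, vs[p])
    tree = np.zeros(uv.shape[0] + 1, dtype=np.int64)
    A = 0
    lo = 0
    for p in range(nt):
        while us[p] - us[lo] >= r:
            _fenwick_add(tree, ranks[lo], -1)
            lo += 1
        below_hi = _fenwick_prefix(tree, _bisect_left(uv, vs[p] + r) - 1)  # v_q < v_p + r
        below_lo = _fenwick_prefix(tree, _bisect_right(uv, vs[p] - r) - 1)  # v_q <= v_p - r
        A += below_hi - below_lo
        _fenwick_add(tree, ranks[p], 1)
    return B, A


#: above this length, m = 1 counting switches to the O(L log L) sorted path
_FAST_PATH_MIN = 4096


@njit(cache=True)
def _match_counts_single(y: np.ndarray, m: int, r: float):
    """Pair-match counts (B, A) at dimensions m and m+1 for a single r."""
    L = y.shape[0]
    nt = L - m
    B = 0
    A = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs(y[i + k] - y[j + k])
                if t > d:
                    d = t
            if d < r:
                B += 1
                t = abs(y[i + m] - y[j + m])
                if t > d:
                    d = t
                if d < r:
                    A += 1
    return B, A


def _pair_counts(y: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Dispatch to the O(L log L) sorted path for long m = 1 series.

    Both paths implement the same strict counting convention; at the float
    boundary d == r (measure zero for continuous data) the quadratic kernel
    is authoritative and is used for every short or discrete-valued fixture.
    """
    if m == 1 and y.size >= _FAST_PATH_MIN:
        return _match_counts_m1_sorted(y, float(r))
    return _match_counts_single(y, int(m), float(r))


def _validate_series(y: np.ndarray, m: int) -> np.ndarray:
    y = np.ascontiguousarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-D series")
    if int(m) != m or m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    if y.size - m < 1:
        raise ValueError(f"series of length {y.size} too short for m = {m}")
    if np.isnan(y).any():
        raise ValueError("series contains NaN")
    return y


def match_statistics(y: np.ndarray, m: int, r: float) -> MatchStatistics:
    """Explicit match bookkeeping for one (m, r) on one series."""
    y = _validate_series(y, m)
    if not r > 0:
        raise ValueError(f"r must be positive, got {r}")
    B, A = _match_counts_single(y, int(m), float(r))
    nt = y.size - int(m)
    n_pairs = nt * (nt - 1) // 2
    c_m = B / n_pairs if n_pairs else np.nan
    c_m1 = A / n_pairs if n_pairs else np.nan
    return MatchStatistics(
        B=int(B), A=int(A), C_m=c_m, C_m1=c_m1, n_templates_m=nt, n_templates_m1=nt
    )


def sample_entropy(y: np.ndarray, m: int, r: float) -> float:
    """Sample entropy of a series already expressed in SD units.

    Returns -ln(A/B) with strict Chebyshev matching (see module docstring);
    NaN when either match count is zero (undefined entropy).
    """
    y = _validate_series(y, m)
    if not r > 0:
        raise ValueError(f"r must be positive, got {r}")
    B, A = _pair_counts(y, int(m), float(r))
    if B == 0 or A == 0:
        return float("nan")
    return -math.log(int(A) / int(B))


def sample_entropy_profile(y: np.ndarray, m: int, r_values: Sequence[float]) -> np.ndarray:
    """Sample entropy at every r in one O(L^2) pass.

    Equivalent to ``[sample_entropy(y, m, r) for r in r_values]`` but shares
    the distance computation across the whole r grid; used by the parameter
    grid search.
    """
    y = _validate_series(y, m)
    r_arr = np.asarray(r_values, dtype=float)
    if r_arr.ndim != 1 or r_arr.size == 0 or not (r_arr > 0).all():
        raise ValueError("r_values must be a non-empty 1-D array of positive values")
    order = np.argsort(r_arr, kind="stable")
    r_sorted = np.ascontiguousarray(r_arr[order])
    if m == 1 and y.size >= _FAST_PATH_MIN:
        B = np.empty(r_sorted.size, dtype=np.int64)
        A = np.empty(r_sorted.size, dtype=np.int64)
        for k, r in enumerate(r_sorted):
            B[k], A[k] = _match_counts_m1_sorted(y, float(r))
    else:
        hist_b, hist_a = _match_histograms(y, int(m), r_sorted)
        B = np.cumsum(hist_b)[: r_sorted.size]
        A = np.cumsum(hist_a)[: r_sorted.size]
    vals = np.array([
        -math.log(int(a) / int(b)) if a > 0 and b > 0 else np.nan
        for a, b in zip(A, B)
    ])
    out = np.empty_like(vals)
    out[order] = vals
    return out


def mse_curve(x: np.ndarray, m: int, r: float, tau_max: int) -> MSECurve:
    """Multiscale entropy curve of a raw series over tau = 1..tau_max.

    The series is z-scored once at scale 1 (so r is in SD units of the
    original series) and then coarse-grained per scale without
    re-normalization.  A zero-variance input yields an all-undefined curve.
    Coarse series shorter than 10*m trigger a length-guidance warning.
    """
    x = np.asarray(x, dtype=float)
    if int(tau_max) != tau_max or tau_max < 1:
        raise ValueError(f"tau_max must be a positive integer, got {tau_max}")
    tau_max = int(tau_max)
    if x.size // tau_max - m < 1:
        raise ValueError(
            f"series length {x.size} too short for tau_max = {tau_max}, m = {m}"
        )
    z = zscore_series(x)
    values = np.full(tau_max, np.nan)
    if np.isnan(z).any():  # zero-variance (degenerate) input
        return MSECurve(values=values, m=m, r=r)
    for tau in range(1, tau_max + 1):
        cs = coarse_grain(z, tau)
        if cs.L < 10 * m:
            warnings.warn(
                f"coarse series length {cs.L} < {10 * m} at tau = {tau}; SampEn "
                f"estimate may be unreliable for m = {m}",
                UserWarning,
                stacklevel=2,
            )
        values[tau - 1] = sample_entropy(cs.y, m, r)
    return MSECurve(values=values, m=m, r=r)


def cohort_entropy_tensor(
    dataset: StudyDataset,
    m_values: Sequence[int],
    r_values: Sequence[float],
    tau_values: Sequence[int],
) -> np.ndarray:
    """Entropy of every subject/region/parameter combination.

    Returns an array of shape (n_subjects, n_regions, n_m, n_tau, n_r) with
    NaN marking undefined entries.  Each regional series is z-scored once at
    scale 1; the whole r grid is computed in a single pass per series.
    """
    m_values = [int(m) for m in m_values]
    tau_values = [int(t) for t in tau_values]
    r_arr = np.asarray(r_values, dtype=float)
    out = np.full(
        (dataset.n_subjects, dataset.n_regions, len(m_values), len(tau_values), r_arr.size),
        np.nan,
    )
    max_m = max(m_values)
    max_tau = max(tau_values)
    if dataset.n_timepoints // max_tau - max_m < 1:
        raise ValueError(
            f"n_timepoints = {dataset.n_timepoints} too short for tau = {max_tau}, "
            f"m = {max_m}"
        )
    for m in m_values:
        for tau in tau_values:
            L = dataset.n_timepoints // tau
            if L < 10 * m:
                warnings.warn(
                    f"coarse series length {L} < {10 * m} at tau = {tau}; SampEn "
                    f"estimates may be unreliable for m = {m}",
                    UserWarning,
                    stacklevel=2,
                )
    for si, subject in enumerate(dataset.subjects):
        for gi in range(dataset.n_regions):
            z = zscore_series(subject.matrix[gi])
            if np.isnan(z).any():
                continue  # degenerate region stays NaN
            for ti, tau in enumerate(tau_values):
                y = coarse_grain(z, tau).y
                for mi, m in enumerate(m_values):
                    out[si, gi, mi, ti] = sample_entropy_profile(y, m, r_arr)
    return out


def entropy_table(
    dataset: StudyDataset, m: int, r: float, tau_max: int
) -> pd.DataFrame:
    """Per-subject, per-region, per-scale entropy table at one (m, r).

    Columns: subject_id, group, region, tau, entropy, defined.  This is the
    batch entry point behind the ``entroscan entropy`` command.
    """
    tensor = cohort_entropy_tensor(dataset, [m], [r], list(range(1, tau_max + 1)))
    rows = []
    for si, subject in enumerate(dataset.subjects):
        for gi, region in enumerate(dataset.region_labels):
            for ti in range(tau_max):
                v = tensor[si, gi, 0, ti, 0]
                rows.append(
                    (subject.subject_id, subject.group, region, ti + 1, v, bool(np.isfinite(v)))
                )
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "region", "tau", "entropy", "defined"]
    )
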