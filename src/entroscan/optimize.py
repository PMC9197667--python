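"""Grid search over (m, r, tau) and sequential selection of entropy
parameters, biomarker regions, and feature vectors.

The optimization replaces subjective, experience-based choice of the
multiscale-entropy parameters with an objective procedure driven by
group-difference statistics:

1. ``run_grid`` computes, for every (m, r, tau, region) cell, the per-subject
   entropy and the two-group Welch t-test and ROC/AUC on it.
2. ``select_m`` picks the embedding dimension whose mean count of significant
   regions (p < alpha) over all (r, tau) cells is largest (tie -> smaller m).
3. ``robust_r_band`` finds the r values that stay significant at every scale
   factor in the grid.
4. ``select_tau_r`` scores each (r, tau) cell in the band by the mean AUC
   over its significant regions and picks the maximizing tau, then r.
5. ``select_biomarkers`` returns the regions significant at the optimum.
6. ``build_features`` assembles the per-subject entropy feature matrix over
   those regions for classification.

All steps are pure functions of (dataset, grids, alpha): repeated runs are
bit-identical.  p-values are uncorrected across regions by default,
replicating the original procedure; an optional Benjamini-Hochberg flag is
available on ``select_biomarkers``.

``EntropyBiomarkerOptimizer`` wraps the sequential procedure in an
estimator-style class (fit on a StudyDataset, fitted attributes with a
trailing underscore, transform to a feature matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .entropy import EntropyParams, coarse_grain, cohort_entropy_tensor, sample_entropy
from .io import StudyDataset, zscore_series
from .stats import _auc_value, welch_t_test

__all__ = [
    "GridResult",
    "OptimalParams",
    "BiomarkerSet",
    "FeatureMatrix",
    "default_r_grid",
    "default_tau_grid",
    "run_grid",
    "count_significant",
    "select_m",
    "robust_r_band",
    "select_tau_r",
    "select_biomarkers",
    "build_features",
    "optimize_parameters",
    "EntropyBiomarkerOptimizer",
]


def default_r_grid() -> np.ndarray:
    """r = 0.05 .. 0.60 in steps of 0.05 (12 values)."""
    return np.round(np.arange(1, 13) * 0.05, 2)


def default_tau_grid() -> np.ndarray:
    """tau = 1 .. 6."""
    return np.arange(1, 7)


@dataclass
class GridResult:
    """Per-cell group statistics over the whole (m, r, tau, region) grid.

    ``table`` has one row per cell with columns m, r, tau, region, n0, n1,
    mean0, mean1, t, p, auc, n_excluded (subjects with undefined entropy in
    that cell; tests and AUC use the same defined subset).
    """

    table: pd.DataFrame
    m_values: tuple[int, ...]
    r_values: tuple[float, ...]
    tau_values: tuple[int, ...]
    region_labels: tuple[str, ...]

    def to_frame_report(self) -> pd.DataFrame:
        return self.table.set_index("region")

    def cell(self, m: int, r: float, tau: int) -> pd.DataFrame:
        t = self.table
        return t[(t.m == m) & (np.isclose(t.r, r)) & (t.tau == tau)]


@dataclass
class OptimalParams:
    """Selected (m, r, tau) with the robust r band and a replayable trace."""

    params: EntropyParams
    robust_r_band: tuple[float, ...]
    selection_trace: dict[str, Any] = field(default_factory=dict)

    def to_dict_report(self) -> dict[str, Any]:
        return {
            "m": self.params.m,
            "r": self.params.r,
            "tau": self.params.tau,
            "robust_r_band": list(self.robust_r_band),
            "selection_trace": self.selection_trace,
        }


@dataclass
class BiomarkerSet:
    """Regions significant at the optimal parameters, ascending p."""

    table: pd.DataFrame  # columns: region, p, auc, t

    @property
    def regions(self) -> list[str]:
        return list(self.table["region"])

    def __len__(self) -> int:
        return len(self.table)

    def to_frame_report(self) -> pd.DataFrame:
        return self.table.set_index("region")


@dataclass
class FeatureMatrix:
    """Per-subject entropy features over the biomarker regions.

    ``values`` is indexed by subject_id with one column per biomarker region
    (in BiomarkerSet order); ``labels`` is the group per retained subject;
    ``dropped`` lists subjects removed for undefined features.
    """

    values: pd.DataFrame
    labels: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def to_frame_report(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "group", self.labels)
        return out


def run_grid(
    dataset: StudyDataset,
    m_values: Sequence[int] = (1, 2),
    r_values: Sequence[float] | None = None,
    tau_values: Sequence[int] | None = None,
) -> GridResult:
    """Compute group statistics for every (m, r, tau, region) cell.

    Per cell: each subject's regional series is z-scored, coarse-grained at
    tau, and its sample entropy at (m, r) computed; Welch t-test and ROC/AUC
    compare the two groups on the defined values.  Deterministic given the
    dataset and grids.
    """
    dataset.require_both_groups()
    r_arr = np.asarray(default_r_grid() if r_values is None else r_values, dtype=float)
    tau_arr = np.asarray(default_tau_grid() if tau_values is None else tau_values, dtype=int)
    m_arr = [int(m) for m in m_values]
    if not len(m_arr) or not r_arr.size or not tau_arr.size:
        raise ValueError("parameter grids must be non-empty")

    tensor = cohort_entropy_tensor(dataset, m_arr, r_arr, tau_arr)
    groups = dataset.groups
    idx0 = np.flatnonzero(groups == 0)
    idx1 = np.flatnonzero(groups == 1)
    n0g, n1g = idx0.size, idx1.size

    rows: list[tuple] = []
    for mi, m in enumerate(m_arr):
        for ti, tau in enumerate(tau_arr):
            for ri, r in enumerate(r_arr):
                X = tensor[:, :, mi, ti, ri]  # (n_subjects, n_regions)
                a = X[idx0]
                b = X[idx1]
                if np.isfinite(a).all() and np.isfinite(b).all():
                    # vectorized across regions (the common, fully-defined case)
                    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        t_vec, p_vec = sps.ttest_ind(a, b, axis=0, equal_var=False)
                    ranks = sps.rankdata(np.vstack([a, b]), axis=0)
                    auc_vec = (ranks[n0g:].sum(axis=0) - n1g * (n1g + 1) / 2.0) / (n0g * n1g)
                    mean0_vec = a.mean(axis=0)
                    mean1_vec = b.mean(axis=0)
                    for gi, region in enumerate(dataset.region_labels):
                        rows.append(
                            (m, float(r), int(tau), region, n0g, n1g,
                             mean0_vec[gi], mean1_vec[gi], float(t_vec[gi]),
                             float(p_vec[gi]), float(auc_vec[gi]), 0)
                        )
                    continue
                for gi, region in enumerate(dataset.region_labels):
                    av = a[:, gi]
                    bv = b[:, gi]
                    av = av[np.isfinite(av)]
                    bv = bv[np.isfinite(bv)]
                    n_excluded = (n0g - av.size) + (n1g - bv.size)
                    if av.size == 0 or bv.size == 0:
                        rows.append(
                            (m, float(r), int(tau), region, av.size, bv.size,
                             np.nan, np.nan, np.nan, np.nan, np.nan, n_excluded)
                        )
                        continue
                    tr = welch_t_test(av, bv)
                    auc = _auc_value(av, bv)
                    rows.append(
                        (m, float(r), int(tau), region, tr.n0, tr.n1,
                         tr.mean0, tr.mean1, tr.t_statistic, tr.p_value, auc,
                         n_excluded)
                    )
    table = pd.DataFrame(
        rows,
        columns=["m", "r", "tau", "region", "n0", "n1", "mean0", "mean1",
                 "t", "p", "auc", "n_excluded"],
    )
    return GridResult(
        table=table,
        m_values=tuple(m_arr),
        r_values=tuple(float(r) for r in r_arr),
        tau_values=tuple(int(t) for t in tau_arr),
        region_labels=tuple(dataset.region_labels),
    )


def count_significant(grid: GridResult, m: int, alpha: float = 0.05) -> pd.DataFrame:
    """Count of significant regions (p < alpha) per (r, tau) cell at one m.

    Returns a DataFrame indexed by r with one column per tau.  Cells whose
    p-value is undefined (all-excluded regions) never count as significant.
    """
    if m not in grid.m_values:
        raise ValueError(f"grid does not cover m = {m}")
    t = grid.table[grid.table.m == m].copy()
    t["sig"] = t["p"] < alpha
    out = t.pivot_table(index="r", columns="tau", values="sig", aggfunc="sum")
    return out.astype(int)


def select_m(grid: GridResult, alpha: float = 0.05) -> int:
    """Embedding dimension maximizing the mean significant-region count over
    all (r, tau) cells; ties break to the smaller m."""
    best_m = None
    best_score = -np.inf
    for m in sorted(grid.m_values):
        score = float(count_significant(grid, m, alpha).to_numpy().mean())
        if score > best_score:  # strict: tie keeps the smaller m
            best_m, best_score = m, score
    assert best_m is not None
    return int(best_m)


def robust_r_band(
    grid: GridResult, m: int, alpha: float = 0.05, min_regions: int = 1
) -> tuple[float, ...]:
    """r values with at least ``min_regions`` significant regions at EVERY tau.

    An empty band falls back (with a warning) to the single r with the best
    worst-case count over tau, ties broken by the mean count over tau, then
    by the smaller r.
    """
    counts = count_significant(grid, m, alpha)
    worst = counts.min(axis=1)  # min over tau, per r
    band = tuple(float(r) for r in worst.index[worst >= min_regions])
    if band:
        return band
    ranking = pd.DataFrame({"worst": worst, "mean": counts.mean(axis=1)})
    ranking = ranking.sort_values(["worst", "mean"], ascending=False, kind="stable")
    fallback = float(ranking.index[0])
    warnings.warn(
        f"no r value keeps >= {min_regions} regions significant at every tau; "
        f"falling back to r = {fallback} (best worst-case count)",
        UserWarning,
        stacklevel=2,
    )
    return (fallback,)


def _cell_scores(
    grid: GridResult, m: int, band: Sequence[float], alpha: float
) -> pd.DataFrame:
    """Mean AUC over significant regions, per (r in band, tau); NaN when a
    cell has no significant region."""
    t = grid.table[(grid.table.m == m)]
    rows = []
    for r in band:
        for tau in grid.tau_values:
            cell = t[np.isclose(t.r, r) & (t.tau == tau)]
            sig = cell[cell.p < alpha]
            score = float(sig["auc"].mean()) if len(sig) else np.nan
            rows.append((float(r), int(tau), score, len(sig)))
    return pd.DataFrame(rows, columns=["r", "tau", "score", "n_significant"])


def select_tau_r(
    grid: GridResult,
    m: int,
    band: Sequence[float],
    alpha: float = 0.05,
) -> OptimalParams:
    """Pick tau then r from the robust band by maximal mean AUC over
    significant regions.

    score(r, tau) = mean AUC over regions with p < alpha in that cell.
    tau* maximizes (over tau) the best score achievable within the band;
    ties break to the smaller tau.  r* then maximizes the score at tau*;
    ties break to the r nearest the band midpoint, then to the smaller r.
    The full score table is recorded in the selection trace.
    """
    band = tuple(float(r) for r in band)
    if not band:
        raise ValueError("robust r band is empty")
    scores = _cell_scores(grid, m, band, alpha)
    if scores["score"].isna().all():
        raise ValueError(
            "no (r, tau) cell in the band has a significant region; widen the "
            "parameter grids or lower alpha"
        )
    per_tau = scores.groupby("tau")["score"].max()
    best = per_tau.max()
    tau_star = int(min(tau for tau, s in per_tau.items() if s == best))
    at_tau = scores[scores.tau == tau_star].dropna(subset=["score"])
    top = at_tau[at_tau.score == at_tau.score.max()]
    midpoint = (band[0] + band[-1]) / 2.0
    top = top.assign(dist=np.abs(top.r - midpoint)).sort_values(["dist", "r"])
    r_star = float(top.iloc[0].r)
    trace = {
        "m": int(m),
        "alpha": float(alpha),
        "band": list(band),
        "scores": scores.to_dict(orient="records"),
        "per_tau_best": {int(k): float(v) for k, v in per_tau.items()},
        "selected": {"tau": tau_star, "r": r_star},
    }
    return OptimalParams(
        params=EntropyParams(m=int(m), r=r_star, tau=tau_star),
        robust_r_band=band,
        selection_trace=trace,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return adj


def select_biomarkers(
    grid: GridResult,
    opt: OptimalParams,
    alpha: float = 0.05,
    fdr_correct: bool = False,
) -> BiomarkerSet:
    """Regions significant at the optimal parameters, sorted by ascending p.

    ``fdr_correct`` applies Benjamini-Hochberg across regions before
    thresholding (off by default, matching the uncorrected original
    procedure).  An empty result raises, with the nearest-miss regions in the
    message for diagnosis.
    """
    p = opt.params
    cell = grid.cell(p.m, p.r, p.tau).dropna(subset=["p"]).copy()
    if fdr_correct and len(cell):
        cell["p_adj"] = _bh_adjust(cell["p"].to_numpy())
        sig = cell[cell.p_adj < alpha]
    else:
        sig = cell[cell.p < alpha]
    if not len(sig):
        near = cell.nsmallest(10, "p")[["region", "p", "auc"]]
        raise ValueError(
            "no region is significant at the optimal parameters "
            f"(m={p.m}, r={p.r}, tau={p.tau}, alpha={alpha}); nearest misses:\n"
            + near.to_string(index=False)
        )
    sig = sig.sort_values(["p", "region"], kind="stable")
    return BiomarkerSet(table=sig[["region", "p", "auc", "t"]].reset_index(drop=True))


def build_features(
    dataset: StudyDataset, opt: OptimalParams, biomarkers: BiomarkerSet
) -> FeatureMatrix:
    """Per-subject entropy vectors over the biomarker regions at the optimum.

    Columns follow BiomarkerSet order; rows follow dataset order.  Subjects
    with any undefined feature are dropped and listed.
    """
    if not len(biomarkers):
        raise ValueError("biomarker set is empty")
    p = opt.params
    region_idx = [dataset.region_labels.index(r) for r in biomarkers.regions]
    values = np.full((dataset.n_subjects, len(region_idx)), np.nan)
    for si, subject in enumerate(dataset.subjects):
        for k, gi in enumerate(region_idx):
            z = zscore_series(subject.matrix[gi])
            if np.isnan(z).any():
                continue
            values[si, k] = sample_entropy(coarse_grain(z, p.tau).y, p.m, p.r)
    defined = np.isfinite(values).all(axis=1)
    dropped = [s.subject_id for s, ok in zip(dataset.subjects, defined) if not ok]
    frame = pd.DataFrame(
        values[defined],
        index=pd.Index([s.subject_id for s, ok in zip(dataset.subjects, defined) if ok],
                       name="subject_id"),
        columns=biomarkers.regions,
    )
    labels = dataset.groups[defined]
    return FeatureMatrix(values=frame, labels=labels, dropped=dropped)


def optimize_parameters(
    dataset: StudyDataset,
    m_values: Sequence[int] = (1, 2),
    r_values: Sequence[float] | None = None,
    tau_values: Sequence[int] | None = None,
    alpha: float = 0.05,
    min_regions: int = 1,
    joint_argmax: bool = False,
) -> tuple[GridResult, OptimalParams]:
    """Full sequential optimization: grid -> m -> robust r band -> (tau, r).

    ``joint_argmax`` replaces the sequential tau-then-r choice with a joint
    argmax of the cell score over the band x tau grid (sensitivity-analysis
    mode); m selection and the band are unchanged.
    """
    grid = run_grid(dataset, m_values, r_values, tau_values)
    m = select_m(grid, alpha)
    band = robust_r_band(grid, m, alpha, min_regions)
    opt = select_tau_r(grid, m, band, alpha)
    if joint_argmax:
        scores = _cell_scores(grid, m, band, alpha).dropna(subset=["score"])
        top = scores.sort_values(["score", "tau", "r"], ascending=[False, True, True])
        best = top.iloc[0]
        opt = OptimalParams(
            params=EntropyParams(m=m, r=float(best.r), tau=int(best.tau)),
            robust_r_band=band,
            selection_trace={**opt.selection_trace,
                             "joint_argmax": {"tau": int(best.tau), "r": float(best.r)}},
        )
    return grid, opt


class EntropyBiomarkerOptimizer(BaseEstimator):
    """Estimator-style wrapper around the sequential optimization.

    Parameters mirror :func:`optimize_parameters`.  After ``fit(dataset)``
    the fitted attributes are ``grid_``, ``m_``, ``r_band_``,
    ``optimal_params_``, ``biomarkers_`` and ``feature_matrix_``;
    ``transform(dataset)`` builds the entropy feature matrix of a (possibly
    different) cohort at the fitted optimum.
    """

    def __init__(
        self,
        m_values: Sequence[int] = (1, 2),
        r_values: Sequence[float] | None = None,
        tau_values: Sequence[int] | None = None,
        alpha: float = 0.05,
        min_regions: int = 1,
        joint_argmax: bool = False,
        fdr_correct: bool = False,
    ) -> None:
        self.m_values = m_values
        self.r_values = r_values
        self.tau_values = tau_values
        self.alpha = alpha
        self.min_regions = min_regions
        self.joint_argmax = joint_argmax
        self.fdr_correct = fdr_correct

    def fit(self, dataset: StudyDataset, y: Any = None) -> "EntropyBiomarkerOptimizer":
        grid, opt = optimize_parameters(
            dataset,
            m_values=self.m_values,
            r_values=self.r_values,
            tau_values=self.tau_values,
            alpha=self.alpha,
            min_regions=self.min_regions,
            joint_argmax=self.joint_argmax,
        )
        self.grid_ = grid
        self.optimal_params_ = opt
        self.m_ = opt.params.m
        self.r_band_ = opt.robust_r_band
        self.biomarkers_ = select_biomarkers(
            grid, opt, alpha=self.alpha, fdr_correct=self.fdr_correct
        )
        self.feature_matrix_ = build_features(dataset, opt, self.biomarkers_)
        return self

    def transform(self, dataset: StudyDataset) -> FeatureMatrix:
        if not hasattr(self, "optimal_params_"):
            raise RuntimeError("EntropyBiomarkerOptimizer is not fitted")
        return build_features(dataset, self.optimal_params_, self.biomarkers_)

    def fit_transform(self, dataset: StudyDataset, y: Any = None) -> FeatureMatrix:
        return self.fit(dataset).feature_matrix_
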