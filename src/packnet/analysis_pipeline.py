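"""Headline analysis: fit the averaged k_nn(k) line and compare predicted
against directly calculated network parameters.

For networks whose clustering is roughly independent of degree, theory
gives k_nn(k) = C k + (1 - C) <k^2>/z (see :mod:`packnet.gf_theory`). An
ordinary least-squares line through the averaged k_nn-vs-k profile
therefore *predicts* the mean clustering coefficient from its slope and
<k^2>/z from its intercept via intercept / (1 - slope), which can be
checked against the same quantities computed directly from the graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph_stats import (ContactGraph, DegreeProfile, build_degree_profile,
                          compute_clustering, compute_degrees)

__all__ = [
    "KnnFit",
    "PRESETS",
    "profile_with_preset",
    "fit_knn_profile",
    "fit_knn_nodes",
    "predict_from_fit",
    "analyze_system",
    "calculated_summary",
    "comparison_table",
]

#: Degree-bin exclusion presets. "rn" drops bins with fewer than 25
#: nodes (residue networks); "mn"/"mn_text" retain degree windows 5..15
#: and 4..15 respectively (two circulating variants of the micellar
#: rule); "none" keeps everything.
PRESETS: dict[str, dict] = {
    "none": {"min_nodes_per_degree": 1, "degree_window": None},
    "rn": {"min_nodes_per_degree": 25, "degree_window": None},
    "mn": {"min_nodes_per_degree": 1, "degree_window": (5, 15)},
    "mn_text": {"min_nodes_per_degree": 1, "degree_window": (4, 15)},
}


def profile_with_preset(graphs, preset: str = "none") -> DegreeProfile:
    """Pooled degree profile under a named degree-bin exclusion preset."""
    try:
        kwargs = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return build_degree_profile(graphs, **kwargs)


@dataclass(frozen=True)
class KnnFit:
    """Least-squares line through the averaged k_nn-vs-k profile and the
    derived predictions.

    C_pred is the slope; k2z_pred is the line's k -> 0 value mapped
    through the linear relation, intercept / (1 - slope). Standard
    errors are the usual OLS estimates, propagated (with the
    slope-intercept covariance) for k2z_pred.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    degrees_used: tuple[int, ...]
    C_pred: float = math.nan
    C_pred_se: float = math.nan
    k2z_pred: float = math.nan
    k2z_pred_se: float = math.nan
    C_calc: float = math.nan
    k2z_calc: float = math.nan

    def line(self, k) -> np.ndarray:
        return self.slope * np.asarray(k, dtype=float) + self.intercept


def fit_knn_profile(profile: DegreeProfile) -> KnnFit:
    """Unweighted OLS of knn_mean against k over the retained degree bins.

    The fit weights each degree bin equally (the fitted object is the
    averaged profile, one point per degree); use
    :func:`fit_knn_nodes` for a node-weighted sensitivity variant.
    """
    k = np.asarray(profile.degrees, dtype=float)
    y = np.asarray(profile.knn_mean, dtype=float)
    # bins where k_nn is undefined (e.g. the k = 0 bin) carry no signal
    finite = np.isfinite(y)
    return _ols(k[finite], y[finite])


def fit_knn_nodes(graphs) -> KnnFit:
    """Node-weighted variant: OLS over every (k_i, k_nn,i) pair."""
    ks, ys = [], []
    for g in graphs:
        from .graph_stats import compute_knn
        k = compute_degrees(g)
        knn = compute_knn(g)
        mask = k >= 1
        ks.append(k[mask])
        ys.append(knn[mask])
    return _ols(np.concatenate(ks).astype(float), np.concatenate(ys))


def _ols(k: np.ndarray, y: np.ndarray) -> KnnFit:
    if len(k) < 3:
        raise ValueError("need at least 3 degree bins to fit a line")
    if np.ptp(k) == 0:
        raise ValueError("zero variance in k: cannot fit a line")
    res = sps.linregress(k, y)
    return KnnFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        degrees_used=tuple(int(v) for v in sorted(set(k.astype(int)))),
    )


def predict_from_fit(fit: KnnFit) -> KnnFit:
    """Derive (C_pred, k2z_pred) with error margins from a completed fit.

    C_pred = slope. The fitted line extrapolated to k -> 0 gives the
    intercept, which the linear relation k_nn = C k + (1 - C) <k^2>/z
    identifies as (1 - C) <k^2>/z, so k2z_pred = intercept / (1 - slope).
    Margins are first-order error propagation using the OLS covariance
    cov(slope, intercept) = -mean(k) var(slope).
    """
    m, a = fit.slope, fit.intercept
    if abs(1.0 - m) < 1e-12:
        raise ValueError("slope of 1 makes the <k^2>/z prediction singular")
    k2z = a / (1.0 - m)
    kbar = float(np.mean(fit.degrees_used))
    cov = -kbar * fit.slope_se ** 2
    da = 1.0 / (1.0 - m)          # d k2z / d intercept
    dm = a / (1.0 - m) ** 2       # d k2z / d slope
    var = (da * fit.intercept_se) ** 2 + (dm * fit.slope_se) ** 2 \
        + 2.0 * da * dm * cov
    k2z_se = math.sqrt(max(var, 0.0))
    return KnnFit(
        slope=m, intercept=a, slope_se=fit.slope_se,
        intercept_se=fit.intercept_se, degrees_used=fit.degrees_used,
        C_pred=m, C_pred_se=fit.slope_se,
        k2z_pred=k2z, k2z_pred_se=k2z_se,
        C_calc=fit.C_calc, k2z_calc=fit.k2z_calc,
    )


def calculated_summary(graphs) -> tuple[float, float, float]:
    """(C_calc, k2z_calc, z) measured directly from pooled graphs.

    C_calc is the mean of per-node clustering over nodes where it is
    defined; k2z_calc = (Σ k²)/(Σ k) over the pooled degree sequence;
    z is the pooled mean degree.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("empty graph set")
    ks, cs = [], []
    for g in graphs:
        ks.append(compute_degrees(g))
        cs.append(compute_clustering(g))
    k = np.concatenate(ks).astype(float)
    c = np.concatenate(cs)
    C_calc = float(np.nanmean(c))
    k2z_calc = float((k ** 2).sum() / k.sum())
    return C_calc, k2z_calc, float(k.mean())


def analyze_system(graphs, preset: str = "none") -> KnnFit:
    """Full comparison for one system: profile, fit, predictions, and the
    directly calculated values, in a single KnnFit."""
    graphs = list(graphs)
    profile = profile_with_preset(graphs, preset)
    fit = fit_knn_profile(profile)
    C_calc, k2z_calc, _z = calculated_summary(graphs)
    fit = KnnFit(**{**fit.__dict__, "C_calc": C_calc, "k2z_calc": k2z_calc})
    return predict_from_fit(fit)


def comparison_table(entries: list[tuple[str, KnnFit]]) -> pd.DataFrame:
    """Calculated-vs-predicted table, one row per system.

    The agreement flag per predicted quantity is true when
    |calculated - predicted| <= the reported margin (one standard
    error of the prediction).
    """
    if not entries:
        raise ValueError("need at least one entry")
    rows = []
    for name, fit in entries:
        rows.append({
            "system": name,
            "C_calc": fit.C_calc,
            "k2z_calc": fit.k2z_calc,
            "C_pred": fit.C_pred,
            "C_pred_se": fit.C_pred_se,
            "k2z_pred": fit.k2z_pred,
            "k2z_pred_se": fit.k2z_pred_se,
            "C_agrees": abs(fit.C_calc - fit.C_pred) <= fit.C_pred_se,
            "k2z_agrees": abs(fit.k2z_calc - fit.k2z_pred) <= fit.k2z_pred_se,
        })
    return pd.DataFrame(rows)
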