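"""Cohort statistics: rank correlation, omnibus tests, trend fits, qPCR ratios.

These are the nonparametric analyses applied to per-mouse ELS summaries
(Spearman age correlation, Kruskal-Wallis with Dunn post hoc and Holm-Sidak
adjustment, a bell-capable regression with R-squared, per-group size
distributions) plus efficiency-corrected relative qPCR quantification
(Pfaffl ratio).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_P_MAX_N = 9


class ConstantInputError(ValueError):
    """Correlation undefined: an input vector is constant."""


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n <= 9 the p-value is exact, computed by
    enumerating all n! pairings of the rank vectors; for larger n the usual
    t approximation is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be 1D of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant input, correlation undefined")
    n = len(x)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    r = _spearman_r(rx, ry)
    if n <= EXACT_P_MAX_N:
        perms = np.asarray(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pyc = perms - perms.mean(axis=1, keepdims=True)
        r_all = (pyc @ rxc) / np.sqrt((pyc**2).sum(axis=1) * (rxc**2).sum())
        p = float(np.mean(np.abs(r_all) >= abs(r) - 1e-12))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r**2))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return r, p


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = groups - 1).

    An all-tied input (every value identical) is defined as H = 0, p = 1:
    the tie-correction denominator vanishes and there is no evidence against
    the null.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    adjust: str = "holm-sidak",
) -> pd.DataFrame:
    """Dunn pairwise z-tests on the pooled ranks behind Kruskal-Wallis.

    Uses the tie-corrected variance sigma^2 = (N(N+1)/12 - sum(t^3 - t) /
    (12(N-1))) * (1/n_i + 1/n_j); two-sided normal p-values, adjusted with the
    stepwise Holm-Sidak procedure.  Returns a table with columns
    ``group_i, group_j, z, p, p_adj``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start : start + len(g)].mean()))
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(2 * sps.norm.sf(abs(z)))
        rows.append({"group_i": labels[i], "group_j": labels[j], "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method=adjust)[1]
    return out


@dataclass(frozen=True)
class BellFit:
    params: dict[str, float]
    r_squared: float
    peak: float | None  # location of the maximum, if the fit is concave
    model: str


def _r_squared(y, yhat) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0  # degenerate: constant response
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def bell_fit(x, y, model: str = "quadratic") -> BellFit:
    """Least-squares bell-capable trend fit with R-squared.

    The default model is the minimal bell-capable polynomial
    ``y = a + b x + c x^2``; a Gaussian bump ``a exp(-(x-mu)^2 / (2 s^2)) + d``
    is available with ``model="gaussian"``.  The peak location (-b/(2c) for
    the quadratic) is reported when the fitted curve is concave.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values")
    if model == "quadratic":
        design = np.c_[np.ones_like(x), x, x**2]
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        a, b, c = (float(v) for v in coef)
        yhat = design @ coef
        peak = -b / (2 * c) if c < 0 else None
        return BellFit({"a": a, "b": b, "c": c}, _r_squared(y, yhat), peak, model)
    if model == "gaussian":
        def f(t, amp, mu, s, d):
            return amp * np.exp(-((t - mu) ** 2) / (2 * s**2)) + d

        p0 = (float(y.max() - y.min()) or 1.0, float(x[np.argmax(y)]),
              float(np.std(x) or 1.0), float(y.min()))
        try:
            popt, _ = optimize.curve_fit(f, x, y, p0=p0, maxfev=10_000)
        except RuntimeError as err:
            raise ValueError(f"gaussian fit failed: {err}") from err
        amp, mu, s, d = (float(v) for v in popt)
        peak = mu if amp > 0 else None
        return BellFit({"amp": amp, "mu": mu, "sigma": s, "offset": d},
                       _r_squared(y, f(x, *popt)), peak, model)
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class QPCRMeasurement:
    """Efficiency-corrected relative qPCR quantification inputs.

    ``e_target`` / ``e_ref`` are amplification efficiencies in fold per cycle
    (2.0 = perfect doubling); ``delta_ct_*`` are control Ct minus sample Ct in
    cycles.
    """

    e_target: float
    delta_ct_target: float
    e_ref: float
    delta_ct_ref: float

    def __post_init__(self):
        if self.e_target <= 1 or self.e_ref <= 1:
            raise ValueError("amplification efficiencies must be > 1")


def pfaffl_fold_change(m: QPCRMeasurement) -> float:
    """Pfaffl ratio: E_target^dCt_target / E_ref^dCt_ref."""
    return float(m.e_target**m.delta_ct_target / m.e_ref**m.delta_ct_ref)


def size_distribution(
    sizes: pd.DataFrame, by: list[str] | str = "age_group"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled per-group structure size lists and their medians.

    ``sizes`` is a long table with an ``area_um2`` column plus grouping
    columns.  Returns ``(long_table, medians)`` where ``medians`` has one row
    per group (NaN median for an empty group).  Pooling is order-invariant.
    """
    if isinstance(by, str):
        by = [by]
    long = sizes.sort_values(by + ["area_um2"], kind="stable").reset_index(drop=True)
    if len(sizes):
        med = (
            sizes.groupby(by, sort=True)["area_um2"]
            .median()
            .reset_index()
            .rename(columns={"area_um2": "median_um2"})
        )
    else:
        med = pd.DataFrame(columns=by + ["median_um2"])
    return long, med
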