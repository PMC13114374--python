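"""Descriptive cohort analytics for the composite index.

Correlation structure (Spearman, pairwise-complete), Kruskal-Wallis group
contrasts, variance-share decomposition of the composite, and the two
sensitivity analyses (alternative domain weightings; shifted TyG
thresholds). All analyses are descriptive: no multiple-testing correction
is applied.

A domain's variance "contribution" is its covariance share
``cov(domain, total) / var(total)``: the only additive decomposition whose
three parts sum exactly to 100%. Raw per-domain variances are reported
alongside the shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .phenotyping import KeywordDictionary, default_dictionaries
from .scoring import ORIGINAL, SCHEMES, WeightingScheme, score_cohort

__all__ = [
    "SpearmanResult",
    "ConstantInputWarning",
    "spearman",
    "kruskal_wallis",
    "variance_shares",
    "correlation_matrix",
    "group_summary",
    "weighting_sensitivity",
    "threshold_sensitivity",
    "ThresholdSensitivityReport",
]

#: variables entering the correlation matrix, and their display labels
CORRELATION_VARIABLES = {
    "total": "NCR-SI",
    "n_points": "N",
    "c_points": "C",
    "r_points": "R",
    "egfr": "eGFR",
    "uacr": "UACR",
    "tyg": "TyG",
}


class ConstantInputWarning(UserWarning):
    """A correlation input was constant; rho is undefined (NaN), not zero."""


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with pairwise-complete missing handling.

    Ties receive mid-ranks; the p-value uses the large-sample t
    approximation. A constant input yields NaN with an explicit warning
    rather than a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "constant input: Spearman rho is undefined", ConstantInputWarning, stacklevel=2
        )
        return SpearmanResult(float("nan"), float("nan"), n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    If every observation is identical the statistic is 0 with p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def variance_shares(
    n: Sequence[int], c: Sequence[int], r: Sequence[int]
) -> tuple[float, float, float]:
    """Covariance shares of each domain in the composite total.

    share_d = cov(domain_d, total) / var(total); the three shares sum to 1
    up to floating tolerance. Raises if the total has zero variance.
    """
    n = np.asarray(n, dtype=float)
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    if not (n.size == c.size == r.size) or n.size < 2:
        raise ValueError("domain vectors must share a length >= 2")
    total = n + c + r
    var_total = float(np.var(total, ddof=1))
    if var_total == 0:
        raise ValueError("total score is constant: variance shares are undefined")
    shares = tuple(
        float(np.cov(d, total, ddof=1)[0, 1] / var_total) for d in (n, c, r)
    )
    return shares


def correlation_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation matrix over total, domains and biomarkers.

    Missing values (e.g. UACR not measured for all patients) are handled
    pairwise-complete. Symmetric with unit diagonal.
    """
    variables = [v for v in CORRELATION_VARIABLES if v in scores.columns]
    labels = [CORRELATION_VARIABLES[v] for v in variables]
    k = len(variables)
    matrix = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            xi = scores[variables[i]].to_numpy(dtype=float)
            xj = scores[variables[j]].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConstantInputWarning)
                rho = spearman(xi, xj).rho
            matrix[i, j] = matrix[j, i] = rho
    return pd.DataFrame(matrix, index=labels, columns=labels)


def group_summary(scores: pd.DataFrame) -> dict:
    """Group-wise medians/IQR of the total, category counts, and KW tests."""
    medians: dict[str, float] = {}
    iqrs: dict[str, tuple[float, float]] = {}
    for group, sub in scores.groupby("group"):
        medians[group] = float(sub["total"].median())
        iqrs[group] = (float(sub["total"].quantile(0.25)), float(sub["total"].quantile(0.75)))
    counts = (
        scores.pivot_table(
            index="group", columns="category", values="patient_id", aggfunc="count", fill_value=0
        )
        .reindex(columns=["low", "moderate", "high"], fill_value=0)
        .astype(int)
    )
    kw_results = {}
    for variable in ("total", "egfr", "tyg", "n_medications"):
        if variable not in scores.columns:
            continue
        groups = [
            sub[variable].dropna().to_numpy(dtype=float)
            for _, sub in scores.groupby("group")
        ]
        if len(groups) >= 2 and all(g.size for g in groups):
            kw_results[variable] = kruskal_wallis(groups)
    return {
        "group_medians": medians,
        "group_iqr": iqrs,
        "category_counts": counts,
        "kw_results": kw_results,
    }


def weighting_sensitivity(
    records: Sequence[PatientRecord],
    dictionaries: Sequence[KeywordDictionary] | None = None,
    schemes: Iterable[WeightingScheme] = tuple(SCHEMES.values()),
) -> pd.DataFrame:
    """Variance shares and total-vs-domain correlations per weighting scheme.

    The same patients are scored under every scheme; one row per scheme
    with the covariance shares, raw domain variances and Spearman
    rho(total, domain).
    """
    if dictionaries is None:
        dictionaries = default_dictionaries()
    rows = []
    for scheme in schemes:
        scored = score_cohort(records, dictionaries, scheme)
        shares = variance_shares(scored["n_points"], scored["c_points"], scored["r_points"])
        row = {
            "scheme": scheme.name,
            "share_n": shares[0],
            "share_c": shares[1],
            "share_r": shares[2],
            "var_n": float(scored["n_points"].var(ddof=1)),
            "var_c": float(scored["c_points"].var(ddof=1)),
            "var_r": float(scored["r_points"].var(ddof=1)),
        }
        for domain, column in (("n", "n_points"), ("c", "c_points"), ("r", "r_points")):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConstantInputWarning)
                row[f"rho_total_{domain}"] = spearman(scored["total"], scored[column]).rho
        rows.append(row)
    return pd.DataFrame(rows).set_index("scheme")


@dataclass(frozen=True)
class ThresholdSensitivityReport:
    """Re-scoring results under shifted TyG cut-offs."""

    deltas: tuple[float, ...]
    group_medians: Mapping[float, Mapping[str, float]]
    category_counts: Mapping[float, pd.DataFrame]
    rho_total_tyg: Mapping[float, float]
    ordering_preserved: bool
    scores: Mapping[float, pd.DataFrame] = field(repr=False, default_factory=dict)


def _median_ordering(medians: Mapping[str, float]) -> bool:
    """renometabolic >= cardiometabolic >= other, where present."""
    reno = medians.get("renometabolic", float("inf"))
    cardio = medians.get("cardiometabolic", float("-inf"))
    other = medians.get("other", float("-inf"))
    return reno >= cardio >= other


def threshold_sensitivity(
    records: Sequence[PatientRecord],
    dictionaries: Sequence[KeywordDictionary] | None = None,
    scheme: WeightingScheme = ORIGINAL,
    deltas: Sequence[float] = (-0.2, 0.0, 0.2),
) -> ThresholdSensitivityReport:
    """Re-score the cohort with all TyG cut-offs shifted by each delta.

    Reports per-group median totals, category counts and rho(total, TyG)
    under each shift, and whether the baseline group-median ordering
    (renometabolic >= cardiometabolic >= other) is preserved throughout.
    """
    if dictionaries is None:
        dictionaries = default_dictionaries()
    group_medians: dict[float, dict[str, float]] = {}
    category_counts: dict[float, pd.DataFrame] = {}
    rho_total_tyg: dict[float, float] = {}
    all_scores: dict[float, pd.DataFrame] = {}
    for delta in deltas:
        scored = score_cohort(records, dictionaries, scheme.with_tyg_shift(delta))
        summary = group_summary(scored)
        group_medians[delta] = summary["group_medians"]
        category_counts[delta] = summary["category_counts"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConstantInputWarning)
            rho_total_tyg[delta] = spearman(scored["total"], scored["tyg"]).rho
        all_scores[delta] = scored
    preserved = all(_median_ordering(group_medians[d]) for d in deltas)
    return ThresholdSensitivityReport(
        deltas=tuple(deltas),
        group_medians=group_medians,
        category_counts=category_counts,
        rho_total_tyg=rho_total_tyg,
        ordering_preserved=preserved,
        scores=all_scores,
    )
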