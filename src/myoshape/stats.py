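"""Cohort-level statistics: correlation screens and group comparisons.

Small-cohort (n ~ 14) non-parametric statistics as used throughout the
profiling study: Spearman rank correlation (with a +/-0.5 coefficient
rule of thumb for "correlated"), Pearson product-moment correlation,
Mann-Whitney and paired Wilcoxon tests, and the 2x2 chi-square test.
Exact small-sample enumeration paths are provided where the asymptotic
approximations are weakest.  Missing values are handled by
pairwise-complete deletion with the effective n reported.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationReport",
    "TestResult",
    "rank_correlation",
    "product_moment_correlation",
    "mann_whitney",
    "wilcoxon_paired",
    "chi_square",
    "demographics_summary",
    "descriptor_fusion_screen",
]

#: |r| above which a coefficient is flagged as a correlation.
CORRELATION_RULE = 0.5


@dataclasses.dataclass
class CorrelationReport:
    """A correlation coefficient with its test and the +/-0.5 flag."""

    r: float
    p: float
    n: int
    method: str
    correlated: bool


@dataclasses.dataclass
class TestResult:
    statistic: float
    p: float
    n: tuple[int, ...]
    method: str


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _report(r: float, p: float, n: int, method: str) -> CorrelationReport:
    correlated = bool(not math.isnan(r) and abs(r) > CORRELATION_RULE)
    return CorrelationReport(r=float(r), p=float(p), n=int(n), method=method,
                             correlated=correlated)


def rank_correlation(x, y, exact: bool = False) -> CorrelationReport:
    """Spearman rho with mid-ranks for ties.

    The p-value uses the t-approximation; ``exact=True`` (n <= 9)
    enumerates all rank permutations instead.  Constant input yields an
    undefined (NaN) coefficient.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("rank correlation requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _report(math.nan, math.nan, n, "rank")
    if exact:
        if n > 9:
            raise ValueError("exact rank-correlation p only for n <= 9")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = _pearson_r(rx, ry)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson_r(rx, np.array(perm))) >= abs(obs) - 1e-12:
                count += 1
        return _report(obs, count / total, n, "rank-exact")
    rho, p = sps.spearmanr(x, y)
    return _report(rho, p, n, "rank")


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else math.nan


def product_moment_correlation(x, y) -> CorrelationReport:
    """Pearson r with the two-sided t-test p-value."""
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("correlation requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return _report(math.nan, math.nan, n, "product-moment")
    r, p = sps.pearsonr(x, y)
    return _report(r, p, n, "product-moment")


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([a, b]))
    ra = ranks[: len(a)].sum()
    return ra - len(a) * (len(a) + 1) / 2.0


def mann_whitney(a, b, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Enumerates all group assignments when the pooled size is at most
    ``exact_max_n`` (tie-safe exact two-sided p on |U - mu|); otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u = _mann_whitney_u(a, b)
    na, nb = len(a), len(b)
    mu = na * nb / 2.0
    if na + nb <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = range(na + nb)
        count = 0
        total = 0
        for comb in itertools.combinations(idx, na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(comb)] = True
            u_perm = _mann_whitney_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= abs(u - mu) - 1e-12:
                count += 1
        return TestResult(u, count / total, (na, nb), "mann-whitney-exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), (na, nb),
                      "mann-whitney-normal")


def wilcoxon_paired(a, b, exact_max_n: int = 10) -> TestResult:
    """Two-sided Wilcoxon signed-rank test, zero differences dropped.

    Exact sign enumeration (tie-safe, on |W+ - mu|) up to
    ``exact_max_n`` non-zero pairs, otherwise the normal approximation.
    An all-zero difference vector is undefined (NaN statistic/p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(math.nan, math.nan, (0,), "wilcoxon-undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    stat = min(w_plus, w_minus)
    mu = n * (n + 1) / 4.0
    if n <= exact_max_n:
        count = 0
        total = 2**n
        for signs in itertools.product((0, 1), repeat=n):
            wp = sum(r for r, s in zip(ranks, signs) if s)
            if abs(wp - mu) >= abs(w_plus - mu) - 1e-12:
                count += 1
        return TestResult(float(stat), count / total, (n,), "wilcoxon-exact")
    res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    return TestResult(float(stat), float(res.pvalue), (n,), "wilcoxon-normal")


def chi_square(table) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), tuple(int(x) for x in table.sum(1)),
                      "chi-square")


# ---------------------------------------------------------------------------
# cohort summaries and screens

_CONTINUOUS = {"age": "Age", "bmi": "BMI", "fusion_index": "FusionIndex"}
_FLAGS = {"tobacco": "Tobacco", "alcohol": "Alcohol", "drug": "NonIVDrug"}


def demographics_summary(cohort: pd.DataFrame) -> dict:
    """Per-sex cohort summary with between-sex tests.

    Returns a nested dict: overall and per-sex mean +/- sample SD of age,
    BMI and fusion index; per-sex percentage of tobacco/alcohol/drug use;
    Mann-Whitney p for each continuous variable and chi-square p for each
    flag.  Missing groups or single-donor groups carry NaN entries.
    """
    out: dict = {"n": int(len(cohort)), "groups": {}, "tests": {}}
    sexes = ("M", "F")
    grouped = {s: cohort[cohort["Sex"] == s] for s in sexes}

    def _block(df: pd.DataFrame) -> dict:
        block: dict = {"n": int(len(df))}
        for key, col in _CONTINUOUS.items():
            vals = df[col].astype(float)
            block[f"{key}_mean"] = float(vals.mean()) if len(vals) else math.nan
            block[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else math.nan
        for key, col in _FLAGS.items():
            if col in df.columns and len(df):
                block[f"{key}_pct"] = float(df[col].astype(float).mean() * 100.0)
            else:
                block[f"{key}_pct"] = math.nan
        return block

    out["overall"] = _block(cohort)
    for s in sexes:
        out["groups"][s] = _block(grouped[s])

    m, f = grouped["M"], grouped["F"]
    for key, col in _CONTINUOUS.items():
        if len(m) and len(f):
            res = mann_whitney(m[col].astype(float), f[col].astype(float))
            out["tests"][key] = {"p": res.p, "method": res.method}
        else:
            out["tests"][key] = {"p": math.nan, "method": "undefined"}
    for key, col in _FLAGS.items():
        if col not in cohort.columns or not (len(m) and len(f)):
            out["tests"][key] = {"p": math.nan, "method": "undefined"}
            continue
        tab = [
            [int(m[col].sum()), int(len(m) - m[col].sum())],
            [int(f[col].sum()), int(len(f) - f[col].sum())],
        ]
        try:
            res = chi_square(tab)
            out["tests"][key] = {"p": res.p, "method": res.method}
        except ValueError:
            out["tests"][key] = {"p": math.nan, "method": "undefined"}
    return out


def descriptor_fusion_screen(
    cohort: pd.DataFrame,
    descriptors: Sequence[str] | None = None,
    passages: Sequence[str] = ("P2", "P3"),
    timepoints: Sequence[str] = ("12h", "24h"),
    alpha: float = 0.05,
    method: str = "rank",
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate every descriptor summary column with the fusion index.

    Expects columns named ``{descriptor}_{passage}_{timepoint}``; each
    cell of the screen reports r, p, n (pairwise-complete), the
    significance flag at ``alpha`` and the +/-0.5 correlated flag.
    Returns (screen table, list of missing columns skipped).
    """
    from .synthetic import SCREEN_DESCRIPTORS

    descriptors = list(descriptors or SCREEN_DESCRIPTORS)
    corr = rank_correlation if method == "rank" else product_moment_correlation
    fi = cohort["FusionIndex"].astype(float)
    rows = []
    missing = []
    for desc in descriptors:
        for p in passages:
            for tp in timepoints:
                col = f"{desc}_{p}_{tp}"
                if col not in cohort.columns:
                    missing.append(col)
                    continue
                rep = corr(cohort[col].astype(float), fi)
                rows.append(
                    dict(
                        descriptor=desc, passage=p, timepoint=tp,
                        n=rep.n, r=rep.r, p=rep.p,
                        significant=bool(not math.isnan(rep.p) and rep.p < alpha),
                        correlated=rep.correlated,
                    )
                )
    return pd.DataFrame(rows), missing
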