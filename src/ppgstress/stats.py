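"""Rank-based group comparisons between stressor phases.

Phase contrasts follow the study convention: A = baseline vs 1st minute
(stressor onset), B = 1st vs 2nd minute, C = 2nd minute vs recovery
(stressor offset). Each contrast is scored with a two-sided Mann-Whitney U
test (significance tiers p < 0.05 and p < 0.01) and with the AUC
U/(n1*n2) — the probability that a value from the first phase ranks above
one from the second, ties counting one half.

Small samples (n1, n2 <= 8) use exact enumeration of all labelings, which
handles ties correctly; larger samples use the normal approximation with
tie and continuity corrections. Missing feature values are dropped before
testing; cells with fewer than two defined values per group are reported
as unavailable.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

CONTRASTS = {"A": ("baseline", "min1"), "B": ("min1", "min2"),
             "C": ("min2", "recovery")}
EXACT_MAX_N = 8
TIERS = ((0.01, "p<0.01"), (0.05, "p<0.05"))


@dataclass
class SummaryTables:
    """Cohort summaries: phase means, significance tiers, and AUCs."""

    table1_2: pd.DataFrame   # mean +- sd per stressor x wavelength x phase x feature
    table3: pd.DataFrame     # Mann-Whitney tiers per contrast A/B/C
    table4: pd.DataFrame     # AUC per contrast A/C, 1 decimal, flag at >= 0.8
    log: list


def _clean(sample) -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    return x[np.isfinite(x)]


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Exact enumeration over all C(n1+n2, n1) labelings when both groups have
    at most 8 observations (valid with ties); otherwise the asymptotic
    normal approximation with tie and continuity corrections.
    """
    a, b = _clean(a), _clean(b)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty after dropping missing values")
    u = _u_statistic(a, b)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        n = n1 + n2
        # pairwise order matrix lets each labeling's U be read off by indexing
        order = (pooled[:, None] > pooled[None, :]) + 0.5 * (pooled[:, None] == pooled[None, :])
        np.fill_diagonal(order, 0.0)
        mu = n1 * n2 / 2.0
        dev = abs(u - mu)
        hits = total = 0
        idx = np.arange(n)
        for comb in combinations(idx, n1):
            rest = np.setdiff1d(idx, comb, assume_unique=True)
            u_perm = order[np.asarray(comb)][:, rest].sum()
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        return u, hits / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return u, float(res.pvalue)


def auc(a, b) -> float:
    """P(a > b) + 0.5 P(a = b) over all cross pairs; equals U/(n1*n2)."""
    a, b = _clean(a), _clean(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty after dropping missing values")
    return _u_statistic(a, b) / (len(a) * len(b))


def significance_tier(p: float) -> str:
    for threshold, label in TIERS:
        if p < threshold:
            return label
    return "ns"


def round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def summarize(features: pd.DataFrame, feature_names=None) -> SummaryTables:
    """Cohort summary tables from the long-format feature table.

    Means/sds and all tests use defined values only; the sd is the
    population form used throughout the feature set.
    """
    if feature_names is None:
        feature_names = ["mean", "sd", "katz", "petrosian", "higuchi",
                         "sampen", "total_sampen", "avg_sampen"]
    log = []
    rows12, rows3, rows4 = [], [], []
    for (stressor, wavelength), group in features.groupby(["stressor", "wavelength"],
                                                          sort=True):
        by_phase = {ph: sub for ph, sub in group.groupby("phase")}
        for feat in feature_names:
            for phase, sub in sorted(by_phase.items()):
                vals = _clean(sub[feat])
                n = len(vals)
                if n == 0:
                    mu = sd = np.nan
                    log.append(f"{stressor}/{wavelength}/{phase}/{feat}: no defined values")
                else:
                    mu = float(np.mean(vals))
                    sd = float(np.sqrt(np.mean((vals - mu) ** 2)))
                rows12.append(dict(stressor=stressor, wavelength=wavelength,
                                   phase=phase, feature=feat, n=n,
                                   mean=mu, sd=sd))
            for contrast, (ph1, ph2) in CONTRASTS.items():
                x = _clean(by_phase.get(ph1, pd.DataFrame({feat: []}))[feat])
                y = _clean(by_phase.get(ph2, pd.DataFrame({feat: []}))[feat])
                available = len(x) >= 2 and len(y) >= 2
                if available:
                    u, p = mann_whitney(x, y)
                    a = auc(x, y)
                else:
                    u = p = a = np.nan
                    log.append(f"{stressor}/{wavelength}/{feat}/{contrast}: "
                               f"unavailable (n1={len(x)}, n2={len(y)})")
                rows3.append(dict(stressor=stressor, wavelength=wavelength,
                                  feature=feat, contrast=contrast,
                                  n1=len(x), n2=len(y), u=u, p=p,
                                  tier=significance_tier(p) if available else "na"))
                if contrast in ("A", "C"):
                    a_rounded = round_half_away(a) if available else np.nan
                    rows4.append(dict(stressor=stressor, wavelength=wavelength,
                                      feature=feat, contrast=contrast,
                                      auc=a, auc_rounded=a_rounded,
                                      flagged=bool(available and a_rounded >= 0.8)))
    return SummaryTables(table1_2=pd.DataFrame(rows12),
                         table3=pd.DataFrame(rows3),
                         table4=pd.DataFrame(rows4), log=log)
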