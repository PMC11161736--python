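"""Shared statistical utilities: BH adjustment, contingency association,
Grubbs outlier test."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contingency_association(
    labels_a: pd.Series | dict,
    labels_b: pd.Series | dict,
    test: str = "chi2",
) -> dict:
    """Cross-tabulate two labelings of (partly) shared samples.

    Returns a dict with the count table, chi-square statistic/dof/p (or
    Fisher exact p for 2x2 with ``test="fisher"``), and per-row percentage
    composition rounded to 2 decimals. Warns when expected counts are small.
    """
    a = pd.Series(labels_a).astype(str)
    b = pd.Series(labels_b).astype(str)
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ValueError("labelings share fewer than 2 samples")
    table = pd.crosstab(a.loc[shared].rename("A"), b.loc[shared].rename("B"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("each labeling needs >= 2 levels on the shared samples")
    if test == "fisher":
        if table.shape != (2, 2):
            raise ValueError("Fisher exact test requires a 2x2 table")
        stat, p = sps.fisher_exact(table.to_numpy())
        dof = 1
    elif test == "chi2":
        res = sps.chi2_contingency(table.to_numpy(), correction=False)
        stat, p, dof = float(res.statistic), float(res.pvalue), int(res.dof)
        if (np.asarray(res.expected_freq) < 5).any():
            warnings.warn("chi-square approximation dubious: expected counts < 5")
    else:
        raise ValueError(f"unknown test {test!r}")
    row_pct = (table.div(table.sum(axis=1), axis=0) * 100).round(2)
    return {"table": table, "statistic": float(stat), "dof": dof, "p": float(p),
            "row_percent": row_pct, "n": int(table.to_numpy().sum())}


def grubbs_test(values, alpha: float = 0.05) -> list[int]:
    """Iterated two-sided Grubbs outlier test; returns outlier indices.

    At each step the most extreme value is tested with
    ``G = max|x - mean| / sd`` against the t-based critical value at level
    ``alpha``; rejection removes it and the test repeats. Assumes
    approximate normality of the inliers. sd = 0 yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Grubbs test needs a 1-d sample with n >= 3")
    active = list(range(x.size))
    outliers: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_max = int(np.argmax(dev))
        G = dev[i_max] / sd
        n = len(active)
        t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
        if G > g_crit:
            outliers.append(active.pop(i_max))
        else:
            break
    return sorted(outliers)
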