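"""Inferential layer: two-group Mann-Whitney comparisons of ROI-level
quantities and Spearman correlations between FTIR indices and histological
protein burden.

Small-sample policy (the study works at n = 10 ROIs per group):

* Mann-Whitney: U from midranks.  With both groups <= 10 and no ties the
  two-sided p is exact, from the full null distribution of U (count
  recursion, equivalent to enumerating all label assignments).  Ties at
  small n switch to a seeded Monte-Carlo permutation test; larger samples
  use the normal approximation with tie and continuity correction.
* Spearman: rho is the Pearson correlation of midranks.  p is exact by
  full permutation enumeration for n <= 8, seeded Monte-Carlo permutation
  for 9 <= n <= 10, and the t approximation for n > 10.

Tests are two-sided throughout and no multiple-testing correction is
applied by default (an optional Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "mann_whitney",
    "spearman",
    "correlate_ftir_histology",
    "benjamini_hochberg",
]

MC_DRAWS = 100_000


@dataclass
class GroupComparison:
    quantity: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_two_sided: float
    significant: bool
    method: str

    def as_dict(self):
        return dict(self.__dict__)


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    rho: float
    p_two_sided: float
    scope: str
    tissue_class: str
    group: str
    method: str
    n_dropped: int
    significant: bool

    def as_dict(self):
        return dict(self.__dict__)


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Frequencies of U = 0..n1*n2 under the no-tie null (count recursion)."""
    if n1 == 0 or n2 == 0:
        return np.ones(1)
    a = _u_null_counts(n1 - 1, n2)
    b = _u_null_counts(n1, n2 - 1)
    out = np.zeros(n1 * n2 + 1)
    out[n2:n2 + a.size] += a
    out[:b.size] += b
    return out


def _exact_u_pvalue(u: float, n1: int, n2: int) -> float:
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    m = n1 * n2
    u_lo = min(u, m - u)
    lo = int(np.floor(u_lo + 1e-9))
    p = (counts[: lo + 1].sum() + counts[m - lo:].sum()) / total
    return float(min(p, 1.0))


def mann_whitney(a: Sequence[float], b: Sequence[float], alpha: float = 0.05,
                 quantity: str = "", group_a: str = "a", group_b: str = "b",
                 seed: int = 0, n_mc: int = MC_DRAWS) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two value groups."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one finite value")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    ties = np.unique(pooled).size < pooled.size
    if n1 <= 10 and n2 <= 10:
        if not ties:
            p = _exact_u_pvalue(u_a, n1, n2)
            method = "exact"
        else:
            rng = np.random.default_rng(seed)
            m = n1 * n2
            dev = abs(u_a - m / 2.0)
            order = rng.random((n_mc, n1 + n2)).argsort(axis=1)
            perm_ranks = ranks[order[:, :n1]]
            u_perm = perm_ranks.sum(axis=1) - n1 * (n1 + 1) / 2.0
            p = float(np.mean(np.abs(u_perm - m / 2.0) >= dev - 1e-9))
            p = max(p, 1.0 / n_mc)
            method = "mc_permutation"
    else:
        res = sps.mannwhitneyu(a, b, use_continuity=True,
                               alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approx"
    return GroupComparison(quantity, group_a, group_b, n1, n2, u_a, p,
                           p < alpha, method)


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int64)


def _perm_rhos(rx: np.ndarray, ry: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    num = ryc[perm_idx] @ rxc
    den = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    return num / den


def spearman(x: Sequence[float], y: Sequence[float], alpha: float = 0.05,
             x_name: str = "x", y_name: str = "y", scope: str = "global",
             tissue_class: str = "", group: str = "", seed: int = 0,
             n_mc: int = MC_DRAWS) -> CorrelationResult:
    """Spearman rank correlation with a small-sample exact/permutation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int(x.size - ok.sum())
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 complete pairs")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(x_name, y_name, n, float("nan"), float("nan"),
                                 scope, tissue_class, group,
                                 "undefined_zero_rank_variance", n_dropped,
                                 False)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        rhos = _perm_rhos(rx, ry, _all_permutations(n))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact_permutation"
    elif n <= 10:
        rng = np.random.default_rng(seed)
        perm_idx = rng.random((n_mc, n)).argsort(axis=1)
        rhos = _perm_rhos(rx, ry, perm_idx)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        p = max(p, 1.0 / n_mc)
        method = "mc_permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "t_approx"
    return CorrelationResult(x_name, y_name, n, rho, p, scope, tissue_class,
                             group, method, n_dropped, p < alpha)


def _resolve_column(df: pd.DataFrame, name: str) -> str:
    if name in df.columns:
        return name
    if f"ratio_{name}" in df.columns:
        return f"ratio_{name}"
    raise KeyError(f"quantity {name!r} not found in the ROI table")


def correlate_ftir_histology(quant: pd.DataFrame, burden: pd.DataFrame,
                             pairs: Sequence[tuple[str, str]],
                             scope: str = "global", alpha: float = 0.05,
                             seed: int = 0) -> list[CorrelationResult]:
    """Spearman correlations of FTIR quantities against stain burden.

    Tables join on (case_id, roi_label, tissue_class); ``pairs`` lists
    (ftir quantity, stain) combinations.  ``scope='global'`` pools all
    cases' ROIs per tissue class; ``scope='per_group'`` stratifies by case.
    Strata with fewer than 3 complete pairs are flagged insufficient.
    """
    if scope not in ("global", "per_group"):
        raise ValueError("scope must be 'global' or 'per_group'")
    results: list[CorrelationResult] = []
    for ftir_q, stain in pairs:
        col = _resolve_column(quant, ftir_q)
        sub_burden = burden[burden["stain"] == stain]
        merged = quant.merge(sub_burden,
                             on=["case_id", "roi_label", "tissue_class"],
                             how="inner")
        for tissue_class, tsub in merged.groupby("tissue_class"):
            strata = ([("all", tsub)] if scope == "global"
                      else list(tsub.groupby("case_id")))
            for group, gsub in strata:
                ok = gsub[[col, "percent_area"]].dropna()
                if len(ok) < 3:
                    results.append(CorrelationResult(
                        ftir_q, stain, len(ok), float("nan"), float("nan"),
                        scope, tissue_class, str(group), "insufficient",
                        len(gsub) - len(ok), False))
                    continue
                results.append(spearman(
                    ok[col], ok["percent_area"], alpha, x_name=ftir_q,
                    y_name=stain, scope=scope, tissue_class=tissue_class,
                    group=str(group), seed=seed))
    return results


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Optional FDR adjustment (off by default everywhere)."""
    return sps.false_discovery_control(np.asarray(pvals, float), method="bh")
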