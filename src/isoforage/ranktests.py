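"""Rank-based comparison of hotspot contributions across years.

Years are blocks, hotspots are treatments. The omnibus test is the
Friedman rank-sum test with the standard tie correction; the all-pairs
post hoc is Conover's Friedman-type test (t distribution with
(b−1)(k−1) df on within-block rank sums), with Benjamini–Hochberg
control of the false discovery rate across the k(k−1)/2 pairs. A
compact letter display summarizes which treatments are statistically
indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .summaries import ContributionTable


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PosthocResult:
    """All-pairs Conover test with BH-adjusted p-values and letters."""

    raw_p: np.ndarray       # k×k symmetric, diagonal 1
    adjusted_p: np.ndarray  # k×k symmetric, diagonal 1
    letters: list[str]      # compact letter display per treatment
    treatments: list[str]
    alpha: float


def _as_blocks(table) -> tuple[np.ndarray, list[str]]:
    """Coerce input to a blocks × treatments array.

    Accepts a ContributionTable (hotspots × years → transposed so years
    are blocks), a DataFrame (rows = blocks), or a 2-D array.
    """
    if isinstance(table, ContributionTable):
        df = table.data.T
        return df.to_numpy(dtype=float), list(df.columns)
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), [str(c) for c in table.columns]
    arr = np.asarray(table, dtype=float)
    return arr, [f"t{j}" for j in range(arr.shape[1])]


def _block_ranks(x: np.ndarray) -> np.ndarray:
    if x.ndim != 2:
        raise ValidationError("table must be 2-D (blocks × treatments)")
    b, k = x.shape
    if b < 2 or k < 2:
        raise ValidationError("need at least 2 blocks and 2 treatments")
    if np.isnan(x).any():
        raise ValidationError("missing cells are not allowed (no imputation)")
    return np.apply_along_axis(stats.rankdata, 1, x)


def friedman(table) -> FriedmanResult:
    """Friedman rank-sum test with tie correction.

    Statistic: (k−1)·Σⱼ(Rⱼ − b(k+1)/2)² / (A − C) with A = Σ r²ᵢⱼ and
    C = bk(k+1)²/4; reduces to the familiar 12/(bk(k+1))·ΣRⱼ² − 3b(k+1)
    when no ties occur. p from χ²(k−1). All columns tied in every block
    gives statistic 0, p = 1.
    """
    x, _ = _as_blocks(table)
    r = _block_ranks(x)
    b, k = x.shape
    rj = r.sum(axis=0)
    a = float((r**2).sum())
    c = b * k * (k + 1) ** 2 / 4.0
    num = (k - 1) * float(((rj - b * (k + 1) / 2.0) ** 2).sum())
    if a - c <= 0:  # every block fully tied
        return FriedmanResult(0.0, k - 1, 1.0)
    statistic = num / (a - c)
    pvalue = float(stats.chi2.sf(statistic, k - 1))
    return FriedmanResult(float(statistic), k - 1, pvalue)


def conover_pairwise(table, alpha: float = 0.05) -> PosthocResult:
    """Conover's all-pairs post hoc for the Friedman design.

    t = |Rᵢ − Rⱼ| / √(2b(A − B)/((b−1)(k−1))) with B = Σ Rⱼ²/b, referred
    to t with (b−1)(k−1) df; BH adjustment over the upper triangle.
    """
    x, names = _as_blocks(table)
    r = _block_ranks(x)
    b, k = x.shape
    rj = r.sum(axis=0)
    a = float((r**2).sum())
    bb = float((rj**2).sum()) / b
    dof = (b - 1) * (k - 1)
    denom2 = 2.0 * b * (a - bb) / dof
    raw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if denom2 <= 0:
                # rankings perfectly consistent across blocks: tied rank
                # sums are indistinguishable, distinct ones maximally so
                p = 1.0 if rj[i] == rj[j] else 0.0
            else:
                t = abs(rj[i] - rj[j]) / np.sqrt(denom2)
                p = float(2.0 * stats.t.sf(t, dof))
            raw[i, j] = raw[j, i] = min(p, 1.0)
    iu = np.triu_indices(k, 1)
    adj_flat = multipletests(raw[iu], method="fdr_bh")[1]
    adj = np.ones((k, k))
    adj[iu] = adj_flat
    adj.T[iu] = adj_flat
    letters = letter_display(adj, alpha=alpha)
    return PosthocResult(raw, adj, letters, names, alpha)


def letter_display(adjusted_p: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Compact letter display by insert-and-absorb.

    Two treatments share a letter iff their adjusted p ≥ alpha. Letter
    classes start as one all-inclusive set and are split at each
    significant pair; absorbed (subset) classes are dropped. Output is
    deterministic in treatment order.
    """
    p = np.asarray(adjusted_p, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k) or not np.allclose(p, p.T):
        raise ValidationError("adjusted p matrix must be square and symmetric")
    classes: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if p[i, j] < alpha:
                new_classes: list[set[int]] = []
                for cls in classes:
                    if i in cls and j in cls:
                        new_classes.extend([cls - {i}, cls - {j}])
                    else:
                        new_classes.append(cls)
                # absorb: drop any class contained in another
                classes = []
                for cls in sorted(new_classes, key=len, reverse=True):
                    if cls and not any(cls <= kept for kept in classes):
                        classes.append(cls)
    # order classes by their first (lowest-index) member for stable letters
    classes.sort(key=min)
    letters = ["" for _ in range(k)]
    for letter_idx, cls in enumerate(classes):
        ch = _letter(letter_idx)
        for t in sorted(cls):
            letters[t] += ch
    if any(not s for s in letters):  # all pairs significant: unique letters
        for t in range(k):
            if not letters[t]:
                letters[t] = _letter(len(classes) + t)
    return letters


def _letter(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out
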