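"""The correlation battery used on per-gene evolutionary-rate estimates.

Spearman's rho (pairwise-complete), partial Spearman controlling for a
third variable, Steiger's test for two dependent correlations sharing a
variable, a 2x2 chi-square on proportions of genes with dN/dS > 1, and a
Kruskal-Wallis distribution comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    variables: tuple[str, str]
    rho: float
    n: int
    p: float


@dataclass
class DependentComparison:
    rho_a: float
    rho_b: float
    rho_ab: float
    t_stat: float
    df: int
    p: float
    method: str = "steiger"


@dataclass
class ProportionShift:
    chi2: float
    p: float
    applicable: bool


def _complete(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    cols = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.logical_and.reduce([np.isfinite(c) for c in cols])
    return tuple(c[mask] for c in cols)


def spearman(
    x: np.ndarray, y: np.ndarray, names: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Spearman rho on average ranks with the t-approximation p-value.

    Incomplete pairs (NaN in either variable) are dropped.
    """
    xc, yc = _complete(x, y)
    if xc.size < 3:
        raise ValueError("spearman requires >= 3 complete pairs")
    if np.unique(xc).size < 2 or np.unique(yc).size < 2:
        raise ValueError("spearman undefined for a constant vector")
    rho, p = stats.spearmanr(xc, yc)
    return CorrelationResult(names, float(rho), int(xc.size), float(p))


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Rank all three variables, then first-order partial correlation.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)), with the
    t-approximation p-value on df = n - 3.
    """
    xc, yc, zc = _complete(x, y, z)
    n = xc.size
    if n < 4:
        raise ValueError("partial_spearman requires >= 4 complete triples")
    if any(np.unique(v).size < 2 for v in (xc, yc, zc)):
        raise ValueError("partial_spearman undefined for a constant vector")
    rx, ry, rz = (stats.rankdata(v) for v in (xc, yc, zc))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        raise ValueError("degenerate control variable (|r| = 1 with x or y)")
    rho = float((r_xy - r_xz * r_yz) / np.sqrt(denom))
    df = n - 3
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(names, rho, n, p)


def compare_dependent_correlations(
    rho_a: float, rho_b: float, rho_ab: float, n: int
) -> DependentComparison:
    """Steiger's test for two correlations sharing one variable.

    ``rho_a`` = cor(x, a), ``rho_b`` = cor(x, b), ``rho_ab`` = cor(a, b).
    Fisher-z transforms the two correlations and refers their difference
    to a t distribution with df = n - 3 (two-sided).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    for name, r in (("rho_a", rho_a), ("rho_b", rho_b), ("rho_ab", rho_ab)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie in (-1, 1), got {r}")
    df = n - 3
    za, zb = np.arctanh(rho_a), np.arctanh(rho_b)
    rbar2 = ((rho_a + rho_b) / 2.0) ** 2
    # pooled covariance of the two dependent correlation estimates
    s = (rho_ab * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - rho_ab**2)) / (
        (1 - rbar2) ** 2
    )
    if za == zb:
        t = 0.0
    else:
        t = float((za - zb) * np.sqrt(df / (2.0 - 2.0 * s)))
    p = float(2 * stats.t.sf(abs(t), df)) if t != 0.0 else 1.0
    return DependentComparison(rho_a, rho_b, rho_ab, t, df, p)


def proportion_shift_test(a: int, b: int, n: int) -> ProportionShift:
    """2x2 chi-square (no continuity correction) on [[a, n-a], [b, n-b]].

    ``a``/``b`` are counts of genes with dN/dS > 1 before/after codon
    removal out of ``n`` genes.  A zero margin (no gene above 1 in either
    condition, or all genes above 1 in both) yields a not-applicable flag.
    """
    if not (0 <= a <= n and 0 <= b <= n):
        raise ValueError("counts must satisfy 0 <= a, b <= n")
    table = np.array([[a, n - a], [b, n - b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ProportionShift(float("nan"), float("nan"), applicable=False)
    total = table.sum()
    det = table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]
    margins = table.sum(axis=0).prod() * table.sum(axis=1).prod()
    chi2 = float(total * det**2 / margins)
    return ProportionShift(chi2, float(stats.chi2.sf(chi2, df=1)), applicable=True)


def distribution_shift_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction across >= 2 groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.unique(flat).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
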