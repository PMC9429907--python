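"""Shared hypothesis tests and multiple-testing adjustment.

Welch's unequal-variance t-test is used to compare virulence indices and
spore yields between strains; the one-sample paired t-test checks whether
induced/control cell-density differences center on zero.  Adjustment wraps
the standard step-down (Holm) and step-up (BH/BY) procedures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WelchResult",
    "PairedTResult",
    "welch_t_test",
    "paired_density_test",
    "adjust_pvalues",
]

_ADJUST_METHODS = {"holm": "holm", "bh": "fdr_bh", "by": "fdr_by"}


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int

    def format(self) -> str:
        """Render as reported in the field, e.g. ``t_12.9 = 1.22, P = 0.25``."""
        return f"t_{self.df:.1f} = {self.t:.2f}, P = {self.p:.2g}"


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    n: int


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Two-sided Welch t-test (difference in means != 0).

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b); degrees of freedom by the
    Welch-Satterthwaite approximation; p two-sided from the t distribution.

    Degenerate inputs: if both groups have zero variance and equal means the
    test is vacuous and p = 1 is returned; zero variance with unequal means
    (or in only one group with the other constant) is rejected.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires n >= 2 in each group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("welch_t_test requires finite samples")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    ma = a.mean()
    mb = b.mean()
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0, ma, mb, a.size, b.size)
        raise ValueError("zero variance in both groups with unequal means")
    sea = va / a.size
    seb = vb / b.size
    se2 = sea + seb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (sea**2 / (a.size - 1) + seb**2 / (b.size - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p, float(ma), float(mb), int(a.size), int(b.size))


def paired_density_test(
    induced_totals: Sequence[float], control_totals: Sequence[float]
) -> PairedTResult:
    """One-sample t-test (mean != 0) on paired induced - control differences."""
    x = np.asarray(induced_totals, dtype=float)
    y = np.asarray(control_totals, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired_density_test requires n >= 2 pairs")
    d = x - y
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if md == 0.0:
            return PairedTResult(0.0, n - 1, 1.0, 0.0, n)
        raise ValueError("zero variance of differences with nonzero mean")
    t = md / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(float(t), n - 1, p, float(md), n)


def adjust_pvalues(p_values: Sequence[float], method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment: Holm step-down, or BH / BY step-up.

    Returns adjusted p-values clipped to 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    try:
        sm_method = _ADJUST_METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown adjustment method {method!r}; choose from {sorted(_ADJUST_METHODS)}")
    return multipletests(p, method=sm_method)[1]
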