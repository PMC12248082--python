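"""Statistical layer: group comparisons, Sholl AUC analysis, and a
from-scratch two-sided Fisher exact test.

The Fisher test follows the sum-of-small-probabilities convention: the
two-sided p-value is the sum of hypergeometric probabilities, over every
2x2 table with the observed margins, that do not exceed the observed
table's probability (within a small relative tolerance for floating-point
ties).  Standard tests (Student's t, one-way ANOVA with Tukey HSD,
Kruskal-Wallis) delegate to scipy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

logger = logging.getLogger(__name__)

_TIE_RTOL = 1e-7


@dataclass
class ContingencyTable2x2:
    """Counts with rows = groups and columns = outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in vals):
            raise ParameterError("contingency counts must be non-negative integers")
        if sum(vals) < 1:
            raise ParameterError("contingency table must hold at least one count")


def _log_hypergeom(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = a) for the hypergeometric table (a, r1-a; c1-a, r2-c1+a)."""
    n = r1 + r2
    return (
        math.lgamma(r1 + 1) - math.lgamma(a + 1) - math.lgamma(r1 - a + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - a + 1) - math.lgamma(r2 - c1 + a + 1)
        - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
    )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Exact two-sided Fisher p-value by enumeration over the margins.

    With any zero margin only one table is possible and p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    log_obs = _log_hypergeom(a, r1, r2, c1)
    cutoff = log_obs + math.log1p(_TIE_RTOL)
    p = 0.0
    for x in range(lo, hi + 1):
        lp = _log_hypergeom(x, r1, r2, c1)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


# --------------------------------------------------------------------------
# Sholl AUC
# --------------------------------------------------------------------------

def sholl_auc(normalized_bins: np.ndarray,
              bin_midpoints: np.ndarray | None = None) -> float:
    """Trapezoidal area under one cell's 10 normalized Sholl bins."""
    y = np.asarray(normalized_bins, dtype=float)
    if bin_midpoints is None:
        bin_midpoints = (np.arange(len(y)) + 0.5) / len(y)
    return float(np.trapezoid(y, bin_midpoints))


def sholl_auc_compare(group_a: list[np.ndarray],
                      group_b: list[np.ndarray]) -> dict:
    """Per-cell Sholl AUCs compared across two groups by Student's t-test."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("each group needs >= 2 cells for a t-test")
    auc_a = np.array([sholl_auc(p) for p in group_a])
    auc_b = np.array([sholl_auc(p) for p in group_b])
    t, p = sps.ttest_ind(auc_a, auc_b, equal_var=True)
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "mean_a": float(auc_a.mean()),
        "mean_b": float(auc_b.mean()),
        "sem_a": float(sps.sem(auc_a)),
        "sem_b": float(sps.sem(auc_b)),
        "t_statistic": float(t),
        "p": float(p),
    }


# --------------------------------------------------------------------------
# generic group comparisons
# --------------------------------------------------------------------------

def _summaries(groups: dict[str, np.ndarray]) -> dict[str, dict]:
    return {
        name: {
            "n": int(len(v)),
            "mean": float(np.mean(v)),
            "sem": float(sps.sem(v)) if len(v) > 1 else float("nan"),
        }
        for name, v in groups.items()
    }


def group_compare(groups: dict[str, "np.ndarray"], design: str,
                  equal_var: bool = True) -> dict:
    """Two-group t-test, multi-group ANOVA + Tukey HSD, or Kruskal-Wallis.

    ``design`` is one of ``two_group``, ``multi_group`` or ``distribution``
    and must match the number of groups (two-group designs take exactly two).
    Results carry per-group mean +/- SEM summaries; Welch's correction is
    available for the t-test via ``equal_var=False``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    names = list(groups)
    if len(names) < 2:
        raise ParameterError("need >= 2 groups")
    if design in ("two_group",) and len(names) != 2:
        raise ParameterError("two_group design requires exactly 2 groups")
    if design == "multi_group" and len(names) < 3:
        raise ParameterError("multi_group design requires >= 3 groups")
    if design in ("two_group", "multi_group"):
        for k, v in groups.items():
            if len(v) < 2:
                raise ParameterError(f"group {k!r} needs >= 2 samples")

    values = [groups[k] for k in names]
    report: dict = {"design": design, "groups": _summaries(groups)}

    if design == "two_group":
        t, p = sps.ttest_ind(values[0], values[1], equal_var=equal_var)
        df = (len(values[0]) + len(values[1]) - 2) if equal_var else float("nan")
        report.update({"test": "student_t" if equal_var else "welch_t",
                       "t": float(t), "df": df, "p": float(p)})
    elif design == "multi_group":
        f, p = sps.f_oneway(*values)
        tk = sps.tukey_hsd(*values)
        pairwise = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairwise[f"{names[i]} vs {names[j]}"] = float(tk.pvalue[i, j])
        report.update({"test": "anova_tukey", "F": float(f), "p": float(p),
                       "tukey_p": pairwise})
    elif design == "distribution":
        h, p = sps.kruskal(*values)
        report.update({"test": "kruskal_wallis", "H": float(h), "p": float(p)})
    else:
        raise ParameterError(f"unknown design {design!r}")

    logger.info("group_compare design=%s groups=%s p=%.4g",
                design, names, report["p"])
    return report
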