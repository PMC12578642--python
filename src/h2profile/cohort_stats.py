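"""Case-control comparison of per-sample copies-per-genome values.

The two-sided Wilcoxon rank-sum test is implemented from first principles:
an exact test by full enumeration of rank assignments (used when the combined
sample size is at most 12 and there are no ties) and a tie-corrected normal
approximation with 0.5 continuity correction otherwise.  Multiple-testing
adjustment is step-down Holm-Bonferroni.  Family-level fold changes and the
group-B : group-A1 style per-sample family ratios complete the comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CohortTable",
    "TestResult",
    "wilcoxon_rank_sum",
    "holm_adjust",
    "compare_cohorts",
    "family_ratio",
    "load_cohort_table",
    "write_results_tsv",
]

EXACT_MAX_N = 12  # combined size above which enumeration is not attempted


@dataclass
class CohortTable:
    """cpg matrix (rows = families, columns = samples) with cohort labels."""

    values: pd.DataFrame
    labels: dict[str, str]  # sample_id -> "case" | "control"

    def __post_init__(self) -> None:
        unlabeled = set(self.values.columns) - set(self.labels)
        if unlabeled:
            raise ValueError(f"samples without cohort labels: {sorted(unlabeled)}")
        bad = {v for v in self.labels.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        if (self.values.values < 0).any():
            raise ValueError("cpg values must be non-negative")

    def cohort_columns(self, cohort: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == cohort]


@dataclass
class TestResult:
    family_id: str
    n_case: int
    n_control: int
    W: float
    p_raw: float
    p_adjusted: float
    fold_change: float
    direction: str  # up_in_case | down_in_case | none


def _rank_sum_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    return float(ranks[: len(x)].sum()), ranks


def _exact_p(w_obs: float, ranks: np.ndarray, m: int) -> float:
    """Two-sided exact p by enumerating all C(n, m) rank splits."""
    sums = np.fromiter(
        (sum(c) for c in itertools.combinations(ranks, m)),
        dtype=float,
    )
    total = len(sums)
    p_le = np.count_nonzero(sums <= w_obs + 1e-9) / total
    p_ge = np.count_nonzero(sums >= w_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_p(w_obs: float, ranks: np.ndarray, m: int) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n_total = len(ranks)
    n = n_total - m
    mean = m * (n_total + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = m * n / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    if var <= 0:
        return 1.0  # all observations tied
    dev = w_obs - mean
    # continuity correction shrinks the deviation by 0.5 toward the mean
    z = (dev - math.copysign(0.5, dev)) / math.sqrt(var) if dev != 0 else 0.0
    p = 2.0 * (1.0 - _phi(abs(z)))
    return min(1.0, p)


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the sum of (mid)ranks of ``x`` in the pooled sample.  ``exact``
    enumerates every rank assignment (legal only without ties); ``normal``
    uses the tie-corrected large-sample approximation with continuity
    correction; ``auto`` picks exact when combined n <= 12 and tie-free.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    w_obs, ranks = _rank_sum_stat(x, y)
    has_ties = len(np.unique(ranks)) < len(ranks)
    if mode == "auto":
        mode = "exact" if (len(ranks) <= EXACT_MAX_N and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode is defined for tie-free data only")
        if len(ranks) > 2 * EXACT_MAX_N:
            raise ValueError("exact enumeration refused for large samples")
        return w_obs, _exact_p(w_obs, ranks, len(x))
    if mode == "normal":
        return w_obs, _normal_p(w_obs, ranks, len(x))
    raise ValueError(f"unknown mode {mode!r}")


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, returned in input order.

    Sorted ascending, p_(i) is scaled by (m - i), a running maximum enforces
    monotonicity, and values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, p[idx] * (m - i))
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def compare_cohorts(
    table: CohortTable, alpha: float = 0.05, eps: float = 1e-6, mode: str = "auto"
) -> list[TestResult]:
    """One Wilcoxon test per family, Holm-adjusted across the family set.

    Fold change is case mean over control mean with pseudocount ``eps`` when
    a mean is zero.  Direction is called only for Holm-significant families.
    """
    case_cols = table.cohort_columns("case")
    control_cols = table.cohort_columns("control")
    if len(case_cols) < 2 or len(control_cols) < 2:
        raise ValueError("need at least 2 samples per cohort")
    families = list(table.values.index)
    raw: list[tuple[str, float, float, float]] = []
    for fam in families:
        x = table.values.loc[fam, case_cols].to_numpy(dtype=float)
        y = table.values.loc[fam, control_cols].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            w, p = float(rankdata(np.concatenate([x, y]))[: len(x)].sum()), 1.0
        else:
            w, p = wilcoxon_rank_sum(x, y, mode=mode)
        case_mean, control_mean = float(x.mean()), float(y.mean())
        fold = (case_mean + (eps if control_mean == 0 else 0)) / (
            control_mean if control_mean > 0 else eps
        )
        raw.append((fam, w, p, fold))
    adjusted = holm_adjust([r[2] for r in raw])
    results = []
    for (fam, w, p, fold), p_adj in zip(raw, adjusted):
        if p_adj < alpha and fold != 1.0:
            direction = "up_in_case" if fold > 1.0 else "down_in_case"
        else:
            direction = "none"
        results.append(
            TestResult(
                family_id=fam,
                n_case=len(case_cols),
                n_control=len(control_cols),
                W=w,
                p_raw=p,
                p_adjusted=p_adj,
                fold_change=fold,
                direction=direction,
            )
        )
    return results


def family_ratio(
    profile_cpg: Mapping[str, float],
    numerator: str,
    denominator: str,
    eps: float = 1e-6,
) -> float:
    """Per-sample ratio of two family cpg values with pseudocount ``eps``.

    Used for the group B : group A1 [FeFe]-hydrogenase ratio; per-sample
    ratios feed wilcoxon_rank_sum across cohorts.
    """
    num = profile_cpg[numerator]
    den = profile_cpg[denominator]
    if num < 0 or den < 0:
        raise ValueError("cpg values must be non-negative")
    return (num + eps) / (den + eps)


def load_cohort_table(cpg_tsv: str | Path, labels_tsv: str | Path) -> CohortTable:
    """Read a cpg matrix TSV (index family_id) and a labels TSV
    (columns sample_id, cohort)."""
    values = pd.read_csv(cpg_tsv, sep="\t", index_col="family_id")
    labels_df = pd.read_csv(labels_tsv, sep="\t", dtype=str)
    labels = dict(zip(labels_df["sample_id"], labels_df["cohort"]))
    return CohortTable(values=values, labels=labels)


def write_results_tsv(results: Sequence[TestResult], path: str | Path) -> None:
    rows = [
        {
            "family_id": r.family_id,
            "n_case": r.n_case,
            "n_control": r.n_control,
            "W": r.W,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "fold_change": r.fold_change,
            "direction": r.direction,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
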