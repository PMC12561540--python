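"""Rank-based comparison of methods across datasets.

Implements the Demšar-style pipeline: a Friedman test on the datasets x
methods score matrix (rows ranked, ties averaged), the Nemenyi critical
difference for the rank diagram, and — only when the Friedman null is
rejected — Wilcoxon signed-rank tests of every method against the control
(the method with the lowest average rank). Paired observations follow the
"two summary statistics per dataset" construction: each dataset contributes
one mean row and one median row, so 15 datasets yield a 30-row matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ScoreMatrix",
    "ComparisonReport",
    "DegenerateDataError",
    "build_score_matrix",
    "friedman_test",
    "nemenyi_cd",
    "wilcoxon_signed_rank",
    "compare_all",
]


class DegenerateDataError(ValueError):
    """Raised when paired data carries no information (all differences zero)."""


@dataclass
class ScoreMatrix:
    """Rows = measurement units (dataset x statistic), columns = methods."""

    values: np.ndarray
    methods: list[str]
    row_labels: list[str]
    higher_is_better: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2-D")
        n, k = self.values.shape
        if k < 2 or n < 2:
            raise ValueError("need at least 2 methods and 2 rows")
        if k != len(self.methods) or n != len(self.row_labels):
            raise ValueError("labels do not match matrix shape")
        if np.isnan(self.values).any():
            raise ValueError("score matrix contains missing entries")


@dataclass
class ComparisonReport:
    average_ranks: dict[str, float]
    friedman_statistic: float
    friedman_p: float
    alpha: float
    nemenyi_cd: float | None = None
    control: str | None = None
    wilcoxon_p: dict[str, float] = field(default_factory=dict)
    significant_vs_control: dict[str, bool] = field(default_factory=dict)
    nemenyi_significant: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "average_ranks": self.average_ranks,
            "friedman_statistic": self.friedman_statistic,
            "friedman_p": self.friedman_p,
            "alpha": self.alpha,
            "nemenyi_cd": self.nemenyi_cd,
            "control": self.control,
            "wilcoxon_p": self.wilcoxon_p,
            "significant_vs_control": self.significant_vs_control,
            "nemenyi_significant": self.nemenyi_significant,
        }


def build_score_matrix(
    summaries: dict[str, dict[str, list[float]]],
    statistics: tuple[str, ...] = ("mean", "median"),
    higher_is_better: bool = False,
) -> ScoreMatrix:
    """Assemble the paired-observation matrix from per-dataset run scores.

    ``summaries`` maps dataset id -> method -> per-run score list.  Each
    dataset contributes one row per summary statistic, so row count =
    |datasets| x |statistics|.
    """
    reducers = {"mean": np.mean, "median": np.median}
    datasets = list(summaries)
    if len(set(datasets)) != len(datasets):
        raise ValueError("duplicate dataset ids")
    methods = list(next(iter(summaries.values())))
    rows, labels = [], []
    for ds_id in datasets:
        per_method = summaries[ds_id]
        if list(per_method) != methods:
            raise ValueError(f"dataset {ds_id!r} does not cover the same methods")
        for stat in statistics:
            rows.append([float(reducers[stat](per_method[m])) for m in methods])
            labels.append(f"{ds_id}:{stat}")
    return ScoreMatrix(
        values=np.array(rows),
        methods=methods,
        row_labels=labels,
        higher_is_better=higher_is_better,
    )


def _row_ranks(m: ScoreMatrix) -> np.ndarray:
    """Within-row ranks, best = 1, ties averaged."""
    vals = -m.values if m.higher_is_better else m.values
    return np.apply_along_axis(sps.rankdata, 1, vals)


def friedman_test(m: ScoreMatrix) -> tuple[float, float, dict[str, float]]:
    """Classic Friedman chi-square over within-row ranks.

    chi2_F = 12N/(k(k+1)) [ sum_j Rbar_j^2 - k(k+1)^2/4 ], df = k-1.
    """
    ranks = _row_ranks(m)
    n, k = ranks.shape
    avg = ranks.mean(axis=0)
    statistic = 12.0 * n / (k * (k + 1)) * (np.sum(avg**2) - k * (k + 1) ** 2 / 4.0)
    p = float(sps.chi2.sf(statistic, k - 1))
    return float(statistic), p, dict(zip(m.methods, avg.tolist()))


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference CD = q_alpha(k) sqrt(k(k+1)/(6N)).

    q_alpha is the studentized-range quantile at infinite degrees of
    freedom divided by sqrt(2), evaluated from scipy's distribution rather
    than a transcribed table.
    """
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 methods and N >= 1 rows")
    q = sps.studentized_range.ppf(1.0 - alpha, k, 1e7) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


def _exact_wilcoxon_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by dynamic programming over all sign assignments."""
    # ranks are untied integers 1..n here; counts[s] = #assignments with sum s
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        counts[r:] += counts[:-r].copy()
    n_assign = counts.sum()
    w = int(round(w_plus))
    p_le = counts[: w + 1].sum() / n_assign
    p_ge = counts[w:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped (Wilcoxon's treatment). The null
    distribution is exact (full enumeration via DP) for n <= 25 untied
    pairs, otherwise a tie-corrected normal approximation. Returns
    (W+ statistic, p).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors must be 1-D of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero: no difference")
    if n < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        p = _exact_wilcoxon_p(w_plus, ranks)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 from the null variance
        _, t = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(t**3 - t) / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return w_plus, min(p, 1.0)


def compare_all(m: ScoreMatrix, alpha: float = 0.05, holm: bool = False) -> ComparisonReport:
    """Full comparison: Friedman gate, then Nemenyi CD and Wilcoxon vs control.

    Post hoc results are populated only when the Friedman null is rejected
    at ``alpha``. The control is the method with the lowest average rank
    and is excluded from its own Wilcoxon comparison. ``holm`` applies a
    Holm step-down correction across the Wilcoxon family (off by default).
    """
    statistic, p, avg_ranks = friedman_test(m)
    report = ComparisonReport(
        average_ranks=avg_ranks,
        friedman_statistic=statistic,
        friedman_p=p,
        alpha=alpha,
    )
    if p >= alpha:
        return report

    n, k = m.values.shape
    cd = nemenyi_cd(k, n, alpha)
    control = min(avg_ranks, key=avg_ranks.get)
    report.nemenyi_cd = cd
    report.control = control
    report.nemenyi_significant = {
        meth: bool(abs(avg_ranks[meth] - avg_ranks[control]) > cd)
        for meth in m.methods
        if meth != control
    }
    ctrl_col = m.methods.index(control)
    pvals = {}
    for j, meth in enumerate(m.methods):
        if meth == control:
            continue
        try:
            _, wp = wilcoxon_signed_rank(m.values[:, j], m.values[:, ctrl_col], alpha)
        except DegenerateDataError:
            wp = 1.0
        pvals[meth] = wp
    if holm:
        order = sorted(pvals, key=pvals.get)
        adjusted, running = {}, 0.0
        for i, meth in enumerate(order):
            running = max(running, (len(order) - i) * pvals[meth])
            adjusted[meth] = min(1.0, running)
        pvals = adjusted
    report.wilcoxon_p = pvals
    report.significant_vs_control = {meth: bool(pv < alpha) for meth, pv in pvals.items()}
    return report
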