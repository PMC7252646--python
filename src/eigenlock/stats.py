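"""Condition-level paired comparisons of connectivity summaries.

Subjects contribute one value per (condition, band, metric) cell — a
time-averaged topology metric or an event frequency — and conditions are
compared pairwise across subjects with the two-sided Wilcoxon signed-rank
test at alpha = 0.05 (exact null distribution for small samples,
zero differences dropped).  No multiple-testing correction is applied by
default; Holm adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "WilcoxonResult",
    "paired_wilcoxon",
    "compare_conditions",
]

CONDITION_COLUMNS = ["subject", "condition", "band", "metric", "value"]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool  # all paired differences were zero
    n: int


def paired_wilcoxon(values_a, values_b, alpha: float = 0.05) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; with n <= 25 nonzero differences the
    exact signed-rank null distribution is used.  A pair set whose
    differences are all zero carries no ordering information and is
    flagged degenerate instead of tested.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for a meaningful test")
    diffs = a - b
    n_nonzero = int((diffs != 0).sum())
    if n_nonzero == 0:
        return WilcoxonResult(np.nan, np.nan, False, True, a.size)
    method = "exact" if n_nonzero <= 25 else "approx"
    res = sstats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                          method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue),
                          bool(res.pvalue < alpha), False, n_nonzero)


def _holm(pvals: np.ndarray, alpha: float) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    significant = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if np.isnan(pvals[idx]) or pvals[idx] > alpha / (m - rank):
            break
        significant[idx] = True
    return significant


def compare_conditions(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise condition comparisons per (band, metric) cell.

    ``table`` is long-form with columns subject, condition, band, metric,
    value, one value per (subject, condition, band, metric).  Each
    requested condition pair is tested per (band, metric) over the shared
    subjects; subjects missing from either condition raise an error naming
    them.  With ``holm=True`` the significance flags are Holm-adjusted
    within the result table.
    """
    missing_cols = [c for c in CONDITION_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"condition table lacks columns {missing_cols}")
    dup = table.duplicated(subset=["subject", "condition", "band", "metric"])
    if dup.any():
        raise ValueError("condition table has duplicate (subject, condition, band, metric) rows")

    rows = []
    for (band, metric), cell in table.groupby(["band", "metric"], sort=False):
        wide = cell.pivot(index="subject", columns="condition", values="value")
        for cond_a, cond_b in pairs:
            for cond in (cond_a, cond_b):
                if cond not in wide.columns:
                    raise ValueError(f"condition {cond!r} absent for band={band!r}, metric={metric!r}")
            sub = wide[[cond_a, cond_b]]
            incomplete = sub.index[sub.isna().any(axis=1)].tolist()
            if incomplete:
                raise ValueError(
                    f"subjects {incomplete} lack values for pair "
                    f"({cond_a}, {cond_b}) in band={band!r}, metric={metric!r}"
                )
            res = paired_wilcoxon(sub[cond_a].to_numpy(), sub[cond_b].to_numpy(),
                                  alpha=alpha)
            rows.append((band, metric, cond_a, cond_b, res.statistic,
                         res.p_value, res.significant, res.degenerate, res.n))
    out = pd.DataFrame(rows, columns=[
        "band", "metric", "condition_a", "condition_b", "statistic",
        "p_value", "significant", "degenerate", "n",
    ])
    if holm and len(out):
        out["significant"] = _holm(out["p_value"].to_numpy(), alpha)
    return out
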