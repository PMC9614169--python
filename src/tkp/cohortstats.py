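"""Contingency-table association analysis for feeding-artery counts.

For categorical tumor characteristics tabulated against a binary artery-count
outcome (e.g. 1-2 vs 3-5 feeding lobar arteries), the univariate logistic
regression of a k-level factor reduces to per-level 2x2 odds ratios against
the reference level.  This module computes those odds ratios with Wald 95%
confidence intervals, plus Pearson chi-square tests of the full table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "odds_ratio_vs_reference",
    "pearson_chi2",
    "or_inverse_check",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """k x 2 integer counts; first row is the reference predictor level.

    Columns are the two outcome levels (reference outcome first, event
    second).
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 2:
            raise ValueError("outcome must be binary: counts must be k x 2")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 predictor levels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != 2:
            raise ValueError("label/shape mismatch")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def swap_outcome(self) -> "ContingencyTable":
        return ContingencyTable(
            self.row_labels, (self.col_labels[1], self.col_labels[0]),
            self.counts[:, ::-1].copy(),
        )


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio of one predictor level against the reference level."""

    level: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or_se: float
    continuity_corrected: bool = False

    def round2(self) -> tuple[float, float, float]:
        """(OR, lo, hi) at report precision: 2 decimals, round-half-even."""
        r = lambda x: float(np.round(x, 2))
        return r(self.odds_ratio), r(self.ci_low), r(self.ci_high)


def _or_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float, float, float]:
    """OR and Wald CI for level cells (non-event a, event b) vs reference (c, d)."""
    or_ = (b * c) / (a * d)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    lo = float(np.exp(np.log(or_) - _Z95 * se))
    hi = float(np.exp(np.log(or_) + _Z95 * se))
    return float(or_), lo, hi, se


def odds_ratio_vs_reference(table: ContingencyTable) -> list[OddsRatioResult]:
    """Per-level odds ratios against the first (reference) row.

    For level cells ``(non-event a, event b)`` and reference cells
    ``(non-event c, event d)``: ``OR = (b*c)/(a*d)`` with Wald 95% CI
    ``exp(ln OR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.  Any zero cell in a
    comparison triggers the Haldane–Anscombe 0.5 continuity correction,
    flagged in the result.
    """
    counts = table.counts
    c, d = float(counts[0, 0]), float(counts[0, 1])
    if c == 0 and d == 0:
        raise ValueError("reference row is all zeros")
    out = []
    for i in range(1, counts.shape[0]):
        a, b = float(counts[i, 0]), float(counts[i, 1])
        cells = (a, b, c, d)
        corrected = any(x == 0 for x in cells)
        if corrected:
            cells = tuple(x + 0.5 for x in cells)
        or_, lo, hi, se = _or_2x2(*cells)
        out.append(
            OddsRatioResult(
                level=table.row_labels[i],
                odds_ratio=or_, ci_low=lo, ci_high=hi, log_or_se=se,
                continuity_corrected=corrected,
            )
        )
    return out


def pearson_chi2(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence: (statistic, df, p)."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def or_inverse_check(result: OddsRatioResult) -> OddsRatioResult:
    """Result under the swapped outcome: OR -> 1/OR, CI bounds reciprocated."""
    return OddsRatioResult(
        level=result.level,
        odds_ratio=1.0 / result.odds_ratio,
        ci_low=1.0 / result.ci_high,
        ci_high=1.0 / result.ci_low,
        log_or_se=result.log_or_se,
        continuity_corrected=result.continuity_corrected,
    )
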