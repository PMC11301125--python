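"""Criteria counts, DSM-5 severity categories and unadjusted group tabulations.

A respondent's criteria count is the plain sum of the eleven yes/no
responses.  DSM-5 grades alcohol use disorder from that count: 0-1 criteria
means no AUD, 2-3 mild, 4-5 moderate and 6-11 severe (the diagnostic
threshold is >= 2 criteria).  ``tabulate`` produces the descriptive layer of
the analysis: per-group item endorsement and severity-category tables with
Wilson confidence intervals, flagged as unadjusted (no covariate
adjustment), plus a chi-square comparison of the severity distributions when
two groups are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError
from .io import ResponseMatrix


@dataclass(frozen=True)
class SeverityRule:
    """Mapping from criteria count ranges to named severity categories.

    The ranges must partition 0..n_items exactly.
    """

    n_items: int = 11
    cuts: tuple[tuple[int, int, str], ...] = (
        (0, 1, "no AUD"),
        (2, 3, "mild"),
        (4, 5, "moderate"),
        (6, 11, "severe"),
    )

    def __post_init__(self) -> None:
        covered = []
        for lo, hi, _ in self.cuts:
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(self.n_items + 1)):
            raise ValidationError(
                f"severity categories must partition 0..{self.n_items} exactly"
            )

    @property
    def categories(self) -> list[str]:
        return [name for _, _, name in self.cuts]

    def category(self, count: int) -> str:
        if not 0 <= count <= self.n_items:
            raise ValidationError(f"criteria count {count} outside 0..{self.n_items}")
        for lo, hi, name in self.cuts:
            if lo <= count <= hi:
                return name
        raise AssertionError("unreachable: cuts partition the range")


DSM5_RULE = SeverityRule()


def criteria_count(responses) -> np.ndarray | int:
    """Number of criteria endorsed: the sum of complete binary responses.

    Accepts a single row (1-D) or a matrix/:class:`ResponseMatrix`; missing
    responses raise (filter first).
    """
    if isinstance(responses, ResponseMatrix):
        return responses.complete_values().sum(axis=1)
    arr = np.asarray(responses, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("responses contain missing items; run filter_complete first")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("responses must be binary")
    total = arr.sum(axis=-1).astype(int)
    return int(total) if arr.ndim == 1 else total


def severity_category(count: int, rule: SeverityRule = DSM5_RULE) -> str:
    """DSM-5 severity label for a criteria count."""
    return rule.category(int(count))


@dataclass
class SeveritySummary:
    """Unadjusted per-group descriptives of a complete response matrix."""

    n_per_group: dict[str, int]
    severity_table: pd.DataFrame      # group x category counts, proportions, Wilson CIs
    item_table: pd.DataFrame          # group x item endorsement with Wilson CIs
    mean_criteria: dict[str, float]
    chi2_severity: tuple[float, float, float] | None = None  # (stat, df, p); None if 1 group
    adjusted: bool = field(default=False, init=False)  # always unadjusted here

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# unadjusted tabulation (no covariate adjustment)\n")
            fh.write("## severity\n")
            self.severity_table.to_csv(fh)
            fh.write("## items\n")
            self.item_table.to_csv(fh)
            fh.write("## mean criteria count\n")
            for g, m in self.mean_criteria.items():
                fh.write(f"{g},{m:.4f}\n")
            if self.chi2_severity is not None:
                stat, df, p = self.chi2_severity
                fh.write(f"## severity chi-square,{stat:.4f},df,{df:g},p,{p:.4g}\n")


def _wilson(count: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def tabulate(data: ResponseMatrix, rule: SeverityRule = DSM5_RULE) -> SeveritySummary:
    """Per-group severity and item-endorsement tables (unadjusted).

    Proportions carry Wilson 95% intervals; with two groups the severity
    distributions are compared by a chi-square test of independence.
    """
    Y = data.complete_values()
    if data.n_items != rule.n_items:
        raise ValidationError(
            f"rule covers 0..{rule.n_items} but the matrix has {data.n_items} items"
        )
    groups = data.groups
    sizes = data.group_sizes()
    for g, n in sizes.items():
        if n == 0:
            raise ValidationError(f"group {g!r} is empty")

    counts = Y.sum(axis=1)
    cats = np.array([rule.category(c) for c in counts], dtype=object)

    sev_rows, item_rows, means = [], [], {}
    for g in groups:
        mask = data.group == g
        n = int(mask.sum())
        means[g] = float(counts[mask].mean())
        for cat in rule.categories:
            k = int((cats[mask] == cat).sum())
            lo, hi = _wilson(k, n)
            sev_rows.append(
                {"group": g, "category": cat, "n": n, "count": k,
                 "proportion": k / n, "ci_low": lo, "ci_high": hi}
            )
        for j, item in enumerate(data.item_ids):
            k = int(Y[mask, j].sum())
            lo, hi = _wilson(k, n)
            item_rows.append(
                {"group": g, "item": item, "n": n, "count": k,
                 "proportion": k / n, "ci_low": lo, "ci_high": hi}
            )

    chi2 = None
    if len(groups) == 2:
        table = np.array(
            [[int(((cats == cat) & (data.group == g)).sum()) for cat in rule.categories]
             for g in groups]
        )
        keep = table.sum(axis=0) > 0
        res = stats.chi2_contingency(table[:, keep])
        chi2 = (float(res.statistic), float(res.dof), float(res.pvalue))

    return SeveritySummary(
        n_per_group=sizes,
        severity_table=pd.DataFrame(sev_rows).set_index(["group", "category"]),
        item_table=pd.DataFrame(item_rows).set_index(["group", "item"]),
        mean_criteria=means,
        chi2_severity=chi2,
    )
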