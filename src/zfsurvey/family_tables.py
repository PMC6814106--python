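"""Cross-tabulations and rounded row/column percentages for family surveys.

Percentages are rounded half-up (not banker's rounding) so that recomputed
cells can be compared digit-for-digit against values printed in survey
tables; ``discrepancy_report`` surfaces any printed cell that does not
match its recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ContingencyTable", "crosstab", "percent", "discrepancy_report"]


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * n/d rounded half-up to ``decimals`` places.

    A zero denominator is undefined and raised; callers render such cells
    blank.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Counts cross-tabulation with a declared percentage denominator."""

    counts: pd.DataFrame            # rows x cols, non-negative ints
    denominator: str                # 'row' | 'col' | 'grand'

    def __post_init__(self):
        if self.denominator not in ("row", "col", "grand"):
            raise ValueError("denominator must be 'row', 'col' or 'grand'")
        if (self.counts.values < 0).any():
            raise ValueError("negative cell count")

    @property
    def row_labels(self) -> list:
        return list(self.counts.index)

    @property
    def col_labels(self) -> list:
        return list(self.counts.columns)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def percents(self, decimals: int = 1) -> pd.DataFrame:
        """Per-cell percentages under the declared denominator; cells whose
        denominator is zero come back as NaN (blank)."""
        out = self.counts.astype(float).copy()
        for r in self.counts.index:
            for c in self.counts.columns:
                if self.denominator == "row":
                    den = self.row_totals[r]
                elif self.denominator == "col":
                    den = self.col_totals[c]
                else:
                    den = self.grand_total
                out.loc[r, c] = (percent(self.counts.loc[r, c], den, decimals)
                                 if den else np.nan)
        return out

    def transpose(self) -> "ContingencyTable":
        flipped = {"row": "col", "col": "row", "grand": "grand"}
        return ContingencyTable(self.counts.T.copy(),
                                flipped[self.denominator])

    def formatted(self, decimals: int = 1) -> pd.DataFrame:
        """"count (percent)" cells, as printed in survey tables."""
        pct = self.percents(decimals)
        out = self.counts.astype(str).copy()
        for r in self.counts.index:
            for c in self.counts.columns:
                p = pct.loc[r, c]
                cell = "" if np.isnan(p) else f" ({p:.{decimals}f})"
                out.loc[r, c] = f"{self.counts.loc[r, c]}{cell}"
        return out

    def to_long(self, decimals: int = 1) -> pd.DataFrame:
        """Machine-readable long format: row, col, count, percent."""
        pct = self.percents(decimals)
        rows = [
            {"row": r, "col": c, "count": int(self.counts.loc[r, c]),
             "percent": pct.loc[r, c]}
            for r in self.counts.index for c in self.counts.columns
        ]
        return pd.DataFrame(rows)


def crosstab(items: Iterable[tuple], denominator: str = "row",
             row_labels: Sequence | None = None,
             col_labels: Sequence | None = None,
             allow_other: bool = False) -> ContingencyTable:
    """Cross-tabulate (row_category, col_category) pairs.

    With declared label sets, unknown labels either raise or (with
    ``allow_other``) collect into an ``other`` row/column.  Empty input
    yields an empty table.
    """
    items = list(items)
    rows, cols = [], []
    for r, c in items:
        if row_labels is not None and r not in row_labels:
            if not allow_other:
                raise ValueError(f"undeclared row label {r!r}")
            r = "other"
        if col_labels is not None and c not in col_labels:
            if not allow_other:
                raise ValueError(f"undeclared column label {c!r}")
            c = "other"
        rows.append(r)
        cols.append(c)
    counts = pd.crosstab(pd.Series(rows, dtype=object),
                         pd.Series(cols, dtype=object))
    counts.index.name = None
    counts.columns.name = None
    if row_labels is not None:
        order = list(row_labels) + (["other"] if "other" in counts.index else [])
        counts = counts.reindex(index=order, fill_value=0)
    if col_labels is not None:
        order = list(col_labels) + (["other"] if "other" in counts.columns else [])
        counts = counts.reindex(columns=order, fill_value=0)
    return ContingencyTable(counts.astype(int), denominator)


def discrepancy_report(table: ContingencyTable, printed: pd.DataFrame,
                       decimals: int = 1) -> pd.DataFrame:
    """Cells where the recomputed percentage differs from the printed one.

    ``printed`` must share the table's shape and labels; NaN printed cells
    are skipped.  Returns columns row, col, recomputed, printed, abs_diff.
    """
    recomputed = table.percents(decimals)
    if (list(printed.index) != list(recomputed.index)
            or list(printed.columns) != list(recomputed.columns)):
        raise ValueError("printed table shape/labels do not match")
    out = []
    for r in recomputed.index:
        for c in recomputed.columns:
            p = printed.loc[r, c]
            q = recomputed.loc[r, c]
            if np.isnan(p) or np.isnan(q):
                continue
            if abs(p - q) > 1e-9:
                out.append({"row": r, "col": c, "recomputed": q,
                            "printed": p, "abs_diff": round(abs(p - q), decimals + 1)})
    return pd.DataFrame(out, columns=["row", "col", "recomputed", "printed",
                                      "abs_diff"])
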