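"""Relative expression from qPCR cycle thresholds (2^-ddCt) and t-tests.

The Livak convention is followed: per replicate, dCt = Ct_target -
Ct_reference; ddCt is the difference of stratum mean dCt values between a
sample and its calibrator (the control condition at the same time point by
default); the reported fold change is 2^-ddCt.  Amplification efficiency
is fixed at 2 (no efficiency correction).  Significance uses the classical
pooled-variance Student t-test on per-replicate fold values (Welch behind
a flag), with the usual one/two-star convention at P < 0.05 / P < 0.01.
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "RelativeExpression",
    "validate_ct_table",
    "relative_expression",
    "t_test",
    "timecourse_summary",
    "direction_counts",
]

CT_COLUMNS = ["gene", "condition", "time_h", "replicate",
              "ct_target", "ct_reference"]


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = ct[col].astype(float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError(f"{col} values must be finite and positive")
    return ct


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    condition: str
    time_h: float
    fold: float
    ddct: float
    sample_folds: tuple[float, ...]      # per-replicate, for the t-test
    calibrator_folds: tuple[float, ...]


def _dct(rows: pd.DataFrame) -> np.ndarray:
    return (rows["ct_target"].astype(float)
            - rows["ct_reference"].astype(float)).to_numpy()


def relative_expression(ct: pd.DataFrame, gene: str, condition: str,
                        time_h: float, calibrator_condition: str = "control",
                        calibrator_time: float | None = None,
                        ) -> RelativeExpression:
    """Fold change of one stratum against its calibrator.

    The calibrator defaults to the control condition at the same time
    point.  Per-replicate folds (2^-(dCt_i - mean dCt_calibrator)) are
    returned for both sides to feed the t-test.
    """
    validate_ct_table(ct)
    cal_time = time_h if calibrator_time is None else calibrator_time
    sample = ct[(ct["gene"] == gene) & (ct["condition"] == condition)
                & (ct["time_h"] == time_h)]
    cal = ct[(ct["gene"] == gene) & (ct["condition"] == calibrator_condition)
             & (ct["time_h"] == cal_time)]
    if sample.empty:
        raise ValueError(f"no rows for ({gene}, {condition}, {time_h} h)")
    if cal.empty:
        raise ValueError(
            f"missing calibrator ({gene}, {calibrator_condition}, {cal_time} h)")
    dct_s = _dct(sample)
    dct_c = _dct(cal)
    ddct = float(dct_s.mean() - dct_c.mean())
    return RelativeExpression(
        gene=gene, condition=condition, time_h=time_h,
        fold=float(2.0 ** -ddct), ddct=ddct,
        sample_folds=tuple(2.0 ** -(dct_s - dct_c.mean())),
        calibrator_folds=tuple(2.0 ** -(dct_c - dct_c.mean())),
    )


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def t_test(sample: np.ndarray | list, control: np.ndarray | list,
           equal_variance: bool = True) -> tuple[float, float, float, str]:
    """Two-sided Student t-test; returns (t, df, p, stars).

    Degenerate zero-variance inputs with equal means give t = 0, p = 1.
    """
    a = np.asarray(sample, dtype=float)
    b = np.asarray(control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per side")
    if np.var(a) == 0 and np.var(b) == 0 and np.isclose(a.mean(), b.mean()):
        df = len(a) + len(b) - 2 if equal_variance else float(len(a) - 1)
        return 0.0, float(df), 1.0, ""
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    df = len(a) + len(b) - 2 if equal_variance else float(res.df)
    p = float(res.pvalue)
    return float(res.statistic), float(df), p, stars(p)


def timecourse_summary(ct: pd.DataFrame, calibrator_condition: str = "control",
                       equal_variance: bool = True,
                       test_on: str = "fold") -> pd.DataFrame:
    """Fold, P and direction per gene x non-control condition x time.

    ``test_on`` selects the quantity tested: per-replicate fold values
    (default) or dCt values.  Direction is 'up' for a starred fold > 1,
    'down' for a starred fold < 1, else 'n.s.'.  Strata lacking a
    calibrator are reported with NaN fold rather than aborting.
    """
    validate_ct_table(ct)
    rows = []
    conditions = [c for c in ct["condition"].unique()
                  if c != calibrator_condition]
    for gene in sorted(ct["gene"].unique()):
        for cond in conditions:
            times = sorted(ct[(ct["gene"] == gene)
                              & (ct["condition"] == cond)]["time_h"].unique())
            for t in times:
                try:
                    rel = relative_expression(ct, gene, cond, t,
                                              calibrator_condition)
                except ValueError:
                    rows.append({"gene": gene, "condition": cond, "time_h": t,
                                 "fold": np.nan, "p": np.nan, "stars": "",
                                 "direction": "incomplete"})
                    continue
                if test_on == "fold":
                    a, b = rel.sample_folds, rel.calibrator_folds
                else:
                    sample = ct[(ct["gene"] == gene) & (ct["condition"] == cond)
                                & (ct["time_h"] == t)]
                    cal = ct[(ct["gene"] == gene)
                             & (ct["condition"] == calibrator_condition)
                             & (ct["time_h"] == t)]
                    a, b = _dct(sample), _dct(cal)
                _, _, p, star = t_test(a, b, equal_variance)
                if star and rel.fold > 1:
                    direction = "up"
                elif star and rel.fold < 1:
                    direction = "down"
                else:
                    direction = "n.s."
                rows.append({"gene": gene, "condition": cond, "time_h": t,
                             "fold": rel.fold, "p": p, "stars": star,
                             "direction": direction})
    return pd.DataFrame(rows, columns=["gene", "condition", "time_h",
                                       "fold", "p", "stars", "direction"])


def direction_counts(summary: pd.DataFrame, condition: str,
                     times: tuple[float, ...] = (1.0, 3.0, 24.0),
                     ) -> tuple[int, int]:
    """Gene-level (n_up, n_down) for one condition over the given times.

    A gene counts as up (down) when its starred calls at those time points
    are mostly up (down); genes with no starred call, or a tie, count in
    neither bucket.
    """
    sub = summary[(summary["condition"] == condition)
                  & (summary["time_h"].isin(times))]
    n_up = n_down = 0
    for _, g in sub.groupby("gene"):
        ups = int((g["direction"] == "up").sum())
        downs = int((g["direction"] == "down").sum())
        if ups > downs:
            n_up += 1
        elif downs > ups:
            n_down += 1
    return n_up, n_down
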