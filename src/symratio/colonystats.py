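"""Colony-level statistics on per-cell marker ratios.

Supports the two auxiliary analyses run alongside mixture-model selection:
a two-level nested ANOVA (cells within branches within colonies) on
arcsine-transformed ratios, and a second-order polynomial regression
relating a cell's total rDNA copy number to its C100 ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "arcsin_transform",
    "nested_anova",
    "quadratic_regression",
    "QuadraticFit",
]


def arcsin_transform(x, use_sqrt: bool = True):
    """Variance-stabilising angular transform for proportions.

    Default is ``arcsin(sqrt(x))`` (the standard transform for proportion
    data); ``use_sqrt=False`` gives plain ``arcsin(x)``.  Monotone increasing
    on [0, 1], mapping 0 to 0 and 1 to pi/2.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr)) if use_sqrt else np.arcsin(arr)
    return out if out.ndim else float(out)


def nested_anova(values, colony, branch) -> pd.DataFrame:
    """Two-level nested ANOVA: ``y ~ Colony + Branch(Colony)``.

    Sums of squares follow the standard nested decomposition about group
    means.  Branch is treated as a random factor nested in colony, so the
    colony effect is tested against the branch mean square
    (``F_colony = MS_colony / MS_branch``) and the branch effect against the
    residual (``F_branch = MS_branch / MS_error``).  P-values come from the
    F distribution with the matching degrees of freedom.

    Returns a table with rows ``Colony``, ``Branch(Colony)``, ``Error`` and
    columns ``df, SS, MS, F, P``.
    """
    y = np.asarray(values, dtype=float)
    colony = np.asarray(colony)
    branch = np.asarray(branch)
    if not (y.size == colony.size == branch.size):
        raise ValueError("values, colony and branch must have equal length")
    df = pd.DataFrame({"y": y, "colony": colony, "branch": branch})
    # a branch label is only meaningful inside its colony
    df["cb"] = df["colony"].astype(str) + "||" + df["branch"].astype(str)
    for cb, sub in df.groupby("cb"):
        if sub["colony"].nunique() != 1:  # pragma: no cover - defensive
            raise ValueError(f"branch {cb} spans multiple colonies")
        if len(sub) < 2:
            raise ValueError("every branch needs >= 2 cells")
    n_colonies = df["colony"].nunique()
    n_branches = df["cb"].nunique()
    if n_colonies < 2 or n_branches <= n_colonies:
        raise ValueError("need >= 2 colonies and >= 2 branches per colony")

    grand = df["y"].mean()
    colony_mean = df.groupby("colony")["y"].transform("mean")
    branch_mean = df.groupby("cb")["y"].transform("mean")
    ss_colony = float(((colony_mean - grand) ** 2).sum())
    ss_branch = float(((branch_mean - colony_mean) ** 2).sum())
    ss_error = float(((df["y"] - branch_mean) ** 2).sum())

    df_colony = n_colonies - 1
    df_branch = n_branches - n_colonies
    df_error = len(df) - n_branches
    if min(df_colony, df_branch, df_error) < 1:
        raise ValueError("zero degrees of freedom in at least one stratum")

    ms_colony = ss_colony / df_colony
    ms_branch = ss_branch / df_branch
    ms_error = ss_error / df_error
    # an all-constant stratum makes the corresponding F undefined (NaN)
    if ms_branch > 0:
        f_colony = ms_colony / ms_branch
        p_colony = float(stats.f.sf(f_colony, df_colony, df_branch))
    else:
        f_colony = p_colony = float("nan")
    if ms_error > 0:
        f_branch = ms_branch / ms_error
        p_branch = float(stats.f.sf(f_branch, df_branch, df_error))
    elif ms_branch > 0:
        f_branch, p_branch = float("inf"), 0.0
    else:
        f_branch = p_branch = float("nan")

    return pd.DataFrame(
        {
            "df": [df_colony, df_branch, df_error],
            "SS": [ss_colony, ss_branch, ss_error],
            "MS": [ms_colony, ms_branch, ms_error],
            "F": [f_colony, f_branch, np.nan],
            "P": [p_colony, p_branch, np.nan],
        },
        index=pd.Index(["Colony", "Branch(Colony)", "Error"], name="Source"),
    )


class QuadraticFit:
    """Least-squares fit of ``y = b0 + b1*x + b2*x**2`` with an overall F test."""

    def __init__(self, coef: np.ndarray, r2: float, f_stat: float, f_pvalue: float, n: int):
        self.coef = coef  # (b0, b1, b2)
        self.r2 = r2
        self.f_stat = f_stat
        self.f_pvalue = f_pvalue
        self.n = n

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        b0, b1, b2 = self.coef
        return b0 + b1 * x + b2 * x**2

    def __repr__(self) -> str:  # pragma: no cover
        b0, b1, b2 = self.coef
        return (
            f"QuadraticFit(y = {b0:.4g} + {b1:.4g} x + {b2:.4g} x^2, "
            f"R2={self.r2:.3f}, p={self.f_pvalue:.3g}, n={self.n})"
        )


def quadratic_regression(x, y) -> QuadraticFit:
    """Second-order polynomial regression with R2 and the model F-test p-value.

    Raises on degenerate designs (n < 4 or fewer than three distinct x
    values, which make the quadratic term unidentifiable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("quadratic regression needs n >= 4 paired observations")
    if np.unique(x).size < 3:
        raise ValueError("quadratic regression needs >= 3 distinct x values")
    X = np.column_stack([np.ones_like(x), x, x**2])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("design matrix is rank-deficient")
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n = x.size
    df_model, df_resid = 2, n - 3
    if ss_tot == 0:
        return QuadraticFit(np.array([y[0], 0.0, 0.0]), 0.0, float("nan"), float("nan"), n)
    r2 = 1.0 - ss_res / ss_tot
    if ss_res == 0:
        return QuadraticFit(coef, r2, float("inf"), 0.0, n)
    f_stat = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
    f_p = float(stats.f.sf(f_stat, df_model, df_resid))
    return QuadraticFit(coef, r2, float(f_stat), f_p, n)
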