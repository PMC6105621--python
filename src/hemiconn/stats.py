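"""Cohort-level statistics: pairwise Pearson correlations and
hierarchical (block-wise) multiple regression.

Correlations use pairwise deletion: each (marker, outcome) cell is
computed on the rows complete for that pair, so a single missing
clinical score only shrinks its own cells.  The hierarchical regression
fits OLS per cumulative block (listwise deletion across all variables
involved), reports R-squared per block, the R-squared change with its
F test,

    F_change = (dR2 / q) / ((1 - R2_2) / (n - p2 - 1)),

and variance inflation factors for the final block's predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

__all__ = [
    "pearson_pairwise",
    "correlation_report",
    "hierarchical_regression",
    "CorrelationReport",
    "HierRegressionReport",
    "read_cohort_table",
    "write_cohort_table",
]

LARGE_R = 0.6  # |r| above this is flagged "large"


def read_cohort_table(path):
    """Read a TSV cohort table; empty cells and 'md' mark missing data."""
    return pd.read_csv(path, sep="\t", na_values=["md", "NA", ""])


def write_cohort_table(table, path):
    table.to_csv(path, sep="\t", index=False, na_rep="")


def pearson_pairwise(x, y):
    """Pearson r on the complete pairs of two columns.

    Returns ``{"r", "p", "n"}``; the two-sided p comes from the t(n-2)
    transform of r.  Raises on fewer than 3 complete pairs or zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a column")
    r, p = sstats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(n)}


@dataclass
class CorrelationReport:
    cells: dict        # (marker, outcome) -> {"r","p","n","large"} or {"error"}
    markers: list
    outcomes: list

    def to_frame(self):
        recs = []
        for (m, o), cell in self.cells.items():
            recs.append({"marker": m, "outcome": o, **cell})
        return pd.DataFrame(recs)


def correlation_report(table, marker_cols, outcome_cols):
    """Full marker x outcome grid of pairwise correlations.

    Per-cell failures (too few pairs, zero variance) are recorded in the
    cell instead of aborting the grid; |r| > 0.6 is flagged large.
    """
    for col in list(marker_cols) + list(outcome_cols):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    cells = {}
    for m in marker_cols:
        for o in outcome_cols:
            try:
                cell = pearson_pairwise(table[m], table[o])
                cell["large"] = abs(cell["r"]) > LARGE_R
            except ValueError as err:
                cell = {"error": str(err)}
            cells[(m, o)] = cell
    return CorrelationReport(cells=cells, markers=list(marker_cols),
                             outcomes=list(outcome_cols))


@dataclass
class HierRegressionReport:
    blocks: list       # per block: r2, r2_adj, f, p, df_model, df_resid, coefficients
    delta_r2: float
    f_change: float
    p_change: float
    vif: dict
    n: int

    def as_dict(self):
        return {
            "n": self.n,
            "blocks": self.blocks,
            "delta_r2": self.delta_r2,
            "f_change": self.f_change,
            "p_change": self.p_change,
            "vif": self.vif,
        }


def _fit_block(y, X):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return model


def hierarchical_regression(table, y_col, block1, block2):
    """Two-block hierarchical OLS of an outcome on marker blocks.

    Block 1 predictors enter first; block 2 adds to them.  Rows missing
    any involved variable are dropped (listwise).  Returns a
    :class:`HierRegressionReport` with unadjusted and adjusted R-squared
    per block (both are reported because with very small n they differ
    materially), the R-squared-change F test, and VIFs computed from
    each final-block predictor regressed on the others.
    """
    cols = [y_col] + list(block1) + list(block2)
    data = table[cols].dropna()
    n = len(data)
    p2 = len(block1) + len(block2)
    if n < p2 + 2:
        raise ValueError("insufficient complete rows for the regression")
    y = data[y_col].to_numpy(dtype=float)
    X1 = data[list(block1)].to_numpy(dtype=float)
    X2 = data[cols[1:]].to_numpy(dtype=float)
    for X in (X1, X2):
        if np.linalg.matrix_rank(sm.add_constant(X)) < X.shape[1] + 1:
            raise ValueError("rank-deficient design within a block")
    blocks = []
    fits = []
    for X, names in ((X1, list(block1)), (X2, cols[1:])):
        fit = _fit_block(y, X)
        fits.append(fit)
        blocks.append({
            "predictors": names,
            "r2": float(fit.rsquared),
            "r2_adj": float(fit.rsquared_adj),
            "f": float(fit.fvalue),
            "p": float(fit.f_pvalue),
            "df_model": int(fit.df_model),
            "df_resid": int(fit.df_resid),
            "coefficients": dict(zip(["intercept"] + names, map(float, fit.params))),
        })
    r2_1, r2_2 = blocks[0]["r2"], blocks[1]["r2"]
    q = len(block2)
    delta = r2_2 - r2_1
    denom = (1.0 - r2_2) / (n - p2 - 1)
    if denom <= 0:
        f_change, p_change = np.inf, 0.0
    else:
        f_change = (delta / q) / denom
        p_change = float(sstats.f.sf(f_change, q, n - p2 - 1))
    vif = {}
    final_names = cols[1:]
    if len(final_names) == 1:
        vif[final_names[0]] = 1.0
    else:
        for j, name in enumerate(final_names):
            others = [k for k in range(len(final_names)) if k != j]
            aux = _fit_block(X2[:, j], X2[:, others])
            vif[name] = float(1.0 / max(1.0 - aux.rsquared, 1e-12))
    return HierRegressionReport(blocks=blocks, delta_r2=float(delta),
                                f_change=float(f_change), p_change=p_change,
                                vif=vif, n=n)
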