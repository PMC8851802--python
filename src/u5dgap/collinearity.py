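"""Variance-inflation-factor screening before decomposition.

Each covariate (categorical covariates expanded to reference-coded dummies)
is regressed on all the others; VIF = 1/(1-R^2).  A variable whose worst
per-dummy VIF exceeds the threshold (default 2.5, strict inequality) is
removed, worst first, with recomputation after every removal so that a
single collinear pair does not cascade into over-removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor

DEFAULT_THRESHOLD = 2.5


@dataclass
class VifReport:
    vif: dict[str, float]            # worst per-dummy VIF at the final step
    dropped: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    history: list[tuple[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "vif": self.vif.get(v, np.nan),
                 "kept": v in self.kept} for v in list(self.kept) + list(self.dropped)]
        return pd.DataFrame(rows)


def _design_blocks(records: pd.DataFrame, covariates: list[str]):
    """Reference-coded dummy design and the column block of each variable."""
    cols, blocks = [], {}
    for var in covariates:
        col = records[var]
        if col.dtype.kind in "biufc":
            blocks[var] = [len(cols)]
            cols.append(col.to_numpy(float))
        else:
            cats = pd.unique(col.astype(str))
            blocks[var] = []
            for cat in cats[1:]:
                blocks[var].append(len(cols))
                cols.append((col.astype(str) == cat).to_numpy(float))
            if len(cats) == 1:  # constant column: keep a literal copy
                blocks[var] = [len(cols)]
                cols.append(np.zeros(len(col)))
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return X, blocks


def _worst_vifs(X: np.ndarray, blocks: dict[str, list[int]]) -> dict[str, float]:
    n = X.shape[0]
    design = np.column_stack([X, np.ones(n)])
    out = {}
    for var, cols in blocks.items():
        worst = 1.0
        for j in cols:
            with np.errstate(divide="ignore", invalid="ignore"):
                v = variance_inflation_factor(design, j)
            if np.isnan(v):
                v = np.inf
            worst = max(worst, float(v))
        out[var] = worst
    return out


def vif_screen(records: pd.DataFrame, covariates: list[str],
               threshold: float = DEFAULT_THRESHOLD,
               exclude: list[str] | None = None) -> VifReport:
    """Iteratively drop covariates with VIF strictly above ``threshold``.

    ``exclude`` names variables removed up front for non-statistical reasons
    (e.g. not collected in every survey); they are listed as dropped with a
    NaN VIF.  Perfectly collinear variables get an infinite VIF and go first.
    """
    exclude = list(exclude or [])
    active = [v for v in covariates if v not in exclude]
    if len(active) < 2:
        raise ValueError("need at least two covariates to screen")
    dropped = list(exclude)
    history: list[tuple[str, float]] = [(v, float("nan")) for v in exclude]
    while True:
        X, blocks = _design_blocks(records, active)
        vifs = _worst_vifs(X, blocks)
        worst_var = max(vifs, key=lambda v: vifs[v])
        # strict ">" rule, robust to float noise at the boundary
        above = (vifs[worst_var] > threshold
                 and not np.isclose(vifs[worst_var], threshold, rtol=1e-9, atol=1e-12))
        if above and len(active) > 1:
            active.remove(worst_var)
            dropped.append(worst_var)
            history.append((worst_var, vifs[worst_var]))
            continue
        break
    report = VifReport(vif=vifs, dropped=dropped, kept=list(active), history=history)
    return report
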