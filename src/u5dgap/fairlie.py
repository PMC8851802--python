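"""Nonlinear (Fairlie-type) decomposition of a binary-outcome group gap.

The male-female gap in death probability splits into an *explained*
(compositional) part — what the gap would be if only the covariate
distributions differed — and an *unexplained* (structural) part, by
substituting predicted probabilities:

    gap = [ mean F(X_A b_A) - mean F(X_B b_A) ]  (explained)
        + [ mean F(X_B b_A) - mean F(X_B b_B) ]  (unexplained)

with F the logistic CDF.  Because F is nonlinear, apportioning the explained
part over covariates requires record-level substitution: the larger group is
randomly subsampled to the smaller group's size, records are paired rank to
rank on predicted probability under pooled coefficients, and each variable's
contribution is the change in mean predicted probability when the paired
group-B values of that variable are replaced by group-A values, walking the
variables in order (already-visited variables hold A's values, unvisited
hold B's).  Contributions telescope exactly to the matched-sample explained
term for every ordering.  Replicating the subsample draw (and optionally the
ordering) D times gives the reported means and replication standard errors.

With the identity link the procedure collapses to the classical
Blinder-Oaxaca decomposition, whose closed form is used as a test oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data_model import COVARIATE_CATEGORIES


def _link(name: str):
    if name == "logit":
        return expit
    if name == "identity":
        return lambda t: t
    raise ValueError(f"unknown link {name!r}")


@dataclass
class DesignInfo:
    """Shared reference-coded dummy design for both groups.

    Category orders are learned once (canonical order where known, first-seen
    otherwise) so group A and group B matrices are column-compatible.
    ``blocks`` maps each decomposed variable to its column indices; control
    variables get columns but no block and are never substituted.
    """

    covariates: list[str]
    controls: list[str]
    categories: dict[str, list[str]]
    numeric: set[str]
    columns: list[str] = field(default_factory=list)
    blocks: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, covariates: list[str],
                   controls: list[str] | None = None) -> "DesignInfo":
        controls = list(controls or [])
        categories, numeric = {}, set()
        for var in covariates + controls:
            col = frame[var]
            if col.dtype.kind in "biufc":
                numeric.add(var)
                continue
            known = COVARIATE_CATEGORIES.get(var)
            seen = set(col.astype(str).unique())
            if known is not None and seen <= set(known):
                categories[var] = [c for c in known if c in seen]
            else:
                categories[var] = list(pd.unique(col.astype(str)))
        info = cls(list(covariates), controls, categories, numeric)
        idx = 1  # column 0 is the intercept
        for var in covariates + controls:
            cols = []
            if var in info.numeric:
                cols = [idx]
                idx += 1
            else:
                for _ in info.categories[var][1:]:
                    cols.append(idx)
                    idx += 1
            if var in covariates:
                info.blocks[var] = cols
        info.columns = ["const"]
        for var in covariates + controls:
            if var in info.numeric:
                info.columns.append(var)
            else:
                info.columns += [f"{var}[{c}]" for c in info.categories[var][1:]]
        return info

    def matrix(self, frame: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(frame))]
        for var in self.covariates + self.controls:
            if var in self.numeric:
                cols.append(frame[var].to_numpy(float))
            else:
                s = frame[var].astype(str)
                for cat in self.categories[var][1:]:
                    cols.append((s == cat).to_numpy(float))
        return np.column_stack(cols)


@dataclass
class LogitCoefficients:
    params: np.ndarray
    columns: list[str]
    provenance: str  # "group_a" | "group_b" | "pooled"
    link: str = "logit"
    group_coef: float = 0.0  # pooled-model group-indicator coefficient, if any


@dataclass
class MatchedPairs:
    a_index: np.ndarray
    b_index: np.ndarray
    seed: object = None

    def __len__(self) -> int:
        return len(self.a_index)


@dataclass
class DecompositionResult:
    total_gap: float
    explained: float
    unexplained: float
    table: pd.DataFrame  # variable, contribution, se, z, p, pct_of_gap, pct_of_explained
    D: int
    seed: object
    ordering_policy: str
    provenance: str
    explained_se: float = 0.0


def fit_logit(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
              link: str = "logit", columns: list[str] | None = None,
              provenance: str = "pooled") -> LogitCoefficients:
    """Maximum-likelihood logit (or weighted least squares for identity link).

    Sampling weights enter the estimating equations; separation and
    non-convergence raise with the offending covariate named when possible.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; cannot fit")
    if link == "identity":
        w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
        sw = np.sqrt(w)
        params, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return LogitCoefficients(params, columns or [], provenance, "identity")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial(),
                           var_weights=np.asarray(weights, float) if weights is not None else None)
            res = model.fit(maxiter=200, tol=1e-10)
        except sm.tools.sm_exceptions.PerfectSeparationError as err:
            raise ValueError(f"perfect separation in logit fit: {err}") from err
        except sm.tools.sm_exceptions.PerfectSeparationWarning as err:
            raise ValueError(f"perfect separation in logit fit: {err}") from err
    params = np.asarray(res.params, float)
    big = np.abs(params) > 30
    if big.any():
        names = [columns[j] if columns else str(j) for j in np.flatnonzero(big)]
        raise ValueError(f"separation suspected: diverging coefficients for {names}")
    if not res.converged:
        raise ValueError("logit fit did not converge")
    return LogitCoefficients(params, columns or [], provenance, "logit")


def decompose_total(XA: np.ndarray, XB: np.ndarray,
                    betaA: LogitCoefficients, betaB: LogitCoefficients,
                    wA: np.ndarray | None = None, wB: np.ndarray | None = None
                    ) -> tuple[float, float, float]:
    """Two-term split of the gap: (total, explained, unexplained).

    With group-fitted maximum-likelihood coefficients (each including an
    intercept) the total equals the observed weighted gap in outcome means to
    numerical precision.
    """
    if XA.shape[1] != XB.shape[1]:
        raise ValueError("covariate sets of the two groups differ")
    F = _link(betaA.link)

    def wmean(v, w):
        if w is None:
            return float(v.mean())
        w = np.asarray(w, float)
        return float(v @ w / w.sum())

    a_own = wmean(F(XA @ betaA.params), wA)
    b_cross = wmean(F(XB @ betaA.params), wB)
    b_own = wmean(F(XB @ betaB.params), wB)
    explained = a_own - b_cross
    unexplained = b_cross - b_own
    return explained + unexplained, explained, unexplained


def match_samples(pred_a: np.ndarray, pred_b: np.ndarray,
                  rng: np.random.Generator) -> MatchedPairs:
    """Subsample the larger group and pair records rank-to-rank.

    A uniform random subsample of the larger group of the smaller group's
    size is drawn, then both groups are sorted by predicted probability and
    paired rank r with rank r.
    """
    na, nb = len(pred_a), len(pred_b)
    m = min(na, nb)
    idx_a = rng.choice(na, size=m, replace=False) if na > m else np.arange(na)
    idx_b = rng.choice(nb, size=m, replace=False) if nb > m else np.arange(nb)
    idx_a = idx_a[np.argsort(pred_a[idx_a], kind="stable")]
    idx_b = idx_b[np.argsort(pred_b[idx_b], kind="stable")]
    return MatchedPairs(idx_a, idx_b)


def sequential_contributions(XA_m: np.ndarray, XB_m: np.ndarray,
                             pooled: LogitCoefficients, blocks: dict[str, list[int]],
                             ordering: list[str]) -> tuple[dict[str, float], float]:
    """Per-variable contributions along one ordering, plus the matched
    explained term they telescope to.

    For variable k, the contribution is the change in the mean predicted
    probability over matched pairs when k's paired group-B values are
    replaced by group-A values, with already-visited variables at A's values
    and unvisited ones at B's.
    """
    if sorted(ordering) != sorted(blocks):
        raise ValueError("ordering must be a permutation of the decomposed variables")
    F = _link(pooled.link)
    beta = pooled.params
    lp = XB_m @ beta
    mean_start = float(F(lp).mean())
    out: dict[str, float] = {}
    for var in ordering:
        cols = blocks[var]
        if cols:
            delta = (XA_m[:, cols] - XB_m[:, cols]) @ beta[cols]
            lp_next = lp + delta
        else:
            lp_next = lp
        out[var] = float(F(lp_next).mean()) - float(F(lp).mean())
        lp = lp_next
    explained_matched = float(F(lp).mean()) - mean_start
    return out, explained_matched


def replicate_decomposition(frameA: pd.DataFrame, frameB: pd.DataFrame,
                            info: DesignInfo, pooled: LogitCoefficients,
                            D: int = 100, randomize_ordering: bool = True,
                            seed: int | None = 0,
                            outcome: str = "died_u5",
                            weight_col: str | None = "weight") -> DecompositionResult:
    """Replicated sequential decomposition with replication-based SEs.

    Each of the D replications draws a fresh subsample of the larger group
    (and a fresh variable ordering when ``randomize_ordering``), rank-matches
    on the pooled-model predicted probability, and walks the substitution.
    Reported contributions are replication means; SEs are replication SDs;
    percentages are relative to the total observed gap and to the explained
    term.  Deterministic given the seed.
    """
    if D < 1:
        raise ValueError("D must be at least 1")
    rng = np.random.default_rng(seed)
    XA, XB = info.matrix(frameA), info.matrix(frameB)
    yA = frameA[outcome].to_numpy(float)
    yB = frameB[outcome].to_numpy(float)
    if weight_col is not None:
        wA = frameA[weight_col].to_numpy(float)
        wB = frameB[weight_col].to_numpy(float)
        total_gap = float(yA @ wA / wA.sum() - yB @ wB / wB.sum())
    else:
        total_gap = float(yA.mean() - yB.mean())
    pred_a = _link(pooled.link)(XA @ pooled.params)
    pred_b = _link(pooled.link)(XB @ pooled.params)

    variables = list(info.blocks)
    contribs = np.empty((D, len(variables)))
    explained_reps = np.empty(D)
    for d in range(D):
        pairs = match_samples(pred_a, pred_b, rng)
        ordering = list(variables)
        if randomize_ordering:
            ordering = [variables[j] for j in rng.permutation(len(variables))]
        got, expl = sequential_contributions(XA[pairs.a_index], XB[pairs.b_index],
                                             pooled, info.blocks, ordering)
        contribs[d] = [got[v] for v in variables]
        explained_reps[d] = expl

    mean = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) if D > 1 else np.zeros(len(variables))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean / se, np.nan)
    p = np.where(np.isnan(z), np.nan, 2 * stats.norm.sf(np.abs(z)))
    explained = float(explained_reps.mean())
    table = pd.DataFrame({
        "variable": variables,
        "contribution": mean,
        "se": se,
        "z": z,
        "p": p,
        "pct_of_gap": 100.0 * mean / total_gap if total_gap != 0 else np.nan,
        "pct_of_explained": 100.0 * mean / explained if explained != 0 else np.nan,
    })
    return DecompositionResult(
        total_gap=total_gap, explained=explained,
        unexplained=total_gap - explained, table=table, D=D, seed=seed,
        ordering_policy="randomized" if randomize_ordering else "fixed",
        provenance=pooled.provenance,
        explained_se=float(explained_reps.std(ddof=1)) if D > 1 else 0.0,
    )


def percent_of_gap(result: DecompositionResult) -> pd.Series:
    """Signed per-variable percentages of the total gap (may exceed 100)."""
    if result.total_gap == 0:
        raise ValueError("total gap is zero; percentages undefined")
    return pd.Series(
        (100.0 * result.table["contribution"] / result.total_gap).to_numpy(),
        index=result.table["variable"].to_numpy(), name="pct_of_gap")


def fairlie_decompose(records: pd.DataFrame, covariates: list[str],
                      controls: list[str] | None = None,
                      group: str = "sex", group_a: str = "male", group_b: str = "female",
                      outcome: str = "died_u5", weight_col: str | None = "weight",
                      D: int = 100, randomize_ordering: bool = True, seed: int = 0,
                      include_group_indicator: bool = True,
                      link: str = "logit") -> DecompositionResult:
    """End-to-end decomposition of the group-A-minus-group-B outcome gap.

    Pooled coefficients come from a logit on the concatenated sample; by
    default the model includes a group indicator (whose coefficient is set
    aside, so substitution predictions are at the indicator's reference
    level).  ``controls`` enter the model but are never substituted.
    """
    frameA = records[records[group] == group_a]
    frameB = records[records[group] == group_b]
    if len(frameA) < 2 or len(frameB) < 2:
        raise ValueError("both groups need at least two records")
    info = DesignInfo.from_frame(records, list(covariates), controls)
    X = info.matrix(records)
    cols = list(info.columns)
    if include_group_indicator:
        X = np.column_stack([X, (records[group] == group_a).to_numpy(float)])
        cols = cols + [f"{group}[{group_a}]"]
    y = records[outcome].to_numpy(float)
    w = records[weight_col].to_numpy(float) if weight_col is not None else None
    fitted = fit_logit(X, y, w, link=link, columns=cols)
    params = fitted.params
    group_coef = 0.0
    if include_group_indicator:
        group_coef = float(params[-1])
        params = params[:-1]
    pooled = LogitCoefficients(params, info.columns, "pooled", link, group_coef)
    return replicate_decomposition(frameA, frameB, info, pooled, D=D,
                                   randomize_ordering=randomize_ordering,
                                   seed=seed, outcome=outcome, weight_col=weight_col)
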