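"""Sex-inequality statistics for under-five deaths.

Per-stratum measures on male/female 2x2 tables — risk difference (RD, per
1000 live births; RD > 0 means excess male deaths, i.e. pro-male
inequality), two-proportion z-test, crude odds ratio — and pooled measures
across countries: the Mantel-Haenszel odds ratio with the
Robins-Breslow-Greenland variance, Cochran's Q / Breslow-Day homogeneity
tests, and DerSimonian-Laird random-effects meta-analysis of RDs.

Counts may be real-valued (sums of sampling weights).  When weighted cells
are used, the optional effective sample sizes ``n_eff_male`` /
``n_eff_female`` — Kish's (sum w)^2 / sum w^2 per sex — drive the variance
formulas so that weighting changes point estimates but precision reflects
the effective number of observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = stats.norm.ppf(0.975)


@dataclass
class TwoByTwo:
    """Sex-by-death table for one stratum (counts may be weighted reals)."""

    label: str
    male_deaths: float
    male_survivors: float
    female_deaths: float
    female_survivors: float
    n_eff_male: float | None = None
    n_eff_female: float | None = None

    def __post_init__(self) -> None:
        cells = (self.male_deaths, self.male_survivors,
                 self.female_deaths, self.female_survivors)
        if any(c < 0 for c in cells):
            raise ValueError("table cells must be nonnegative")

    @property
    def n_male(self) -> float:
        return self.male_deaths + self.male_survivors

    @property
    def n_female(self) -> float:
        return self.female_deaths + self.female_survivors

    @property
    def n(self) -> float:
        return self.n_male + self.n_female

    def swapped(self) -> "TwoByTwo":
        """Same table with the sex labels exchanged."""
        return TwoByTwo(self.label, self.female_deaths, self.female_survivors,
                        self.male_deaths, self.male_survivors,
                        self.n_eff_female, self.n_eff_male)


@dataclass
class EffectEstimate:
    effect: float
    variance: float
    ci_low: float
    ci_high: float
    p_value: float
    scale: str = "rd_per_1000"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.ci_low <= self.effect <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


@dataclass
class MetaResult:
    estimates: list[EffectEstimate]
    fixed_effect: EffectEstimate
    random_effect: EffectEstimate
    Q: float
    df: int
    I2: float
    tau2: float
    weights_pct: np.ndarray = field(repr=False)


@dataclass
class QuadrantLabel:
    country: str
    prevalence_level: str  # "high" | "low"
    inequality: str        # "pro-male" | "pro-female" | "pro-neither"
    significant: bool


def weighted_prevalence(records: pd.DataFrame, mask=None) -> float:
    """Sampling-weighted U5D prevalence per 1000 live births."""
    sub = records if mask is None else records.loc[mask]
    if len(sub) == 0:
        raise ValueError("empty subgroup")
    w = sub["weight"].to_numpy(float)
    y = sub["died_u5"].to_numpy(float)
    return 1000.0 * float(w @ y) / float(w.sum())


def table_from_records(records: pd.DataFrame, label: str = "", weighted: bool = True) -> TwoByTwo:
    """Build a sex-by-death table from child records.

    With ``weighted=True`` cells are sums of sampling weights and Kish
    effective sample sizes are attached for variance computation.
    """
    out = {}
    neff = {}
    for sex in ("male", "female"):
        sub = records[records["sex"] == sex]
        w = sub["weight"].to_numpy(float) if weighted else np.ones(len(sub))
        y = sub["died_u5"].to_numpy(float)
        out[sex] = (float(w[y == 1].sum()), float(w[y == 0].sum()))
        sw = float(w.sum())
        neff[sex] = sw * sw / float((w * w).sum()) if len(sub) else 0.0
    return TwoByTwo(label, out["male"][0], out["male"][1],
                    out["female"][0], out["female"][1],
                    n_eff_male=neff["male"], n_eff_female=neff["female"])


def risk_difference(t: TwoByTwo) -> EffectEstimate:
    """Male-minus-female risk difference per 1000 with a Wald binomial CI."""
    if t.n_male <= 0 or t.n_female <= 0:
        raise ValueError("both sex margins must be positive")
    pm = t.male_deaths / t.n_male
    pf = t.female_deaths / t.n_female
    nm = t.n_eff_male if t.n_eff_male else t.n_male
    nf = t.n_eff_female if t.n_eff_female else t.n_female
    rd = 1000.0 * (pm - pf)
    var = 1000.0 ** 2 * (pm * (1 - pm) / nm + pf * (1 - pf) / nf)
    se = math.sqrt(var)
    z = rd / se if se > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
    return EffectEstimate(rd, var, rd - Z95 * se, rd + Z95 * se, p,
                          scale="rd_per_1000", label=t.label)


def z_test_two_proportions(t: TwoByTwo) -> tuple[float, float]:
    """Pooled-variance z-test of equal male/female death proportions."""
    nm = t.n_eff_male if t.n_eff_male else t.n_male
    nf = t.n_eff_female if t.n_eff_female else t.n_female
    pm = t.male_deaths / t.n_male
    pf = t.female_deaths / t.n_female
    pooled = (pm * nm + pf * nf) / (nm + nf)
    if not 0 < pooled < 1:
        raise ValueError("degenerate pooled proportion")
    se = math.sqrt(pooled * (1 - pooled) * (1 / nm + 1 / nf))
    z = (pm - pf) / se
    return z, 2 * stats.norm.sf(abs(z))


def reconstruct_country_table(row) -> TwoByTwo:
    """Rebuild a country's sex-by-death table from its printed summary row.

    Sex margins come from n_children and percent male; death cells from the
    printed per-1000 rates.  Rounding is half-up to integers, with deaths
    capped at their margin.
    """
    def half_up(x: float) -> int:
        return int(math.floor(x + 0.5))

    n_male = half_up(row["n_children"] * row["pct_male"] / 100.0)
    n_female = int(row["n_children"]) - n_male
    male_deaths = min(half_up(n_male * row["u5d_male"] / 1000.0), n_male)
    female_deaths = min(half_up(n_female * row["u5d_female"] / 1000.0), n_female)
    return TwoByTwo(str(row["country"]), male_deaths, n_male - male_deaths,
                    female_deaths, n_female - female_deaths)


def crude_or(t: TwoByTwo, correction: bool = True) -> tuple[float, float]:
    """Crude log odds ratio and its Woolf variance for one stratum.

    A 0.5 continuity correction is added to every cell only when a zero cell
    would otherwise block the estimate.
    """
    a, b, c, d = (t.male_deaths, t.male_survivors,
                  t.female_deaths, t.female_survivors)
    if min(a, b, c, d) == 0:
        if not correction:
            raise ValueError(f"zero cell in stratum {t.label!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log(a * d / (b * c)), 1 / a + 1 / b + 1 / c + 1 / d


def mh_pooled_or(tables: list[TwoByTwo]) -> EffectEstimate:
    """Mantel-Haenszel pooled odds ratio across strata.

    CI and p use the Robins-Breslow-Greenland variance of the pooled log OR;
    the p-value tests OR = 1.
    """
    if not tables:
        raise ValueError("at least one stratum required")
    a = np.array([t.male_deaths for t in tables], float)
    b = np.array([t.male_survivors for t in tables], float)
    c = np.array([t.female_deaths for t in tables], float)
    d = np.array([t.female_survivors for t in tables], float)
    n = a + b + c + d
    R, S = a * d / n, b * c / n
    sumR, sumS = R.sum(), S.sum()
    if sumR == 0 or sumS == 0:
        raise ValueError("all strata have an empty diagonal")
    or_mh = sumR / sumS
    P = (a + d) / n
    Qq = (b + c) / n
    var_log = (float((P * R).sum()) / (2 * sumR ** 2)
               + float((P * S + Qq * R).sum()) / (2 * sumR * sumS)
               + float((Qq * S).sum()) / (2 * sumS ** 2))
    se = math.sqrt(var_log)
    log_or = math.log(or_mh)
    z = log_or / se if se > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
    return EffectEstimate(or_mh, var_log,
                          math.exp(log_or - Z95 * se),
                          math.exp(log_or + Z95 * se),
                          p, scale="odds_ratio", label="MH pooled")


def or_heterogeneity(tables: list[TwoByTwo], method: str = "cochran-q") -> tuple[float, int, float, float]:
    """Heterogeneity of stratum odds ratios: (statistic, df, p, I2 percent).

    ``cochran-q`` is the inverse-variance Q on log ORs; ``breslow-day`` tests
    homogeneity around the MH pooled OR.
    """
    if len(tables) < 2:
        raise ValueError("at least two strata required")
    df = len(tables) - 1
    if method == "cochran-q":
        lor, var = zip(*(crude_or(t) for t in tables))
        w = 1.0 / np.asarray(var)
        lor = np.asarray(lor)
        pooled = float(w @ lor / w.sum())
        Q = float(w @ (lor - pooled) ** 2)
    elif method == "breslow-day":
        or_mh = mh_pooled_or(tables).effect
        Q = 0.0
        for t in tables:
            a, n1 = t.male_deaths, t.n_male
            m1, n2 = t.male_deaths + t.female_deaths, t.n_female
            # expected male-death cell x under the common OR solves
            # x(n2-m1+x) = OR (n1-x)(m1-x): quadratic with one admissible root
            A = 1 - or_mh
            B = (n1 + m1) * or_mh + (n2 - m1)
            C = -or_mh * m1 * n1
            if abs(A) < 1e-12:
                a_exp = -C / B
            else:
                disc = math.sqrt(B * B - 4 * A * C)
                roots = [(-B + disc) / (2 * A), (-B - disc) / (2 * A)]
                lo, hi = max(0.0, m1 - n2), min(n1, m1)
                a_exp = next(r for r in roots if lo - 1e-9 <= r <= hi + 1e-9)
            b_exp, c_exp, d_exp = n1 - a_exp, m1 - a_exp, n2 - m1 + a_exp
            v = 1.0 / (1 / a_exp + 1 / b_exp + 1 / c_exp + 1 / d_exp)
            Q += (a - a_exp) ** 2 / v
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stats.chi2.sf(Q, df))
    I2 = 100.0 * max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return Q, df, p, I2


def meta_rd(estimates: list[EffectEstimate]) -> MetaResult:
    """Fixed- and random-effects meta-analysis of per-stratum risk differences.

    Fixed effect is inverse-variance pooled; between-stratum variance tau^2 is
    the DerSimonian-Laird moment estimator floored at zero; the random effect
    re-pools with weights 1/(v_i + tau^2).
    """
    if len(estimates) < 2:
        raise ValueError("at least two strata required")
    eff = np.array([e.effect for e in estimates])
    v = np.array([e.variance for e in estimates])
    if (v <= 0).any():
        raise ValueError("all stratum variances must be positive")
    w = 1.0 / v
    fixed = float(w @ eff / w.sum())
    Q = float(w @ (eff - fixed) ** 2)
    df = len(eff) - 1
    denom = w.sum() - float(w @ w) / w.sum()
    tau2 = max(0.0, (Q - df) / denom)
    wr = 1.0 / (v + tau2)
    rand = float(wr @ eff / wr.sum())

    def pooled_estimate(effect: float, wsum: float, label: str) -> EffectEstimate:
        se = math.sqrt(1.0 / wsum)
        z = effect / se
        return EffectEstimate(effect, 1.0 / wsum, effect - Z95 * se,
                              effect + Z95 * se, 2 * stats.norm.sf(abs(z)),
                              scale=estimates[0].scale, label=label)

    I2 = 100.0 * max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return MetaResult(
        estimates=list(estimates),
        fixed_effect=pooled_estimate(fixed, float(w.sum()), "fixed"),
        random_effect=pooled_estimate(rand, float(wr.sum()), "random"),
        Q=Q, df=df, I2=I2, tau2=tau2,
        weights_pct=100.0 * wr / wr.sum(),
    )


def quadrant_classify(prevalence_per_1000: float, rd: EffectEstimate,
                      threshold: float) -> QuadrantLabel:
    """Place a country in the prevalence-by-inequality four-quadrant scheme."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    level = "high" if prevalence_per_1000 >= threshold else "low"
    if rd.effect > 0:
        direction = "pro-male"
    elif rd.effect < 0:
        direction = "pro-female"
    else:
        direction = "pro-neither"
    significant = rd.ci_low > 0 or rd.ci_high < 0
    return QuadrantLabel(rd.label, level, direction, significant)
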