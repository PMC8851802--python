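"""Two-level clustered survey simulator with a known male-female mortality gap.

Children are nested in clusters nested in countries.  Each child's death
before age five is Bernoulli with logistic probability

    logit P(death) = alpha_country + b_cluster + s * 1[male] + eta(x)

where ``b_cluster ~ Normal(0, cluster_sd^2)``, ``s`` is the direct sex
effect on the log-odds scale, and ``eta(x)`` sums per-category log-odds
effects of the child's categorical covariates.  Covariate categories are
drawn from sex-specific probability vectors, so the male-female gap has a
compositional (explained) part — males drawn into riskier categories — and
a structural (unexplained) part from ``s``.  Positive sampling weights are
attached but never enter the outcome model.

Because the generator's parameters are known, the population decomposition
of the gap (total, explained, unexplained, and single-covariate swap
contributions) can be computed exactly by enumerating the finite covariate
space and integrating the cluster effect by Gauss-Hermite quadrature, or by
Monte Carlo for large covariate spaces.  That truth is the oracle against
which the sample-based decomposition is validated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .data_model import validate_children

_GH_NODES = 41


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical covariate: categories, sex-specific laws, effects."""

    name: str
    categories: tuple[str, ...]
    probs_female: tuple[float, ...]
    probs_male: tuple[float, ...]
    effects: tuple[float, ...]  # log-odds per category; reference usually 0

    def __post_init__(self) -> None:
        k = len(self.categories)
        for pv in (self.probs_female, self.probs_male):
            if len(pv) != k or len(self.effects) != k:
                raise ValueError(f"{self.name}: length mismatch")
            if abs(sum(pv) - 1.0) > 1e-12:
                raise ValueError(f"{self.name}: probabilities must sum to 1")
            if any(p < 0 for p in pv):
                raise ValueError(f"{self.name}: negative probability")


def _default_covariates() -> tuple[CovariateSpec, ...]:
    """Desk-scale covariate set: composition differs by sex only for birth weight."""
    return (
        CovariateSpec("maternal_education", ("none", "primary", "secondary+"),
                      (0.35, 0.25, 0.40), (0.35, 0.25, 0.40), (0.0, -0.2, -0.5)),
        CovariateSpec("maternal_age_group", ("15-24", "25-34", "35-49"),
                      (0.30, 0.50, 0.20), (0.30, 0.50, 0.20), (0.0, -0.15, 0.10)),
        CovariateSpec("birth_order", ("1", "2", "3", "4+"),
                      (0.28, 0.24, 0.16, 0.32), (0.28, 0.24, 0.16, 0.32),
                      (0.0, -0.10, 0.0, 0.30)),
        CovariateSpec("birth_weight", ("average+", "small", "very small"),
                      (0.88, 0.08, 0.04), (0.85, 0.10, 0.05), (0.0, 0.8, 1.8)),
        CovariateSpec("twin", ("single", "multiple"),
                      (0.975, 0.025), (0.975, 0.025), (0.0, 1.5)),
        CovariateSpec("residence", ("urban", "rural"),
                      (0.30, 0.70), (0.30, 0.70), (0.0, 0.15)),
    )


@dataclass(frozen=True)
class SimConfig:
    """Simulation scenario.

    Defaults are a desk-scale version of a 59-country pooled survey: 10
    countries x 50 clusters x 30 children, under-five mortality near 51 per
    1000 with a pro-male gap near 7 per 1000, cluster heterogeneity of 0.3 on
    the log-odds scale, and gamma sampling weights with mean one.
    ``baseline_logodds`` may be a scalar, a per-country sequence, a
    ``("normal", mean, sd)`` spec (resolved deterministically from the seed),
    or ``None`` to solve the intercept for ``target_prevalence``.
    """

    n_countries: int = 10
    clusters_per_country: int = 50
    children_per_cluster: int = 30
    baseline_logodds: object = None
    target_prevalence: float = 0.051
    cluster_sd: float = 0.3
    sex_logodds: float = 0.10
    p_male: float = 0.5
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    weight_model: tuple = ("gamma", 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_countries, self.clusters_per_country, self.children_per_cluster) <= 0:
            raise ValueError("population sizes must be positive")
        if self.cluster_sd < 0:
            raise ValueError("cluster_sd must be nonnegative")


@dataclass
class TruthRecord:
    """Population decomposition of the male-female death-probability gap."""

    total_gap: float
    explained: float
    unexplained: float
    contributions: dict[str, float]
    response: str
    method: str
    mc_se: float = 0.0
    config: dict = field(default_factory=dict)


def _gh_rule(sd: float):
    nodes, weights = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return nodes * sd, weights / weights.sum()


def resolve_baselines(config: SimConfig) -> np.ndarray:
    """Per-country intercepts implied by the config (deterministic)."""
    b = config.baseline_logodds
    if b is None:
        b = solve_baseline(config)
    if isinstance(b, tuple) and len(b) == 3 and b[0] == "normal":
        rng = np.random.default_rng([int(config.seed) % (2 ** 31), 17])
        return rng.normal(b[1], b[2], config.n_countries)
    if np.isscalar(b):
        return np.full(config.n_countries, float(b))
    arr = np.asarray(b, float)
    if arr.shape != (config.n_countries,):
        raise ValueError("baseline_logodds sequence must have one entry per country")
    return arr


def marginal_prevalence(config: SimConfig, baseline: float | None = None) -> float:
    """Exact marginal death probability under the scenario (both sexes mixed)."""
    if baseline is not None:
        base = np.full(config.n_countries, float(baseline))
    else:
        base = resolve_baselines(config)
    (p_male_law, p_female_law), etas, _ = _pattern_tables(config)
    nodes, gw = _gh_rule(config.cluster_sd)
    out = 0.0
    for sex, pm in (("male", config.p_male), ("female", 1 - config.p_male)):
        off = config.sex_logodds if sex == "male" else 0.0
        lp = base[:, None, None] + nodes[None, :, None] + off + etas[None, None, :]
        p_pat = expit(lp)  # countries x nodes x patterns
        pw = p_male_law if sex == "male" else p_female_law
        out += pm * float(np.einsum("cnp,n,p->", p_pat, gw, pw) / len(base))
    return out


def solve_baseline(config: SimConfig) -> float:
    """Scalar intercept giving the configured marginal prevalence."""
    target = config.target_prevalence
    if target is None:
        raise ValueError("either baseline_logodds or target_prevalence is required")

    def f(c: float) -> float:
        return marginal_prevalence(replace(config, baseline_logodds=None), baseline=c) - target

    lo = math.log(target / (1 - target)) - 4
    hi = math.log(target / (1 - target)) + 4
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _pattern_tables(config: SimConfig):
    """Enumerate the covariate space: (male/female pattern probs, pattern etas)."""
    cats = [range(len(c.categories)) for c in config.covariates]
    patterns = np.array(list(itertools.product(*cats)), dtype=int)
    pm = np.ones(len(patterns))
    pf = np.ones(len(patterns))
    eta = np.zeros(len(patterns))
    for j, cov in enumerate(config.covariates):
        idx = patterns[:, j]
        pm *= np.asarray(cov.probs_male)[idx]
        pf *= np.asarray(cov.probs_female)[idx]
        eta += np.asarray(cov.effects)[idx]
    return (pm, pf), eta, patterns


def _n_patterns(config: SimConfig) -> int:
    n = 1
    for c in config.covariates:
        n *= len(c.categories)
    return n


def generate(config: SimConfig, seed: int | None = None) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one dataset from the scenario; byte-identical for the same seed.

    Returns the child table (canonical schema) and the population truth for
    the scenario (enumeration when the covariate space is small enough).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    base = resolve_baselines(config)
    n_clusters = config.n_countries * config.clusters_per_country
    n = n_clusters * config.children_per_cluster

    country_idx = np.repeat(np.arange(config.n_countries),
                            config.clusters_per_country * config.children_per_cluster)
    cluster_idx = np.repeat(np.arange(n_clusters), config.children_per_cluster)
    cluster_eff = rng.normal(0.0, config.cluster_sd, n_clusters)[cluster_idx]

    male = rng.random(n) < config.p_male
    lp = base[country_idx] + cluster_eff + config.sex_logodds * male

    frame = pd.DataFrame({
        "child_id": [f"c{i:07d}" for i in range(n)],
        "country": [f"C{k:02d}" for k in country_idx],
        "cluster_id": [f"C{k:02d}_cl{j:04d}" for k, j in
                       zip(country_idx, cluster_idx % config.clusters_per_country)],
        "sex": np.where(male, "male", "female"),
    })
    for cov in config.covariates:
        draw = np.empty(n, dtype=int)
        for is_male, probs in ((True, cov.probs_male), (False, cov.probs_female)):
            mask = male == is_male
            cum = np.cumsum(probs)
            draw[mask] = np.searchsorted(cum, rng.random(mask.sum()), side="right")
        draw = np.minimum(draw, len(cov.categories) - 1)
        lp += np.asarray(cov.effects)[draw]
        frame[cov.name] = np.asarray(cov.categories, dtype=object)[draw]

    frame["died_u5"] = (rng.random(n) < expit(lp)).astype(int)
    if config.weight_model[0] == "gamma":
        shape = float(config.weight_model[1])
        frame["weight"] = rng.gamma(shape, 1.0 / shape, n)
    elif config.weight_model[0] == "constant":
        frame["weight"] = 1.0
    else:
        raise ValueError(f"unknown weight model {config.weight_model!r}")

    truth = true_decomposition(config)
    return validate_children(frame), truth


def true_decomposition(config: SimConfig, n_mc: int | None = None,
                       response: str = "female", seed: int | None = None,
                       method: str = "swap", n_orderings: int = 48) -> TruthRecord:
    """Population decomposition of the sex gap from the generator's parameters.

    ``total_gap`` is E[death | male] - E[death | female].  The
    explained/unexplained split substitutes covariate laws under the male
    response (the nonlinear-decomposition identity).  Per-covariate
    contributions come in two flavours:

    * ``method="swap"`` — independent single-covariate law swaps (female law
      -> male law for that covariate, all others at the female law), by exact
      enumeration of the covariate space (Gauss-Hermite integration of the
      cluster effect) or Monte Carlo when ``n_mc`` is given or the space is
      too large.
    * ``method="matched"`` — the population analogue of the rank-matched
      sequential-substitution procedure: male- and female-law draws are
      comonotonically coupled on their true risk score, variables are
      switched along random orderings, and contributions are
      ordering-averaged means of the change in true (cluster-marginal) death
      probability.  This is the estimand of the sample decomposition; it
      differs from the independent swap because the coupling correlates the
      substituted values with the partner's risk and the response is
      nonlinear.

    ``response`` fixes the sex level of the response used for contributions:
    "female" (default, matching a pooled model's reference-level prediction
    convention), "male" or "average".
    """
    if response not in ("female", "male", "average"):
        raise ValueError("response must be 'female', 'male' or 'average'")
    if method == "matched":
        return _truth_matched(config, response, n_mc or 400_000, n_orderings,
                              config.seed if seed is None else seed)
    if method != "swap":
        raise ValueError("method must be 'swap' or 'matched'")
    if n_mc is None and _n_patterns(config) > 200_000:
        raise ValueError("covariate space too large to enumerate; pass n_mc")
    if n_mc is None:
        return _truth_enumerate(config, response)
    return _truth_mc(config, response, n_mc,
                     config.seed if seed is None else seed)


def _response_offsets(config: SimConfig, response: str) -> float:
    return {"female": 0.0, "male": config.sex_logodds,
            "average": 0.5 * config.sex_logodds}[response]


def _truth_enumerate(config: SimConfig, response: str) -> TruthRecord:
    base = resolve_baselines(config)
    (pm, pf), eta, patterns = _pattern_tables(config)
    nodes, gw = _gh_rule(config.cluster_sd)

    def p_of(eta_vec: np.ndarray, sex_off: float) -> np.ndarray:
        lp = base[:, None, None] + nodes[None, :, None] + sex_off + eta_vec[None, None, :]
        return np.einsum("cnp,n->p", expit(lp), gw) / len(base)

    p_male = p_of(eta, config.sex_logodds)
    p_female = p_of(eta, 0.0)
    p_resp = p_of(eta, _response_offsets(config, response))

    total = float(pm @ p_male - pf @ p_female)
    explained = float(pm @ p_male - pf @ p_male)
    unexplained = float(pf @ (p_male - p_female))

    contributions: dict[str, float] = {}
    for j, cov in enumerate(config.covariates):
        # swap covariate j's marginal from female to male law
        idx = patterns[:, j]
        probs_f = np.asarray(cov.probs_female)[idx]
        probs_m = np.asarray(cov.probs_male)[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(probs_f > 0, probs_m / probs_f, 0.0)
        p_swap = pf * ratio
        if probs_f.min() == 0:  # female law has a zero cell: rebuild exactly
            p_swap = np.ones(len(patterns))
            for jj, cv in enumerate(config.covariates):
                law = cv.probs_male if jj == j else cv.probs_female
                p_swap *= np.asarray(law)[patterns[:, jj]]
        contributions[cov.name] = float(p_swap @ p_resp - pf @ p_resp)

    return TruthRecord(total, explained, unexplained, contributions,
                       response, "enumerate", 0.0, asdict(config))


def _truth_mc(config: SimConfig, response: str, n_mc: int, seed: int) -> TruthRecord:
    rng = np.random.default_rng([int(seed) % (2 ** 31), 101])
    base = resolve_baselines(config)
    nodes, gw = _gh_rule(config.cluster_sd)

    def draw_eta(law: str, swap: str | None = None) -> np.ndarray:
        eta = np.zeros(n_mc)
        for cov in config.covariates:
            probs = cov.probs_male if (law == "male") != (cov.name == swap) else cov.probs_female
            cum = np.cumsum(probs)
            idx = np.minimum(np.searchsorted(cum, rng.random(n_mc), side="right"),
                             len(cov.categories) - 1)
            eta += np.asarray(cov.effects)[idx]
        return eta

    def mean_p(eta: np.ndarray, sex_off: float) -> tuple[float, float]:
        lp = base[:, None, None] + nodes[None, :, None] + sex_off + eta[None, None, :]
        per_draw = np.einsum("cnp,n->p", expit(lp), gw) / len(base)
        return float(per_draw.mean()), float(per_draw.std(ddof=1) / math.sqrt(n_mc))

    eta_m, eta_f = draw_eta("male"), draw_eta("female")
    off_r = _response_offsets(config, response)
    pA, seA = mean_p(eta_m, config.sex_logodds)
    pB, seB = mean_p(eta_f, 0.0)
    pBA, _ = mean_p(eta_f, config.sex_logodds)
    contributions = {}
    base_resp, se_base = mean_p(eta_f, off_r)
    worst_se = max(seA, seB, se_base)
    for cov in config.covariates:
        swapped, se_s = mean_p(draw_eta("female", swap=cov.name), off_r)
        contributions[cov.name] = swapped - base_resp
        worst_se = max(worst_se, se_s)
    # every reported quantity is a difference of two independent means
    return TruthRecord(pA - pB, pA - pBA, pBA - pB, contributions,
                       response, "mc", math.sqrt(2) * worst_se, asdict(config))


def _truth_matched(config: SimConfig, response: str, n_mc: int,
                   n_orderings: int, seed: int, n_batches: int = 12) -> TruthRecord:
    """Large-sample population value of the rank-matched sequential procedure.

    Each batch draws ``n_mc`` covariate vectors from each sex's law, pairs
    them comonotonically on the true linear risk score (predicted probability
    is monotone in it), and averages sequential-substitution contributions
    over ``n_orderings`` random variable orderings; probabilities are the
    true cluster-marginal ones, evaluated through a dense interpolation grid.
    No model fitting is involved.  Rank coupling makes pairs strongly
    dependent, so the Monte-Carlo error is estimated across ``n_batches``
    independent batches rather than across pairs.
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), 202])
    base = resolve_baselines(config)
    nodes, gw = _gh_rule(config.cluster_sd)
    off = _response_offsets(config, response)
    covs = config.covariates
    k = len(covs)

    lo = sum(min(c.effects) for c in covs) - 0.5
    hi = sum(max(c.effects) for c in covs) + 0.5
    grid = np.linspace(lo, hi, 4001)
    lp = base[:, None, None] + nodes[None, :, None] + off + grid[None, None, :]
    fbar = np.einsum("cng,n->g", expit(lp), gw) / len(base)

    def draw_pieces(law: str) -> list[np.ndarray]:
        pieces = []
        for cov in covs:
            probs = cov.probs_male if law == "male" else cov.probs_female
            cum = np.cumsum(probs)
            idx = np.minimum(np.searchsorted(cum, rng.random(n_mc), side="right"),
                             len(cov.categories) - 1)
            pieces.append(np.asarray(cov.effects)[idx])
        return pieces

    # The ordering-average of sequential contributions is the Shapley value of
    # v(S) = mean F(eta_B + sum_{j in S} (pieceA_j - pieceB_j)); with few
    # covariates all 2^k subsets are enumerated, removing ordering noise.
    fact = [math.factorial(i) for i in range(k + 1)]
    shapley_w = [fact[s] * fact[k - s - 1] / fact[k] for s in range(k)]
    batch_means = np.zeros((n_batches, k))
    for b in range(n_batches):
        pieces_a = draw_pieces("male")
        pieces_b = draw_pieces("female")
        order_a = np.argsort(np.sum(pieces_a, axis=0), kind="stable")
        order_b = np.argsort(np.sum(pieces_b, axis=0), kind="stable")
        delta = [pa[order_a] - pb[order_b] for pa, pb in zip(pieces_a, pieces_b)]
        eta_b = np.sum(pieces_b, axis=0)[order_b]
        v = np.empty(1 << k)
        for mask in range(1 << k):
            eta = eta_b.copy()
            for j in range(k):
                if mask >> j & 1:
                    eta += delta[j]
            v[mask] = float(np.interp(eta, grid, fbar).mean())
        acc = np.zeros(k)
        for mask in range(1 << k):
            s = bin(mask).count("1")
            for j in range(k):
                if not mask >> j & 1:
                    acc[j] += shapley_w[s] * (v[mask | (1 << j)] - v[mask])
        batch_means[b] = acc

    mean = batch_means.mean(axis=0)
    mc_se = float(batch_means.std(axis=0, ddof=1).max() / math.sqrt(n_batches))
    contributions = {c.name: float(mean[j]) for j, c in enumerate(covs)}

    exact = _truth_enumerate(config, response) if _n_patterns(config) <= 200_000 \
        else _truth_mc(config, response, n_mc, seed)
    return TruthRecord(exact.total_gap, exact.explained, exact.unexplained,
                       contributions, response, "matched", mc_se, asdict(config))
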