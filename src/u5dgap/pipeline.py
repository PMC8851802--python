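"""End-to-end orchestration: recode -> SES -> per-country inequality ->
pooled MH/meta statistics -> quadrant table -> VIF screen -> decomposition.

All stage outputs are plain CSV/JSON files in the run directory and are
byte-identical across runs with the same configuration and seed (no
timestamps).  The same machinery drives a summary-only mode that consumes
the packaged country table instead of child-level records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import data_model, inequality_stats as ineq, ses_index, collinearity, fairlie
from .synthetic_data import SimConfig, CovariateSpec, generate, _default_covariates

logger = logging.getLogger(__name__)


def full_covariates() -> tuple[CovariateSpec, ...]:
    """Desk covariates plus the SES-source variables, so every pipeline stage runs."""
    extra = (
        CovariateSpec("media_access", ("yes", "no"),
                      (0.60, 0.40), (0.60, 0.40), (0.0, 0.25)),
        CovariateSpec("maternal_employment", ("employed", "unemployed"),
                      (0.55, 0.45), (0.55, 0.45), (0.0, -0.10)),
        CovariateSpec("wealth_quintile",
                      ("poorest", "poorer", "middle", "richer", "richest"),
                      (0.26, 0.22, 0.20, 0.17, 0.15), (0.26, 0.22, 0.20, 0.17, 0.15),
                      (0.0, -0.05, -0.15, -0.25, -0.45)),
    )
    return _default_covariates() + extra


@dataclass
class RunConfig:
    """One pipeline run.

    ``input_path`` may be a child table, ``"simulate"`` (generate from
    ``sim``), or ``"fixture"`` (summary-only mode on the packaged country
    table).
    """

    out_dir: str
    input_path: str = "simulate"
    codebook_path: str | None = None
    sim: SimConfig | None = None
    covariates: list[str] | None = None
    exclusions: list[str] = field(default_factory=list)
    vif_threshold: float = 2.5
    alpha: float = 0.05
    quadrant_threshold: float | None = None  # default: median country prevalence
    selection_measure: str = "or"  # "or" | "rd"
    D: int = 100
    randomize_ordering: bool = True
    seed: int = 0
    decompose: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            covs = sim.pop("covariates", None)
            if covs == "full":
                sim["covariates"] = full_covariates()
            elif covs == "desk" or covs is None:
                pass
            else:
                sim["covariates"] = tuple(CovariateSpec(**c) for c in covs)
            cfg.sim = SimConfig(**sim)
        return cfg


def select_promale_countries(country_table: pd.DataFrame, alpha: float,
                             measure: str = "or") -> list[str]:
    """Countries with significant excess male mortality.

    With ``measure="or"`` selection requires OR > 1 and its p-value below
    alpha; with ``"rd"`` it uses the risk-difference z-test instead.
    """
    if measure == "or":
        mask = (country_table["odds_ratio"] > 1) & (country_table["or_p"] < alpha)
    elif measure == "rd":
        mask = (country_table["rd"] > 0) & (country_table["rd_p"] < alpha)
    else:
        raise ValueError("measure must be 'or' or 'rd'")
    return sorted(country_table.loc[mask, "country"].tolist())


def _country_stats(tables: list[ineq.TwoByTwo], prevalences: dict[str, float]) -> pd.DataFrame:
    rows = []
    for t in tables:
        rd = ineq.risk_difference(t)
        z, p = ineq.z_test_two_proportions(t)
        lor, vlor = ineq.crude_or(t)
        or_z = lor / np.sqrt(vlor)
        rows.append({
            "country": t.label,
            "prevalence_per_1000": prevalences[t.label],
            "male_rate_per_1000": 1000 * t.male_deaths / t.n_male,
            "female_rate_per_1000": 1000 * t.female_deaths / t.n_female,
            "rd": rd.effect, "rd_ci_low": rd.ci_low, "rd_ci_high": rd.ci_high,
            "rd_var": rd.variance, "rd_z": z, "rd_p": rd.p_value,
            "odds_ratio": float(np.exp(lor)),
            "or_ci_low": float(np.exp(lor - ineq.Z95 * np.sqrt(vlor))),
            "or_ci_high": float(np.exp(lor + ineq.Z95 * np.sqrt(vlor))),
            "or_p": float(2 * stats.norm.sf(abs(or_z))),
        })
    return pd.DataFrame(rows).sort_values("country").reset_index(drop=True)


def _meta_outputs(tables, country_df, out, log):
    rd_estimates = [
        ineq.EffectEstimate(r.rd, r.rd_var, r.rd_ci_low, r.rd_ci_high, r.rd_p,
                            label=r.country)
        for r in country_df.itertuples()
    ]
    meta = ineq.meta_rd(rd_estimates)
    mh = ineq.mh_pooled_or(tables)
    q, df, p, i2 = ineq.or_heterogeneity(tables, "cochran-q")
    bd_q, _, bd_p, bd_i2 = ineq.or_heterogeneity(tables, "breslow-day")
    summary = {
        "mh_or": mh.effect, "mh_or_ci": [mh.ci_low, mh.ci_high], "mh_or_p": mh.p_value,
        "or_heterogeneity": {"Q": q, "df": df, "p": p, "I2_pct": i2},
        "or_heterogeneity_breslow_day": {"Q": bd_q, "p": bd_p, "I2_pct": bd_i2},
        "rd_fixed": meta.fixed_effect.effect,
        "rd_fixed_ci": [meta.fixed_effect.ci_low, meta.fixed_effect.ci_high],
        "rd_random": meta.random_effect.effect,
        "rd_random_ci": [meta.random_effect.ci_low, meta.random_effect.ci_high],
        "rd_Q": meta.Q, "rd_df": meta.df, "rd_I2_pct": meta.I2, "rd_tau2": meta.tau2,
    }
    with open(out / "meta_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    forest = country_df[["country", "rd", "rd_ci_low", "rd_ci_high"]].copy()
    forest["weight_pct"] = [
        float(meta.weights_pct[[e.label for e in meta.estimates].index(c)])
        for c in forest["country"]
    ]
    forest.to_csv(out / "forest_rd.csv", index=False)
    log.append(f"meta: MH OR {mh.effect:.4f}, random RD {meta.random_effect.effect:.3f}")
    return meta


def run_full_analysis(config: RunConfig) -> Path:
    """Run the whole analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed: {config.seed}"]

    if config.input_path == "fixture":
        _run_summary_only(config, out, log)
        _finish(config, out, log)
        return out

    # stage: data
    if config.input_path == "simulate":
        sim = config.sim or SimConfig(covariates=full_covariates(), seed=config.seed)
        records, truth = generate(sim, seed=sim.seed)
        log.append(f"data: simulated {len(records)} children, "
                   f"{records['cluster_id'].nunique()} clusters, "
                   f"{records['country'].nunique()} countries")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump({"total_gap": truth.total_gap, "explained": truth.explained,
                       "unexplained": truth.unexplained,
                       "contributions": truth.contributions}, fh, indent=2, sort_keys=True)
    else:
        mapping = (data_model.CodebookMapping.from_yaml(config.codebook_path)
                   if config.codebook_path else None)
        records, rlog = data_model.read_child_table(config.input_path, mapping)
        log += [f"recode: {line}" for line in rlog.lines()]

    # stage: neighborhood SES
    ses_vars = {"maternal_education", "wealth_quintile", "media_access", "maternal_employment"}
    if ses_vars <= set(records.columns):
        records = ses_index.neighborhood_ses(records)
        scored = ses_index.quintile_cut(ses_index.pca_score(
            ses_index.cluster_proportions(records)))
        profiles = ses_index.cluster_proportions(records).merge(scored, on="cluster_id")
        profiles.to_csv(out / "cluster_ses.csv", index=False)
        log.append(f"ses: scored {len(profiles)} clusters")
    else:
        log.append("ses: skipped (source variables not all present)")

    # stage: per-country inequality
    tables, prevalences = [], {}
    for country, sub in records.groupby("country", sort=True):
        tables.append(ineq.table_from_records(sub, label=str(country)))
        prevalences[str(country)] = ineq.weighted_prevalence(sub)
    country_df = _country_stats(tables, prevalences)
    log.append(f"inequality: {len(tables)} countries")

    # stage: pooled MH / meta
    meta = _meta_outputs(tables, country_df, out, log)

    # stage: quadrants
    threshold = config.quadrant_threshold
    if threshold is None:
        threshold = float(country_df["prevalence_per_1000"].median())
    quad_rows = []
    for r, est in zip(country_df.itertuples(), meta.estimates):
        lab = ineq.quadrant_classify(r.prevalence_per_1000, est, threshold)
        quad_rows.append({"country": lab.country, "prevalence_level": lab.prevalence_level,
                          "inequality": lab.inequality, "significant": lab.significant})
    country_df.to_csv(out / "country_table.csv", index=False)
    pd.DataFrame(quad_rows).to_csv(out / "quadrant_table.csv", index=False)
    log.append(f"quadrants: threshold {threshold:.3f} per 1000")

    # stage: selection + VIF + decomposition
    selected = select_promale_countries(country_df, config.alpha, config.selection_measure)
    log.append(f"selection: {len(selected)} pro-male countries: {', '.join(selected) or '-'}")
    if config.decompose and selected:
        covariates = config.covariates
        if covariates is None:
            covariates = [c for c in records.columns
                          if c in data_model.COVARIATE_CATEGORIES]
        pooled_sel = records[records["country"].isin(selected)]
        pooled_sel, dropped = data_model.complete_cases(pooled_sel, covariates)
        log.append(f"complete cases: dropped {dropped} records")
        report = collinearity.vif_screen(pooled_sel, covariates,
                                         threshold=config.vif_threshold,
                                         exclude=config.exclusions)
        report.to_frame().to_csv(out / "vif_report.csv", index=False)
        log.append(f"vif: kept {len(report.kept)}, dropped {report.dropped or '-'}")
        rng = np.random.default_rng(config.seed)
        for country in selected:
            sub = records[records["country"] == country]
            sub, _ = data_model.complete_cases(sub, report.kept)
            res = fairlie.fairlie_decompose(
                sub, covariates=report.kept, D=config.D,
                randomize_ordering=config.randomize_ordering,
                seed=int(rng.integers(2 ** 31)))
            tab = res.table.copy()
            tab.insert(0, "country", country)
            tab.to_csv(out / f"decomposition_{country}.csv", index=False)
            log.append(f"decompose {country}: gap {1000 * res.total_gap:.2f}/1000, "
                       f"explained {1000 * res.explained:.2f}/1000 (D={res.D})")
    elif config.decompose:
        log.append("decompose: skipped (no pro-male countries selected)")
    else:
        log.append("decompose: disabled")

    _finish(config, out, log)
    return out


def _run_summary_only(config: RunConfig, out: Path, log: list[str]) -> None:
    """Summary-level products from the packaged country table (no microdata)."""
    fx = data_model.load_table1_fixture(country_rows_only=True)
    tables = [ineq.reconstruct_country_table(row) for _, row in fx.iterrows()]
    prevalences = {str(r.country): float(r.u5d_overall) for r in fx.itertuples()}
    country_df = _country_stats(tables, prevalences)
    country_df.to_csv(out / "country_table.csv", index=False)
    meta = _meta_outputs(tables, country_df, out, log)
    threshold = config.quadrant_threshold or float(country_df["prevalence_per_1000"].median())
    quad = []
    for r, est in zip(country_df.itertuples(), meta.estimates):
        lab = ineq.quadrant_classify(r.prevalence_per_1000, est, threshold)
        quad.append({"country": lab.country, "prevalence_level": lab.prevalence_level,
                     "inequality": lab.inequality, "significant": lab.significant})
    pd.DataFrame(quad).to_csv(out / "quadrant_table.csv", index=False)
    selected = select_promale_countries(country_df, config.alpha, config.selection_measure)
    (out / "selected_promale.json").write_text(
        json.dumps({"selected": selected,
                    "published_25": sorted(data_model.PRO_MALE_COUNTRIES),
                    "overlap": sorted(set(selected) & set(data_model.PRO_MALE_COUNTRIES))},
                   indent=2, sort_keys=True), encoding="utf-8")
    log.append(f"summary-only: {len(tables)} countries, {len(selected)} selected pro-male")


def _finish(config: RunConfig, out: Path, log: list[str]) -> None:
    meta = asdict(config)
    meta.pop("out_dir", None)  # keep artifacts byte-identical across run dirs
    meta["sim"] = None if config.sim is None else {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config.sim).items()}
    with open(out / "run_meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    (out / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    for line in log:
        logger.info("%s", line)
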