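"""Neighborhood socioeconomic disadvantage index.

Cluster-level proportions of respondents with no education, household in the
two lowest wealth quintiles, no media access, and unemployed are combined by
the first principal component (on the correlation matrix of the standardized
proportions) into a disadvantage score, oriented so that larger scores mean
more disadvantage, then cut into quintiles (1 = least disadvantaged, 5 =
most disadvantaged) at nearest-rank 20/40/60/80th percentiles with ties
sharing the lower category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_model import MISSING

PROPORTION_COLUMNS = ("prop_no_education", "prop_bottom_two_wealth",
                      "prop_no_media", "prop_unemployed")

_SOURCE = {
    "prop_no_education": ("maternal_education", ("none",)),
    "prop_bottom_two_wealth": ("wealth_quintile", ("poorest", "poorer")),
    "prop_no_media": ("media_access", ("no",)),
    "prop_unemployed": ("maternal_employment", ("unemployed",)),
}


def cluster_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-cluster shares of the four disadvantage indicators.

    Records missing any of the four source variables are excluded from that
    cluster's denominator; a cluster with no usable record raises.
    """
    needed = {var for var, _ in _SOURCE.values()}
    for var in needed:
        if var not in records.columns:
            raise ValueError(f"records lack required variable {var!r}")
    usable = records
    for var in needed:
        usable = usable[usable[var].astype(str) != MISSING]
    counts = usable.groupby("cluster_id").size()
    empty = set(records["cluster_id"].unique()) - set(counts.index)
    if empty:
        raise ValueError(f"clusters with no usable records: {sorted(empty)[:5]}")
    out = pd.DataFrame({"cluster_id": counts.index, "n_respondents": counts.values})
    for col, (var, cats) in _SOURCE.items():
        share = usable.assign(_hit=usable[var].isin(cats)).groupby("cluster_id")["_hit"].mean()
        out[col] = share.reindex(counts.index).values
    return out.reset_index(drop=True)


def pca_score(profiles: pd.DataFrame) -> pd.DataFrame:
    """First-principal-component disadvantage score per cluster.

    Proportions are standardized (z-scored) before extraction, i.e. the
    component comes from their correlation matrix; the score's sign is fixed
    by requiring positive correlation with the mean of the four proportions.
    """
    if len(profiles) < 2:
        raise ValueError("at least two clusters required")
    X = profiles.loc[:, list(PROPORTION_COLUMNS)].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all proportions are constant; index is degenerate")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    scores = PCA(n_components=1).fit_transform(Z)[:, 0]
    orient = np.corrcoef(scores, X.mean(axis=1))[0, 1]
    if orient < 0:
        scores = -scores
    out = profiles[["cluster_id"]].copy()
    out["score"] = scores
    return out


def quintile_cut(scores: pd.DataFrame, column: str = "score") -> pd.DataFrame:
    """Attach quintile labels 1..5 using nearest-rank percentile boundaries.

    Boundaries are the 20/40/60/80th nearest-rank order statistics; a score
    equal to a boundary stays in the lower category, so tied values always
    share a quintile.
    """
    vals = scores[column].to_numpy(float)
    if len(np.unique(vals)) < 5:
        raise ValueError("fewer than 5 distinct scores; quintile cut is degenerate")
    srt = np.sort(vals)
    n = len(srt)
    bounds = [srt[int(np.ceil(q * n)) - 1] for q in (0.2, 0.4, 0.6, 0.8)]
    quint = 1 + np.searchsorted(np.asarray(bounds), vals, side="left")
    # searchsorted(left) puts a value equal to a boundary below it (lower category)
    out = scores.copy()
    out["quintile"] = quint.astype(int)
    return out


def neighborhood_ses(records: pd.DataFrame) -> pd.DataFrame:
    """Compute cluster SES quintiles and attach them to the child records."""
    profiles = cluster_proportions(records)
    scored = quintile_cut(pca_score(profiles))
    merged = records.merge(scored[["cluster_id", "quintile"]], on="cluster_id", how="left")
    merged["neighborhood_ses"] = merged.pop("quintile").astype(int).astype(str)
    return merged
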