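"""Rank correlations and presence/absence contrasts between surveys and maps.

The headline association analysis is a Spearman rank-correlation matrix over
eight variables per location: four survey measures (total cassava area,
its density-weighted variant, monoculture-only and intercrop-only areas)
and four map extractions (production and harvested area from each of two
disaggregation products).  A two-country layout places one country's
coefficients in the upper triangle and the other's in the lower.

The complementary view contrasts map predictions between locations where
cassava was present and absent (five-number summaries per group, with an
optional exploratory rank-sum test).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: canonical column order of the association matrix
DEFAULT_VARIABLES = (
    "tot_cassava_area",
    "tot_cassava_area_w",
    "tot_monoculture_area",
    "tot_intercrop_area",
    "map_production",
    "map_harvest_area",
    "coarse_production",
    "coarse_harvest_area",
)


def spearman_matrix(data: pd.DataFrame, variables=None, min_pairs: int = 5) -> pd.DataFrame:
    """Spearman rank-correlation matrix with pairwise-complete observations.

    Ties receive average ranks.  Constant variables yield missing
    coefficients with a warning; pairs with fewer than ``min_pairs``
    complete rows are likewise missing.
    """
    variables = list(variables) if variables is not None else [c for c in data.columns]
    frame = data[variables].astype(float)
    for v in variables:
        col = frame[v].dropna()
        if col.nunique() <= 1:
            warnings.warn(f"variable {v!r} is constant; its correlations are missing", stacklevel=2)
    k = len(variables)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = frame.iloc[:, [i, j]].dropna()
            if len(pair) < min_pairs:
                continue
            xi, xj = pair.iloc[:, 0], pair.iloc[:, 1]
            if xi.nunique() <= 1 or xj.nunique() <= 1:
                continue
            if i == j:
                out[i, j] = 1.0
                continue
            rho = stats.spearmanr(xi, xj).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=variables, columns=variables)


def two_country_matrix(upper: pd.DataFrame, lower: pd.DataFrame) -> pd.DataFrame:
    """Combine two per-country matrices into one (upper/lower triangle) table."""
    if list(upper.columns) != list(lower.columns):
        raise ValueError("the two matrices must share the same variables in the same order")
    k = len(upper.columns)
    combined = np.full((k, k), np.nan)
    iu = np.triu_indices(k, 1)
    il = np.tril_indices(k, -1)
    combined[iu] = upper.to_numpy()[iu]
    combined[il] = lower.to_numpy()[il]
    return pd.DataFrame(combined, index=upper.columns, columns=upper.columns)


def presence_groups(
    predictions: pd.DataFrame,
    presence,
    rank_test: bool = True,
) -> pd.DataFrame:
    """Five-number summaries of map predictions by cassava presence/absence.

    ``predictions`` holds one column per prediction layer; ``presence`` is a
    boolean vector over the same rows.  An optional Wilcoxon rank-sum
    statistic is attached per layer, labelled exploratory.  If one group is
    empty, summaries for the other are still returned with a warning.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.size != len(predictions):
        raise ValueError("presence vector length must match the prediction table")
    groups = {"present": predictions.loc[presence], "absent": predictions.loc[~presence]}
    empty = [g for g, d in groups.items() if len(d) == 0]
    for g in empty:
        warnings.warn(f"{g} group is empty; summaries reported for the other group only", stacklevel=2)

    rows = []
    for layer in predictions.columns:
        test_p = test_stat = float("nan")
        if rank_test and not empty:
            x = groups["present"][layer].dropna()
            y = groups["absent"][layer].dropna()
            if len(x) and len(y):
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                test_stat, test_p = float(res.statistic), float(res.pvalue)
        for gname, gdata in groups.items():
            vals = gdata[layer].dropna().to_numpy()
            if vals.size == 0:
                continue
            q25, q50, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "layer": layer,
                    "group": gname,
                    "n": int(vals.size),
                    "min": float(vals.min()),
                    "q25": float(q25),
                    "median": float(q50),
                    "q75": float(q75),
                    "max": float(vals.max()),
                    "ranksum_stat_exploratory": test_stat,
                    "ranksum_p_exploratory": test_p,
                }
            )
    return pd.DataFrame(rows)
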