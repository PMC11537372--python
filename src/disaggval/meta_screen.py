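"""Unbalanced-ANOVA screening of information criteria across the model space.

Every fitted model in the factorial search contributes one row: its AIC as
the response and its design factors (linear vs additive model type, cassava
variable type, buffer distance and summary statistic, inclusion and
structure of the population and settlement covariates) as treatments.  The
screen fits the factorial treatment model

    modeltype * (cass_type * population_type * settlement_type
                 + cass_type * cass_dist * cass_summary
                 + population_type / population_dist * population_summary
                 + settlement_type / settlement_dist)

where ``/`` denotes nesting (distance and summary factors only vary within
models that include the covariate).  Because the design is unbalanced and
partially confounded, type-II F statistics are computed by
marginality-respecting model comparison: the sum of squares for a term is
the RSS drop from adding it to the model containing every term that does
not contain it.  Wholly aliased terms are reported as dropped rather than
silently omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats

logger = logging.getLogger(__name__)

#: Treatment model for the AIC screen.
DEFAULT_FORMULA = (
    "modeltype * (cass_type * population_type * settlement_type"
    " + cass_type * cass_dist * cass_summary"
    " + population_type / population_dist * population_summary"
    " + settlement_type / settlement_dist)"
)


#: Nesting structure of the screening factors: distance and summary factors
#: only vary within models that include the covariate, so for marginality
#: purposes any term involving them implicitly contains the inclusion factor.
DEFAULT_NESTING = {
    "population_dist": "population_type",
    "population_summary": "population_type",
    "settlement_dist": "settlement_type",
}


@dataclass
class AnovaResult:
    term: str
    df: int
    sum_sq: float
    F: float
    p_value: float


def assemble_screen_table(results) -> pd.DataFrame:
    """One screening row per converged fitted model.

    Accepts a list of ``FitResult`` or the results table from
    :func:`disaggval.model_search.results_frame`.  Distances become
    categorical labels ("0km", "2km", ...); absent covariates are coded with
    type = excluded and a single "none" level for their nested distance and
    summary factors.
    """
    from .model_search import results_frame

    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        frame = results_frame(results)
    frame = frame[frame["converged"]].reset_index(drop=True)
    if len(frame) < 2:
        raise ValueError("screening requires at least two converged models")

    def dist_label(d):
        return "none" if pd.isna(d) else f"{int(d)}km"

    table = pd.DataFrame(
        {
            "AIC": frame["AIC"].astype(float),
            "modeltype": frame["modeltype"],
            "cass_type": frame["cass_type"],
            "cass_dist": frame["cass_dist"].map(dist_label),
            "cass_summary": frame["cass_summary"],
            "population_type": frame["population_type"],
            "population_dist": frame["population_dist"].map(dist_label),
            "population_summary": frame["population_summary"].replace("", "none"),
            "settlement_type": frame["settlement_type"],
            "settlement_dist": frame["settlement_dist"].map(dist_label),
        }
    )
    factor_cols = [c for c in table.columns if c != "AIC"]
    if all(table[c].nunique() == 1 for c in factor_cols):
        raise ValueError("all screening factors are constant; no contrasts to test")
    return table


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of a (possibly deficient) design."""
    if X.shape[1] == 0:
        return float(y @ y), 0
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def type2_screen(
    table: pd.DataFrame,
    formula: str = DEFAULT_FORMULA,
    nesting: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Type-II F statistics for every term of the treatment model.

    ``nesting`` maps a nested factor to the factor it is nested within
    (default: the screening factors' structure); terms involving a nested
    factor are treated as containing its parent when deciding which terms a
    comparison model may keep.  Returns a table with one row per estimable
    term plus a ``Residual`` row; wholly aliased terms appear with df = 0
    and missing statistics.
    """
    if nesting is None:
        nesting = DEFAULT_NESTING
    y = table["AIC"].to_numpy(dtype=float)
    design = patsy.dmatrix(formula, table, return_type="dataframe")
    info = design.design_info
    X_full = design.to_numpy()
    n = X_full.shape[0]

    rss_full, rank_full = _rss(X_full, y)
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValueError("screening design leaves no residual degrees of freedom")
    s2 = rss_full / df_resid

    terms = [t for t in info.terms if t.name() != "Intercept"]
    term_cols = {t: list(range(*info.term_slices[t].indices(X_full.shape[1]))) for t in info.terms}

    def closure(term) -> set[str]:
        names = {f.name() for f in term.factors}
        return names | {nesting[n] for n in names if n in nesting}

    rows = []
    for term in terms:
        fset = closure(term)
        # marginality: the comparison model contains every term that does not
        # strictly contain this one (nested factors carry their parent)
        keep = [t for t in info.terms if t is not term and not fset < closure(t)]
        cols_without = sorted(c for t in keep for c in term_cols[t])
        cols_with = sorted(cols_without + term_cols[term])
        rss0, rank0 = _rss(X_full[:, cols_without], y)
        rss1, rank1 = _rss(X_full[:, cols_with], y)
        df_term = rank1 - rank0
        if df_term == 0:
            logger.info("term %s is wholly aliased and was dropped from the screen", term.name())
            rows.append({"term": term.name(), "df": 0, "sum_sq": float("nan"), "F": float("nan"), "p_value": float("nan")})
            continue
        ss = max(rss0 - rss1, 0.0)
        F = (ss / df_term) / s2
        p = float(stats.f.sf(F, df_term, df_resid))
        rows.append({"term": term.name(), "df": df_term, "sum_sq": ss, "F": F, "p_value": p})

    rows.append({"term": "Residual", "df": df_resid, "sum_sq": rss_full, "F": float("nan"), "p_value": float("nan")})
    return pd.DataFrame(rows)
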