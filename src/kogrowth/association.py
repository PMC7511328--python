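"""Growth-expression association: Spearman correlation and randomization null.

Joins each knockout strain's mean exponential rate with the wild-type
expression level of the deleted gene, then quantifies the relationship at
the gene level (Spearman with a column-shuffling randomization null) and at
the functional-category level (across category means, and within each
sufficiently large category).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

__all__ = [
    "join_growth_expression",
    "spearman_growth_expression",
    "randomization_test",
    "RandomizationResult",
    "category_level_correlation",
]

logger = logging.getLogger(__name__)


def join_growth_expression(
    rate_table: pd.DataFrame,
    expression_table: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Inner join of knockout rates and wild-type expression on gene id.

    One row per gene x medium with ``gene, medium, mu_mean, expr_mean,
    category``.  Strain ids in the rate table are gene ids (one knockout per
    gene).  Unmatched ids on either side are logged, not errors; duplicated
    gene ids are errors.
    """
    for name, frame, col in (
        ("rate table", rate_table, "strain"),
        ("expression table", expression_table, "gene"),
    ):
        dup = frame.groupby([col, "medium"]).size()
        dup = dup[dup > 1]
        if len(dup):
            raise UndefinedStatisticError(
                f"duplicate id in {name}: {dup.index[0][0]!r}"
            )
    rates = rate_table.rename(columns={"strain": "gene"})[["gene", "medium", "mu_mean", "max_od_mean"]]
    expr = expression_table[["gene", "medium", "mean"]].rename(columns={"mean": "expr_mean"})
    joined = rates.merge(expr, on=["gene", "medium"], how="inner")
    if len(joined) == 0:
        raise UndefinedStatisticError("no genes shared between rates and expression")
    cats = annotation.set_index("gene")["category"]
    joined["category"] = joined["gene"].map(cats)
    n_rate_only = len(set(zip(rates["gene"], rates["medium"])) - set(zip(joined["gene"], joined["medium"])))
    n_expr_only = len(set(zip(expr["gene"], expr["medium"])) - set(zip(joined["gene"], joined["medium"])))
    logger.info(
        "join_growth_expression: %d rows, %d rate-only, %d expression-only",
        len(joined), n_rate_only, n_expr_only,
    )
    return joined


def _medium_slice(join: pd.DataFrame, medium: str) -> pd.DataFrame:
    sub = join[join["medium"] == medium]
    if len(sub) == 0:
        raise UndefinedStatisticError(f"no rows for medium {medium!r}")
    return sub


def spearman_growth_expression(join: pd.DataFrame, medium: str) -> tuple[float, float]:
    """Spearman correlation (tie-corrected p) of rate vs expression."""
    sub = _medium_slice(join, medium)
    if len(sub) < 3:
        raise UndefinedStatisticError("need >= 3 rows for a correlation")
    x = sub["expr_mean"].to_numpy()
    y = sub["mu_mean"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant column: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RandomizationResult:
    observed_rho: float
    n_shuffles: int
    null_rho: dict[str, np.ndarray] = field(default_factory=dict)
    empirical_p: dict[str, float] = field(default_factory=dict)


def randomization_test(
    join: pd.DataFrame,
    medium: str,
    n_shuffles: int = 1000,
    seed: int = 0,
    columns: tuple[str, ...] = ("mu_mean", "expr_mean"),
) -> RandomizationResult:
    """Column-shuffling null for the growth-expression correlation.

    Each named column is shuffled independently ``n_shuffles`` times (its
    own seed stream) and the Spearman correlation recomputed; the two-sided
    empirical p uses the add-one convention
    ``(#{|rho_null| >= |rho_obs|} + 1) / (n_shuffles + 1)``, which can never
    report an exact zero.
    """
    import warnings as _warnings

    if n_shuffles < 100:
        _warnings.warn("n_shuffles < 100 gives a coarse null")
    sub = _medium_slice(join, medium)
    if len(sub) < 10:
        raise UndefinedStatisticError("need >= 10 rows for a randomization test")
    obs, _ = spearman_growth_expression(join, medium)
    x = sub["expr_mean"].to_numpy()
    y = sub["mu_mean"].to_numpy()
    result = RandomizationResult(observed_rho=obs, n_shuffles=n_shuffles)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    for col_idx, col in enumerate(columns):
        rng = np.random.default_rng([seed, col_idx])
        shuffled_ranks = ry if col == "mu_mean" else rx
        fixed_ranks = rx if col == "mu_mean" else ry
        nulls = np.empty(n_shuffles)
        fc = fixed_ranks - fixed_ranks.mean()
        fden = np.sqrt((fc**2).sum())
        for s in range(n_shuffles):
            perm = rng.permutation(shuffled_ranks)
            pc = perm - perm.mean()
            nulls[s] = float((fc * pc).sum() / (fden * np.sqrt((pc**2).sum())))
        result.null_rho[col] = nulls
        result.empirical_p[col] = float(
            (np.sum(np.abs(nulls) >= abs(obs)) + 1) / (n_shuffles + 1)
        )
    return result


def category_level_correlation(
    join: pd.DataFrame, medium: str, min_genes: int = 30
) -> dict:
    """Category-mean correlation and the within-category correlations.

    Categories with more than ``min_genes`` genes are retained; their mean
    rate and mean expression correlate across categories (Spearman), and the
    gene-level Spearman is reported within each retained category.
    """
    sub = _medium_slice(join, medium)
    sizes = sub.groupby("category").size()
    kept = sizes[sizes > min_genes].index
    if len(kept) == 0:
        raise UndefinedStatisticError(
            f"no category exceeds min_genes={min_genes}"
        )
    means = (
        sub[sub["category"].isin(kept)]
        .groupby("category")
        .agg(mu_mean=("mu_mean", "mean"), expr_mean=("expr_mean", "mean"),
             n_genes=("gene", "size"))
        .reset_index()
    )
    if len(means) >= 3:
        rho, p = stats.spearmanr(means["expr_mean"], means["mu_mean"])
        across = (float(rho), float(p))
    else:
        across = (float("nan"), float("nan"))
    within_rows = []
    for cat in kept:
        grp = sub[sub["category"] == cat]
        rho_c, p_c = stats.spearmanr(grp["expr_mean"], grp["mu_mean"])
        within_rows.append(
            {"category": cat, "n_genes": len(grp), "rho": float(rho_c), "p": float(p_c)}
        )
    return {
        "category_means": means,
        "across_rho": across[0],
        "across_p": across[1],
        "within": pd.DataFrame(within_rows),
    }
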