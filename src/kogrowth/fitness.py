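"""Five-class fitness assignment and functional-category enrichment.

A knockout strain's exponential rate is placed against the box-and-whisker
fences of the per-medium rate distribution (Q1/Q3 quartiles, 1.5*IQR
fences).  Class semantics invert the rate: a strain that grows *faster*
without its gene reveals a gene with a *negative* growth contribution, so
rates above the upper fence map to ``very_negative`` and rates below the
lower fence to ``very_positive``.

Category enrichment of any selected gene set is a one-sided binomial test
per flat functional-category code, Bonferroni-corrected over the categories
tested.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

__all__ = [
    "CLASSES",
    "classify_genes",
    "binomial_enrichment",
    "class_overlap",
    "reevaluate_by_replicates",
]

CLASSES = ("very_negative", "negative", "neutral", "positive", "very_positive")


def classify_genes(rate_table: pd.DataFrame, medium: str) -> pd.DataFrame:
    """Assign each strain's missing gene to one of the five fitness classes.

    Quartiles use linear interpolation (the common "type 7" convention).
    Boundary values are inclusive toward the inner class: a rate exactly at a
    quartile is neutral, exactly at a fence is negative/positive.  Returns a
    frame with ``strain, medium, mu_mean, fitness_class`` and the quartiles
    and fences in ``attrs``.
    """
    sub = rate_table[rate_table["medium"] == medium]
    if len(sub) == 0:
        raise UndefinedStatisticError(f"no rates for medium {medium!r}")
    if len(sub) < 5:
        raise UndefinedStatisticError("need >= 5 strains to place quartile fences")
    r = sub["mu_mean"].to_numpy(dtype=float)
    q1, q3 = np.quantile(r, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr

    cls = np.full(r.size, "neutral", dtype=object)
    cls[(r > q3) & (r <= hi_fence)] = "negative"
    cls[r > hi_fence] = "very_negative"
    cls[(r < q1) & (r >= lo_fence)] = "positive"
    cls[r < lo_fence] = "very_positive"

    out = pd.DataFrame(
        {
            "strain": sub["strain"].to_numpy(),
            "medium": medium,
            "mu_mean": r,
            "fitness_class": cls,
        }
    )
    out.attrs.update(
        {"q1": float(q1), "q3": float(q3),
         "lower_fence": float(lo_fence), "upper_fence": float(hi_fence)}
    )
    return out


def binomial_enrichment(
    selected: Iterable[str],
    annotation: pd.DataFrame,
    background: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-sided (over-representation) binomial enrichment per category.

    With ``M`` background genes of which ``m`` carry the category, and ``x``
    of the ``n`` selected genes carrying it, ``p = P(X >= x)`` for
    ``X ~ Binomial(n, m/M)``; Bonferroni multiplies by the number of
    categories tested.  ``background`` defaults to the full annotation;
    pass the non-essential subset when the selection was drawn from the
    knockout library.
    """
    if background is None:
        background = annotation
    selected = set(selected)
    bg_genes = set(background["gene"])
    stray = selected - bg_genes
    if stray:
        raise UndefinedStatisticError(
            f"{len(stray)} selected genes missing from the background"
        )
    cat_of = dict(zip(background["gene"], background["category"]))
    big_m = len(bg_genes)
    n = len(selected)
    rows = []
    categories = sorted(background["category"].unique())
    for cat in categories:
        m = sum(1 for g in bg_genes if cat_of[g] == cat)
        if m == 0:
            warnings.warn(f"category {cat!r} absent from background; skipped")
            continue
        x = sum(1 for g in selected if cat_of[g] == cat)
        p = float(stats.binom.sf(x - 1, n, m / big_m)) if n > 0 else 1.0
        rows.append({"category": cat, "m": m, "x": x, "n": n, "M": big_m, "p": p})
    res = pd.DataFrame(rows)
    res["p_bonferroni"] = np.minimum(1.0, res["p"] * len(res))
    return res.sort_values("p", kind="stable").reset_index(drop=True)


def class_overlap(
    assignments_a: pd.DataFrame, assignments_b: pd.DataFrame, fitness_class: str
) -> dict:
    """Venn counts of one fitness class between two media.

    Returns ``{'only_a', 'only_b', 'both'}`` counts plus the gene lists.
    """
    set_a = set(assignments_a.loc[assignments_a["fitness_class"] == fitness_class, "strain"])
    set_b = set(assignments_b.loc[assignments_b["fitness_class"] == fitness_class, "strain"])
    return {
        "only_a": len(set_a - set_b),
        "only_b": len(set_b - set_a),
        "both": len(set_a & set_b),
        "genes_only_a": sorted(set_a - set_b),
        "genes_only_b": sorted(set_b - set_a),
        "genes_both": sorted(set_a & set_b),
    }


def reevaluate_by_replicates(
    assignments: pd.DataFrame,
    replicate_estimates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Demote non-neutral calls whose replicates cannot reject the median.

    For each non-neutral strain, a two-sided one-sample t-test of its
    replicate rates against the medium's median rate must reject at
    ``alpha``; otherwise the call demotes to neutral.  Strains with fewer
    than two replicates are exempt (flagged, never demoted).

    ``replicate_estimates`` is the frame from
    :func:`kogrowth.growth.estimates_frame`.
    """
    medium = assignments["medium"].iloc[0]
    median_rate = float(np.median(assignments["mu_mean"]))
    reps = replicate_estimates[
        (replicate_estimates["medium"] == medium) & (~replicate_estimates["no_growth"])
    ]
    out = assignments.copy()
    out["reevaluated_class"] = out["fitness_class"]
    out["demoted"] = False
    out["exempt"] = False
    for i, row in out.iterrows():
        if row["fitness_class"] == "neutral":
            continue
        mus = reps.loc[reps["strain"] == row["strain"], "mu"].to_numpy()
        if mus.size < 2:
            out.at[i, "exempt"] = True
            continue
        if np.ptp(mus) == 0:
            # degenerate: identical replicates reject iff they differ from the median
            reject = mus[0] != median_rate
        else:
            _, p = stats.ttest_1samp(mus, median_rate)
            reject = p < alpha
        if not reject:
            out.at[i, "reevaluated_class"] = "neutral"
            out.at[i, "demoted"] = True
    return out
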