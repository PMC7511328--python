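"""Global normalization and rank-product differential analysis.

Expression tables from different media are brought to a common median
(log10 RPKM) by a per-dataset additive shift.  Differential items between
two media — differentially expressed genes (DEGs) on expression, strains
with differentiated growth rates (DGGs) on replicate growth rates — are
called with the rank product: in every cross-media replicate pair the items
are ranked by fold difference, the per-item geometric mean of ranks is the
statistic, and significance comes from a permutation null built by
shuffling the raw replicate columns across genes.  The native false-discovery
measure is the proportion of false positives (pfp); Benjamini-Hochberg on
the permutation p-values is reported alongside.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedStatisticError

__all__ = [
    "global_normalize",
    "rank_product",
    "identify_significant",
    "deg_dgg_overlap",
]


def global_normalize(tables: Sequence[pd.DataFrame]) -> list[pd.DataFrame]:
    """Shift each dataset so all medians meet at the mean of input medians.

    The shift is a constant per dataset, so within-dataset rank order is
    untouched.  Genes whose replicate values are all missing are dropped
    with a warning.  The per-gene ``mean`` column is recomputed.
    """
    rep_cols = [
        [c for c in t.columns if c.startswith("rep")] for t in tables
    ]
    medians = [
        float(np.nanmedian(t[cols].to_numpy(dtype=float)))
        for t, cols in zip(tables, rep_cols)
    ]
    target = float(np.mean(medians))
    out = []
    for t, cols, med in zip(tables, rep_cols, medians):
        t = t.copy()
        all_missing = t[cols].isna().all(axis=1)
        if all_missing.any():
            warnings.warn(
                f"dropping {int(all_missing.sum())} genes with no finite value"
            )
            t = t[~all_missing].reset_index(drop=True)
        t[cols] = t[cols] + (target - med)
        t["mean"] = t[cols].mean(axis=1)
        t.attrs["normalization_shift"] = target - med
        out.append(t)
    return out


def _geo_mean_ranks(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.log(ranks).mean(axis=-1))


def _pair_diffs(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """All R_A x R_B cross-condition fold differences, shape (G, R_A*R_B)."""
    n_items = values_a.shape[0]
    return (values_a[:, :, None] - values_b[:, None, :]).reshape(n_items, -1)


def _shuffle_columns(
    values: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, G, R): each raw replicate column permuted across items."""
    n_items, n_rep = values.shape
    keys = rng.random((n_perm, n_items, n_rep))
    order = np.argsort(keys, axis=1)
    return np.take_along_axis(
        np.broadcast_to(values, (n_perm, n_items, n_rep)), order, axis=1
    )


def _null_rps(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Null RP pools for both directions.

    Each permutation shuffles every *raw replicate column* independently
    across items and recomputes the fold-difference ranks.  Shuffling the
    derived comparison columns instead would decouple columns that share a
    replicate and understate how extreme a null RP can be; permuting at the
    replicate level keeps that coupling, which is what makes the null
    p-values uniform under no effect.
    """
    n_items = values_a.shape[0]
    up_a, up_b = [], []
    done = 0
    while done < n_perm:
        nb = min(batch, n_perm - done)
        pa = _shuffle_columns(values_a, nb, rng)
        pb = _shuffle_columns(values_b, nb, rng)
        diffs = (pa[:, :, :, None] - pb[:, :, None, :]).reshape(nb, n_items, -1)
        ranks_desc = rankdata(-diffs, axis=1, method="average")
        up_a.append(_geo_mean_ranks(ranks_desc).ravel())
        ranks_asc = rankdata(diffs, axis=1, method="average")
        up_b.append(_geo_mean_ranks(ranks_asc).ravel())
        done += nb
    return np.concatenate(up_a), np.concatenate(up_b)


def _direction_stats(
    diffs: np.ndarray, sign: float, null: np.ndarray, n_perm: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RP, permutation p and pfp for one direction (sign=+1: up in A)."""
    # rank 1 = strongest change in this direction; mid-rank on ties
    ranks = rankdata(-sign * diffs, axis=0, method="average")
    rp = _geo_mean_ranks(ranks)
    null = np.sort(null)
    c = np.searchsorted(null, rp, side="right")  # null RPs <= observed
    p = (c + 1.0) / (null.size + 1.0)
    expected_fp = c / n_perm
    order_rank = rankdata(rp, method="average")
    pfp = expected_fp / order_rank
    # enforce monotone q in p (step-up style)
    idx = np.argsort(p, kind="stable")
    pfp_sorted = np.maximum.accumulate(pfp[idx])
    pfp_mono = np.empty_like(pfp)
    pfp_mono[idx] = pfp_sorted
    return rp, p, pfp_mono


def rank_product(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-direction rank-product test between conditions A and B.

    ``values_a`` (G x R_A) and ``values_b`` (G x R_B) hold per-replicate
    values on a log-like scale (log10 RPKM, or growth rates in h^-1).  The
    comparison columns are all R_A x R_B unpaired replicate pairs with fold
    difference A - B.  Per direction, the permutation p-value of item g is
    ``(#{null RP <= RP_g} + 1) / (n_perm * G + 1)``, with the null drawn by
    permuting each raw replicate column across items (see ``_null_rps``).

    Returns a frame with one row per item and direction:
    ``id, direction, rp, p, pfp_q, bh_q``.
    """
    values_a = np.atleast_2d(np.asarray(values_a, dtype=float))
    values_b = np.atleast_2d(np.asarray(values_b, dtype=float))
    n_items = values_a.shape[0]
    if values_b.shape[0] != n_items:
        raise UndefinedStatisticError("A and B cover different item sets")
    if n_items < 2:
        raise UndefinedStatisticError("rank product needs >= 2 items")
    if values_a.shape[1] == 0 or values_b.shape[1] == 0:
        raise UndefinedStatisticError("zero replicate columns")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation null")
    if ids is None:
        ids = [str(i) for i in range(n_items)]

    # all cross-media replicate pairs as comparison columns
    diffs = _pair_diffs(values_a, values_b)
    rng = np.random.default_rng(seed)
    null_a, null_b = _null_rps(values_a, values_b, n_perm, rng)
    frames = []
    for direction, sign, null in (("up_in_A", 1.0, null_a), ("up_in_B", -1.0, null_b)):
        rp, p, pfp = _direction_stats(diffs, sign, null, n_perm)
        bh = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {"id": list(ids), "direction": direction,
                 "rp": rp, "p": p, "pfp_q": pfp, "bh_q": bh}
            )
        )
    return pd.concat(frames, ignore_index=True)


def identify_significant(
    results: pd.DataFrame, q_threshold: float = 0.05, q_col: str = "pfp_q"
) -> dict[str, set[str]]:
    """Items below the FDR threshold, per direction and as a union."""
    out: dict[str, set[str]] = {}
    for direction, grp in results.groupby("direction"):
        out[direction] = set(grp.loc[grp[q_col] < q_threshold, "id"])
    out["union"] = set().union(*out.values()) if out else set()
    return out


def deg_dgg_overlap(
    degs: set[str],
    dggs: set[str],
    deg_universe: set[str],
    dgg_universe: set[str],
    features: dict[str, pd.Series] | None = None,
) -> dict:
    """Venn counts of DEGs vs DGGs plus a per-gene feature table.

    The two calls must share a gene universe.  ``features`` maps column
    names to per-gene Series (expression means, growth means, fitness
    classes...) joined onto the union of called genes.
    """
    shared = deg_universe & dgg_universe
    if not shared:
        raise UndefinedStatisticError("DEG and DGG universes are disjoint")
    degs = degs & shared
    dggs = dggs & shared
    union = sorted(degs | dggs)
    table = pd.DataFrame(
        {
            "gene": union,
            "is_deg": [g in degs for g in union],
            "is_dgg": [g in dggs for g in union],
        }
    ).set_index("gene")
    if features:
        for name, series in features.items():
            table[name] = series.reindex(table.index)
    return {
        "deg_only": len(degs - dggs),
        "dgg_only": len(dggs - degs),
        "both": len(degs & dggs),
        "table": table.reset_index(),
    }
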