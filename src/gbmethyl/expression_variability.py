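"""Expression-level ranks and coefficient-of-variation statistics.

CV = sample SD (n-1 denominator) / mean of TPM across replicates within
one tissue and species; it is undefined (NaN, flagged) for genes with mean
TPM 0.  Expression ranks (quintiles/octiles) are equal-count bins of the
per-gene mean TPM across replicates.  The methylation rank places
completely unmethylated genes (gene-body mean exactly 0 over retained
CpGs) at rank 0 and splits the remaining genes into deciles 1..10; genes
without sufficient CpG data are excluded rather than placed at rank 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def compute_cv(tpm: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene mean TPM and CV across replicate columns.

    ``tpm`` is genes x replicates, indexed by gene id, with >= 2 replicate
    columns of finite, non-negative TPM values.
    """
    if tpm.shape[1] < 2:
        raise ValueError("CV needs at least two replicates")
    values = tpm.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("TPM values must be finite and non-negative")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return pd.DataFrame(
        {"gene_id": tpm.index, "mean_tpm": mean, "cv": cv, "cv_defined": mean > 0}
    ).reset_index(drop=True)


def expression_ranks(mean_tpm: pd.Series, k: int = 5) -> pd.Series:
    """Equal-count expression bins 1..k by mean TPM (1 = lowest).

    Ties are broken deterministically by gene id order; bin sizes differ by
    at most one.  Raises with fewer genes than bins.
    """
    n = len(mean_tpm)
    if n < k:
        raise ValueError(f"cannot form {k} ranks from {n} genes")
    order = np.lexsort((np.asarray(mean_tpm.index), mean_tpm.to_numpy()))
    ranks = np.empty(n, dtype=int)
    # split sorted genes into k contiguous chunks, sizes differing by <= 1
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    for b in range(k):
        ranks[order[bounds[b] : bounds[b + 1]]] = b + 1
    return pd.Series(ranks, index=mean_tpm.index, name=f"rank_{k}")


def methylation_rank(summaries: pd.DataFrame, n_deciles: int = 10) -> pd.Series:
    """Methylation rank 0..10 per gene.

    Rank 0: completely unmethylated genes (mean ratio exactly 0).  Ranks
    1..10: deciles of gene-body mean among the remaining genes.  Genes with
    class 'insufficient' or NaN mean are excluded from the result.
    """
    ok = summaries[
        (summaries["meth_class"] != "insufficient") & summaries["mean_ratio"].notna()
    ]
    rank = pd.Series(index=ok["gene_id"].to_numpy(), dtype=float, name="meth_rank")
    zero = ok["mean_ratio"] == 0.0
    rank[ok.loc[zero, "gene_id"].to_numpy()] = 0
    rest = ok[~zero]
    if len(rest):
        deciles = pd.qcut(
            rest["mean_ratio"].rank(method="first"), n_deciles, labels=False
        ) + 1
        rank[rest["gene_id"].to_numpy()] = deciles.to_numpy()
    return rank.astype(int)


def cv_by_methylation(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Summaries of CV per methylation rank and the rank-CV trend.

    ``records`` needs columns meth_rank and cv (one row per gene).  Returns
    a per-rank table (median, IQR, n) plus a trend dict with Spearman rho
    and p computed over genes (rank vs CV); the trend is flagged undefined
    with fewer than two occupied ranks.
    """
    ok = records.dropna(subset=["meth_rank", "cv"])
    per_rank = (
        ok.groupby("meth_rank")["cv"]
        .agg(
            median_cv="median",
            iqr_cv=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
            n="size",
        )
        .reset_index()
    )
    if per_rank["meth_rank"].nunique() < 2:
        trend = {"rho": np.nan, "p_value": np.nan, "defined": False}
    else:
        rho, p = stats.spearmanr(ok["meth_rank"], ok["cv"])
        trend = {"rho": float(rho), "p_value": float(p), "defined": True}
    return per_rank, trend


def expression_methylation_profile(
    expr_rank: pd.Series, summaries: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Methylation distribution per expression rank plus a quadratic trend.

    Fits mean methylation ~ a + b*rank + c*rank^2 over genes and reports
    the curvature sign; a negative curvature is the inverted-U (parabolic)
    coupling where the extreme expression ranks are undermethylated.
    """
    df = summaries.merge(
        expr_rank.rename("expr_rank"), left_on="gene_id", right_index=True
    )
    df = df[(df["meth_class"] != "insufficient") & df["mean_ratio"].notna()]
    per_rank = (
        df.groupby("expr_rank")["mean_ratio"]
        .agg(mean_meth="mean", median_meth="median", n="size")
        .reset_index()
    )
    if per_rank["expr_rank"].nunique() < 3:
        fit = {"curvature": np.nan, "vertex": np.nan, "defined": False}
    else:
        c2, c1, _c0 = np.polyfit(
            df["expr_rank"].to_numpy(float), df["mean_ratio"].to_numpy(float), 2
        )
        fit = {
            "curvature": float(c2),
            "vertex": float(-c1 / (2 * c2)) if c2 != 0 else np.nan,
            "defined": True,
        }
    return per_rank, fit


def variability_table(
    tpm: pd.DataFrame,
    summaries: pd.DataFrame,
    k_expr: int = 5,
) -> pd.DataFrame:
    """Join CV, expression rank and methylation rank into one gene table."""
    cv = compute_cv(tpm)
    cv["expr_rank"] = expression_ranks(
        cv.set_index("gene_id")["mean_tpm"], k_expr
    ).to_numpy()
    defined = cv["cv_defined"]
    quint = np.full(len(cv), np.nan)
    if defined.sum() >= 5:
        quint[defined.to_numpy()] = (
            pd.qcut(cv.loc[defined, "cv"].rank(method="first"), 5, labels=False) + 1
        )
    cv["cv_quintile"] = quint
    mrank = methylation_rank(summaries)
    out = cv.merge(
        mrank.rename("meth_rank"), left_on="gene_id", right_index=True, how="left"
    ).merge(summaries[["gene_id", "mean_ratio", "meth_class"]], on="gene_id", how="left")
    return out
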