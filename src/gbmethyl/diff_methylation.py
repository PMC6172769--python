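"""Per-gene differential methylation.

Between tissues: per shared CpG position the mean ratio of each sample
group is computed and the paired per-position differences feed a Wilcoxon
signed-rank test (p cutoff 0.1, no multiple-testing correction by default,
matching common practice for this kind of screen; Benjamini-Hochberg is
available as an option).  An unpaired rank-sum variant over the pooled
per-position values is available behind a flag.

Between species: a gene is differentially methylated when the absolute
difference of its gene-body means exceeds 0.1 (strict inequality); the
sign of the difference is recorded so directional summaries (which species
is more methylated) can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TISSUE_P_CUTOFF = 0.1
SPECIES_DELTA = 0.1
MIN_SHARED_CPGS = 5


@dataclass
class DMGResult:
    gene_id: str
    mean_a: float
    mean_b: float
    delta: float  # mean_a - mean_b
    statistic: Optional[float]
    p_value: Optional[float]
    significant: bool
    note: str = ""


def _signed_rank(diff: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank on paired differences.

    Zero differences are dropped; the exact null distribution is used up to
    n = 25 (no ties), otherwise the normal approximation with continuity
    correction and average ranks.
    """
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        return np.nan, 1.0
    ties = len(np.unique(np.abs(diff))) < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        diff, zero_method="wilcox", correction=True, alternative="two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def tissue_dmg_test(
    gene_id: str,
    ratios: pd.DataFrame,
    groups: Mapping[str, str],
    p_cutoff: float = TISSUE_P_CUTOFF,
    min_shared: int = MIN_SHARED_CPGS,
    paired: bool = True,
) -> DMGResult:
    """Test one gene for differential methylation between two tissue groups.

    ``ratios`` is a CpG-position x sample table of methylation ratios for
    the gene, restricted by the caller to positions retained in every
    sample (rows with any NaN are dropped here).  ``groups`` maps sample
    name to one of exactly two group labels.

    With ``paired=True`` (default) per-position group means are formed and
    their paired differences tested by Wilcoxon signed-rank; with
    ``paired=False`` the per-position group means are compared by the
    unpaired Mann-Whitney rank-sum test.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a_cols = [s for s in ratios.columns if groups.get(s) == labels[0]]
    b_cols = [s for s in ratios.columns if groups.get(s) == labels[1]]
    if not a_cols or not b_cols:
        raise ValueError("each group needs at least one sample")
    shared = ratios.dropna()
    mean_per_pos_a = shared[a_cols].mean(axis=1).to_numpy()
    mean_per_pos_b = shared[b_cols].mean(axis=1).to_numpy()
    mean_a = float(mean_per_pos_a.mean()) if len(shared) else np.nan
    mean_b = float(mean_per_pos_b.mean()) if len(shared) else np.nan
    delta = mean_a - mean_b
    if len(shared) < min_shared:
        return DMGResult(gene_id, mean_a, mean_b, delta, None, None, False, "underpowered")
    if paired:
        stat, p = _signed_rank(mean_per_pos_a - mean_per_pos_b)
        if np.isnan(stat):  # all differences exactly zero
            return DMGResult(gene_id, mean_a, mean_b, delta, None, 1.0, False, "no_nonzero_diff")
    else:
        res = stats.mannwhitneyu(mean_per_pos_a, mean_per_pos_b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return DMGResult(gene_id, mean_a, mean_b, delta, stat, p, bool(p < p_cutoff))


def tissue_dmg_table(
    gene_ratio_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    p_cutoff: float = TISSUE_P_CUTOFF,
    min_shared: int = MIN_SHARED_CPGS,
    paired: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run :func:`tissue_dmg_test` over many genes; optional BH correction."""
    rows = [
        tissue_dmg_test(gid, tab, groups, p_cutoff, min_shared, paired)
        for gid, tab in gene_ratio_tables.items()
    ]
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "mean_a": [r.mean_a for r in rows],
            "mean_b": [r.mean_b for r in rows],
            "delta": [r.delta for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "significant": [r.significant for r in rows],
            "note": [r.note for r in rows],
        }
    )
    if fdr:
        tested = df["p_value"].notna()
        q = np.full(len(df), np.nan)
        if tested.any():
            q[tested.to_numpy()] = stats.false_discovery_control(
                df.loc[tested, "p_value"].to_numpy()
            )
        df["q_value"] = q
        df["significant"] = df["q_value"] < p_cutoff
    return df


def species_dmg(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    delta: float = SPECIES_DELTA,
) -> pd.DataFrame:
    """Between-species differential methylation by gene-body mean difference.

    Inputs are per-gene summary tables (gene_id, mean_ratio, meth_class)
    for species A and B; genes flagged insufficient or missing in either
    species are skipped.  A gene is a DMG iff |mean_A - mean_B| > delta
    (strict); delta's sign (A - B) is recorded.
    """
    a = summaries_a[summaries_a["meth_class"] != "insufficient"][["gene_id", "mean_ratio"]]
    b = summaries_b[summaries_b["meth_class"] != "insufficient"][["gene_id", "mean_ratio"]]
    merged = a.merge(b, on="gene_id", suffixes=("_a", "_b")).dropna()
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "mean_a": merged["mean_ratio_a"],
            "mean_b": merged["mean_ratio_b"],
        }
    )
    out["delta"] = out["mean_a"] - out["mean_b"]
    out["dmg"] = out["delta"].abs() > delta
    return out


def dmg_direction_summary(dmg_table: pd.DataFrame) -> dict[str, float]:
    """Fractions of DMGs more methylated in each species (by delta sign)."""
    dmgs = dmg_table[dmg_table["dmg"]]
    n = len(dmgs)
    if n == 0:
        raise ValueError("no DMGs to summarize")
    higher_a = int((dmgs["delta"] > 0).sum())
    return {
        "n_dmg": n,
        "frac_higher_a": higher_a / n,
        "frac_higher_b": (n - higher_a) / n,
    }


def group_mean_comparison(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[str],
) -> dict[str, float]:
    """Two-tailed two-sample t test on per-gene values between two groups
    (used for gene-body means and, reused, for per-gene CV)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    a, b = values[labels == uniq[0]], values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two genes per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return {"statistic": np.nan, "p_value": np.nan, "mean_a": a.mean(), "mean_b": b.mean(),
                "degenerate": True}
    res = stats.ttest_ind(a, b, equal_var=True)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "degenerate": False,
    }
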