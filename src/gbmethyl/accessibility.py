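"""TSS-centered chromatin accessibility from ATAC fragment intervals.

Coverage is the per-base count of fragments overlapping each position of
the window [TSS - flank, TSS + flank) (default flank 2 kb), strand-oriented
so positive offsets point into the gene body.  Metagene profiles average
these vectors over gene strata (expression rank, methylation class or
quintile, variability) with optional 10-bp binning; values are raw mean
fragment coverage — no library-size normalization by default, with a
counts-per-million switch for multi-library input.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, GenomeIndex

log = logging.getLogger(__name__)

DEFAULT_FLANK = 2000
PROMOTER_UPSTREAM = 1000   # promoter window [TSS-1000, TSS+500), strand-oriented
PROMOTER_DOWNSTREAM = 500


def tss_coverage(
    fragments: pd.DataFrame,
    annotation: AnnotationSet,
    genome: GenomeIndex,
    flank: int = DEFAULT_FLANK,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-gene, per-base fragment coverage around the TSS.

    Returns (gene table, coverage matrix, valid mask); matrix row g column
    j is the fragment count at strand-oriented offset j - flank from gene
    g's TSS.  Window parts outside the scaffold are masked invalid (and
    logged), not filled with zeros.
    """
    genes = annotation.gene_frame()
    width = 2 * flank
    cov = np.zeros((len(genes), width))
    valid = np.ones((len(genes), width), dtype=bool)
    lengths = genome.lengths
    by_chrom = {}
    for c, g in fragments.groupby("chrom"):
        g = g.sort_values("start")
        starts, ends = g["start"].to_numpy(), g["end"].to_numpy()
        max_len = int((ends - starts).max()) if len(g) else 0
        by_chrom[c] = (starts, ends, max_len)
    for i, gene in enumerate(genes.itertuples()):
        length = lengths[gene.chrom]
        if gene.strand == "+":
            win_start, win_end = gene.tss - flank, gene.tss + flank
        else:
            # reversed below so that offset 0 lands exactly on the TSS
            win_start, win_end = gene.tss - flank + 1, gene.tss + flank + 1
        lo, hi = max(win_start, 0), min(win_end, length)
        if lo > win_start or hi < win_end:
            log.warning("TSS window of %s truncated at scaffold bounds", gene.gene_id)
        diff = np.zeros(width + 1)
        if gene.chrom in by_chrom:
            starts, ends, max_len = by_chrom[gene.chrom]
            a0 = np.searchsorted(starts, lo - max_len)
            b0 = np.searchsorted(starts, hi)
            sel = ends[a0:b0] > lo
            for s, e in zip(starts[a0:b0][sel], ends[a0:b0][sel]):
                a = max(int(s), lo) - win_start
                b = min(int(e), hi) - win_start
                diff[a] += 1
                diff[b] -= 1
        vec = np.cumsum(diff[:-1])
        mask = np.zeros(width, dtype=bool)
        mask[lo - win_start : hi - win_start] = True
        if gene.strand == "-":
            vec, mask = vec[::-1], mask[::-1]
        cov[i] = vec
        valid[i] = mask
    return genes, cov, valid


def metagene(
    genes: pd.DataFrame,
    coverage: np.ndarray,
    valid: np.ndarray,
    strata: Mapping[str, Sequence[str]],
    flank: int = DEFAULT_FLANK,
    bin_size: int = 10,
    per_million: float | None = None,
) -> pd.DataFrame:
    """Average coverage per offset for each gene stratum.

    ``strata`` maps stratum label -> gene ids; empty strata are omitted
    with a logged warning.  Offsets are binned to ``bin_size`` (the offset
    reported is the bin midpoint relative to the TSS).  ``per_million``
    optionally rescales to counts per million fragments.
    """
    idx = {g: i for i, g in enumerate(genes["gene_id"])}
    width = coverage.shape[1]
    nb = width // bin_size
    offsets = (np.arange(nb) * bin_size + bin_size / 2) - flank
    rows = []
    for label, gene_ids in strata.items():
        members = [idx[g] for g in gene_ids if g in idx]
        if not members:
            log.warning("stratum %r has no genes; omitted", label)
            continue
        cov = coverage[members]
        msk = valid[members]
        with np.errstate(invalid="ignore"):
            per_base = np.where(msk, cov, np.nan)
        mean = np.nanmean(
            per_base[:, : nb * bin_size].reshape(len(members), nb, bin_size), axis=(0, 2)
        )
        if per_million:
            mean = mean * 1e6 / per_million
        for off, val in zip(offsets, mean):
            rows.append((label, float(off), float(val), len(members)))
    return pd.DataFrame(rows, columns=["stratum", "offset", "mean_coverage", "n_genes"])


def central_signal(profile: pd.DataFrame, half_width: int = 200) -> pd.Series:
    """Mean profile value within +/- half_width of the TSS, per stratum."""
    near = profile[profile["offset"].abs() <= half_width]
    return near.groupby("stratum")["mean_coverage"].mean()


def stratify_by_variability(
    summaries: pd.DataFrame,
    variability: pd.DataFrame,
    meth_split: float = 0.4,
    stable_quintile: int = 1,
    variable_quintile: int = 5,
) -> dict[str, list[str]]:
    """Four strata crossing methylation (< / > ``meth_split`` on the
    gene-body mean) with expression variability (CV quintile 1 = stable,
    quintile 5 = variable)."""
    df = summaries.merge(variability[["gene_id", "cv_quintile"]], on="gene_id")
    df = df[df["meth_class"] != "insufficient"].dropna(subset=["mean_ratio", "cv_quintile"])
    low = df["mean_ratio"] < meth_split
    high = df["mean_ratio"] > meth_split
    stable = df["cv_quintile"] == stable_quintile
    variable = df["cv_quintile"] == variable_quintile
    return {
        "low_meth_stable": df.loc[low & stable, "gene_id"].tolist(),
        "low_meth_variable": df.loc[low & variable, "gene_id"].tolist(),
        "high_meth_stable": df.loc[high & stable, "gene_id"].tolist(),
        "high_meth_variable": df.loc[high & variable, "gene_id"].tolist(),
    }


def methylation_strata(
    summaries: pd.DataFrame, n_quantiles: int = 5
) -> dict[str, list[str]]:
    """Unmethylated genes plus methylation quintiles 1..n of the rest."""
    ok = summaries[
        (summaries["meth_class"] != "insufficient") & summaries["mean_ratio"].notna()
    ]
    out: dict[str, list[str]] = {}
    zero = ok["mean_ratio"] == 0
    if zero.any():
        out["unmethylated"] = ok.loc[zero, "gene_id"].tolist()
    rest = ok[~zero]
    if len(rest) >= n_quantiles:
        q = pd.qcut(rest["mean_ratio"].rank(method="first"), n_quantiles, labels=False) + 1
        for b in range(1, n_quantiles + 1):
            out[f"meth_q{b}"] = rest.loc[q.to_numpy() == b, "gene_id"].tolist()
    return out


def expression_strata(expr_rank: pd.Series) -> dict[str, list[str]]:
    return {
        f"expr_q{b}": expr_rank.index[expr_rank == b].tolist()
        for b in sorted(expr_rank.unique())
    }


def peak_promoter_overlap(
    peaks: pd.DataFrame,
    annotation: AnnotationSet,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> tuple[int, pd.DataFrame]:
    """Count peaks overlapping >= 1 promoter window.

    The promoter is [TSS - upstream, TSS + downstream) oriented by strand.
    Each peak counts once however many promoters it touches; the returned
    table carries a per-peak flag and per-gene overlap flags.
    """
    genes = annotation.gene_frame()
    proms = {}
    for g in genes.itertuples():
        if g.strand == "+":
            s, e = g.tss - upstream, g.tss + downstream
        else:
            s, e = g.tss - downstream + 1, g.tss + upstream + 1
        proms.setdefault(g.chrom, []).append((s, e, g.gene_id))
    flags = np.zeros(len(peaks), dtype=bool)
    gene_hit = {g: False for g in genes["gene_id"]}
    for i, p in enumerate(peaks.itertuples()):
        for s, e, gid in proms.get(p.chrom, ()):
            if p.start < e and p.end > s:
                flags[i] = True
                gene_hit[gid] = True
    peak_table = peaks.copy()
    peak_table["promoter_overlap"] = flags
    peak_table.attrs["gene_promoter_hit"] = gene_hit
    return int(flags.sum()), peak_table


def replicate_correlation(tracks: Sequence[np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlation between replicate coverage tracks,
    supporting the confirm-then-pool replicate workflow."""
    n = len(tracks)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.corrcoef(tracks[i], tracks[j])[0, 1])
            rows.append((i, j, r))
    return pd.DataFrame(rows, columns=["rep_a", "rep_b", "pearson_r"])


def pool_fragments(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(replicates, ignore_index=True)
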