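"""Methylome summaries: windowed tracks, per-feature and per-gene
methylation, bimodality histograms, CpG observed/expected classes, repeat
methylation by class and location, and methylated-CpG density tracks.

Gene-body methylation is the unweighted mean of per-CpG methylation ratios
inside the gene interval (both strands); coverage weighting is deliberately
avoided so depth does not leak into the methylation estimate.  Genes are
split into low- and high-methylated classes at 0.4 (high iff mean > 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, GenomeIndex, GeneRecord, GENE_SUBFEATURES
from .meth_calling import classify_methylated

METH_CLASS_BOUNDARY = 0.4  # high iff mean ratio > 0.4
OE_LOW, OE_HIGH = 0.6, 1.2  # CpG o/e class boundaries
MIN_CPGS = 5  # genes with fewer retained CpGs are flagged insufficient


def window_methylation(
    sites: pd.DataFrame,
    genome: GenomeIndex,
    window: int = 2000,
    step: int | None = None,
) -> pd.DataFrame:
    """Mean CpG methylation ratio in sliding windows across each scaffold.

    Returns (chrom, start, end, n_cpg, mean_ratio); windows with no
    retained CpG carry NaN.  ``step`` defaults to ``window``
    (non-overlapping tiling).
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    step = step or window
    rows = []
    for chrom, length in genome.lengths.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        ratio = sub["ratio"].to_numpy()
        order = np.argsort(pos)
        pos, ratio = pos[order], ratio[order]
        for start in range(0, length, step):
            end = min(start + window, length)
            lo, hi = np.searchsorted(pos, (start, end))
            n = hi - lo
            mean = float(ratio[lo:hi].mean()) if n else np.nan
            rows.append((chrom, start, end, n, mean))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg", "mean_ratio"])


def _mean_ratio_in(sites: pd.DataFrame, chrom: str, intervals) -> tuple[int, float]:
    sub = sites[sites["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    mask = np.zeros(len(sub), dtype=bool)
    for s, e in intervals:
        mask |= (pos >= s) & (pos < e)
    n = int(mask.sum())
    return n, (float(sub["ratio"].to_numpy()[mask].mean()) if n else np.nan)


def feature_methylation(sites: pd.DataFrame, annotation: AnnotationSet) -> pd.DataFrame:
    """Mean methylation over retained CpGs per feature class plus the
    genome-wide mean.  Features with no CpGs report NaN, not 0."""
    rows = [("genome", len(sites), float(sites["ratio"].mean()) if len(sites) else np.nan)]
    for ftype in ("gene",) + GENE_SUBFEATURES:
        n_tot, total = 0, 0.0
        vals = []
        for g in annotation.genes:
            ivs = [(g.start, g.end)] if ftype == "gene" else g.features.get(ftype, [])
            if not ivs:
                continue
            sub = sites[sites["chrom"] == g.chrom]
            pos = sub["pos"].to_numpy()
            mask = np.zeros(len(sub), dtype=bool)
            for s, e in ivs:
                mask |= (pos >= s) & (pos < e)
            vals.append(sub["ratio"].to_numpy()[mask])
        allv = np.concatenate(vals) if vals else np.array([])
        rows.append((ftype, len(allv), float(allv.mean()) if len(allv) else np.nan))
    if annotation.repeats:
        vals = []
        for r in annotation.repeats:
            sub = sites[sites["chrom"] == r.chrom]
            pos = sub["pos"].to_numpy()
            vals.append(sub["ratio"].to_numpy()[(pos >= r.start) & (pos < r.end)])
        allv = np.concatenate(vals) if vals else np.array([])
        rows.append(("repeat", len(allv), float(allv.mean()) if len(allv) else np.nan))
    return pd.DataFrame(rows, columns=["feature", "n_cpg", "mean_ratio"])


@dataclass
class GeneMethylationSummary:
    gene_id: str
    mean_ratio: float
    n_cpgs: int
    feature_means: dict[str, float]
    meth_class: str  # low / high / unmethylated / insufficient
    oe: Optional[float] = None
    oe_class: Optional[str] = None


def _meth_class(mean_ratio: float, boundary: float = METH_CLASS_BOUNDARY) -> str:
    if mean_ratio == 0.0:
        return "unmethylated"
    return "high" if mean_ratio > boundary else "low"


def gene_body_summary(
    sites: pd.DataFrame,
    gene: GeneRecord,
    min_cpgs: int = MIN_CPGS,
    class_boundary: float = METH_CLASS_BOUNDARY,
) -> GeneMethylationSummary:
    """Summarize one gene: unweighted mean CpG ratio over the gene body and
    each sub-feature; class at the 0.4 boundary (0.4 itself is low)."""
    sub = sites[sites["chrom"] == gene.chrom]
    pos = sub["pos"].to_numpy()
    ratio = sub["ratio"].to_numpy()
    body = ratio[(pos >= gene.start) & (pos < gene.end)]
    feature_means = {}
    for ftype in GENE_SUBFEATURES:
        ivs = gene.features.get(ftype, [])
        if not ivs:
            feature_means[ftype] = np.nan
            continue
        mask = np.zeros(len(sub), dtype=bool)
        for s, e in ivs:
            mask |= (pos >= s) & (pos < e)
        feature_means[ftype] = float(ratio[mask].mean()) if mask.any() else np.nan
    n = len(body)
    mean = float(body.mean()) if n else np.nan
    cls = "insufficient" if n < min_cpgs else _meth_class(mean, class_boundary)
    return GeneMethylationSummary(gene.gene_id, mean, n, feature_means, cls)


def gene_methylation_table(
    sites: pd.DataFrame,
    annotation: AnnotationSet,
    min_cpgs: int = MIN_CPGS,
    class_boundary: float = METH_CLASS_BOUNDARY,
) -> pd.DataFrame:
    """Vectorized per-gene summaries for all genes (gene_id, chrom, n_cpgs,
    mean_ratio, meth_class).  Genes with fewer than ``min_cpgs`` retained
    CpGs are flagged 'insufficient' and should be excluded from histograms
    and class-based stratifications."""
    frames = []
    genes = annotation.gene_frame()
    for chrom, gsub in genes.groupby("chrom", sort=False):
        sub = sites[sites["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(sub["ratio"].to_numpy())])
        lo = np.searchsorted(pos, gsub["start"].to_numpy())
        hi = np.searchsorted(pos, gsub["end"].to_numpy())
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gsub["gene_id"].to_numpy(),
                    "chrom": chrom,
                    "n_cpgs": n,
                    "mean_ratio": mean,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene_id", "chrom", "n_cpgs", "mean_ratio"]
    )
    cls = np.where(
        df["n_cpgs"] < min_cpgs,
        "insufficient",
        np.where(
            df["mean_ratio"] == 0.0,
            "unmethylated",
            np.where(df["mean_ratio"] > class_boundary, "high", "low"),
        ),
    )
    df["meth_class"] = cls
    return df


def methylation_histogram(summaries: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of gene-body means in fixed-width bins (default 0.1),
    excluding genes flagged insufficient."""
    ok = summaries[summaries["meth_class"] != "insufficient"]
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    counts, _ = np.histogram(ok["mean_ratio"].clip(0, 1 - 1e-12), bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def histogram_modes(hist: pd.DataFrame) -> list[float]:
    """Left edges of local maxima of the bin counts (plateau-aware)."""
    c = hist["count"].to_numpy().astype(float)
    modes = []
    for i in range(len(c)):
        left = c[i - 1] if i > 0 else -np.inf
        right = c[i + 1] if i < len(c) - 1 else -np.inf
        if c[i] > left and c[i] >= right and c[i] > 0:
            modes.append(float(hist["bin_left"].iloc[i]))
    return modes


def cpg_oe(sequence: str) -> float:
    """CpG observed/expected ratio: (#CpG * L) / (#C * #G).

    Raises ValueError when the sequence contains no C or no G.
    """
    seq = sequence.upper()
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c == 0 or n_g == 0:
        raise ValueError("CpG o/e undefined: sequence lacks C or G")
    return seq.count("CG") * len(seq) / (n_c * n_g)


def oe_class(value: float, low: float = OE_LOW, high: float = OE_HIGH) -> str:
    """Classes: low (< 0.6), medium (>= 0.6, < 1.2), high (>= 1.2)."""
    if value < low:
        return "low"
    if value < high:
        return "medium"
    return "high"


def gene_oe_table(genome: GenomeIndex, annotation: AnnotationSet) -> pd.DataFrame:
    rows = []
    for g in annotation.genes:
        seq = genome.fetch(g.chrom, g.start, g.end)
        try:
            v = cpg_oe(seq)
            rows.append((g.gene_id, v, oe_class(v)))
        except ValueError:
            rows.append((g.gene_id, np.nan, "undefined"))
    return pd.DataFrame(rows, columns=["gene_id", "oe", "oe_class"])


def repeat_methylation(sites: pd.DataFrame, annotation: AnnotationSet) -> pd.DataFrame:
    """Mean methylation per (repeat class, intragenic/intergenic) stratum.

    Strata whose repeats contain no retained CpG report NaN."""
    rows = []
    reps = annotation.repeat_frame()
    if reps.empty:
        return pd.DataFrame(columns=["repeat_class", "location", "n_repeats", "n_cpg", "mean_ratio"])
    for (cls, intragenic), group in reps.groupby(["repeat_class", "intragenic"]):
        vals = []
        for row in group.itertuples():
            sub = sites[sites["chrom"] == row.chrom]
            pos = sub["pos"].to_numpy()
            vals.append(sub["ratio"].to_numpy()[(pos >= row.start) & (pos < row.end)])
        allv = np.concatenate(vals) if vals else np.array([])
        rows.append(
            (
                cls,
                "intragenic" if intragenic else "intergenic",
                len(group),
                len(allv),
                float(allv.mean()) if len(allv) else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["repeat_class", "location", "n_repeats", "n_cpg", "mean_ratio"])


def mcpg_density(
    sites: pd.DataFrame,
    genome: GenomeIndex,
    window: int = 1000,
    ratio_threshold: float = 0.8,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Strand-specific methylated-CpG density: count of methylated CpGs
    (ratio >= 0.8, coverage >= 3) per non-overlapping window, divided by
    window length in kb."""
    is_m = classify_methylated(
        sites["ratio"].to_numpy(), sites["coverage"].to_numpy(), ratio_threshold, min_cov
    )
    msites = sites[is_m]
    rows = []
    for chrom, length in genome.lengths.items():
        for strand in "+-":
            sub = msites[(msites["chrom"] == chrom) & (msites["strand"] == strand)]
            pos = np.sort(sub["pos"].to_numpy())
            for start in range(0, length, window):
                end = min(start + window, length)
                lo, hi = np.searchsorted(pos, (start, end))
                rows.append((chrom, start, end, strand, (hi - lo) / ((end - start) / 1000)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "density_per_kb"])
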