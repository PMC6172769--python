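"""Per-CpG methylation calling under base-quality and coverage filters.

A CpG dyad has a cytosine on each strand: at position ``p`` on '+' and
``p + 1`` on '-'.  Each strand is called independently: a read observation
is kept when the quality of the base at the C position is at least
``q_c`` (default 30) and the qualities of the two read bases before and
after it are all at least ``q_flank`` (default 20).  A strand's site is
retained only with at least ``min_per_strand`` (default 3) surviving reads.
The methylation ratio is C / (C + T) over the bisulfite-informative
alphabet; other observed bases (sequencing error) contribute to neither
count.  Bisulfite conversion efficiency is estimated from cytosines in
non-CpG context, which are assumed unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .io_formats import PileupColumn, _STATE_BASES


@dataclass(frozen=True)
class CallingFilters:
    """Quality and coverage thresholds for methylation calling."""

    q_c: int = 30          # min Phred at the C position
    q_flank: int = 20      # min Phred at the two bases before/after the C
    min_per_strand: int = 3  # min surviving reads per strand

    def __post_init__(self) -> None:
        if min(self.q_c, self.q_flank, self.min_per_strand) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class CpGSite:
    """One strand-specific CpG cytosine with its methylation evidence."""

    chrom: str
    pos: int
    strand: str
    meth: int
    unmeth: int

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def ratio(self) -> float:
        if self.coverage == 0:
            raise ValueError("ratio undefined at zero coverage")
        return self.meth / self.coverage


@dataclass
class ConversionReport:
    observed: int
    converted: int

    @property
    def rate(self) -> Optional[float]:
        """T / (C + T) at non-CpG cytosines; None with no usable data."""
        if self.observed == 0:
            return None
        return self.converted / self.observed


def filter_read_bases(column: PileupColumn, filters: CallingFilters) -> PileupColumn:
    """Keep only observations passing the C-position and flanking-quality
    filters; observations lacking a flank (read end) are dropped."""
    kept = [
        o
        for o in column.observations
        if o.quality >= filters.q_c
        and all(q is not None and q >= filters.q_flank for q in o.flanks)
    ]
    return PileupColumn(column.chrom, column.pos, column.strand, kept)


def _count_states(column: PileupColumn) -> tuple[int, int]:
    states = _STATE_BASES[column.strand]
    meth = sum(1 for o in column.observations if states.get(o.base) == "C")
    unmeth = sum(1 for o in column.observations if states.get(o.base) == "T")
    return meth, unmeth


def call_cpg(
    column_plus: PileupColumn,
    column_minus: PileupColumn,
    filters: CallingFilters = CallingFilters(),
) -> tuple[Optional[CpGSite], Optional[CpGSite]]:
    """Call both strands of one CpG dyad.

    The two columns must be the paired cytosines of one dyad (position p on
    '+', p + 1 on '-').  Each strand's site is returned only when its
    post-filter informative coverage reaches ``filters.min_per_strand``.
    """
    if (
        column_plus.strand != "+"
        or column_minus.strand != "-"
        or column_minus.pos != column_plus.pos + 1
        or column_minus.chrom != column_plus.chrom
    ):
        raise ValueError("columns do not form a CpG dyad (p on '+', p+1 on '-')")
    out = []
    for col in (column_plus, column_minus):
        meth, unmeth = _count_states(filter_read_bases(col, filters))
        if meth + unmeth >= filters.min_per_strand:
            out.append(CpGSite(col.chrom, col.pos, col.strand, meth, unmeth))
        else:
            out.append(None)
    return out[0], out[1]


def call_sites(
    columns: Iterable[PileupColumn], filters: CallingFilters = CallingFilters()
) -> pd.DataFrame:
    """Call every cytosine column independently; returns the retained-site
    table (chrom, pos, strand, meth, unmeth, coverage, ratio).

    Columns may arrive in any grouping; the per-strand coverage rule needs
    no dyad pairing, so this is the bulk entry point for whole-pileup runs.
    """
    rows = []
    for col in columns:
        meth, unmeth = _count_states(filter_read_bases(col, filters))
        if meth + unmeth >= filters.min_per_strand:
            rows.append((col.chrom, col.pos, col.strand, meth, unmeth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    return sites_from_counts(df)


def sites_from_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Attach coverage and ratio columns to a (meth, unmeth) count table."""
    df = df.copy()
    df["coverage"] = df["meth"] + df["unmeth"]
    df["ratio"] = np.where(df["coverage"] > 0, df["meth"] / df["coverage"].replace(0, 1), np.nan)
    return df


def estimate_conversion(
    columns: Iterable[PileupColumn], filters: CallingFilters = CallingFilters()
) -> ConversionReport:
    """Estimate bisulfite conversion from non-CpG cytosine columns.

    Rate = T observations / (C + T observations) after base-quality
    filtering; non-CpG cytosines are assumed unmethylated.
    """
    observed = converted = 0
    for col in columns:
        meth, unmeth = _count_states(filter_read_bases(col, filters))
        observed += meth + unmeth
        converted += unmeth
    return ConversionReport(observed=observed, converted=converted)


def classify_methylated(
    ratio: float | np.ndarray,
    coverage: int | np.ndarray,
    ratio_threshold: float = 0.8,
    min_cov: int = 3,
):
    """A site counts as methylated when ratio >= 0.8 and coverage >= 3."""
    return (np.asarray(ratio) >= ratio_threshold) & (np.asarray(coverage) >= min_cov)


def dyad_view(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge retained strand sites into per-dyad ratios (derived view).

    Dyads are keyed by the position of the '+' strand C; counts from both
    strands are pooled.  Per-strand sites remain the primary calls.
    """
    df = sites.copy()
    df["dyad_pos"] = np.where(df["strand"] == "+", df["pos"], df["pos"] - 1)
    g = df.groupby(["chrom", "dyad_pos"], as_index=False)[["meth", "unmeth"]].sum()
    g["coverage"] = g["meth"] + g["unmeth"]
    g["ratio"] = g["meth"] / g["coverage"]
    return g.rename(columns={"dyad_pos": "pos"})
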