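"""Seeded generator for miniature methylome studies with known truth.

The generator emits a small genome, gene/repeat annotation, bisulfite
evidence (per-CpG read counts, optional paired-end SAM alignments),
replicate TPM matrices and ATAC fragments, wired together with the
couplings the downstream analyses look for:

* gene-body methylation is a two-component mixture (low / high Beta
  components) producing a bimodal gene histogram;
* housekeeping genes are drawn preferentially from the high component;
* high-methylation genes are longer and CpG-poorer (lower CpG o/e);
* two tissues of one animal share the same methylation truth (tissue
  invariance) and differ only by sampling noise;
* a second species carries planted gene-body methylation differences of a
  configured size and direction asymmetry;
* expression variability follows CV = a - b * methylation + noise;
* TSS accessibility amplitude rises with expression, falls with
  methylation, and (for low-methylated genes only) rises with expression
  stability;
* intragenic repeats inherit their host gene's methylation while
  intergenic repeats sit on the hypomethylated background.

Every draw consumes a single :class:`numpy.random.Generator` stream, so a
fixed seed reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .io_formats import (
    AnnotationSet,
    GeneRecord,
    GenomeIndex,
    RepeatRecord,
    write_fasta,
    write_fragments_bed,
    write_gff3,
    write_peaks_bed,
    write_repeats_bed,
    write_sites_tsv,
)


@dataclass
class SynthConfig:
    """All generator knobs; defaults are the 'paper-like' study conditions.

    Depth is the total read depth per CpG dyad (split evenly between
    strands); conversion is the bisulfite conversion rate applied to
    unmethylated cytosines; error_rate is the per-base miscall rate.
    """

    seed: int = 17
    # genome / annotation
    n_scaffolds: int = 2
    scaffold_length: int = 500_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (1_200, 3_600)
    cpg_rate_intergenic: float = 0.012   # dyads per bp
    cpg_rate_low: float = 0.022          # low-methylation genes: CpG-rich
    cpg_rate_high: float = 0.011         # high-methylation genes: CpG-poor
    intergenic_meth_beta: tuple[float, float] = (1.0, 40.0)
    # methylation mixture
    mixture_low_weight: float = 0.45
    beta_low: tuple[float, float] = (1.5, 20.0)
    beta_high: tuple[float, float] = (20.0, 3.0)
    housekeeping_fraction: float = 0.12
    hk_high_bias: float = 0.9            # P(hk gene comes from high component)
    # repeats
    repeat_counts: dict[str, int] = field(
        default_factory=lambda: {"LINE": 50, "SINE": 30, "DNA": 15, "LTR": 12, "simple": 8}
    )
    repeat_length_range: tuple[int, int] = (200, 800)
    repeat_intragenic_fraction: float = 0.4
    # bisulfite sampling
    depth: float = 20.0
    conversion: float = 0.99
    error_rate: float = 0.001
    quality_levels: tuple[tuple[int, float], ...] = (
        (37, 0.85), (33, 0.06), (25, 0.05), (12, 0.04),
    )
    # species contrast
    n_dmg: int = 50
    dmg_delta: float = 0.3
    dmg_frac_higher_a: float = 0.9       # fraction of DMGs more methylated in species A
    # expression / variability
    n_replicates: int = 3
    expr_log_mu: float = 2.0             # ln TPM
    expr_log_sd: float = 1.2
    parabola_coupling: float = 0.25      # extreme expression ranks undermethylated
    cv_a: float = 0.6
    cv_b: float = 0.4                    # CV = cv_a - cv_b * methylation + noise
    cv_noise_sd: float = 0.15
    cv_min: float = 0.05
    # accessibility: amplitude = (1 + expr_weight * u_expr)
    #   * exp(-meth_decay * methylation) * stability boost (low-meth only)
    atac_frags_per_gene: float = 30.0
    atac_background_per_kb: float = 0.5
    atac_expr_weight: float = 1.5
    atac_meth_decay: float = 1.5
    atac_stable_weight: float = 1.0
    atac_tss_sd: float = 150.0
    fragment_length_range: tuple[int, int] = (120, 260)
    peak_bin: int = 200
    peak_factor: float = 5.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def paper_like(seed: int = 17, **overrides) -> SynthConfig:
    """The default preset: bimodal methylome, all couplings on."""
    return dataclasses.replace(SynthConfig(seed=seed), **overrides)


def null_preset(seed: int = 17, **overrides) -> SynthConfig:
    """No couplings: CV independent of methylation, no planted species
    differences, flat accessibility."""
    cfg = SynthConfig(
        seed=seed,
        cv_b=0.0,
        n_dmg=0,
        parabola_coupling=0.0,
        atac_expr_weight=0.0,
        atac_meth_decay=0.0,
        atac_stable_weight=0.0,
    )
    return dataclasses.replace(cfg, **overrides)


def high_noise(seed: int = 17, **overrides) -> SynthConfig:
    cfg = SynthConfig(seed=seed, depth=8.0, conversion=0.97, error_rate=0.005,
                      cv_noise_sd=0.3)
    return dataclasses.replace(cfg, **overrides)


@dataclass
class Truth:
    """Ground truth linking every emitted record to its generating values."""

    genes: pd.DataFrame        # per-gene truth
    cpg_sites: pd.DataFrame    # per-dyad truth: chrom, pos, gene_id, true_m
    config: SynthConfig


# ---------------------------------------------------------------------------
# genome + annotation


def _spaced_positions(rng: np.random.Generator, start: int, end: int, rate: float,
                      min_gap: int = 3) -> np.ndarray:
    """Candidate dyad positions in [start, end-2) at ~rate per bp, spaced
    at least min_gap apart (so inserted CGs never collide)."""
    n = end - 2 - start
    if n <= 0:
        return np.array([], dtype=int)
    cand = start + np.where(rng.random(n) < rate)[0]
    keep = []
    last = -min_gap
    for p in cand:
        if p - last >= min_gap:
            keep.append(p)
            last = p
    return np.asarray(keep, dtype=int)


def _gene_subfeatures(start: int, end: int, strand: str,
                      rng: np.random.Generator) -> dict[str, list[tuple[int, int]]]:
    """5'UTR, alternating exons/introns and 3'UTR tiling the gene body."""
    length = end - start
    u5 = max(50, int(length * rng.uniform(0.05, 0.1)))
    u3 = max(50, int(length * rng.uniform(0.05, 0.1)))
    inner_start, inner_end = start + u5, end - u3
    n_exons = int(rng.integers(2, 7))
    cuts = np.linspace(inner_start, inner_end, 2 * n_exons).astype(int)
    exons = [(int(cuts[i]), int(cuts[i + 1])) for i in range(0, len(cuts) - 1, 2)]
    introns = [(int(cuts[i]), int(cuts[i + 1])) for i in range(1, len(cuts) - 1, 2)]
    left, right = (start, start + u5), (end - u3, end)
    if strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    return {
        "five_prime_utr": [utr5],
        "exon": exons,
        "intron": introns,
        "three_prime_utr": [utr3],
    }


def generate_genome(config: SynthConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[GenomeIndex, AnnotationSet, Truth]:
    """Generate the genome, annotation and per-gene / per-CpG truth."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_genes
    lo, hi = config.gene_length_range

    # components, methylation truth, housekeeping flags
    component = np.where(rng.random(n) < config.mixture_low_weight, "low", "high")
    m = np.where(
        component == "low",
        rng.beta(*config.beta_low, size=n),
        rng.beta(*config.beta_high, size=n),
    )
    n_hk = int(round(config.housekeeping_fraction * n))
    w = np.where(component == "high", config.hk_high_bias, 1 - config.hk_high_bias)
    hk = np.zeros(n, dtype=bool)
    hk[rng.choice(n, size=n_hk, replace=False, p=w / w.sum())] = True

    # longer genes preferentially from the high component
    span = hi - lo
    lengths = np.where(
        component == "high",
        rng.integers(lo + int(0.3 * span), hi + 1, size=n),
        rng.integers(lo, lo + int(0.7 * span) + 1, size=n),
    )

    # expression percentile; optional parabolic undermethylation of the
    # extreme expression ranks
    u_expr = rng.random(n)
    if config.parabola_coupling > 0:
        m = np.clip(m * (1 - config.parabola_coupling * (2 * (u_expr - 0.5)) ** 2), 0, 1)

    # planted species DMGs
    dmg = np.zeros(n, dtype=bool)
    delta_signed = np.zeros(n)
    if config.n_dmg > 0:
        # plant shifts only on genes with room for the full delta, so the
        # planted effect size is not silently clipped at 0 or 1
        margin = config.dmg_delta + 0.05
        n_down = int(round(config.dmg_frac_higher_a * config.n_dmg))
        eligible_down = np.where(m >= margin)[0]
        eligible_up = np.where(m <= 1 - margin)[0]
        down = rng.choice(eligible_down, size=min(n_down, len(eligible_down)),
                          replace=False)
        up_pool = np.setdiff1d(eligible_up, down)
        up = rng.choice(up_pool, size=min(config.n_dmg - len(down), len(up_pool)),
                        replace=False)
        # species B subtracts delta where A is the more methylated species
        dmg[down] = dmg[up] = True
        delta_signed[down] = -config.dmg_delta
        delta_signed[up] = config.dmg_delta

    # place genes without overlap, round-robin over scaffolds
    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    per_scaffold: dict[str, list[int]] = {s: [] for s in scaffolds}
    for gi in range(n):
        per_scaffold[scaffolds[gi % len(scaffolds)]].append(gi)
    gene_rows = []
    for scaf in scaffolds:
        members = per_scaffold[scaf]
        total = sum(int(lengths[gi]) for gi in members)
        slack = config.scaffold_length - total
        if slack < len(members) + 1:
            raise ValueError("genes cannot fit; increase scaffold_length")
        gaps = rng.multinomial(slack - len(members) - 1, np.ones(len(members) + 1) / (len(members) + 1))
        cursor = 0
        for k, gi in enumerate(members):
            cursor += int(gaps[k]) + 1
            start = cursor
            end = start + int(lengths[gi])
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((gi, f"g{gi:04d}", scaf, start, end, strand))
    gene_rows.sort(key=lambda r: r[0])

    # sequence scaffolds without accidental CpGs, then stamp in dyads
    seqs: dict[str, np.ndarray] = {}
    for scaf in scaffolds:
        arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=config.scaffold_length)
        cg = np.where((arr[:-1] == b"C") & (arr[1:] == b"G"))[0]
        arr[cg + 1] = b"T"  # break background CG dinucleotides
        seqs[scaf] = arr

    site_rows = []
    genes: list[GeneRecord] = []
    covered: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    for gi, gid, scaf, start, end, strand in gene_rows:
        rate = config.cpg_rate_high if component[gi] == "high" else config.cpg_rate_low
        pos = _spaced_positions(rng, start, end, rate)
        for p in pos:
            site_rows.append((scaf, int(p), gid, float(m[gi])))
        covered[scaf].append((start, end))
        genes.append(
            GeneRecord(gid, scaf, start, end, strand,
                       _gene_subfeatures(start, end, strand, rng), bool(hk[gi]))
        )
    # intergenic CpGs
    ab_int = config.intergenic_meth_beta
    for scaf in scaffolds:
        ivs = sorted(covered[scaf])
        cursor = 0
        for s, e in ivs + [(config.scaffold_length, config.scaffold_length)]:
            if s > cursor:
                pos = _spaced_positions(rng, cursor, s, config.cpg_rate_intergenic)
                mm = rng.beta(*ab_int, size=len(pos))
                for p, mi in zip(pos, mm):
                    site_rows.append((scaf, int(p), "", float(mi)))
            cursor = max(cursor, e)
    for scaf in scaffolds:
        arr = seqs[scaf]
        ps = np.array([p for s, p, *_ in site_rows if s == scaf], dtype=int)
        arr[ps] = b"C"
        arr[ps + 1] = b"G"
    genome = GenomeIndex({s: seqs[s].tobytes().decode() for s in scaffolds})

    # repeats
    repeats: list[RepeatRecord] = []
    gene_ivs = {s: sorted(covered[s]) for s in scaffolds}
    rlo, rhi = config.repeat_length_range
    for cls, count in config.repeat_counts.items():
        for _ in range(count):
            length = int(rng.integers(rlo, rhi + 1))
            intragenic = rng.random() < config.repeat_intragenic_fraction
            for _attempt in range(200):
                if intragenic:
                    g = genes[int(rng.integers(len(genes)))]
                    if g.length <= length + 2:
                        continue
                    start = int(rng.integers(g.start, g.end - length))
                    repeats.append(RepeatRecord(g.chrom, start, start + length, cls))
                    break
                scaf = scaffolds[int(rng.integers(len(scaffolds)))]
                start = int(rng.integers(0, config.scaffold_length - length))
                if not any(start < e and start + length > s for s, e in gene_ivs[scaf]):
                    repeats.append(RepeatRecord(scaf, start, start + length, cls))
                    break
    annotation = AnnotationSet(genes=genes, repeats=repeats)
    annotation.compute_intragenic_flags()

    # per-gene derived truth: CV, accessibility amplitude
    true_cv = np.maximum(
        config.cv_min, config.cv_a - config.cv_b * m + rng.normal(0, config.cv_noise_sd, n)
    )
    u_cv = stats.rankdata(true_cv) / n  # percentile of variability (1 = most variable)
    amp = (
        (1 + config.atac_expr_weight * u_expr)
        * np.exp(-config.atac_meth_decay * m)
        * np.where(m < 0.4, 1 + config.atac_stable_weight * (1 - u_cv), 1.0)
    )

    genes_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "length": lengths,
            "component": component,
            "true_meth": m,
            "housekeeping": hk,
            "expr_percentile": u_expr,
            "true_cv": true_cv,
            "cv_percentile": u_cv,
            "atac_amplitude": amp,
            "dmg": dmg,
            "dmg_delta_signed": delta_signed,
        }
    )
    sites_df = pd.DataFrame(site_rows, columns=["chrom", "pos", "gene_id", "true_m"])
    sites_df = sites_df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return genome, annotation, Truth(genes_df, sites_df, config)


# ---------------------------------------------------------------------------
# bisulfite evidence


def expected_called_ratio(m, conversion: float, error_rate: float = 0.0):
    """Expected C/(C+T) read fraction at a site with true methylation m,
    under the given conversion and per-base error rates."""
    m = np.asarray(m, dtype=float)
    e = error_rate
    p_c = m * (1 - e) + (1 - m) * ((1 - conversion) * (1 - e) + conversion * e / 3)
    p_t = m * e / 3 + (1 - m) * (conversion * (1 - e) + (1 - conversion) * e / 3)
    return p_c / (p_c + p_t)


def species_b_truth(truth: Truth) -> pd.DataFrame:
    """Per-CpG truth for the second species: planted DMG genes shift their
    gene-body methylation by the signed delta, clipped to [0, 1]."""
    shift = truth.genes.set_index("gene_id")["dmg_delta_signed"]
    sites = truth.cpg_sites.copy()
    delta = sites["gene_id"].map(shift).fillna(0.0)
    sites["true_m"] = np.clip(sites["true_m"] + delta, 0, 1)
    return sites


def generate_site_counts(
    sites_truth: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
    depth: float | None = None,
) -> pd.DataFrame:
    """Simulate per-strand read counts at every CpG dyad (counts level).

    For each dyad, each strand receives Poisson(depth / 2) reads whose
    methylation states are Bernoulli(true m); unmethylated cytosines read
    T with probability = conversion rate, and base errors move a small
    fraction of reads between / out of the informative states.  Returns
    the raw table (chrom, pos, strand, meth, unmeth, coverage, ratio) with
    '-' strand cytosines at dyad position + 1; no coverage filter applied.
    """
    depth = config.depth if depth is None else depth
    m = sites_truth["true_m"].to_numpy()
    e, conv = config.error_rate, config.conversion
    p_c = m * (1 - e) + (1 - m) * ((1 - conv) * (1 - e) + conv * e / 3)
    p_t = m * e / 3 + (1 - m) * (conv * (1 - e) + (1 - conv) * e / 3)
    frames = []
    for strand, offset in (("+", 0), ("-", 1)):
        cov = rng.poisson(depth / 2.0, size=len(m))
        k_c = rng.binomial(cov, p_c)
        rem = cov - k_c
        with np.errstate(invalid="ignore", divide="ignore"):
            p_t_given = np.where(p_c < 1, p_t / (1 - p_c), 0.0)
        k_t = rng.binomial(rem, p_t_given)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": sites_truth["chrom"].to_numpy(),
                    "pos": sites_truth["pos"].to_numpy() + offset,
                    "strand": strand,
                    "meth": k_c,
                    "unmeth": k_t,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["coverage"] = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore"):
        df["ratio"] = np.where(df["coverage"] > 0, df["meth"] / np.maximum(df["coverage"], 1), np.nan)
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def retained_sites(counts: pd.DataFrame, min_per_strand: int = 3) -> pd.DataFrame:
    """Apply the per-strand coverage rule to a simulated count table."""
    return counts[counts["coverage"] >= min_per_strand].reset_index(drop=True)


def _sample_qualities(rng: np.random.Generator, size: int,
                      levels: Sequence[tuple[int, float]]) -> np.ndarray:
    quals = np.array([q for q, _ in levels])
    probs = np.array([p for _, p in levels], dtype=float)
    return quals[rng.choice(len(quals), size=size, p=probs / probs.sum())]


def generate_alignments(
    genome: GenomeIndex,
    truth: Truth,
    path: str | Path,
    rng: np.random.Generator,
    n_pairs: int = 500,
    read_length: int = 80,
    fragment_length: int = 160,
) -> None:
    """Write a coordinate-sorted paired-end bisulfite SAM file.

    Each fragment picks a scaffold position and a bisulfite strand (ZS
    tag); CpG cytosines read C/T by their true methylation, non-CpG
    cytosines convert at the configured rate, and '-' strand cytosines
    appear as G/A in forward orientation.  Both mates are proper-paired,
    MAPQ 42, with per-base qualities from the configured distribution.
    """
    cfg = truth.config
    sites = truth.cpg_sites
    meth_by_pos = {
        (c, int(p)): float(m)
        for c, p, m in zip(sites["chrom"], sites["pos"], sites["true_m"])
    }
    scaffolds = list(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": s, "LN": len(genome.sequences[s])} for s in scaffolds],
    }
    reads = []
    for i in range(n_pairs):
        scaf = scaffolds[int(rng.integers(len(scaffolds)))]
        seq = genome.sequences[scaf]
        start = int(rng.integers(0, len(seq) - fragment_length))
        bs_strand = "+" if rng.random() < 0.5 else "-"
        frag = list(seq[start : start + fragment_length])
        # bisulfite-convert the fragment in forward orientation
        for j in range(fragment_length):
            p = start + j
            if bs_strand == "+" and frag[j] == "C":
                is_cpg = seq[p + 1 : p + 2] == "G"
                m = meth_by_pos.get((scaf, p), 0.0) if is_cpg else 0.0
                methylated = rng.random() < m
                if not methylated and rng.random() < cfg.conversion:
                    frag[j] = "T"
            elif bs_strand == "-" and frag[j] == "G":
                is_cpg = seq[p - 1 : p] == "C"
                m = meth_by_pos.get((scaf, p - 1), 0.0) if is_cpg else 0.0
                methylated = rng.random() < m
                if not methylated and rng.random() < cfg.conversion:
                    frag[j] = "A"
            if rng.random() < cfg.error_rate:
                frag[j] = "ACGT"[int(rng.integers(4))]
        mate1 = "".join(frag[:read_length])
        mate2 = "".join(frag[-read_length:])
        m2_start = start + fragment_length - read_length
        q1 = _sample_qualities(rng, read_length, cfg.quality_levels)
        q2 = _sample_qualities(rng, read_length, cfg.quality_levels)
        reads.append((scaf, start, f"frag{i:06d}", mate1, q1, True, m2_start, bs_strand))
        reads.append((scaf, m2_start, f"frag{i:06d}", mate2, q2, False, start, bs_strand))
    reads.sort(key=lambda r: (scaffolds.index(r[0]), r[1], r[2]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for scaf, pos, name, seq_str, quals, is_read1, mate_pos, bs_strand in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = seq_str
            a.reference_name = scaf
            a.reference_start = pos
            a.mapping_quality = 42
            a.cigarstring = f"{len(seq_str)}M"
            a.flag = 0x1 | 0x2 | (0x40 if is_read1 else 0x80)
            a.next_reference_name = scaf
            a.next_reference_start = mate_pos
            a.template_length = fragment_length if is_read1 else -fragment_length
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            a.set_tag("ZS", bs_strand)
            out.write(a)


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    truth: Truth,
    rng: np.random.Generator,
    n_replicates: int | None = None,
    site_truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Replicate TPM matrix (genes x replicates) for one tissue.

    Per gene, the mean TPM is log-normal in the gene's expression
    percentile and replicate values are Gamma-distributed with the gene's
    true CV.  Passing ``site_truth`` (e.g. the second species' shifted
    truth) recomputes CV from that species' gene-body methylation, keeping
    the CV-methylation coupling consistent across species.
    """
    cfg = truth.config
    n_replicates = n_replicates or cfg.n_replicates
    g = truth.genes
    z = stats.norm.ppf(np.clip(g["expr_percentile"].to_numpy(), 1e-9, 1 - 1e-9))
    mean_tpm = np.exp(cfg.expr_log_mu + cfg.expr_log_sd * z)
    if site_truth is not None:
        meth = site_truth.groupby("gene_id")["true_m"].mean().reindex(g["gene_id"])
        meth = meth.fillna(g.set_index("gene_id")["true_meth"]).to_numpy()
        cv = np.maximum(
            cfg.cv_min, cfg.cv_a - cfg.cv_b * meth + rng.normal(0, cfg.cv_noise_sd, len(g))
        )
    else:
        cv = g["true_cv"].to_numpy()
    shape = 1.0 / cv**2
    tpm = rng.gamma(shape[:, None], (mean_tpm * cv**2)[:, None],
                    size=(len(g), n_replicates))
    return pd.DataFrame(
        tpm, index=pd.Index(g["gene_id"], name="gene_id"),
        columns=[f"rep{r + 1}" for r in range(n_replicates)],
    )


# ---------------------------------------------------------------------------
# ATAC


def generate_atac(
    genome: GenomeIndex,
    truth: Truth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fragments (uniform background + Gaussian TSS-centred per-gene
    enrichment proportional to the truth amplitude) and the peak intervals
    where binned fragment rate exceeds the background by the configured
    factor."""
    cfg = truth.config
    rows = []
    flo, fhi = cfg.fragment_length_range
    lengths = genome.lengths
    for chrom, length in lengths.items():
        n_bg = rng.poisson(cfg.atac_background_per_kb * length / 1000)
        starts = rng.integers(0, length - fhi, size=n_bg)
        sizes = rng.integers(flo, fhi + 1, size=n_bg)
        for s, L in zip(starts, sizes):
            rows.append((chrom, int(s), int(s + L)))
    for g in truth.genes.itertuples():
        n_frag = rng.poisson(cfg.atac_frags_per_gene * g.atac_amplitude)
        centers = rng.normal(g.tss, cfg.atac_tss_sd, size=n_frag)
        sizes = rng.integers(flo, fhi + 1, size=n_frag)
        limit = lengths[g.chrom]
        for c, L in zip(centers, sizes):
            s = int(np.clip(c - L / 2, 0, limit - L))
            rows.append((g.chrom, s, s + int(L)))
    fragments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    fragments = fragments.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    # peak calling stand-in: binned midpoint counts vs genome background
    peaks = []
    mids = (fragments["start"] + fragments["end"]) // 2
    for chrom, length in lengths.items():
        sel = fragments["chrom"] == chrom
        counts, edges = np.histogram(
            mids[sel], bins=np.arange(0, length + cfg.peak_bin, cfg.peak_bin)
        )
        background = max(np.median(counts), 0.5)
        hot = counts > cfg.peak_factor * background
        i = 0
        while i < len(hot):
            if hot[i]:
                j = i
                while j + 1 < len(hot) and hot[j + 1]:
                    j += 1
                peaks.append((chrom, int(edges[i]), int(edges[j + 1])))
                i = j + 1
            else:
                i += 1
    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
    return fragments, peaks_df


# ---------------------------------------------------------------------------
# full dataset emission


def emit_dataset(config: SynthConfig, outdir: str | Path) -> Path:
    """Generate and write a complete miniature study to ``outdir``:
    genome.fa, annot.gff3, repeats.bed, per-sample retained-site tables for
    two tissues x two animals and a second species, TPM matrices, ATAC
    fragments and peaks, truth tables and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, annotation, truth = generate_genome(config, rng)
    write_fasta(genome, outdir / "genome.fa")
    write_gff3(annotation, outdir / "annot.gff3")
    write_repeats_bed(annotation.repeats, outdir / "repeats.bed")

    samples = {
        "spA_animal1_hepatopancreas": truth.cpg_sites,
        "spA_animal1_muscle": truth.cpg_sites,
        "spA_animal2_hepatopancreas": truth.cpg_sites,
        "spA_animal2_muscle": truth.cpg_sites,
        "spB_animal1_hepatopancreas": species_b_truth(truth),
    }
    for name, site_truth in samples.items():
        counts = generate_site_counts(site_truth, config, rng)
        write_sites_tsv(retained_sites(counts), outdir / f"wgbs_{name}.sites.tsv")

    for tissue in ("hepatopancreas", "muscle", "hemocytes"):
        tpm = generate_expression(truth, rng)
        tpm.to_csv(outdir / f"tpm_{tissue}.tsv", sep="\t", float_format="%.6g")

    fragments, peaks = generate_atac(genome, truth, rng)
    write_fragments_bed(fragments, outdir / "atac_frags.bed")
    write_peaks_bed(peaks, outdir / "atac_peaks.bed")

    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False,
                       float_format="%.8g")
    truth.cpg_sites.to_csv(outdir / "truth_cpgs.tsv", sep="\t", index=False,
                           float_format="%.8g")
    (outdir / "config.json").write_text(config.to_json())
    return outdir
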