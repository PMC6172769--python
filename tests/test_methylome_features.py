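"""Methylome summaries: windows, features, gene bodies, o/e, repeats."""

import numpy as np
import pandas as pd
import pytest

from gbmethyl import methylome_features as mf
from gbmethyl import synthetic_data as sd
from gbmethyl.io_formats import AnnotationSet, GeneRecord, GenomeIndex, RepeatRecord


def sites_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    df["coverage"] = df["meth"] + df["unmeth"]
    df["ratio"] = df["meth"] / df["coverage"]
    return df


# -- windows ----------------------------------------------------------------

def test_window_mean_and_missing():
    genome = GenomeIndex({"s": "A" * 4000})
    sites = sites_df([("s", 10, "+", 0, 5), ("s", 20, "+", 5, 0)])
    track = mf.window_methylation(sites, genome, window=2000)
    assert track["mean_ratio"].iloc[0] == pytest.approx(0.5)
    assert np.isnan(track["mean_ratio"].iloc[1])  # window without CpGs
    assert track["n_cpg"].tolist() == [2, 0]


def test_window_rejects_nonpositive_window():
    genome = GenomeIndex({"s": "A" * 100})
    with pytest.raises(ValueError):
        mf.window_methylation(sites_df([]), genome, window=0)


def test_window_means_match_bruteforce_oracle():
    rng = np.random.default_rng(4)
    genome = GenomeIndex({"s": "A" * 10_000})
    pos = np.sort(rng.choice(10_000, 300, replace=False))
    ratios = rng.random(300)
    sites = pd.DataFrame(
        {"chrom": "s", "pos": pos, "strand": "+", "meth": 0, "unmeth": 0,
         "coverage": 5, "ratio": ratios}
    )
    track = mf.window_methylation(sites, genome, window=2000, step=2000)
    for row in track.itertuples():
        inside = ratios[(pos >= row.start) & (pos < row.end)]
        if len(inside):
            assert row.mean_ratio == pytest.approx(inside.mean())
        else:
            assert np.isnan(row.mean_ratio)


# -- feature methylation ----------------------------------------------------

def test_feature_means_reflect_construction():
    gene = GeneRecord("g1", "s", 100, 300, "+", {"exon": [(100, 300)]})
    ann = AnnotationSet(genes=[gene])
    sites = sites_df(
        [("s", 150, "+", 9, 1), ("s", 200, "+", 9, 1), ("s", 500, "+", 1, 9)]
    )
    table = mf.feature_methylation(sites, ann).set_index("feature")
    assert table.loc["exon", "mean_ratio"] == pytest.approx(0.9)
    assert table.loc["exon", "mean_ratio"] > table.loc["genome", "mean_ratio"]


def test_feature_without_cpgs_is_missing_not_zero():
    gene = GeneRecord("g1", "s", 100, 300, "+", {"exon": [(100, 200)], "intron": [(200, 300)]})
    ann = AnnotationSet(genes=[gene])
    sites = sites_df([("s", 150, "+", 5, 5)])
    table = mf.feature_methylation(sites, ann).set_index("feature")
    assert np.isnan(table.loc["intron", "mean_ratio"])


def test_generator_enriches_gene_bodies(small_study, small_sites):
    """Exon/intron means exceed the genome mean, which exceeds repeats."""
    _, annotation, _ = small_study
    table = mf.feature_methylation(small_sites, annotation).set_index("feature")
    assert table.loc["exon", "mean_ratio"] > table.loc["genome", "mean_ratio"]
    assert table.loc["intron", "mean_ratio"] > table.loc["genome", "mean_ratio"]
    assert table.loc["genome", "mean_ratio"] > table.loc["repeat", "mean_ratio"]
    assert table.loc["gene", "mean_ratio"] > table.loc["genome", "mean_ratio"]


# -- gene-body summaries ----------------------------------------------------

def test_gene_body_mean_and_class():
    gene = GeneRecord("g1", "s", 0, 100, "+")
    sites = sites_df([("s", 10, "+", 9, 1), ("s", 20, "+", 8, 2), ("s", 30, "+", 10, 0)])
    summary = mf.gene_body_summary(sites, gene, min_cpgs=3)
    assert summary.mean_ratio == pytest.approx(0.9)
    assert summary.meth_class == "high"


def test_gene_mean_exactly_at_boundary_is_low():
    gene = GeneRecord("g1", "s", 0, 100, "+")
    sites = sites_df([("s", i, "+", 4, 6) for i in range(5)])  # mean 0.4
    summary = mf.gene_body_summary(sites, gene)
    assert summary.mean_ratio == pytest.approx(0.4)
    assert summary.meth_class == "low"  # high requires mean > 0.4


def test_insufficient_cpgs_flagged():
    gene = GeneRecord("g1", "s", 0, 100, "+")
    sites = sites_df([("s", 10, "+", 5, 5)])
    assert mf.gene_body_summary(sites, gene).meth_class == "insufficient"


def test_gene_table_matches_per_gene_summaries(small_study, small_sites):
    _, annotation, _ = small_study
    table = mf.gene_methylation_table(small_sites, annotation).set_index("gene_id")
    for gene in annotation.genes[:10]:
        single = mf.gene_body_summary(small_sites, gene)
        assert table.loc[gene.gene_id, "mean_ratio"] == pytest.approx(single.mean_ratio)
        assert table.loc[gene.gene_id, "n_cpgs"] == single.n_cpgs


def test_bimodal_histogram_has_two_component_modes():
    """Beta components near 0.05 and 0.85 appear as separated histogram modes."""
    cfg = sd.paper_like(seed=8, parabola_coupling=0.0)
    rng = np.random.default_rng(cfg.seed)
    _, annotation, truth = sd.generate_genome(cfg, rng)
    counts = sd.generate_site_counts(truth.cpg_sites, cfg, rng)
    summaries = mf.gene_methylation_table(sd.retained_sites(counts), annotation)
    hist = mf.methylation_histogram(summaries)
    modes = mf.histogram_modes(hist)
    assert any(m < 0.2 for m in modes), modes    # low component
    assert any(m >= 0.7 for m in modes), modes   # high component


# -- CpG o/e ----------------------------------------------------------------

def test_cpg_oe_arithmetic_and_classes():
    assert mf.cpg_oe("CGCG") == pytest.approx(2.0)
    assert mf.oe_class(2.0) == "high"
    assert mf.cpg_oe("CATGCATG") == 0.0
    assert mf.oe_class(0.0) == "low"
    assert mf.oe_class(0.6) == "medium"  # boundary: >= 0.6 is medium
    assert mf.oe_class(1.2) == "high"


def test_cpg_oe_undefined_without_c_or_g():
    with pytest.raises(ValueError):
        mf.cpg_oe("AATT")


def test_cpg_oe_matches_recount_oracle():
    rng = np.random.default_rng(30)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 200))))
        n_c, n_g = seq.count("C"), seq.count("G")
        if n_c == 0 or n_g == 0:
            continue
        n_cg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        assert mf.cpg_oe(seq) == pytest.approx(n_cg * len(seq) / (n_c * n_g))


def test_high_methylation_genes_are_cpg_poorer(small_study):
    """The generator couples the high component to lower CpG o/e."""
    genome, annotation, truth = small_study
    oe = mf.gene_oe_table(genome, annotation).set_index("gene_id")["oe"]
    g = truth.genes.set_index("gene_id")
    assert oe[g.index[g["component"] == "high"]].mean() < \
        oe[g.index[g["component"] == "low"]].mean()


# -- repeats ----------------------------------------------------------------

def test_repeat_strata_means():
    genes = [GeneRecord("g1", "s", 0, 1000, "+")]
    repeats = [RepeatRecord("s", 100, 200, "LINE"), RepeatRecord("s", 2000, 2100, "LINE")]
    ann = AnnotationSet(genes=genes, repeats=repeats)
    ann.compute_intragenic_flags()
    sites = sites_df([("s", 150, "+", 8, 2), ("s", 2050, "+", 1, 9)])
    table = mf.repeat_methylation(sites, ann).set_index("location")
    assert table.loc["intragenic", "mean_ratio"] == pytest.approx(0.8)
    assert table.loc["intergenic", "mean_ratio"] == pytest.approx(0.1)


def test_repeat_stratum_without_cpgs_is_missing():
    ann = AnnotationSet(genes=[], repeats=[RepeatRecord("s", 0, 50, "SINE")])
    ann.compute_intragenic_flags()
    table = mf.repeat_methylation(sites_df([]), ann)
    assert np.isnan(table["mean_ratio"].iloc[0])


def test_intragenic_repeats_more_methylated(small_study, small_sites):
    """Repeats inside genes inherit the (higher) host-gene methylation."""
    _, annotation, _ = small_study
    table = mf.repeat_methylation(small_sites, annotation)
    by_loc = table.groupby("location").apply(
        lambda t: np.average(t["mean_ratio"].fillna(0), weights=t["n_cpg"].clip(lower=1)),
        include_groups=False,
    )
    assert by_loc["intragenic"] > by_loc["intergenic"]


# -- methylated-CpG density -------------------------------------------------

def test_mcpg_density_counts():
    genome = GenomeIndex({"s": "A" * 2000})
    sites = sites_df([("s", i * 10, "+", 9, 1) for i in range(5)])
    track = mf.mcpg_density(sites, genome, window=1000)
    dens = track.set_index(["start", "strand"])["density_per_kb"]
    assert dens[(0, "+")] == 5.0
    assert dens[(1000, "+")] == 0.0
    assert dens[(0, "-")] == 0.0


def test_mcpg_density_zero_when_all_below_threshold():
    genome = GenomeIndex({"s": "A" * 1000})
    sites = sites_df([("s", i, "+", 7, 3) for i in range(10, 50, 10)])  # ratio 0.7
    track = mf.mcpg_density(sites, genome)
    assert (track["density_per_kb"] == 0).all()


def test_mcpg_density_matches_bruteforce_oracle(small_study, small_sites):
    genome, _, _ = small_study
    track = mf.mcpg_density(small_sites, genome, window=1000)
    is_m = (small_sites["ratio"] >= 0.8) & (small_sites["coverage"] >= 3)
    msites = small_sites[is_m]
    for row in track.sample(50, random_state=0).itertuples():
        n = (
            (msites["chrom"] == row.chrom)
            & (msites["strand"] == row.strand)
            & (msites["pos"] >= row.start)
            & (msites["pos"] < row.end)
        ).sum()
        assert row.density_per_kb == pytest.approx(n / ((row.end - row.start) / 1000))
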