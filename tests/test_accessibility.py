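"""TSS coverage extraction, metagene profiles, strata, peak overlap."""

import numpy as np
import pandas as pd
import pytest

from gbmethyl import accessibility as acc
from gbmethyl.io_formats import AnnotationSet, GeneRecord, GenomeIndex


def make_annotation(genes):
    return AnnotationSet(genes=genes)


GENOME = GenomeIndex({"s": "A" * 50_000})


def frag(start, end, chrom="s"):
    return {"chrom": chrom, "start": start, "end": end}


def test_single_fragment_coverage_offsets():
    gene = GeneRecord("g1", "s", 10_000, 12_000, "+")
    frags = pd.DataFrame([frag(10_000, 10_100)])
    genes, cov, valid = acc.tss_coverage(frags, make_annotation([gene]), GENOME, flank=200)
    vec = cov[0]
    assert vec[200:300].tolist() == [1.0] * 100  # offsets 0..99
    assert vec[:200].sum() == 0 and vec[300:].sum() == 0
    assert valid.all()


def test_minus_strand_coverage_is_mirrored():
    gene = GeneRecord("g1", "s", 8_000, 10_001, "-")  # TSS at 10_000
    frags = pd.DataFrame([frag(10_000, 10_100)])
    genes, cov, _ = acc.tss_coverage(frags, make_annotation([gene]), GENOME, flank=200)
    vec = cov[0]
    # base TSS+k (genomic) is offset -k for a '-' gene: fragment covers
    # genomic [TSS, TSS+100) -> offsets -99..0
    assert vec[101:201].tolist() == [1.0] * 100
    assert vec[201:].sum() == 0


def test_coverage_matches_bruteforce_oracle():
    rng = np.random.default_rng(19)
    genes = [
        GeneRecord(f"g{i}", "s", int(s), int(s) + 1000, "+" if i % 2 else "-")
        for i, s in enumerate(rng.integers(3_000, 40_000, 8))
    ]
    starts = rng.integers(0, 49_000, 500)
    frags = pd.DataFrame(
        {"chrom": "s", "start": starts, "end": starts + rng.integers(50, 400, 500)}
    )
    flank = 500
    table, cov, valid = acc.tss_coverage(frags, make_annotation(genes), GENOME, flank=flank)
    for gi, g in enumerate(genes):
        expected = np.zeros(2 * flank)
        for f in frags.itertuples():
            for off in range(-flank, flank):
                p = g.tss + off if g.strand == "+" else g.tss - off
                if f.start <= p < f.end:
                    expected[off + flank] += 1
        np.testing.assert_array_equal(cov[gi], expected)


def test_coverage_conservation():
    """Sum of the vector equals total fragment bases inside the window."""
    gene = GeneRecord("g1", "s", 10_000, 12_000, "+")
    frags = pd.DataFrame([frag(9_900, 10_050), frag(9_000, 9_100), frag(10_150, 10_160)])
    _, cov, _ = acc.tss_coverage(frags, make_annotation([gene]), GENOME, flank=200)
    overlap = (10_050 - 9_800) + 0 + 10  # fragment 2 outside window
    assert cov[0].sum() == min(10_050, 10_200) - max(9_900, 9_800) + 10


def test_window_truncated_at_scaffold_start_is_masked(caplog):
    gene = GeneRecord("g1", "s", 50, 500, "+")
    frags = pd.DataFrame([frag(0, 100)])
    with caplog.at_level("WARNING"):
        _, cov, valid = acc.tss_coverage(frags, make_annotation([gene]), GENOME, flank=200)
    assert not valid[0, :150].any()  # offsets before scaffold start
    assert valid[0, 150:].all()
    assert "truncated" in caplog.text


def test_metagene_mean_and_empty_stratum(caplog):
    g1 = GeneRecord("g1", "s", 10_000, 12_000, "+")
    g2 = GeneRecord("g2", "s", 20_000, 22_000, "+")
    frags = pd.DataFrame([frag(10_000, 10_010), frag(10_000, 10_010)])
    genes, cov, valid = acc.tss_coverage(
        frags, make_annotation([g1, g2]), GENOME, flank=100
    )
    with caplog.at_level("WARNING"):
        prof = acc.metagene(
            genes, cov, valid, {"both": ["g1", "g2"], "none": []}, flank=100, bin_size=10
        )
    assert set(prof["stratum"]) == {"both"}
    at_tss = prof[(prof["stratum"] == "both") & (prof["offset"] == 5.0)]
    assert at_tss["mean_coverage"].iloc[0] == pytest.approx(1.0)  # (2 + 0) / 2


def test_strand_reversal_leaves_metagene_unchanged():
    """Mirroring fragments about the TSS and flipping strand is a no-op."""
    tss = 10_000
    rng = np.random.default_rng(23)
    starts = tss + rng.integers(-400, 400, 100)
    frags_fwd = pd.DataFrame({"chrom": "s", "start": starts, "end": starts + 50})
    # mirrored: interval [s, e) about tss becomes [2*tss - e + 1, 2*tss - s + 1)
    frags_rev = pd.DataFrame(
        {"chrom": "s", "start": 2 * tss - (starts + 50) + 1, "end": 2 * tss - starts + 1}
    )
    g_fwd = GeneRecord("g", "s", tss, tss + 1000, "+")
    g_rev = GeneRecord("g", "s", tss - 1000, tss + 1, "-")
    out = []
    for g, fr in ((g_fwd, frags_fwd), (g_rev, frags_rev)):
        genes, cov, valid = acc.tss_coverage(fr, make_annotation([g]), GENOME, flank=500)
        out.append(acc.metagene(genes, cov, valid, {"all": ["g"]}, flank=500))
    pd.testing.assert_frame_equal(out[0], out[1])


# -- strata -----------------------------------------------------------------

def variability(quintiles):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(len(quintiles))], "cv_quintile": quintiles}
    )


def summaries(means):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(means))],
            "mean_ratio": means,
            "meth_class": ["high" if m > 0.4 else "low" for m in means],
        }
    )


def test_stratify_by_variability_rules():
    s = summaries([0.3, 0.41, 0.39, 0.8])
    v = variability([1, 5, 3, 1])
    strata = acc.stratify_by_variability(s, v)
    assert strata["low_meth_stable"] == ["g0"]
    assert strata["high_meth_variable"] == ["g1"]  # 0.41 > 0.4 boundary
    assert strata["high_meth_stable"] == ["g3"]
    assert all("g2" not in v for v in strata.values())  # quintile 3: neither


def test_stratify_matches_predicate_oracle():
    rng = np.random.default_rng(29)
    means = rng.random(1000)
    quint = rng.integers(1, 6, 1000)
    strata = acc.stratify_by_variability(summaries(means), variability(quint))
    for i in range(1000):
        gid = f"g{i}"
        expected = None
        if means[i] < 0.4 and quint[i] == 1:
            expected = "low_meth_stable"
        elif means[i] < 0.4 and quint[i] == 5:
            expected = "low_meth_variable"
        elif means[i] > 0.4 and quint[i] == 1:
            expected = "high_meth_stable"
        elif means[i] > 0.4 and quint[i] == 5:
            expected = "high_meth_variable"
        for label, members in strata.items():
            assert (gid in members) == (label == expected)


# -- peak-promoter overlap --------------------------------------------------

def test_peak_counted_once_across_two_promoters():
    g1 = GeneRecord("g1", "s", 10_000, 12_000, "+")
    g2 = GeneRecord("g2", "s", 10_200, 13_000, "+")
    peaks = pd.DataFrame([frag(9_500, 10_400)])  # hits both promoters
    n, table = acc.peak_promoter_overlap(peaks, make_annotation([g1, g2]))
    assert n == 1
    assert table["promoter_overlap"].tolist() == [True]


def test_no_peaks_gives_zero():
    g = GeneRecord("g1", "s", 10_000, 12_000, "+")
    n, _ = acc.peak_promoter_overlap(
        pd.DataFrame(columns=["chrom", "start", "end"]), make_annotation([g])
    )
    assert n == 0


def test_peak_overlap_matches_bruteforce_oracle():
    rng = np.random.default_rng(31)
    genes = [
        GeneRecord(f"g{i}", "s", int(s), int(s) + 500, "+" if i % 2 else "-")
        for i, s in enumerate(rng.integers(2_000, 45_000, 30))
    ]
    starts = rng.integers(0, 49_000, 200)
    peaks = pd.DataFrame(
        {"chrom": "s", "start": starts, "end": starts + rng.integers(100, 900, 200)}
    )
    n, table = acc.peak_promoter_overlap(peaks, make_annotation(genes), 1000, 500)
    expected_flags = []
    for p in peaks.itertuples():
        hit = False
        for g in genes:
            if g.strand == "+":
                ps, pe = g.tss - 1000, g.tss + 500
            else:
                ps, pe = g.tss - 499, g.tss + 1001
            if p.start < pe and p.end > ps:
                hit = True
        expected_flags.append(hit)
    assert table["promoter_overlap"].tolist() == expected_flags
    assert n == sum(expected_flags)


def test_replicate_correlation_and_pooling():
    rng = np.random.default_rng(37)
    base = rng.poisson(20, 500).astype(float)
    reps = [base + rng.normal(0, 1, 500) for _ in range(3)]
    table = acc.replicate_correlation(reps)
    assert (table["pearson_r"] > 0.9).all()
    frames = [pd.DataFrame([frag(0, 10)]), pd.DataFrame([frag(5, 15)])]
    assert len(acc.pool_fragments(frames)) == 2
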