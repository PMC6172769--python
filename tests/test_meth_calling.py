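"""Methylation calling: quality filters, per-strand coverage, conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gbmethyl.io_formats import PileupColumn, ReadObservation
from gbmethyl import meth_calling as mc
from gbmethyl import synthetic_data as sd


def obs(base="C", q=37, flanks=(30, 30, 30, 30), name=""):
    return ReadObservation(base, q, tuple(flanks), name)


def col(observations, chrom="s", pos=10, strand="+"):
    return PileupColumn(chrom, pos, strand, list(observations))


# -- base filtering ---------------------------------------------------------

@pytest.mark.parametrize(
    "quality, flanks, kept",
    [
        (30, (20, 20, 20, 20), True),   # both thresholds exactly met
        (29, (20, 20, 20, 20), False),  # C-position quality below 30
        (30, (20, 19, 20, 20), False),  # one flank below 20
        (37, (None, 20, 20, 20), False),  # C within 2 bases of a read end
    ],
)
def test_filter_boundaries(quality, flanks, kept):
    out = mc.filter_read_bases(col([obs(q=quality, flanks=flanks)]), mc.CallingFilters())
    assert (len(out.observations) == 1) is kept


def test_filter_matches_predicate_oracle():
    rng = np.random.default_rng(7)
    observations = [
        obs(
            q=int(rng.integers(0, 45)),
            flanks=tuple(int(q) for q in rng.integers(0, 45, 4)),
            name=f"r{i}",
        )
        for i in range(100)
    ]
    filters = mc.CallingFilters()
    out = mc.filter_read_bases(col(observations), filters)
    expected = [
        o for o in observations
        if o.quality >= 30 and all(q >= 20 for q in o.flanks)
    ]
    assert out.observations == expected


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    q_c=st.integers(0, 45),
    q_flank=st.integers(0, 45),
    seed=st.integers(0, 1000),
)
def test_filter_monotonicity(q_c, q_flank, seed):
    """Raising any threshold never increases the retained count."""
    rng = np.random.default_rng(seed)
    column = col(
        obs(q=int(rng.integers(0, 45)), flanks=tuple(int(x) for x in rng.integers(0, 45, 4)))
        for _ in range(30)
    )
    base = len(mc.filter_read_bases(column, mc.CallingFilters(q_c, q_flank)).observations)
    stricter = len(
        mc.filter_read_bases(column, mc.CallingFilters(q_c + 1, q_flank + 1)).observations
    )
    assert stricter <= base


# -- dyad calling -----------------------------------------------------------

def _minus_base(state):
    return {"C": "G", "T": "A"}[state]


def test_call_cpg_both_strands_retained():
    plus = col([obs("C") for _ in range(5)], pos=10, strand="+")
    minus = col(
        [obs("G"), obs("G"), obs("A")], pos=11, strand="-"
    )
    site_p, site_m = mc.call_cpg(plus, minus)
    assert site_p.ratio == 1.0 and site_p.coverage == 5
    assert site_m.ratio == pytest.approx(2 / 3) and site_m.coverage == 3


def test_call_cpg_coverage_below_three_drops_strand():
    plus = col([obs("C"), obs("C")], pos=10, strand="+")
    minus = col([obs("G")] * 4, pos=11, strand="-")
    site_p, site_m = mc.call_cpg(plus, minus)
    assert site_p is None  # 2 reads < 3 per strand
    assert site_m is not None


def test_call_cpg_non_dyad_errors():
    with pytest.raises(ValueError, match="dyad"):
        mc.call_cpg(col([], pos=10, strand="+"), col([], pos=12, strand="-"))


def test_call_cpg_ignores_noninformative_bases():
    # sequencing-error bases (G on '+') count toward neither state
    plus = col([obs("C"), obs("C"), obs("T"), obs("G")], pos=10, strand="+")
    minus = col([obs("G")] * 3, pos=11, strand="-")
    site_p, _ = mc.call_cpg(plus, minus)
    assert (site_p.meth, site_p.unmeth) == (2, 1)


def test_thousand_dyads_match_recount_oracle():
    """Retained sites and ratios equal a brute-force recount on random dyads."""
    rng = np.random.default_rng(42)
    filters = mc.CallingFilters()
    for i in range(1000):
        dyad = []
        for strand, pos in (("+", 100), ("-", 101)):
            n = int(rng.integers(0, 12))
            observations = []
            for j in range(n):
                state = "C" if rng.random() < rng.random() else "T"
                base = state if strand == "+" else _minus_base(state)
                if rng.random() < 0.02:  # occasional miscall
                    base = "ACGT"[int(rng.integers(4))]
                observations.append(
                    obs(
                        base,
                        q=int(rng.integers(20, 45)),
                        flanks=tuple(int(x) for x in rng.integers(10, 45, 4)),
                        name=f"r{i}_{strand}{j}",
                    )
                )
            dyad.append(col(observations, pos=pos, strand=strand))
        got = mc.call_cpg(dyad[0], dyad[1], filters)
        for column, site in zip(dyad, got):
            informative = {"+": {"C": "C", "T": "T"}, "-": {"G": "C", "A": "T"}}[column.strand]
            passing = [
                o for o in column.observations
                if o.quality >= 30 and all(q is not None and q >= 20 for q in o.flanks)
            ]
            m = sum(1 for o in passing if informative.get(o.base) == "C")
            u = sum(1 for o in passing if informative.get(o.base) == "T")
            if m + u >= 3:
                assert site is not None
                assert (site.meth, site.unmeth) == (m, u)
                assert site.ratio == pytest.approx(m / (m + u))
            else:
                assert site is None


# -- conversion -------------------------------------------------------------

def test_conversion_arithmetic():
    cols = [col([obs("T")] * 99 + [obs("C")], pos=i * 5) for i in range(1)]
    report = mc.estimate_conversion(cols)
    assert report.rate == pytest.approx(0.99)
    all_c = mc.estimate_conversion([col([obs("C")] * 10)])
    assert all_c.rate == 0.0


def test_conversion_zero_observations_flagged():
    report = mc.estimate_conversion([col([])])
    assert report.rate is None


def test_conversion_simulation_within_binomial_ci():
    rng = np.random.default_rng(9)
    true = 0.98
    n_sites, depth = 10_000, 1
    k = rng.binomial(1, true, size=n_sites)
    cols = [
        col([obs("T" if ki else "C")], pos=3 * i) for i, ki in enumerate(k)
    ]
    report = mc.estimate_conversion(cols)
    sd_hat = np.sqrt(true * (1 - true) / n_sites)
    assert abs(report.rate - true) < 3 * sd_hat


# -- methylated-site classification ----------------------------------------

@pytest.mark.parametrize(
    "ratio, cov, expected",
    [(0.8, 3, True), (0.79, 100, False), (0.9, 2, False), (1.0, 3, True)],
)
def test_classify_methylated_boundaries(ratio, cov, expected):
    assert bool(mc.classify_methylated(ratio, cov)) is expected


def test_classify_methylated_matches_predicate_oracle():
    rng = np.random.default_rng(12)
    ratio = rng.random(500)
    cov = rng.integers(0, 30, 500)
    got = mc.classify_methylated(ratio, cov)
    np.testing.assert_array_equal(got, (ratio >= 0.8) & (cov >= 3))


# -- statistical properties -------------------------------------------------

def test_parameter_recovery_at_depth_30():
    """Mean called ratio converges to the site truth (conversion 1.0)."""
    rng = np.random.default_rng(21)
    m = 0.3
    cfg = sd.paper_like(conversion=1.0, error_rate=0.0)
    truth = sd.Truth(
        genes=None,
        cpg_sites=__import__("pandas").DataFrame(
            {"chrom": "s", "pos": np.arange(1000) * 10, "gene_id": "", "true_m": m}
        ),
        config=cfg,
    )
    counts = sd.generate_site_counts(truth.cpg_sites, cfg, rng, depth=30)
    retained = sd.retained_sites(counts)
    grand_mean = retained["ratio"].mean()
    se = np.sqrt(m * (1 - m) / retained["coverage"].sum())
    assert abs(grand_mean - m) < 3 * np.sqrt(m * (1 - m) / 15 / len(retained))
    assert se < 0.01  # sanity: plenty of evidence


def test_symmetric_dyads_correlate_across_strands():
    """Symmetric dyad methylation gives strand-ratio correlation > 0.9."""
    rng = np.random.default_rng(33)
    import pandas as pd

    m = rng.beta(0.4, 0.4, size=2000)  # spread of per-dyad truths
    cfg = sd.paper_like(conversion=1.0, error_rate=0.0)
    sites = pd.DataFrame({"chrom": "s", "pos": np.arange(2000) * 10, "gene_id": "", "true_m": m})
    counts = sd.generate_site_counts(sites, cfg, rng, depth=30)
    plus = counts[counts["strand"] == "+"].reset_index(drop=True)
    minus = counts[counts["strand"] == "-"].reset_index(drop=True)
    ok = (plus["coverage"] >= 3) & (minus["coverage"] >= 3)
    r = np.corrcoef(plus.loc[ok, "ratio"], minus.loc[ok, "ratio"])[0, 1]
    assert r > 0.9
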