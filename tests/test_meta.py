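"""TE metaplots, TSS histograms, centile stratification, correlations,
overlap counting, chromosome profiles."""

import numpy as np
import pandas as pd
import pytest

from mossmeth import (
    CentileScheme,
    chromosome_profile,
    correlation_matrix,
    overlap_summary,
    stratify_quantiles,
    te_metaplot,
    te_tss_histogram,
)
from mossmeth.meta import histone_log_ratio
from mossmeth.tracks import WindowTracks

from conftest import make_calls


def ann(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "type", "id"])


# ------------------------------------------------------------- te_metaplot

def brute_metaplot(calls, tes, interval, flank=0):
    """Independent pooled-mean computation by explicit per-TE loops."""
    pooled = {}
    for _, te in tes.iterrows():
        for _, c in calls[calls["chrom"] == te["chrom"]].iterrows():
            if te["strand"] == "-":
                if not (te["start"] <= c["pos"] < te["end"] + flank):
                    continue
                off = (te["end"] - 1) - c["pos"]
            else:
                if not (te["start"] - flank <= c["pos"] < te["end"]):
                    continue
                off = c["pos"] - te["start"]
            pooled.setdefault((off // interval) * interval, []).append(c["level"])
    return {k: float(np.mean(v)) for k, v in sorted(pooled.items())}


def test_metaplot_matches_hand_pooling():
    tes = ann([("chr1", 100, 350, "+", "TE", "t1"),
               ("chr1", 600, 750, "-", "TE", "t2")])
    calls = make_calls(
        [("chr1", 110, "+", "CG", 8, 2),
         ("chr1", 250, "+", "CG", 1, 3),
         ("chr1", 340, "-", "CG", 1, 1),
         ("chr1", 610, "+", "CG", 3, 1),    # offset 139 on the minus TE
         ("chr1", 740, "+", "CG", 0, 4),    # offset 9 on the minus TE
         ("chr1", 900, "+", "CG", 9, 1)]    # outside both
    )
    prof = te_metaplot(calls, tes, interval=100)
    want = brute_metaplot(calls, tes, 100)
    assert dict(zip(prof["offset"], prof["mean_level"])) == pytest.approx(want)
    # a 250-bp element contributes nothing beyond offset 200
    single = te_metaplot(calls, tes.iloc[[0]], interval=100)
    assert single["offset"].max() < 300
    assert single.loc[single["offset"] == 200, "n_te"].tolist() == [1]


def test_metaplot_flank_and_empty():
    tes = ann([("chr1", 100, 200, "+", "TE", "t1")])
    calls = make_calls([("chr1", 60, "+", "CG", 1, 0)])
    prof = te_metaplot(calls, tes, interval=50, flank=50)
    assert prof["offset"].tolist() == [-50]
    assert te_metaplot(calls, ann([]), interval=100).empty


# -------------------------------------------------------- te_tss_histogram

def brute_tss_hist(genes, tes, window, upstream):
    """Enumerate all gene-edge pairs; count each gene once at its closest
    facing TE edge."""
    n_windows = -(-upstream // window)
    counts = np.zeros(n_windows, int)
    for _, gene in genes.iterrows():
        best = None
        for _, te in tes.iterrows():
            if te["chrom"] != gene["chrom"]:
                continue
            if gene["strand"] == "+":
                d = gene["start"] - (te["end"] - 1)
            else:
                d = te["start"] - (gene["end"] - 1)
            if 1 <= d <= upstream and (best is None or d < best):
                best = d
        if best is not None:
            counts[(best - 1) // window] += 1
    return counts


def test_tss_histogram_matches_brute_force():
    genes = ann([("chr1", 1000, 2000, "+", "gene", "g1"),
                 ("chr1", 3000, 4000, "-", "gene", "g2"),
                 ("chr1", 5000, 6000, "+", "gene", "g3"),
                 ("chr2", 500, 900, "+", "gene", "g4")])
    tes = ann([("chr1", 800, 991, "+", "TE", "t1"),    # ends 10 bp before g1 TSS
               ("chr1", 4100, 4400, "+", "TE", "t2"),  # starts 101 bp past g2 TSS
               ("chr1", 4800, 4960, "+", "TE", "t3"),  # 41 bp upstream of g3
               ("chr1", 100, 700, "+", "TE", "t4")])
    hist = te_tss_histogram(genes, tes, window=25, upstream=500)
    want = brute_tss_hist(genes, tes, 25, 500)
    np.testing.assert_array_equal(hist["n_genes"].to_numpy(), want)
    np.testing.assert_allclose(hist["percent"].to_numpy(), want / 4 * 100)
    # the 10-bp-upstream edge lands in the first (0-25 bp) window
    assert hist.loc[0, "n_genes"] >= 1


def test_tss_histogram_counts_each_gene_at_most_once():
    genes = ann([("chr1", 1000, 2000, "+", "gene", "g1")])
    tes = ann([("chr1", 700, 960, "+", "TE", "t1"),
               ("chr1", 400, 600, "+", "TE", "t2")])  # farther edge ignored
    hist = te_tss_histogram(genes, tes)
    assert hist["n_genes"].sum() == 1
    assert hist.loc[hist["n_genes"] == 1, "offset"].tolist() == [25]  # d = 41


def test_tss_histogram_empty_and_unstranded():
    genes = ann([("chr1", 1000, 2000, "+", "gene", "g1")])
    hist = te_tss_histogram(genes, ann([]))
    assert (hist["percent"] == 0).all()
    bad = ann([("chr1", 10, 20, ".", "gene", "g")])
    with pytest.raises(ValueError, match="strand"):
        te_tss_histogram(bad, ann([]))


# ----------------------------------------------------- stratify_quantiles

def test_stratify_equal_groups_for_increasing_feature():
    idx = pd.RangeIndex(100)
    values = pd.Series(np.arange(100.0), index=idx)
    feature = pd.Series(np.arange(100.0) * 2 + 1, index=idx)
    res = stratify_quantiles(values, feature, CentileScheme("f", 5))
    sizes = res.groups.value_counts()
    assert sorted(sizes.tolist()) == [20] * 5
    assert res.summary.loc[res.summary["group"] == "q1", "median"].iloc[0] == 9.5


def test_stratify_nd_and_constant_feature():
    idx = pd.RangeIndex(10)
    values = pd.Series(np.arange(10.0), index=idx)
    feature = pd.Series(1.0, index=idx)
    nd = pd.Series([True] + [False] * 9, index=idx)
    res = stratify_quantiles(values, feature, CentileScheme("f", 4), nd_mask=nd)
    assert (res.groups.iloc[0]) == "ND"
    # constant feature: all non-ND windows collapse into the lowest centile
    assert set(res.groups.iloc[1:]) == {"q1"}
    # union of groups covers the input
    assert res.groups.notna().all()


def test_histone_log_ratio_flags_nd_windows():
    tracks = WindowTracks(50, {"chr1": 200})
    tracks.set("H3K9me2", "chr1", [1.0, 0.0, 2.0, 1.0])
    tracks.set("H3K4me3", "chr1", [1.0, 1.0, 1.0, 1.0])
    tracks.set("H3", "chr1", [1.0, 1.0, 0.0, 3.0])
    ratio, nd = histone_log_ratio(tracks, "H3K9me2", "H3K4me3", eps=1.0)
    assert nd.tolist() == [False, True, True, False]
    assert ratio.iloc[0] == pytest.approx(0.0)
    assert ratio.iloc[3] == pytest.approx(np.log2(2 / 4))


# ------------------------------------------------------ correlation_matrix

def test_correlation_matrix_closed_form():
    rng = np.random.default_rng(3)
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    table = pd.DataFrame({"x": x, "neg_x": -x, "y": y, "const": np.ones(10)})
    corr = correlation_matrix(table)
    assert corr.loc["x", "x"] == pytest.approx(1.0)
    assert corr.loc["x", "neg_x"] == pytest.approx(-1.0)
    # textbook Pearson
    want = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert corr.loc["x", "y"] == pytest.approx(want)
    assert np.isnan(corr.loc["x", "const"])  # zero variance flagged as NaN
    # pairwise-complete deletion with too few windows
    table2 = pd.DataFrame({"a": [1.0, np.nan, np.nan, 2.0],
                           "b": [1.0, 2.0, 3.0, np.nan]})
    assert np.isnan(correlation_matrix(table2).loc["a", "b"])


# --------------------------------------------------------- overlap_summary

def overlap_fixture():
    tes = ann([("chr1", i * 1000, i * 1000 + 500, "+", "TE", f"t{i}")
               for i in range(10)])
    rows = []
    for i in range(10):
        level = (9, 1) if i < 4 else (0, 10)  # TEs 0-3 methylated (0.9)
        rows.append(("chr1", i * 1000 + 10, "+", "CHH", *level))
    calls = make_calls(rows)
    tracks = WindowTracks(50, {"chr1": 10_000})
    sirna = np.zeros(200)
    return tes, calls, tracks, sirna


def test_overlap_counts_and_fraction():
    tes, calls, tracks, sirna = overlap_fixture()
    sirna[0] = 5     # TE 0 (methylated)
    sirna[20] = 5    # TE 1 (methylated)
    sirna[100] = 5   # TE 5 (unmethylated)
    tracks.set("siRNA", "chr1", sirna)
    out = overlap_summary(tracks, calls, tes, min_te_level=0.5, min_sirna_count=1)
    assert out == {"n_te": 10, "n_methylated": 4, "n_sirna": 3, "n_both": 2,
                   "fraction_methylated_with_sirna": 0.5}


def test_overlap_everywhere_and_nowhere():
    tes, calls, tracks, sirna = overlap_fixture()
    tracks.set("siRNA", "chr1", np.ones(200))
    assert overlap_summary(tracks, calls, tes, 0.5, 1)[
        "fraction_methylated_with_sirna"] == 1.0
    tracks.set("siRNA", "chr1", np.zeros(200))
    assert overlap_summary(tracks, calls, tes, 0.5, 1)[
        "fraction_methylated_with_sirna"] == 0.0


# ------------------------------------------------------ chromosome_profile

def test_profile_constant_and_single_bin():
    rows = [("chr1", p, "+", "CG", 3, 7) for p in range(100, 20_000, 400)]
    prof = chromosome_profile(make_calls(rows), "chr1", 20_000, bin_size=2000)
    np.testing.assert_allclose(prof["smoothed"].dropna(), 0.3)
    single = chromosome_profile(make_calls(rows), "chr1", 20_000, bin_size=50_000)
    assert len(single) == 1
    assert single["smoothed"].iloc[0] == pytest.approx(0.3)


def test_profile_monotone_gradient_stays_monotone():
    rows = []
    for i, p in enumerate(range(100, 40_000, 200)):
        level = i / 200.0
        rows.append(("chr1", p, "+", "CG", int(level * 100), 100 - int(level * 100)))
    prof = chromosome_profile(make_calls(rows), "chr1", 40_000, bin_size=4000,
                              span=0.4)
    sm = prof["smoothed"].dropna().to_numpy()
    assert (np.diff(sm) >= -1e-9).all()
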