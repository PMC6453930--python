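"""Genome-scale meta-analyses over TEs, chromatin and methylation.

Covers the summary analyses layered on top of the single-c and window
tables: TE metaplots aligned at the 5' end, the TE-edge frequency histogram
upstream of gene TSSs, centile stratification of per-window percent change
by chromatin features, Pearson correlation matrices, siRNA/methylation/TE
overlap counting, and LOWESS-smoothed chromosome-scale profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from mossmeth.tracks import WindowTracks

#: pseudocount used in histone log2(mark/H3) ratios
HISTONE_EPS = 1.0


def te_metaplot(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    interval: int = 100,
    flank: int = 0,
    context: str | None = None,
    feature_type: str = "TE",
) -> pd.DataFrame:
    """Average methylation profile of TEs aligned at their 5' ends.

    Offsets run 5'->3' into each element (negative offsets cover the
    upstream flank); at each ``interval``-bp offset bin the unweighted mean
    of per-cytosine levels pooled over all contributing elements is
    reported, together with the number of contributing elements and
    cytosines. Returns a frame: offset (bin start, bp from the 5' alignment
    point), mean_level, n_te, n_cytosines. Empty annotation -> empty frame.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    tes = annotations[annotations["type"] == feature_type]
    cols = ["offset", "mean_level", "n_te", "n_cytosines"]
    if len(tes) == 0:
        return pd.DataFrame(columns=cols)
    sel = calls if context is None else calls[calls["context"] == context]

    offsets, levels, te_ids = [], [], []
    for te_i, te in enumerate(tes.itertuples(index=False)):
        here = sel[sel["chrom"] == te.chrom]
        if te.strand == "-":
            lo, hi = te.start, te.end + flank
            inside = here[(here["pos"] >= lo) & (here["pos"] < hi)]
            off = (te.end - 1) - inside["pos"].to_numpy()
        else:
            lo, hi = te.start - flank, te.end
            inside = here[(here["pos"] >= lo) & (here["pos"] < hi)]
            off = inside["pos"].to_numpy() - te.start
        offsets.append(off)
        levels.append(inside["level"].to_numpy())
        te_ids.append(np.full(len(inside), te_i))
    off = np.concatenate(offsets) if offsets else np.array([], int)
    lev = np.concatenate(levels) if levels else np.array([])
    tid = np.concatenate(te_ids) if te_ids else np.array([], int)
    bins = np.floor_divide(off, interval) * interval
    frame = pd.DataFrame({"offset": bins, "level": lev, "te": tid})
    out = frame.groupby("offset").agg(
        mean_level=("level", "mean"),
        n_te=("te", "nunique"),
        n_cytosines=("level", "size"),
    ).reset_index()
    return out[cols]


def te_tss_histogram(
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    window: int = 25,
    upstream: int = 500,
) -> pd.DataFrame:
    """Percent of genes with their closest TE edge per 25-bp upstream window.

    For plus-strand genes the TE END edges are tested; for minus-strand
    genes the TE START edges (in both cases the edge facing the gene). Each
    gene contributes at most once, in the window of its closest qualifying
    edge within ``upstream`` bp of the TSS. Returns a frame: offset (window
    start, bp upstream of TSS), n_genes, percent.
    """
    genes = genes[genes["type"] == "gene"] if "type" in genes else genes
    if (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("genes must be stranded (+/-)")
    te_rows = tes[tes["type"] == "TE"] if "type" in tes else tes

    n_windows = -(-upstream // window)
    counts = np.zeros(n_windows, dtype=int)
    n_genes = len(genes)
    # TE edge entries, one per edge, scored 1 (start and end kept separately)
    edges_end = {c: np.sort(g["end"].to_numpy() - 1)
                 for c, g in te_rows.groupby("chrom")}
    edges_start = {c: np.sort(g["start"].to_numpy())
                   for c, g in te_rows.groupby("chrom")}

    for gene in genes.itertuples(index=False):
        if gene.strand == "+":
            tss = gene.start
            cand = edges_end.get(gene.chrom, np.array([], int))
            dist = tss - cand  # edge strictly upstream: dist >= 1
        else:
            tss = gene.end - 1
            cand = edges_start.get(gene.chrom, np.array([], int))
            dist = cand - tss
        dist = dist[(dist >= 1) & (dist <= upstream)]
        if len(dist) == 0:
            continue
        counts[(dist.min() - 1) // window] += 1

    offsets = np.arange(n_windows) * window
    percent = counts / n_genes * 100.0 if n_genes else np.zeros(n_windows)
    return pd.DataFrame({"offset": offsets, "n_genes": counts, "percent": percent})


@dataclass(frozen=True)
class CentileScheme:
    """How a feature is split into ascending centile groups.

    Continuous genomic features use 5 centiles (GC ratio, TE size), siRNA
    counts 10, and histone log2(mark/H3) ratios 4 plus an extra "ND" group
    for windows lacking any signal in the mark, the opposite mark, or H3.
    """

    feature: str
    n_centiles: int

    def __post_init__(self):
        if self.n_centiles < 1:
            raise ValueError("need at least one centile")


GC_SCHEME = CentileScheme("GC", 5)
TE_SIZE_SCHEME = CentileScheme("TE_length", 5)
SIRNA_SCHEME = CentileScheme("siRNA", 10)
H3K9ME2_SCHEME = CentileScheme("H3K9me2_log2_H3", 4)
H3K4ME3_SCHEME = CentileScheme("H3K4me3_log2_H3", 4)


def histone_log_ratio(
    tracks: WindowTracks, mark: str, other_mark: str, eps: float = HISTONE_EPS
):
    """Per-window log2((mark+eps)/(H3+eps)) and the ND mask.

    ND marks windows with no signal (zero or missing) in either the mark,
    the other histone mark, or total H3. Returns two aligned Series indexed
    by (chrom, start).
    """
    table = tracks.window_table().set_index(["chrom", "start"])
    m = table[mark]
    o = table[other_mark]
    h3 = table["H3"]
    nd = (m.fillna(0) == 0) | (o.fillna(0) == 0) | (h3.fillna(0) == 0)
    ratio = np.log2((m + eps) / (h3 + eps))
    return ratio.rename(f"{mark}_log2_H3"), nd.rename("ND")


@dataclass
class StratifiedResult:
    groups: pd.Series       # group label per window ("q1".."qk" or "ND")
    summary: pd.DataFrame   # per-group n, median, q1, q3, whisker bounds


def stratify_quantiles(
    values: pd.Series,
    feature: pd.Series,
    scheme: CentileScheme,
    nd_mask: pd.Series | None = None,
) -> StratifiedResult:
    """Assign windows to ascending feature centiles and summarise values.

    ``values`` (e.g. per-window percent methylation change) and ``feature``
    must share an index. Centile boundaries are empirical quantiles of the
    feature over non-ND windows; ties resolve to the lower centile. Windows
    flagged by ``nd_mask`` form the extra "ND" group. The summary reports
    box-plot statistics (median, quartiles, 1.5 x IQR whisker bounds).
    """
    if not values.index.equals(feature.index):
        raise ValueError("values and feature must share an index")
    if nd_mask is not None and not nd_mask.index.equals(values.index):
        raise ValueError("nd_mask must share the index")
    nd = (
        nd_mask.astype(bool)
        if nd_mask is not None
        else pd.Series(False, index=values.index)
    )
    nd = nd | feature.isna()
    groups = pd.Series("ND", index=values.index, dtype=object)
    active = feature[~nd]
    k = scheme.n_centiles
    if len(active):
        qs = np.quantile(active.to_numpy(), np.arange(1, k) / k)
        idx = np.searchsorted(qs, active.to_numpy(), side="left")
        groups[~nd] = [f"q{i + 1}" for i in idx]

    rows = []
    order = [f"q{i + 1}" for i in range(k)] + (["ND"] if nd.any() else [])
    for label in order:
        v = values[groups == label].dropna()
        if len(v) == 0:
            rows.append({"group": label, "n": 0, "median": np.nan, "q1": np.nan,
                         "q3": np.nan, "lo_whisker": np.nan, "hi_whisker": np.nan})
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append({"group": label, "n": len(v), "median": med, "q1": q1,
                     "q3": q3, "lo_whisker": lo, "hi_whisker": hi})
    return StratifiedResult(groups=groups, summary=pd.DataFrame(rows))


def correlation_matrix(table: pd.DataFrame, min_windows: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations with pairwise-complete deletion.

    Columns of ``table`` are per-window variables (context methylation
    fractions, GC, histone marks, ...). Pairs with fewer than
    ``min_windows`` complete observations, and zero-variance columns, yield
    NaN. Diagonal is 1 for non-degenerate columns.
    """
    return table.corr(method="pearson", min_periods=min_windows)


def overlap_summary(
    tracks: WindowTracks,
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    min_te_level: float,
    min_sirna_count: float,
    context: str = "CHH",
) -> dict:
    """Three-way overlap of TE annotation, methylation, and siRNA signal.

    A TE is "methylated" when the unweighted mean of its per-cytosine levels
    in ``context`` reaches ``min_te_level``, and "siRNA-positive" when its
    summed per-window siRNA count reaches ``min_sirna_count``. Both
    thresholds are mandatory. Returns counts plus the fraction of methylated
    TEs that are siRNA-overlapped.
    """
    tes = annotations[annotations["type"] == "TE"].reset_index(drop=True)
    sel = calls[calls["context"] == context]
    n_meth = n_sirna = n_both = 0
    w = tracks.window
    for te in tes.itertuples(index=False):
        inside = sel[
            (sel["chrom"] == te.chrom)
            & (sel["pos"] >= te.start)
            & (sel["pos"] < te.end)
        ]
        methylated = len(inside) > 0 and inside["level"].mean() >= min_te_level
        vals = tracks.get("siRNA", te.chrom)[te.start // w : (te.end - 1) // w + 1]
        sirna_pos = np.nansum(vals) >= min_sirna_count
        n_meth += methylated
        n_sirna += sirna_pos
        n_both += methylated and sirna_pos
    return {
        "n_te": len(tes),
        "n_methylated": n_meth,
        "n_sirna": n_sirna,
        "n_both": n_both,
        "fraction_methylated_with_sirna": (n_both / n_meth) if n_meth else np.nan,
    }


def chromosome_profile(
    calls: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    bin_size: int = 100_000,
    span: float = 0.1,
    context: str | None = None,
) -> pd.DataFrame:
    """Binned methylation along a chromosome with LOWESS smoothing.

    Per ``bin_size`` bin the unweighted mean of per-cytosine levels is
    computed, then locally weighted linear regression with fraction ``span``
    smooths the bin means; output at bin midpoints. A chromosome shorter
    than one bin yields a single unsmoothed value.
    """
    sel = calls[calls["chrom"] == chrom]
    if context is not None:
        sel = sel[sel["context"] == context]
    n_bins = max(1, -(-chrom_length // bin_size))
    idx = np.minimum(sel["pos"].to_numpy() // bin_size, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        v = sel["level"].to_numpy()[idx == b]
        if len(v):
            means[b] = v.mean()
    mids = np.minimum(
        np.arange(n_bins) * bin_size + bin_size // 2, chrom_length - 1
    ).astype(float)
    if n_bins == 1:
        smoothed = means.copy()
    else:
        ok = ~np.isnan(means)
        smoothed = np.full(n_bins, np.nan)
        if ok.sum() >= 2:
            fit = lowess(means[ok], mids[ok], frac=max(span, 2.0 / ok.sum()),
                         return_sorted=False)
            smoothed[ok] = fit
        else:
            smoothed = means.copy()
    return pd.DataFrame({"midpoint": mids, "mean_level": means, "smoothed": smoothed})
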