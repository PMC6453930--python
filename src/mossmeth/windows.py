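"""Window aggregation, differential methylation, and clone-level analyses.

Fractional methylation is pooled in fixed 50-bp genomic tiles: a window's
fraction is pooled retained / (retained + converted) over its context
cytosines (count-weighted), and its number of "informative sequenced
cytosines" is that pooled read total. Two genotypes are compared per window
with the percent-methylation-change statistic — the difference in
methylation normalised by the higher of the two levels, signed so that
mutant loss is positive — and Fisher's exact test on the pooled 2x2 count
table. A differentially methylated region (DMR) here is a window with at
least ``min_fraction`` methylation in either sample, at least
``min_informative`` informative cytosines in both, and a two-sided Fisher
p-value below alpha.

The clone-level functions cover the transgene-style assay in which a
bisulfite PCR amplicon is Sanger-sequenced from individual clones: each
reference forward-strand cytosine scores 1 (read C) or 0 (read T) per clone,
and genotypes are compared with a classical paired t-test across sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mossmeth.genome import Genome
from mossmeth.calls import CONTEXTS, context_table


def window_methylation(
    calls: pd.DataFrame,
    window_size: int = 50,
    context: str | None = None,
    step: int | None = None,
) -> pd.DataFrame:
    """Pool per-cytosine counts into genomic windows.

    Returns the window table: chrom, start (0-based window start), context,
    retained, converted, n_informative, fraction. Windows with no
    informative cytosines are absent. ``context=None`` keeps contexts
    separate (one row per window x context). The default tiling is
    non-overlapping; ``step`` (a divisor of ``window_size``) slides the
    window instead, so each cytosine contributes to window_size/step
    windows.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    if step is not None and step != window_size:
        if step <= 0 or window_size % step:
            raise ValueError("step must be a positive divisor of window_size")
        parts = []
        for offset in range(0, window_size, step):
            shifted = calls.assign(pos=calls["pos"] - offset)
            shifted = shifted[shifted["pos"] >= 0]
            part = window_methylation(shifted, window_size, context)
            part["start"] = part["start"] + offset
            parts.append(part)
        out = pd.concat(parts, ignore_index=True).sort_values(
            ["chrom", "start"], kind="mergesort").reset_index(drop=True)
        out.attrs["window_size"] = window_size
        return out
    sel = calls
    if context is not None:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        sel = sel[sel["context"] == context]
    if len(sel) == 0:
        out = pd.DataFrame(
            columns=["chrom", "start", "context", "retained", "converted",
                     "n_informative", "fraction"]
        )
        out.attrs["window_size"] = window_size
        return out
    grp = sel.assign(start=(sel["pos"] // window_size) * window_size).groupby(
        ["chrom", "start", "context"], as_index=False, observed=True
    )[["retained", "converted"]].sum()
    grp["n_informative"] = grp["retained"] + grp["converted"]
    grp = grp[grp["n_informative"] > 0]
    grp["fraction"] = grp["retained"] / grp["n_informative"]
    grp = grp.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    grp.attrs["window_size"] = window_size
    return grp


def percent_methylation_change(wt, mut):
    """Percent change normalised by the higher of the two levels.

    Positive when the first sample (WT) is the more methylated one:
    (wt - mut) / wt * 100 if wt > mut, -(mut - wt) / mut * 100 if wt < mut,
    and 0 at equality (including both zero). Accepts scalars or arrays;
    result is bounded in [-100, 100] and antisymmetric in its arguments.
    """
    wt_arr = np.asarray(wt, dtype=float)
    mut_arr = np.asarray(mut, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        hypo = (wt_arr - mut_arr) / wt_arr * 100.0
        hyper = -(mut_arr - wt_arr) / mut_arr * 100.0
    out = np.where(wt_arr > mut_arr, hypo, np.where(wt_arr < mut_arr, hyper, 0.0))
    if np.isscalar(wt) and np.isscalar(mut):
        return float(out)
    return out


def _check_tiling(wt: pd.DataFrame, mut: pd.DataFrame):
    ws_wt = wt.attrs.get("window_size")
    ws_mut = mut.attrs.get("window_size")
    if ws_wt is not None and ws_mut is not None and ws_wt != ws_mut:
        raise ValueError(f"mismatched tilings: {ws_wt} vs {ws_mut} bp windows")


def compare_windows(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    min_fraction: float = 0.1,
    min_informative: int = 10,
) -> pd.DataFrame:
    """Fisher's exact test on every shared window passing the filters.

    A window is tested when its fraction is >= ``min_fraction`` in EITHER
    sample and its informative-cytosine count >= ``min_informative`` in BOTH.
    Returns a frame with both samples' counts and fractions plus
    percent_change, p_value, and direction ("hypo" when the mutant is the
    less methylated sample, "hyper" otherwise).
    """
    _check_tiling(wt, mut)
    merged = wt.merge(
        mut, on=["chrom", "start", "context"], suffixes=("_wt", "_mut"), how="inner"
    )
    keep = (
        (merged["fraction_wt"] >= min_fraction)
        | (merged["fraction_mut"] >= min_fraction)
    ) & (
        (merged["n_informative_wt"] >= min_informative)
        & (merged["n_informative_mut"] >= min_informative)
    )
    merged = merged[keep].reset_index(drop=True)
    pvals = np.empty(len(merged))
    for i, row in enumerate(merged.itertuples(index=False)):
        table = [
            [row.retained_wt, row.converted_wt],
            [row.retained_mut, row.converted_mut],
        ]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided").pvalue
    merged["p_value"] = pvals
    merged["percent_change"] = percent_methylation_change(
        merged["fraction_wt"].to_numpy(), merged["fraction_mut"].to_numpy()
    )
    merged["direction"] = np.where(
        merged["fraction_mut"] < merged["fraction_wt"], "hypo", "hyper"
    )
    return merged


@dataclass
class DMRResult:
    """DMR windows plus the full tested table and direction tallies."""

    records: pd.DataFrame
    tested: pd.DataFrame
    n_hypo: int
    n_hyper: int

    def __len__(self) -> int:
        return len(self.records)


def call_dmrs(
    wt: pd.DataFrame,
    mut: pd.DataFrame,
    min_fraction: float = 0.1,
    min_informative: int = 10,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> DMRResult:
    """Call 50-bp-window DMRs between two genotypes.

    Filters and test as in :func:`compare_windows`; windows with (raw, or
    Benjamini-Hochberg-adjusted if ``bh_correct``) p below ``alpha`` are
    returned as DMR records with percent change and hypo/hyper direction.
    """
    tested = compare_windows(wt, mut, min_fraction, min_informative)
    pcol = "p_value"
    if bh_correct and len(tested):
        from statsmodels.stats.multitest import multipletests

        tested = tested.copy()
        tested["p_adjusted"] = multipletests(
            tested["p_value"].to_numpy(), method="fdr_bh"
        )[1]
        pcol = "p_adjusted"
    records = tested[tested[pcol] < alpha].reset_index(drop=True)
    n_hypo = int((records["direction"] == "hypo").sum())
    n_hyper = int((records["direction"] == "hyper").sum())
    return DMRResult(records=records, tested=tested, n_hypo=n_hypo, n_hyper=n_hyper)


@dataclass
class CloneMatrix:
    """Binary methylation states of amplicon clones.

    ``matrix``: sites (0-based reference C positions) x clone names, values
    1 (methylated), 0 (unmethylated) or NaN (unreadable). ``fractions``:
    per-site methylated fraction over scored clones. ``contexts``: per-site
    CG/CHG/CHH (or "undefined") from the reference forward strand.
    """

    matrix: pd.DataFrame
    fractions: pd.Series
    contexts: pd.Series

    def site_fractions(self, context: str | None = None) -> pd.Series:
        if context is None:
            return self.fractions
        return self.fractions[self.contexts == context]


def clone_methylation_matrix(
    reference: str, clones: dict[str, str], max_bad_fraction: float = 0.1
) -> CloneMatrix:
    """Score bisulfite-PCR clones against the amplicon reference.

    Clones must align end-to-end (same length as the reference, bisulfite
    space). At each reference forward-strand C the clone base maps C -> 1,
    T -> 0, anything else -> NaN. A clone with more than ``max_bad_fraction``
    non-C/T bases at C sites is rejected with a warning.
    """
    ref = reference.upper()
    c_sites = [i for i, b in enumerate(ref) if b == "C"]
    if not c_sites:
        raise ValueError("reference amplicon contains no cytosines")
    mini = Genome({"amplicon": ref})
    ctx = context_table(mini)
    fwd = ctx[ctx["strand"] == "+"].set_index("pos")["context"]
    contexts = pd.Series(
        [fwd.get(i, "undefined") for i in c_sites], index=c_sites, name="context"
    )

    cols = {}
    for name, seq in clones.items():
        s = seq.upper()
        if len(s) != len(ref):
            raise ValueError(
                f"clone {name!r} length {len(s)} != reference {len(ref)}"
            )
        states = []
        bad = 0
        for i in c_sites:
            b = s[i]
            if b == "C":
                states.append(1.0)
            elif b == "T":
                states.append(0.0)
            else:
                states.append(np.nan)
                bad += 1
        if bad / len(c_sites) > max_bad_fraction:
            warnings.warn(
                f"clone {name!r} rejected: {bad}/{len(c_sites)} unreadable C sites"
            )
            continue
        cols[name] = states
    matrix = pd.DataFrame(cols, index=pd.Index(c_sites, name="pos"))
    fractions = matrix.mean(axis=1, skipna=True)
    return CloneMatrix(matrix=matrix, fractions=fractions, contexts=contexts)


def paired_t_test(a, b, contexts=None, context: str | None = None):
    """Classical paired t-test on per-site differences.

    ``a`` and ``b`` are per-site methylation fractions paired by position;
    NaN pairs are dropped, and an optional per-site ``contexts`` vector with
    ``context`` restricts the comparison. Returns ``(t, two_sided_p)``.
    Degenerate inputs: fewer than 2 complete pairs raises ValueError; all
    differences equal and nonzero gives ``(inf * sign, 0.0)``; identical
    vectors give ``(0.0, 1.0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    if contexts is not None and context is not None:
        keep &= np.asarray(contexts) == context
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    d = a - b
    # constant differences up to float rounding: t degenerates
    if np.ptp(d) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
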