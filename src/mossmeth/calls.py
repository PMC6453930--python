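"""Context-resolved per-cytosine methylation calling.

Sequence contexts follow the plant convention: CG, CHG and CHH with
H = A, C or T, read 5'->3' on the cytosine's own strand. Subcontexts refine
them: NCG records the 5' neighbour of a CG (ACG/CCG/GCG/TCG; DCG is the
non-CCG remainder with D = A, G or T); CHG splits into CWG (CAG/CTG,
W = A or T) and CCG; within CHH, CWH marks a W in the middle position and
CWA additionally marks a terminal A. A cytosine whose context-defining
neighbours fall off the chromosome or contain N has an undefined context and
is excluded from every table.

The per-cytosine methylation level is retained / (retained + converted),
i.e. C / (C + T) read observations; cytosines with no informative reads are
not emitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mossmeth.genome import Genome

H_BASES = frozenset("ACT")
W_BASES = frozenset("AT")
D_BASES = frozenset("AGT")

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")
_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y

CONTEXTS = ("CG", "CHG", "CHH")


class NoDataError(ValueError):
    """Raised when an average is requested over an empty selection."""


def assign_context(genome: Genome, chrom: str, pos: int, strand: str):
    """Context and subcontext set of the cytosine at (chrom, pos, strand).

    Returns ``(context, subcontexts)`` where context is one of
    ``"CG" | "CHG" | "CHH" | "undefined"`` and subcontexts is a frozenset.
    Raises ValueError if the base at the position is not a strand-space C.
    """
    seq = genome[chrom]
    L = len(seq)
    if not 0 <= pos < L:
        raise ValueError(f"position {pos} outside {chrom}")
    base = seq[pos]
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}+ is {base}, not C")
        get = lambda off: seq[pos + off] if 0 <= pos + off < L else None
        n1, n2, prev5 = get(1), get(2), get(-1)
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}- is {base} on the forward strand, not G")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        get = lambda off: comp[seq[pos - off]] if 0 <= pos - off < L else None
        n1, n2, prev5 = get(1), get(2), get(-1)
    else:
        raise ValueError(f"invalid strand {strand!r}")

    def defined(b):
        return b is not None and b in "ACGT"

    if not defined(n1):
        return "undefined", frozenset()
    if n1 == "G":
        subs = set()
        if defined(prev5):
            subs.add(prev5 + "CG")
        return "CG", frozenset(subs)
    # n1 in H = {A, C, T}
    if not defined(n2):
        return "undefined", frozenset()
    if n2 == "G":
        return "CHG", frozenset({"CCG"} if n1 == "C" else {"CWG"})
    # CHH
    subs = set()
    if n1 in W_BASES:
        subs.add("CWH")
        if n2 == "A":
            subs.add("CWA")
    return "CHH", frozenset(subs)


def _strand_context(arr: np.ndarray, strand: str):
    """Vectorised context call for one strand of one chromosome.

    Returns (positions, context codes, subcontext strings) for cytosines with
    a defined context. Context codes: 0=CG, 1=CHG, 2=CHH.
    """
    L = len(arr)
    if strand == "+":
        pos = np.flatnonzero(arr == _C)
        n1 = np.where(pos + 1 < L, arr[np.minimum(pos + 1, L - 1)], 0)
        n2 = np.where(pos + 2 < L, arr[np.minimum(pos + 2, L - 1)], 0)
        p5 = np.where(pos - 1 >= 0, arr[np.maximum(pos - 1, 0)], 0)
    else:
        pos = np.flatnonzero(arr == _G)
        n1 = np.where(pos - 1 >= 0, _COMP[arr[np.maximum(pos - 1, 0)]], 0)
        n2 = np.where(pos - 2 >= 0, _COMP[arr[np.maximum(pos - 2, 0)]], 0)
        p5 = np.where(pos + 1 < L, _COMP[arr[np.minimum(pos + 1, L - 1)]], 0)

    def is_acgt(x):
        return (x == _A) | (x == _C) | (x == _G) | (x == _T)

    in_h = (n1 == _A) | (n1 == _C) | (n1 == _T)
    in_w = (n1 == _A) | (n1 == _T)
    is_cg = is_acgt(n1) & (n1 == _G)
    is_chg = is_acgt(n1) & in_h & is_acgt(n2) & (n2 == _G)
    is_chh = is_acgt(n1) & in_h & is_acgt(n2) & ((n2 == _A) | (n2 == _C) | (n2 == _T))
    defined = is_cg | is_chg | is_chh
    code = np.select([is_cg, is_chg, is_chh], [0, 1, 2], default=-1)

    sub = np.empty(len(pos), dtype=object)
    sub[:] = ""
    cg_named = is_cg & is_acgt(p5)
    p5_chars = np.frombuffer(p5.astype(np.uint8).tobytes(), dtype="S1").astype("U1")
    sub[cg_named] = np.char.add(p5_chars[cg_named], "CG")
    sub[is_chg & (n1 == _C)] = "CCG"
    sub[is_chg & in_w] = "CWG"
    chh_w = is_chh & in_w
    sub[chh_w & (n2 != _A)] = "CWH"
    sub[chh_w & (n2 == _A)] = "CWH,CWA"

    keep = defined
    return pos[keep], code[keep], sub[keep]


def context_table(genome: Genome) -> pd.DataFrame:
    """Every context-defined cytosine of a genome, both strands.

    Columns: chrom, pos (0-based), strand, context, subcontext (comma list,
    possibly empty). Sorted by chromosome, position, strand.
    """
    parts = []
    names = np.array(CONTEXTS)
    for chrom in genome:
        arr = genome.array(chrom)
        for strand in "+-":
            pos, code, sub = _strand_context(arr, strand)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "context": names[code],
                        "subcontext": sub,
                    }
                )
            )
    table = pd.concat(parts, ignore_index=True)
    table.sort_values(["chrom", "pos", "strand"], inplace=True, kind="mergesort")
    return table.reset_index(drop=True)


def call_single_c(
    pileup: pd.DataFrame, genome: Genome, ctx: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-cytosine methylation calls ("single-c" table) from a pileup.

    Parameters
    ----------
    pileup : frame with columns chrom, pos, strand, retained, converted.
    genome : reference the pileup was produced against.
    ctx : optional precomputed :func:`context_table` for the same genome.

    Returns the single-c frame: chrom, pos, strand, context, subcontext,
    retained, converted, level — one row per covered, context-defined
    cytosine, sorted by chromosome then position. Raises ValueError if the
    pileup references a position that is not a reference cytosine of the
    stated strand.
    """
    pile = pileup.copy()
    for chrom, grp in pile.groupby("chrom", sort=False):
        arr = genome.array(chrom)
        fwd = grp["strand"] == "+"
        bases = arr[grp["pos"].to_numpy()]
        ok = np.where(fwd, bases == _C, bases == _G)
        if not ok.all():
            bad = grp[~ok].iloc[0]
            raise ValueError(
                f"pileup position {chrom}:{bad['pos']}{bad['strand']} is not a "
                "reference cytosine"
            )
    if ctx is None:
        ctx = context_table(genome)
    pile = pile[(pile["retained"] + pile["converted"]) > 0]
    out = ctx.merge(pile, on=["chrom", "pos", "strand"], how="inner")
    out["level"] = out["retained"] / (out["retained"] + out["converted"])
    out.sort_values(["chrom", "pos", "strand"], inplace=True, kind="mergesort")
    return out.reset_index(drop=True)


def _select(calls, context=None, chromosomes=None, min_coverage=1):
    sel = calls
    if context is not None:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        sel = sel[sel["context"] == context]
    if chromosomes is not None:
        sel = sel[sel["chrom"].isin(chromosomes)]
    if min_coverage > 1:
        sel = sel[(sel["retained"] + sel["converted"]) >= min_coverage]
    return sel


def genome_average(
    calls: pd.DataFrame,
    context: str | None = None,
    chromosomes=None,
    min_coverage: int = 1,
) -> float:
    """Unweighted mean of per-cytosine levels over the selection.

    ``chromosomes`` restricts to a compartment (e.g. nuclear vs organelle).
    Raises :class:`NoDataError` when the selection is empty.
    """
    sel = _select(calls, context, chromosomes, min_coverage)
    if len(sel) == 0:
        raise NoDataError(
            f"no cytosines for context={context!r}, chromosomes={chromosomes!r}"
        )
    return float(sel["level"].mean())


def in_features(
    calls: pd.DataFrame, annotations: pd.DataFrame, feature_type: str = "TE"
) -> np.ndarray:
    """Boolean mask: call lies inside a feature of the given type."""
    mask = np.zeros(len(calls), dtype=bool)
    feats = annotations[annotations["type"] == feature_type]
    pos_all = calls["pos"].to_numpy()
    chrom_all = calls["chrom"].to_numpy()
    for chrom, grp in feats.groupby("chrom"):
        ivals = grp[["start", "end"]].sort_values("start").to_numpy()
        if len(ivals) == 0:
            continue
        starts, ends = ivals[:, 0], ivals[:, 1]
        here = chrom_all == chrom
        pos = pos_all[here]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
        mask[np.flatnonzero(here)[inside]] = True
    return mask


def feature_average(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    feature_type: str = "TE",
    context: str | None = None,
    min_coverage: int = 1,
) -> float:
    """Genome average restricted to cytosines inside features of one type."""
    sel = calls[in_features(calls, annotations, feature_type)]
    sel = _select(sel, context, None, min_coverage)
    if len(sel) == 0:
        raise NoDataError(
            f"no cytosines in {feature_type} features for context={context!r}"
        )
    return float(sel["level"].mean())
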