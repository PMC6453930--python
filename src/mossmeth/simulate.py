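"""Synthetic genome, methylome and bisulfite-read simulation.

The simulator builds a small multi-chromosome genome with embedded
transposable elements (TEs) and genes, chromatin tracks coupled to TE size
(H3K9me2 rising and H3K4me3 falling with TE length, long TEs in higher-GC
neighbourhoods), a ground-truth methylome concentrated in heterochromatic
TEs, genotype knockout effects expressed as per-context retention factors,
and directional single-end bisulfite reads with a truth sidecar. Everything
downstream of the sequencer can thus be verified against known truth.

Default methylome levels inside TEs are CG 0.8, CHG 0.7, CHH 0.2 — a
moss-like, TE-restricted landscape in which methylation is high in the
symmetric contexts and low but real in CHH. Reads are error-free apart from
bisulfite chemistry: an unmethylated C is read as T with probability
``conversion_rate`` and a methylated C is read as T with probability
``methylation_failure_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from mossmeth.genome import Genome
from mossmeth.tracks import WindowTracks
from mossmeth.calls import CONTEXTS, context_table, in_features

_A, _C, _G, _T = (ord(b) for b in "ACGT")
_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y

DEFAULT_BASE_LEVELS = {"CG": 0.8, "CHG": 0.7, "CHH": 0.2}

#: margin kept free around every placed feature (bp)
_PLACEMENT_GAP = 50
#: neighbourhood re-drawn around a TE to couple local GC to TE size (bp)
_GC_NEIGHBOURHOOD = 200


class ConfigurationError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    ``conversion_rate`` is the probability that an UNmethylated cytosine is
    bisulfite-converted and read as T; ``methylation_failure_rate`` is the
    probability that a methylated cytosine is nevertheless read as T.
    """

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    te_count: int = 40
    te_size_range: tuple[int, int] = (100, 3000)
    gene_count: int = 30
    gc_content: float = 0.34
    depth: float = 30.0
    read_length: int = 75
    conversion_rate: float = 0.995
    methylation_failure_rate: float = 0.005
    seed: int = 0
    window: int = 50
    sirna_euchromatic_fraction: float = 0.05

    def __post_init__(self):
        for name in ("gc_content", "conversion_rate", "methylation_failure_rate",
                     "sirna_euchromatic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.te_size_range
        if lo < 50:
            raise ConfigurationError("te_size_range minimum must be >= 50 bp")
        if hi > self.chrom_length / 4:
            raise ConfigurationError(
                "te_size_range maximum must be <= chrom_length / 4"
            )
        if lo > hi:
            raise ConfigurationError("te_size_range min exceeds max")
        if self.n_chromosomes < 1 or self.chrom_length < 1000:
            raise ConfigurationError("need >= 1 chromosome of >= 1000 bp")
        if self.read_length < 20:
            raise ConfigurationError("read_length must be >= 20 bp")


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative methylation retention of a genotype relative to WT.

    ``r_cg``/``r_chg``/``r_chh`` scale the wild-type methylation probability
    per context (1 = unaffected, 0 = complete loss). ``subcontext_overrides``
    maps a subcontext label (optionally ``"CONTEXT:LABEL"`` to disambiguate,
    e.g. ``"CHG:CCG"``) to a retention factor that replaces the context-level
    one at matching sites. ``chh_redistribution`` moves CHH methylation from
    heterochromatin to euchromatin: the CHH probability is additionally
    scaled by ``1 - chh_redistribution * z`` where z is the H3K9me2 z-score
    of the surrounding window (clipped to stay in [0, 1]).
    """

    name: str = "wt"
    r_cg: float = 1.0
    r_chg: float = 1.0
    r_chh: float = 1.0
    subcontext_overrides: dict | None = None
    chh_redistribution: float = 0.0

    def __post_init__(self):
        for name in ("r_cg", "r_chg", "r_chh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.chh_redistribution < 0:
            raise ValueError("chh_redistribution must be >= 0")

    @property
    def retention(self) -> dict[str, float]:
        return {"CG": self.r_cg, "CHG": self.r_chg, "CHH": self.r_chh}


def identity_effect() -> GenotypeEffect:
    return GenotypeEffect(name="wt")


def met_like() -> GenotypeEffect:
    """CG-maintenance knockout: 93% CG loss."""
    return GenotypeEffect(name="met", r_cg=0.07)


def cmt_like(redistribution: float = 0.5) -> GenotypeEffect:
    """CHG-methylase knockout: 97% CHG loss plus CHH redistribution from
    heterochromatin toward euchromatin."""
    return GenotypeEffect(name="cmt", r_chg=0.03, chh_redistribution=redistribution)


def dnmt3b_like() -> GenotypeEffect:
    """CHH-methylase knockout: 95% CHH loss."""
    return GenotypeEffect(name="dnmt3b", r_chh=0.05)


class MethylomeModel:
    """Ground-truth methylome: one record per context-defined cytosine.

    ``table`` columns: chrom, pos (0-based), strand, context, subcontext,
    p (true methylation probability in [0, 1]).
    """

    def __init__(self, table: pd.DataFrame, chrom_lengths: dict[str, int]):
        if not ((table["p"] >= 0) & (table["p"] <= 1)).all():
            raise ValueError("p_true outside [0, 1]")
        self.table = table
        self.chrom_lengths = dict(chrom_lengths)
        self._dense: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def p_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Dense per-position p on (+) C positions and (-) C (forward G)
        positions; NaN where no record exists."""
        if chrom not in self._dense:
            L = self.chrom_lengths[chrom]
            fwd = np.full(L, np.nan)
            rev = np.full(L, np.nan)
            sub = self.table[self.table["chrom"] == chrom]
            plus = sub[sub["strand"] == "+"]
            minus = sub[sub["strand"] == "-"]
            fwd[plus["pos"].to_numpy()] = plus["p"].to_numpy()
            rev[minus["pos"].to_numpy()] = minus["p"].to_numpy()
            self._dense[chrom] = (fwd, rev)
        return self._dense[chrom]

    def context_mean(self, context: str, mask: np.ndarray | None = None) -> float:
        sel = self.table["context"] == context
        if mask is not None:
            sel &= mask
        return float(self.table.loc[sel, "p"].mean())

    def equals(self, other: "MethylomeModel") -> bool:
        return self.table.equals(other.table)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _draw_bases(rng, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs
    ).astype(np.uint8)


def _place_features(rng, chrom_length: int, lengths: list[int]) -> list[tuple[int, int]]:
    """Place intervals of the given lengths into one chromosome without
    overlap, keeping a small gap between neighbours. Longest first."""
    free = [(0, chrom_length)]
    placed = {}
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    for i in order:
        flen = lengths[i]
        slots = np.array([max(e - s - flen + 1, 0) for s, e in free])
        if slots.sum() == 0:
            raise ConfigurationError("infeasible packing: no gap fits feature")
        gap_i = rng.choice(len(free), p=slots / slots.sum())
        s, e = free[gap_i]
        start = int(s + rng.integers(0, e - s - flen + 1))
        placed[i] = (start, start + flen)
        del free[gap_i]
        if start - _PLACEMENT_GAP > s:
            free.append((s, start - _PLACEMENT_GAP))
        if start + flen + _PLACEMENT_GAP < e:
            free.append((start + flen + _PLACEMENT_GAP, e))
    return [placed[i] for i in range(len(lengths))]


def simulate_genome(config: SimConfig):
    """Simulate the reference genome, its annotations, and chromatin tracks.

    Returns ``(genome, annotations, tracks)``. Annotations are a frame with
    columns chrom, start, end (0-based half-open), strand, type ("TE" or
    "gene"), id. Tracks are per-50-bp windows for H3K9me2, H3K4me3, H3,
    siRNA, TE_expression, GC and TE_length; H3K9me2 rises and H3K4me3 falls
    with TE length, and long TEs sit in locally GC-enriched neighbourhoods.
    """
    rng = _rng(config.seed, 0)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    lo, hi = config.te_size_range
    te_lengths = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=config.te_count)
    ).astype(int)
    gene_lengths = rng.integers(
        500, min(2000, config.chrom_length // 10) + 1, size=config.gene_count
    )
    total_feat = int(te_lengths.sum() + gene_lengths.sum())
    genome_len = config.n_chromosomes * config.chrom_length
    if total_feat > 0.8 * genome_len:
        raise ConfigurationError(
            f"total feature length {total_feat} exceeds 80% of genome {genome_len}"
        )

    # rank fraction of each TE by length (0 = shortest) drives chromatin
    if config.te_count > 1:
        te_rank = np.argsort(np.argsort(te_lengths)) / (config.te_count - 1)
    else:
        te_rank = np.full(config.te_count, 0.5)

    feat_chrom = rng.integers(0, config.n_chromosomes, size=config.te_count
                              + config.gene_count)
    feat_lengths = np.concatenate([te_lengths, gene_lengths])
    feat_type = ["TE"] * config.te_count + ["gene"] * config.gene_count

    seqs = {}
    rows = []
    for ci, chrom in enumerate(chrom_names):
        arr = _draw_bases(rng, config.chrom_length, config.gc_content)
        idx_here = np.flatnonzero(feat_chrom == ci)
        intervals = _place_features(rng, config.chrom_length,
                                    [int(feat_lengths[i]) for i in idx_here])
        for j, fi in enumerate(idx_here):
            start, end = intervals[j]
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "strand": strand,
                 "type": feat_type[fi], "id": f"{feat_type[fi]}_{fi:04d}",
                 "_rank": te_rank[fi] if fi < config.te_count else np.nan}
            )
            if feat_type[fi] == "TE":
                r = te_rank[fi]
                gc_local = float(np.clip(config.gc_content - 0.08 + 0.30 * r,
                                         0.05, 0.95))
                lo_n = max(0, start - _GC_NEIGHBOURHOOD)
                hi_n = min(config.chrom_length, end + _GC_NEIGHBOURHOOD)
                arr[lo_n:hi_n] = _draw_bases(rng, hi_n - lo_n, gc_local)
        seqs[chrom] = arr.tobytes().decode()

    annotations = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "type", "id", "_rank"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    genome = Genome(seqs)
    tracks = _simulate_tracks(rng, config, genome, annotations)
    annotations = annotations.drop(columns=["_rank"])
    return genome, annotations, tracks


def _simulate_tracks(rng, config, genome, annotations) -> WindowTracks:
    w = config.window
    tracks = WindowTracks(w, genome.lengths)
    for chrom in genome:
        n_win = tracks.n_windows(chrom)
        h3 = np.clip(1.0 + 0.15 * rng.normal(size=n_win), 0.05, None)
        k9 = np.clip(0.15 + 0.10 * rng.normal(size=n_win), 0.0, None)
        k4 = np.clip(0.80 + 0.15 * rng.normal(size=n_win), 0.0, None)
        sirna_lam = np.full(n_win, 0.05)
        te_expr = np.zeros(n_win)

        feats = annotations[annotations["chrom"] == chrom]
        for _, f in feats.iterrows():
            first, last = int(f["start"]) // w, (int(f["end"]) - 1) // w
            sl = slice(first, last + 1)
            nw = last + 1 - first
            if f["type"] == "gene":
                k4[sl] = np.clip(1.3 + 0.2 * rng.normal(size=nw), 0.0, None)
            else:
                r = float(f["_rank"])
                k9[sl] = np.clip(0.3 + 1.6 * r + 0.15 * rng.normal(size=nw), 0.0, None)
                k4[sl] = np.clip(1.5 - 1.3 * r + 0.15 * rng.normal(size=nw), 0.02, None)
                sirna_lam[sl] = 0.05 + 4.0 * r ** 2
                if r < 0.3 and rng.random() < config.sirna_euchromatic_fraction:
                    sirna_lam[sl] += 3.0
                if rng.random() < 0.3 * (1.0 - r):
                    te_expr[sl] = rng.gamma(2.0, 2.0, size=nw)

        sirna = rng.poisson(sirna_lam).astype(float)
        # a sliver of windows with no chromatin signal at all (the "ND" class)
        nd = rng.random(n_win) < 0.01
        h3[nd] = 0.0
        k9[nd] = 0.0
        k4[nd] = 0.0

        tracks.set("H3", chrom, h3)
        tracks.set("H3K9me2", chrom, k9)
        tracks.set("H3K4me3", chrom, k4)
        tracks.set("siRNA", chrom, sirna)
        tracks.set("TE_expression", chrom, te_expr)
    tracks.add_gc(genome)
    tracks.add_te_length(annotations.drop(columns=["_rank"]))
    return tracks


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.nan_to_num(x, nan=np.nanmean(x) if np.isfinite(x).any() else 0.0)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_methylome(
    genome: Genome,
    annotations: pd.DataFrame,
    tracks: WindowTracks,
    effect: GenotypeEffect | None = None,
    base_levels: dict[str, float] | None = None,
    landscape: str = "te_restricted",
    ctx: pd.DataFrame | None = None,
) -> MethylomeModel:
    """Ground-truth methylation probabilities for every cytosine.

    Wild-type p is a logistic function of local H3K9me2 and GC, calibrated
    per context so the mean over TE cytosines equals ``base_levels``;
    cytosines outside TEs get p = 0 under the default "te_restricted"
    landscape ("uniform" methylates the whole genome at the same calibrated
    levels, useful for null-calibration studies). ``effect`` (a
    :class:`GenotypeEffect`) is applied on top; None means wild type.
    """
    if base_levels is None:
        base_levels = dict(DEFAULT_BASE_LEVELS)
    unknown = set(base_levels) - set(CONTEXTS)
    if unknown:
        raise KeyError(f"unknown context keys in base_levels: {sorted(unknown)}")
    missing = set(CONTEXTS) - set(base_levels)
    if missing:
        raise KeyError(f"base_levels missing contexts: {sorted(missing)}")
    if landscape not in ("te_restricted", "uniform"):
        raise ValueError(f"unknown landscape {landscape!r}")

    table = (context_table(genome) if ctx is None else ctx).copy()
    te_mask = in_features(table, annotations, "TE")
    chrom_arr = table["chrom"].to_numpy()
    pos_arr = table["pos"].to_numpy()
    k9 = tracks.values_at("H3K9me2", chrom_arr, pos_arr)
    gc = tracks.values_at("GC", chrom_arr, pos_arr)
    active = te_mask if landscape == "te_restricted" else np.ones(len(table), bool)
    mod = expit(0.7 * _zscore(k9[active]) + 0.7 * _zscore(gc[active]))

    p = np.zeros(len(table))
    ctx_active = table["context"].to_numpy()[active]
    p_active = np.zeros(active.sum())
    for context, base in base_levels.items():
        sel = ctx_active == context
        if not sel.any():
            continue
        if base >= 1.0:
            p_active[sel] = 1.0
            continue
        raw = mod[sel]
        scale = base / raw.mean() if base > 0 else 0.0
        for _ in range(60):
            cur = np.clip(scale * raw, 0.0, 1.0)
            m = cur.mean()
            if base == 0 or abs(m - base) < 1e-4:
                break
            scale *= base / m
        p_active[sel] = np.clip(scale * raw, 0.0, 1.0)
    p[active] = p_active
    table["p"] = p

    model = MethylomeModel(table, genome.lengths)
    if effect is not None:
        model = apply_genotype_effect(model, effect, tracks)
    return model


def apply_genotype_effect(
    model: MethylomeModel, effect: GenotypeEffect, tracks: WindowTracks | None = None
) -> MethylomeModel:
    """Scale a wild-type methylome by a genotype's retention factors.

    The identity effect returns an equal model. CHH redistribution requires
    ``tracks`` (for the H3K9me2 z-score of each cytosine's window).
    """
    table = model.table.copy()
    ctx = table["context"].to_numpy()
    factor = np.ones(len(table))
    for context, r in effect.retention.items():
        factor[ctx == context] = r
    if effect.subcontext_overrides:
        subs = table["subcontext"].to_numpy()
        for key, r in effect.subcontext_overrides.items():
            if ":" in key:
                key_ctx, label = key.split(":", 1)
                if key_ctx not in CONTEXTS:
                    raise KeyError(f"unknown context in override key {key!r}")
            else:
                key_ctx, label = None, key
            match = np.array([label in s.split(",") if s else False for s in subs])
            if key_ctx is not None:
                match &= ctx == key_ctx
            factor[match] = r
    p_wt = table["p"].to_numpy()
    p = p_wt * factor
    if effect.chh_redistribution > 0:
        if tracks is None:
            raise ValueError("chh_redistribution requires chromatin tracks")
        # z-score over the methylated CHH population, so that euchromatic
        # (low-H3K9me2) methylated sites gain and heterochromatic ones lose
        chh = (ctx == "CHH") & (p_wt > 0)
        k9 = tracks.values_at(
            "H3K9me2", table["chrom"].to_numpy()[chh], table["pos"].to_numpy()[chh]
        )
        red = np.clip(1.0 - effect.chh_redistribution * _zscore(k9), 0.0, None)
        p[chh] = p[chh] * red
    table["p"] = np.clip(p, 0.0, 1.0)
    return MethylomeModel(table, model.chrom_lengths)


def expected_measured_level(
    model: MethylomeModel, config: SimConfig, context: str,
    mask: np.ndarray | None = None,
) -> float:
    """Expected genome-average level the pipeline measures for a context.

    Bisulfite chemistry biases the observable level away from p_true: a
    cytosine is read as C with probability
    p * (1 - methylation_failure_rate) + (1 - p) * (1 - conversion_rate).
    The mean of that quantity over the model's cytosines is what an
    unweighted per-cytosine average estimates.
    """
    sel = model.table["context"] == context
    if mask is not None:
        sel &= mask
    p = model.table.loc[sel, "p"].to_numpy()
    obs = p * (1.0 - config.methylation_failure_rate) + (1.0 - p) * (
        1.0 - config.conversion_rate
    )
    return float(obs.mean())


@dataclass
class ReadSet:
    """Simulated reads plus the per-read origin truth sidecar."""

    ids: list[str]
    seqs: list[str]
    truth: pd.DataFrame  # read_id, chrom, pos, strand

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))


def simulate_bisulfite_reads(
    genome: Genome,
    methylome: MethylomeModel,
    config: SimConfig,
    seed: int | None = None,
) -> ReadSet:
    """Draw directional single-end bisulfite reads from both strands.

    Read count is depth * genome_length / read_length; starts are uniform
    per chromosome (weighted by placeable positions) and strands equiprobable.
    Each covered strand-space cytosine is methylated Bernoulli(p_true); the
    observed base is then T with probability ``methylation_failure_rate`` if
    methylated, and with probability ``conversion_rate`` if not. Cytosines
    without a methylome record (undefined context) behave as unmethylated.
    """
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(config.seed if seed is None else seed, 777)
    L = config.read_length
    chroms = [c for c in genome]
    weights = np.array([max(genome.lengths[c] - L + 1, 0) for c in chroms], float)
    if weights.sum() == 0:
        raise ValueError("all chromosomes shorter than read_length")
    n_reads = int(round(config.depth * genome.total_length / L))

    chrom_idx = rng.choice(len(chroms), size=n_reads, p=weights / weights.sum())
    strands = rng.integers(0, 2, size=n_reads)  # 0 = '+', 1 = '-'
    starts = np.empty(n_reads, dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        m = chrom_idx == ci
        starts[m] = rng.integers(0, genome.lengths[chrom] - L + 1, size=m.sum())

    dense = {c: methylome.p_arrays(c) for c in chroms}
    arrays = {c: genome.array(c) for c in chroms}

    ids, seqs = [], []
    t_chrom, t_pos, t_strand = [], [], []
    for i in range(n_reads):
        chrom = chroms[chrom_idx[i]]
        s = int(starts[i])
        window = arrays[chrom][s : s + L]
        if strands[i] == 0:
            read = window.copy()
            cpos = np.flatnonzero(read == _C)
            p = np.nan_to_num(dense[chrom][0][s + cpos])
            strand = "+"
        else:
            read = _COMP[window][::-1].copy()
            cpos = np.flatnonzero(read == _C)
            gpos = s + L - 1 - cpos  # forward coordinate of the reverse-strand C
            p = np.nan_to_num(dense[chrom][1][gpos])
            strand = "-"
        if len(cpos):
            meth = rng.random(len(cpos)) < p
            u = rng.random(len(cpos))
            as_t = np.where(
                meth, u < config.methylation_failure_rate, u < config.conversion_rate
            )
            read[cpos[as_t]] = _T
        rid = f"read{i:07d}"
        ids.append(rid)
        seqs.append(read.tobytes().decode())
        t_chrom.append(chrom)
        t_pos.append(s)
        t_strand.append(strand)

    truth = pd.DataFrame(
        {"read_id": ids, "chrom": t_chrom, "pos": t_pos, "strand": t_strand}
    )
    return ReadSet(ids=ids, seqs=seqs, truth=truth)
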