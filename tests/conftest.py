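import math

import numpy as np
import pandas as pd
import pytest

from mossmeth import (
    ConvertedIndex,
    Genome,
    SimConfig,
    align,
    call_single_c,
    context_table,
    pileup,
    simulate_bisulfite_reads,
    simulate_genome,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def small_sim():
    """One 40-kb chromosome with TEs and genes plus chromatin tracks."""
    cfg = SimConfig(
        seed=7, n_chromosomes=1, chrom_length=40_000, te_count=10,
        te_size_range=(100, 2000), gene_count=8, depth=20,
    )
    genome, annotations, tracks = simulate_genome(cfg)
    return cfg, genome, annotations, tracks


@pytest.fixture(scope="session")
def small_ctx(small_sim):
    _, genome, _, _ = small_sim
    return context_table(genome)


@pytest.fixture(scope="session")
def small_wt_model(small_sim, small_ctx):
    _, genome, annotations, tracks = small_sim
    return simulate_methylome(genome, annotations, tracks, ctx=small_ctx)


@pytest.fixture(scope="session")
def small_run(small_sim, small_ctx, small_wt_model):
    """Reads drawn from the wild-type methylome, pushed through
    align -> pileup -> single-c once for the whole session."""
    cfg, genome, _, _ = small_sim
    readset = simulate_bisulfite_reads(genome, small_wt_model, cfg, seed=99)
    index = ConvertedIndex(genome)
    alignments, stats = align(list(readset), index)
    pile = pileup(alignments, dict(iter(readset)), genome)
    calls = call_single_c(pile, genome, ctx=small_ctx)
    return {
        "readset": readset,
        "alignments": alignments,
        "stats": stats,
        "pileup": pile,
        "calls": calls,
    }


def toy_genome(seq: str, name: str = "chr1") -> Genome:
    return Genome({name: seq})


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p.

    Sums, over all 2x2 tables with the observed margins, the probabilities
    no larger than the observed table's. Exact integer arithmetic, so ties
    are handled without float tolerance.
    """
    r1, r2, n1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, n1)
    num_obs = math.comb(r1, a) * math.comb(r2, n1 - a)
    lo, hi = max(0, n1 - r2), min(r1, n1)
    total = sum(
        num
        for x in range(lo, hi + 1)
        if (num := math.comb(r1, x) * math.comb(r2, n1 - x)) <= num_obs
    )
    return total / denom


@pytest.fixture
def fisher_oracle():
    return fisher_two_sided


def make_window_table(rows, window_size=50):
    """Build a window table from (chrom, start, context, retained, converted)."""
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "context", "retained", "converted"]
    )
    frame["n_informative"] = frame["retained"] + frame["converted"]
    frame["fraction"] = frame["retained"] / frame["n_informative"]
    frame.attrs["window_size"] = window_size
    return frame


def make_calls(rows):
    """Build a single-c frame from (chrom, pos, strand, context, ret, conv)."""
    frame = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "retained", "converted"]
    )
    frame["subcontext"] = ""
    frame["level"] = frame["retained"] / (frame["retained"] + frame["converted"])
    return frame
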