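"""Simulator: genome/annotation structure, methylome calibration, reads."""

import numpy as np
import pandas as pd
import pytest

from mossmeth import (
    SimConfig,
    GenotypeEffect,
    simulate_genome,
    simulate_methylome,
    simulate_bisulfite_reads,
)
from mossmeth.calls import context_table, in_features
from mossmeth.genome import revcomp
from mossmeth.simulate import (
    ConfigurationError,
    apply_genotype_effect,
    identity_effect,
    expected_measured_level,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"gc_content": 1.5},
        {"conversion_rate": -0.1},
        {"te_size_range": (20, 1000)},
        {"te_size_range": (100, 60_000)},
        {"te_size_range": (500, 100)},
        {"read_length": 5},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ConfigurationError):
        SimConfig(**kwargs)


def test_infeasible_packing_rejected():
    cfg = SimConfig(
        n_chromosomes=1, chrom_length=20_000, te_count=100,
        te_size_range=(500, 5000), gene_count=0,
    )
    with pytest.raises(ConfigurationError):
        simulate_genome(cfg)


def test_same_seed_is_bit_identical():
    cfg = SimConfig(seed=42, n_chromosomes=1, chrom_length=20_000,
                    te_count=5, te_size_range=(100, 1000), gene_count=3)
    a = simulate_genome(cfg)
    b = simulate_genome(cfg)
    assert a[0] == b[0]
    pd.testing.assert_frame_equal(a[1], b[1])
    for feature in a[2].features:
        np.testing.assert_array_equal(a[2].get(feature, "chr1"),
                                      b[2].get(feature, "chr1"))
    ctx = context_table(a[0])
    ma = simulate_methylome(a[0], a[1], a[2], ctx=ctx)
    mb = simulate_methylome(b[0], b[1], b[2], ctx=ctx)
    assert ma.equals(mb)
    ra = simulate_bisulfite_reads(a[0], ma, cfg)
    rb = simulate_bisulfite_reads(b[0], mb, cfg)
    assert ra.seqs == rb.seqs and ra.ids == rb.ids
    pd.testing.assert_frame_equal(ra.truth, rb.truth)


def test_no_tes_means_no_te_intervals():
    cfg = SimConfig(seed=3, n_chromosomes=1, chrom_length=20_000,
                    te_count=0, gene_count=4)
    genome, annotations, tracks = simulate_genome(cfg)
    assert (annotations["type"] == "TE").sum() == 0
    assert {"H3K9me2", "H3K4me3", "H3", "siRNA", "GC"} <= set(tracks.features)


def test_features_do_not_overlap(small_sim):
    _, _, annotations, _ = small_sim
    ivals = annotations.sort_values("start")[["start", "end"]].to_numpy()
    assert (ivals[1:, 0] >= ivals[:-1, 1]).all()


def test_h3k9me2_rises_and_h3k4me3_falls_with_te_length():
    cfg = SimConfig(seed=11, n_chromosomes=2, chrom_length=100_000,
                    te_count=50, te_size_range=(100, 5000), gene_count=10)
    genome, annotations, tracks = simulate_genome(cfg)
    tes = annotations[annotations["type"] == "TE"]
    lengths, k9, k4 = [], [], []
    for te in tes.itertuples(index=False):
        first, last = te.start // 50, (te.end - 1) // 50
        lengths.append(te.end - te.start)
        k9.append(tracks.get("H3K9me2", te.chrom)[first:last + 1].mean())
        k4.append(tracks.get("H3K4me3", te.chrom)[first:last + 1].mean())
    assert np.corrcoef(lengths, k9)[0, 1] > 0.5
    assert np.corrcoef(lengths, k4)[0, 1] < -0.5


def test_methylome_hits_base_levels_in_tes():
    cfg = SimConfig(seed=1)  # 2 x 100 kb default
    genome, annotations, tracks = simulate_genome(cfg)
    base = {"CG": 0.8, "CHG": 0.7, "CHH": 0.2}
    model = simulate_methylome(genome, annotations, tracks, base_levels=base)
    te = in_features(model.table, annotations, "TE")
    assert te.sum() > 5000
    for context, want in base.items():
        assert model.context_mean(context, te) == pytest.approx(want, abs=0.02)
    # TE-restricted landscape: nothing outside TEs
    assert model.table.loc[~te, "p"].max() == 0.0


def test_identity_effect_is_a_noop(small_sim, small_ctx, small_wt_model):
    _, genome, annotations, tracks = small_sim
    mutant = apply_genotype_effect(small_wt_model, identity_effect(), tracks)
    assert mutant.equals(small_wt_model)


def test_retention_factor_scales_one_context(small_sim, small_ctx, small_wt_model):
    _, genome, annotations, tracks = small_sim
    effect = GenotypeEffect(name="chh_ko", r_chh=0.05)
    mutant = apply_genotype_effect(small_wt_model, effect, tracks)
    wt_p = small_wt_model.table["p"].to_numpy()
    mut_p = mutant.table["p"].to_numpy()
    ctx = small_wt_model.table["context"].to_numpy()
    np.testing.assert_allclose(mut_p[ctx == "CHH"], 0.05 * wt_p[ctx == "CHH"])
    np.testing.assert_array_equal(mut_p[ctx != "CHH"], wt_p[ctx != "CHH"])


def test_subcontext_override_targets_only_matching_sites(small_sim, small_wt_model):
    _, _, _, tracks = small_sim
    effect = GenotypeEffect(name="x", r_cg=0.1,
                            subcontext_overrides={"CHG:CCG": 0.5})
    mutant = apply_genotype_effect(small_wt_model, effect, tracks)
    t_wt, t_mut = small_wt_model.table, mutant.table
    ccg = (t_wt["context"] == "CHG") & (t_wt["subcontext"] == "CCG")
    other_chg = (t_wt["context"] == "CHG") & ~ccg
    np.testing.assert_allclose(t_mut.loc[ccg, "p"], 0.5 * t_wt.loc[ccg, "p"])
    np.testing.assert_array_equal(t_mut.loc[other_chg, "p"], t_wt.loc[other_chg, "p"])


def test_redistribution_keeps_p_in_unit_interval(small_sim, small_wt_model):
    _, _, _, tracks = small_sim
    effect = GenotypeEffect(name="cmt", r_chg=0.03, chh_redistribution=1.5)
    mutant = apply_genotype_effect(small_wt_model, effect, tracks)
    assert mutant.table["p"].between(0, 1).all()


def test_unknown_base_level_key_rejected(small_sim, small_ctx):
    _, genome, annotations, tracks = small_sim
    with pytest.raises(KeyError):
        simulate_methylome(genome, annotations, tracks,
                           base_levels={"CG": 0.5, "CHG": 0.5, "CXX": 0.1},
                           ctx=small_ctx)


def test_read_count_matches_depth(small_sim, small_wt_model):
    cfg, genome, _, _ = small_sim
    readset = simulate_bisulfite_reads(genome, small_wt_model, cfg, seed=5)
    expected = cfg.depth * genome.total_length / cfg.read_length
    assert abs(len(readset) - expected) <= 3 * np.sqrt(expected)
    with pytest.raises(ValueError):
        simulate_bisulfite_reads(genome, small_wt_model, SimConfig(seed=1, depth=0))


def test_reads_differ_from_origin_only_at_cytosines(small_sim, small_wt_model,
                                                    small_run):
    """Bisulfite conservation: a read equals its origin-strand substring
    except (possibly) at strand-space C positions."""
    cfg, genome, _, _ = small_sim
    readset = small_run["readset"]
    truth = readset.truth.set_index("read_id")
    for rid, seq in list(readset)[::500]:
        t = truth.loc[rid]
        window = genome[t["chrom"]][t["pos"] : t["pos"] + cfg.read_length]
        origin = window if t["strand"] == "+" else revcomp(window)
        for got, ref in zip(seq, origin):
            if got != ref:
                assert ref == "C" and got == "T"


def test_extreme_methylomes_fix_read_bases(small_sim, small_ctx, small_wt_model):
    cfg, genome, annotations, tracks = small_sim
    full = SimConfig(seed=7, n_chromosomes=1, chrom_length=40_000, te_count=10,
                     te_size_range=(100, 2000), gene_count=8, depth=2,
                     conversion_rate=1.0, methylation_failure_rate=0.0)
    # p_true = 0 everywhere and certain conversion: no C survives
    zero = simulate_methylome(genome, annotations, tracks, ctx=small_ctx,
                              base_levels={"CG": 0.0, "CHG": 0.0, "CHH": 0.0})
    reads = simulate_bisulfite_reads(genome, zero, full, seed=1)
    assert not any("C" in seq for seq in reads.seqs)
    # p_true = 1 everywhere (uniform landscape) and no failures: every
    # origin-strand C position reads C
    one = simulate_methylome(genome, annotations, tracks, ctx=small_ctx,
                             base_levels={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
                             landscape="uniform")
    reads = simulate_bisulfite_reads(genome, one, full, seed=2)
    truth = reads.truth.set_index("read_id")
    for rid, seq in list(reads)[::200]:
        t = truth.loc[rid]
        window = genome[t["chrom"]][t["pos"] : t["pos"] + full.read_length]
        origin = window if t["strand"] == "+" else revcomp(window)
        for got, ref in zip(seq, origin):
            if ref == "C":
                assert got == "C"


def test_expected_measured_level_accounts_for_chemistry(small_wt_model):
    cfg = SimConfig(conversion_rate=0.99, methylation_failure_rate=0.01)
    got = expected_measured_level(small_wt_model, cfg, "CG")
    p = small_wt_model.table.query("context == 'CG'")["p"].to_numpy()
    assert got == pytest.approx((p * 0.99 + (1 - p) * 0.01).mean())
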