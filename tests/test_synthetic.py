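"""Tests for the synthetic generators: determinism and planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from l1regkit import g4, quant, synthetic as sy
from l1regkit import offtarget as ot
from l1regkit.offtarget import ShRNA
from l1regkit.setstats import consistent_degs, directional_concordance

GUIDE = "GATTCGCGGATACCGTTAAGC"


# --------------------------------------------------------------------------- #
# universe

def test_universe_unique_and_deterministic():
    u1 = sy.gen_universe(10, seed=1)
    u2 = sy.gen_universe(10, seed=1)
    assert u1.genes == u2.genes
    assert len(set(u1.genes)) == 10


def test_universe_large_and_invalid():
    assert len(sy.gen_universe(20000, seed=7)) == 20000
    with pytest.raises(ValueError):
        sy.gen_universe(0)


# --------------------------------------------------------------------------- #
# DE tables

def _spec(**kw):
    base = dict(
        conditions=("a", "b"),
        n_up={"a": 50, "b": 60},
        n_down={"a": 40, "b": 30},
        common_up=20,
        common_down=10,
    )
    base.update(kw)
    return sy.DESpec(**base)


def test_de_tables_exact_planted_intersections():
    u = sy.gen_universe(500, 1)
    tables, truth = sy.gen_de_tables(u, _spec(), seed=3)
    up_a = tables["a"].significant("up").members
    up_b = tables["b"].significant("up").members
    down_a = tables["a"].significant("down").members
    down_b = tables["b"].significant("down").members
    assert (len(up_a), len(up_b)) == (50, 60)
    assert (len(down_a), len(down_b)) == (40, 30)
    assert len(up_a & up_b) == 20
    assert len(down_a & down_b) == 10
    assert up_a & up_b == set(truth.truth["common_up"])


def test_de_tables_full_intersection_gives_identical_sets():
    u = sy.gen_universe(300, 1)
    spec = _spec(n_up={"a": 30, "b": 30}, common_up=30, n_down={"a": 5, "b": 5}, common_down=0)
    tables, _ = sy.gen_de_tables(u, spec, seed=2)
    assert tables["a"].significant("up").members == tables["b"].significant("up").members


def test_de_tables_infeasible_intersection_rejected():
    u = sy.gen_universe(300, 1)
    with pytest.raises(ValueError, match="intersections exceed"):
        sy.gen_de_tables(u, _spec(common_up=55), seed=1)
    with pytest.raises(ValueError, match="universe"):
        sy.gen_de_tables(sy.gen_universe(100, 1), _spec(), seed=1)


def test_de_tables_opposite_block_recovered():
    u = sy.gen_universe(800, 1)
    tables, truth = sy.gen_de_tables(u, _spec(opposite=15), seed=4)
    d = directional_concordance(tables["a"], tables["b"])
    assert len(d.up_down) == 15
    assert d.up_down.members == set(truth.truth["opposite_up_down"])


def test_de_tables_common_core_recovered_in_four_way_design():
    u = sy.gen_universe(1500, 1)
    spec = sy.DESpec(
        conditions=("c1", "c2", "c3", "c4"),
        n_up={c: 100 for c in ("c1", "c2", "c3", "c4")},
        n_down={c: 80 for c in ("c1", "c2", "c3", "c4")},
        common_up=35,
        common_down=25,
    )
    tables, truth = sy.gen_de_tables(u, spec, seed=5)
    core_up = consistent_degs(list(tables.values()), "up")
    core_down = consistent_degs(list(tables.values()), "down")
    assert core_up.members == set(truth.truth["common_up"])
    assert core_down.members == set(truth.truth["common_down"])


def test_de_tables_deterministic():
    u = sy.gen_universe(400, 1)
    t1, _ = sy.gen_de_tables(u, _spec(), seed=9)
    t2, _ = sy.gen_de_tables(u, _spec(), seed=9)
    for c in ("a", "b"):
        pd.testing.assert_frame_equal(t1[c].frame, t2[c].frame)


# --------------------------------------------------------------------------- #
# sequences

def _seq_spec(**sub_kw):
    sub = dict(n_sequences=3, length=2000, n_g4=3)
    sub.update(sub_kw)
    return sy.SeqSpec(subfamilies={"L1MdTf": sy.SubfamilySeqSpec(**sub)}, g_freq=0.0)


def test_planted_g4_recovered_exactly_at_zero_g_background():
    seqs, truth_ivs, truth = sy.gen_l1_sequences(_seq_spec(), seed=6)
    for s in seqs:
        found = g4.find_g4(s)
        planted = sorted(
            (iv.start, iv.end) for iv in truth_ivs if iv.seq_id == s.id and iv.strand == "+"
        )
        assert sorted((h.start, h.end) for h in found) == planted
        assert len(found) == 3
        # planted near the 3' end: every hit in the 3' half
        assert all(h.start >= len(s) // 2 for h in found)


def test_minus_strand_units_found_only_on_minus_scan():
    seqs, truth_ivs, _ = sy.gen_l1_sequences(_seq_spec(n_g4=0, n_g4_minus=2), seed=7)
    for s in seqs:
        assert g4.find_g4(s, strand="+") == []
        found = g4.find_g4(s, strand="-")
        planted = sorted(
            (iv.start, iv.end) for iv in truth_ivs if iv.seq_id == s.id and iv.strand == "-"
        )
        assert sorted((h.start, h.end) for h in found) == planted


def test_planted_motif_interval_recorded_verbatim():
    seqs, truth_ivs, truth = sy.gen_l1_sequences(
        _seq_spec(n_g4=0, motif_intervals=((100, 120),)), seed=8
    )
    motifs = [iv for iv in truth_ivs if iv.label == "Suz12_site"]
    assert len(motifs) == len(seqs)
    assert all((iv.start, iv.end) == (100, 120) for iv in motifs)


def test_planted_interval_exceeding_length_rejected():
    with pytest.raises(ValueError, match="bounds"):
        sy.gen_l1_sequences(_seq_spec(motif_intervals=((1990, 2050),)), seed=1)


def test_sequences_deterministic_and_within_alphabet():
    s1, iv1, _ = sy.gen_l1_sequences(_seq_spec(), seed=11)
    s2, iv2, _ = sy.gen_l1_sequences(_seq_spec(), seed=11)
    assert [x.sequence for x in s1] == [x.sequence for x in s2]
    assert iv1 == iv2


# --------------------------------------------------------------------------- #
# Ct tables

def test_ct_table_knockdown_recovered_exactly_without_noise():
    frame, _ = sy.gen_ct_table(sy.CtSpec(knockdown={"L1": 0.60}, noise_sd=0.0), seed=1)
    r = quant.ddct(frame, "L1", "Ref")
    assert r.kd_percent == pytest.approx(60.0, abs=1e-9)


def test_ct_table_zero_knockdown_gives_zero_ddct():
    frame, _ = sy.gen_ct_table(sy.CtSpec(knockdown={"L1": 0.0}, noise_sd=0.0), seed=1)
    r = quant.ddct(frame, "L1", "Ref")
    assert r.ddct == pytest.approx(0.0, abs=1e-12)
    assert r.kd_percent == pytest.approx(0.0, abs=1e-9)


def test_ct_table_half_knockdown_is_one_cycle():
    frame, _ = sy.gen_ct_table(sy.CtSpec(knockdown={"L1": 0.5}, noise_sd=0.0), seed=1)
    assert quant.ddct(frame, "L1", "Ref").ddct == pytest.approx(1.0, abs=1e-12)


def test_ct_table_rejects_complete_knockdown():
    with pytest.raises(ValueError):
        sy.gen_ct_table(sy.CtSpec(knockdown={"L1": 1.0}), seed=1)


# --------------------------------------------------------------------------- #
# transcriptome

def test_planted_exact_offtarget_site_found_and_only_it():
    spec = sy.OfftargetSpec(
        guides={"sh1": GUIDE},
        n_transcripts=8,
        transcript_length=600,
        planted=(sy.PlantedSite("sh1", 3, mismatches=0),),
    )
    tx, expr, truth = sy.gen_transcriptome(spec, seed=2)
    hits = ot.scan(ShRNA("sh1", GUIDE), tx, max_mm=0)
    (site,) = truth.truth["planted_sites"]
    assert [(h.transcript_id, h.offset, h.mismatches) for h in hits] == [
        (site["transcript_id"], site["offset"], 0)
    ]


def test_planted_one_mismatch_site_invisible_at_zero_budget():
    spec = sy.OfftargetSpec(
        guides={"sh1": GUIDE},
        n_transcripts=6,
        transcript_length=500,
        planted=(sy.PlantedSite("sh1", 1, mismatches=1),),
    )
    tx, _, truth = sy.gen_transcriptome(spec, seed=3)
    assert ot.scan(ShRNA("sh1", GUIDE), tx, max_mm=0) == []
    hits = ot.scan(ShRNA("sh1", GUIDE), tx, max_mm=1)
    (site,) = truth.truth["planted_sites"]
    assert [(h.transcript_id, h.offset, h.mismatches) for h in hits] == [
        (site["transcript_id"], site["offset"], 1)
    ]


def test_expressed_truth_matches_classifier():
    spec = sy.OfftargetSpec(
        guides={"sh1": GUIDE},
        n_transcripts=10,
        transcript_length=400,
        expressed_transcripts=(0, 2, 4, 6),
    )
    tx, expr, truth = sy.gen_transcriptome(spec, seed=4)
    flags = {tid: (tid in expr.expressed_genes()) for tid in tx}
    assert flags == truth.truth["expressed"]


# --------------------------------------------------------------------------- #
# radial, chromatogram, fractions

def test_radial_uniform_weights_give_ten_percent_bins():
    depths, truth = sy.gen_radial_cells(100_000, [1] * 10, seed=5)
    dist = quant.radial_distribution(depths)
    assert all(abs(p - 10.0) <= 1.0 for p in dist.percentages)
    assert list(dist.counts) == truth.truth["bin_counts"]


def test_radial_zero_weights_rejected():
    with pytest.raises(ValueError):
        sy.gen_radial_cells(10, [0, 0], seed=1)


def test_chromatogram_full_methylation_zeroes_a_peak():
    frame, _ = sy.gen_chromatogram([100.0], noise_sd=0.0, seed=1)
    assert frame["a_height"].iloc[0] == 0.0
    assert quant.methylation_percent(frame["g_height"].iloc[0], frame["a_height"].iloc[0]) == 100.0


def test_chromatogram_standard_series_recovered_monotonically():
    truth_series = [0.0, 25.0, 50.0, 75.0, 100.0]
    frame, _ = sy.gen_chromatogram(truth_series, noise_sd=0.01, seed=2)
    estimates = [
        quant.methylation_percent(g, a) for g, a in zip(frame["g_height"], frame["a_height"])
    ]
    assert all(b > a for a, b in zip(estimates, estimates[1:]))
    assert all(abs(e - t) < 5 for e, t in zip(estimates, truth_series))


def test_fraction_defaults_recover_chromatin_dominance():
    frame, truth = sy.gen_fraction_qpcr(sy.FractionSpec(noise_sd=0.0), seed=6)
    sub = frame[frame["target"] == "L1MdA"]
    means = sub.groupby("compartment", sort=False)["level"].mean()
    prof = quant.fraction_percent(means["cytosol"], means["nucleoplasm"], means["chromatin"])
    assert prof.chromatin == pytest.approx(90.64, abs=1e-9)
    assert truth.truth["percent"]["L1MdTf"][2] == pytest.approx(94.35)


def test_artifact_streams_are_independent():
    """The child-seed schedule isolates artifacts: generating one artifact
    does not depend on whether another was generated first."""
    f1, _ = sy.gen_ct_table(sy.CtSpec(knockdown={"L1": 0.4}, noise_sd=0.2), seed=42)
    sy.gen_radial_cells(100, [1, 2, 3], seed=42)  # unrelated draw in between
    f2, _ = sy.gen_ct_table(sy.CtSpec(knockdown={"L1": 0.4}, noise_sd=0.2), seed=42)
    pd.testing.assert_frame_equal(f1, f2)
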