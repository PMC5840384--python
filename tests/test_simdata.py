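"""Synthetic-data generator: meiosis model, rearrangements, transcripts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radmap import (
    CrossSpec,
    Fusion,
    HitNoise,
    Inversion,
    RearrangementSpec,
    Translocation,
    TrueMap,
    derive_reference_genome,
    kosambi_inverse,
    simulate_family,
    simulate_true_map,
    simulate_unplaced_transcripts,
)


def test_true_map_counts_and_order():
    tm = simulate_true_map(1, 2, 50, seed=0)
    assert tm.n_markers == 2
    assert np.all(np.diff(tm.table["cm"]) > 0)
    tm = simulate_true_map(24, 130, 180, seed=1)
    assert len(tm.chromosomes) == 24
    assert tm.n_markers == 24 * 130


def test_true_map_determinism_and_validation():
    a = simulate_true_map(2, 50, 100, seed=9)
    b = simulate_true_map(2, 50, 100, seed=9)
    pd.testing.assert_frame_equal(a.table, b.table)
    for bad in [(0, 5, 100), (2, 1, 100), (2, 5, 0)]:
        with pytest.raises(ValueError):
            simulate_true_map(*bad, seed=0)
    with pytest.raises(ValueError):
        TrueMap(pd.DataFrame({"chrom": ["c", "c"], "marker": ["m", "m"], "cm": [1.0, 2.0], "bp": [1, 2]}))


def _two_marker_map(gap_cM: float) -> TrueMap:
    return TrueMap(
        pd.DataFrame(
            {"chrom": ["chr01", "chr01"], "marker": ["mA", "mB"],
             "cm": [10.0, 10.0 + gap_cM], "bp": [100_000, 200_000]}
        )
    )


def test_zero_distance_means_zero_recombinants():
    tm = _two_marker_map(1e-9)
    gm, truth = simulate_family(tm, CrossSpec(n_offspring=500, missing_rate=0, error_rate=0, seed=3))
    trans = truth.transmissions  # (parent, marker, offspring), noise-free
    for par in (0, 1):
        # haplotype switch pattern = transmission XOR phase; must be constant
        rec = trans[par, 0] ^ trans[par, 1]
        assert len(set(rec.tolist())) == 1


def test_unlinked_markers_recombine_half_the_time():
    tm = _two_marker_map(500.0)  # inverse Kosambi ~ 0.5
    spec = CrossSpec(n_offspring=1200, missing_rate=0, error_rate=0, seed=4)
    gm, truth = simulate_family(tm, spec)
    ph = truth.markers[["phase1", "phase2"]].to_numpy()
    frac = []
    for par in (0, 1):
        hap = truth.transmissions[par] ^ ph[:, par][:, None]
        frac.append(np.mean(hap[0] != hap[1]))
    rate = np.mean(frac)  # 2400 meioses
    assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / 2400)


def test_mendelian_class_frequencies_without_distortion():
    tm = simulate_true_map(100, 2, 300, seed=5)
    gm, truth = simulate_family(
        tm, CrossSpec(n_offspring=94, missing_rate=0, error_rate=0, distorted_fraction=0.0, seed=6)
    )
    from radmap.markerqc import genotype_class_counts, classify_cross_type, expected_ratio

    pvals = []
    for m in gm.markers:
        counts, _ = genotype_class_counts(gm, m)
        ct = classify_cross_type(gm.p1[m], gm.p2[m])
        exp = expected_ratio(ct) * counts.sum()
        pvals.append(stats.chisquare(counts, f_exp=exp).pvalue)
    reject = np.mean(np.asarray(pvals) < 0.05)
    assert 0.02 < reject < 0.09  # nominal alpha within Monte-Carlo slack


def test_distortion_shifts_transmission_ratio():
    tm = simulate_true_map(50, 2, 300, seed=7)
    spec = CrossSpec(n_offspring=500, missing_rate=0, error_rate=0,
                     distorted_fraction=0.9, distortion_strength=0.5, seed=8)
    gm, truth = simulate_family(tm, spec)
    # selected-against allele transmitted with probability (1-s)/2 = 0.25
    rates = []
    for k, (m, row) in enumerate(truth.markers.iterrows()):
        if not row["distorted"]:
            continue
        par, al = row["distorted_parent"] - 1, row["distorted_allele"]
        rates.append(np.mean(truth.transmissions[par, k] == al))
    assert np.mean(rates) == pytest.approx(0.25, abs=0.01)


def test_family_determinism():
    tm = simulate_true_map(2, 10, 80, seed=10)
    spec = CrossSpec(n_offspring=40, seed=11)
    a, _ = simulate_family(tm, spec)
    b, _ = simulate_family(tm, spec)
    pd.testing.assert_frame_equal(a.calls, b.calls)


def test_family_output_is_valid():
    tm = simulate_true_map(2, 10, 80, seed=12)
    gm, _ = simulate_family(tm, CrossSpec(n_offspring=60, error_rate=0.05, seed=13))
    gm.validate()  # error model never produces unproducible calls


def test_cross_spec_validation():
    with pytest.raises(ValueError):
        CrossSpec(n_offspring=0)
    with pytest.raises(ValueError):
        CrossSpec(cross_type_proportions=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        CrossSpec(missing_rate=1.0)


# ---------------------------------------------------------------------------
# reference genome derivation


@pytest.fixture(scope="module")
def tmap():
    return simulate_true_map(3, 40, 120, seed=20)


def test_identity_rearrangement_preserves_order(tmap):
    genome, hits = derive_reference_genome(tmap, RearrangementSpec(), "sp", seed=1)
    for chrom, sub in genome.table.groupby("chrom"):
        src = tmap.table[tmap.table["marker"].isin(sub["marker"])]
        assert list(sub.sort_values("bp")["marker"]) == list(src.sort_values("bp")["marker"])
    # every marker present with at least one hit below the cutoff
    best = hits.sort_values("bitscore", ascending=False).groupby("query").head(1)
    assert set(best["query"]) == set(tmap.table["marker"])
    assert (best["evalue"] < 1e-9).all()


def test_inversion_reverses_exact_bp_run(tmap):
    sub = tmap.chrom_table("chr02")
    lo, hi = int(sub["bp"].iloc[10]), int(sub["bp"].iloc[20])
    genome, _ = derive_reference_genome(
        tmap, RearrangementSpec(operations=[Inversion("chr02", lo, hi)]), "sp", seed=2
    )
    derived = genome.table.set_index("marker")
    inverted = sub["marker"].iloc[10:21]
    got = derived.loc[inverted, "bp"].to_numpy()
    assert np.all(np.diff(got) < 0)  # reversed
    untouched = sub["marker"].iloc[:10]
    assert np.all(np.diff(derived.loc[untouched, "bp"].to_numpy()) > 0)


def test_fusion_unions_marker_sets(tmap):
    genome, _ = derive_reference_genome(
        tmap, RearrangementSpec(operations=[Fusion("chr01", "chr03")]), "sp", seed=3
    )
    origin = genome.chrom_origin
    fused = [c for c in genome.table["chrom"].unique() if origin[c] == "chr01"]
    assert len(fused) == 1
    members = set(genome.table.loc[genome.table["chrom"] == fused[0], "marker"])
    want = set(tmap.table.loc[tmap.table["chrom"].isin(["chr01", "chr03"]), "marker"])
    assert members == want


def test_translocation_moves_segment(tmap):
    sub = tmap.chrom_table("chr01")
    op = Translocation("chr01", int(sub["bp"].iloc[5]), int(sub["bp"].iloc[9]), "chr02", 1_500_000)
    genome, _ = derive_reference_genome(tmap, RearrangementSpec(operations=[op]), "sp", seed=4)
    derived = genome.table.set_index("marker")
    moved = sub["marker"].iloc[5:10]
    dest = {c for c in derived.loc[moved, "chrom"]}
    assert len(dest) == 1 and genome.chrom_origin[dest.pop()] == "chr02"


def test_self_fusion_rejected(tmap):
    with pytest.raises(ValueError):
        derive_reference_genome(tmap, RearrangementSpec(operations=[Fusion("chr01", "chr01")]), "sp", seed=5)


def test_repetitive_markers_exceed_hit_cap(tmap):
    spec = RearrangementSpec(hit_noise=HitNoise(no_hit=0.0, repetitive=0.3, wrong_chrom=0.0))
    genome, hits = derive_reference_genome(tmap, spec, "sp", seed=6)
    per_query = hits.groupby("query").size()
    n_rep = (per_query > 10).sum()
    assert 0.2 * tmap.n_markers < n_rep < 0.4 * tmap.n_markers


# ---------------------------------------------------------------------------
# transcripts


def test_single_hit_fraction_one_gives_one_hit_per_species(tmap):
    genomes = {
        sp: derive_reference_genome(tmap, RearrangementSpec(), sp, seed=k)[0]
        for k, sp in enumerate(["spA", "spB"])
    }
    truth, hits = simulate_unplaced_transcripts(tmap, genomes, 50, single_hit_fraction=1.0, seed=30)
    for sp, df in hits.items():
        assert (df.groupby("query").size() == 1).all()
        assert set(df["query"]) == set(truth["transcript"])
    # determinism
    truth2, hits2 = simulate_unplaced_transcripts(tmap, genomes, 50, single_hit_fraction=1.0, seed=30)
    pd.testing.assert_frame_equal(truth, truth2)
    pd.testing.assert_frame_equal(hits["spA"], hits2["spA"])


def test_transcript_cm_between_flanking_markers(tmap):
    genomes = {"spA": derive_reference_genome(tmap, RearrangementSpec(), "spA", seed=1)[0]}
    truth, _ = simulate_unplaced_transcripts(tmap, genomes, 100, seed=31)
    for _, r in truth.iterrows():
        sub = tmap.chrom_table(r["chrom"])
        k = int(np.searchsorted(sub["bp"].to_numpy(), r["bp"])) - 1
        k = min(max(k, 0), len(sub) - 2)
        assert sub["cm"].iloc[k] - 1e-9 <= r["cm"] <= sub["cm"].iloc[k + 1] + 1e-9


def test_transcripts_validation(tmap):
    with pytest.raises(ValueError):
        simulate_unplaced_transcripts(tmap, {}, 0, seed=0)
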