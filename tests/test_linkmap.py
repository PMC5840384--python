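"""Two-point estimation, grouping, ordering, Kosambi transform, map build."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radmap import (
    MapConfig,
    build_map,
    estimate_all_pairs,
    estimate_rf,
    group_markers,
    kosambi_cm,
    kosambi_inverse,
    order_markers,
    pair_likelihood,
    summarize_groups,
)
from radmap.linkmap import TwoPointEstimates, _sarf
from radmap.markerqc import parse_genotype

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Kosambi


def test_kosambi_closed_forms():
    assert kosambi_cm(0.0) == 0.0
    assert kosambi_cm(0.25) == pytest.approx(25 * math.log(3.0))


@settings(deadline=None, max_examples=200)
@given(st.floats(min_value=0.0, max_value=200.0))
def test_kosambi_round_trip(d):
    assert kosambi_cm(kosambi_inverse(d)) == pytest.approx(d, abs=1e-10)


def test_kosambi_domain():
    with pytest.raises(ValueError):
        kosambi_cm(0.5)
    with pytest.raises(ValueError):
        kosambi_cm(-0.01)
    with pytest.warns(UserWarning):
        kosambi_cm(0.49995)


# ---------------------------------------------------------------------------
# pair likelihood: brute-force gamete enumeration oracle


def _brute_force_loglik(p1, p2_, calls1, calls2, phase, rf):
    """Enumerate all 4x4 parental gamete combinations per offspring."""
    a1, b1 = parse_genotype(p1[0]), parse_genotype(p2_[0])  # parent alleles at m1
    a2, b2 = parse_genotype(p1[1]), parse_genotype(p2_[1])  # at m2
    ph1, ph2 = phase
    total = 0.0
    for g1, g2 in zip(calls1, calls2):
        if g1 == "-" or g2 == "-":
            continue
        obs1 = tuple(sorted(parse_genotype(g1)))
        obs2 = tuple(sorted(parse_genotype(g2)))
        prob = 0.0
        for i1, i2 in itertools.product((0, 1), repeat=2):  # parent-1 gamete
            pr1 = (1 - rf) / 2 if (i1 ^ i2) == ph1 else rf / 2
            for j1, j2 in itertools.product((0, 1), repeat=2):  # parent-2 gamete
                pr2 = (1 - rf) / 2 if (j1 ^ j2) == ph2 else rf / 2
                if tuple(sorted((a1[i1], b1[j1]))) == obs1 and tuple(sorted((a2[i2], b2[j2]))) == obs2:
                    prob += pr1 * pr2
        total += math.log(prob)
    return total


def test_pair_likelihood_matches_enumeration():
    gm = make_matrix(
        {
            "m1": ("a/b", "a/c", ["a/a", "a/c", "b/c", "a/b", "-", "a/a"]),
            "m2": ("a/b", "a/b", ["a/a", "a/b", "b/b", "a/b", "a/a", "b/b"]),
        }
    )
    for phase in itertools.product((0, 1), repeat=2):
        for rf in (0.01, 0.1, 0.3, 0.5):
            got = pair_likelihood(gm, "m1", "m2", phase, rf)
            want = _brute_force_loglik(
                ("a/b", "a/b"), ("a/c", "a/b"),
                list(gm.calls.loc["m1"]), list(gm.calls.loc["m2"]), phase, rf,
            )
            assert got == pytest.approx(want, rel=1e-12)


def test_rf_half_is_phase_independent():
    gm = make_matrix(
        {
            "m1": ("a/b", "c/d", ["a/c", "b/d", "a/d", "b/c"] * 5),
            "m2": ("a/b", "c/d", ["a/d", "b/c", "a/c", "b/d"] * 5),
        }
    )
    lls = {ph: pair_likelihood(gm, "m1", "m2", ph, 0.5) for ph in itertools.product((0, 1), repeat=2)}
    assert len({round(v, 10) for v in lls.values()}) == 1


# ---------------------------------------------------------------------------
# estimate_rf: count-ratio MLE on a fully informative pair


def _fully_informative_pair(n_rec1=19, n=94):
    """AB x CD at both markers, coupling phase; parent 1 contributes
    ``n_rec1`` recombinant meioses, parent 2 none: 19 of 188."""
    m1c, m2c = [], []
    p1a, p2a = ("a", "b"), ("c", "d")
    for k in range(n):
        i = k % 2  # parent-1 parental gamete (i, i)
        j = (k // 2) % 2  # parent-2 parental gamete (j, j)
        i2 = 1 - i if k < n_rec1 else i  # recombinant at m2 for first n_rec1
        m1c.append("/".join(sorted((p1a[i], p2a[j]))))
        m2c.append("/".join(sorted((p1a[i2], p2a[j]))))
    return make_matrix({"m1": ("a/b", "c/d", m1c), "m2": ("a/b", "c/d", m2c)})


def test_estimate_rf_equals_count_ratio():
    gm = _fully_informative_pair()
    est = estimate_rf(gm, "m1", "m2")
    assert est.rf == pytest.approx(19 / 188, abs=1e-3)
    assert est.n_scorable == 94


def test_identical_vectors_give_zero_rf_and_max_lod():
    gm = _fully_informative_pair(n_rec1=0)
    est = estimate_rf(gm, "m1", "m2")
    assert est.rf < 1e-3
    # 94 fully informative offspring: LOD ~ 94 * log10(4) at r=0
    assert est.lod > 40
    sparse = make_matrix({"m1": ("a/b", "c/d", ["a/c", "-"]), "m2": ("a/b", "c/d", ["-", "a/c"])})
    with pytest.raises(ValueError, match="jointly non-missing"):
        estimate_rf(sparse, "m1", "m2")


def test_lod_invariant_to_allele_relabel_and_parent_swap():
    gm = _fully_informative_pair()
    base = estimate_rf(gm, "m1", "m2")
    # relabel a<->b in parent 1's alphabet
    relab = {"a": "b", "b": "a", "c": "c", "d": "d"}
    calls = gm.calls.map(lambda g: "/".join(sorted(relab[x] for x in g.split("/"))))
    gm2 = make_matrix(
        {
            "m1": ("a/b", "c/d", list(calls.loc["m1"])),
            "m2": ("a/b", "c/d", list(calls.loc["m2"])),
        }
    )
    swap = make_matrix(
        {
            "m1": ("c/d", "a/b", list(gm.calls.loc["m1"])),
            "m2": ("c/d", "a/b", list(gm.calls.loc["m2"])),
        }
    )
    for other in (gm2, swap):
        est = estimate_rf(other, "m1", "m2")
        assert est.lod == pytest.approx(base.lod, abs=1e-6)
        assert est.rf == pytest.approx(base.rf, abs=1e-4)


def test_bulk_estimates_match_single_pair(small_family):
    _, gm, _ = small_family
    markers = gm.markers[:8]
    est = estimate_all_pairs(gm, markers=markers)
    df = est.to_frame()
    for _, row in df.iloc[::5].iterrows():
        single = estimate_rf(gm, row["m1"], row["m2"])
        assert row["rf"] == pytest.approx(single.rf, abs=2e-3)
        assert row["lod"] == pytest.approx(single.lod, abs=0.05)


def test_unlinked_markers_show_no_linkage(small_family):
    tmap, gm, truth = small_family
    est = estimate_all_pairs(gm)
    df = est.to_frame()
    chrom = truth.markers["chrom"]
    cross = df[chrom.loc[df["m1"]].to_numpy() != chrom.loc[df["m2"]].to_numpy()]
    assert np.median(cross["rf"]) > 0.4
    assert (cross["lod"] < 3).mean() > 0.95


# ---------------------------------------------------------------------------
# grouping & ordering


def _manual_estimates(markers, entries):
    m = len(markers)
    iu, ju = np.triu_indices(m, k=1)
    rf = np.full(len(iu), 0.5)
    lod = np.zeros(len(iu))
    for (a, b), (r, l) in entries.items():
        i, j = sorted((markers.index(a), markers.index(b)))
        off = i * m - i * (i + 1) // 2 + (j - i - 1)
        rf[off] = r
        lod[off] = l
    return TwoPointEstimates(markers, iu, ju, rf, lod, np.zeros(len(iu), dtype=np.uint8), np.full(len(iu), 94))


def test_grouping_transitive_closure():
    est = _manual_estimates(
        ["a", "b", "c", "d"],
        {("a", "b"): (0.05, 20), ("b", "c"): (0.05, 20), ("a", "c"): (0.45, 1)},
    )
    groups, unassigned = group_markers(est, MapConfig(grouping_lod=14))
    assert groups == [["a", "b", "c"]]
    assert unassigned == ["d"]


def test_grouping_no_edges_all_unassigned():
    est = _manual_estimates(["a", "b", "c"], {})
    groups, unassigned = group_markers(est, MapConfig())
    assert groups == []
    assert unassigned == ["a", "b", "c"]


def test_ordering_three_markers_forced_by_additivity():
    markers = ["ma", "mb", "mc"]
    est = _manual_estimates(
        markers,
        {("ma", "mb"): (0.05, 50), ("mb", "mc"): (0.05, 50), ("ma", "mc"): (0.10, 40)},
    )
    gm = make_matrix({m: ("a/b", "c/d", ["a/c"] * 4) for m in markers})
    order = order_markers(gm, markers, est, MapConfig(ordering_seed_size=3))
    assert order in (["ma", "mb", "mc"], ["mc", "mb", "ma"])
    rfM, _ = est.matrices(markers)
    idx = [markers.index(m) for m in order]
    assert _sarf(idx, rfM) == pytest.approx(_sarf(idx[::-1], rfM))


def test_ordering_rejects_singleton():
    est = _manual_estimates(["a", "b"], {("a", "b"): (0.1, 30)})
    gm = make_matrix({m: ("a/b", "c/d", ["a/c"] * 4) for m in ["a", "b"]})
    with pytest.raises(ValueError):
        order_markers(gm, ["a"], est)


def test_noiseless_recovery_exact_up_to_reversal(clean_family):
    tmap, gm, _ = clean_family
    est = estimate_all_pairs(gm)
    groups, unassigned = group_markers(est, MapConfig(grouping_lod=6))
    assert len(groups) == 1 and not unassigned
    order = order_markers(gm, groups[0], est)
    truth = tmap.table["marker"].to_list()
    assert order == truth or order == truth[::-1]


# ---------------------------------------------------------------------------
# map assembly and summary arithmetic


def test_build_map_two_marker_closed_form():
    est = _manual_estimates(["a", "b"], {("a", "b"): (0.1, 30)})
    gmap = build_map([["a", "b"]], est)
    size = 25 * math.log(1.2 / 0.8)
    gs = gmap.group_summary()
    assert gs.loc["LG1", "size_cM"] == pytest.approx(size, abs=1e-6)
    assert gs.loc["LG1", "mean_spacing_cM"] == pytest.approx(size, abs=1e-6)
    assert gs.loc["LG1", "largest_gap_cM"] == pytest.approx(size, abs=1e-6)


def test_map_positions_nondecreasing(clean_family):
    tmap, gm, _ = clean_family
    est = estimate_all_pairs(gm)
    groups, _ = group_markers(est, MapConfig(grouping_lod=6))
    order = order_markers(gm, groups[0], est)
    gmap = build_map([order], est)
    pos = gmap.table["position_cM"].to_numpy()
    assert np.all(np.diff(pos) >= 0)
    s = gmap.map_summary()
    assert s["total_loci"] == len(order)
    gs = gmap.group_summary()
    n, size = gs.loc["LG1", "n_loci"], gs.loc["LG1", "size_cM"]
    assert gs.loc["LG1", "mean_spacing_cM"] == pytest.approx(size / (n - 1))


def test_summarize_groups_arithmetic():
    df, totals = summarize_groups([203.2357744, 87.79384775], [147, 65], ["g1", "g2"])
    assert df.loc["g1", "mean_spacing_cM"] == pytest.approx(203.2357744 / 146, rel=1e-12)
    assert totals["total_loci"] == 212
    assert totals["mean_interval_cM"] == pytest.approx((203.2357744 + 87.79384775) / 210)
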