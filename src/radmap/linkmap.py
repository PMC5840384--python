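"""Two-point linkage mapping for an outbred full-sib family.

The chain mirrors classical outcross mapping practice: maximum-likelihood
two-point recombination fractions with per-pair parental phase, LOD-based
grouping by transitive closure, within-group ordering by minimum sum of
adjacent recombination fractions (SARF) with a window "ripple" refinement,
and Kosambi map distances.

Two-point model
---------------
For a pair of markers, each parent transmits one of its two alleles at each
marker.  Under phase ``ph`` (0 = coupling: same allele index on the same
homolog) a gamete combining allele indices ``(i1, i2)`` is parental when
``i1 XOR i2 == ph`` and has probability ``(1-r)/2``; recombinant gametes
have probability ``r/2``.  The joint offspring genotype probability sums
over both parents' gametes; the per-pair likelihood is maximised over
``r`` in [1e-6, 0.4999] under each of the four phase configurations and
the best phase is kept.  ``LOD = log10 L(r_hat) - log10 L(0.5)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse import csgraph

from .markerqc import (
    CROSS_TYPE_PRIORITY,
    MISSING,
    MISSING_CODE,
    GenotypeMatrix,
    classify_cross_type,
)

RF_MIN = 1e-6
RF_MAX = 0.4999
_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Kosambi map function


def kosambi_cm(rf):
    """Kosambi map distance d = 25 * ln((1+2r)/(1-2r)) in centiMorgans.

    Accepts scalars or arrays with 0 <= rf < 0.5; values >= 0.4999 are
    capped there with a warning.
    """
    r = np.asarray(rf, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if np.any(r >= RF_MAX):
        warnings.warn("recombination fraction >= 0.4999 capped for Kosambi transform")
        r = np.minimum(r, RF_MAX)
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if np.isscalar(rf) else d


def kosambi_inverse(d):
    """Inverse Kosambi: r = tanh(d/50) / 2 for map distance d in cM."""
    r = 0.5 * np.tanh(np.asarray(d, dtype=float) / 50.0)
    return float(r) if np.isscalar(d) else r


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class MapConfig:
    """Thresholds of the mapping chain (two-point screen, grouping, ordering)."""

    twopoint_lod_min: float = 4.0
    twopoint_rf_max: float = 0.4
    grouping_lod: float = 14.0
    grouping_rf_max: float = 0.4
    ordering_seed_size: int = 6
    ordering_lod: float = 3.0
    ripple_window: int = 4

    def __post_init__(self) -> None:
        if min(self.twopoint_lod_min, self.grouping_lod, self.ordering_lod) <= 0:
            raise ValueError("LOD thresholds must be positive")
        if not (0 < self.twopoint_rf_max <= 0.5 and 0 < self.grouping_rf_max <= 0.5):
            raise ValueError("rf bounds must lie in (0, 0.5]")
        if self.ordering_seed_size < 2 or self.ripple_window < 2:
            raise ValueError("ordering window sizes must be >= 2")


# ---------------------------------------------------------------------------
# Joint genotype-class probability tables
#
# Offspring classes per marker are the canonical transmission codes of
# markerqc.encode_marker; a pooled (ab x ab) marker has 3 classes, others 4.
# Joint class (c1, c2) is stored flat as c1*5 + c2 (code 4 = missing).  The
# joint probability is a quadratic in r:
#     P = (A (1-r)^2 + B r(1-r) + C r^2) / 4
# with integer coefficients counting (parental, parental), mixed, and
# (recombinant, recombinant) gamete-pair terms under the phase pair.


def _transmission_sets(pooled: bool) -> list[list[tuple[int, int]]]:
    if pooled:
        return [[(0, 0)], [(0, 1), (1, 0)], [(1, 1)]]
    return [[(0, 0)], [(0, 1)], [(1, 0)], [(1, 1)]]


def _pair_coeffs(pooled1: bool, pooled2: bool) -> np.ndarray:
    """Coefficient tensor of shape (3, 4, 25): (A,B,C) x phase-pair x class-pair."""
    coeff = np.zeros((3, 4, 25))
    t1 = _transmission_sets(pooled1)
    t2 = _transmission_sets(pooled2)
    for c1, s1 in enumerate(t1):
        for c2, s2 in enumerate(t2):
            col = c1 * 5 + c2
            for (i1, j1) in s1:
                for (i2, j2) in s2:
                    for pp in range(4):
                        ph1, ph2 = pp >> 1, pp & 1
                        n_rec = int((i1 ^ i2) != ph1) + int((j1 ^ j2) != ph2)
                        coeff[n_rec if n_rec != 1 else 1, pp, col] += 1.0
    # index 0 = A (0 recombinant factors), 1 = B, 2 = C
    return coeff


_COEFF_CACHE = {
    (p1, p2): _pair_coeffs(p1, p2) for p1 in (False, True) for p2 in (False, True)
}


def _log_joint(coeff: np.ndarray, pp: int, r: np.ndarray) -> np.ndarray:
    """log P over the 25 flat class pairs at recombination fractions r.

    Returns shape ``r.shape + (25,)``; impossible/missing class pairs get 0
    so they drop out of count-weighted sums.
    """
    A, B, C = coeff[0, pp], coeff[1, pp], coeff[2, pp]
    r = np.asarray(r, dtype=float)[..., None]
    P = (A * (1 - r) ** 2 + B * r * (1 - r) + C * r * r) / 4.0
    valid = (A + B + C) > 0
    return np.where(valid, np.log(np.maximum(P, 1e-300)), 0.0)


def _joint_counts(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Flat 25-bin joint class counts for one pair of code vectors."""
    return np.bincount(c1.astype(np.int32) * 5 + c2, minlength=25).astype(float)


def _encode_all(gm: GenotypeMatrix, markers: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    codes = np.empty((len(markers), gm.n_offspring), dtype=np.uint8)
    pooled = np.zeros(len(markers), dtype=bool)
    for k, m in enumerate(markers):
        coding = gm.coding(m)
        codes[k] = coding.codes
        pooled[k] = coding.pooled
    return codes, pooled


# ---------------------------------------------------------------------------
# Public two-point operations


def pair_likelihood(gm: GenotypeMatrix, m1: str, m2: str, phase: tuple[int, int], rf: float) -> float:
    """Natural-log likelihood of the offspring data for one marker pair.

    ``phase = (ph1, ph2)`` gives each parent's configuration (0 coupling,
    1 repulsion).  Offspring missing at either marker contribute 0.
    """
    if not RF_MIN - 1e-12 <= rf <= 0.5:
        raise ValueError("rf outside [0, 0.5]")
    ph1, ph2 = phase
    cod1, cod2 = gm.coding(m1), gm.coding(m2)
    counts = _joint_counts(cod1.codes, cod2.codes)
    coeff = _COEFF_CACHE[(cod1.pooled, cod2.pooled)]
    logP = _log_joint(coeff, ph1 * 2 + ph2, np.asarray(rf))
    return float(counts @ logP)


@dataclass
class TwoPointEstimate:
    """Best two-point estimate for one marker pair."""

    m1: str
    m2: str
    rf: float
    lod: float
    phase: tuple[int, int]
    n_scorable: int


def _valid_mask(coeff: np.ndarray) -> np.ndarray:
    return coeff[:, 0].sum(axis=0) > 0


def estimate_rf(gm: GenotypeMatrix, m1: str, m2: str) -> TwoPointEstimate:
    """ML recombination fraction, phase and LOD for one marker pair.

    Maximises the likelihood over rf in [1e-6, 0.4999] (bounded scalar
    optimisation, tolerance 1e-4, restarted from a coarse grid) separately
    under each of the 4 phase configurations; ties resolved toward the
    smaller rf.
    """
    cod1, cod2 = gm.coding(m1), gm.coding(m2)
    counts = _joint_counts(cod1.codes, cod2.codes)
    coeff = _COEFF_CACHE[(cod1.pooled, cod2.pooled)]
    valid = _valid_mask(coeff)
    n_scorable = int(counts[valid.nonzero()[0]].sum())
    if n_scorable < 2:
        raise ValueError(f"pair ({m1}, {m2}): fewer than 2 jointly non-missing offspring")

    ll05 = float(counts @ _log_joint(coeff, 0, np.asarray(0.5)))
    best = None
    grid = np.linspace(RF_MIN, RF_MAX, 101)
    for pp in range(4):
        def negll(r, pp=pp):
            return -float(counts @ _log_joint(coeff, pp, np.asarray(r)))

        g = counts @ _log_joint(coeff, pp, grid).T
        k = int(np.argmax(g))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
        cand = (-res.fun, -float(res.x), pp)  # prefer higher ll, then smaller rf
        if best is None or cand > best:
            best = cand
    ll, neg_r, pp = best
    lod = max((ll - ll05) / _LN10, 0.0)
    return TwoPointEstimate(m1, m2, float(-neg_r), lod, (pp >> 1, pp & 1), n_scorable)


@dataclass
class TwoPointEstimates:
    """All-pairs two-point estimates over a marker set (condensed i<j layout)."""

    markers: list[str]
    i: np.ndarray
    j: np.ndarray
    rf: np.ndarray
    lod: np.ndarray
    phase: np.ndarray  # 0..3, (ph1 << 1) | ph2
    n_scorable: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.markers)
        return pd.DataFrame(
            {
                "m1": names[self.i],
                "m2": names[self.j],
                "rf": self.rf,
                "lod": self.lod,
                "phase1": self.phase >> 1,
                "phase2": self.phase & 1,
                "n": self.n_scorable,
            }
        )

    def _index(self) -> dict[str, int]:
        return {m: k for k, m in enumerate(self.markers)}

    def matrices(self, subset: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Dense (rf, lod) matrices over ``subset`` (default: all markers)."""
        idx = self._index()
        names = list(subset) if subset is not None else self.markers
        sel = np.array([idx[m] for m in names])
        m = len(self.markers)
        rfM = np.full((len(names), len(names)), 0.5)
        lodM = np.zeros((len(names), len(names)))
        # condensed index of (i<j): i*m - i(i+1)/2 + (j-i-1)
        ii, jj = np.meshgrid(sel, sel, indexing="ij")
        a = np.minimum(ii, jj)
        b = np.maximum(ii, jj)
        off = a * m - a * (a + 1) // 2 + (b - a - 1)
        mask = a != b
        rfM[mask] = self.rf[off[mask]]
        lodM[mask] = self.lod[off[mask]]
        np.fill_diagonal(rfM, 0.0)
        return rfM, lodM


def estimate_all_pairs(
    gm: GenotypeMatrix,
    markers: Sequence[str] | None = None,
    grid_size: int = 256,
    refine_points: int = 41,
    block: int = 4096,
) -> TwoPointEstimates:
    """Vectorised ML two-point estimates for every marker pair.

    A coarse likelihood grid over rf x phase is followed by a local grid
    refinement around the coarse optimum (net rf resolution ~1e-4).  Pairs
    are processed in blocks grouped by class structure (pooled ab x ab vs
    four-class markers) so each block is a single matrix product.
    """
    names = list(markers) if markers is not None else gm.markers
    m = len(names)
    if m < 2:
        raise ValueError("need at least two markers")
    codes, pooled = _encode_all(gm, names)
    iu, ju = np.triu_indices(m, k=1)
    npairs = len(iu)
    rf = np.empty(npairs)
    lod = np.empty(npairs)
    phase = np.empty(npairs, dtype=np.uint8)
    nsc = np.empty(npairs, dtype=np.int64)

    r1 = np.linspace(RF_MIN, RF_MAX, grid_size)
    step = r1[1] - r1[0]
    cat = pooled[iu].astype(int) * 2 + pooled[ju].astype(int)
    for c in range(4):
        sel = np.flatnonzero(cat == c)
        if sel.size == 0:
            continue
        coeff = _COEFF_CACHE[(bool(c >> 1), bool(c & 1))]
        valid = _valid_mask(coeff)
        vcols = np.flatnonzero(valid)
        # stage-1 table: (25, 4 * grid)
        logT = np.stack([_log_joint(coeff, pp, r1) for pp in range(4)])  # (4, grid, 25)
        logT = logT.transpose(2, 0, 1).reshape(25, 4 * grid_size)
        log05 = _log_joint(coeff, 0, np.asarray(0.5))
        A, B, C = coeff
        for s in range(0, sel.size, block):
            blk = sel[s : s + block]
            bi, bj = iu[blk], ju[blk]
            J = codes[bi].astype(np.int32) * 5 + codes[bj]
            J += (np.arange(len(blk)) * 25)[:, None]
            counts = np.bincount(J.ravel(), minlength=len(blk) * 25).reshape(len(blk), 25).astype(float)
            nsc[blk] = counts[:, vcols].sum(axis=1).astype(np.int64)
            LL = counts @ logT
            best = LL.argmax(axis=1)
            pp_b = (best // grid_size).astype(np.uint8)
            r_b = r1[best % grid_size]
            # local refinement at fixed best phase
            lo = np.clip(r_b - step, RF_MIN, RF_MAX)
            hi = np.clip(r_b + step, RF_MIN, RF_MAX)
            t = np.linspace(0.0, 1.0, refine_points)
            rloc = lo[:, None] + (hi - lo)[:, None] * t
            Ab, Bb, Cb = A[pp_b], B[pp_b], C[pp_b]  # (B, 25)
            P = (
                Ab[:, None, :] * (1 - rloc)[..., None] ** 2
                + Bb[:, None, :] * (rloc * (1 - rloc))[..., None]
                + Cb[:, None, :] * (rloc**2)[..., None]
            ) / 4.0
            logP = np.where(valid[None, None, :], np.log(np.maximum(P, 1e-300)), 0.0)
            ll_loc = np.einsum("bc,bnc->bn", counts, logP)
            kk = ll_loc.argmax(axis=1)
            ar = np.arange(len(blk))
            ll_best = ll_loc[ar, kk]
            rf[blk] = rloc[ar, kk]
            phase[blk] = pp_b
            lod[blk] = np.maximum((ll_best - counts @ log05) / _LN10, 0.0)
    return TwoPointEstimates(names, iu, ju, rf, lod, phase, nsc)


# ---------------------------------------------------------------------------
# Grouping


def group_markers(est: TwoPointEstimates, config: MapConfig | None = None) -> tuple[list[list[str]], list[str]]:
    """Partition markers into linkage groups by transitive closure.

    An edge links two markers when ``lod >= grouping_lod`` and
    ``rf <= grouping_rf_max``.  Returns (groups, unassigned): groups of
    size >= 2 sorted by decreasing size then first marker id; singletons
    are reported as unassigned.
    """
    config = config or MapConfig()
    linked = (est.lod >= config.grouping_lod) & (est.rf <= config.grouping_rf_max)
    m = len(est.markers)
    g = sparse.coo_matrix(
        (np.ones(int(linked.sum())), (est.i[linked], est.j[linked])), shape=(m, m)
    )
    n_comp, labels = csgraph.connected_components(g, directed=False)
    groups: list[list[str]] = []
    unassigned: list[str] = []
    for comp in range(n_comp):
        members = sorted(np.asarray(est.markers)[labels == comp])
        if len(members) >= 2:
            groups.append(members)
        else:
            unassigned.extend(members)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, sorted(unassigned)


def scan_grouping_lod(
    est: TwoPointEstimates,
    lods: Sequence[float],
    rf_max: float = 0.4,
) -> pd.DataFrame:
    """Group counts across a range of grouping LOD thresholds.

    Companion utility for choosing the grouping stringency: the natural rule
    is the LOD whose group count matches the karyotype's haploid chromosome
    number while minimising unassigned markers.
    """
    rows = []
    for lod in lods:
        cfg = MapConfig(grouping_lod=lod, grouping_rf_max=rf_max)
        groups, unassigned = group_markers(est, cfg)
        rows.append({"lod": lod, "n_groups": len(groups), "n_unassigned": len(unassigned)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ordering (SARF seriation with ripple refinement)


def _sarf(order: list[int], rfM: np.ndarray) -> float:
    idx = np.asarray(order)
    return float(rfM[idx[:-1], idx[1:]].sum())


def order_markers(
    gm: GenotypeMatrix,
    group: Sequence[str],
    est: TwoPointEstimates,
    config: MapConfig | None = None,
) -> list[str]:
    """Order one linkage group by minimising the sum of adjacent rf (SARF).

    A seed of the most informative markers (cross-type priority
    ab x cd > ab x ac > ab x ab, then most scorable meioses, then marker id)
    is ordered exhaustively; the remaining markers are inserted greedily at
    the SARF-minimising position (markers with no within-group pair at
    ``ordering_lod`` are inserted last); a sliding-window ripple pass
    permutes every ``ripple_window`` consecutive markers and keeps strict
    improvements.  The returned orientation places the smaller terminal
    marker id first (orientation itself is unidentifiable).
    """
    config = config or MapConfig()
    group = list(group)
    if len(group) < 2:
        raise ValueError("cannot order a group of size < 2")
    rfM, lodM = est.matrices(group)
    ct = {m: classify_cross_type(gm.p1[m], gm.p2[m]) for m in group}
    scorable = {m: 2 * int((gm.calls.loc[m] != MISSING).sum()) for m in group}
    rank = sorted(
        range(len(group)),
        key=lambda k: (-CROSS_TYPE_PRIORITY[ct[group[k]]], -scorable[group[k]], group[k]),
    )
    np.fill_diagonal(lodM, 0.0)
    well_linked = lodM.max(axis=1) >= config.ordering_lod
    primary = [k for k in rank if well_linked[k]]
    deferred = [k for k in rank if not well_linked[k]]
    if not primary:
        primary, deferred = rank, []

    seed = primary[: min(config.ordering_seed_size, len(primary))]
    best = None
    for perm in itertools.permutations(seed):
        if perm[0] > perm[-1]:
            continue  # reversal-equivalent
        cand = (_sarf(list(perm), rfM), perm)
        if best is None or cand < best:
            best = cand
    order = list(best[1])

    for k in primary[len(seed):] + deferred:
        # insertion delta: end positions add one edge, interior swaps one edge
        deltas = [rfM[k, order[0]]]
        deltas += [
            rfM[order[p - 1], k] + rfM[k, order[p]] - rfM[order[p - 1], order[p]]
            for p in range(1, len(order))
        ]
        deltas.append(rfM[order[-1], k])
        best_pos = int(np.argmin(np.asarray(deltas)))
        order.insert(best_pos, k)

    # ripple: permute sliding windows, accept strict improvements
    def local_cost(seq: tuple[int, ...], left: int | None, right: int | None) -> float:
        c = sum(rfM[a, b] for a, b in zip(seq[:-1], seq[1:]))
        if left is not None:
            c += rfM[left, seq[0]]
        if right is not None:
            c += rfM[seq[-1], right]
        return c

    w = min(config.ripple_window, len(order))
    improved = True
    sweeps = 0
    while improved and sweeps < 25:
        improved = False
        sweeps += 1
        for s in range(len(order) - w + 1):
            left = order[s - 1] if s > 0 else None
            right = order[s + w] if s + w < len(order) else None
            window = tuple(order[s : s + w])
            base = local_cost(window, left, right)
            best_perm = min(
                itertools.permutations(sorted(window)),
                key=lambda perm: (local_cost(perm, left, right), perm),
            )
            if local_cost(best_perm, left, right) < base - 1e-12:
                order[s : s + w] = list(best_perm)
                improved = True
    if group[order[0]] > group[order[-1]]:
        order = order[::-1]
    return [group[k] for k in order]


# ---------------------------------------------------------------------------
# Map assembly


@dataclass
class GeneticMap:
    """Ordered linkage groups with cumulative Kosambi positions.

    ``table`` columns: group, rank (0-based within group), marker,
    position_cM (starting at 0 per group, non-decreasing).
    """

    table: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def positions(self) -> pd.Series:
        return self.table.set_index("marker")["position_cM"]

    def group_of(self) -> pd.Series:
        return self.table.set_index("marker")["group"]

    def group_table(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    def group_summary(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            pos = self.group_table(g)["position_cM"].to_numpy()
            size = float(pos[-1])
            n = len(pos)
            gaps = np.diff(pos)
            rows.append(
                {
                    "group": g,
                    "n_loci": n,
                    "size_cM": size,
                    "mean_spacing_cM": size / (n - 1) if n > 1 else np.nan,
                    "largest_gap_cM": float(gaps.max()) if len(gaps) else 0.0,
                }
            )
        return pd.DataFrame(rows).set_index("group")

    def map_summary(self) -> dict:
        gs = self.group_summary()
        total_loci = int(gs["n_loci"].sum())
        total_size = float(gs["size_cM"].sum())
        n_groups = len(gs)
        return {
            "n_groups": n_groups,
            "total_loci": total_loci,
            "total_size_cM": total_size,
            "mean_interval_cM": total_size / (total_loci - n_groups),
            "largest_gap_cM": float(gs["largest_gap_cM"].max()),
        }


def build_map(
    orders: Sequence[Sequence[str]],
    est: TwoPointEstimates,
    group_names: Sequence[str] | None = None,
) -> GeneticMap:
    """Assemble a GeneticMap from ordered groups and two-point estimates.

    Positions are the cumulative Kosambi distances of adjacent-pair rf
    estimates within each ordered group.
    """
    if group_names is None:
        group_names = [f"LG{k + 1}" for k in range(len(orders))]
    rows = []
    for gname, order in zip(group_names, orders):
        order = list(order)
        rfM, _ = est.matrices(order)
        adj = rfM[np.arange(len(order) - 1), np.arange(1, len(order))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pos = np.concatenate([[0.0], np.cumsum(kosambi_cm(np.minimum(adj, RF_MAX)))])
        for rank, (m, p) in enumerate(zip(order, pos)):
            rows.append({"group": gname, "rank": rank, "marker": m, "position_cM": float(p)})
    return GeneticMap(pd.DataFrame(rows))


def summarize_groups(sizes_cM: Sequence[float], n_loci: Sequence[int], names: Sequence[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Summary arithmetic for a printed per-group map table.

    Given each group's span (cM) and locus count, returns the per-group mean
    inter-marker spacing size/(n-1) and the map totals (locus sum, size sum,
    and genome-wide mean interval total_size/(total_loci - n_groups)).
    """
    sizes = np.asarray(sizes_cM, dtype=float)
    counts = np.asarray(n_loci, dtype=int)
    if sizes.shape != counts.shape or sizes.ndim != 1:
        raise ValueError("sizes and counts must be 1-D and equally long")
    names = list(names) if names is not None else [f"LG{k + 1}" for k in range(len(sizes))]
    df = pd.DataFrame(
        {
            "group": names,
            "size_cM": sizes,
            "n_loci": counts,
            "mean_spacing_cM": sizes / (counts - 1),
        }
    ).set_index("group")
    totals = {
        "total_loci": int(counts.sum()),
        "total_size_cM": float(sizes.sum()),
        "mean_interval_cM": float(sizes.sum() / (counts.sum() - len(sizes))),
    }
    return df, totals
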