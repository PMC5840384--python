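"""Collinearity-block detection between a linkage group and a homologous
reference chromosome.

A collinear block is a run of at least two anchored loci whose map (cM) and
chromosome (bp) orders agree, in either orientation, uninterrupted on the
chromosome by mapped loci of another linkage group.  Order violations
between loci separated by less than 5% of the linkage group's cM length OR
5% of the chromosome's bp length are tolerated, absorbing local
rearrangements and small ordering errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnchorSet:
    """Orthologous loci shared by one (linkage group, species chromosome).

    ``anchors`` columns: marker, cm (map position), bp (chromosome position,
    midpoint of the best hit).
    """

    group: str
    species: str
    chrom: str
    anchors: pd.DataFrame
    lg_length_cM: float
    chrom_length_bp: float

    def __post_init__(self) -> None:
        self.anchors = self.anchors.sort_values("bp", kind="mergesort").reset_index(drop=True)


@dataclass
class CollinearBlock:
    """A maximal run of order-consistent anchors."""

    group: str
    species: str
    chrom: str
    markers: list[str]
    orientation: str  # "+" or "-"
    cm_lo: float
    cm_hi: float
    bp_lo: float
    bp_hi: float
    n_mismatch: int
    anchors: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _grow_run(
    cm: np.ndarray,
    bp: np.ndarray,
    start: int,
    sign: int,
    tol_cm: float,
    tol_bp: float,
    interruptions: np.ndarray,
) -> tuple[list[int], int]:
    """Greedy monotone extension from ``start`` in bp order.

    Violations are measured against the running cM extreme of the run, so a
    reversed segment stops the run within the tolerance span instead of
    being eaten one small step at a time.  The run is trimmed to end on an
    order-consistent anchor; returns (member indices, tolerated mismatches).
    """
    run = [start]
    viol = [False]
    extreme = cm[start]
    extreme_bp = bp[start]
    for k in range(start + 1, len(cm)):
        lo, hi = bp[run[-1]], bp[k]
        if interruptions.size and np.any((interruptions > lo) & (interruptions < hi)):
            break
        if sign * (cm[k] - extreme) >= 0:
            run.append(k)
            viol.append(False)
            extreme, extreme_bp = cm[k], bp[k]
        elif abs(cm[k] - extreme) < tol_cm or abs(bp[k] - extreme_bp) < tol_bp:
            run.append(k)
            viol.append(True)
        else:
            break
    while viol and viol[-1]:
        run.pop()
        viol.pop()
    # symmetric pass: rescanning from the far end with flipped orientation
    # trims tolerated violations at the leading edge too, so a run cannot
    # absorb the fringe of an oppositely-oriented segment
    run = _backward_trim(run, cm, bp, sign, tol_cm, tol_bp)
    return run, _count_mismatches(run, cm, sign)


def _backward_trim(
    run: list[int], cm: np.ndarray, bp: np.ndarray, sign: int, tol_cm: float, tol_bp: float
) -> list[int]:
    if len(run) < 2:
        return run
    rev = run[::-1]
    keep = [rev[0]]
    viol = [False]
    extreme, extreme_bp = cm[rev[0]], bp[rev[0]]
    for k in rev[1:]:
        if -sign * (cm[k] - extreme) >= 0:
            keep.append(k)
            viol.append(False)
            extreme, extreme_bp = cm[k], bp[k]
        elif abs(cm[k] - extreme) < tol_cm or abs(bp[k] - extreme_bp) < tol_bp:
            keep.append(k)
            viol.append(True)
        else:
            break
    while viol and viol[-1]:
        keep.pop()
        viol.pop()
    return keep[::-1]


def _count_mismatches(run: list[int], cm: np.ndarray, sign: int) -> int:
    mism = 0
    extreme = None
    for k in run:
        if extreme is None or sign * (cm[k] - extreme) >= 0:
            extreme = cm[k]
        else:
            mism += 1
    return mism


def detect_blocks(
    anchor_set: AnchorSet,
    tolerance: float = 0.05,
    interruptions: np.ndarray | None = None,
) -> list[CollinearBlock]:
    """Detect collinear blocks in one anchor set.

    ``interruptions`` are bp positions on the chromosome of mapped loci
    belonging to *other* linkage groups; a run never spans one.  Candidate
    runs are grown from every start in both orientations and kept
    longest-first (ties: smaller bp start), fragments left by overlap
    removal are re-kept when still >= 2 anchors.
    """
    a = anchor_set.anchors
    if len(a) < 2:
        raise ValueError("need at least two anchors")
    cm = a["cm"].to_numpy(dtype=float)
    bp = a["bp"].to_numpy(dtype=float)
    tol_cm = tolerance * anchor_set.lg_length_cM
    tol_bp = tolerance * anchor_set.chrom_length_bp
    inter = np.asarray(interruptions if interruptions is not None else [], dtype=float)

    candidates: list[tuple[list[int], int, int]] = []
    for start in range(len(a) - 1):
        for sign in (+1, -1):
            run, mism = _grow_run(cm, bp, start, sign, tol_cm, tol_bp, inter)
            if len(run) >= 2:
                candidates.append((run, mism, sign))
    candidates.sort(key=lambda c: (-len(c[0]), c[0][0]))

    used = np.zeros(len(a), dtype=bool)
    blocks: list[CollinearBlock] = []
    queue = list(candidates)
    while queue:
        run, mism, sign = queue.pop(0)
        free = [k for k in run if not used[k]]
        if len(free) < 2:
            continue
        if len(free) < len(run):
            # split into contiguous unused fragments and re-queue them
            frags: list[list[int]] = [[free[0]]]
            for k in free[1:]:
                if k == frags[-1][-1] + 1:
                    frags[-1].append(k)
                else:
                    frags.append([k])
            refrag = [(f, 0, sign) for f in frags if len(f) >= 2]
            queue = sorted(queue + refrag, key=lambda c: (-len(c[0]), c[0][0]))
            continue
        used[run] = True
        sub = a.iloc[run]
        tau = stats.kendalltau(sub["bp"], sub["cm"]).statistic
        orient = "+" if (tau if not np.isnan(tau) else sign) >= 0 else "-"
        blocks.append(
            CollinearBlock(
                group=anchor_set.group,
                species=anchor_set.species,
                chrom=anchor_set.chrom,
                markers=sub["marker"].to_list(),
                orientation=orient,
                cm_lo=float(sub["cm"].min()),
                cm_hi=float(sub["cm"].max()),
                bp_lo=float(sub["bp"].min()),
                bp_hi=float(sub["bp"].max()),
                n_mismatch=mism,
                anchors=sub.reset_index(drop=True),
            )
        )
    blocks.sort(key=lambda b: b.bp_lo)
    return blocks


def build_anchor_sets(
    map_table: pd.DataFrame,
    assignments: dict[str, pd.DataFrame],
    chrom_lengths: dict[str, dict[str, float]] | None = None,
) -> list[AnchorSet]:
    """Assemble AnchorSets for every (group, species, chromosome) pair.

    ``map_table`` is the genetic-map table (group, marker, position_cM);
    ``assignments`` maps species -> (marker, chrom, bp) best-hit frame.
    Chromosome lengths default to the largest anchored bp per chromosome.
    """
    pos = map_table.set_index("marker")["position_cM"]
    group_of = map_table.set_index("marker")["group"]
    lg_len = map_table.groupby("group")["position_cM"].max()
    out = []
    for species, asg in assignments.items():
        asg = asg[asg["marker"].isin(pos.index)]
        merged = pd.DataFrame(
            {
                "marker": asg["marker"].to_numpy(),
                "group": group_of.loc[asg["marker"]].to_numpy(),
                "cm": pos.loc[asg["marker"]].to_numpy(),
                "chrom": asg["chrom"].to_numpy(),
                "bp": asg["bp"].to_numpy(),
            }
        )
        for (g, c), sub in merged.groupby(["group", "chrom"], sort=True):
            if len(sub) < 2:
                continue
            if chrom_lengths and species in chrom_lengths and c in chrom_lengths[species]:
                clen = float(chrom_lengths[species][c])
            else:
                clen = float(merged[merged["chrom"] == c]["bp"].max())
            out.append(
                AnchorSet(
                    group=g,
                    species=species,
                    chrom=c,
                    anchors=sub[["marker", "cm", "bp"]].reset_index(drop=True),
                    lg_length_cM=float(lg_len[g]),
                    chrom_length_bp=clen,
                )
            )
    return out


def detect_all_blocks(
    anchor_sets: list[AnchorSet],
    tolerance: float = 0.05,
) -> list[CollinearBlock]:
    """Run block detection over every anchor set, interrupting runs at
    anchors of other linkage groups on the same chromosome."""
    by_chrom: dict[tuple[str, str], list[AnchorSet]] = {}
    for aset in anchor_sets:
        by_chrom.setdefault((aset.species, aset.chrom), []).append(aset)
    blocks = []
    for (species, chrom), sets in sorted(by_chrom.items()):
        for aset in sets:
            other = np.sort(
                np.concatenate(
                    [s.anchors["bp"].to_numpy(dtype=float) for s in sets if s.group != aset.group]
                    or [np.empty(0)]
                )
            )
            blocks.extend(detect_blocks(aset, tolerance=tolerance, interruptions=other))
    return blocks


def blocks_frame(blocks: list[CollinearBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": b.group,
                "species": b.species,
                "chrom": b.chrom,
                "orientation": b.orientation,
                "n_markers": b.n_markers,
                "n_mismatch": b.n_mismatch,
                "cm_lo": b.cm_lo,
                "cm_hi": b.cm_hi,
                "bp_lo": b.bp_lo,
                "bp_hi": b.bp_hi,
                "markers": ";".join(b.markers),
            }
            for b in blocks
        ],
        columns=[
            "group", "species", "chrom", "orientation", "n_markers",
            "n_mismatch", "cm_lo", "cm_hi", "bp_lo", "bp_hi", "markers",
        ],
    )


def oxford_grid_data(map_table: pd.DataFrame, anchor_sets: list[AnchorSet]) -> pd.DataFrame:
    """One row per anchored marker per species for dot-plot rendering.

    Columns: marker, group, cm, species, chrom, bp — x proportional to
    physical position, y to Kosambi cM.
    """
    rows = []
    for aset in anchor_sets:
        for _, r in aset.anchors.iterrows():
            rows.append(
                {
                    "marker": r["marker"],
                    "group": aset.group,
                    "cm": r["cm"],
                    "species": aset.species,
                    "chrom": aset.chrom,
                    "bp": r["bp"],
                }
            )
    return pd.DataFrame(rows, columns=["marker", "group", "cm", "species", "chrom", "bp"])
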