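"""Map-interval inference for unplaced transcripts.

Two strategies, applied in order of directness:

* ``direct_assign`` — a transcript whose sequence matches a mapped marker
  inherits that marker's exact (linkage group, cM) position.
* ``collinearity_place`` — a transcript with a single genome hit in a
  reference species is located inside a collinear block; the nearest left
  and right flanking anchors (by chromosome bp) bound its map interval.
  Evidence from all species is combined: species voting for the modal
  linkage group contribute their intervals, which are intersected when they
  pairwise overlap, otherwise the smallest single interval wins; the
  consensus is never wider than any contributing species interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collinear import CollinearBlock
from .linkmap import GeneticMap
from .synteny import EVALUE_GENOME, hit_midpoint


@dataclass
class SpeciesEvidence:
    """One reference species' placement evidence for a transcript."""

    species: str
    chrom: str
    bp: float
    group: str | None = None
    left_marker: str | None = None
    left_cm: float | None = None
    right_marker: str | None = None
    right_cm: float | None = None
    status: str = "outside"  # ok | edge | outside

    @property
    def interval(self) -> tuple[float, float] | None:
        if self.left_cm is None or self.right_cm is None:
            return None
        return (min(self.left_cm, self.right_cm), max(self.left_cm, self.right_cm))


@dataclass
class PlacementResult:
    """Inferred linkage-group interval for one transcript."""

    transcript: str
    status: str  # placed | edge | ambiguous | conflict | unplaced
    group: str | None = None
    cm_lo: float | None = None
    cm_hi: float | None = None
    n_species: int = 0
    note: str = ""
    evidence: list[SpeciesEvidence] = field(default_factory=list)


def direct_assign(marker_hits: pd.DataFrame, genetic_map: GeneticMap) -> list[PlacementResult]:
    """Point placements for transcripts hitting mapped markers directly.

    ``marker_hits`` is a one-best-hit table with query = transcript and
    subject = marker id.  Hits to markers absent from the map give an
    unplaced result with a reason.
    """
    pos = genetic_map.positions()
    grp = genetic_map.group_of()
    out = []
    for _, row in marker_hits.iterrows():
        tx, marker = row["query"], row["subject"]
        if marker in pos.index:
            p = float(pos[marker])
            out.append(
                PlacementResult(tx, "placed", group=str(grp[marker]), cm_lo=p, cm_hi=p, n_species=0, note=f"direct:{marker}")
            )
        else:
            out.append(PlacementResult(tx, "unplaced", note=f"hit to unmapped marker {marker}"))
    return out


def _species_evidence(
    species: str,
    chrom: str,
    mid: float,
    blocks: list[CollinearBlock],
) -> SpeciesEvidence:
    ev = SpeciesEvidence(species=species, chrom=chrom, bp=mid)
    chrom_blocks = [b for b in blocks if b.species == species and b.chrom == chrom]
    for b in chrom_blocks:
        if b.bp_lo <= mid <= b.bp_hi:
            bps = b.anchors["bp"].to_numpy(dtype=float)
            left = int(np.searchsorted(bps, mid, side="right")) - 1
            right = int(np.searchsorted(bps, mid, side="left"))
            left = max(left, 0)
            right = min(right, len(bps) - 1)
            ev.group = b.group
            ev.left_marker = b.anchors["marker"].iloc[left]
            ev.left_cm = float(b.anchors["cm"].iloc[left])
            ev.right_marker = b.anchors["marker"].iloc[right]
            ev.right_cm = float(b.anchors["cm"].iloc[right])
            ev.status = "ok"
            return ev
    # edge: within one mean anchor spacing beyond a block terminus
    best = None
    for b in chrom_blocks:
        spacing = (b.bp_hi - b.bp_lo) / max(b.n_markers - 1, 1)
        if b.bp_lo - spacing <= mid < b.bp_lo:
            d, side = b.bp_lo - mid, "lo"
        elif b.bp_hi < mid <= b.bp_hi + spacing:
            d, side = mid - b.bp_hi, "hi"
        else:
            continue
        if best is None or d < best[0]:
            best = (d, side, b)
    if best is not None:
        _, side, b = best
        k = 0 if side == "lo" else -1
        ev.group = b.group
        ev.left_marker = ev.right_marker = b.anchors["marker"].iloc[k]
        ev.left_cm = ev.right_cm = float(b.anchors["cm"].iloc[k])
        ev.status = "edge"
    return ev


def collinearity_place(
    transcript_hits: dict[str, pd.DataFrame],
    blocks: list[CollinearBlock],
    e_max: float = EVALUE_GENOME,
) -> list[PlacementResult]:
    """Infer map intervals for transcripts from per-species genome hits.

    ``transcript_hits`` maps species -> 12-column hit table.  Per species a
    transcript is retained only when it has a single hit at ``e_max``; the
    hit midpoint is located inside a collinear block and flanked.  See the
    module docstring for the consensus rule.
    """
    per_tx: dict[str, list[SpeciesEvidence]] = {}
    for species in sorted(transcript_hits):
        hits = transcript_hits[species]
        hits = hits[hits["evalue"] <= e_max]
        counts = hits.groupby("query")["subject"].size()
        singles = set(counts.index[counts == 1])
        for _, row in hits[hits["query"].isin(singles)].iterrows():
            ev = _species_evidence(species, row["subject"], hit_midpoint(row), blocks)
            per_tx.setdefault(row["query"], []).append(ev)

    results = []
    for tx in sorted(per_tx):
        evidence = per_tx[tx]
        usable = [e for e in evidence if e.status in ("ok", "edge")]
        if not usable:
            status = "ambiguous" if evidence else "unplaced"
            results.append(PlacementResult(tx, status, evidence=evidence, note="no block containment"))
            continue
        votes = pd.Series([e.group for e in usable]).value_counts()
        top = votes[votes == votes.iloc[0]]
        if len(top) > 1:
            results.append(
                PlacementResult(tx, "conflict", n_species=len(usable), evidence=evidence,
                                note="tied linkage-group votes: " + ",".join(sorted(top.index)))
            )
            continue
        g = votes.index[0]
        in_group = [e for e in usable if e.group == g]
        # two-flank evidence bounds the interval; one-flank (edge) evidence
        # is a degenerate point and only used when nothing better exists
        contrib = [e for e in in_group if e.status == "ok"] or in_group
        ivals = [e.interval for e in contrib]
        lo = max(i[0] for i in ivals)
        hi = min(i[1] for i in ivals)
        note = ""
        if lo > hi:  # disjoint: smallest-interval rule
            widths = sorted((i[1] - i[0], i) for i in ivals)
            lo, hi = widths[0][1]
            note = "partial"
        status = "placed" if any(e.status == "ok" for e in contrib) else "edge"
        results.append(
            PlacementResult(tx, status, group=g, cm_lo=float(lo), cm_hi=float(hi),
                            n_species=len(contrib), note=note, evidence=evidence)
        )
    return results


def placements_frame(results: list[PlacementResult]) -> pd.DataFrame:
    """Flatten placement results for TSV output."""
    rows = []
    for r in results:
        rows.append(
            {
                "transcript": r.transcript,
                "status": r.status,
                "group": r.group or "",
                "cm_lo": r.cm_lo if r.cm_lo is not None else np.nan,
                "cm_hi": r.cm_hi if r.cm_hi is not None else np.nan,
                "n_species": r.n_species,
                "note": r.note,
                "evidence": ";".join(
                    f"{e.species}:{e.chrom}:{int(e.bp)}:{e.status}" for e in r.evidence
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript", "status", "group", "cm_lo", "cm_hi", "n_species", "note", "evidence"]
    )


def phenogram_frame(results: list[PlacementResult]) -> pd.DataFrame:
    """PhenoGram-style rows: chromosome = linkage group, position = interval
    midpoint in cM, annotation = transcript id."""
    rows = [
        {"chromosome": r.group, "position": (r.cm_lo + r.cm_hi) / 2.0, "annotation": r.transcript}
        for r in results
        if r.status in ("placed", "edge") and r.group is not None
    ]
    return pd.DataFrame(rows, columns=["chromosome", "position", "annotation"])
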