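"""Homology-hit filtering and chromosome-level synteny tabulation.

Hit tables follow the 12-column tabular convention (query, subject, percent
identity, alignment length, mismatches, gap opens, query start/end, subject
start/end, e-value, bit score); subject coordinates are 1-based inclusive
with start > end on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: default e-value cutoffs: vs reference genomes, vs the transcriptome
EVALUE_GENOME = 1e-9
EVALUE_TRANSCRIPTOME = 1e-20


def subject_interval(row) -> tuple[int, int, str]:
    """Normalise subject coordinates to 0-based half-open plus strand."""
    s, e = int(row["sstart"]), int(row["send"])
    if s <= e:
        return s - 1, e, "+"
    return e - 1, s, "-"


def hit_midpoint(row) -> float:
    """Midpoint of the subject interval in 1-based coordinates."""
    return (float(row["sstart"]) + float(row["send"])) / 2.0


def filter_hits(hits: pd.DataFrame, e_max: float = EVALUE_GENOME, max_hits: int = 10) -> pd.DataFrame:
    """Reduce a hit table to one best hit per query.

    Drops rows with e-value above ``e_max``; queries with more than
    ``max_hits`` surviving rows are excluded entirely (repetitive); for the
    rest the highest bit score wins (ties: lowest e-value, then
    lexicographic subject id).  Idempotent.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table lacks columns: {missing}")
    kept = hits[hits["evalue"] <= e_max]
    if kept.empty:
        return kept.copy()
    n_hits = kept.groupby("query")["subject"].transform("size")
    kept = kept[n_hits <= max_hits]
    if kept.empty:
        return kept.copy()
    kept = kept.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return kept.groupby("query", as_index=False).head(1).reset_index(drop=True)


def assignments_from_hits(best_hits: pd.DataFrame, provenance: str = "direct") -> pd.DataFrame:
    """Turn one-best-hit rows into marker -> (chromosome, bp) assignments.

    Position is the midpoint of the best hit's subject interval.
    """
    if best_hits.empty:
        return pd.DataFrame(columns=["marker", "chrom", "bp", "provenance"])
    return pd.DataFrame(
        {
            "marker": best_hits["query"].to_numpy(),
            "chrom": best_hits["subject"].to_numpy(),
            "bp": [hit_midpoint(r) for _, r in best_hits.iterrows()],
            "provenance": provenance,
        }
    )


def anchor_via_transcriptome(
    marker_tx_hits: pd.DataFrame,
    tx_genome_hits: pd.DataFrame,
) -> pd.DataFrame:
    """Rescue unmatched markers through their best transcriptome contig.

    Both inputs must already be one-best-hit tables (``filter_hits``): the
    marker inherits the genome position of its single best contig; rows are
    flagged ``provenance="transcriptome-anchored"``.  Markers whose contig
    has no genome hit stay unmatched (no row).
    """
    if marker_tx_hits.empty or tx_genome_hits.empty:
        return pd.DataFrame(columns=["marker", "chrom", "bp", "provenance"])
    contig_pos = assignments_from_hits(tx_genome_hits).rename(columns={"marker": "contig"})
    link = marker_tx_hits[["query", "subject"]].rename(columns={"query": "marker", "subject": "contig"})
    merged = link.merge(contig_pos, on="contig", how="inner")
    out = merged[["marker", "chrom", "bp"]].copy()
    out["provenance"] = "transcriptome-anchored"
    return out.reset_index(drop=True)


@dataclass
class SyntenyTable:
    """Chromosome-level synteny of map linkage groups against one or more
    reference species.

    ``counts``: long table (group, species, chrom, n_loci).
    ``assigned``: per (group, species) the homologous chromosome(s) and the
    total number of uniquely hit loci.
    """

    counts: pd.DataFrame
    assigned: pd.DataFrame

    def per_group_totals(self) -> pd.DataFrame:
        """Homolog counts per linkage group and species (bar-plot style)."""
        return (
            self.counts.groupby(["group", "species"])["n_loci"].sum().reset_index()
        )


def build_synteny_table(
    group_of: pd.Series,
    assignments: dict[str, pd.DataFrame],
    majority_min: float = 0.5,
    count_min: int = 5,
) -> SyntenyTable:
    """Tabulate homologous chromosomes per linkage group and species.

    ``group_of`` maps mapped marker -> linkage group; ``assignments`` maps
    species -> assignment frame (marker, chrom, bp, provenance).  A group's
    homolog is every chromosome holding a fraction > ``majority_min`` of its
    hits; failing that, the top two chromosomes jointly holding more than
    ``majority_min`` with each at least ``count_min`` loci (fused/split
    pattern) are both reported.
    """
    count_rows = []
    assigned_rows = []
    groups = list(dict.fromkeys(group_of))
    for species, asg in assignments.items():
        asg = asg[asg["marker"].isin(group_of.index)]
        lg = group_of.loc[asg["marker"]].to_numpy()
        tab = pd.DataFrame({"group": lg, "chrom": asg["chrom"].to_numpy()})
        for g in groups:
            sub = tab[tab["group"] == g]
            total = len(sub)
            if total == 0:
                assigned_rows.append({"group": g, "species": species, "chroms": "", "n_loci": 0})
                continue
            counts = sub["chrom"].value_counts().sort_values(ascending=False)
            for c, k in counts.items():
                count_rows.append({"group": g, "species": species, "chrom": c, "n_loci": int(k)})
            top = counts.index[0]
            if counts.iloc[0] / total > majority_min:
                chroms = [top]
            elif (
                len(counts) >= 2
                and counts.iloc[1] >= count_min
                and counts.iloc[0] >= count_min
                and (counts.iloc[0] + counts.iloc[1]) / total > majority_min
            ):
                chroms = sorted(counts.index[:2])
            else:
                chroms = []
            assigned_rows.append(
                {"group": g, "species": species, "chroms": ",".join(map(str, chroms)), "n_loci": total}
            )
    return SyntenyTable(
        counts=pd.DataFrame(count_rows, columns=["group", "species", "chrom", "n_loci"]),
        assigned=pd.DataFrame(assigned_rows, columns=["group", "species", "chroms", "n_loci"]),
    )


def homology_percentages(per_species_counts: dict[str, int], total_mapped: int) -> dict[str, float]:
    """Percent of mapped loci with homology per species, to 2 decimals."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return {sp: round(100.0 * n / total_mapped, 2) for sp, n in per_species_counts.items()}
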