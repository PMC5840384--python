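"""File formats and run configuration.

All formats are plain text with deterministic row order and number
formatting (cM with 6 decimals, bp as integers) so identical runs produce
byte-identical files.  Every writer has a matching reader.

Formats
-------
* genotype TSV — header ``marker_id  P1  P2  <offspring...>``; cells are
  unordered allele pairs ``x/y`` over {a,b,c,d}, missing ``-``.
* hit tables — headerless 12-column tabular (the BLAST ``outfmt 6``
  dialect); subject coordinates 1-based inclusive, start > end on the
  minus strand.
* map TSV — ``group  rank  marker  position_cM``.
* Circos karyotype/links — linkage groups in integer units of cM x 1e4,
  chromosomes in bp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .collinear import CollinearBlock
from .linkmap import GeneticMap, MapConfig
from .markerqc import MISSING, GenotypeMatrix
from .synteny import HIT_COLUMNS

CM_SCALE = 10_000  # Circos integer units per cM


# ---------------------------------------------------------------------------
# Genotype TSV


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = gm.calls.copy()
    df.insert(0, "P2", gm.p2)
    df.insert(0, "P1", gm.p1)
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t")


def read_genotypes(path, validate: bool = True) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for col in ("P1", "P2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.isna().any().any():
        r = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: row {r!r}: non-rectangular table (empty cell)")
    df.index.name = None
    gm = GenotypeMatrix(calls=df.drop(columns=["P1", "P2"]), p1=df["P1"], p2=df["P2"])
    if validate:
        gm.validate()
    return gm


# ---------------------------------------------------------------------------
# Hit tables (12-column tabular)


def write_hits(hits: pd.DataFrame, path) -> None:
    out = hits[HIT_COLUMNS].copy()
    out["evalue"] = out["evalue"].map(lambda e: f"{e:.2e}")
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.2f")


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    if df.empty:
        return df
    bad = df["evalue"] < 0
    if bad.any():
        raise ValueError(f"{path}: row {int(np.flatnonzero(bad)[0]) + 1}: negative e-value")
    return df


# ---------------------------------------------------------------------------
# Map, QC and summary tables


def write_map(gmap: GeneticMap, path) -> None:
    out = gmap.table.copy()
    out["position_cM"] = out["position_cM"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "marker": str})
    df["position_cM"] = df["position_cM"].astype(float)
    return GeneticMap(df)


def write_map_summary(gmap: GeneticMap, path) -> None:
    gs = gmap.group_summary().copy()
    for c in ("size_cM", "mean_spacing_cM", "largest_gap_cM"):
        gs[c] = gs[c].map(lambda v: f"{v:.6f}")
    gs.to_csv(path)


def write_qc_report(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out["presence"] = out["presence"].map(lambda v: f"{v:.6f}")
    for c in ("chi2", "p"):
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out["df"] = out["df"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def read_qc_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df["reason"] = df["reason"].fillna("")
    return df


# ---------------------------------------------------------------------------
# Collinearity outputs


def write_blocks(blocks_df: pd.DataFrame, path) -> None:
    out = blocks_df.copy()
    for c in ("cm_lo", "cm_hi"):
        out[c] = out[c].map(lambda v: f"{v:.6f}")
    for c in ("bp_lo", "bp_hi"):
        out[c] = out[c].map(lambda v: str(int(round(v))))
    out.to_csv(path, index=False)


def read_blocks(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_circos(
    blocks: list[CollinearBlock],
    lg_lengths_cM: dict[str, float],
    chrom_lengths_bp: dict[str, float],
    karyotype_path,
    links_path,
) -> None:
    """Emit Circos karyotype and link files for map-vs-genome synteny.

    Linkage groups are scaled to integer units of cM x 1e4; reference
    chromosomes stay in bp.  One link line per block:
    ``lg lg_start lg_end chrom chrom_start chrom_end``.
    """
    if any(v < 0 for v in lg_lengths_cM.values()) or any(v < 0 for v in chrom_lengths_bp.values()):
        raise ValueError("negative coordinates in karyotype")
    with open(karyotype_path, "w") as fh:
        for k, (lg, ln) in enumerate(sorted(lg_lengths_cM.items())):
            fh.write(f"chr - {lg} {lg} 0 {int(round(ln * CM_SCALE))} chr{k % 24 + 1}\n")
        for k, (c, ln) in enumerate(sorted(chrom_lengths_bp.items())):
            fh.write(f"chr - {c} {c} 0 {int(round(ln))} grey\n")
    with open(links_path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.group, b.species, b.chrom, b.bp_lo)):
            fh.write(
                f"{b.group} {int(round(b.cm_lo * CM_SCALE))} {int(round(b.cm_hi * CM_SCALE))} "
                f"{b.chrom} {int(round(b.bp_lo))} {int(round(b.bp_hi))}\n"
            )


def read_circos_links(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows.append(
                {
                    "group": parts[0],
                    "cm_lo": int(parts[1]) / CM_SCALE,
                    "cm_hi": int(parts[2]) / CM_SCALE,
                    "chrom": parts[3],
                    "bp_lo": int(parts[4]),
                    "bp_hi": int(parts[5]),
                }
            )
    return pd.DataFrame(rows, columns=["group", "cm_lo", "cm_hi", "chrom", "bp_lo", "bp_hi"])


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Generic deterministic table writer (cM floats to 6 decimals)."""
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Truth record


def write_truth(path, **sections) -> None:
    """Write a structured truth record (JSON).  DataFrame values are stored
    as ``records`` lists; dataclasses as dicts."""
    doc = {}
    for name, val in sections.items():
        if isinstance(val, pd.DataFrame):
            doc[name] = val.reset_index().to_dict(orient="records")
        elif dataclasses.is_dataclass(val):
            doc[name] = dataclasses.asdict(val)
        else:
            doc[name] = val
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All pipeline thresholds in one validated record."""

    seed: int = 1
    presence_threshold: float = 0.80
    alpha: float = 0.05
    twopoint_lod_min: float = 4.0
    twopoint_rf_max: float = 0.4
    grouping_lod: float = 14.0
    grouping_rf_max: float = 0.4
    ordering_seed_size: int = 6
    ordering_lod: float = 3.0
    ripple_window: int = 4
    evalue_genome: float = 1e-9
    evalue_transcriptome: float = 1e-20
    max_hits: int = 10
    collinear_tolerance: float = 0.05
    majority_min: float = 0.5
    count_min: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.presence_threshold <= 1 or not 0 < self.alpha <= 1:
            raise ValueError("presence_threshold and alpha must lie in (0, 1]")
        if self.evalue_genome <= 0 or self.evalue_transcriptome <= 0:
            raise ValueError("e-value cutoffs must be positive")
        if not 0 < self.collinear_tolerance < 1 or not 0 < self.majority_min < 1:
            raise ValueError("tolerance and majority_min must lie in (0, 1)")
        self.map_config()  # validates the mapping thresholds

    def map_config(self) -> MapConfig:
        return MapConfig(
            twopoint_lod_min=self.twopoint_lod_min,
            twopoint_rf_max=self.twopoint_rf_max,
            grouping_lod=self.grouping_lod,
            grouping_rf_max=self.grouping_rf_max,
            ordering_seed_size=self.ordering_seed_size,
            ordering_lod=self.ordering_lod,
            ripple_window=self.ripple_window,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
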