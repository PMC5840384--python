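"""Ground-truthed synthetic inputs for the mapping pipeline.

Emulates a RAD-seq mapping design: one female x one male outbred cross,
F1 full-sib offspring genotyped at bi-allelic markers heterozygous in both
parents (cross types ab x ab / ab x ac / ab x cd), plus reference genomes
related to the map by inversions, translocations and chromosome fusions,
and unplaced transcripts with genome hits.  Every generator returns its
truth record so downstream recovery can be scored exactly.

Defaults follow the emulated study design: 94 offspring, cross-type
proportions 1896:1114:136, 5% missing calls, 0.5% allele-call error.
Recombination between adjacent markers is simulated without interference,
with probability equal to the inverse Kosambi transform of the cM gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .linkmap import kosambi_inverse
from .markerqc import GenotypeMatrix

#: default bp spacing between adjacent markers (only relative order matters)
BP_SPACING = 100_000
RAD_LOCUS_LEN = 95
TRANSCRIPT_HIT_LEN = 500

#: cross-type proportions of the emulated family (ab x ab, ab x ac, ab x cd)
DEFAULT_CROSS_PROPORTIONS = (1896 / 3146, 1114 / 3146, 136 / 3146)

_PARENT_ALLELES = {
    0: (("a", "b"), ("a", "b")),  # ab x ab
    1: (("a", "b"), ("a", "c")),  # ab x ac
    2: (("a", "b"), ("c", "d")),  # ab x cd
}


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class TrueMap:
    """The simulated truth: per-chromosome marker order in cM and bp.

    ``table`` columns: chrom, marker, cm, bp — cM and bp strictly increasing
    and order-consistent within each chromosome; marker ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["marker"].duplicated().any():
            raise ValueError("marker ids must be unique genome-wide")
        for c, sub in t.groupby("chrom", sort=False):
            if not (np.all(np.diff(sub["cm"]) > 0) and np.all(np.diff(sub["bp"]) > 0)):
                raise ValueError(f"chromosome {c}: cM/bp must be strictly increasing")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)

    def marker_chrom(self) -> pd.Series:
        return self.table.set_index("marker")["chrom"]


@dataclass
class CrossSpec:
    """Design of the simulated family (sizes, noise and distortion rates)."""

    n_offspring: int = 94
    cross_type_proportions: tuple[float, float, float] = DEFAULT_CROSS_PROPORTIONS
    missing_rate: float = 0.05
    error_rate: float = 0.005
    distorted_fraction: float = 0.0
    distortion_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("need at least one offspring")
        if abs(sum(self.cross_type_proportions) - 1.0) > 1e-9:
            raise ValueError("cross type proportions must sum to 1")
        for r in (self.missing_rate, self.error_rate, self.distorted_fraction, self.distortion_strength):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


@dataclass
class FamilyTruth:
    """Everything needed to reconstruct the simulated meioses.

    ``markers``: per-marker chrom, cross type, parental phases, distortion
    flags.  ``crossovers``: one row per realised crossover (offspring,
    parent, chrom, interval index between adjacent markers).
    """

    markers: pd.DataFrame
    crossovers: pd.DataFrame


@dataclass
class Inversion:
    chrom: str
    start_bp: int
    end_bp: int


@dataclass
class Translocation:
    src_chrom: str
    src_start: int
    src_end: int
    dest_chrom: str
    insert_bp: int


@dataclass
class Fusion:
    chrom_a: str
    chrom_b: str


@dataclass
class HitNoise:
    """Fractions of markers with degraded homology evidence."""

    no_hit: float = 0.0
    repetitive: float = 0.0
    wrong_chrom: float = 0.0

    def __post_init__(self) -> None:
        if min(self.no_hit, self.repetitive, self.wrong_chrom) < 0 or self.no_hit + self.repetitive + self.wrong_chrom >= 1:
            raise ValueError("hit-noise fractions must be non-negative and sum below 1")


@dataclass
class RearrangementSpec:
    """Operations relating a reference species genome to the true map."""

    operations: list = field(default_factory=list)
    hit_noise: HitNoise = field(default_factory=HitNoise)
    bp_jitter: float = 0.0


#: a realistic default noise level for recovery experiments
DEFAULT_HIT_NOISE = HitNoise(no_hit=0.2, repetitive=0.05, wrong_chrom=0.02)


@dataclass
class SpeciesGenome:
    """Per-marker positions on a derived reference genome plus truth."""

    species: str
    table: pd.DataFrame  # marker, chrom, bp
    chrom_lengths: dict
    operations: list
    chrom_origin: dict  # species chrom id -> original chrom label

    def marker_position(self) -> pd.DataFrame:
        return self.table.set_index("marker")


# ---------------------------------------------------------------------------
# Operations


def simulate_true_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    mean_length_cM: float,
    seed: int = 0,
) -> TrueMap:
    """Draw a random true genome: uniform marker cM positions per chromosome,
    chromosome lengths uniform in [0.5, 1.5] x mean, bp on a jittered 100 kb
    grid (monotone in cM by construction)."""
    if n_chromosomes < 1 or markers_per_chromosome < 2 or mean_length_cM <= 0:
        raise ValueError("need >= 1 chromosome, >= 2 markers/chromosome, positive length")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_chromosomes):
        length = mean_length_cM * rng.uniform(0.5, 1.5)
        k = markers_per_chromosome
        cm = np.sort(rng.uniform(0.0, length, k)) + np.arange(k) * 1e-9
        bp = (np.arange(k) + 1) * BP_SPACING + rng.integers(-25_000, 25_001, k)
        chrom = f"chr{c + 1:02d}"
        for i in range(k):
            rows.append({"chrom": chrom, "marker": f"c{c + 1:02d}m{i + 1:04d}", "cm": float(cm[i]), "bp": int(bp[i])})
    return TrueMap(pd.DataFrame(rows))


def simulate_family(true_map: TrueMap, spec: CrossSpec) -> tuple[GenotypeMatrix, FamilyTruth]:
    """Simulate offspring genotypes by a no-interference crossover process.

    Each parent transmits, per chromosome, a haplotype that switches homolog
    between adjacent markers with probability equal to the inverse Kosambi
    of the cM gap.  Distorted markers then flip the selected-against allele
    with probability ``distortion_strength`` (transmission ratio
    (1-s):(1+s)); allele-call errors flip one transmitted allele to the
    transmitting parent's other allele; finally calls go missing at
    ``missing_rate``.
    """
    if true_map.n_markers == 0:
        raise ValueError("empty true map")
    rng = np.random.default_rng(spec.seed)
    t = true_map.table
    M, n = len(t), spec.n_offspring

    ctype = rng.choice(3, size=M, p=list(spec.cross_type_proportions))
    phases = rng.integers(0, 2, size=(M, 2))
    p1_alleles = np.array([_PARENT_ALLELES[c][0] for c in ctype])
    p2_alleles = np.array([_PARENT_ALLELES[c][1] for c in ctype])

    hap = np.empty((2, M, n), dtype=np.int8)  # parent x marker x offspring
    xo_rows = []
    offs = [f"off{k + 1:03d}" for k in range(n)]
    for chrom in true_map.chromosomes:
        sel = np.flatnonzero((t["chrom"] == chrom).to_numpy())
        cm = t["cm"].to_numpy()[sel]
        r_adj = kosambi_inverse(np.diff(cm))
        for par in (0, 1):
            h0 = rng.integers(0, 2, size=n)
            rec = rng.random((n, len(sel) - 1)) < r_adj
            h = (h0[:, None] + np.concatenate([np.zeros((n, 1), dtype=int), np.cumsum(rec, axis=1)], axis=1)) % 2
            hap[par, sel, :] = h.T
            oi, ii = np.nonzero(rec)
            for o, i in zip(oi, ii):
                xo_rows.append({"offspring": offs[o], "parent": par + 1, "chrom": chrom, "interval": int(i)})

    phase_col = phases.T[:, :, None]  # (2, M, 1)
    trans = hap ^ phase_col  # transmitted allele index per parent

    # transmission-ratio distortion
    distorted = rng.random(M) < spec.distorted_fraction
    d_parent = rng.integers(0, 2, size=M)
    d_allele = rng.integers(0, 2, size=M)
    for m in np.flatnonzero(distorted):
        par = d_parent[m]
        hit = (trans[par, m] == d_allele[m]) & (rng.random(n) < spec.distortion_strength)
        trans[par, m, hit] ^= 1

    truth_trans = trans.copy()

    # genotyping error: flip one parent's transmitted allele
    err = rng.random((M, n)) < spec.error_rate
    which = rng.integers(0, 2, size=(M, n))
    for par in (0, 1):
        flip = err & (which == par)
        trans[par][flip] ^= 1

    a1 = p1_alleles[np.arange(M)[:, None], trans[0]]
    a2 = p2_alleles[np.arange(M)[:, None], trans[1]]
    lo = np.where(a1 <= a2, a1, a2)
    hi = np.where(a1 <= a2, a2, a1)
    calls = np.char.add(np.char.add(lo, "/"), hi)
    missing = rng.random((M, n)) < spec.missing_rate
    calls = np.where(missing, "-", calls)

    gm = GenotypeMatrix(
        calls=pd.DataFrame(calls, index=t["marker"].to_list(), columns=offs),
        p1=pd.Series(["/".join(a) for a in p1_alleles], index=t["marker"].to_list()),
        p2=pd.Series(["/".join(a) for a in p2_alleles], index=t["marker"].to_list()),
    )
    marker_truth = pd.DataFrame(
        {
            "marker": t["marker"].to_list(),
            "chrom": t["chrom"].to_list(),
            "cm": t["cm"].to_list(),
            "cross_type": [("ABxAB", "ABxAC", "ABxCD")[c] for c in ctype],
            "phase1": phases[:, 0],
            "phase2": phases[:, 1],
            "distorted": distorted,
            "distorted_parent": np.where(distorted, d_parent + 1, 0),
            "distorted_allele": np.where(distorted, d_allele, -1),
        }
    ).set_index("marker")
    truth = FamilyTruth(markers=marker_truth, crossovers=pd.DataFrame(xo_rows, columns=["offspring", "parent", "chrom", "interval"]))
    # expose the noise-free transmissions for calibration tests
    truth.transmissions = truth_trans  # type: ignore[attr-defined]
    return gm, truth


def _apply_operations(table: pd.DataFrame, operations: Sequence) -> pd.DataFrame:
    t = table.copy()

    def chroms() -> set:
        return set(t["chrom"])

    for op in operations:
        if isinstance(op, Inversion):
            if op.chrom not in chroms():
                raise ValueError(f"inversion on unknown chromosome {op.chrom!r}")
            sel = (t["chrom"] == op.chrom) & (t["bp"] >= op.start_bp) & (t["bp"] <= op.end_bp)
            t.loc[sel, "bp"] = op.start_bp + op.end_bp - t.loc[sel, "bp"]
        elif isinstance(op, Translocation):
            if op.src_chrom not in chroms() or op.dest_chrom not in chroms():
                raise ValueError("translocation references unknown chromosome")
            span = op.src_end - op.src_start
            moved = (t["chrom"] == op.src_chrom) & (t["bp"] >= op.src_start) & (t["bp"] <= op.src_end)
            t.loc[(t["chrom"] == op.src_chrom) & (t["bp"] > op.src_end), "bp"] -= span
            t.loc[(t["chrom"] == op.dest_chrom) & (t["bp"] >= op.insert_bp), "bp"] += span
            t.loc[moved, "bp"] = op.insert_bp + (t.loc[moved, "bp"] - op.src_start)
            t.loc[moved, "chrom"] = op.dest_chrom
        elif isinstance(op, Fusion):
            if op.chrom_a == op.chrom_b:
                raise ValueError("cannot fuse a chromosome with itself")
            if op.chrom_a not in chroms() or op.chrom_b not in chroms():
                raise ValueError("fusion references unknown chromosome")
            offset = int(t.loc[t["chrom"] == op.chrom_a, "bp"].max()) + BP_SPACING
            sel = t["chrom"] == op.chrom_b
            t.loc[sel, "bp"] += offset
            t.loc[sel, "chrom"] = op.chrom_a
        else:
            raise TypeError(f"unknown rearrangement operation: {op!r}")
    return t


def _hit_row(query, subject, sstart, send, pident, evalue, bitscore, qlen):
    mism = int(round((100.0 - pident) * qlen / 100.0))
    return {
        "query": query,
        "subject": subject,
        "pident": round(pident, 2),
        "length": qlen,
        "mismatch": mism,
        "gapopen": 0,
        "qstart": 1,
        "qend": qlen,
        "sstart": int(sstart),
        "send": int(send),
        "evalue": evalue,
        "bitscore": round(bitscore, 1),
    }


def derive_reference_genome(
    true_map: TrueMap,
    rspec: RearrangementSpec,
    species_id: str,
    seed: int = 0,
) -> tuple[SpeciesGenome, pd.DataFrame]:
    """Derive a rearranged reference genome and a tabular hit file.

    Applies the rearrangement operations to the true marker bp coordinates,
    then emits one strong best hit per marker (strand random) except for the
    noise fractions: dropped markers get no row, repetitive markers get 12
    sub-cutoff-passing decoys (so the >10-hits rule removes them), and
    wrong-chromosome markers get their best hit elsewhere.  Ordinary markers
    may carry up to two clearly weaker decoy hits.
    """
    rng = np.random.default_rng(seed)
    t = _apply_operations(true_map.table[["chrom", "marker", "bp"]], rspec.operations)
    if rspec.bp_jitter > 0:
        t["bp"] = t["bp"] + rng.normal(0.0, rspec.bp_jitter, len(t)).round().astype(int)
        t["bp"] = t["bp"].clip(lower=1)
    # relabel chromosomes into species coordinates, preserving origin
    origin = {}
    final = {}
    for k, c in enumerate(sorted(set(t["chrom"]))):
        name = f"{species_id}.{k + 1}"
        final[c] = name
        origin[name] = c
    t["chrom"] = t["chrom"].map(final)
    lengths = {c: int(sub["bp"].max()) + 2 * BP_SPACING for c, sub in t.groupby("chrom")}
    chrom_list = sorted(lengths)

    hn = rspec.hit_noise
    u = rng.random(len(t))
    rows = []
    for k, (_, rec) in enumerate(t.iterrows()):
        marker, chrom, bp = rec["marker"], rec["chrom"], int(rec["bp"])
        if u[k] < hn.no_hit:
            continue
        if u[k] < hn.no_hit + hn.repetitive:
            for _ in range(12):
                c = chrom_list[rng.integers(len(chrom_list))]
                p = int(rng.integers(1, lengths[c] - RAD_LOCUS_LEN))
                rows.append(
                    _hit_row(marker, c, p, p + RAD_LOCUS_LEN - 1, rng.uniform(90, 99),
                             10.0 ** -rng.uniform(12, 30), rng.uniform(80, 140), RAD_LOCUS_LEN)
                )
            continue
        if u[k] < hn.no_hit + hn.repetitive + hn.wrong_chrom:
            others = [c for c in chrom_list if c != chrom] or chrom_list
            chrom = others[rng.integers(len(others))]
            bp = int(rng.integers(1, lengths[chrom] - RAD_LOCUS_LEN))
        s, e = (bp, bp + RAD_LOCUS_LEN - 1)
        if rng.random() < 0.5:
            s, e = e, s
        pid = rng.uniform(92, 100)
        rows.append(_hit_row(marker, chrom, s, e, pid, 10.0 ** -rng.uniform(25, 60), 170 - 1.8 * (100 - pid) + rng.uniform(0, 1), RAD_LOCUS_LEN))
        for _ in range(rng.integers(0, 3)):
            c = chrom_list[rng.integers(len(chrom_list))]
            p = int(rng.integers(1, lengths[c] - RAD_LOCUS_LEN))
            rows.append(_hit_row(marker, c, p, p + RAD_LOCUS_LEN - 1, rng.uniform(85, 92),
                                 10.0 ** -rng.uniform(10, 18), rng.uniform(60, 110), RAD_LOCUS_LEN))

    hits = pd.DataFrame(rows)
    genome = SpeciesGenome(species=species_id, table=t.reset_index(drop=True), chrom_lengths=lengths, operations=list(rspec.operations), chrom_origin=origin)
    return genome, hits


def simulate_unplaced_transcripts(
    true_map: TrueMap,
    genomes: dict[str, SpeciesGenome],
    n: int,
    single_hit_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Place ``n`` transcripts at random true positions and emit genome hits.

    Each transcript's species-genome position is interpolated between its
    two flanking markers' derived positions (when both landed on the same
    species chromosome; otherwise it snaps to the nearer flank).
    Transcripts beyond ``single_hit_fraction`` receive a second decoy hit so
    the single-hit retention rule removes them.  Returns the truth table
    (transcript, chrom, cm, bp) and per-species hit tables.
    """
    if n < 1:
        raise ValueError("need n >= 1 transcripts")
    rng = np.random.default_rng(seed)
    t = true_map.table
    chroms = true_map.chromosomes
    truth_rows = []
    hits: dict[str, list] = {sp: [] for sp in genomes}
    single = rng.random(n) < single_hit_fraction
    for k in range(n):
        tx = f"tx{k + 1:04d}"
        chrom = chroms[rng.integers(len(chroms))]
        sub = true_map.chrom_table(chrom)
        bp_t = float(rng.uniform(sub["bp"].iloc[0], sub["bp"].iloc[-1]))
        cm_t = float(np.interp(bp_t, sub["bp"], sub["cm"]))
        truth_rows.append({"transcript": tx, "chrom": chrom, "cm": cm_t, "bp": int(bp_t)})
        left = int(np.searchsorted(sub["bp"].to_numpy(), bp_t, side="right")) - 1
        left = min(max(left, 0), len(sub) - 2)
        m_l, m_r = sub["marker"].iloc[left], sub["marker"].iloc[left + 1]
        frac = (bp_t - sub["bp"].iloc[left]) / (sub["bp"].iloc[left + 1] - sub["bp"].iloc[left])
        for sp, genome in genomes.items():
            pos = genome.marker_position()
            if m_l not in pos.index or m_r not in pos.index:
                continue
            pl, pr = pos.loc[m_l], pos.loc[m_r]
            if pl["chrom"] == pr["chrom"]:
                schrom = pl["chrom"]
                sbp = int(round(pl["bp"] + frac * (pr["bp"] - pl["bp"])))
            else:
                near = pl if frac <= 0.5 else pr
                schrom, sbp = near["chrom"], int(near["bp"]) + int(rng.integers(-2000, 2001))
            sbp = max(sbp, 1)
            hits[sp].append(_hit_row(tx, schrom, sbp, sbp + TRANSCRIPT_HIT_LEN - 1, rng.uniform(95, 100), 10.0 ** -rng.uniform(40, 80), rng.uniform(700, 950), TRANSCRIPT_HIT_LEN))
            if not single[k]:
                c = sorted(genome.chrom_lengths)[rng.integers(len(genome.chrom_lengths))]
                p = int(rng.integers(1, genome.chrom_lengths[c] - TRANSCRIPT_HIT_LEN))
                hits[sp].append(_hit_row(tx, c, p, p + TRANSCRIPT_HIT_LEN - 1, rng.uniform(90, 98), 10.0 ** -rng.uniform(25, 40), rng.uniform(400, 650), TRANSCRIPT_HIT_LEN))
    cols = ["query", "subject", "pident", "length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    return (
        pd.DataFrame(truth_rows),
        {sp: pd.DataFrame(rows, columns=cols) for sp, rows in hits.items()},
    )
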