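"""Marker quality control for an outbred full-sib (CP) mapping family.

Markers are bi-allelic per parent and written as unordered allele pairs over
the four-symbol alphabet ``a,b,c,d`` ("a/b" == "b/a", missing = "-").  A
marker is informative only when both parents are heterozygous, which leaves
three cross types:

========  =================  ==========================  ====
type      parents            offspring classes            df
========  =================  ==========================  ====
ab x ab   a/b  x  a/b        aa : ab : bb  = 1:2:1         2
ab x ac   a/b  x  a/c        aa : ac : ab : bc = 1:1:1:1   3
ab x cd   a/b  x  c/d        ac : ad : bc : bd = 1:1:1:1   3
========  =================  ==========================  ====

Retention applies three rules, in order: presence in at least 80% of the
offspring, no significant segregation distortion (Pearson chi-square against
the Mendelian ratio, retain at p >= alpha), and an informative cross type.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = "-"
ALLELES = ("a", "b", "c", "d")

#: class code used for a missing (or un-encodable) genotype call
MISSING_CODE = 4


class CrossType(str, Enum):
    """Parental configuration of a marker in an outbred full-sib family."""

    AB_X_AB = "ABxAB"
    AB_X_AC = "ABxAC"
    AB_X_CD = "ABxCD"
    UNINFORMATIVE = "uninformative"

    @property
    def informative(self) -> bool:
        return self is not CrossType.UNINFORMATIVE


#: ordering priority for marker informativeness (higher = more informative)
CROSS_TYPE_PRIORITY = {
    CrossType.AB_X_CD: 2,
    CrossType.AB_X_AC: 1,
    CrossType.AB_X_AB: 0,
    CrossType.UNINFORMATIVE: -1,
}


def parse_genotype(call: str) -> tuple[str, str]:
    """Parse an unordered allele-pair string like ``"a/b"``.

    Raises ``ValueError`` on anything that is not two valid allele symbols
    separated by ``/``.
    """
    parts = str(call).split("/")
    if len(parts) != 2 or not all(p in ALLELES for p in parts):
        raise ValueError(f"malformed genotype string: {call!r}")
    x, y = sorted(parts)
    return x, y


def format_genotype(pair: Sequence[str]) -> str:
    x, y = sorted(pair)
    return f"{x}/{y}"


def classify_cross_type(parent1: str, parent2: str) -> CrossType:
    """Classify a marker's cross type from the two parental genotypes."""
    p1 = parse_genotype(parent1)
    p2 = parse_genotype(parent2)
    if p1[0] == p1[1] or p2[0] == p2[1]:
        return CrossType.UNINFORMATIVE
    shared = len(set(p1) & set(p2))
    return {2: CrossType.AB_X_AB, 1: CrossType.AB_X_AC, 0: CrossType.AB_X_CD}[shared]


@dataclass
class MarkerCoding:
    """Canonical offspring-genotype classes for one informative marker.

    Class ``c`` corresponds to transmission ``(i, j)`` of parental allele
    index ``i`` from parent 1 and ``j`` from parent 2.  For ab x ab markers
    the two heterozygote transmissions (0,1) and (1,0) are observationally
    identical and pooled into a single class (``pooled=True``), giving the
    1:2:1 expectation; otherwise the four classes are distinct (1:1:1:1).
    """

    classes: list[str]
    codes: np.ndarray  # uint8 per offspring; MISSING_CODE when missing
    pooled: bool

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def encode_marker(p1: str, p2: str, calls: Iterable[str]) -> MarkerCoding:
    """Encode offspring calls of an informative marker into class codes."""
    a1 = parse_genotype(p1)
    a2 = parse_genotype(p2)
    if a1[0] == a1[1] or a2[0] == a2[1]:
        raise ValueError("encode_marker requires both parents heterozygous")
    pooled = set(a1) == set(a2)
    lookup: dict[str, int] = {}
    classes: list[str] = []
    for i in (0, 1):
        for j in (0, 1):
            g = format_genotype((a1[i], a2[j]))
            if g in lookup:
                continue
            lookup[g] = len(classes)
            classes.append(g)
    calls = list(calls)
    codes = np.full(len(calls), MISSING_CODE, dtype=np.uint8)
    for k, call in enumerate(calls):
        if call == MISSING:
            continue
        g = format_genotype(parse_genotype(call))
        if g not in lookup:
            raise ValueError(f"offspring call {call!r} not producible from parents {p1}/{p2}")
        codes[k] = lookup[g]
    return MarkerCoding(classes=classes, codes=codes, pooled=pooled)


@dataclass
class GenotypeMatrix:
    """Genotype calls of a two-parent full-sib family.

    ``calls`` is a markers x offspring frame of allele-pair strings
    ("-" = missing); ``p1``/``p2`` hold the parental genotypes indexed by
    marker.  Parents are never missing.
    """

    calls: pd.DataFrame
    p1: pd.Series
    p2: pd.Series

    def __post_init__(self) -> None:
        self.p1 = self.p1.reindex(self.calls.index)
        self.p2 = self.p2.reindex(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def offspring(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_offspring(self) -> int:
        return self.calls.shape[1]

    def cross_types(self) -> pd.Series:
        return pd.Series(
            [classify_cross_type(self.p1[m], self.p2[m]) for m in self.calls.index],
            index=self.calls.index,
            name="cross_type",
        )

    def coding(self, marker: str) -> MarkerCoding:
        return encode_marker(self.p1[marker], self.p2[marker], list(self.calls.loc[marker]))

    def presence(self) -> pd.Series:
        """Fraction of offspring (parents excluded) with a non-missing call."""
        return (self.calls != MISSING).mean(axis=1).rename("presence")

    def subset(self, markers: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(markers)].copy(), self.p1.loc[list(markers)].copy(), self.p2.loc[list(markers)].copy())

    def validate(self) -> None:
        """Check structural invariants; raise ValueError naming the bad cell."""
        if self.p1.isna().any() or self.p2.isna().any():
            bad = self.p1.index[self.p1.isna() | self.p2.isna()][0]
            raise ValueError(f"marker {bad!r}: parental genotype missing")
        for m in self.calls.index:
            pa = set(parse_genotype(self.p1[m]))
            pb = set(parse_genotype(self.p2[m]))
            for ind, call in self.calls.loc[m].items():
                if call == MISSING:
                    continue
                x, y = parse_genotype(call)
                ok = ({x} <= pa and {y} <= pb) or ({y} <= pa and {x} <= pb)
                if not ok:
                    raise ValueError(
                        f"marker {m!r}, individual {ind!r}: call {call!r} not producible from parents {self.p1[m]}/{self.p2[m]}"
                    )


def expected_ratio(cross_type: CrossType) -> np.ndarray:
    """Mendelian genotype-class expectation for a cross type."""
    if cross_type is CrossType.AB_X_AB:
        return np.array([0.25, 0.5, 0.25])
    if cross_type in (CrossType.AB_X_AC, CrossType.AB_X_CD):
        return np.full(4, 0.25)
    raise ValueError("uninformative markers have no segregation expectation")


def segregation_chisq(counts: Sequence[int], cross_type: CrossType) -> tuple[float, int, float]:
    """Pearson chi-square of offspring genotype-class counts vs Mendelian ratio.

    Returns ``(statistic, df, p)``; df = #classes - 1 (2 for ab x ab, 3 for
    the four-class types).  Missing individuals are excluded from ``counts``.
    """
    obs = np.asarray(counts, dtype=float)
    ratio = expected_ratio(cross_type)
    if obs.shape != ratio.shape:
        raise ValueError(f"expected {len(ratio)} genotype classes for {cross_type.value}, got {len(obs)}")
    total = obs.sum()
    if total <= 0:
        raise ValueError("zero total count")
    stat, p = stats.chisquare(obs, f_exp=ratio * total)
    return float(stat), len(obs) - 1, float(p)


def genotype_class_counts(gm: GenotypeMatrix, marker: str) -> tuple[np.ndarray, list[str]]:
    """Observed counts over the marker's genotype classes (missing excluded)."""
    coding = gm.coding(marker)
    counts = np.bincount(coding.codes[coding.codes != MISSING_CODE], minlength=coding.n_classes)
    return counts, coding.classes


def filter_markers(
    gm: GenotypeMatrix,
    presence_threshold: float = 0.80,
    alpha: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the three retention rules and report every marker's fate.

    Rules are evaluated in order (a marker is charged to the first rule it
    fails): presence >= ``presence_threshold`` over offspring; segregation
    p >= ``alpha``; informative cross type.  Returns the retained matrix and
    a QC report with one row per input marker (columns: cross_type, presence,
    chi2, df, p, retained, reason).
    """
    if not 0 < presence_threshold <= 1 or not 0 < alpha <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    if gm.n_markers == 0:
        raise ValueError("no markers in genotype matrix")

    presence = gm.presence()
    rows = []
    for m in gm.markers:
        ct = classify_cross_type(gm.p1[m], gm.p2[m])
        chi2 = df = p = np.nan
        if ct.informative:
            counts, _ = genotype_class_counts(gm, m)
            if counts.sum() > 0:
                chi2, df, p = segregation_chisq(counts, ct)
        if presence[m] < presence_threshold:
            reason = "presence"
        elif ct.informative and not np.isnan(p) and p < alpha:
            reason = "distortion"
        elif not ct.informative:
            reason = "uninformative"
        else:
            reason = ""
        rows.append(
            {
                "marker": m,
                "cross_type": ct.value,
                "presence": presence[m],
                "chi2": chi2,
                "df": df,
                "p": p,
                "retained": reason == "",
                "reason": reason,
            }
        )
    report = pd.DataFrame(rows).set_index("marker")
    retained = report.index[report["retained"]]
    return gm.subset(list(retained)), report
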