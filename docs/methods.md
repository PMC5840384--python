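# Methods

`radmap` implements the computational chain behind a RAD-seq linkage-map
study of an outbred full-sib (CP) family: marker quality control, two-point
linkage mapping with the Kosambi map function, comparative synteny and
collinearity against reference genomes, and collinearity-based placement of
unplaced transcripts. This note records the models, the defaults and the
design decisions, in that order of importance.

## The cross and its marker types

One female and one male produce F1 full-sib offspring. Only markers
heterozygous in **both** parents are informative; with unordered allele
pairs over the alphabet {a, b, c, d} three configurations exist:

| cross type | parents      | offspring classes        | Mendelian ratio | df |
|-----------|---------------|--------------------------|-----------------|----|
| ab × ab   | a/b × a/b     | aa, ab, bb               | 1:2:1           | 2  |
| ab × ac   | a/b × a/c     | aa, ac, ab, bc           | 1:1:1:1         | 3  |
| ab × cd   | a/b × c/d     | ac, ad, bc, bd           | 1:1:1:1         | 3  |

Informativeness rises left to right: in an ab × cd marker every offspring
genotype identifies both transmitted alleles, while in ab × ab the
heterozygote pools two indistinguishable transmissions.

## Marker quality control

Three retention rules are applied in order, and each marker is charged to
the first rule it fails (so input = retained + dropped-by-presence +
dropped-by-distortion + dropped-uninformative):

1. **presence** — the marker is called in ≥ 80% of the offspring (parents
   excluded from the denominator);
2. **segregation** — Pearson chi-square of the offspring genotype-class
   counts against the Mendelian ratio; retained when p ≥ α (default
   α = 0.05). Missing calls are excluded from the counts;
3. **informativeness** — both parents heterozygous.

Both thresholds are configurable. Filtering is idempotent.

## Two-point estimation

For a marker pair, each parent's **phase** says which allele at the first
marker sits on the same homolog as which allele at the second (coupling or
repulsion; 4 joint configurations). Under phase `ph` a parental gamete
carrying allele indices `(i1, i2)` has probability `(1−r)/2` when
`i1 XOR i2 = ph` and `r/2` otherwise. The offspring joint-genotype
probability sums over both parents' four gametes; because each class pair
collects terms of the form `(1−r)²/4`, `r(1−r)/4`, `r²/4`, the likelihood
reduces to integer coefficient tables — the log-likelihood of a pair is a
dot product of its 25-bin joint class counts with a log-probability
vector. Offspring missing at either marker contribute nothing.

`estimate_rf` maximises the likelihood over `r ∈ [1e−6, 0.4999]` under
each phase (bounded scalar optimisation after a coarse grid; net tolerance
well below 1e−4) and keeps the best phase, breaking ties toward smaller
`r`. `estimate_all_pairs` vectorises the same computation for all pairs:
a 256-point grid over r × 4 phases evaluated as one matrix product per
block of pairs, followed by a 41-point local refinement around the grid
optimum (resolution ≈ 1e−4). `LOD = log10 L(r̂) − log10 L(0.5)`, clipped
at 0.

Phase is estimated per pair and never reconciled globally; grouping and
ordering consume only (rf, LOD). Sex-specific recombination is not
modelled (the map is a between-sex average by construction).

## Grouping, ordering, map assembly

**Grouping** is the transitive closure of the relation
{LOD ≥ grouping_lod AND rf ≤ grouping_rf_max} (defaults 14 and 0.4),
computed on a sparse graph. Singletons are reported as unassigned, not
mapped. `scan_grouping_lod` tabulates group counts across thresholds; the
natural selection rule — used in the recovery experiments — is the LOD
whose group count equals the karyotype's haploid chromosome number while
minimising unassigned markers. No automatic selection is imposed.

**Ordering** minimises the sum of adjacent recombination fractions (SARF),
a deterministic seriation criterion that is exact on noiseless data:

1. a seed of the `ordering_seed_size` (default 6) most informative markers
   (cross-type priority ab × cd > ab × ac > ab × ab, then most scorable
   meioses, then marker id) is ordered exhaustively;
2. remaining markers are inserted greedily at the SARF-minimising position
   (markers with no within-group pair at LOD ≥ `ordering_lod` go last);
3. a ripple pass permutes every sliding window of `ripple_window`
   (default 4) consecutive markers and accepts strict improvements, until
   stable.

A multipoint likelihood would use more information but is neither
deterministic nor cheaply testable; SARF was chosen as the package's
ordering criterion and its exactness on clean data is tested. Orientation
of a group is unidentifiable; the canonical output puts the smaller
terminal marker id first.

**Positions** are cumulative Kosambi distances of adjacent-pair rf:
`d = 25·ln((1+2r)/(1−2r))` cM, inverse `r = tanh(d/50)/2`. Values
r ≥ 0.4999 are capped with a warning. Per-group summaries report size
(last position), locus count, mean spacing = size/(n−1) and largest gap;
the map-wide mean interval is total_size/(total_loci − n_groups).

## Synteny

Homology evidence is consumed as 12-column tabular hit files (1-based
inclusive subject coordinates, start > end on the minus strand; internal
normalisation is 0-based half-open with a strand flag). `filter_hits`
drops rows above the e-value cutoff (defaults: 1e−9 vs genomes, 1e−20 vs
the transcriptome), excludes queries with more than 10 surviving hits as
repetitive, and keeps the highest bit score per query (ties: lower
e-value, then lexicographic subject id). A locus's chromosome position is
the midpoint of its best hit's subject interval. Markers without a direct
genome hit can inherit their best transcriptome contig's genome position
(`anchor_via_transcriptome`), flagged as transcriptome-anchored.

A linkage group's homologous chromosome is any chromosome holding more
than `majority_min` (default 0.5) of its hits; failing that, the top two
chromosomes are both reported when each holds ≥ `count_min` (default 5)
loci and jointly a majority — the fused/split pattern. "Most loci" is not
a precise published rule; the majority default reflects tables whose rows
are dominated by single chromosomes, and both knobs are configurable.

## Collinearity blocks

Anchors (markers with both a cM and a bp position) are sorted by bp. A
block is a maximal run monotone in cM (either orientation) satisfying:

- an order violation between the candidate anchor and the run's current
  cM extreme is tolerated iff the two are separated by less than 5% of the
  linkage group's cM length **or** 5% of the chromosome's bp length (the
  tolerance side is deliberately inclusive — either axis suffices);
- a run terminates when an anchor of a *different* linkage group
  intervenes on the chromosome (intervening unmapped genes do not break
  blocks, and same-group distant anchors do not either);
- runs are trimmed, from both ends, so they start and end on
  order-consistent anchors. Without the symmetric trim a monotone run
  greedily swallows the fringe of an adjacent inverted segment one
  "tolerated" small step at a time; with it, simulated inversion
  breakpoints are recovered to within one marker;
- overlapping candidate runs are resolved longest-first (ties: smaller bp
  start); fragments left by overlap removal are re-queued when still ≥ 2
  anchors. Blocks are disjoint in bp and each anchor belongs to at most
  one block.

Orientation is the sign of the Kendall correlation of (bp, cM) over the
members. Blocks of ≥ 2 anchors are reported with their cM and bp extents
and the number of absorbed mismatches.

## Transcript placement

A transcript with a direct hit to a mapped marker inherits that marker's
(group, cM) as a zero-width interval. Otherwise, per reference species, a
transcript is used only when it has a **single** genome hit below the
cutoff; the hit midpoint is located in the block whose bp extent contains
it and the nearest anchors left/right by bp become flanks, bounding a cM
interval. A midpoint within one mean anchor spacing beyond a block's end
yields one-flank "edge" evidence — a degenerate point at the block's cM
terminus. Consensus across species:

- species vote with their block's linkage group; a tie among the modal
  groups is a **conflict** (reported, not resolved);
- among species voting for the modal group, two-flank intervals are
  intersected when they pairwise overlap; otherwise the smallest single
  interval is used and flagged `partial`. One-flank (edge) evidence votes
  but only bounds the interval when no two-flank evidence exists —
  intersecting a degenerate point would collapse the consensus and, under
  realistic noise, evict the true position;
- the consensus is therefore never wider than any interval that entered
  the combination, and with a single species it equals that species'
  interval.

## The synthetic-data generator

The generator defines the study conditions for every recovery experiment:

- **family**: 94 offspring; cross types drawn in proportions
  1896 : 1114 : 136 (ab × ab : ab × ac : ab × cd); parental phases uniform.
- **meiosis**: no crossover interference — between adjacent markers a
  gamete switches homolog with probability equal to the inverse Kosambi
  of the cM gap, independently per interval. Using the Kosambi function
  downstream while simulating without interference is mildly inconsistent
  (Kosambi implies interference); the simplification is deliberate and the
  recovery tolerances absorb it.
- **noise defaults** (not published values; chosen once as realistic for
  a de-novo RAD dataset): 5% missing calls, 0.5% allele-call error. The
  error model flips one transmitted allele to the transmitting parent's
  other allele, chosen uniformly — this keeps every call producible from
  the parents, a structural invariant of the genotype matrix.
- **segregation distortion**: a distorted marker flips the
  selected-against allele after transmission with probability *s*
  (transmission ratio (1−s):(1+s)); marker-local, so family size and
  other markers are untouched. Defaults: fraction 0 (distortion is
  switched on per experiment), strength 0.5.
- **genomes**: markers sit on a 100 kb grid with jitter; reference species
  are derived by inversions, translocations and fusions applied to marker
  coordinates. Hit noise defaults for recovery-at-noise experiments: 20%
  of markers with no hit, 5% repetitive (12 decoy hits, caught by the
  >10-hit rule), 2% with a wrong-chromosome best hit, and 10 kb positional
  jitter.
- **transcripts**: placed at uniform true positions; their species-genome
  coordinates are interpolated between the flanking markers' derived
  positions (snapping to the nearer flank across rearrangement
  breakpoints). A configurable fraction receives a second decoy hit so the
  single-hit retention rule is exercised.

What the generator does **not** emulate: sequence content (ids and
coordinates only), read-level artefacts (depth, allele dropout at
restriction sites, paralog collapse), linkage disequilibrium structure
beyond a single meiosis, sex-specific recombination, and real cross-species
divergence in hit quality. Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated generative model, not
robustness to every failure mode of real RAD data.

## Numerical and procedural choices

- rf optimisation bounds [1e−6, 0.4999]; ties toward smaller rf; LOD
  clipped at 0. cM serialised with 6 decimals, bp as integers,
  deterministic row order, so identical runs are byte-identical.
- The chi-square test at n = 94 is essentially exactly calibrated; with 5%
  missing calls (counts ≈ 89) it becomes mildly conservative through
  discreteness. Calibration experiments therefore use complete calls.
- Problem sizes in the test-suite experiments are chosen to keep the whole
  suite fast while leaving each estimate well-determined: linkage recovery
  uses 6 chromosomes × 130 markers at 94 offspring (the per-chromosome
  design of the emulated study, with fewer chromosomes); ordering
  exactness uses one 20-marker chromosome at 500 noise-free offspring;
  calibration pools three families of 600 independent markers;
  collinearity and placement use 4 species over 4 × 60 markers with 200
  transcripts.

## Known limitations

- SARF ordering can swap markers separated by ~0 observed recombinants;
  with 94 offspring, markers ~1 cM apart are frequently tied. The map is
  locally fuzzy at that scale, exactly as two-point maps are.
- Grouping at a fixed LOD can split a chromosome with a large central gap;
  the scan utility exposes the trade-off but picks nothing automatically.
- Block detection is greedy, not optimal; pathological anchor patterns
  could split differently than an exact algorithm would.
- Placement treats hit midpoints as exact; sub-block-scale positional
  error in real alignments is not modelled beyond the generator's jitter.
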