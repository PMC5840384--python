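# radmap

Linkage mapping and comparative gene placement for outbred full-sib
(CP) RAD-seq families.

Non-model organisms usually lack a reference genome, but a single wild
mating pair and its clutch of F1 offspring are enough to build a dense
genetic map: RAD-seq genotypes the family at thousands of SNP markers, and
markers heterozygous in both parents (cross types ab×ab, ab×ac, ab×cd)
carry linkage information. `radmap` implements the full chain that turns
such genotypes into biology:

1. **markerqc** — cross-type classification and the two retention filters:
   presence in ≥ 80% of offspring and Mendelian segregation
   (chi-square, retain at p ≥ 0.05);
2. **linkmap** — maximum-likelihood two-point recombination fractions with
   parental phase, LOD grouping by transitive closure (default LOD 14,
   rf ≤ 0.4), SARF ordering with a ripple refinement, and Kosambi map
   distances d = 25·ln((1+2r)/(1−2r)) cM;
3. **synteny / collinear** — best-hit filtering of tabular homology hits
   (e ≤ 1e−9, > 10 hits = repetitive, top bit score kept), transcriptome
   anchoring for unmatched markers, chromosome-level synteny tables, and
   collinear-block detection with a 5% order-mismatch tolerance;
4. **placement** — map intervals for unplaced transcripts from the nearest
   left/right flanking markers inside a collinear block, combined across
   reference species into the smallest consistent interval;
5. **simdata** — a ground-truthed generator (meiosis without interference,
   recombination probability = inverse Kosambi of the marker gap;
   genotyping error, missing calls, segregation distortion; reference
   genomes derived by inversions/translocations/fusions) so every stage is
   testable without any sequencing data.

See `docs/methods.md` for the models and design decisions.

## Worked example

```python
from radmap import (CrossSpec, MapConfig, build_map, estimate_all_pairs,
                    filter_markers, group_markers, order_markers,
                    simulate_family, simulate_true_map)

tmap = simulate_true_map(n_chromosomes=3, markers_per_chromosome=60,
                         mean_length_cM=140, seed=11)
gm, truth = simulate_family(tmap, CrossSpec(n_offspring=94, seed=12))
retained, report = filter_markers(gm)
est = estimate_all_pairs(retained)
groups, unassigned = group_markers(est, MapConfig(grouping_lod=10))
orders = [order_markers(retained, g, est) for g in groups]
gmap = build_map(orders, est)
print(gmap.group_summary().round(3))
```

prints

```
       n_loci  size_cM  mean_spacing_cM  largest_gap_cM
group
LG1        60  138.096            2.341          13.303
LG2        59  104.167            1.796           9.189
LG3        57  209.177            3.735          24.823
```

one linkage group per simulated chromosome; `size_cM` is the cumulative
Kosambi span, `mean_spacing_cM` = size/(n−1), and the largest gap flags
the weakest-supported region of each group. The `examples/` directory has
one short script per capability (QC, mapping, synteny/collinearity,
transcript placement, map-table arithmetic).

A thin CLI chains the stages on files:

```sh
radmap simulate --out-dir sim --seed 3 --n-chromosomes 3 \
    --markers-per-chromosome 25 --n-species 2 --n-transcripts 30
radmap qc  --genotypes sim/genotypes.tsv --out-dir qc
radmap map --genotypes qc/genotypes_filtered.tsv --out-dir map --grouping-lod 8
radmap synteny --map map/map.tsv --hits sp1=sim/hits_sp1.tsv \
    --hits sp2=sim/hits_sp2.tsv --out-dir syn
```

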