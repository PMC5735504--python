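# tsplink

Genetic linkage map construction from high-density marker data, built on
traveling-salesperson-problem (TSP) solvers.

## The problem

Genotyping-by-sequencing routinely yields thousands of markers per mapping
population, with 1–5% erroneous calls and 5–10% missing data. Building a
linkage map from such data means solving two problems at scale: assigning
markers to linkage groups (chromosomes), and ordering the markers within each
group. Ordering is naturally a minimum-weight Hamiltonian path problem —
markers are vertices, pairwise recombination frequencies (rf) are edge
weights, and the best order minimises the summed rf along the path — which is
exactly a TSP once a zero-weight *dummy vertex* is added so the tour can close
without paying for the edge between the two chromosome ends.

`tsplink` implements the full pipeline for populations derived from inbred
parents (recombinant inbred lines by selfing, F2 intercross, backcross):

1. **Filter** duplicate, excessively heterozygous, and near-identical markers.
2. **Estimate rf** for every marker pair — direct mismatch fractions with a
   missing-data midpoint adjustment for homozygous designs and backcrosses, an
   EM fit of the two-locus F2 model for intercrosses; rf above a cutoff
   (default 0.4) is inflated to 0.5 as uninformative. A precomputed rf matrix
   (e.g. from R/qtl) can be supplied instead for other designs.
3. **Cluster**: build the minimum spanning tree of the rf graph, cut its
   largest edges (1.5·k cuts for a user-supplied chromosome count k, extended
   until at least k clusters reach the significance size s = m/2k), then run
   each cluster through a fast heuristic path solver and break it wherever
   adjacent markers jump above an rf threshold.
4. **Merge** the over-cut pieces smallest-first through three stages — direct
   rf evidence, joint-path analysis, reciprocal best-match — into final
   linkage groups.
5. **Order** each group with a provably optimal Held–Karp solver (small
   groups) or a seeded high-budget local search (2-opt + Or-opt with
   double-bridge restarts), and emit a map with Haldane or Kosambi cM
   positions.

A simulator for all three designs (Haldane Markov chain, configurable error
rate η and missing rate γ) and the standard quality statistics — erroneous
pairs *E* (orientation-minimised inversion count), group count *c*, rank
correlation with truth — make the whole pipeline testable end to end with no
external data.

## Worked example

```bash
tsplink simulate --n 300 --m 200 --k 2 --eta 0.01 --gamma 0.05 --seed 1 --out demo/pop
tsplink map --genotypes demo/pop.genotypes.csv --k 2 --seed 1 --out demo/run
tsplink evaluate --map demo/run.map.csv --truth demo/pop.truth.csv
```

This simulates a 300-line RIL population (200 markers on 2 chromosomes, 1%
genotyping error, 5% missing), builds the map, and scores it against the
simulated truth:

```
2 linkage groups, 200 markers -> demo/run.map.csv
{
  "E": 1,
  "c": 2,
  "per_group_E": [1, 0],
  "order_correlation": 0.9999939993999399,
  "group_purity": 1.0,
  "n_misassigned": 0
}
```

Both chromosomes are recovered as separate groups (`c = 2`, purity 1.0), and
the 200-marker order contains a single discordant pair (`E = 1`, one adjacent
swap of two markers whose true separation is below the resolution of 300
lines), giving a rank correlation of 0.99999. The map itself is a tidy CSV:

```
group_id,order_index,marker,rf_to_prev,position_cM
LG1,0,C02M0002,,0
LG1,1,C02M0001,0.08167,8.916875184
LG1,2,C02M0003,0.08667,18.43496484
...
```

The same pipeline is available as a library (`tsplink.construct_map`), and a
`tsplink benchmark` subcommand runs a factorial η × γ grid and reports mean
*E* and *c* per cell.

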