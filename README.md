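# pentad

Average-compartment ("pentad") analysis of Hi-C contact maps. Given a
binned Hi-C matrix in the cooler HDF5 format and an A/B compartment signal
(typically PC1, positive = A, negative = B) in bedGraph format at the same
bin size, the tool:

- converts observed contacts into observed-over-expected (O/E) maps
  (per-diagonal mean expectation in cis, scalar mean in trans);
- segments the signal into A/B intervals and enumerates the five area
  types of the O/E map: short-range A and B (on-diagonal squares),
  long-range A–A and B–B, and inter-compartment A–B rectangles;
- filters areas (minimum dimension in bins, maximum empty-pixel fraction,
  optional anchor-distance cutoff), rescales survivors to a fixed odd-sized
  square by bilinear interpolation with missing-value propagation, and
  median-averages them genome wide into the five-panel pile-up — in cis,
  in trans, or stratified by anchor distance;
- quantifies per-chromosome compartment strength as the mean within-panel
  O/E over the mean of the edge-cropped A–B panel, and compares two
  conditions with a paired two-sided Wilcoxon signed-rank test.

A seeded synthetic-data module generates cooler + bedGraph fixtures with
planted compartment structure (contrast `f`, distance decay, optional
Poisson noise and missing bins) for testing and calibration.

## CLI

```sh
# synthetic fixture: 2 chromosomes, planted contrast f=2, Poisson noise
pentad simulate --seed 7 --contrast 2 --noise poisson --out-prefix sim

# five-panel average compartment in cis (JSON + optional figure)
pentad cis sim.cool sim.bedgraph --out-prefix result --figure

# trans and distance-stratified variants
pentad trans sim.cool sim.bedgraph --out-prefix result_trans
pentad distance sim.cool sim.bedgraph --distance-bins 10000000,25000000,50000000

# per-chromosome strength table and condition comparison
pentad strength sim.cool sim.bedgraph --crop 0.25 --out-prefix cond1
pentad compare cond1_strength.tsv cond2_strength.tsv --out-prefix cmp

# re-render a stored pile-up
pentad plot result.json --format svg
```

Useful flags: `--resolution` (required for `.mcool` containers),
`--rescale-size` (default 33), `--min-dimension` (default 3 bins),
`--max-zeros` (default 0.5), `--cutoff` (anchor-distance filter, bp),
`--exclude-chroms`, `--no-balance`, `--crop` (default 0.25). Every output
embeds the full run configuration; identical configurations reproduce
outputs bit for bit.

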